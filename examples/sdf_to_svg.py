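"""The SDF round trip: write a conformer as a V2000 molblock, parse it
back, and render it with hydrogens excluded.

This mirrors the command-line usage
    vecmol -i input.sdf -o output.svg --style ball-and-stick --exclude H
from Python. The printed numbers show how excluding hydrogens shrinks both
the model (atoms and bonds drop) and the output file.
"""

from pathlib import Path

from vecmol import DepictionStyle, DrawRequest, Look, draw_molecule, parse_sdf
from vecmol.fixtures import make_linear_alkane, write_sdf

sdf_text = write_sdf(make_linear_alkane(12, with_hydrogens=True))
(mol,) = parse_sdf(sdf_text)
print(f"parsed {mol.name}: {len(mol.atoms)} atoms, {len(mol.bonds)} bonds")

for exclude in ([], ["H"]):
    svg = draw_molecule(
        DrawRequest(atoms=mol.atoms, bonds=mol.bonds,
                    style=DepictionStyle.BALL_AND_STICK, look=Look.CARTOON,
                    resolution=50, exclude_atoms=exclude)
    )
    tag = "heavy-only" if exclude else "with-H"
    out = Path(__file__).parent / f"alkane_{tag}.svg"
    out.write_text(svg)
    print(f"  {tag:10s} -> {out.name}: {len(svg.encode())} bytes")
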