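"""Render one synthetic conformer in every depiction style and look.

Builds a 20-heavy-atom random packing (a drug-like stand-in), renders it at
resolution 50 with each of the four depiction types and both looks, writes
the SVGs next to this script, and prints their sizes. The printed byte
counts show the expected ordering: wireframe files are tiny (bare line
segments), ball-and-stick files are the largest (about twice the polygon
count of space-filling), and glossy files exceed their cartoon twins by the
cost of the gradient definitions.
"""

from pathlib import Path

from vecmol import DepictionStyle, DrawRequest, Look, draw_molecule
from vecmol.fixtures import make_random_packing

mol = make_random_packing(20, seed=11)
out_dir = Path(__file__).parent

print(f"molecule: {len(mol.atoms)} heavy atoms, {len(mol.bonds)} bonds")
for style in DepictionStyle:
    for look in Look:
        svg = draw_molecule(
            DrawRequest(atoms=mol.atoms, bonds=mol.bonds, style=style,
                        look=look, resolution=50)
        )
        name = f"styles_{style.value}_{look.value}.svg"
        (out_dir / name).write_text(svg)
        print(f"  {style.value:15s} {look.value:8s} {len(svg.encode()):7d} bytes")
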