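# vecmol

**vecmol** renders 3D small-molecule models directly to compact, editable
SVG from pure Python, with no third-party dependencies, no triangulation
and no ray tracing. It exists for the common cheminformatics situation
where a 3D conformer — a docking pose, a generated conformation, a ligand
in context — needs to end up in a figure that will be polished in Inkscape
or Illustrator: raster screenshots from OpenGL viewers don't edit, and
triangulated SVG exports balloon into megabytes of tiny facets.

## The algorithm

Instead of meshing surfaces, vecmol approximates each primitive's visible
silhouette as a single convex polygon:

1. **Sample** points on every primitive's surface. A sphere gets an
   inclusive angular grid of (resolution + 1) azimuthal × (resolution + 1)
   polar angles; a cylinder gets (resolution + 1) circle centers along its
   axis with `resolution` points per circumference, optionally round-capped
   with hemisphere grids.
2. **Sort** primitives far-to-near by centroid *z* (the camera looks down
   the positive *z*-axis toward the origin).
3. **Filter**: for each primitive, discard sampled points lying strictly
   inside any *earlier* (farther) primitive — those patches sit behind a
   surface whose polygon is painted underneath anyway. A cheap vicinity
   pre-check (sum of radii vs. center/axis distance) skips provably
   disjoint pairs; it can be disabled for exact-per-pair filtering.
4. **Project** survivors to 2D — orthographic by default, or perspective
   `(x·f/(f−z), y·f/(f−z))` when a focal length *f* is set — and drop *z*.
5. **Hull** each projected cloud with quickhull into its smallest convex
   polygon.
6. **Paint** polygons back-to-front (painter's algorithm) with either a
   solid *cartoon* fill or a *glossy* gradient (radial for spheres, linear
   for cylinders).

The output is one `<path>` per primitive with inline styling — small files
whose every shape remains individually selectable in a vector editor.

Four depiction styles (space-filling, ball-and-stick, tube, wireframe) and
two looks (cartoon, glossy) are built in; atom colors follow the CPK
convention and sphere radii the PubChem van der Waals values, both shipped
as auditable data tables. Per-atom/per-bond overrides and raw `Scene`
access allow full customization.

## Worked example

```python
from vecmol import DepictionStyle, DrawRequest, Look, draw_molecule
from vecmol.fixtures import make_random_packing

mol = make_random_packing(20, seed=11)          # synthetic drug-like conformer
for style in DepictionStyle:
    svg = draw_molecule(DrawRequest(atoms=mol.atoms, bonds=mol.bonds,
                                    style=style, look=Look.CARTOON,
                                    resolution=50))
    print(style.value, len(svg.encode()), "bytes")
```

prints

```
space-filling 13845 bytes
ball-and-stick 68434 bytes
tube 47931 bytes
wireframe 5669 bytes
```

Wireframes are tiny because bare line segments need no sampled polygons;
ball-and-stick is the largest because every bond contributes two half-bond
cylinders on top of the atom spheres. All four files are in the
tens-of-kilobytes range — the point of the direct-to-SVG approach.

The `examples/` directory has short narrative scripts for the style matrix
(`depiction_styles.py`), raw `Scene` usage with per-primitive styles and
the intersection pre-check switch (`custom_scene.py`), and the SDF round
trip (`sdf_to_svg.py`).

A thin CLI wraps the same API:

```bash
vecmol -i conformer.sdf -o model.svg --style ball-and-stick --look glossy \
       --resolution 50 --exclude H
```

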