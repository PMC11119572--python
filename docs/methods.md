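# Methods

## Model

vecmol draws a 3D scene of spheres, cylinders and wires as a stack of 2D
convex polygons. The governing approximation is that, seen from a fixed
viewpoint, the visible part of a convex primitive projects to (nearly) a
convex region, and that hidden-surface removal between primitives can be
replaced by two cheaper mechanisms acting together:

* **painter's order** — primitives are drawn far-to-near by the *z* of
  their centroid, so a nearer polygon covers whatever part of a farther
  one it overlaps;
* **point-level occlusion filtering** — before hulling, a primitive's
  sampled surface points that lie strictly inside any *earlier* (farther)
  primitive's volume are discarded, so the hull shrinks to roughly the
  visible silhouette instead of the full outline.

Only earlier primitives filter later ones. A far primitive needs no
filtering against a near one because the near polygon is painted on top of
it; a near primitive's points inside a far volume are behind the far
surface facing the camera, which is exactly what the far polygon shows.
This asymmetry is what makes a single far-to-near pass sufficient.

The camera convention is: viewer on the positive *z* side, looking toward
the origin; larger *z* is nearer. "Far-to-near" therefore means ascending
centroid *z*, applied identically in sorting, occlusion and perspective.

The approximation is deliberate: intersection curves between primitives
are not computed, polygons are never split, and concave visible regions
(possible when a small sphere bites into a large one) are replaced by
their convex hull. Resolution controls how closely the polygon tracks the
true silhouette.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `resolution` | 50 | angular sampling density; a sphere gets (res+1)² points, a cylinder body (res+1)·res. 50–100 suffices visually; cost grows quadratically |
| `scale` | 1.0 | uniform multiplier on coordinates *and* radii (so proportions survive); scene units are Å × scale |
| `focal_length` | none | none = orthographic; a value f gives perspective x·f/(f−z), smaller f = stronger depth exaggeration. Requires all points at z < f |
| `rotation_over_{x,y,z}_axis` | 0 | radians, composed in fixed order X→Y→Z about the origin |
| `filter_intersecting` | on | vicinity pre-check before per-point occlusion tests; off = test every earlier pair exactly |
| `exclude_atoms` | [] | element symbols removed with their incident bonds before scene building |
| coordinate precision | 3 decimals | SVG path rounding; the main file-size lever |
| view-box padding | 2.0 scene units | margin added around the tight bounding box |

Depiction proportions (ball-and-stick sphere shrink 0.33, stick radius
0.1 Å, tube radius 0.3 Å, gradient stops at 0/0.5/1 with ±35% lightness)
are package constants chosen to match conventional molecular graphics;
nothing in the algorithm depends on them.

## Style-dependent occlusion policy

Per-point tests are the dominant cost, so each depiction style declares
which primitive pairs are worth testing: ball-and-stick skips
cylinder/cylinder pairs (stick ends are hidden inside atom spheres whose
radii are several times the stick radius); tube tests all pairs (bond
cylinders there are thick and visibly interpenetrate); space-filling tests
its spheres; wireframe tests nothing — wires have no volume and are only
depth-sorted. Raw `Scene` users can substitute any pair policy.

## Numerical choices

* **Containment is strict** (`< r`, open segment for cylinders): points on
  a tangent surface are *not* considered inside, so touching primitives
  never erase each other's silhouette points.
* **Sphere sampling** uses the inclusive grid over azimuth [0, 2π] and
  polar [0, π]; seam and pole duplicates are kept — they are harmless to a
  convex hull and keep the advertised point counts exact. Round cylinder
  caps reuse the parent resolution and keep the outward-facing half of a
  sphere grid.
* **Quickhull** drops collinear points on hull edges (fewer vertices =
  smaller files), breaks farthest-point ties lexicographically, and
  returns counter-clockwise vertices starting from the lexicographically
  smallest — rendering is therefore fully deterministic, and identical
  scenes serialize to identical bytes. Clouds that collapse to ≤2 distinct
  or all-collinear points are flagged degenerate; the renderer skips them.
* **Rotation matrices snap** sines/cosines within 1e-12 of −1/0/1 to the
  exact value, so quarter- and full-turn rotations are exact and a 2π
  rotation reproduces the input byte-for-byte.
* Primitives left with <3 visible points after filtering are dropped with
  a debug log line: a fully occluded primitive is legitimately invisible.
* The SVG y-axis points down while scene y points up; the output is a
  mirror image in y. This affects apparent chirality only and can be
  undone with a negative y scale in any editor; no flip is applied so
  projected coordinates stay exactly the scene coordinates.
* The vicinity pre-check compares center/axis distance against the sum of
  radii with no extra margin: exact for sphere/sphere and sphere/cylinder,
  conservative (no false negatives) for cylinder/cylinder.

## Synthetic conformers

The `fixtures` module generates all test inputs programmatically:

* `make_linear_alkane(n, with_hydrogens)` — zig-zag carbon chain, C–C
  1.54 Å, tetrahedral angles, idealized C–H at 1.09 Å; used for scaling
  series.
* `make_ring(n)` — planar regular carbon ring with 1.54 Å sides.
* `make_random_packing(n, seed)` — a connected cluster grown one atom at a
  time at 1.4–1.7 Å from a random anchor, rejecting placements closer than
  1.3 Å to any atom; elements drawn C-heavy from {C, N, O, S}; anchor
  bonds give a spanning tree, then near pairs (<1.7 Å) are bonded nearest
  first up to 50 bonds. This emulates the size band of drug-like ligands
  (10–45 heavy atoms, 10–50 bonds) used for benchmarking. All generators
  are pure functions of their arguments.

These fixtures reproduce the *geometry* of small organic molecules —
distances, packing density, connectivity — but not chemistry: valences,
bond orders and element placement are not chemically valid. Passing tests
therefore demonstrate geometric and rendering correctness on realistic
point configurations, not correct handling of any specific compound class.
Real SDF conformers exercise exactly the same code path via `parse_sdf`.

The benchmark measurement (`scripts/acceptance.py`) uses the 45-heavy-atom
packing at seed 2024, resolution 50, hydrogens excluded — 45 atoms and 50
bonds rendered as 45 spheres + 100 half-bond cylinders, the top of the
intended molecule-size band. It completes in about a second on one CPU.

## Known limitations

* No exact visible-surface computation: intersection lines between
  primitives are approximate, and very large resolution does not converge
  to an exact rendering of interpenetration curves.
* Convex-hull outlines cannot represent concave visible regions or holes.
* Transparency is per-polygon SVG opacity, not physically layered.
* One cylinder (split at the midpoint for two-color bonds) per bond
  regardless of bond order; no multi-line double bonds.
* V2000 SDF only; no SMILES, PDB or conformer generation — upstream
  toolkits handle those.
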