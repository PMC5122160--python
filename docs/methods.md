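# Methods

## Model and procedure

`cif2print` automates the manual workflow of preparing a crystal structure
for 3D printing. The structural model is standard crystallography: a unit
cell (a, b, c, α, β, γ), a set of affine symmetry operators written in xyz
form, and an asymmetric unit of atom sites in fractional coordinates. The
full contents are generated by applying every operator **x′** = R**x** + **t**
to every site. Operators are parsed with exact arithmetic — R has integer
entries in {−1, 0, 1} with det R = ±1, and **t** is kept as rationals
reduced mod 1, with decimal translations (0.3333) snapped to the nearest
fraction with denominator ≤ 12 — so that parsing and formatting round-trip
and no floating-point drift enters the group action.

Fractional coordinates map to Cartesian Å through the orthogonalization
matrix with **a** along x and **b** in the xy plane. The metric tensor
G_ij = **v**_i·**v**_j provides an independent route to interatomic
distances (√(Δxᵀ G Δx)) and is used only as a cross-check, never in the
pipeline itself.

Packing ("show everything inside one unit cell, with atoms on boundaries
repeated on every incident face") is implemented by enumerating integer
lattice translations in {−1, 0, …, range} per axis and keeping a copy iff
every fractional coordinate lies in [−ε, range+ε]. A corner atom of a
single cell therefore appears 8 times; an interior atom once.

Chemistry enters only through bond perception: atoms i, j are bonded iff
0.4 Å < d(i,j) ≤ r_cov(i) + r_cov(j) + bond_tol, with Cordero-style
single-bond covalent radii taken from gemmi's element table. Connected
components of the bond graph are the molecules (or the one network of an
extended solid). The component with the most atoms is kept; all others —
symmetry duplicates, solvents, counterions — are deleted. This selection
rule is deliberately chemistry-blind and inherits a known failure mode: a
counterion with more atoms than the molecule of interest wins, and in a
racemate either enantiomer could be meant. We keep the rule (it is the
method), make the racemate tie deterministic (lowest contained atom index,
so batch runs are byte-reproducible), and provide per-molecule export as
the mitigation: one model per fragment, the user chooses.

## Mesh generation and the printability contract

The exported geometry is ball-and-stick: per atom a geodesic sphere
(icosahedron subdivided `sphere_level` times, vertices projected to the
sphere: 10·4^L + 2 vertices, 20·4^L triangles), per bond two capped
cylinders from each atom center to the bond midpoint, each colored by its
atom's element (CPK palette). Every shell satisfies, by construction and
verified by `validate_shell`:

- zero boundary edges and zero non-manifold edges (every undirected edge
  borders exactly two triangles);
- consistent counter-clockwise winding (the two triangles traverse their
  shared edge in opposite directions) with positive signed volume, i.e.
  outward normals (signed volume via the divergence theorem,
  Σ v₀·(v₁×v₂)/6);
- no degenerate triangles (area ≤ 1e−12 model units²);
- a feature-thickness proxy: the shell's smallest bounding-box extent must
  exceed twice a minimum printable radius (default 0.3 model units), since
  infinitely thin geometry renders fine on screen but cannot print.

Design choices worth recording:

- **No boolean union.** Overlapping closed shells are emitted as-is;
  slicers union them robustly, whereas CSG on near-tangent spheres and
  cylinders is numerically fragile. Each shell is independently watertight,
  which is the contract printers actually need.
- **Flat, buried caps instead of rounded endcaps.** Half-bond cylinders end
  flush at atom centers, and a style invariant guarantees every bonded
  element's sphere radius exceeds the bond radius, so the flat caps can
  never surface. Rounded endcaps shared between abutting cylinders are
  thereby unnecessary.
- **Half-phase ring offset.** The two halves of a bond meet at the midpoint
  with their vertex rings rotated by half a segment, so tools that weld on
  exact coordinates (including our own STL validator) keep the shells
  distinct instead of fusing them into a non-manifold edge loop.
- **Scaling.** Coordinates are centered on the fragment's bounding box and
  multiplied by `scale` (default 10). Reading model units as millimetres,
  1 Å → 10 mm, which puts typical molecules at the 1–10 cm scale most
  printers handle.

## Serialization

VRML 2.0 output contains only IndexedFaceSet nodes (coordinates, −1
terminated index runs, per-vertex color, 6 significant digits); the
high-level Sphere/Cylinder/Cone primitives never appear, so no
post-processing is needed before printing. Binary STL is written exactly as
80-byte header + uint32 count + 50 bytes per triangle with normals
recomputed from winding; ASCII STL uses the standard solid/facet dialect.
STL collapses all shells into one solid since the format carries no color.
The reader auto-detects dialect (ASCII iff the file starts with `solid`
*and* parses fully as ASCII) and rejects binary bodies whose length
disagrees with the declared count.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `scale` | 10 | coordinate multiplier; 1 Å → 10 mm |
| `sphere_fraction` | 0.23 | atom radius as fraction of the vdW radius |
| `bond_radius` | 0.15 Å | bond cylinder radius (before scaling) |
| `sphere_level` | 2 | geodesic subdivision (320 triangles/atom) |
| `cyl_segments` | 16 | cylinder facets (64 triangles/half-bond) |
| `bond_tol` | 0.45 Å | slack added to the covalent-radius sum |
| `dedup_tol` | 0.01 Å | merge distance for coincident symmetry images |
| `boundary_eps` | 1e−4 | fractional tolerance for packing membership |

`dedup_tol` is chosen so coordinates printed to 4 decimal places merge
reliably; `boundary_eps` is a repo choice (viewers do not document theirs),
so packed atom counts can differ from other software for atoms sitting
exactly on a boundary. Sites with occupancy < 0.5 are dropped and the rest
treated as fully occupied — disorder handling has no canonical answer, and
this yields one self-consistent model per file. Deduplication merges only
same-element images; a close hetero-element contact is kept and logged as a
likely disorder artifact. H–H bonds are never formed.

## Synthetic fixtures: what they cover and what they do not

`cif2print.fixtures` generates four archetypes with ground truth known by
construction and re-verified in tests by brute-force oracles (full image
enumeration with pairwise-distance dedup; transitive-closure components):
an isolated molecule in P1 (water), a P-1 co-crystal
(molecule + solvents + counterion, with a `large_counterion` switch that
reproduces the documented mis-selection), a rock-salt solid with an
explicit face-centering operator list, and a racemate (a chiral fragment
plus its inversion image). The seed jitters coordinates by ≤ 0.001
fractional — enough to exercise tolerance code, never enough to change any
count.

These fixtures use explicit operator lists, full occupancies, and cleanly
separated fragments. Real database CIFs additionally contain disorder,
polymeric structures that cross cell boundaries (which expansion wraps and
may split), unusual elements, and formatting quirks; passing the fixture
suite demonstrates the pipeline's contracts (symmetry, selection,
watertightness, format exactness, batch isolation), not robustness to every
production CIF. Molecules straddling the cell boundary are the main known
gap: images are wrapped atom-by-atom, so such a molecule fragments rather
than being completed across the boundary.

## Problem sizes

The test suite and the acceptance script run the four fixtures across 10
and 3 seeds respectively, a 100-file batch, and 1000 random triclinic
cells for the metric-tensor cross-check; the full suite completes in well
under a minute on one CPU. Larger collections scale linearly in files and
near-linearly in atoms (spatial indexing in bond perception).

## Limitations

- No space-group lookup by Hermann–Mauguin symbol: operators must be listed
  in the CIF (identity is assumed when absent).
- No bond orders, aromaticity or coordination chemistry; selection is by
  atom count only.
- Biomolecules would need strut supports between chains; not generated.
- X3D/OBJ/PLY/3MF export and repair of externally produced meshes are out
  of scope.
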