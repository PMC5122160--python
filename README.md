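# cif2print

Batch conversion of crystal structures — CIF files, the standard exchange
format of crystallography — into 3D-printable STL and VRML 2.0 models.

3D-printed crystal structures are widely used in chemistry teaching and
research, but turning a CIF into a file a printer will accept is tedious by
hand: the asymmetric unit must be expanded by the space-group symmetry,
solvent molecules and counterions removed, the model scaled to a printable
size, and the exported mesh must be *watertight* — every surface closed,
every triangle wound consistently so its normal points outward. `cif2print`
automates the whole chain for any number of files:

1. **Parse** the CIF: cell parameters (a, b, c, α, β, γ), symmetry
   operators in xyz form, and the asymmetric-unit atom sites in fractional
   coordinates.
2. **Expand** the space-group symmetry: every operator **x′** = R**x** + **t**
   is applied to every site, images are wrapped into the unit cell and
   deduplicated (atoms on special positions collapse to one copy). For
   extended solids the cell can be **packed**: all lattice translations are
   enumerated and every copy whose fractional coordinates fall inside one
   cell (with a boundary tolerance) is kept, so face, edge and corner atoms
   appear on every incident boundary.
3. **Perceive bonds** by the covalent-radius criterion
   0.4 Å < d(i,j) ≤ r_cov(i) + r_cov(j) + 0.45 Å and partition the atoms
   into connected fragments (molecules, or one extended-solid network).
4. **Select** the fragment with the greatest number of atoms and delete the
   rest (duplicate symmetry copies, solvents, smaller counterions); ties —
   e.g. the two enantiomers of a racemate — break deterministically by
   lowest atom index. `--per-molecule` instead exports every fragment as
   its own model, so nothing is lost.
5. **Mesh** the selection as ball-and-stick, scaled ×10 (1 Å → 10 mm):
   a geodesic sphere per atom, two half-cylinders per bond colored by their
   adjacent atoms' elements. Every shell is independently closed and
   outward-wound; overlapping shells are unioned by the printer's slicer.
6. **Write** VRML 2.0 (IndexedFaceSet nodes only, per-vertex color, for
   multi-color printing) and/or STL (binary or ASCII, geometry only) —
   files that go straight to a print service with no repair step.

## Worked example

The package ships a generator for synthetic CIFs with known ground truth
(`cif2print make-fixture`). The `cocrystal` fixture is a centrosymmetric
(P-1) co-crystal whose asymmetric unit holds a 10-atom molecule, two 3-atom
solvents and a chloride counterion — 17 sites that expand to 34 atoms in
8 fragments:

```
$ cif2print make-fixture cocrystal --seed 0 --out cocrystal.cif
wrote cocrystal.cif: P-1 co-crystal: molecule + 2 solvents + counterion

$ cif2print convert cocrystal.cif --out models
INFO selected 10-atom fragment; deleting 7 other fragment(s) (24 atoms)
INFO cocrystal.cif: deleted 7 smaller/duplicate fragment(s)
cocrystal.cif: ok (1/8 fragments, 10 atoms -> 2 file(s))
```

Only one copy of the 10-atom molecule survives — its symmetry duplicate,
both solvent pairs and the counterions are deleted — and it is exported as
`models/cocrystal.wrl` and `models/cocrystal.stl` at ×10 scale. The
printability check welds the STL back together and verifies every shell:

```
$ cif2print validate models/cocrystal.stl
...
shell 10: ok (tris=1152 boundary=0 nonmanifold=0 oriented=True volume=900.2)
models/cocrystal.stl: 11 shell(s), 0 defective
```

(zero boundary edges, zero non-manifold edges, consistent winding, positive
volume — for every shell). For an extended solid, run with `--packed`:
the `rocksalt` fixture packs to 27 atoms forming a single network, which is
exported whole. Batch mode processes a text list of CIF paths with per-file
isolation — one malformed file is logged and skipped, never aborting the
run:

```
$ cif2print batch list.txt --out models
3 file(s): 2 ok, 1 failed
```

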