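import math

import numpy as np
import pytest
import trimesh

import cif2print as cp
from cif2print.errors import DegenerateBondError


def _as_trimesh(mesh: cp.TriangleMesh) -> trimesh.Trimesh:
    return trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)


class TestIcosphere:
    @pytest.mark.parametrize("level", [0, 1, 2, 3])
    def test_counts_and_euler_characteristic(self, level):
        m = cp.icosphere((0, 0, 0), 1.0, level)
        assert m.n_vertices == 10 * 4**level + 2
        assert m.n_triangles == 20 * 4**level
        edges = {tuple(sorted(e)) for t in m.triangles for e in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0]))}
        assert m.n_vertices - len(edges) + m.n_triangles == 2

    def test_level3_volume_within_2pct_of_sphere(self):
        m = cp.icosphere((0, 0, 0), 1.0, 3)
        assert m.signed_volume() == pytest.approx(4 * math.pi / 3, rel=0.02)

    def test_vertices_on_sphere_of_given_radius(self):
        m = cp.icosphere((1.0, -2.0, 3.0), 2.5, 2)
        r = np.linalg.norm(m.vertices - (1.0, -2.0, 3.0), axis=1)
        assert np.allclose(r, 2.5, atol=1e-12)

    def test_watertight_per_trimesh_oracle(self):
        tm = _as_trimesh(cp.icosphere((0, 0, 0), 1.0, 2))
        assert tm.is_watertight and tm.is_winding_consistent
        assert tm.volume > 0


class TestCappedCylinder:
    def test_counts(self):
        m = cp.capped_cylinder((0, 0, 0), (0, 0, 2), 1.0, segments=16)
        assert m.n_triangles == 64
        assert m.n_vertices == 34

    def test_volume_within_1pct(self):
        m = cp.capped_cylinder((0, 0, 0), (0, 0, 2), 1.0, segments=64)
        assert m.signed_volume() == pytest.approx(2 * math.pi, rel=0.01)
        assert m.signed_volume() < 2 * math.pi  # inscribed tessellation deficit

    @pytest.mark.parametrize("axis", [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1), (-0.3, 2.0, 0.4)])
    def test_closed_for_arbitrary_axes(self, axis):
        m = cp.capped_cylinder((0.5, -1, 2), np.add((0.5, -1, 2), axis), 0.4, segments=9)
        rep = cp.validate_shell(m)
        assert rep.boundary_edges == 0 and rep.nonmanifold_edges == 0
        assert rep.oriented and rep.signed_volume > 0
        tm = _as_trimesh(m)
        assert tm.is_watertight and tm.is_winding_consistent

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(DegenerateBondError):
            cp.capped_cylinder((1, 1, 1), (1, 1, 1), 0.5)


class TestStyleConfig:
    @pytest.mark.parametrize(
        "kw", [dict(scale=0), dict(sphere_fraction=0), dict(sphere_fraction=1.5),
               dict(bond_radius=-1), dict(sphere_level=-1), dict(cyl_segments=2)],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            cp.StyleConfig(**kw)

    def test_bond_radius_exceeding_sphere_radius_rejected_at_build(self, water):
        rec, _ = water
        atoms = cp.expand(rec)
        frags = cp.find_fragments(atoms, cp.perceive_bonds(atoms))
        style = cp.StyleConfig(bond_radius=0.30)  # H sphere = 0.23*1.2 = 0.276 Å
        with pytest.raises(ValueError, match="bond_radius"):
            cp.build_ballstick(frags[0], atoms, style)


def _primary_shells(rec, spec, style=None):
    atoms = cp.pack_cell(rec) if spec.packed else cp.expand(rec)
    frags = cp.find_fragments(atoms, cp.perceive_bonds(atoms))
    return atoms, cp.select_primary(frags), cp.build_ballstick(cp.select_primary(frags), atoms, style)


class TestBuildBallstick:
    def test_diatomic_scaled_ten_times(self):
        atoms = [
            cp.ExpandedAtom("C", (0, 0, 0), (0.0, 0.0, 0.0), 0, 0),
            cp.ExpandedAtom("O", (0, 0, 0), (1.13, 0.0, 0.0), 1, 0),
        ]
        frag = cp.Fragment(atom_indices=(0, 1), bonds=(cp.Bond(0, 1, 1.13),))
        shells = cp.build_ballstick(frag, atoms, cp.StyleConfig(scale=10))
        assert len(shells) == 4  # 2 spheres + 2 half-bonds
        c0 = shells[0].vertices.mean(axis=0)
        c1 = shells[1].vertices.mean(axis=0)
        assert np.linalg.norm(c1 - c0) == pytest.approx(11.3, rel=1e-6)

    def test_single_atom_one_shell(self):
        atoms = [cp.ExpandedAtom("Ne", (0, 0, 0), (0.0, 0.0, 0.0), 0, 0)]
        frag = cp.Fragment(atom_indices=(0,), bonds=())
        assert len(cp.build_ballstick(frag, atoms)) == 1

    def test_water_shell_count_and_half_bond_midpoints(self, water):
        rec, _ = water
        atoms, frag, shells = _primary_shells(rec, cp.FixtureSpec("p1_molecule", rec.cell, False))
        assert len(shells) == 3 + 4  # 3 spheres, 2 bonds × 2 halves
        style = cp.StyleConfig()
        carts = np.array([atoms[i].cart for i in frag.atom_indices])
        center = (carts.min(axis=0) + carts.max(axis=0)) / 2
        for k, bond in enumerate(frag.bonds):
            pi = (np.asarray(atoms[bond.i].cart) - center) * style.scale
            pj = (np.asarray(atoms[bond.j].cart) - center) * style.scale
            mid = (pi + pj) / 2  # recomputed independently from input geometry
            half_i = shells[3 + 2 * k]
            half_j = shells[3 + 2 * k + 1]
            ring_end_i = half_i.vertices[len(half_i.vertices) - 1]  # top-center vertex
            assert np.allclose(ring_end_i, mid, atol=1e-9)
            assert np.allclose(half_j.vertices[len(half_j.vertices) - 2], mid, atol=1e-9)
            # two-tone coloring: each half carries its atom's element color
            assert tuple(half_i.vertex_colors[0]) == cp.StyleConfig().color(atoms[bond.i].element)
            assert tuple(half_j.vertex_colors[0]) == cp.StyleConfig().color(atoms[bond.j].element)

    @pytest.mark.parametrize("kind", cp.FIXTURE_KINDS)
    def test_pairwise_distances_scale_exactly(self, fixture_records, kind):
        rec, spec = fixture_records[kind]
        atoms, frag, shells = _primary_shells(rec, spec)
        carts = np.array([atoms[i].cart for i in frag.atom_indices])
        centers = np.array([shells[k].vertices.mean(axis=0) for k in range(frag.natoms)])
        din = np.linalg.norm(carts[:, None] - carts[None, :], axis=-1)
        dout = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        assert np.allclose(dout, 10.0 * din, rtol=1e-6, atol=1e-9)

    @pytest.mark.parametrize("kind", cp.FIXTURE_KINDS)
    def test_bounding_box_in_printable_range(self, fixture_records, kind):
        _, _, shells = _primary_shells(*fixture_records[kind])
        allv = np.vstack([s.vertices for s in shells])
        extent = allv.max(axis=0) - allv.min(axis=0)
        assert np.all(extent > 1.0) and np.all(extent < 100.0)  # 1-10 cm in mm


class TestValidateShell:
    def test_icosphere_passes(self):
        rep = cp.validate_shell(cp.icosphere((0, 0, 0), 1.0, 2))
        assert rep.watertight
        assert rep.degenerate_triangles == 0

    def test_deleted_triangle_reports_three_boundary_edges(self):
        m = cp.icosphere((0, 0, 0), 1.0, 1)
        m.triangles = m.triangles[:-1]
        rep = cp.validate_shell(m)
        assert rep.boundary_edges == 3
        assert not rep.watertight

    def test_flipped_triangle_breaks_orientation(self):
        m = cp.icosphere((0, 0, 0), 1.0, 1)
        m.triangles[0] = m.triangles[0, ::-1]
        rep = cp.validate_shell(m)
        assert not rep.oriented and not rep.watertight

    def test_inverted_shell_has_negative_volume(self):
        m = cp.icosphere((0, 0, 0), 1.0, 1)
        m.triangles = m.triangles[:, ::-1]
        rep = cp.validate_shell(m)
        assert rep.signed_volume < 0 and not rep.watertight

    def test_thin_feature_flagged(self):
        m = cp.capped_cylinder((0, 0, 0), (5, 0, 0), 0.1, segments=8)
        rep = cp.validate_shell(m, min_radius=0.3)
        assert rep.thin_feature and rep.watertight  # thin but still closed

    @pytest.mark.parametrize("kind", cp.FIXTURE_KINDS)
    def test_agreement_with_trimesh_on_fixture_shells(self, fixture_records, kind):
        _, _, shells = _primary_shells(*fixture_records[kind])
        for shell in shells[:: max(1, len(shells) // 8)]:
            rep = cp.validate_shell(shell)
            tm = _as_trimesh(shell)
            assert rep.watertight == (tm.is_watertight and tm.is_winding_consistent and tm.volume > 0)
            assert rep.signed_volume == pytest.approx(tm.volume, rel=1e-9)
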