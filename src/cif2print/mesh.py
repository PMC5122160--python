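"""Watertight ball-and-stick triangle meshes for a selected fragment.

Every emitted part is an independently closed, outward-wound shell: a
geodesic sphere per atom and two half-bond cylinders per bond (split at the
bond midpoint so each half carries its atom's element color). Printability
for STL/VRML demands exactly this — no open cylinder ends, no missing
triangles in the atom geodesics, counter-clockwise winding so every normal
points outward, and no infinitely thin surfaces. Overlapping shells are not
boolean-unioned: printer slicers union them, and independent closure is far
more robust than CSG.

Coordinates are centered on the fragment's bounding box and multiplied by
``StyleConfig.scale`` (default 10). Model units are read as millimetres by
print services, so a 1 Å bond becomes 10 mm — molecular models come out at
the centimetre scale most printers want.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import cpk_color, vdw_radius
from .errors import DegenerateBondError
from .fragments import Fragment
from .symmetry import ExpandedAtom

DEGENERATE_AREA = 1e-12  # model-units²; triangles at or below count as degenerate
MIN_PRINT_RADIUS = 0.3  # model units (mm); features thinner than 2× are flagged


@dataclass
class StyleConfig:
    """Ball-and-stick appearance and scaling.

    scale           unitless enlargement applied to all coordinates (10 ->
                    1 Å prints as 10 model units / mm)
    sphere_fraction fraction of the element's van-der-Waals radius used for
                    atom spheres (0.23 approximates the classic look)
    bond_radius     bond cylinder radius in Å, before scaling
    sphere_level    geodesic subdivision level (level L -> 20·4^L triangles)
    cyl_segments    cylinder facet count around the bond axis
    color_table     optional element -> (r, g, b) override, 0-255
    """

    scale: float = 10.0
    sphere_fraction: float = 0.23
    bond_radius: float = 0.15
    sphere_level: int = 2
    cyl_segments: int = 16
    color_table: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not 0 < self.sphere_fraction <= 1:
            raise ValueError("sphere_fraction must be in (0, 1]")
        if self.bond_radius <= 0:
            raise ValueError("bond_radius must be positive")
        if self.sphere_level < 0:
            raise ValueError("sphere_level must be >= 0")
        if self.cyl_segments < 3:
            raise ValueError("cyl_segments must be >= 3")

    def color(self, element: str) -> tuple[int, int, int]:
        return self.color_table.get(element, cpk_color(element))

    def sphere_radius(self, element: str) -> float:
        return self.sphere_fraction * vdw_radius(element)


@dataclass
class TriangleMesh:
    """Indexed triangle shell with per-vertex RGB color, in model units."""

    vertices: np.ndarray  # (n, 3) float64
    triangles: np.ndarray  # (m, 3) int64
    vertex_colors: np.ndarray  # (n, 3) uint8

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.vertex_colors = np.asarray(self.vertex_colors, dtype=np.uint8)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def signed_volume(self) -> float:
        """Divergence-theorem volume; positive iff winding is outward."""
        v = self.vertices
        t = self.triangles
        a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def transformed(self, offset, scale: float) -> "TriangleMesh":
        return TriangleMesh(
            vertices=(self.vertices + np.asarray(offset, dtype=float)) * scale,
            triangles=self.triangles.copy(),
            vertex_colors=self.vertex_colors.copy(),
        )


@dataclass(frozen=True)
class ShellReport:
    """Printability report for one shell (validation never mutates)."""

    boundary_edges: int
    nonmanifold_edges: int
    oriented: bool
    signed_volume: float
    degenerate_triangles: int
    feature_thickness: float
    thin_feature: bool

    @property
    def watertight(self) -> bool:
        return (
            self.boundary_edges == 0
            and self.nonmanifold_edges == 0
            and self.oriented
            and self.signed_volume > 0
            and self.degenerate_triangles == 0
        )


# classic icosahedron with outward-wound faces
_PHI = (1.0 + 5.0**0.5) / 2.0
_ICO_VERTS = np.array(
    [
        (-1, _PHI, 0), (1, _PHI, 0), (-1, -_PHI, 0), (1, -_PHI, 0),
        (0, -1, _PHI), (0, 1, _PHI), (0, -1, -_PHI), (0, 1, -_PHI),
        (_PHI, 0, -1), (_PHI, 0, 1), (-_PHI, 0, -1), (-_PHI, 0, 1),
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=np.int64,
)


def icosphere(center, radius: float, level: int = 2,
              color: tuple[int, int, int] = (200, 200, 200)) -> TriangleMesh:
    """Geodesic sphere: 4-way icosahedron subdivision, vertices projected out.

    Exactly 20·4^level triangles and 10·4^level + 2 vertices; closed and
    outward-wound by construction.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if level < 0:
        raise ValueError("level must be >= 0")
    verts = [v / np.linalg.norm(v) for v in _ICO_VERTS]
    faces = [tuple(f) for f in _ICO_FACES]
    for _ in range(level):
        midpoint: dict[tuple[int, int], int] = {}

        def mid(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            if key not in midpoint:
                m = verts[i] + verts[j]
                verts.append(m / np.linalg.norm(m))
                midpoint[key] = len(verts) - 1
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    vertices = np.asarray(verts) * radius + np.asarray(center, dtype=float)
    colors = np.tile(np.asarray(color, dtype=np.uint8), (len(vertices), 1))
    return TriangleMesh(vertices=vertices, triangles=np.asarray(faces), vertex_colors=colors)


def capped_cylinder(p_start, p_end, radius: float, segments: int = 16,
                    color: tuple[int, int, int] = (200, 200, 200),
                    phase: float = 0.0) -> TriangleMesh:
    """Closed cylinder: tube facets plus two fan-triangulated end disks.

    2·segments + 2 vertices, 4·segments triangles, outward-wound. ``phase``
    rotates the ring vertices by that fraction of one segment, so two
    cylinders meeting on the same axis need not share ring vertices.
    """
    p0 = np.asarray(p_start, dtype=float)
    p1 = np.asarray(p_end, dtype=float)
    axis = p1 - p0
    height = np.linalg.norm(axis)
    if height == 0:
        raise DegenerateBondError("cylinder endpoints coincide")
    if radius <= 0:
        raise ValueError("radius must be positive")
    d = axis / height
    # deterministic orthonormal frame: reference axis least aligned with d
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(d)))] = 1.0
    u = np.cross(ref, d)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)  # u × v = d

    theta = 2.0 * np.pi * (np.arange(segments) + phase) / segments
    ring = radius * (np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v))
    bottom = p0 + ring
    top = p1 + ring
    verts = np.vstack([bottom, top, p0[None, :], p1[None, :]])
    cb, ct = 2 * segments, 2 * segments + 1

    faces = []
    for k in range(segments):
        k1 = (k + 1) % segments
        b, b1, t, t1 = k, k1, segments + k, segments + k1
        faces += [(b, b1, t), (b1, t1, t)]  # tube, outward
        faces.append((ct, t, t1))  # top cap, normal +d
        faces.append((cb, b1, b))  # bottom cap, normal -d
    colors = np.tile(np.asarray(color, dtype=np.uint8), (len(verts), 1))
    return TriangleMesh(vertices=verts, triangles=np.asarray(faces, dtype=np.int64),
                        vertex_colors=colors)


def build_ballstick(fragment: Fragment, atoms: list[ExpandedAtom],
                    style: StyleConfig | None = None) -> list[TriangleMesh]:
    """One sphere shell per atom, two half-bond shells per bond.

    The fragment is centered on its bounding-box center, then every
    coordinate is multiplied by ``style.scale``. Each half-bond runs from an
    atom center to the bond midpoint and carries that atom's element color;
    flat cylinder caps are buried inside the (larger) atom spheres, so no
    open ends can surface. Every shell is independently closed and
    instantiated exactly once.
    """
    style = style or StyleConfig()
    if fragment.natoms == 0:
        raise ValueError("empty fragment")

    # sphere must bury the cylinder cap at the atom end of every half-bond
    for el in {atoms[i].element for i in fragment.atom_indices}:
        if style.sphere_radius(el) <= style.bond_radius:
            raise ValueError(
                f"sphere radius for {el} ({style.sphere_radius(el):.3f} Å) must exceed "
                f"bond_radius ({style.bond_radius} Å) or cylinder ends would surface"
            )

    carts = np.array([atoms[i].cart for i in fragment.atom_indices])
    center = (carts.min(axis=0) + carts.max(axis=0)) / 2.0

    shells: list[TriangleMesh] = []
    for i in fragment.atom_indices:
        a = atoms[i]
        mesh = icosphere(
            (np.asarray(a.cart) - center) * style.scale,
            style.sphere_radius(a.element) * style.scale,
            level=style.sphere_level,
            color=style.color(a.element),
        )
        shells.append(mesh)
    for bond in fragment.bonds:
        pi = (np.asarray(atoms[bond.i].cart) - center) * style.scale
        pj = (np.asarray(atoms[bond.j].cart) - center) * style.scale
        mid = (pi + pj) / 2.0
        r = style.bond_radius * style.scale
        # half-phase offset on the far half: the two halves share the midpoint
        # but never ring vertices, so exact-weld tools keep the shells distinct
        shells.append(capped_cylinder(pi, mid, r, style.cyl_segments,
                                      color=style.color(atoms[bond.i].element)))
        shells.append(capped_cylinder(mid, pj, r, style.cyl_segments,
                                      color=style.color(atoms[bond.j].element),
                                      phase=0.5))
    return shells


def validate_shell(mesh: TriangleMesh, min_radius: float = MIN_PRINT_RADIUS) -> ShellReport:
    """Check one shell against the printability contract.

    Reports boundary-edge and non-manifold-edge counts (both must be 0),
    whether every shared edge is traversed in opposite directions by its two
    triangles (consistent counter-clockwise winding), the signed volume
    (positive iff normals point outward), the degenerate-triangle count, and
    a feature-thickness proxy (smallest bounding-box extent; shells thinner
    than 2×``min_radius`` would print as unprintably thin features).
    """
    tris = mesh.triangles
    edge_count: dict[tuple[int, int], int] = {}
    directed: dict[tuple[int, int], int] = {}
    for a, b, c in tris:
        for i, j in ((a, b), (b, c), (c, a)):
            key = (int(i), int(j)) if i < j else (int(j), int(i))
            edge_count[key] = edge_count.get(key, 0) + 1
            dkey = (int(i), int(j))
            directed[dkey] = directed.get(dkey, 0) + 1
    boundary = sum(1 for n in edge_count.values() if n == 1)
    nonmanifold = sum(1 for n in edge_count.values() if n > 2)
    oriented = all(n == 1 for n in directed.values())

    v = mesh.vertices
    a, b, c = v[tris[:, 0]], v[tris[:, 1]], v[tris[:, 2]]
    areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    degenerate = int(np.sum(areas <= DEGENERATE_AREA))

    extents = v.max(axis=0) - v.min(axis=0)
    thickness = float(extents.min())
    return ShellReport(
        boundary_edges=boundary,
        nonmanifold_edges=nonmanifold,
        oriented=oriented,
        signed_volume=mesh.signed_volume(),
        degenerate_triangles=degenerate,
        feature_thickness=thickness,
        thin_feature=thickness < 2.0 * min_radius,
    )
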