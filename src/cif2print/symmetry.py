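"""Space-group symmetry expansion and unit-cell packing.

Operators are parsed from their xyz form ("-x+1/2, y, -z+1/2") into an exact
integer rotation part and rational translation, applied to the asymmetric
unit, and the resulting images wrapped into [0, 1) and deduplicated. Packing
enumerates integer lattice translations so that atoms sitting on cell faces,
edges and corners appear on every incident boundary — the behavior crystal
viewers produce for a "packed" unit-cell load.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.spatial import cKDTree

from .cif_io import CrystalCell, StructureRecord
from .errors import InvalidCellError, SymopParseError

logger = logging.getLogger("cif2print")

DEDUP_TOL = 0.01  # Å; merges coordinates printed to 4 decimal places reliably
BOUNDARY_EPS = 1e-4  # fractional tolerance for boundary membership when packing


@dataclass(frozen=True)
class SymOp:
    """Affine symmetry operator: integer rotation R, rational translation t.

    R entries are in {-1, 0, 1}; t components are Fractions reduced mod 1.
    """

    R: tuple[tuple[int, int, int], ...]
    t: tuple[Fraction, Fraction, Fraction]

    def __post_init__(self) -> None:
        det = round(np.linalg.det(np.asarray(self.R, dtype=float)))
        if det not in (-1, 1):
            raise SymopParseError(f"operator rotation part has det {det}, expected ±1")

    @property
    def rotation(self) -> np.ndarray:
        return np.asarray(self.R, dtype=np.int64)

    @property
    def translation(self) -> np.ndarray:
        return np.asarray([float(x) for x in self.t])

    def apply(self, frac) -> np.ndarray:
        """Map a fractional coordinate (no wrapping)."""
        return self.rotation @ np.asarray(frac, dtype=float) + self.translation

    def __str__(self) -> str:
        parts = []
        for row, trans in zip(self.R, self.t):
            s = ""
            for coef, axis in zip(row, "xyz"):
                if coef == 1:
                    s += f"+{axis}" if s else axis
                elif coef == -1:
                    s += f"-{axis}"
            if trans != 0:
                s += f"+{trans}" if s else str(trans)
            parts.append(s or "0")
        return ",".join(parts)


_TOKEN_RE = re.compile(r"\s*([+-]?)\s*(\d+/\d+|\d+(?:\.\d+)?|[xyz])", re.IGNORECASE)


def parse_symop(op_string: str) -> SymOp:
    """Parse an xyz operator string into an exact :class:`SymOp`.

    The grammar per component is a signed sum of the tokens x, y, z, integer
    or decimal constants, and fractions like 1/2, in any order. Decimal
    translations (0.5) and fractions (1/2) parse identically; translations
    are reduced into [0, 1). Anything outside the grammar raises
    :class:`SymopParseError` naming the offending component.
    """
    comps = [c for c in op_string.split(",")]
    if len(comps) != 3:
        raise SymopParseError(f"expected 3 comma-separated components in {op_string!r}")
    R = [[0, 0, 0] for _ in range(3)]
    t = [Fraction(0)] * 3
    for i, comp in enumerate(comps):
        pos = 0
        stripped = comp.strip()
        if not stripped:
            raise SymopParseError(f"empty component {i + 1} in {op_string!r}")
        while pos < len(comp):
            if comp[pos:].strip() == "":
                break
            m = _TOKEN_RE.match(comp, pos)
            if not m:
                raise SymopParseError(
                    f"cannot parse component {i + 1} ({comp.strip()!r}) of {op_string!r}"
                )
            sign = -1 if m.group(1) == "-" else 1
            tok = m.group(2).lower()
            if tok in "xyz":
                axis = "xyz".index(tok)
                R[i][axis] += sign
                if abs(R[i][axis]) > 1:
                    raise SymopParseError(
                        f"rotation coefficient outside {{-1,0,1}} in component {comp.strip()!r}"
                    )
            elif "/" in tok:
                num, den = tok.split("/")
                t[i] += sign * Fraction(int(num), int(den))
            else:
                # decimals like 0.3333 are snapped to the nearest small fraction
                t[i] += sign * Fraction(tok).limit_denominator(12)
            pos = m.end()
        t[i] %= 1
    return SymOp(R=tuple(tuple(row) for row in R), t=tuple(t))


def orthogonalization_matrix(cell: CrystalCell) -> np.ndarray:
    """3×3 map from fractional to Cartesian Å.

    Convention: **a** along the first Cartesian axis, **b** in the first-second
    plane. Columns are the cell vectors.
    """
    ca, cb, cg = (math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    sg = math.sin(math.radians(cell.gamma))
    v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if v2 <= 0 or sg <= 0:
        raise InvalidCellError(f"degenerate cell: {cell}")
    v = math.sqrt(v2)
    return np.array(
        [
            [cell.a, cell.b * cg, cell.c * cb],
            [0.0, cell.b * sg, cell.c * (ca - cb * cg) / sg],
            [0.0, 0.0, cell.c * v / sg],
        ]
    )


def frac_to_cart(cell: CrystalCell, frac) -> np.ndarray:
    """Convert fractional coordinates to Cartesian Å (single point or array)."""
    M = orthogonalization_matrix(cell)
    return (M @ np.asarray(frac, dtype=float).T).T


def metric_tensor(cell: CrystalCell) -> np.ndarray:
    """Cell metric G_ij = v_i · v_j, from the cell parameters directly."""
    ca, cb, cg = (math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    a, b, c = cell.a, cell.b, cell.c
    return np.array(
        [
            [a * a, a * b * cg, a * c * cb],
            [a * b * cg, b * b, b * c * ca],
            [a * c * cb, b * c * ca, c * c],
        ]
    )


@dataclass(frozen=True)
class ExpandedAtom:
    """A symmetry-generated atom instance with full provenance."""

    element: str
    frac: tuple[float, float, float]
    cart: tuple[float, float, float]
    site_index: int
    symop_index: int
    shift: tuple[int, int, int] = (0, 0, 0)

    @property
    def provenance(self) -> tuple[int, int, tuple[int, int, int]]:
        return (self.site_index, self.symop_index, self.shift)


def _wrap01(frac: np.ndarray) -> np.ndarray:
    wrapped = frac - np.floor(frac)
    # 0.9999999999 wraps to 0 rather than surviving as a duplicate of 1.0
    wrapped[np.isclose(wrapped, 1.0, atol=1e-9)] = 0.0
    return wrapped


def _dedup(candidates: list[ExpandedAtom], dedup_tol: float) -> list[ExpandedAtom]:
    """Merge same-element images closer than ``dedup_tol``, keeping the first.

    Candidates must already be ordered by provenance (site-major, then symop,
    then shift), so "first" is the lowest provenance. A close hetero-element
    contact is kept and logged as a likely disorder artifact.
    """
    kept: list[ExpandedAtom] = []
    carts: dict[str, list[np.ndarray]] = {}
    for atom in candidates:
        cart = np.asarray(atom.cart)
        same = carts.get(atom.element)
        if same:
            d2 = np.sum((np.asarray(same) - cart) ** 2, axis=1)
            if d2.min() <= dedup_tol * dedup_tol:
                continue
        kept.append(atom)
        carts.setdefault(atom.element, []).append(cart)

    if len(kept) > 1:
        pts = np.array([a.cart for a in kept])
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(r=dedup_tol):
            if kept[i].element != kept[j].element:
                logger.warning(
                    "hetero-element contact %s/%s at %.4f Å kept (likely disorder)",
                    kept[i].element,
                    kept[j].element,
                    float(np.linalg.norm(pts[i] - pts[j])),
                )
    return kept


def expand(structure: StructureRecord, dedup_tol: float = DEDUP_TOL) -> list[ExpandedAtom]:
    """Apply every symmetry operator to every site; wrap, deduplicate.

    Output order is deterministic (site-major, then operator). Same-element
    images closer than ``dedup_tol`` Å merge, keeping the lowest
    (site_index, symop_index) — this is how atoms on special positions
    collapse to a single copy.
    """
    if dedup_tol <= 0:
        raise ValueError("dedup_tol must be positive")
    ops = [parse_symop(s) for s in structure.symop_strings]
    M = orthogonalization_matrix(structure.cell)
    candidates: list[ExpandedAtom] = []
    for si, site in enumerate(structure.sites):
        for oi, op in enumerate(ops):
            frac = _wrap01(op.apply(site.frac))
            cart = M @ frac
            candidates.append(
                ExpandedAtom(
                    element=site.element,
                    frac=tuple(frac),
                    cart=tuple(cart),
                    site_index=si,
                    symop_index=oi,
                )
            )
    return _dedup(candidates, dedup_tol)


def pack_cell(
    structure: StructureRecord,
    ranges: tuple[int, int, int] = (1, 1, 1),
    boundary_eps: float = BOUNDARY_EPS,
    dedup_tol: float = DEDUP_TOL,
) -> list[ExpandedAtom]:
    """Pack ``ranges`` unit cells, keeping every boundary copy of each atom.

    Starting from the wrapped symmetry images, integer lattice translations
    in {-1, 0, ..., range} per axis are enumerated; a copy is retained iff
    every fractional coordinate lies within [-boundary_eps, range +
    boundary_eps]. Atoms on faces/edges/corners therefore appear on every
    incident boundary (a corner atom of a single cell appears 8 times).
    """
    if boundary_eps < 0:
        raise ValueError("boundary_eps must be >= 0")
    base = expand(structure, dedup_tol=dedup_tol)
    M = orthogonalization_matrix(structure.cell)
    lo = -boundary_eps
    hi = np.asarray(ranges, dtype=float) + boundary_eps
    candidates: list[ExpandedAtom] = []
    shift_iter = list(
        itertools.product(*(range(-1, r + 1) for r in ranges))
    )
    for atom in base:
        frac0 = np.asarray(atom.frac)
        for shift in shift_iter:
            frac = frac0 + np.asarray(shift, dtype=float)
            if np.all(frac >= lo) and np.all(frac <= hi):
                cart = M @ frac
                candidates.append(
                    ExpandedAtom(
                        element=atom.element,
                        frac=tuple(frac),
                        cart=tuple(cart),
                        site_index=atom.site_index,
                        symop_index=atom.symop_index,
                        shift=shift,
                    )
                )
    return _dedup(candidates, dedup_tol)
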