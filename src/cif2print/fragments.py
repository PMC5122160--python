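"""Bond perception, connected fragments, and primary-fragment selection.

A bond is perceived between atoms i and j when

    0.4 Å < d(i, j) <= r_cov(i) + r_cov(j) + bond_tol

with Cordero-style single-bond covalent radii and a default tolerance of
0.45 Å — the heuristic crystallographic viewers use for ball-and-stick
display. The lower bound rejects coincidence duplicates that survived
deduplication; H–H bonds are never formed (they only arise from disorder).

Connected components of the bond graph are the molecules (or extended-solid
networks). The fragment with the greatest atom count is selected for export
and everything else is discarded — solvents, counterions, and duplicate
symmetry copies. Ties (e.g. the two mirror images of a racemate) are broken
deterministically by the lowest contained atom index, so batch runs are
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .elements import covalent_radius
from .symmetry import ExpandedAtom

logger = logging.getLogger("cif2print")

BOND_TOL = 0.45  # Å added to the covalent-radius sum
MIN_BOND_DIST = 0.4  # Å floor below which a contact is a duplicate, not a bond


@dataclass(frozen=True)
class Bond:
    """An undirected bond between expanded-atom indices i < j."""

    i: int
    j: int
    length: float


@dataclass(frozen=True)
class Fragment:
    """A connected set of atoms with its internal bonds."""

    atom_indices: tuple[int, ...]  # sorted ascending
    bonds: tuple[Bond, ...]

    @property
    def natoms(self) -> int:
        return len(self.atom_indices)


def perceive_bonds(atoms: list[ExpandedAtom], bond_tol: float = BOND_TOL) -> list[Bond]:
    """Distance-based bond perception over a spatial index."""
    n = len(atoms)
    if n < 2:
        return []
    carts = np.array([a.cart for a in atoms])
    radii = np.array([covalent_radius(a.element) for a in atoms])
    elements = [a.element for a in atoms]
    cutoff = 2.0 * radii.max() + bond_tol
    tree = cKDTree(carts)
    bonds: list[Bond] = []
    for i, j in sorted(tree.query_pairs(r=cutoff)):
        if elements[i] == "H" and elements[j] == "H":
            continue
        d = float(np.linalg.norm(carts[i] - carts[j]))
        if MIN_BOND_DIST < d <= radii[i] + radii[j] + bond_tol:
            bonds.append(Bond(i=min(i, j), j=max(i, j), length=d))
    return bonds


def find_fragments(atoms: list[ExpandedAtom], bonds: list[Bond]) -> list[Fragment]:
    """Connected components of the bond graph; isolated atoms are singletons.

    Sorted by atom count descending, then by lowest contained atom index.
    """
    n = len(atoms)
    if n == 0:
        return []
    if bonds:
        rows = [b.i for b in bonds]
        cols = [b.j for b in bonds]
        graph = coo_matrix((np.ones(len(bonds)), (rows, cols)), shape=(n, n))
        _, labels = connected_components(graph, directed=False)
    else:
        labels = np.arange(n)
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(idx)
    by_label_bonds: dict[int, list[Bond]] = {lab: [] for lab in groups}
    for b in bonds:
        by_label_bonds[int(labels[b.i])].append(b)
    frags = [
        Fragment(atom_indices=tuple(sorted(members)), bonds=tuple(by_label_bonds[lab]))
        for lab, members in groups.items()
    ]
    frags.sort(key=lambda f: (-f.natoms, f.atom_indices[0]))
    return frags


def select_primary(fragments: list[Fragment]) -> Fragment:
    """The fragment with the greatest atom count; ties -> lowest atom index.

    Everything else is deleted downstream: duplicate symmetry copies,
    solvents and smaller counterions. Invariant under permutation of the
    input list.
    """
    if not fragments:
        raise ValueError("no fragments to select from")
    best = min(fragments, key=lambda f: (-f.natoms, f.atom_indices[0]))
    dropped = len(fragments) - 1
    if dropped:
        logger.info(
            "selected %d-atom fragment; deleting %d other fragment(s) (%d atoms)",
            best.natoms,
            dropped,
            sum(f.natoms for f in fragments) - best.natoms,
        )
    return best
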