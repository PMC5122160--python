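import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cif2print as cp

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_records():
    """kind -> (StructureRecord, FixtureSpec) for seed 0."""
    out = {}
    for kind in cp.FIXTURE_KINDS:
        text, spec = cp.make_fixture(kind, seed=0)
        out[kind] = (cp.read_cif(text), spec)
    return out


@pytest.fixture(scope="session")
def water(fixture_records):
    return fixture_records["p1_molecule"]


@pytest.fixture(scope="session")
def cocrystal(fixture_records):
    return fixture_records["cocrystal"]


@pytest.fixture(scope="session")
def rocksalt(fixture_records):
    return fixture_records["rocksalt"]


@pytest.fixture(scope="session")
def enantiomer(fixture_records):
    return fixture_records["enantiomer_pair"]


def brute_force_fragments(atoms, bonds):
    """Transitive-closure component oracle, independent of scipy csgraph."""
    n = len(atoms)
    adj = [set() for _ in range(n)]
    for b in bonds:
        adj[b.i].add(b.j)
        adj[b.j].add(b.i)
    seen = [False] * n
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(sorted(comp))
    return comps


def brute_force_expand(record, dedup_tol=0.01):
    """Independent symmetry-image enumeration with pairwise-distance dedup."""
    M = cp.orthogonalization_matrix(record.cell)
    kept = []
    for site in record.sites:
        for op_str in record.symop_strings:
            op = cp.parse_symop(op_str)
            frac = op.apply(site.frac)
            frac = frac - np.floor(frac)
            frac[np.isclose(frac, 1.0, atol=1e-9)] = 0.0
            cart = M @ frac
            dup = any(
                el == site.element and np.linalg.norm(c - cart) <= dedup_tol
                for el, c in kept
            )
            if not dup:
                kept.append((site.element, cart))
    return kept
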