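import numpy as np
import pytest

from epimixed.pedigree import Pedigree

# The worked example pedigree: founders 1, 2, 3; 4 = 1 x 2; 5, 6 = 1 x 3
# (full sibs); 7 = 6 x unknown.  Its T matrix has the four canonical
# relative classes: parent-offspring (1,4), full sibs (5,6), half sibs
# (4,5), uncle-nephew (5,7).
EXAMPLE_RECORDS = [
    (1, 0, 0), (2, 0, 0), (3, 0, 0),
    (4, 1, 2), (5, 1, 3), (6, 1, 3), (7, 6, 0),
]


@pytest.fixture(scope="session")
def example_pedigree() -> Pedigree:
    return Pedigree.from_records(EXAMPLE_RECORDS)


@pytest.fixture(scope="session")
def trio() -> Pedigree:
    return Pedigree.from_records([(1, 0, 0), (2, 0, 0), (3, 1, 2)])


def layered_pedigree(
    n_founders: int,
    n_gens: int,
    n_per_gen: int,
    rng: np.random.Generator,
    single_parent_frac: float = 0.2,
) -> Pedigree:
    """Random multi-generation pedigree; parents drawn from the previous
    layer (related matings and single parents allowed)."""
    records = [(i, 0, 0) for i in range(1, n_founders + 1)]
    prev = list(range(1, n_founders + 1))
    nid = n_founders
    for _ in range(n_gens):
        layer = []
        for _ in range(n_per_gen):
            nid += 1
            if len(prev) < 2 or rng.uniform() < single_parent_frac:
                p = prev[rng.integers(len(prev))]
                records.append((nid, p, 0) if rng.uniform() < 0.5 else (nid, 0, p))
            else:
                s, d = rng.choice(len(prev), size=2, replace=False)
                records.append((nid, prev[s], prev[d]))
            layer.append(nid)
        prev = layer
    return Pedigree.from_records(records)


def outcross_pedigree(
    n_founders: int, n_per_gen: int, rng: np.random.Generator
) -> Pedigree:
    """Two-offspring-generation pedigree in which no mate pair shares an
    ancestor: founders split into two lineages, generation 1 bred within
    each lineage, generation 2 by crossing the lineages.  Breeding
    individuals stay non-inbred and mates epigenetically unrelated, the
    regime in which A and T have exactly unit diagonals."""
    assert n_founders >= 4 and n_founders % 4 == 0
    records = [(i, 0, 0) for i in range(1, n_founders + 1)]
    half = n_founders // 2
    pool_a = list(range(1, half + 1))
    pool_b = list(range(half + 1, n_founders + 1))
    nid = n_founders
    gen1 = {0: [], 1: []}
    for k, pool in enumerate((pool_a, pool_b)):
        for _ in range(n_per_gen):
            nid += 1
            s, d = rng.choice(len(pool), size=2, replace=False)
            records.append((nid, pool[s], pool[d]))
            gen1[k].append(nid)
    for _ in range(n_per_gen):
        nid += 1
        s = gen1[0][rng.integers(len(gen1[0]))]
        d = gen1[1][rng.integers(len(gen1[1]))]
        records.append((nid, s, d))
    return Pedigree.from_records(records)
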