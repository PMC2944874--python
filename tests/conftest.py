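import numpy as np
import pytest

from troutmorph.pedigree import (
    IndividualRecord,
    additive_relationship_matrix,
    assinica_design,
    pedigree_from_design,
)
from troutmorph.simulate import default_mean_shape


@pytest.fixture(scope="session")
def assinica():
    """Assinica-like pedigree (30 families x 8 offspring) with A restricted to
    the offspring, plus dam/sire/family labels — the workhorse design for
    parameter-recovery checks."""
    ped = pedigree_from_design(assinica_design(), 8)
    rel = additive_relationship_matrix(ped)
    off = [r for r in ped if r.sire is not None]
    ids = [r.id for r in off]
    A = rel.subset(ids).values
    return {
        "pedigree": ped,
        "A": A,
        "ids": ids,
        "dam": np.array([r.dam for r in off]),
        "sire": np.array([r.sire for r in off]),
        "family": np.array([f"{r.sire}x{r.dam}" for r in off]),
        "n": len(off),
    }


@pytest.fixture(scope="session")
def mean_shape():
    return default_mean_shape()


def random_pedigree(rng, n_max=15):
    """Random valid pedigree (topologically ordered, possibly inbred)."""
    n = int(rng.integers(3, n_max + 1))
    records = []
    for i in range(n):
        if i < 2 or rng.random() < 0.3:
            records.append(IndividualRecord(f"i{i}"))
        else:
            s, d = rng.integers(0, i, size=2)
            records.append(IndividualRecord(f"i{i}", sire=f"i{s}", dam=f"i{d}"))
    return records


def kinship_oracle(pedigree):
    """Independent brute-force coefficient-of-coancestry recursion.

    f(i, i) = 0.5 (1 + f(sire_i, dam_i)); for i != j with i the later-born,
    f(i, j) = 0.5 (f(sire_i, j) + f(dam_i, j)).  A = 2 f.
    """
    parents = {r.id: (r.sire, r.dam) for r in pedigree}
    order = {r.id: k for k, r in enumerate(pedigree)}
    memo = {}

    def f(a, b):
        if a is None or b is None:
            return 0.0
        if order[a] < order[b]:
            a, b = b, a
        key = (a, b)
        if key in memo:
            return memo[key]
        s, d = parents[a]
        if a == b:
            val = 0.5 * (1.0 + f(s, d))
        else:
            val = 0.5 * (f(s, b) + f(d, b))
        memo[key] = val
        return val

    ids = [r.id for r in pedigree]
    n = len(ids)
    A = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = 2.0 * f(ids[i], ids[j])
    return A


def similarity_transform(rng, pts):
    """Random rotation + positive scale + translation of a (k, 2) config."""
    th = rng.uniform(-np.pi, np.pi)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return pts @ R.T * rng.uniform(0.3, 3.0) + rng.uniform(-10, 10, 2)
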