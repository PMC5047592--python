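"""Shared fixtures: pedigrees, kinship oracles and small synthetic data sets."""

import numpy as np
import pytest

from ceramic.pedigree import Individual, Pedigree, compute_kinship
from ceramic.simulation import build_fixture_pedigree


def pairwise_kinship_oracle(ped):
    """Independent brute-force kinship: memoized per-pair recursion.

    phi(i, i) = (1 + phi(f_i, m_i)) / 2; for i != j, recurse on the
    individual with greater generation depth (which therefore cannot be an
    ancestor of the other): phi(i, j) = (phi(f_i, j) + phi(m_i, j)) / 2.
    """
    depth = ped.generation_depth()
    memo = {}

    def phi(i, j):
        if i > j:
            i, j = j, i
        if (i, j) in memo:
            return memo[(i, j)]
        fi, mi = int(ped.father_idx[i]), int(ped.mother_idx[i])
        fj, mj = int(ped.father_idx[j]), int(ped.mother_idx[j])
        if i == j:
            val = 0.5 if fi < 0 else 0.5 * (1.0 + phi(fi, mi))
        elif depth[i] >= depth[j]:
            val = 0.0 if fi < 0 else 0.5 * (phi(fi, j) + phi(mi, j))
        else:
            val = 0.0 if fj < 0 else 0.5 * (phi(fj, i) + phi(mj, i))
        memo[(i, j)] = val
        return val

    n = ped.n
    out = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            out[i, j] = out[j, i] = phi(i, j)
    return out


def dense_kinship(ped):
    """2*phi off-diagonal / 1+h diagonal, from the brute-force oracle."""
    return 2.0 * pairwise_kinship_oracle(ped)


@pytest.fixture(scope="session")
def fixture_ped():
    return build_fixture_pedigree()


@pytest.fixture(scope="session")
def fixture_K(fixture_ped):
    return compute_kinship(fixture_ped)


def make_pedigree(rows, fid="F1"):
    """rows: (iid, father, mother, sex) tuples."""
    return Pedigree([Individual(fid, i, f, m, s) for i, f, m, s in rows])


@pytest.fixture()
def trio_ped():
    return make_pedigree([("dad", None, None, 1), ("mom", None, None, 2),
                          ("kid", "dad", "mom", 1)])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231107)
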