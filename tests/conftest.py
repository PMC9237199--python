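"""Shared fixtures and independent oracles.

Oracles live here so every test module checks the package against the
same naive reference implementations (double-loop Pearson, rank-assignment
enumeration for the rank-sum test, brute-force BH).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from sctip.matrix_io import CountMatrix
from sctip.preprocess import NormalizedMatrix


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson coefficient, no vectorized shortcuts."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def pair_mean_oracle(data: np.ndarray, absolute: bool) -> float:
    """Mean correlation over unordered distinct row pairs via double loop."""
    n = data.shape[0]
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            r = pearson_oracle(data[i], data[j])
            vals.append(abs(r) if absolute else r)
    return float(np.mean(vals))


def ranksum_enumeration_oracle(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments.

    Requires tie-free pooled data.  p = 2 * min(P(U <= u), P(U >= u)),
    capped at 1, with the observed point included in both tails.
    """
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    na = len(a)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in a) - na * (na + 1) / 2
    us = []
    for idx in combinations(range(len(pooled)), na):
        r_sum = sum(i + 1 for i in idx)
        us.append(r_sum - na * (na + 1) / 2)
    us = np.asarray(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return float(min(1.0, 2 * min(lo, hi)))


def bh_oracle(pvalues) -> np.ndarray:
    """Brute-force Benjamini-Hochberg: sort, p*m/rank, cummin from the top."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, p[i] * m / (pos + 1))
        adjusted[i] = running
    return adjusted


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def small_counts(rng) -> CountMatrix:
    values = rng.negative_binomial(2, 0.2, size=(50, 100))
    genes = [f"g{i:03d}" for i in range(50)]
    cells = [f"c{i:03d}" for i in range(100)]
    return CountMatrix(values, genes, cells)


def make_normalized(values: np.ndarray, prefix_g="g", prefix_c="c") -> NormalizedMatrix:
    """Wrap a raw value matrix (genes x cells) without renormalizing."""
    g = [f"{prefix_g}{i}" for i in range(values.shape[0])]
    c = [f"{prefix_c}{j}" for j in range(values.shape[1])]
    return NormalizedMatrix(np.asarray(values, dtype=float), g, c)


@pytest.fixture
def collinear_nm() -> NormalizedMatrix:
    # 2 genes x 3 cells; cells (1,2), (2,4), (3,6): g2 = 2 * g1
    return make_normalized(np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]]))
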