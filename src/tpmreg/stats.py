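"""Nonparametric two-sample statistics used throughout the wave analysis.

The per-timepoint comparison of ensemble traces uses a Mann-Whitney U test
together with Cliff's delta as the effect size.  Both are implemented here
from first principles: the exact Mann-Whitney p-value is obtained by full
enumeration of group-label assignments (valid under ties, unlike the
classical null tables), and Cliff's delta is the signed fraction of
discordant observation pairs.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["mann_whitney_u", "cliffs_delta"]


def _as_sample(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"sample {name!r} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"sample {name!r} contains non-finite values")
    return arr


def mann_whitney_u(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    Returns ``(U, p)`` where ``U`` is the statistic for sample ``x``
    (number of (x, y) pairs with x > y, ties counted half).

    For small samples (both sizes <= ``exact_max_n``) the p-value is exact:
    every assignment of the pooled observations to the two groups is
    enumerated and the two-sided p-value is the fraction of assignments
    whose U is at least as far from the null mean n*m/2 as the observed U.
    Larger samples use the normal approximation with tie and continuity
    corrections.
    """
    xs = _as_sample(x, "x")
    ys = _as_sample(y, "y")
    n, m = xs.size, ys.size

    pooled = np.concatenate([xs, ys])
    ranks = rankdata(pooled)
    u_x = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    mu = n * m / 2.0

    if n <= exact_max_n and m <= exact_max_n:
        idx = np.fromiter(
            (i for c in combinations(range(n + m), n) for i in c),
            dtype=np.intp,
            count=comb(n + m, n) * n,
        ).reshape(-1, n)
        u_all = ranks[idx].sum(axis=1) - n * (n + 1) / 2.0
        # tolerance guards float equality of midrank sums
        p = float(np.mean(np.abs(u_all - mu) >= np.abs(u_x - mu) - 1e-9))
        return u_x, p

    big_n = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    sigma2 = n * m / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if sigma2 <= 0:  # every pooled value identical
        return u_x, 1.0
    z = max(abs(u_x - mu) - 0.5, 0.0) / np.sqrt(sigma2)
    p = min(2.0 * float(norm.sf(z)), 1.0)
    return u_x, p


def cliffs_delta(x, y) -> float:
    """Cliff's delta effect size: P(x > y) - P(x < y), in [-1, 1].

    Computed by exhaustive pairwise comparison; tied pairs contribute zero.
    Antisymmetric in its arguments.
    """
    xs = _as_sample(x, "x")
    ys = _as_sample(y, "y")
    diff = xs[:, None] - ys[None, :]
    n_gt = int(np.count_nonzero(diff > 0))
    n_lt = int(np.count_nonzero(diff < 0))
    return (n_gt - n_lt) / (xs.size * ys.size)
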