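"""Shared rank statistics: Spearman with p-values, rank-sum tests, BH FDR.

Small-sample tests (both groups <= 8, or n <= 10 for Spearman) are computed
by exact enumeration of the null distribution; larger samples use the
standard tie-corrected normal / t approximations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_GROUP_MAX = 8  # exact rank-sum enumeration when both groups are this small
EXACT_SPEARMAN_MAX = 10  # exact Spearman permutation null up to this n


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values; NaNs are passed through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _spearman_r_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        return math.nan
    return float(rx @ ry) / denom


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (average ranks on ties) and two-sided p.

    For n > EXACT_SPEARMAN_MAX the p-value uses the t approximation with
    n - 2 degrees of freedom; otherwise the exact permutation null of the
    rank correlation is enumerated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = _spearman_r_from_ranks(rx, ry)
    if math.isnan(r):
        return math.nan, math.nan
    if n > EXACT_SPEARMAN_MAX:
        return r, _spearman_t_pvalue(r, n)
    # exact two-sided p: proportion of permutations with |rho| >= |r|
    count = 0
    total = 0
    target = abs(r) - 1e-12
    for perm in itertools.permutations(ry):
        rho = _spearman_r_from_ranks(rx, np.asarray(perm))
        total += 1
        if abs(rho) >= target:
            count += 1
    return r, count / total


def _spearman_t_pvalue(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * stats.t.sf(abs(t), df=n - 2)


def spearman_matrix(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman of each row of X (features x obs) against y.

    Vectorised; p-values use the t approximation (callers with n <= 10
    should use :func:`spearman` per row instead). Constant rows yield NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    RX = stats.rankdata(X, axis=1)
    ry = stats.rankdata(y)
    RX = RX - RX.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    num = RX @ ry
    denom = np.sqrt((RX * RX).sum(axis=1) * float(ry @ ry))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, np.where(np.abs(r) >= 1.0, 0.0, p))
    return r, p


def _ranksum_u(x_ranks_sum: float, n1: int) -> float:
    return x_ranks_sum - n1 * (n1 + 1) / 2.0


def mannwhitney_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann–Whitney p by enumeration of group assignments.

    Handles ties naturally (ranks are recomputed per assignment of the
    pooled values, which are fixed, so average ranks are fixed too).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n = x.size, pooled.size
    u_obs = _ranksum_u(float(ranks[:n1].sum()), n1)
    mu = n1 * (n - n1) / 2.0
    dev = abs(u_obs - mu) - 1e-12
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        u = _ranksum_u(float(ranks[list(combo)].sum()), n1)
        total += 1
        if abs(u - mu) >= dev:
            count += 1
    return count / total


def mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U and p.

    Exact enumeration when both groups have <= EXACT_GROUP_MAX samples,
    otherwise the tie-corrected normal approximation (no continuity
    correction, so exact and asymptotic branches agree asymptotically).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = _ranksum_u(float(ranks[: x.size].sum()), x.size)
    if x.size <= EXACT_GROUP_MAX and y.size <= EXACT_GROUP_MAX:
        return u, mannwhitney_exact(x, y)
    _, p = stats.mannwhitneyu(
        x, y, alternative="two-sided", use_continuity=False, method="asymptotic"
    )
    return u, float(p)


def ranksum_matrix(
    X: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided rank-sum test of X[:, mask] vs X[:, ~mask].

    Tie-corrected normal approximation, vectorised over rows. Returns
    (z, p). Rows that are entirely constant get z=0, p=1.
    """
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n1 = int(mask.sum())
    n2 = int((~mask).sum())
    n = n1 + n2
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(X, axis=1)
    r1 = ranks[:, mask].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction: sum of (t^3 - t) over tie groups, per row
    srt = np.sort(X, axis=1)
    ties = np.zeros(X.shape[0])
    boundaries = np.diff(srt, axis=1) != 0
    for i in range(X.shape[0]):
        # run lengths of equal values
        idx = np.flatnonzero(boundaries[i])
        edges = np.concatenate([[-1], idx, [n - 1]])
        t = np.diff(edges).astype(float)
        ties[i] = float((t**3 - t).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (u - mu) / np.sqrt(var), 0.0)
    p = np.where(var > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return z, p


def hypergeom_enrichment_p(k: int, universe: int, n_sig: int, n_top: int) -> float:
    """One-sided (greater) Fisher/hypergeometric tail: P[X >= k]."""
    return float(stats.hypergeom.sf(k - 1, universe, n_sig, n_top))
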