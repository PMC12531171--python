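"""Empirical-Bayes location/scale batch adjustment for merged cohorts.

The model follows the standard parametric ComBat scheme: per gene,
standardize by the batch-size-weighted grand mean and pooled variance;
estimate per-(batch, gene) location (gamma) and scale (delta) on the
standardized data; optionally shrink them with parametric empirical-Bayes
priors (normal on gamma, inverse-gamma on delta, method-of-moments
hyperparameters, fixed-point iteration); then remove the batch location/
scale and back-transform.

Variance conventions: population (1/n) denominators are used for both the
pooled variance and the per-batch scale estimates. This consistent choice
makes the eb=False adjustment exactly idempotent and makes each batch's
post-adjustment mean/variance equal the grand mean/pooled variance to
numerical precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix

__all__ = ["BatchModel", "combat_adjust"]

EB_TOL = 1e-6
EB_MAX_ITER = 500


@dataclass
class BatchModel:
    batches: list[str]
    gene_ids: list[str]
    grand_mean: np.ndarray  # per gene
    pooled_var: np.ndarray  # per gene (1/n denominator)
    gamma_hat: np.ndarray  # batches x genes, raw location
    delta_hat: np.ndarray  # batches x genes, raw scale (variance)
    gamma_star: np.ndarray  # batches x genes, applied location
    delta_star: np.ndarray  # batches x genes, applied scale
    eb_enabled: bool
    gamma_bar: np.ndarray | None = None  # per batch, normal prior mean
    tau2: np.ndarray | None = None  # per batch, normal prior variance
    a_prior: np.ndarray | None = None  # per batch, inverse-gamma shape
    b_prior: np.ndarray | None = None  # per batch, inverse-gamma rate


def _aprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return (2 * s2 + m * m) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _eb_fit(
    Z: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    n_b: int,
    gamma_bar: float,
    tau2: float,
    a: float,
    b: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-point iteration for one batch's posterior gamma*/delta*.

    Z is the batch's standardized data (genes x samples in batch).
    """
    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    for _ in range(EB_MAX_ITER):
        g_new = (n_b * tau2 * gamma_hat + d_old * gamma_bar) / (n_b * tau2 + d_old)
        ssq = ((Z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (b + 0.5 * ssq) / (n_b / 2.0 + a - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
            np.abs(d_new - d_old).max() / max(np.abs(d_old).max(), 1e-12),
        )
        g_old, d_old = g_new, d_new
        if change < EB_TOL:
            break
    return g_old, d_old


def combat_adjust(
    m: ExpressionMatrix,
    batch_labels: np.ndarray | list[str],
    eb: bool = True,
) -> tuple[ExpressionMatrix, BatchModel]:
    """Remove per-batch location/scale effects from a log-scale matrix.

    A single batch is an identity map. Genes with zero pooled variance
    are passed through untouched with a warning. With ``eb=False`` the
    raw per-batch estimates are used (diagnostic mode): each batch's
    per-gene mean and population variance then equal the grand mean and
    pooled variance exactly.
    """
    labels = np.asarray([str(b) for b in batch_labels])
    if labels.size != len(m.obs_ids):
        raise ValueError("batch labels not aligned to observations")
    X = np.array(m.values, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite expression values")
    batches = sorted(set(labels.tolist()))
    masks = {b: labels == b for b in batches}
    sizes = {b: int(masks[b].sum()) for b in batches}
    small = [b for b in batches if sizes[b] < 2]
    if small:
        raise ValueError(f"batches with fewer than 2 samples: {small}")
    G, N = X.shape

    if len(batches) == 1:
        model = BatchModel(
            batches=batches,
            gene_ids=list(m.gene_ids),
            grand_mean=X.mean(axis=1),
            pooled_var=X.var(axis=1),
            gamma_hat=np.zeros((1, G)),
            delta_hat=np.ones((1, G)),
            gamma_star=np.zeros((1, G)),
            delta_star=np.ones((1, G)),
            eb_enabled=eb,
        )
        return ExpressionMatrix(X, m.gene_ids, m.obs_ids, "adjusted"), model

    batch_means = np.vstack([X[:, masks[b]].mean(axis=1) for b in batches])
    weights = np.array([sizes[b] / N for b in batches])
    grand = weights @ batch_means  # per gene
    pooled = ((X - grand[:, None]) ** 2).mean(axis=1)
    ok = pooled > 0
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} zero-variance genes passed through unadjusted",
            stacklevel=2,
        )

    out = X.copy()
    sd = np.sqrt(pooled[ok])
    Z = (X[ok] - grand[ok, None]) / sd[:, None]

    n_batches = len(batches)
    n_ok = int(ok.sum())
    gamma_hat = np.zeros((n_batches, n_ok))
    delta_hat = np.ones((n_batches, n_ok))
    for i, b in enumerate(batches):
        Zb = Z[:, masks[b]]
        gamma_hat[i] = Zb.mean(axis=1)
        delta_hat[i] = Zb.var(axis=1)  # population (1/n) variance
    if (delta_hat <= 0).any():
        warnings.warn(
            "zero within-batch variance encountered; clamped for stability",
            stacklevel=2,
        )
        delta_hat = np.maximum(delta_hat, 1e-12)

    gamma_bar = tau2 = a_pr = b_pr = None
    if eb:
        gamma_bar = gamma_hat.mean(axis=1)
        tau2 = gamma_hat.var(axis=1, ddof=1)
        a_pr = np.array([_aprior(delta_hat[i]) for i in range(n_batches)])
        b_pr = np.array([_bprior(delta_hat[i]) for i in range(n_batches)])
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i, b in enumerate(batches):
            gamma_star[i], delta_star[i] = _eb_fit(
                Z[:, masks[b]],
                gamma_hat[i],
                delta_hat[i],
                sizes[b],
                gamma_bar[i],
                tau2[i],
                a_pr[i],
                b_pr[i],
            )
    else:
        gamma_star = gamma_hat
        delta_star = delta_hat

    adj = np.empty_like(Z)
    for i, b in enumerate(batches):
        adj[:, masks[b]] = (Z[:, masks[b]] - gamma_star[i][:, None]) / np.sqrt(
            delta_star[i][:, None]
        )
    out[ok] = adj * sd[:, None] + grand[ok, None]

    def expand(arr2d: np.ndarray) -> np.ndarray:
        full = np.zeros((n_batches, G))
        full[:, ok] = arr2d
        if arr2d is delta_hat or arr2d is delta_star:
            full[:, ~ok] = 1.0
        return full

    model = BatchModel(
        batches=batches,
        gene_ids=list(m.gene_ids),
        grand_mean=grand,
        pooled_var=pooled,
        gamma_hat=expand(gamma_hat),
        delta_hat=expand(delta_hat),
        gamma_star=expand(gamma_star),
        delta_star=expand(delta_star),
        eb_enabled=eb,
        gamma_bar=gamma_bar,
        tau2=tau2,
        a_prior=a_pr,
        b_prior=b_pr,
    )
    return ExpressionMatrix(out, m.gene_ids, m.obs_ids, "adjusted"), model
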