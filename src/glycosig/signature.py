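"""Cross-dataset derivation of the glycolytic gene signature.

Per single-cell dataset, two candidate gene sets are formed among
malignant cells:

* **Gx** — genes whose expression correlates positively with the
  per-cell glycolysis enrichment score (Spearman R > 0, BH FDR < 1e-5,
  strict inequalities);
* **Gy** — genes significantly overexpressed in malignant cells versus
  all other cells (two-sided rank-sum test, BH FDR < 0.05, log-scale
  mean difference > 0.25);

and intersected into **Gn**. Across datasets, each gene's positive
Spearman R values (from the datasets whose Gn contains it) are combined
by geometric mean; genes with geometric-mean R strictly above 0.3 (and
support in at least ``min_datasets`` datasets) form the signature.

FDR is adjusted within each dataset separately, never pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _stats
from .io import ExpressionMatrix, GeneSet
from .scoring import score_gene_set

__all__ = [
    "GeneCorrelation",
    "DatasetGeneSets",
    "SignatureAggregate",
    "DerivationParams",
    "correlate_with_glycolysis",
    "select_gx",
    "select_gy",
    "derive_dataset_sets",
    "aggregate_signature",
]


@dataclass(frozen=True)
class GeneCorrelation:
    gene: str
    spearman_r: float
    p_value: float
    fdr: float
    n_obs: int


@dataclass
class DatasetGeneSets:
    dataset_id: str
    gx: frozenset[str]
    gy: frozenset[str]
    gn: frozenset[str]
    correlations: dict[str, GeneCorrelation]


@dataclass(frozen=True)
class SignatureAggregate:
    gene: str
    per_dataset_r: dict[str, float]
    geo_mean_r: float
    n_datasets: int
    in_signature: bool


@dataclass(frozen=True)
class DerivationParams:
    """Thresholds of the derivation; defaults are the published rules
    where stated (Gx, geometric-mean cut) and conventional single-cell
    marker defaults where not (Gy)."""

    gx_r_min: float = 0.0
    gx_fdr_max: float = 1e-5
    gy_fdr_max: float = 0.05
    gy_min_logfc: float = 0.25
    r_threshold: float = 0.3
    min_datasets: int = 1
    score_method: str = "ssgsea"
    score_alpha: float = 0.25


def correlate_with_glycolysis(
    m: ExpressionMatrix,
    glyc_scores: np.ndarray,
    obs_mask: np.ndarray | None = None,
) -> list[GeneCorrelation]:
    """Per-gene Spearman correlation with the glycolysis score.

    ``glyc_scores`` is aligned to ``m.obs_ids``; ``obs_mask`` restricts
    the correlation to (typically malignant) observations. Two-sided
    p-values use the t approximation for n > 10 and exact enumeration
    otherwise; BH FDR is computed across the dataset's non-constant
    genes. Constant genes get R = NaN and are excluded from FDR.
    """
    glyc = np.asarray(glyc_scores, dtype=float)
    if glyc.size != len(m.obs_ids):
        raise ValueError("glycolysis scores not aligned to observations")
    if obs_mask is None:
        obs_mask = np.ones(glyc.size, dtype=bool)
    obs_mask = np.asarray(obs_mask, dtype=bool)
    n = int(obs_mask.sum())
    if n < 3:
        raise ValueError("need at least 3 masked observations")
    y = glyc[obs_mask]
    if np.ptp(y) == 0:
        raise ValueError("glycolysis score vector is constant on the mask")
    X = m.values[:, obs_mask]
    if n > _stats.EXACT_SPEARMAN_MAX:
        r, p = _stats.spearman_matrix(X, y)
    else:
        r = np.empty(X.shape[0])
        p = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            if np.ptp(X[i]) == 0:
                r[i] = p[i] = math.nan
            else:
                r[i], p[i] = _stats.spearman(X[i], y)
    fdr = _stats.bh_fdr(p)
    return [
        GeneCorrelation(g, float(r[i]), float(p[i]), float(fdr[i]), n)
        for i, g in enumerate(m.gene_ids)
    ]


def select_gx(
    corrs: list[GeneCorrelation], r_min: float = 0.0, fdr_max: float = 1e-5
) -> frozenset[str]:
    """Genes positively correlated with glycolysis: R > r_min and FDR < fdr_max."""
    if not corrs:
        raise ValueError("no correlation records")
    return frozenset(
        c.gene
        for c in corrs
        if math.isfinite(c.spearman_r) and c.spearman_r > r_min and c.fdr < fdr_max
    )


def select_gy(
    m: ExpressionMatrix,
    malignant_mask: np.ndarray,
    fdr_max: float = 0.05,
    min_logfc: float = 0.25,
) -> frozenset[str]:
    """Genes overexpressed in malignant cells.

    Two-sided rank-sum test malignant vs rest (exact enumeration when
    both groups have <= 8 observations, tie-corrected normal
    approximation otherwise), BH FDR across tested genes, and log-scale
    mean difference (malignant - rest) > min_logfc.
    """
    mask = np.asarray(malignant_mask, dtype=bool)
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("need both malignant and non-malignant observations")
    X = m.values
    if n1 <= _stats.EXACT_GROUP_MAX and n2 <= _stats.EXACT_GROUP_MAX:
        p = np.array(
            [_stats.mannwhitney(X[i, mask], X[i, ~mask])[1] for i in range(X.shape[0])]
        )
    else:
        _, p = _stats.ranksum_matrix(X, mask)
    fdr = _stats.bh_fdr(p)
    logfc = X[:, mask].mean(axis=1) - X[:, ~mask].mean(axis=1)
    keep = (fdr < fdr_max) & (logfc > min_logfc)
    return frozenset(np.array(m.gene_ids)[keep].tolist())


def derive_dataset_sets(
    dataset_id: str,
    m: ExpressionMatrix,
    annotations: pd.DataFrame,
    glyc_set: GeneSet,
    params: DerivationParams = DerivationParams(),
) -> DatasetGeneSets:
    """Run the per-dataset half of the derivation.

    Scores the glycolysis set on all cells, correlates gene expression
    with that score among malignant cells, forms Gx and Gy, and
    intersects them into Gn. ``annotations`` must carry a boolean
    ``malignant`` column aligned to the matrix observations.
    """
    mal = annotations.loc[list(m.obs_ids), "malignant"].to_numpy(dtype=bool)
    if not mal.any():
        raise ValueError(f"{dataset_id}: no malignant cells annotated")
    scores = score_gene_set(
        m, glyc_set, method=params.score_method, alpha=params.score_alpha
    ).vector()
    corrs = correlate_with_glycolysis(m, scores, mal)
    gx = select_gx(corrs, params.gx_r_min, params.gx_fdr_max)
    gy = select_gy(m, mal, params.gy_fdr_max, params.gy_min_logfc)
    gn = gx & gy
    return DatasetGeneSets(
        dataset_id=dataset_id,
        gx=gx,
        gy=gy,
        gn=gn,
        correlations={c.gene: c for c in corrs if c.gene in gn},
    )


def aggregate_signature(
    sets: list[DatasetGeneSets],
    r_threshold: float = 0.3,
    min_datasets: int = 1,
    name: str = "GLYC.SIG",
) -> tuple[GeneSet | None, list[SignatureAggregate]]:
    """Combine per-dataset Gn sets into the final signature.

    For every gene in the union of Gn sets, the Spearman R values from
    the datasets whose Gn contains it (all positive by construction of
    Gx) are combined by geometric mean; membership requires
    geo_mean_r > r_threshold (strict) and support in >= min_datasets
    datasets. Output is independent of the order of ``sets``. Returns
    (signature or None if empty, per-gene aggregates sorted by gene).
    """
    if not sets:
        raise ValueError("need at least one dataset")
    per_gene: dict[str, dict[str, float]] = {}
    for ds in sorted(sets, key=lambda d: d.dataset_id):
        for gene in ds.gn:
            r = ds.correlations[gene].spearman_r
            if not (r > 0):
                raise ValueError(
                    f"{ds.dataset_id}:{gene} in Gn with non-positive R={r}"
                )
            per_gene.setdefault(gene, {})[ds.dataset_id] = r
    aggregates: list[SignatureAggregate] = []
    for gene in sorted(per_gene):
        rs = per_gene[gene]
        vals = np.array(list(rs.values()))
        geo = float(np.exp(np.log(vals).mean()))
        aggregates.append(
            SignatureAggregate(
                gene=gene,
                per_dataset_r=dict(rs),
                geo_mean_r=geo,
                n_datasets=len(rs),
                # strict >, with a small guard so values equal to the
                # threshold up to rounding are excluded
                in_signature=geo - r_threshold > 1e-12 and len(rs) >= min_datasets,
            )
        )
    members = tuple(a.gene for a in aggregates if a.in_signature)
    signature = GeneSet(name=name, genes=members) if members else None
    return signature, aggregates
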