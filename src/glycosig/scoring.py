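"""Cell QC, library-size log-normalization, and single-sample gene-set scores.

The single-sample scorer is the ssGSEA rank statistic: within each
observation genes are ranked by expression (average ranks on ties) and a
weighted Kolmogorov–Smirnov random walk is accumulated over the ranking,
with in-set increments proportional to rank**alpha and uniform out-of-set
increments; the score is the sum of the running sum (the area between the
in-set and out-of-set empirical CDFs). Scores are then min–max rescaled
across the observations of the matrix to span [-1, 1], so scores are only
comparable within one scored matrix. Being purely rank-based, the score is
invariant to any strictly monotone per-observation transform of expression.

A ``zmean`` fallback (mean of gene-wise z-scores over the set) is provided
for bulk matrices where a parametric location score is preferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ExpressionMatrix, GeneSet

__all__ = [
    "QcThresholds",
    "EnrichmentScores",
    "qc_filter_cells",
    "log_normalize",
    "score_gene_set",
]


@dataclass(frozen=True)
class QcThresholds:
    """Cell exclusion thresholds; all comparisons are strict.

    A cell is removed when genes detected > max_genes or < min_genes,
    total reads > max_reads, or mitochondrial read fraction >
    max_mito_frac.
    """

    max_genes: int = 7500
    min_genes: int = 200
    max_reads: float = 75000
    max_mito_frac: float = 0.20

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be below max_genes")
        if not (0.0 <= self.max_mito_frac <= 1.0):
            raise ValueError("max_mito_frac must be in [0, 1]")


@dataclass
class EnrichmentScores:
    """Per-(set, observation) enrichment scores."""

    obs_ids: list[str]
    set_names: list[str]
    scores: np.ndarray  # sets x observations

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.set_names), len(self.obs_ids)):
            raise ValueError("score matrix shape does not match id lists")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite enrichment scores")

    def vector(self, set_name: str | None = None) -> np.ndarray:
        if set_name is None:
            if len(self.set_names) != 1:
                raise ValueError("set_name required when several sets were scored")
            return self.scores[0]
        return self.scores[self.set_names.index(set_name)]


def qc_filter_cells(
    m: ExpressionMatrix,
    mito_genes: GeneSet | None,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Drop low-quality cells from a counts matrix.

    ``mito_genes`` may be None when no mitochondrial annotation exists
    (the mito criterion then removes nothing). Returns the filtered
    matrix and the number of cells failing each criterion (a cell can
    fail several).
    """
    if m.layer_tag != "counts":
        raise ValueError("QC filtering expects the counts layer")
    counts = m.values
    detected = (counts > 0).sum(axis=0)
    total = counts.sum(axis=0)
    if mito_genes is not None:
        mito_present = mito_genes.intersect(m.gene_ids)
    else:
        mito_present = ()
    if mito_present:
        mito_reads = counts[m.gene_index(mito_present)].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(total > 0, mito_reads / total, 0.0)
    else:
        mito_frac = np.zeros(counts.shape[1])

    too_many_genes = detected > thresholds.max_genes
    too_few_genes = detected < thresholds.min_genes
    too_many_reads = total > thresholds.max_reads
    too_mito = mito_frac > thresholds.max_mito_frac
    drop = too_many_genes | too_few_genes | too_many_reads | too_mito
    report = {
        "genes_gt_max": int(too_many_genes.sum()),
        "genes_lt_min": int(too_few_genes.sum()),
        "reads_gt_max": int(too_many_reads.sum()),
        "mito_gt_max": int(too_mito.sum()),
        "removed": int(drop.sum()),
        "retained": int((~drop).sum()),
    }
    if drop.all():
        raise ValueError("QC removed every cell")
    return m.subset_obs(~drop), report


def log_normalize(m: ExpressionMatrix, scale: float = 10000.0) -> ExpressionMatrix:
    """LogNormalize: per cell, count -> ln(1 + scale * count / cell_total)."""
    if m.layer_tag != "counts":
        raise ValueError("log_normalize expects the counts layer")
    total = m.values.sum(axis=0)
    zero = np.flatnonzero(total == 0)
    if zero.size:
        raise ValueError(
            f"cells with zero total counts: {[m.obs_ids[i] for i in zero[:5]]}"
        )
    out = np.log1p(scale * m.values / total)
    return ExpressionMatrix(out, m.gene_ids, m.obs_ids, layer_tag="lognorm")


def _ssgsea_scores(values: np.ndarray, in_set: np.ndarray, alpha: float) -> np.ndarray:
    """Raw ssGSEA statistic per observation (column)."""
    G, n = values.shape
    s = int(in_set.sum())
    out = np.empty(n)
    ranks = stats.rankdata(values, axis=0)  # average ranks, 1..G
    for j in range(n):
        # walk from highest expression to lowest; stable order within ties
        order = np.argsort(-ranks[:, j], kind="stable")
        member = in_set[order]
        w = ranks[order, j] ** alpha
        inc = np.where(member, w, 0.0)
        denom = inc.sum()
        inc = inc / denom
        dec = np.where(member, 0.0, 1.0 / (G - s))
        running = np.cumsum(inc - dec)
        out[j] = running.sum()
    return out


def score_gene_set(
    m: ExpressionMatrix,
    s: GeneSet | list[GeneSet],
    method: str = "ssgsea",
    alpha: float = 0.25,
) -> EnrichmentScores:
    """Score one or more gene sets per observation.

    ``ssgsea``: weighted KS random-walk statistic (see module docstring),
    min–max rescaled across observations to span [-1, 1] per set.
    ``zmean``: mean over set genes of gene-wise z-scored expression;
    zero-variance genes are skipped with a warning.

    Set genes absent from the matrix are dropped with a warning; fewer
    than 2 present genes is an error.
    """
    sets = [s] if isinstance(s, GeneSet) else list(s)
    if method not in ("ssgsea", "zmean"):
        raise ValueError(f"unknown scoring method {method!r}")
    rows = []
    for gs in sets:
        present = gs.intersect(m.gene_ids)
        absent = len(gs) - len(present)
        if absent:
            warnings.warn(
                f"{gs.name}: {absent} set genes absent from matrix", stacklevel=2
            )
        if len(present) < 2:
            raise ValueError(f"{gs.name}: fewer than 2 set genes present in matrix")
        idx = m.gene_index(present)
        in_set = np.zeros(len(m.gene_ids), dtype=bool)
        in_set[idx] = True
        if method == "ssgsea":
            raw = _ssgsea_scores(m.values, in_set, alpha)
            lo, hi = raw.min(), raw.max()
            if hi > lo:
                scores = 2.0 * (raw - lo) / (hi - lo) - 1.0
            else:
                scores = np.zeros_like(raw)
        else:
            sub = m.values[idx]
            sd = sub.std(axis=1, ddof=0)
            ok = sd > 0
            if not ok.any():
                scores = np.zeros(len(m.obs_ids))
            else:
                if (~ok).any():
                    warnings.warn(
                        f"{gs.name}: {int((~ok).sum())} zero-variance genes skipped",
                        stacklevel=2,
                    )
                z = (sub[ok] - sub[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
                scores = z.mean(axis=0)
        rows.append(scores)
    return EnrichmentScores(
        obs_ids=list(m.obs_ids),
        set_names=[gs.name for gs in sets],
        scores=np.vstack(rows),
    )
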