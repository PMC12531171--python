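"""Associations between signature scores and immune features.

Covers feature-wise Spearman correlation with BH FDR, marker-mean
immune-infiltration scores (populations are user-supplied marker sets;
the score is the arithmetic mean of marker expression), median-split
signature x TMB quadrant labels, and pairwise Mann–Whitney group
comparisons.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _stats
from .io import ExpressionMatrix, GeneSet

__all__ = [
    "InfiltrationScores",
    "QuadrantLabel",
    "correlate_score_with_features",
    "marker_infiltration",
    "median_quadrants",
    "compare_groups",
]

QUADRANTS = ("HGHT", "HGLT", "LGHT", "LGLT")


@dataclass
class InfiltrationScores:
    obs_ids: list[str]
    population_names: list[str]
    scores: np.ndarray  # populations x observations

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not self.population_names:
            raise ValueError("need at least one population")
        if self.scores.shape != (len(self.population_names), len(self.obs_ids)):
            raise ValueError("score matrix shape does not match id lists")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite infiltration scores")


@dataclass(frozen=True)
class QuadrantLabel:
    sample_id: str
    label: str  # HGHT / HGLT / LGHT / LGLT


def correlate_score_with_features(
    score: np.ndarray,
    features: ExpressionMatrix | pd.DataFrame,
) -> pd.DataFrame:
    """Spearman correlation of one score vector against every feature row.

    ``features`` is a genes/features x samples matrix aligned to the
    score vector. Returns a DataFrame (feature, spearman_r, p_value,
    fdr); BH adjustment is across features.
    """
    score = np.asarray(score, dtype=float)
    if isinstance(features, ExpressionMatrix):
        names, X = features.gene_ids, features.values
    else:
        names, X = features.index.tolist(), features.to_numpy(dtype=float)
    if X.shape[1] != score.size:
        raise ValueError("features not aligned to score vector")
    if score.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(score) == 0:
        raise ValueError("score vector is constant")
    if score.size > _stats.EXACT_SPEARMAN_MAX:
        r, p = _stats.spearman_matrix(X, score)
    else:
        r = np.empty(X.shape[0])
        p = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            if np.ptp(X[i]) == 0:
                r[i] = p[i] = np.nan
            else:
                r[i], p[i] = _stats.spearman(X[i], score)
    return pd.DataFrame(
        {
            "feature": names,
            "spearman_r": r,
            "p_value": p,
            "fdr": _stats.bh_fdr(p),
        }
    ).set_index("feature", drop=False)


def marker_infiltration(
    m: ExpressionMatrix, marker_sets: list[GeneSet]
) -> InfiltrationScores:
    """Marker-mean abundance per population: arithmetic mean of the
    population's marker genes' expression in each sample. Absent markers
    are dropped with a warning; a population with no present markers is
    skipped with a warning."""
    names: list[str] = []
    rows: list[np.ndarray] = []
    for gs in marker_sets:
        present = gs.intersect(m.gene_ids)
        if not present:
            warnings.warn(f"{gs.name}: no marker genes present; skipped", stacklevel=2)
            continue
        if len(present) < len(gs):
            warnings.warn(
                f"{gs.name}: {len(gs) - len(present)} marker genes absent",
                stacklevel=2,
            )
        names.append(gs.name)
        rows.append(m.values[m.gene_index(present)].mean(axis=0))
    if not names:
        raise ValueError("no population had any marker gene present")
    return InfiltrationScores(list(m.obs_ids), names, np.vstack(rows))


def median_quadrants(
    sig_scores: pd.Series, tmb: pd.Series
) -> list[QuadrantLabel]:
    """Median-split samples on signature score and TMB into four groups.

    "High" means strictly greater than the median; ties go to "low".
    Labels: HGHT (high signature/high TMB), HGLT, LGHT, LGLT.
    """
    if not sig_scores.index.equals(tmb.index):
        tmb = tmb.reindex(sig_scores.index)
        if tmb.isna().any():
            raise ValueError("signature scores and TMB not aligned")
    if len(sig_scores) < 4:
        raise ValueError("need at least 4 samples for a median split")
    for name, v in (("signature score", sig_scores), ("TMB", tmb)):
        if v.nunique() < 2:
            raise ValueError(f"{name} vector is constant; median split undefined")
    med_s = sig_scores.median()
    med_t = tmb.median()
    labels = []
    for sid in sig_scores.index:
        hg = "H" if sig_scores[sid] > med_s else "L"
        ht = "H" if tmb[sid] > med_t else "L"
        labels.append(QuadrantLabel(sample_id=str(sid), label=f"{hg}G{ht}T"))
    return labels


def compare_groups(
    values: np.ndarray, group_labels: np.ndarray
) -> pd.DataFrame:
    """Pairwise two-sided Mann–Whitney tests between groups, BH-adjusted.

    Exact enumeration when both groups have <= 8 samples. Groups with
    fewer than 2 samples are skipped with a warning. Returns a DataFrame
    (group_a, group_b, n_a, n_b, u_statistic, p_value, fdr).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    usable = []
    for g in groups:
        if (labels == g).sum() >= 2:
            usable.append(g)
        else:
            warnings.warn(f"group {g!r} has <2 samples; its pairs are skipped",
                          stacklevel=2)
    if len(usable) < 2:
        raise ValueError("need at least two groups with >= 2 samples")
    rows = []
    for ga, gb in itertools.combinations(usable, 2):
        a = values[labels == ga]
        b = values[labels == gb]
        u, p = _stats.mannwhitney(a, b)
        rows.append((ga, gb, a.size, b.size, u, p))
    df = pd.DataFrame(
        rows, columns=["group_a", "group_b", "n_a", "n_b", "u_statistic", "p_value"]
    )
    df["fdr"] = _stats.bh_fdr(df["p_value"].to_numpy())
    return df
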