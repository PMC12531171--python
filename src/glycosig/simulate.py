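"""Synthetic data generators with recorded ground truth.

Each generator emulates the statistical structure one pipeline stage
assumes — a single-cell dataset in which malignant cells overexpress a
planted gene program tied to a latent glycolysis activity, bulk
immunotherapy cohorts with batch effects and response/survival linked to
signature activity, and CRISPR screens with planted immune-resistance
genes — and returns the generating truth alongside the data so recovery
can be tested. All generators are bit-reproducible given (parameters,
seed); no truth is ever inferred back from the generated data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalRecord, ExpressionMatrix, GeneSet

__all__ = [
    "ScSimTruth",
    "CohortSimTruth",
    "ScreenSimTruth",
    "simulate_sc_dataset",
    "simulate_ici_cohorts",
    "simulate_crispr_screens",
]


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


@dataclass
class ScSimTruth:
    """Ground truth for a simulated single-cell dataset.

    ``corr_strength`` in (0, 1] sets how tightly planted-gene expression
    tracks the latent per-cell glycolysis activity ``a ~ Uniform(0, 1)``:
    planted-gene means in malignant cells are multiplied by
    ``a**corr_strength / E[a**corr_strength]`` (mean-one, so
    ``malignant_logfc`` is the mean log-fold overexpression regardless of
    corr_strength; as corr_strength -> 0 the dependence on ``a``
    vanishes).
    """

    planted_program_genes: GeneSet
    malignant_logfc: float = 1.0
    corr_strength: float = 1.0
    seed: int = 0


@dataclass
class CohortSimTruth:
    """Ground truth for simulated bulk immunotherapy cohorts.

    ``signature_effect`` is the additive shift (log-scale expression
    units) applied to signature genes in non-responders. Batch effects
    are per-(cohort, gene): additive location ~ Normal(0, batch_location_sd)
    and multiplicative scale ~ LogNormal(0, batch_scale_sd). ``true_hr``
    multiplies the exponential event hazard for non-responders.
    """

    signature_effect: float = 1.0
    batch_location_sd: float = 1.0
    batch_scale_sd: float = 0.2
    true_hr: float = 2.0
    nr_fraction: float = 0.5
    baseline_median_os: float = 20.0  # months
    censor_quantile: float = 0.7
    seed: int = 0
    batch_shifts: dict = field(default_factory=dict)  # filled by the generator


@dataclass
class ScreenSimTruth:
    """Ground truth for simulated CRISPR screens."""

    resistance_genes: GeneSet
    lfc_shift: float = -2.0
    n_datasets: int = 10
    missing_rate: float = 0.0
    sgrnas_per_gene: int = 3
    sgrna_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_datasets < 2:
            raise ValueError("need at least 2 screen datasets")
        if self.lfc_shift >= 0:
            warnings.warn(
                "lfc_shift >= 0: planted resistance genes will not rank low",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# Single-cell


def simulate_sc_dataset(
    n_genes: int,
    n_cells: int,
    cell_type_props: dict[str, float],
    truth: ScSimTruth,
    malignant_type: str = "malignant",
    n_patients: int = 4,
    dispersion: float = 0.5,
    base_mean: float = 2.0,
    base_log_sd: float = 1.0,
    libsize_log_sd: float = 0.3,
) -> tuple[ExpressionMatrix, pd.DataFrame, np.ndarray]:
    """Simulate a droplet-style counts matrix with a planted glycolytic program.

    Counts are negative binomial (variance mu + dispersion * mu^2) around
    per-gene log-normal base means times a per-cell log-normal library
    factor. Each cell carries a latent glycolysis activity
    ``a ~ Uniform(0, 1)``; in malignant cells the planted-program genes'
    means are scaled by ``exp(malignant_logfc) * a**c / E[a**c]`` with
    ``c = corr_strength``.

    Returns
    -------
    (counts, annotations, glyc_activity)
        ``annotations`` has columns cell_id, cell_type, malignant,
        patient; ``glyc_activity`` is the latent ``a`` per cell.
    """
    props = dict(cell_type_props)
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("cell type proportions must sum to 1")
    if malignant_type not in props:
        raise ValueError(f"no cell type flagged malignant ({malignant_type!r} missing)")
    rng = _rng(truth.seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    planted = truth.planted_program_genes.genes
    if len(planted) > n_genes:
        raise ValueError("planted program larger than gene universe")
    missing = [g for g in planted if g not in set(gene_ids)]
    if missing:
        raise ValueError(f"planted genes outside simulated universe: {missing[:5]}")

    types = list(props)
    counts_per_type = np.floor(np.array([props[t] for t in types]) * n_cells).astype(int)
    counts_per_type[0] += n_cells - counts_per_type.sum()
    cell_types = np.repeat(types, counts_per_type)
    malignant = cell_types == malignant_type

    base = base_mean * np.exp(rng.normal(0.0, base_log_sd, size=n_genes) - base_log_sd**2 / 2)
    lib = np.exp(rng.normal(0.0, libsize_log_sd, size=n_cells) - libsize_log_sd**2 / 2)
    a = rng.uniform(0.0, 1.0, size=n_cells)

    mu = np.outer(base, lib)  # genes x cells
    p_idx = np.array([gene_ids.index(g) for g in planted])
    c = truth.corr_strength
    mean_ac = 1.0 / (1.0 + c)  # E[a^c] for a ~ U(0,1)
    mult = np.exp(truth.malignant_logfc) * (a[malignant] ** c) / mean_ac
    mu[np.ix_(p_idx, np.flatnonzero(malignant))] *= mult

    r = 1.0 / dispersion  # NB shape so that var = mu + dispersion mu^2
    counts = rng.negative_binomial(r, r / (r + mu))

    obs_ids = [f"C{i:05d}" for i in range(n_cells)]
    annotations = pd.DataFrame(
        {
            "cell_id": obs_ids,
            "cell_type": cell_types,
            "malignant": malignant,
            "patient": [f"P{i % n_patients}" for i in range(n_cells)],
        }
    ).set_index("cell_id", drop=False)
    m = ExpressionMatrix(counts.astype(float), gene_ids, obs_ids, layer_tag="counts")
    return m, annotations, a


# ---------------------------------------------------------------------------
# Bulk ICI cohorts


def simulate_ici_cohorts(
    n_cohorts: int,
    n_per_cohort: int,
    signature: GeneSet,
    truth: CohortSimTruth,
    n_genes: int = 1000,
    gene_ids: list[str] | None = None,
) -> tuple[dict[str, ExpressionMatrix], list[ClinicalRecord]]:
    """Simulate bulk log-scale expression cohorts with response and survival.

    Non-responders' signature genes are shifted up by
    ``truth.signature_effect``; every gene then receives its cohort's
    location/scale batch perturbation. Survival is exponential with the
    non-responder hazard multiplied by ``truth.true_hr`` and
    administrative censoring at the ``censor_quantile`` of event times.
    The realised per-cohort batch perturbations are stored in
    ``truth.batch_shifts``.
    """
    if n_per_cohort < 10:
        raise ValueError("need at least 10 samples per cohort")
    if gene_ids is None:
        extra = [f"B{i:05d}" for i in range(n_genes)]
        gene_ids = list(signature.genes) + extra[: max(0, n_genes - len(signature))]
    gene_ids = [g.upper() for g in gene_ids]
    sig_present = signature.intersect(gene_ids)
    if not sig_present:
        raise ValueError("signature is disjoint from the gene universe")
    rng = _rng(truth.seed)
    G = len(gene_ids)
    base_mu = rng.normal(0.0, 1.0, size=G)
    sig_idx = np.array([gene_ids.index(g) for g in sig_present])

    cohorts: dict[str, ExpressionMatrix] = {}
    records: list[ClinicalRecord] = []
    truth.batch_shifts = {}
    lam0 = np.log(2.0) / truth.baseline_median_os
    all_times: list[np.ndarray] = []
    all_meta: list[tuple[str, np.ndarray]] = []

    for b in range(n_cohorts):
        cohort = f"K{b + 1}"
        nr = rng.random(n_per_cohort) < truth.nr_fraction
        X = base_mu[:, None] + rng.normal(0.0, 1.0, size=(G, n_per_cohort))
        X[np.ix_(sig_idx, np.flatnonzero(nr))] += truth.signature_effect
        gamma = rng.normal(0.0, truth.batch_location_sd, size=G)
        delta = np.exp(rng.normal(0.0, truth.batch_scale_sd, size=G))
        Xb = (X - base_mu[:, None]) * delta[:, None] + base_mu[:, None] + gamma[:, None]
        truth.batch_shifts[cohort] = {"location": gamma, "scale": delta}
        obs = [f"{cohort}S{i:03d}" for i in range(n_per_cohort)]
        cohorts[cohort] = ExpressionMatrix(Xb, gene_ids, obs, layer_tag="lognorm")
        hazard = lam0 * np.where(nr, truth.true_hr, 1.0)
        times = rng.exponential(1.0 / hazard)
        all_times.append(times)
        all_meta.append((cohort, nr))

    censor_at = float(np.quantile(np.concatenate(all_times), truth.censor_quantile))
    for (cohort, nr), times in zip(all_meta, all_times):
        for i, (t, is_nr) in enumerate(zip(times, nr)):
            event = 1 if t <= censor_at else 0
            records.append(
                ClinicalRecord(
                    sample_id=f"{cohort}S{i:03d}",
                    cohort=cohort,
                    response="NR" if is_nr else "R",
                    os_months=float(min(t, censor_at)),
                    event=event,
                )
            )
    return cohorts, records


# ---------------------------------------------------------------------------
# CRISPR screens


def simulate_crispr_screens(
    n_genes: int,
    truth: ScreenSimTruth,
) -> list[pd.DataFrame]:
    """Simulate sgRNA-level log-fold-change tables for several screens.

    Per dataset, each gene has a latent effect ~ Normal(0, 1), shifted by
    ``truth.lfc_shift`` for planted resistance genes; sgRNA LFCs scatter
    around the gene effect with sd ``truth.sgrna_sd``. Each (gene,
    dataset) pair is dropped independently with probability
    ``truth.missing_rate``.
    """
    rng = _rng(truth.seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    planted = truth.resistance_genes.genes
    missing = [g for g in planted if g not in set(gene_ids)]
    if missing:
        raise ValueError(f"resistance genes outside simulated universe: {missing[:5]}")
    p_idx = np.array([gene_ids.index(g) for g in planted])

    tables: list[pd.DataFrame] = []
    for d in range(truth.n_datasets):
        effect = rng.normal(0.0, 1.0, size=n_genes)
        effect[p_idx] += truth.lfc_shift
        keep = rng.random(n_genes) >= truth.missing_rate
        rows = []
        for gi in np.flatnonzero(keep):
            for s in range(truth.sgrnas_per_gene):
                rows.append(
                    (
                        f"D{d + 1}",
                        gene_ids[gi],
                        f"{gene_ids[gi]}_sg{s + 1}",
                        effect[gi] + rng.normal(0.0, truth.sgrna_sd),
                    )
                )
        tables.append(
            pd.DataFrame(rows, columns=["dataset", "gene", "sgrna", "lfc"])
        )
    return tables
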