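"""Multi-dataset CRISPR screen integration and resistance-gene ranking.

Per screen dataset: sgRNA log-fold changes are averaged per gene, then
Z-normalized within the dataset for cross-dataset comparability. Genes
are ranked by the average Z across the datasets in which they were
measured (missing (gene, dataset) pairs are simply skipped); more
negative mean Z indicates a stronger immune-resistance candidate, since
guides against such genes deplete under immune pressure. Top-fraction
sets use the floor rule (for a 22,505-gene universe, the top 5%/10%/20%
contain 1,125 / 2,250 / 4,501 genes), and signature enrichment among the
top-ranked genes is tested with the one-sided hypergeometric (Fisher)
tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _stats
from .io import GeneSet

__all__ = [
    "ScreenZTable",
    "RankedGene",
    "gene_level_lfc",
    "zscore_normalize",
    "aggregate_rank",
    "top_fraction",
    "enrichment_test",
]


@dataclass
class ScreenZTable:
    dataset_id: str
    z: pd.Series  # gene -> z, mean 0 / sample sd 1 over recorded genes

    def __post_init__(self) -> None:
        vals = self.z.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"{self.dataset_id}: non-finite Z values")
        if vals.size >= 2:
            if abs(vals.mean()) > 1e-9 or abs(vals.std(ddof=1) - 1.0) > 1e-9:
                raise ValueError(f"{self.dataset_id}: Z values not standardized")

    @property
    def n_genes(self) -> int:
        return len(self.z)


@dataclass(frozen=True)
class RankedGene:
    gene: str
    mean_z: float
    n_datasets_present: int
    rank: int  # 1 = lowest mean Z = strongest resistance candidate
    percentile: float


def gene_level_lfc(screen_table: pd.DataFrame) -> pd.Series:
    """Collapse sgRNA rows to genes: arithmetic mean of sgRNA LFCs.

    Expects columns ``gene`` and ``lfc`` (extra columns such as
    ``dataset``/``sgrna`` are ignored).
    """
    for col in ("gene", "lfc"):
        if col not in screen_table.columns:
            raise ValueError(f"screen table missing column {col!r}")
    tbl = screen_table.assign(gene=screen_table["gene"].str.upper())
    return tbl.groupby("gene", sort=True)["lfc"].mean()


def zscore_normalize(gene_lfc: pd.Series, dataset_id: str) -> ScreenZTable:
    """Standardize a dataset's gene-level LFCs: z = (lfc - mean) / sample sd."""
    vals = gene_lfc.to_numpy(dtype=float)
    if vals.size < 2:
        raise ValueError(f"{dataset_id}: need at least 2 genes")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError(f"{dataset_id}: constant LFC vector cannot be standardized")
    return ScreenZTable(dataset_id=dataset_id, z=(gene_lfc - vals.mean()) / sd)


def aggregate_rank(
    tables: list[ScreenZTable], min_presence: int = 1
) -> list[RankedGene]:
    """Rank genes by mean Z across the datasets that recorded them.

    Genes present in fewer than ``min_presence`` datasets are excluded.
    Sorted ascending by mean Z; equal means are broken lexicographically
    by gene symbol. Output is independent of dataset order.
    """
    if not tables:
        raise ValueError("need at least one Z table")
    wide = pd.DataFrame({t.dataset_id: t.z for t in tables})
    wide = wide[sorted(wide.columns)]  # order-independent summation
    wide = wide.sort_index()
    if wide.empty:
        raise ValueError("union of screen genes is empty")
    presence = wide.notna().sum(axis=1)
    wide = wide.loc[presence >= min_presence]
    if wide.empty:
        raise ValueError("no gene meets the min_presence requirement")
    mean_z = wide.mean(axis=1, skipna=True)
    order = sorted(mean_z.index, key=lambda g: (mean_z[g], g))
    n = len(order)
    return [
        RankedGene(
            gene=g,
            mean_z=float(mean_z[g]),
            n_datasets_present=int(presence[g]),
            rank=i + 1,
            percentile=(i + 1) / n,
        )
        for i, g in enumerate(order)
    ]


def top_fraction(ranked: list[RankedGene], frac: float, name: str | None = None) -> GeneSet:
    """The first floor(frac * N) genes of the ascending mean-Z ranking."""
    if not (0.0 < frac < 1.0):
        raise ValueError("frac must be in (0, 1)")
    k = int(np.floor(frac * len(ranked)))
    if k == 0:
        raise ValueError(f"top fraction {frac} of {len(ranked)} genes is empty")
    genes = tuple(r.gene for r in sorted(ranked, key=lambda r: r.rank)[:k])
    return GeneSet(name=name or f"TOP_{frac:g}", genes=genes)


def enrichment_test(
    signature: GeneSet,
    top: GeneSet,
    universe: GeneSet,
    sided: str = "greater",
) -> tuple[int, float, float]:
    """Fisher's exact test for signature enrichment among top-ranked genes.

    The signature is restricted to the universe before testing; ``top``
    must be a subset of the universe. Returns (overlap k, proportion of
    the restricted signature found in top, p). ``sided="greater"`` uses
    the hypergeometric upper tail; ``"two-sided"`` uses Fisher's exact
    test on the 2x2 table.
    """
    uni = set(universe.genes)
    top_genes = set(top.genes)
    if not top_genes <= uni:
        raise ValueError("top set is not contained in the universe")
    sig = set(signature.genes) & uni
    if not sig:
        raise ValueError("signature has no genes in the universe")
    k = len(sig & top_genes)
    proportion = k / len(sig)
    if sided == "greater":
        p = _stats.hypergeom_enrichment_p(k, len(uni), len(sig), len(top_genes))
    elif sided == "two-sided":
        table = [
            [k, len(sig) - k],
            [len(top_genes) - k, len(uni) - len(sig) - len(top_genes) + k],
        ]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        raise ValueError("sided must be 'greater' or 'two-sided'")
    return k, proportion, p
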