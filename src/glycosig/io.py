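"""Readers and writers for the plain-text formats the pipeline touches.

Conventions enforced at ingest:

* expression matrices are **genes in rows, observations in columns**,
  with unique identifiers on both axes;
* gene symbols are upper-cased everywhere, and all cross-table joins are
  by exact symbol match;
* missing values in clinical tables are encoded as the empty string or
  ``"NA"`` — no other sentinel is accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "ClinicalRecord",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "clinical_frame",
]

_LAYERS = ("counts", "lognorm", "adjusted")
_RESPONSES = ("R", "NR", "NA")


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered, deduplicated set of upper-case gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(str(g).upper(), None)
        if not seen:
            raise ValueError(f"gene set {self.name!r} is empty after deduplication")
        object.__setattr__(self, "genes", tuple(seen))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def intersect(self, symbols: Iterable[str]) -> tuple[str, ...]:
        """Members present in ``symbols``, preserving this set's order."""
        pool = {str(s).upper() for s in symbols}
        return tuple(g for g in self.genes if g in pool)


class ExpressionMatrix:
    """Genes x observations numeric matrix with unique ids on both axes.

    Parameters
    ----------
    values
        2-D numeric array, one row per gene.
    gene_ids, obs_ids
        Unique identifiers; gene symbols are upper-cased.
    layer_tag
        ``counts`` (raw, non-negative), ``lognorm`` or ``adjusted``.
    """

    def __init__(
        self,
        values: np.ndarray | pd.DataFrame,
        gene_ids: Sequence[str] | None = None,
        obs_ids: Sequence[str] | None = None,
        layer_tag: str = "counts",
    ) -> None:
        if isinstance(values, pd.DataFrame):
            gene_ids = values.index.tolist() if gene_ids is None else gene_ids
            obs_ids = values.columns.tolist() if obs_ids is None else obs_ids
            values = values.to_numpy()
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if gene_ids is None or obs_ids is None:
            raise ValueError("gene_ids and obs_ids are required")
        genes = [str(g).upper() for g in gene_ids]
        obs = [str(o) for o in obs_ids]
        for label, ids in (("gene", genes), ("observation", obs)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise ValueError(f"duplicate {label} ids: {dupes}")
        if arr.shape != (len(genes), len(obs)):
            raise ValueError(
                f"value matrix shape {arr.shape} does not match "
                f"{len(genes)} genes x {len(obs)} observations"
            )
        if layer_tag not in _LAYERS:
            raise ValueError(f"layer_tag must be one of {_LAYERS}, got {layer_tag!r}")
        if layer_tag == "counts":
            if not np.all(np.isfinite(arr)):
                raise ValueError("counts layer contains non-finite entries")
            if (arr < 0).any():
                raise ValueError("counts layer contains negative entries")
        self.values = arr
        self.gene_ids = genes
        self.obs_ids = obs
        self.layer_tag = layer_tag

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.obs_ids)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lut[str(g).upper()] for g in genes], dtype=int)

    def subset_obs(self, obs: Sequence[str] | np.ndarray) -> "ExpressionMatrix":
        if isinstance(obs, np.ndarray) and obs.dtype == bool:
            idx = np.flatnonzero(obs)
        else:
            lut = {o: i for i, o in enumerate(self.obs_ids)}
            idx = np.array([lut[str(o)] for o in obs], dtype=int)
        return ExpressionMatrix(
            self.values[:, idx],
            self.gene_ids,
            [self.obs_ids[i] for i in idx],
            layer_tag=self.layer_tag,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({len(self.gene_ids)} genes x "
            f"{len(self.obs_ids)} obs, layer={self.layer_tag})"
        )


@dataclass
class ClinicalRecord:
    """One sample's clinical annotation for the immunotherapy analyses."""

    sample_id: str
    cohort: str
    response: str  # "R", "NR" or "NA"
    os_months: float | None = None
    event: int | None = None
    tmb: float | None = None
    ith: float | None = None

    def __post_init__(self) -> None:
        if self.response not in _RESPONSES:
            raise ValueError(
                f"sample {self.sample_id}: response {self.response!r} not in {_RESPONSES}"
            )
        if self.os_months is not None:
            if self.os_months < 0:
                raise ValueError(f"sample {self.sample_id}: negative os_months")
            if self.event is None:
                raise ValueError(
                    f"sample {self.sample_id}: os_months given without event flag"
                )
        if self.event is not None and self.event not in (0, 1):
            raise ValueError(f"sample {self.sample_id}: event must be 0 or 1")
        if self.tmb is not None and self.tmb < 0:
            raise ValueError(f"sample {self.sample_id}: negative tmb")
        if self.ith is not None and not (0.0 <= self.ith <= 1.0):
            raise ValueError(f"sample {self.sample_id}: ith outside [0, 1]")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse an MSigDB-dialect GMT file (name, description, genes...)."""
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
            )
        name, _desc, *genes = fields
        genes = [g for g in genes if g.strip()]
        if not genes:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
        sets.append(GeneSet(name=name, genes=tuple(genes)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path, description: str = "na") -> None:
    lines = ["\t".join([s.name, description, *s.genes]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression(
    path: str | Path,
    format: str = "tsv",
    layer_tag: str = "counts",
    genes_path: str | Path | None = None,
    obs_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x observations matrix from dense TSV/CSV or sparse MTX.

    For ``format="mtx"`` the row (gene) and column (observation) names are
    read from sidecar text files, one id per line, defaulting to
    ``<stem>.genes.txt`` / ``<stem>.obs.txt`` next to the matrix file.
    """
    path = Path(path)
    if format == "tsv":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        bad = df.map(lambda v: not isinstance(v, (int, float, np.integer, np.floating)))
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"{path}: non-numeric value at gene {df.index[r]!r}, "
                f"observation {df.columns[c]!r}"
            )
        return ExpressionMatrix(df, layer_tag=layer_tag)
    if format == "mtx":
        genes_path = genes_path or path.with_suffix("").with_suffix(".genes.txt")
        obs_path = obs_path or path.with_suffix("").with_suffix(".obs.txt")
        mat = scipy.io.mmread(str(path))
        genes = Path(genes_path).read_text().split()
        obs = Path(obs_path).read_text().split()
        return ExpressionMatrix(
            np.asarray(scipy.sparse.coo_matrix(mat).todense()),
            genes,
            obs,
            layer_tag=layer_tag,
        )
    raise ValueError(f"unknown expression format {format!r}")


def write_expression(
    m: ExpressionMatrix,
    path: str | Path,
    format: str = "tsv",
) -> None:
    path = Path(path)
    if format == "tsv":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        m.to_frame().to_csv(path, sep=sep, float_format="%.10g")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(m.values))
        path.with_suffix("").with_suffix(".genes.txt").write_text(
            "\n".join(m.gene_ids) + "\n"
        )
        path.with_suffix("").with_suffix(".obs.txt").write_text(
            "\n".join(m.obs_ids) + "\n"
        )
    else:
        raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# Clinical tables

_REQUIRED_CLINICAL = ("sample_id", "cohort", "response")
_OPTIONAL_CLINICAL = ("os_months", "event", "tmb", "ith")


def _parse_na(value, caster):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    if s in ("", "NA"):
        return None
    return caster(s)


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read a clinical TSV into validated records.

    Required columns: sample_id, cohort, response; optional: os_months,
    event, tmb, ith. Empty string and "NA" are the only missing sentinels.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _REQUIRED_CLINICAL:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    records = []
    for _, row in df.iterrows():
        resp = row["response"].strip() or "NA"
        records.append(
            ClinicalRecord(
                sample_id=row["sample_id"],
                cohort=row["cohort"],
                response=resp,
                os_months=_parse_na(row.get("os_months"), float),
                event=_parse_na(row.get("event"), lambda s: int(float(s))),
                tmb=_parse_na(row.get("tmb"), float),
                ith=_parse_na(row.get("ith"), float),
            )
        )
    return records


def clinical_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Records as a DataFrame indexed by sample_id (NA -> NaN)."""
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "cohort": [r.cohort for r in records],
            "response": [r.response for r in records],
            "os_months": [np.nan if r.os_months is None else r.os_months for r in records],
            "event": [np.nan if r.event is None else r.event for r in records],
            "tmb": [np.nan if r.tmb is None else r.tmb for r in records],
            "ith": [np.nan if r.ith is None else r.ith for r in records],
        }
    )
    return df.set_index("sample_id", drop=False)


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    def fmt(v):
        return "NA" if v is None else (f"{v:.10g}" if isinstance(v, float) else str(v))

    lines = ["\t".join(_REQUIRED_CLINICAL + _OPTIONAL_CLINICAL)]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.sample_id,
                    r.cohort,
                    r.response,
                    fmt(r.os_months),
                    fmt(r.event),
                    fmt(r.tmb),
                    fmt(r.ith),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
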