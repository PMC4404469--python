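"""Cq data containers, delimited-text I/O, sample QC and technical-replicate handling.

The quantification cycle (Cq) is the PCR cycle at which a reaction's
fluorescence crosses the detection threshold; lower Cq means more abundant
template.  A run produces a genes x samples table of Cq values in which an
entry may be *missing* (no amplification by the final cycle).  This module
owns that container (:class:`CqTable`), the per-sample annotations that
accompany it, RNA-quality filtering, and the averaging of qPCR technical
replicates into one value per biological sample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CqTable",
    "CqParseError",
    "CqValidationError",
    "QcReport",
    "read_cq_table",
    "write_cq_table",
    "qc_filter_samples",
    "aggregate_technical_replicates",
    "summarize_cq_distribution",
]

#: Cell contents treated as "no amplification" when reading delimited text.
MISSING_SENTINELS = {"", "na", "n/a", "nan", "undetermined", "undet", "no cq"}

#: Per-sample annotation columns recognised in long-layout files and sidecars.
METADATA_COLUMNS = [
    "tissue",
    "treatment",
    "temperature",
    "week",
    "bio_rep",
    "tech_rep",
    "rqi",
    "a260_280",
]

_NUMERIC_META = ["temperature", "week", "bio_rep", "tech_rep", "rqi", "a260_280"]

#: Columns that jointly identify one biological sample (technical replicates
#: of the same RNA share all of these).
REPLICATE_KEY = ["tissue", "treatment", "temperature", "week", "bio_rep"]


class CqParseError(ValueError):
    """A delimited Cq file could not be parsed (bad header or cell)."""


class CqValidationError(ValueError):
    """Parsed Cq data violates a structural invariant."""


@dataclass
class CqTable:
    """Genes x samples matrix of quantification-cycle values.

    Parameters
    ----------
    cq : pandas.DataFrame
        Rows are genes, columns are samples; ``NaN`` marks a missing entry
        (no amplification by ``max_cycles``).
    max_cycles : float
        Final PCR cycle of the run; all present Cq values must lie in
        ``(0, max_cycles]``.
    """

    cq: pd.DataFrame
    max_cycles: float = 40.0

    def __post_init__(self) -> None:
        cq = pd.DataFrame(self.cq).astype(float)
        if cq.index.has_duplicates:
            dupes = cq.index[cq.index.duplicated()].tolist()
            raise CqValidationError(f"duplicated gene identifiers: {dupes}")
        if cq.columns.has_duplicates:
            dupes = cq.columns[cq.columns.duplicated()].tolist()
            raise CqValidationError(f"duplicated sample identifiers: {dupes}")
        if self.max_cycles <= 0:
            raise CqValidationError("max_cycles must be positive")
        vals = cq.to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if present.any():
            pv = vals[present]
            if not np.isfinite(pv).all():
                raise CqValidationError("Cq values must be finite")
            if ((pv <= 0) | (pv > self.max_cycles)).any():
                raise CqValidationError(
                    f"Cq values must lie in (0, {self.max_cycles}]"
                )
        # axis labels carry no information; normalising them makes
        # write/read round-trips exact
        cq.index.name = None
        cq.columns.name = None
        self.cq = cq

    @property
    def genes(self) -> list:
        return list(self.cq.index)

    @property
    def samples(self) -> list:
        return list(self.cq.columns)

    @property
    def n_missing(self) -> int:
        return int(self.cq.isna().to_numpy().sum())

    def subset_samples(self, samples: Sequence) -> "CqTable":
        """Return a new table restricted to ``samples`` (order preserved)."""
        missing = [s for s in samples if s not in self.cq.columns]
        if missing:
            raise CqValidationError(f"unknown sample identifiers: {missing}")
        return CqTable(self.cq.loc[:, list(samples)], max_cycles=self.max_cycles)


def _parse_cq_cell(raw: str, row_number: int) -> float:
    s = str(raw).strip()
    if s.lower() in MISSING_SENTINELS:
        return np.nan
    try:
        return float(s)
    except ValueError:
        raise CqParseError(
            f"non-numeric Cq value {raw!r} at row {row_number}"
        ) from None


def _read_long(path: Path) -> tuple[CqTable, pd.DataFrame]:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    df.columns = [str(c).strip() for c in df.columns]
    for col in ("gene", "sample", "cq"):
        if col not in df.columns:
            raise CqParseError(f"missing required column '{col}' in {path}")
    # +2: one for the header line, one for 1-based numbering.
    cq_vals = [
        _parse_cq_cell(v, i + 2) for i, v in enumerate(df["cq"].tolist())
    ]
    dup = df.duplicated(subset=["gene", "sample"], keep=False)
    if dup.any():
        pairs = sorted(set(map(tuple, df.loc[dup, ["gene", "sample"]].to_numpy())))
        raise CqValidationError(f"duplicated (gene, sample) measurements: {pairs}")
    genes = list(dict.fromkeys(df["gene"]))
    samples = list(dict.fromkeys(df["sample"]))
    wide = pd.DataFrame(np.nan, index=genes, columns=samples)
    for g, s, v in zip(df["gene"], df["sample"], cq_vals):
        wide.at[g, s] = v

    meta_cols = [c for c in METADATA_COLUMNS if c in df.columns]
    meta = _build_meta(df[["sample"] + meta_cols], samples)
    return CqTable(wide), meta


def _build_meta(df: pd.DataFrame, samples: Sequence) -> pd.DataFrame:
    meta = df.drop_duplicates()
    if meta["sample"].duplicated().any():
        bad = sorted(set(meta.loc[meta["sample"].duplicated(), "sample"]))
        raise CqValidationError(f"conflicting metadata for samples: {bad}")
    meta = meta.set_index("sample").reindex(samples)
    for col in meta.columns:
        if col in _NUMERIC_META:
            cleaned = meta[col].map(
                lambda v: np.nan
                if str(v).strip().lower() in MISSING_SENTINELS
                else v
            )
            meta[col] = pd.to_numeric(cleaned)
    return meta


def _read_wide(path: Path, meta_path) -> tuple[CqTable, pd.DataFrame]:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False, index_col=0)
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for i, (_, row) in enumerate(df.iterrows()):
        for col in df.columns:
            parsed.at[row.name, col] = _parse_cq_cell(row[col], i + 2)
    if meta_path is not None:
        mdf = pd.read_csv(meta_path, dtype=str, keep_default_na=False)
        mdf.columns = [str(c).strip() for c in mdf.columns]
        if "sample" not in mdf.columns:
            raise CqParseError(f"missing required column 'sample' in {meta_path}")
        keep = ["sample"] + [c for c in METADATA_COLUMNS if c in mdf.columns]
        meta = _build_meta(mdf[keep], list(parsed.columns))
    else:
        meta = pd.DataFrame(index=pd.Index(list(parsed.columns), name="sample"))
    return CqTable(parsed), meta


def read_cq_table(path, layout: str = "long", meta_path=None) -> tuple[CqTable, pd.DataFrame]:
    """Read a delimited Cq file and its sample metadata.

    Parameters
    ----------
    path : path-like
        CSV/TSV file.  ``layout="long"`` expects columns ``gene, sample, cq``
        plus optional metadata columns; ``layout="wide"`` expects a genes x
        samples matrix with gene identifiers in the first column and sample
        metadata in a sidecar file (``meta_path``).
    layout : {"long", "wide"}
    meta_path : path-like, optional
        Sidecar metadata CSV for the wide layout (columns ``sample`` plus
        any of ``tissue, treatment, temperature, week, bio_rep, tech_rep,
        rqi, a260_280``).

    Returns
    -------
    (CqTable, pandas.DataFrame)
        The validated table and a metadata frame indexed by sample id.
        Empty cells and the sentinels ``NA``/``Undetermined`` become missing
        entries.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "long":
        return _read_long(path)
    if layout == "wide":
        return _read_wide(path, meta_path)
    raise ValueError(f"unknown layout {layout!r}; expected 'long' or 'wide'")


def write_cq_table(table: CqTable, path, meta: pd.DataFrame | None = None,
                   layout: str = "wide", meta_path=None) -> None:
    """Write a :class:`CqTable` (and optionally its metadata) to CSV.

    The wide layout round-trips bit-exactly through :func:`read_cq_table`
    (floats are written with ``repr`` precision, missing entries as ``NA``).
    """
    path = Path(path)
    if layout == "wide":
        out = table.cq.copy()
        out.index.name = "gene"
        out.to_csv(path, na_rep="NA")
        if meta is not None and meta_path is not None:
            m = meta.copy()
            m.index.name = "sample"
            m.to_csv(meta_path, na_rep="NA")
    elif layout == "long":
        long = table.cq.stack(future_stack=True).rename("cq").reset_index()
        long.columns = ["gene", "sample", "cq"]
        if meta is not None:
            long = long.merge(meta, left_on="sample", right_index=True, how="left")
        long.to_csv(path, index=False, na_rep="NA")
    else:
        raise ValueError(f"unknown layout {layout!r}")


@dataclass
class QcReport:
    """Outcome of RNA-quality filtering: an exhaustive, disjoint partition."""

    kept: list
    rejected: dict  # sample id -> list of reason codes
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kept": list(self.kept),
            "rejected": {str(k): list(v) for k, v in self.rejected.items()},
            "thresholds": dict(self.thresholds),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def qc_filter_samples(meta: pd.DataFrame, rqi_min: float = 7.0,
                      ratio_low: float = 1.9, ratio_high: float = 2.1,
                      missing_policy: str = "reject") -> QcReport:
    """Partition samples into kept/rejected by RNA-quality thresholds.

    A sample is kept iff its RNA Quality Indicator exceeds ``rqi_min``
    (strictly) and its A260/280 absorbance ratio lies in
    ``[ratio_low, ratio_high]``.  Defaults follow common practice for
    RT-qPCR input RNA (RQI above 7, ratio between 1.9 and 2.1).

    Rejections carry machine-readable reason codes: ``"rqi"``, ``"ratio"``,
    or ``"missing_qc"`` (a QC field absent; policy configurable via
    ``missing_policy`` = ``"reject"`` or ``"keep"``).
    """
    if missing_policy not in ("reject", "keep"):
        raise ValueError("missing_policy must be 'reject' or 'keep'")
    kept, rejected = [], {}
    for sample in meta.index:
        row = meta.loc[sample]
        rqi = row.get("rqi", np.nan)
        ratio = row.get("a260_280", np.nan)
        reasons = []
        missing = pd.isna(rqi) or pd.isna(ratio)
        if missing:
            if missing_policy == "reject":
                reasons.append("missing_qc")
        if not pd.isna(rqi) and not rqi > rqi_min:
            reasons.append("rqi")
        if not pd.isna(ratio) and not (ratio_low <= ratio <= ratio_high):
            reasons.append("ratio")
        if reasons:
            rejected[sample] = reasons
        else:
            kept.append(sample)
    return QcReport(
        kept=kept,
        rejected=rejected,
        thresholds={
            "rqi_min": rqi_min,
            "ratio_low": ratio_low,
            "ratio_high": ratio_high,
            "missing_policy": missing_policy,
        },
    )


def _fmt_key(value) -> str:
    if isinstance(value, float) and float(value).is_integer():
        return str(int(value))
    return str(value)


def aggregate_technical_replicates(
    table: CqTable, meta: pd.DataFrame, tolerance: float = 1.0
) -> tuple[CqTable, pd.DataFrame]:
    """Average qPCR technical replicates into one column per biological sample.

    Technical replicates are samples sharing all of
    ``tissue, treatment, temperature, week, bio_rep`` (whichever of those
    columns the metadata carries).  Each aggregated entry is the arithmetic
    mean of the present replicate Cq values; a group with no present value
    stays missing.  Replicates of one biological sample disagreeing by more
    than ``tolerance`` cycles trigger a warning (instrument-level
    repeatability is usually well under one cycle), never an error.

    Returns the aggregated table and a metadata frame with one row per
    biological sample (the ``tech_rep`` column dropped).
    """
    key_cols = [c for c in REPLICATE_KEY if c in meta.columns]
    if not key_cols:
        raise CqValidationError(
            "metadata has none of the replicate-identifying columns "
            f"{REPLICATE_KEY}"
        )
    missing = [s for s in table.samples if s not in meta.index]
    if missing:
        raise CqValidationError(f"samples missing from metadata: {missing}")
    meta = meta.loc[table.samples]

    groups: dict[tuple, list] = {}
    for sample in table.samples:
        key = tuple(meta.at[sample, c] for c in key_cols)
        groups.setdefault(key, []).append(sample)

    new_cols, new_meta_rows, new_ids = [], [], []
    for key, members in groups.items():
        new_id = "_".join(_fmt_key(v) for v in key)
        sub = table.cq[members]
        spread = sub.max(axis=1) - sub.min(axis=1)
        discordant = spread[spread > tolerance]
        if len(discordant):
            warnings.warn(
                f"technical replicates of '{new_id}' disagree by more than "
                f"{tolerance} cycles for genes: {list(discordant.index)}",
                stacklevel=2,
            )
        new_cols.append(sub.mean(axis=1, skipna=True))
        row = meta.loc[members[0]].drop(labels=["tech_rep"], errors="ignore")
        new_meta_rows.append(row)
        new_ids.append(new_id)
    if len(set(new_ids)) != len(new_ids):
        raise CqValidationError("replicate keys do not uniquely name samples")

    agg = pd.concat(new_cols, axis=1)
    agg.columns = new_ids
    out_meta = pd.DataFrame(new_meta_rows)
    out_meta.index = pd.Index(new_ids, name="sample")
    return CqTable(agg, max_cycles=table.max_cycles), out_meta


def summarize_cq_distribution(table: CqTable) -> pd.DataFrame:
    """Per-gene summary of the Cq distribution over all present values.

    Returns a frame indexed by gene with columns ``n, min, p5, q1, median,
    q3, p95, max``.  Percentiles use linear interpolation between order
    statistics.  Genes with no present value are omitted with a warning.
    """
    rows = {}
    for gene in table.genes:
        vals = table.cq.loc[gene].dropna().to_numpy()
        if vals.size == 0:
            warnings.warn(f"gene '{gene}' has no present Cq value; omitted",
                          stacklevel=2)
            continue
        p5, q1, med, q3, p95 = np.percentile(
            vals, [5, 25, 50, 75, 95], method="linear"
        )
        rows[gene] = {
            "n": vals.size,
            "min": vals.min(),
            "p5": p5,
            "q1": q1,
            "median": med,
            "q3": q3,
            "p95": p95,
            "max": vals.max(),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    return out
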