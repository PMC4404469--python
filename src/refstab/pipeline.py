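"""End-to-end orchestration: QC -> transform -> geNorm + NormFinder -> consensus.

A pipeline run reads a Cq table with metadata, QC-filters samples, averages
technical replicates, then analyses one or more *panels* (named sample
subsets defined by metadata filters, e.g. leaves only, or all samples) and
writes per-panel CSV/JSON reports.  Panels are plain config-defined filters
so datasets from other organisms or designs work unchanged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .consensus import ConsensusRanking, consensus_rank
from .curves import fit_standard_curve
from .data import (
    CqTable,
    QcReport,
    aggregate_technical_replicates,
    qc_filter_samples,
    read_cq_table,
    summarize_cq_distribution,
)
from .genorm import GeNormResult, genorm_analysis
from .normfinder import NormFinderResult, grouped_stability, log_transform, ungrouped_stability
from .quantities import cq_to_quantities

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "PanelReport",
    "default_panels",
    "run_pipeline",
    "export_tables",
]

logger = logging.getLogger("refstab")


class PipelineError(RuntimeError):
    pass


def default_panels() -> dict:
    """Panels mirroring the emulated study: per-tissue/treatment subsets
    plus the heterogeneous all-samples panel."""
    return {
        "leaves": {"tissue": "leaves", "treatment": "control", "temperature": 20},
        "stems": {"tissue": "stems"},
        "pgpr_leaves": {"tissue": "leaves", "treatment": "PGPR"},
        "seeds_flowers": {"tissue": ["seeds", "flowers"]},
        "temperature": {"tissue": "leaves", "temperature": [15, 25]},
        "all": {},
    }


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    input: str
    layout: str = "long"
    meta: str | None = None  # sidecar metadata for wide layout
    efficiency_source: str = "default"  # default | per_gene_table | standard_curves
    efficiencies: str | Mapping | None = None  # path or mapping, per source
    missing_policy: str = "drop"  # drop | impute
    rqi_min: float = 7.0
    ratio_low: float = 1.9
    ratio_high: float = 2.1
    qc_missing_policy: str = "reject"
    tech_rep_tolerance: float = 1.0
    group_by: str = "tissue"
    v_cutoff: float = 0.15
    panels: Mapping | None = None
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layout not in ("long", "wide"):
            raise ValueError("layout must be 'long' or 'wide'")
        if self.efficiency_source not in ("default", "per_gene_table", "standard_curves"):
            raise ValueError(
                "efficiency_source must be 'default', 'per_gene_table' or "
                "'standard_curves'"
            )
        if self.missing_policy not in ("drop", "impute"):
            raise ValueError("missing_policy must be 'drop' or 'impute'")
        if self.panels is None:
            self.panels = default_panels()
        self.panels = {str(k): dict(v) for k, v in self.panels.items()}
        if not self.panels:
            raise ValueError("at least one panel is required")

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {unknown}")
        if "input" not in data:
            raise ValueError("configuration requires an 'input' path")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, Mapping):
            raise ValueError(f"configuration file {path} must hold a mapping")
        return cls.from_dict(data)


@dataclass
class PanelReport:
    """All artefacts computed for one sample panel."""

    name: str
    samples: list
    qc: QcReport
    cq_summary: pd.DataFrame
    genorm: GeNormResult
    normfinder: NormFinderResult
    consensus: ConsensusRanking
    top2: dict  # method -> two most stable genes

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "samples": list(self.samples),
            "qc": self.qc.to_dict(),
            "cq_summary": self.cq_summary.reset_index().to_dict(orient="records"),
            "genorm": self.genorm.to_dict(),
            "normfinder": self.normfinder.to_dict(),
            "consensus": self.consensus.to_dict(),
            "top2": {k: list(v) for k, v in self.top2.items()},
        }


def _panel_samples(meta: pd.DataFrame, filt: Mapping, name: str) -> list:
    mask = pd.Series(True, index=meta.index)
    for column, wanted in filt.items():
        if column not in meta.columns:
            raise PipelineError(
                f"panel '{name}' filters on unknown metadata column {column!r}"
            )
        values = wanted if isinstance(wanted, (list, tuple, set)) else [wanted]
        mask &= meta[column].isin(list(values))
    return list(meta.index[mask])


def _load_efficiencies(config: PipelineConfig, genes) -> float | pd.Series:
    if config.efficiency_source == "default":
        return 2.0
    if config.efficiencies is None:
        raise PipelineError(
            f"efficiency_source={config.efficiency_source!r} needs 'efficiencies'"
        )
    if config.efficiency_source == "per_gene_table":
        if isinstance(config.efficiencies, Mapping):
            table = pd.Series(config.efficiencies, dtype=float)
        else:
            df = pd.read_csv(config.efficiencies)
            if not {"gene", "efficiency_percent"} <= set(df.columns):
                raise PipelineError(
                    "per-gene efficiency table needs columns "
                    "'gene' and 'efficiency_percent'"
                )
            table = df.set_index("gene")["efficiency_percent"].astype(float)
        return 1.0 + table / 100.0  # percent -> amplification factor
    # standard_curves: CSV of (gene, log10_dilution, cq)
    df = pd.read_csv(config.efficiencies)
    needed = {"gene", "log10_dilution", "cq"}
    if not needed <= set(df.columns):
        raise PipelineError(
            "standard-curve table needs columns 'gene', 'log10_dilution', 'cq'"
        )
    factors = {}
    for gene, sub in df.groupby("gene"):
        curve = fit_standard_curve(
            sub[["log10_dilution", "cq"]].to_numpy(), gene_id=str(gene)
        )
        factors[gene] = curve.amplification_factor
        logger.info(
            "standard curve %s: slope=%.4f r2=%.4f E=%.1f%%",
            gene, curve.slope, curve.r_squared, curve.efficiency_percent,
        )
    return pd.Series(factors)


def _analyze_panel(
    name: str,
    table: CqTable,
    meta: pd.DataFrame,
    qc: QcReport,
    config: PipelineConfig,
    efficiencies,
) -> PanelReport:
    summary = summarize_cq_distribution(table)
    quantities = cq_to_quantities(
        table, efficiencies=efficiencies, missing=config.missing_policy
    )
    genorm = genorm_analysis(quantities, cutoff=config.v_cutoff)

    logy = log_transform(quantities)
    groups = None
    if config.group_by in meta.columns:
        labels = meta.loc[quantities.samples, config.group_by]
        counts = labels.value_counts()
        if len(counts) >= 2 and (counts >= 2).all():
            groups = labels
    if groups is not None:
        normfinder = grouped_stability(logy, groups)
        logger.info("panel %s: grouped NormFinder by %r (%d groups)",
                    name, config.group_by, groups.nunique())
    else:
        normfinder = ungrouped_stability(logy)
        logger.info("panel %s: ungrouped NormFinder", name)

    # geNorm's final pair is passed to the consensus as a tie.
    genorm_order = [genorm.final_pair] + list(reversed(genorm.exclusion_order))
    consensus = consensus_rank(
        {"genorm": genorm_order, "normfinder": normfinder.stability_order}
    )
    top2 = {
        "genorm": list(genorm.final_pair),
        "normfinder": normfinder.stability_order[:2],
        "consensus": consensus.final_order[:2],
    }
    return PanelReport(
        name=name,
        samples=list(table.samples),
        qc=qc,
        cq_summary=summary,
        genorm=genorm,
        normfinder=normfinder,
        consensus=consensus,
        top2=top2,
    )


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Run QC, transformation, both stability algorithms and the consensus
    for every configured panel; optionally write the report bundle.

    Returns ``{panel name: PanelReport}``.
    """
    table, meta = read_cq_table(config.input, layout=config.layout,
                                meta_path=config.meta)
    qc = qc_filter_samples(
        meta,
        rqi_min=config.rqi_min,
        ratio_low=config.ratio_low,
        ratio_high=config.ratio_high,
        missing_policy=config.qc_missing_policy,
    )
    for sample, reasons in qc.rejected.items():
        logger.info("QC rejected sample %s: %s", sample, ",".join(reasons))
    if not qc.kept:
        raise PipelineError("no sample passed QC")
    table = table.subset_samples(qc.kept)
    meta_kept = meta.loc[qc.kept]
    table, bio_meta = aggregate_technical_replicates(
        table, meta_kept, tolerance=config.tech_rep_tolerance
    )
    efficiencies = _load_efficiencies(config, table.genes)

    reports = {}
    for name, filt in config.panels.items():
        samples = _panel_samples(bio_meta, filt, name)
        if not samples:
            raise PipelineError(f"panel '{name}' is empty after QC")
        logger.info("panel %s: %d samples", name, len(samples))
        reports[name] = _analyze_panel(
            name,
            table.subset_samples(samples),
            bio_meta.loc[samples],
            qc,
            config,
            efficiencies,
        )
    if write:
        export_tables(reports, config.outdir)
    return reports


def export_tables(reports: Mapping[str, PanelReport], outdir) -> None:
    """Write the report bundle: per-panel CSV/JSON plus summary tables.

    JSON files round-trip losslessly (full float precision); CSVs use the
    same repr-precision floats.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    top2_rows = []
    consensus_rows = []
    for name, report in reports.items():
        panel_dir = outdir / name
        panel_dir.mkdir(exist_ok=True)
        report.qc.to_json(panel_dir / "qc.json")
        report.cq_summary.to_csv(panel_dir / "cq_summary.csv")
        m_table = report.genorm.m_table()
        m_table.insert(0, "panel", name)
        m_table.to_csv(panel_dir / "genorm_m.csv", index=False)
        (panel_dir / "genorm.json").write_text(
            json.dumps(report.genorm.to_dict(), indent=2)
        )
        report.normfinder.to_frame().to_csv(
            panel_dir / "normfinder.csv", index=False
        )
        (panel_dir / "normfinder.json").write_text(
            json.dumps(report.normfinder.to_dict(), indent=2)
        )
        report.consensus.to_frame().to_csv(
            panel_dir / "consensus.csv", index=False
        )
        (panel_dir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2)
        )
        top2_rows.append(
            {
                "panel": name,
                "genorm_top2": " / ".join(map(str, report.top2["genorm"])),
                "normfinder_top2": " / ".join(map(str, report.top2["normfinder"])),
                "consensus_top2": " / ".join(map(str, report.top2["consensus"])),
            }
        )
        consensus_rows.append(
            {
                "panel": name,
                "most_to_least_stable": ", ".join(
                    map(str, report.consensus.final_order)
                ),
            }
        )
    pd.DataFrame(top2_rows).to_csv(outdir / "top2.csv", index=False)
    pd.DataFrame(consensus_rows).to_csv(outdir / "consensus_overview.csv", index=False)
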