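"""Synthetic Cq-data generator with known ground truth.

Emulates a factorial RT-qPCR validation design on *Buglossoides arvensis*:
ten candidate reference genes measured in four tissues (leaves, stems,
flowers, seeds) with/without PGPR inoculation, at three growth temperatures
(15/20/25 degC) and three sampling weeks (4/6/8), three biological
replicates per condition cell and two qPCR technical replicates each.

The generative model mirrors the one the stability estimators assume: on
the log2 expression scale

    y_igj = b_gj + d_ig + eps_igj,

with a sample-wide effect b (SD ``sample_effect_sd``, shared by all genes —
RNA loading/RT efficiency), an optional zero-sum differential group effect
d_ig, and per-gene noise eps (SD ``gene_noise_sd[i]``).  Cq values follow as

    Cq_igj = baseline_i - y_igj / log2(efficiency_i),

technical replicates add independent N(0, tech_rep_sd) cycles, and any
value beyond ``max_cycles`` (or hit by the ``missing_rate`` censoring
probability) becomes missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import CqTable

__all__ = [
    "PAPER_GENES",
    "SimulationConfig",
    "SyntheticTruth",
    "table1_design",
    "simulate",
    "make_fixture",
]

#: The ten candidate reference genes of the emulated study.
PAPER_GENES = [
    "18S_rRNA",
    "beta_actin",
    "EF1a",
    "alpha_tub",
    "UBQ",
    "CAC",
    "GAPDH",
    "PP2a",
    "alpha_actin",
    "RUBISCO",
]

#: Per-gene mean Cq (cycles), spanning the wide abundance range seen in
#: real panels (rRNA genes amplify very early; scarce transcripts late).
_DEFAULT_BASELINE = {
    "18S_rRNA": 11.6,
    "beta_actin": 24.0,
    "EF1a": 33.0,
    "alpha_tub": 23.0,
    "UBQ": 22.0,
    "CAC": 25.0,
    "GAPDH": 26.0,
    "PP2a": 24.5,
    "alpha_actin": 28.0,
    "RUBISCO": 30.7,
}

#: Default per-gene log2 noise SD ladder {0.05, 0.1, 0.3, 0.5, ...}
#: assigned so the implied stability order matches the consensus order the
#: emulated study reported for its full sample panel (CAC and alpha-tub
#: most stable, alpha-actin least).
_DEFAULT_NOISE = {
    "CAC": 0.05,
    "alpha_tub": 0.1,
    "UBQ": 0.3,
    "PP2a": 0.5,
    "GAPDH": 0.7,
    "beta_actin": 0.9,
    "RUBISCO": 1.1,
    "18S_rRNA": 1.3,
    "EF1a": 1.5,
    "alpha_actin": 1.7,
}


def table1_design() -> list[dict]:
    """The study's 24 condition cells (tissue x treatment x temperature x week)."""
    cells: list[dict] = []

    def add(tissue, treatment, temperature, weeks):
        for week in weeks:
            cells.append(
                {
                    "tissue": tissue,
                    "treatment": treatment,
                    "temperature": temperature,
                    "week": week,
                }
            )

    add("leaves", "control", 20, (4, 6, 8))
    add("leaves", "PGPR", 20, (4, 6, 8))
    add("stems", "PGPR", 20, (4, 6, 8))
    add("stems", "control", 20, (4, 6, 8))
    add("flowers", "control", 20, (6, 8))
    add("seeds", "control", 20, (6, 8))
    add("flowers", "PGPR", 20, (6, 8))
    add("seeds", "PGPR", 20, (6, 8))
    add("leaves", "control", 15, (4, 6))
    add("leaves", "control", 25, (4, 6))
    return cells


@dataclass
class SimulationConfig:
    """Generative parameters; defaults reproduce the emulated study design."""

    genes: Sequence[str] | None = None
    design: Sequence[Mapping] | None = None
    bio_reps: int = 3
    tech_reps: int = 2
    baseline_cq: Mapping | Sequence | None = None  # cycles
    sample_effect_sd: float = 1.0  # log2 units, shared across genes
    gene_noise_sd: Mapping | Sequence | None = None  # log2 units per gene
    group_effects: Mapping | None = None  # {group label: {gene: d_ig}}
    group_by: str = "tissue"
    efficiency: float | Mapping = 2.0  # per-cycle amplification factor
    tech_rep_sd: float = 0.1  # cycles
    missing_rate: float = 0.0
    max_cycles: float = 40.0
    rqi_range: tuple = (7.0, 10.0)
    ratio_range: tuple = (1.9, 2.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genes is None:
            self.genes = list(PAPER_GENES)
        self.genes = list(self.genes)
        if self.design is None:
            self.design = table1_design()
        self.design = [dict(cell) for cell in self.design]
        if self.baseline_cq is None:
            self.baseline_cq = {
                g: _DEFAULT_BASELINE.get(g, 25.0) for g in self.genes
            }
        if self.gene_noise_sd is None:
            self.gene_noise_sd = {
                g: _DEFAULT_NOISE.get(g, 0.5) for g in self.genes
            }
        self.baseline_cq = self._per_gene(self.baseline_cq, "baseline_cq")
        self.gene_noise_sd = self._per_gene(self.gene_noise_sd, "gene_noise_sd")
        if np.isscalar(self.efficiency):
            self.efficiency = {g: float(self.efficiency) for g in self.genes}
        else:
            self.efficiency = self._per_gene(self.efficiency, "efficiency")
        self._validate()

    def _per_gene(self, values, name: str) -> dict:
        if isinstance(values, Mapping):
            missing = [g for g in self.genes if g not in values]
            if missing:
                raise ValueError(f"{name} missing for genes: {missing}")
            return {g: float(values[g]) for g in self.genes}
        values = list(values)
        if len(values) != len(self.genes):
            raise ValueError(
                f"{name} has {len(values)} entries for {len(self.genes)} genes"
            )
        return {g: float(v) for g, v in zip(self.genes, values)}

    def _validate(self) -> None:
        if self.bio_reps < 1 or self.tech_reps < 1:
            raise ValueError("bio_reps and tech_reps must be >= 1")
        if self.sample_effect_sd < 0 or self.tech_rep_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if any(v < 0 for v in self.gene_noise_sd.values()):
            raise ValueError("gene_noise_sd values must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if any(not 1.0 < v <= 3.0 for v in self.efficiency.values()):
            raise ValueError("efficiencies must lie in (1, 3]")
        if self.group_effects is not None:
            for label, effects in self.group_effects.items():
                total = sum(float(effects.get(g, 0.0)) for g in self.genes)
                if abs(total) > 1e-9:
                    raise ValueError(
                        f"group_effects for {label!r} must sum to zero over "
                        f"genes (got {total:.3g})"
                    )

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "design": [dict(c) for c in self.design],
            "bio_reps": self.bio_reps,
            "tech_reps": self.tech_reps,
            "baseline_cq": dict(self.baseline_cq),
            "sample_effect_sd": self.sample_effect_sd,
            "gene_noise_sd": dict(self.gene_noise_sd),
            "group_effects": None
            if self.group_effects is None
            else {str(k): dict(v) for k, v in self.group_effects.items()},
            "group_by": self.group_by,
            "efficiency": dict(self.efficiency),
            "tech_rep_sd": self.tech_rep_sd,
            "missing_rate": self.missing_rate,
            "max_cycles": self.max_cycles,
            "rqi_range": list(self.rqi_range),
            "ratio_range": list(self.ratio_range),
            "seed": self.seed,
        }


@dataclass
class SyntheticTruth:
    """Ground truth paired with one generated dataset."""

    config: SimulationConfig
    log_expression: pd.DataFrame  # genes x biological samples (y)
    stability_order: list  # ascending total variation (noise SD + mean |d|)


def _fmt(value) -> str:
    if isinstance(value, float) and float(value).is_integer():
        return str(int(value))
    return str(value)


def _bio_sample_id(cell: Mapping, rep: int) -> str:
    return (
        f"{cell['tissue']}_{cell['treatment']}_{_fmt(cell['temperature'])}"
        f"_{_fmt(cell['week'])}_{rep}"
    )


def simulate(config: SimulationConfig) -> tuple[CqTable, pd.DataFrame, SyntheticTruth]:
    """Generate one dataset: Cq table (technical-replicate level), sample
    metadata and the paired ground truth.  Bit-reproducible from the config
    (including its ``seed``)."""
    rng = np.random.default_rng(config.seed)
    genes = list(config.genes)
    G = len(genes)
    cells = [dict(c) for c in config.design]

    bio_cells = [(cell, rep) for cell in cells for rep in range(1, config.bio_reps + 1)]
    n_bio = len(bio_cells)
    bio_ids = [_bio_sample_id(cell, rep) for cell, rep in bio_cells]
    if len(set(bio_ids)) != n_bio:
        raise ValueError("design cells x bio_reps do not name unique samples")

    b = rng.normal(0.0, config.sample_effect_sd, size=n_bio)
    noise_sd = np.array([config.gene_noise_sd[g] for g in genes])
    eps = rng.normal(0.0, 1.0, size=(G, n_bio)) * noise_sd[:, None]

    d = np.zeros((G, n_bio))
    if config.group_effects is not None:
        for j, (cell, _rep) in enumerate(bio_cells):
            label = cell.get(config.group_by)
            effects = config.group_effects.get(label)
            if effects:
                d[:, j] = [float(effects.get(g, 0.0)) for g in genes]

    y = b[None, :] + d + eps
    baseline = np.array([config.baseline_cq[g] for g in genes])
    log2_eff = np.log2([config.efficiency[g] for g in genes])
    cq_bio = baseline[:, None] - y / log2_eff[:, None]

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    rqi = rng.uniform(*config.rqi_range, size=n_bio)
    ratio = rng.uniform(*config.ratio_range, size=n_bio)
    for j, (cell, rep) in enumerate(bio_cells):
        for t in range(1, config.tech_reps + 1):
            col = cq_bio[:, j].copy()
            if config.tech_rep_sd > 0:
                col = col + rng.normal(0.0, config.tech_rep_sd, size=G)
            censored = col > config.max_cycles
            if config.missing_rate > 0:
                censored |= rng.random(size=G) < config.missing_rate
            col[censored] = np.nan
            sample_id = f"{bio_ids[j]}_t{t}"
            columns[sample_id] = col
            meta_rows.append(
                {
                    "sample": sample_id,
                    "tissue": cell["tissue"],
                    "treatment": cell["treatment"],
                    "temperature": cell["temperature"],
                    "week": cell["week"],
                    "bio_rep": rep,
                    "tech_rep": t,
                    "rqi": rqi[j],
                    "a260_280": ratio[j],
                }
            )

    table = CqTable(
        pd.DataFrame(columns, index=genes), max_cycles=config.max_cycles
    )
    meta = pd.DataFrame(meta_rows).set_index("sample")

    total_var = noise_sd + np.abs(d).mean(axis=1)
    order = [genes[i] for i in np.argsort(total_var, kind="stable")]
    truth = SyntheticTruth(
        config=config,
        log_expression=pd.DataFrame(y, index=genes, columns=bio_ids),
        stability_order=order,
    )
    return table, meta, truth


def _tiny_fixture() -> tuple[CqTable, pd.DataFrame, None]:
    cq = pd.DataFrame(
        {
            "s1": [20.0, 22.0, 25.0],
            "s2": [21.0, 23.1, 26.2],
            "s3": [19.5, 21.4, 24.8],
            "s4": [20.5, 22.6, 25.9],
        },
        index=["g1", "g2", "g3"],
    )
    meta = pd.DataFrame(
        {
            "tissue": ["leaves", "leaves", "stems", "stems"],
            "treatment": ["control"] * 4,
            "temperature": [20.0] * 4,
            "week": [4, 4, 4, 4],
            "bio_rep": [1, 2, 1, 2],
            "tech_rep": [1, 1, 1, 1],
            "rqi": [8.5, 9.0, 8.0, 9.5],
            "a260_280": [2.0, 1.95, 2.05, 2.0],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"),
    )
    return CqTable(cq), meta, None


FIXTURES = ("tiny", "paper_design", "null_model", "one_bad_gene")


def make_fixture(name: str, seed: int = 0):
    """Deterministic canned datasets for tests and documentation.

    - ``tiny``: hand-written 3 genes x 4 complete samples.
    - ``paper_design``: the full factorial design with the default noise
      ladder (24 condition cells x 3 biological replicates).
    - ``null_model``: same design, every gene with log2 noise SD 0.3 and no
      group effects (no gene is genuinely better than another).
    - ``one_bad_gene``: all genes at SD 0.2 except ``alpha_actin`` at 2.0
      (ten-fold noisier).

    Returns ``(CqTable, metadata, SyntheticTruth | None)``; ``tiny`` has no
    generative truth.
    """
    if name == "tiny":
        return _tiny_fixture()
    if name == "paper_design":
        return simulate(SimulationConfig(seed=seed))
    if name == "null_model":
        return simulate(
            SimulationConfig(gene_noise_sd=[0.3] * 10, seed=seed)
        )
    if name == "one_bad_gene":
        noise = {g: 0.2 for g in PAPER_GENES}
        noise["alpha_actin"] = 2.0
        return simulate(SimulationConfig(gene_noise_sd=noise, seed=seed))
    raise ValueError(f"unknown fixture {name!r}; options: {list(FIXTURES)}")
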