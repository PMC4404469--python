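"""geNorm expression-stability analysis.

For genes j, k with relative quantities q over a common set of samples, the
pairwise variation is the sample standard deviation (n-1 denominator) of the
log2 quantity ratios,

    V_jk = SD_s( log2(q_js / q_ks) ),

and a gene's expression stability is the average of its pairwise variations
against all other panel genes,

    M_j = sum_{k != j} V_jk / (G - 1).

Low M means a gene's expression moves in concert with the rest of the panel.
The ranking removes the highest-M gene, recomputes M on the reduced panel
and repeats until two genes remain; those two cannot be resolved further and
are reported as a tied best pair.  The pairwise-variation series
V_n/n+1 = SD_s(log2(NF_n / NF_{n+1})) — where NF_n is the per-sample
geometric mean of the n most stable genes — gauges whether adding an
(n+1)-th reference gene still changes the normalization factor; values at or
below 0.15 are conventionally read as "n genes suffice".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .quantities import QuantityMatrix

__all__ = [
    "GeNorm",
    "GeNormResult",
    "GeneCountRecommendation",
    "pairwise_variation",
    "pairwise_variation_matrix",
    "m_values",
    "rank_by_stepwise_exclusion",
    "normalization_factor",
    "v_n_series",
    "recommend_gene_count",
    "classify_m",
    "genorm_analysis",
]

#: Conventional pairwise-variation cutoff below which adding another
#: reference gene is considered unnecessary.
V_CUTOFF = 0.15

_TIE_TOL = 1e-12


def _as_frame(q) -> pd.DataFrame:
    """Accept QuantityMatrix / DataFrame / array; return genes x samples frame."""
    if isinstance(q, QuantityMatrix):
        return q.q
    frame = pd.DataFrame(q).astype(float)
    vals = frame.to_numpy()
    if not np.isfinite(vals).all() or (vals <= 0).any():
        raise ValueError("relative quantities must be finite and > 0")
    return frame


def _log2(q) -> pd.DataFrame:
    return np.log2(_as_frame(q))


def pairwise_variation(q, gene_j, gene_k) -> float:
    """Pairwise variation V_jk: SD of log2 quantity ratios of two genes."""
    L = _log2(q)
    for g in (gene_j, gene_k):
        if g not in L.index:
            raise KeyError(f"gene {g!r} not in quantity matrix")
    ratios = (L.loc[gene_j] - L.loc[gene_k]).dropna()
    if len(ratios) < 2:
        raise ValueError("pairwise variation needs >=2 common samples")
    return float(np.std(ratios.to_numpy(), ddof=1))


def pairwise_variation_matrix(q) -> pd.DataFrame:
    """Symmetric G x G matrix of all pairwise variations (diagonal 0)."""
    L = _log2(q)
    if L.shape[1] < 2:
        raise ValueError("pairwise variation needs >=2 samples")
    a = L.to_numpy()
    diff = a[:, None, :] - a[None, :, :]
    V = diff.std(axis=2, ddof=1)
    np.fill_diagonal(V, 0.0)
    return pd.DataFrame(V, index=L.index, columns=L.index)


def m_values(q) -> pd.Series:
    """Expression stability M for every gene of the panel (>=3 genes)."""
    V = pairwise_variation_matrix(q)
    G = V.shape[0]
    if G < 3:
        raise ValueError(
            "M is defined for panels of >=3 genes (a lone pair only shares "
            "its pairwise variation)"
        )
    return V.sum(axis=1) / (G - 1)


def _excluded_index(m: np.ndarray) -> int:
    """Index to exclude: highest M; ties (within 1e-12) resolved to the
    gene latest in input order."""
    top = m.max()
    candidates = np.flatnonzero(m >= top - _TIE_TOL)
    return int(candidates[-1])


@dataclass
class GeNormResult:
    """Full geNorm output for one panel of genes."""

    genes: list
    m_values: pd.Series  # full-panel M
    per_step_m: list  # Series per exclusion step, down to the final pair
    exclusion_order: list  # least stable first
    final_pair: tuple
    stability_order: list  # best -> worst (final pair first, tied)
    ranking: pd.Series  # 1 = most stable; final pair tied at 1.5
    v_series: list = field(default_factory=list)  # [(n, V_n/n+1)]
    recommended_n: int | None = None
    optional_extra_n: int | None = None
    cutoff_met: bool | None = None

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "m_values": {g: float(v) for g, v in self.m_values.items()},
            "per_step_m": [
                {g: float(v) for g, v in step.items()} for step in self.per_step_m
            ],
            "exclusion_order": list(self.exclusion_order),
            "final_pair": list(self.final_pair),
            "stability_order": list(self.stability_order),
            "ranking": {g: float(v) for g, v in self.ranking.items()},
            "v_series": [[int(n), float(v)] for n, v in self.v_series],
            "recommended_n": self.recommended_n,
            "optional_extra_n": self.optional_extra_n,
            "cutoff_met": self.cutoff_met,
        }

    def m_table(self) -> pd.DataFrame:
        """Tidy frame of per-step M values: columns (step, gene, m)."""
        rows = [
            {"step": i + 1, "gene": g, "m": float(v)}
            for i, step in enumerate(self.per_step_m)
            for g, v in step.items()
        ]
        return pd.DataFrame(rows, columns=["step", "gene", "m"])


def rank_by_stepwise_exclusion(q) -> GeNormResult:
    """Rank genes by iteratively excluding the least stable one.

    At each step M is recomputed on the remaining panel and the highest-M
    gene removed (ties go to the gene latest in input order), until two
    genes remain; geNorm cannot rank those two, so they are reported as a
    tied pair (rank 1.5 each).
    """
    frame = _as_frame(q)
    genes = list(frame.index)
    G = len(genes)
    if G < 3:
        raise ValueError("stepwise exclusion needs >=3 genes")

    remaining = list(genes)
    per_step: list[pd.Series] = []
    exclusion: list = []
    full_m: pd.Series | None = None
    while len(remaining) > 2:
        m = m_values(frame.loc[remaining])
        if full_m is None:
            full_m = m
        per_step.append(m)
        out = remaining[_excluded_index(m.to_numpy())]
        exclusion.append(out)
        remaining.remove(out)

    pair_v = pairwise_variation(frame, remaining[0], remaining[1])
    per_step.append(pd.Series([pair_v, pair_v], index=remaining))
    final_pair = tuple(remaining)

    stability_order = list(final_pair) + list(reversed(exclusion))
    ranking = pd.Series(index=genes, dtype=float)
    ranking[list(final_pair)] = 1.5
    for pos, gene in enumerate(reversed(exclusion), start=3):
        ranking[gene] = float(pos)
    return GeNormResult(
        genes=genes,
        m_values=full_m,
        per_step_m=per_step,
        exclusion_order=exclusion,
        final_pair=final_pair,
        stability_order=stability_order,
        ranking=ranking,
    )


def normalization_factor(q, genes_subset: Sequence) -> pd.Series:
    """Per-sample normalization factor: geometric mean of the subset's quantities."""
    frame = _as_frame(q)
    subset = list(genes_subset)
    if not subset:
        raise ValueError("genes_subset must be non-empty")
    missing = [g for g in subset if g not in frame.index]
    if missing:
        raise KeyError(f"genes not in quantity matrix: {missing}")
    L = np.log2(frame.loc[subset].to_numpy())
    return pd.Series(2.0 ** L.mean(axis=0), index=frame.columns)


def v_n_series(q, stability_order: Sequence) -> list[tuple[int, float]]:
    """Pairwise variation V_n/n+1 of successive normalization factors.

    ``stability_order`` lists genes best-first (from
    :func:`rank_by_stepwise_exclusion`).  For n = 2..G-1, V_n/n+1 is the
    sample SD over samples of log2(NF_n / NF_{n+1}).
    """
    frame = _as_frame(q)
    order = list(stability_order)
    if sorted(order) != sorted(frame.index):
        raise ValueError("stability_order must be a permutation of the genes")
    G = len(order)
    if G < 3:
        raise ValueError("V_n/n+1 needs >=3 genes")
    L = np.log2(frame.loc[order].to_numpy())
    log_nf = np.cumsum(L, axis=0) / np.arange(1, G + 1)[:, None]
    series = []
    for n in range(2, G):
        diff = log_nf[n - 1] - log_nf[n]
        series.append((n, float(np.std(diff, ddof=1))))
    return series


@dataclass(frozen=True)
class GeneCountRecommendation:
    recommended_n: int
    optional_extra_n: int | None
    cutoff_met: bool


def recommend_gene_count(
    v_series: Sequence[tuple[int, float]], cutoff: float = V_CUTOFF
) -> GeneCountRecommendation:
    """How many reference genes suffice, by the V_n/n+1 <= cutoff convention.

    ``recommended_n`` is the smallest n whose V_n/n+1 is at or below the
    cutoff (that many genes suffice).  ``optional_extra_n`` is the largest m
    such that every V_k/k+1 with k < m is also at or below the cutoff —
    i.e. genes that "could also be used" without degrading normalization.
    If no V meets the cutoff, ``recommended_n`` falls back to the full panel
    size with ``cutoff_met=False`` and a warning.
    """
    series = sorted((int(n), float(v)) for n, v in v_series)
    if not series:
        raise ValueError("v_series must be non-empty")
    G = series[-1][0] + 1
    recommended = next((n for n, v in series if v <= cutoff), None)
    if recommended is None:
        warnings.warn(
            f"no V_n/n+1 at or below {cutoff}; the full panel of {G} genes "
            "is recommended",
            stacklevel=2,
        )
        return GeneCountRecommendation(G, None, False)
    extra = 2
    for n, v in series:
        if v <= cutoff:
            extra = n + 1
        else:
            break
    return GeneCountRecommendation(recommended, extra, True)


def classify_m(m: float, panel: str = "homogeneous") -> str:
    """Classify an M value as stable / acceptable / unstable.

    For homogeneous sample panels, M <= 0.5 is considered stable; for
    heterogeneous panels values up to 1 are still acceptable.
    """
    if m < 0:
        raise ValueError("M must be non-negative")
    if panel == "homogeneous":
        return "stable" if m <= 0.5 else "unstable"
    if panel == "heterogeneous":
        if m <= 0.5:
            return "stable"
        return "acceptable" if m <= 1.0 else "unstable"
    raise ValueError("panel must be 'homogeneous' or 'heterogeneous'")


def genorm_analysis(q, cutoff: float = V_CUTOFF) -> GeNormResult:
    """Complete geNorm run: ranking, V-series and gene-count recommendation."""
    result = rank_by_stepwise_exclusion(q)
    result.v_series = v_n_series(q, result.stability_order)
    rec = recommend_gene_count(result.v_series, cutoff=cutoff)
    result.recommended_n = rec.recommended_n
    result.optional_extra_n = rec.optional_extra_n
    result.cutoff_met = rec.cutoff_met
    return result


class GeNorm(BaseEstimator):
    """Scikit-learn-style estimator wrapping the geNorm analysis.

    ``X`` follows the sklearn orientation ``(n_samples, n_genes)`` and must
    hold positive linear-scale relative quantities (see
    :func:`refstab.quantities.cq_to_quantities`).

    Parameters
    ----------
    v_cutoff : float, default 0.15
        Pairwise-variation cutoff for the gene-count recommendation.

    Attributes
    ----------
    m_values_ : ndarray of shape (n_genes,)
        Full-panel expression stability M per gene (input order).
    ranking_ : ndarray of shape (n_genes,)
        1 = most stable; the final pair is tied at 1.5.
    stability_order_ : list
        Genes best to worst.
    exclusion_order_, final_pair_, per_step_m_, v_series_,
    recommended_n_, optional_extra_n_, cutoff_met_ :
        See :class:`GeNormResult`; also available bundled as ``result_``.
    """

    def __init__(self, v_cutoff: float = V_CUTOFF):
        self.v_cutoff = v_cutoff

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            frame = X.astype(float).T
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2:
                raise ValueError("X must be 2-dimensional (samples x genes)")
            frame = pd.DataFrame(
                arr.T, index=[f"gene{i}" for i in range(arr.shape[1])]
            )
        self.n_features_in_ = frame.shape[0]
        result = genorm_analysis(frame, cutoff=self.v_cutoff)
        self.result_ = result
        self.genes_ = list(result.genes)
        self.m_values_ = result.m_values.loc[self.genes_].to_numpy()
        self.ranking_ = result.ranking.loc[self.genes_].to_numpy()
        self.stability_order_ = list(result.stability_order)
        self.exclusion_order_ = list(result.exclusion_order)
        self.final_pair_ = result.final_pair
        self.per_step_m_ = result.per_step_m
        self.v_series_ = list(result.v_series)
        self.recommended_n_ = result.recommended_n
        self.optional_extra_n_ = result.optional_extra_n
        self.cutoff_met_ = result.cutoff_met
        return self
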