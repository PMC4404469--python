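"""NormFinder model-based reference-gene stability estimation.

NormFinder models log2 expression within each sample group g as a two-way
layout per gene i and sample j,

    y_igj = alpha_ig + beta_gj + eps_igj,      eps_igj ~ N(0, sigma2_ig),

where beta_gj is a sample-wide effect (RNA amount, RT efficiency) common to
all genes and alpha_ig splits into an overall gene level plus a
*differential* group effect d_ig (sum_i d_ig = 0).  A good reference gene
has both small intra-group variance sigma2_ig and a small group effect.

Estimation follows the model-based decomposition: two-way centering within
each group yields residuals whose scaled row sums z_ig are bias-corrected
into unbiased variance estimates

    sigma2_hat_ig = (z_ig - S_hat_g / G^2) * G / (G - 2),
    S_hat_g       = (G / (G - 1)) * sum_i z_ig,

(G = number of genes); the group effects d_hat_ig are two-way-centred group
means, their dispersion in excess of sampling noise estimates the
between-group effect variance tau2, and each gene's effect is shrunk by
tau2 / (tau2 + sigma2_hat_ig / n_g).  The per-gene stability value combines
the magnitude of the shrunken effect with its posterior spread and is
averaged over groups; the lowest stability value marks the most stable
gene.  With a single group the stability reduces to
sqrt(max(0, sigma2_hat_i)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .quantities import QuantityMatrix

__all__ = [
    "NormFinder",
    "NormFinderResult",
    "log_transform",
    "intragroup_variance",
    "ungrouped_stability",
    "grouped_stability",
    "rank_genes",
]


def log_transform(q) -> pd.DataFrame:
    """log2 of a positive relative-quantity matrix (genes x samples)."""
    if isinstance(q, QuantityMatrix):
        q = q.q
    frame = pd.DataFrame(q).astype(float)
    vals = frame.to_numpy()
    if not np.isfinite(vals).all() or (vals <= 0).any():
        raise ValueError("quantities must be finite and > 0 before log transform")
    return np.log2(frame)


def _as_log_frame(y) -> pd.DataFrame:
    if isinstance(y, QuantityMatrix):
        return log_transform(y)
    frame = pd.DataFrame(y).astype(float)
    if not np.isfinite(frame.to_numpy()).all():
        raise ValueError("log-expression matrix must be finite")
    return frame


def _group_blocks(samples: Sequence, groups) -> dict:
    """Ordered mapping group label -> list of sample positions."""
    if isinstance(groups, (pd.Series, Mapping)):
        labels = pd.Series(groups).reindex(samples)
        if labels.isna().any():
            missing = [s for s, v in labels.items() if pd.isna(v)]
            raise ValueError(f"no group label for samples: {missing}")
        values = labels.tolist()
    else:
        values = list(groups)
        if len(values) != len(samples):
            raise ValueError("groups must have one label per sample")
    blocks: dict = {}
    for pos, lab in enumerate(values):
        blocks.setdefault(lab, []).append(pos)
    return blocks


def two_way_residuals(y_block: np.ndarray) -> np.ndarray:
    """Residuals of one group after removing gene and sample means.

    ``R_ij = y_ij - mean_i - mean_j + grand`` for a genes x samples block.
    """
    row = y_block.mean(axis=1, keepdims=True)
    col = y_block.mean(axis=0, keepdims=True)
    grand = y_block.mean()
    return y_block - row - col + grand


def _z_statistics(y_block: np.ndarray) -> np.ndarray:
    n = y_block.shape[1]
    R = two_way_residuals(y_block)
    return (R ** 2).sum(axis=1) / (n - 1)


def _sigma2_from_z(z: np.ndarray, G: int, floor: bool) -> np.ndarray:
    s_hat = (G / (G - 1)) * z.sum()
    sigma2 = (z - s_hat / G ** 2) * G / (G - 2)
    if floor:
        sigma2 = np.maximum(sigma2, 0.0)
    return sigma2


def intragroup_variance(y, groups=None, floor: bool = True) -> pd.DataFrame:
    """Unbiased per-gene intra-group variance estimates (genes x groups).

    ``floor=True`` clips negative estimates at zero (the default used by
    the stability computation); ``floor=False`` returns the raw unbiased
    estimates, which is what a bias check must average.
    """
    frame = _as_log_frame(y)
    G, S = frame.shape
    if G < 3:
        raise ValueError("variance estimation needs >=3 genes (divides by G-2)")
    if groups is None:
        groups = ["all"] * S
    blocks = _group_blocks(frame.columns, groups)
    out = {}
    for lab, pos in blocks.items():
        if len(pos) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
        z = _z_statistics(frame.to_numpy()[:, pos])
        out[lab] = _sigma2_from_z(z, G, floor)
    return pd.DataFrame(out, index=frame.index)


@dataclass
class NormFinderResult:
    """Per-gene stability values and diagnostics from one NormFinder run."""

    genes: list
    stability: pd.Series  # >= 0, lower = more stable
    rank: pd.Series  # 1 = most stable, ties share mean rank
    grouped: bool
    intra_var: pd.DataFrame  # genes x groups, floored at 0
    inter_effect: pd.DataFrame | None = None  # d_hat, grouped mode only
    tau2: float | None = None
    fallback_ungrouped: bool = False

    @property
    def stability_order(self) -> list:
        """Genes best to worst (ascending stability, input order on ties)."""
        return list(self.stability.sort_values(kind="stable").index)

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "stability": {g: float(v) for g, v in self.stability.items()},
            "rank": {g: float(v) for g, v in self.rank.items()},
            "grouped": self.grouped,
            "intra_var": {
                str(c): {g: float(v) for g, v in self.intra_var[c].items()}
                for c in self.intra_var.columns
            },
            "inter_effect": None
            if self.inter_effect is None
            else {
                str(c): {g: float(v) for g, v in self.inter_effect[c].items()}
                for c in self.inter_effect.columns
            },
            "tau2": None if self.tau2 is None else float(self.tau2),
            "fallback_ungrouped": self.fallback_ungrouped,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "stability": self.stability.loc[self.genes].to_numpy(),
                "rank": self.rank.loc[self.genes].to_numpy(),
            }
        )


def _ranks(stability: pd.Series) -> pd.Series:
    return pd.Series(
        stats.rankdata(stability.to_numpy(), method="average"),
        index=stability.index,
    )


def ungrouped_stability(y) -> NormFinderResult:
    """Stability treating all samples as one group: sqrt(max(0, sigma2_hat))."""
    frame = _as_log_frame(y)
    G, S = frame.shape
    if G < 3:
        raise ValueError("NormFinder needs >=3 genes")
    if S < 3:
        raise ValueError("NormFinder needs >=3 samples")
    sigma2 = intragroup_variance(frame, floor=True)
    stability = np.sqrt(sigma2.iloc[:, 0])
    return NormFinderResult(
        genes=list(frame.index),
        stability=stability,
        rank=_ranks(stability),
        grouped=False,
        intra_var=sigma2,
    )


def grouped_stability(y, groups) -> NormFinderResult:
    """Stability combining intra-group variance and shrunken group effects.

    ``groups`` maps each sample to its subgroup label (e.g. tissue); every
    group needs at least two samples.  When the estimated between-group
    effect variance tau2 is zero the grouped stability degenerates to zero
    for all genes, so the result falls back to the ungrouped estimate with
    ``fallback_ungrouped=True`` to preserve a usable ranking.
    """
    frame = _as_log_frame(y)
    G = frame.shape[0]
    if G < 3:
        raise ValueError("NormFinder needs >=3 genes")
    blocks = _group_blocks(frame.columns, groups)
    n_groups = len(blocks)
    if n_groups == 1:
        # Single-group input degenerates to the ungrouped model.
        return ungrouped_stability(frame)

    arr = frame.to_numpy()
    labels = list(blocks)
    n_g = np.array([len(blocks[lab]) for lab in labels])
    if (n_g < 2).any():
        small = [lab for lab, n in zip(labels, n_g) if n < 2]
        raise ValueError(f"groups with fewer than 2 samples: {small}")

    sigma2 = np.column_stack(
        [
            _sigma2_from_z(_z_statistics(arr[:, blocks[lab]]), G, floor=True)
            for lab in labels
        ]
    )
    # Differential group effects: two-way centering of the G x Gamma matrix
    # of group means (unweighted over groups, so sum_i d_ig = 0 per group
    # even for unbalanced designs).
    group_means = np.column_stack(
        [arr[:, blocks[lab]].mean(axis=1) for lab in labels]
    )
    d_hat = two_way_residuals(group_means)

    samp_var = sigma2 / n_g[None, :]
    tau2 = max(
        0.0,
        (d_hat ** 2).sum() / ((G - 1) * (n_groups - 1)) - samp_var.mean(),
    )

    intra = pd.DataFrame(sigma2, index=frame.index, columns=labels)
    inter = pd.DataFrame(d_hat, index=frame.index, columns=labels)
    if tau2 == 0.0:
        fallback = ungrouped_stability(frame)
        return NormFinderResult(
            genes=list(frame.index),
            stability=fallback.stability,
            rank=fallback.rank,
            grouped=True,
            intra_var=intra,
            inter_effect=inter,
            tau2=0.0,
            fallback_ungrouped=True,
        )

    shrink = tau2 / (tau2 + samp_var)
    d_tilde = d_hat * shrink
    rho = np.abs(d_tilde) + np.sqrt(samp_var * shrink)
    stability = pd.Series(rho.mean(axis=1), index=frame.index)
    return NormFinderResult(
        genes=list(frame.index),
        stability=stability,
        rank=_ranks(stability),
        grouped=True,
        intra_var=intra,
        inter_effect=inter,
        tau2=tau2,
    )


def rank_genes(result: NormFinderResult) -> list:
    """Genes ordered most to least stable (ascending stability value)."""
    return result.stability_order


class NormFinder(BaseEstimator):
    """Scikit-learn-style estimator wrapping the NormFinder analysis.

    ``X`` is ``(n_samples, n_genes)`` of positive linear-scale relative
    quantities; they are log2-transformed internally.  Pass per-sample
    subgroup labels to ``fit`` to enable the grouped model.

    Attributes
    ----------
    stability_ : ndarray of shape (n_genes,)
        Stability values (lower = more stable), input gene order.
    ranks_ : ndarray of shape (n_genes,)
        1 = most stable; ties share the mean rank.
    stability_order_ : list
        Genes best to worst.
    tau2_ : float or None
        Estimated between-group effect variance (grouped mode).
    fallback_ungrouped_ : bool
        True when tau2 collapsed to zero and the ungrouped estimate was
        used instead.
    """

    def __init__(self, log_input: bool = False):
        # log_input=True means X is already on the log2 scale.
        self.log_input = log_input

    def fit(self, X, y=None, groups=None):
        if isinstance(X, pd.DataFrame):
            frame = X.astype(float).T
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            sample_index = list(X.index)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2:
                raise ValueError("X must be 2-dimensional (samples x genes)")
            frame = pd.DataFrame(
                arr.T, index=[f"gene{i}" for i in range(arr.shape[1])]
            )
            sample_index = list(range(arr.shape[0]))
        self.n_features_in_ = frame.shape[0]
        logy = frame if self.log_input else log_transform(frame)
        if groups is None:
            result = ungrouped_stability(logy)
        else:
            if isinstance(groups, (pd.Series, Mapping)):
                groups = pd.Series(groups).reindex(sample_index)
            result = grouped_stability(logy, groups)
        self.result_ = result
        self.genes_ = list(result.genes)
        self.stability_ = result.stability.loc[self.genes_].to_numpy()
        self.ranks_ = result.rank.loc[self.genes_].to_numpy()
        self.stability_order_ = result.stability_order
        self.grouped_ = result.grouped
        self.tau2_ = result.tau2
        self.fallback_ungrouped_ = result.fallback_ungrouped
        return self
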