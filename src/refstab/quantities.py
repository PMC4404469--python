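"""Transform Cq values into the relative-quantity matrix used for stability analysis.

geNorm and NormFinder operate on linear-scale relative quantities, not raw
Cq.  With per-gene amplification factor ``A_g`` the standard delta-Cq
transform relative to a calibrator sample is

    q_gs = A_g ** (Cq_g,calibrator - Cq_gs),

so the calibrator gets q = 1 and one extra cycle divides the quantity by
``A_g``.  The default calibrator is each gene's minimum-Cq (most expressed)
sample, making ``max_s q_gs = 1`` per gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data import CqTable, CqValidationError

__all__ = ["QuantityMatrix", "cq_to_quantities", "CqQuantityTransformer"]


@dataclass
class QuantityMatrix:
    """Genes x samples matrix of positive, linear-scale relative quantities."""

    q: pd.DataFrame
    efficiencies: pd.Series  # per-gene amplification factor (1 + E/100)

    def __post_init__(self) -> None:
        q = pd.DataFrame(self.q).astype(float)
        if not np.isfinite(q.to_numpy()).all() or (q.to_numpy() <= 0).any():
            raise ValueError("relative quantities must be finite and > 0")
        eff = pd.Series(self.efficiencies, dtype=float).reindex(q.index)
        if eff.isna().any():
            raise ValueError("an amplification factor is required for every gene")
        self.q = q
        self.efficiencies = eff

    @property
    def genes(self) -> list:
        return list(self.q.index)

    @property
    def samples(self) -> list:
        return list(self.q.columns)


def _efficiency_series(efficiencies, genes) -> pd.Series:
    if np.isscalar(efficiencies):
        eff = pd.Series(float(efficiencies), index=genes)
    else:
        eff = pd.Series(efficiencies, dtype=float).reindex(genes)
        if eff.isna().any():
            missing = list(eff.index[eff.isna()])
            raise ValueError(f"no amplification factor for genes: {missing}")
    bad = eff[(eff <= 1.0) | (eff > 3.0)]
    if len(bad):
        raise ValueError(
            "amplification factors must lie in (1, 3] "
            f"(100% efficiency = 2.0); offending genes: {list(bad.index)}"
        )
    return eff


def cq_to_quantities(
    table: CqTable,
    efficiencies: float | Mapping | pd.Series = 2.0,
    missing: str = "drop",
    calibrator: str | None = None,
) -> QuantityMatrix:
    """Convert a (technical-replicate-aggregated) CqTable to relative quantities.

    Parameters
    ----------
    table : CqTable
    efficiencies : float or per-gene mapping
        Per-cycle amplification factor(s) in (1, 3]; default 2.0, i.e. 100%
        efficiency.
    missing : {"drop", "impute"}
        ``"drop"`` excludes every sample with any missing gene (both
        downstream algorithms need complete matrices); ``"impute"`` fills
        missing entries with ``table.max_cycles`` (detection-limit
        censoring).
    calibrator : sample id, optional
        Reference sample for each gene.  Default: the per-gene minimum-Cq
        sample, so quantities are <= 1 with max exactly 1 per gene.
    """
    cq = table.cq
    eff = _efficiency_series(efficiencies, table.genes)

    all_missing = cq.index[cq.isna().all(axis=1)]
    if len(all_missing):
        raise CqValidationError(
            f"gene(s) missing in every sample: {list(all_missing)}"
        )
    if missing == "drop":
        complete = cq.columns[cq.notna().all(axis=0)]
        if len(complete) == 0:
            raise CqValidationError(
                "no sample has a complete Cq profile; consider missing='impute'"
            )
        cq = cq[complete]
    elif missing == "impute":
        cq = cq.fillna(table.max_cycles)
    else:
        raise ValueError("missing must be 'drop' or 'impute'")

    if calibrator is None:
        ref = cq.min(axis=1)
    else:
        if calibrator not in cq.columns:
            raise ValueError(f"calibrator sample {calibrator!r} not in table")
        ref = cq[calibrator]
    a = eff.to_numpy()[:, None]
    q = a ** (ref.to_numpy()[:, None] - cq.to_numpy())
    return QuantityMatrix(
        q=pd.DataFrame(q, index=cq.index, columns=cq.columns),
        efficiencies=eff,
    )


class CqQuantityTransformer(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer mapping Cq values to relative quantities.

    Follows the sklearn orientation: ``X`` is ``(n_samples, n_genes)``.
    ``fit`` learns each gene's calibrator Cq (the column minimum over the
    training data); ``transform`` returns
    ``efficiency ** (calibrator_cq - X)``.  Missing (NaN) entries propagate.

    Parameters
    ----------
    efficiency : float, default 2.0
        Per-cycle amplification factor applied to every gene; 2.0 means
        100% efficiency.
    """

    def __init__(self, efficiency: float = 2.0):
        self.efficiency = efficiency

    def fit(self, X, y=None):
        X = self._check(X, reset=True)
        self.calibrator_cq_ = np.nanmin(X, axis=0)
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "calibrator_cq_")
        X = self._check(X, reset=False)
        return self.efficiency ** (self.calibrator_cq_[None, :] - X)

    def get_feature_names_out(self, input_features=None):
        if input_features is not None:
            return np.asarray(input_features, dtype=object)
        if hasattr(self, "feature_names_in_"):
            return np.asarray(self.feature_names_in_, dtype=object)
        return np.asarray(
            [f"gene{i}" for i in range(self.n_features_in_)], dtype=object
        )

    def _check(self, X, reset: bool) -> np.ndarray:
        if not 1.0 < self.efficiency <= 3.0:
            raise ValueError("efficiency must lie in (1, 3]")
        if isinstance(X, pd.DataFrame):
            names = np.asarray(X.columns, dtype=object)
            arr = X.to_numpy(dtype=float)
        else:
            names = None
            arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x genes)")
        if reset:
            self.n_features_in_ = arr.shape[1]
            if names is not None:
                self.feature_names_in_ = names
        elif arr.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {arr.shape[1]} genes, expected {self.n_features_in_}"
            )
        return arr
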