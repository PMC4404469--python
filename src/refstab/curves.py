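"""Standard-curve fitting, amplification efficiency and fold-abundance.

A qPCR standard curve regresses Cq on log10 template dilution over a serial
dilution series.  The slope gives the reaction's amplification efficiency

    E(%) = (10^(-1/slope) - 1) x 100,

which is 100% (perfect per-cycle doubling) at slope -1/log10(2) = -3.3219.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "compute_efficiency",
    "fit_standard_curve",
    "fold_abundance",
]


def compute_efficiency(slope: float) -> float:
    """Amplification efficiency in percent from a standard-curve slope.

    ``slope`` is in cycles per log10 dilution unit and must be negative
    (Cq decreases with more template).  Returns
    ``(10 ** (-1 / slope) - 1) * 100``.
    """
    if not np.isfinite(slope) or slope >= 0:
        raise ValueError(
            f"standard-curve slope must be negative, got {slope!r}"
        )
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


@dataclass(frozen=True)
class StandardCurve:
    """Ordinary least-squares fit of Cq on log10 relative template amount."""

    gene_id: str
    log10_dilutions: tuple
    mean_cq_per_dilution: tuple
    slope: float  # cycles per log10 unit, < 0
    intercept: float  # cycles
    r_squared: float

    @property
    def efficiency_percent(self) -> float:
        return compute_efficiency(self.slope)

    @property
    def amplification_factor(self) -> float:
        """Per-cycle amplification factor, ``1 + E/100`` (2.0 at 100%)."""
        return 1.0 + self.efficiency_percent / 100.0


def fit_standard_curve(
    dilution_cq_pairs: Iterable[Sequence[float]], gene_id: str = ""
) -> StandardCurve:
    """Fit a standard curve to ``(log10 dilution, mean Cq)`` pairs.

    Requires at least three distinct dilution levels.  A non-negative slope
    (no amplification trend) is rejected.
    """
    pairs = np.asarray(list(dilution_cq_pairs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("expected pairs of (log10 dilution, mean Cq)")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.unique(x).size < 3:
        raise ValueError(
            f"need >=3 distinct dilution levels, got {np.unique(x).size}"
        )
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(
            f"non-amplifying curve: slope {fit.slope:.4g} >= 0"
        )
    return StandardCurve(
        gene_id=gene_id,
        log10_dilutions=tuple(x),
        mean_cq_per_dilution=tuple(y),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


def fold_abundance(cq_low: float, cq_high: float,
                   amplification_factor: float = 2.0) -> float:
    """Fold difference in template abundance implied by two Cq values.

    With per-cycle amplification factor ``A`` the template reaching threshold
    ``cq_high - cq_low`` cycles later is ``A ** (cq_high - cq_low)``-fold less
    abundant; that factor is returned (values below 1 when
    ``cq_high < cq_low``).
    """
    if amplification_factor <= 1:
        raise ValueError("amplification_factor must exceed 1")
    return float(amplification_factor) ** (cq_high - cq_low)
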