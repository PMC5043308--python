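"""Log-log power-law (allometric) fits of metabolic quantities on body mass.

Kleiber's law states whole-organism metabolic rate scales as B ∝ M^(3/4),
so the mass-specific rate B_c = B/M scales as M^(−1/4).  Fitting is
ordinary least squares in log10–log10 space: the slope is the allometric
exponent, and r/p come from the Pearson correlation of the logged
variables.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import ValidationError

__all__ = ["AllometricFit", "fit_power_law"]


@dataclass(frozen=True)
class AllometricFit:
    """OLS fit of log10(rate) on log10(mass).

    ``exponent`` is the slope (scaling exponent per decade of mass),
    ``exponent_se`` its standard OLS standard error, and ``r``/``p_value``
    the Pearson correlation of the logged variables with a two-sided t test
    at n − 2 degrees of freedom.
    """

    exponent: float
    exponent_se: float
    intercept_log10: float
    r: float
    p_value: float
    n: int


def fit_power_law(mass: np.ndarray, rate: np.ndarray) -> AllometricFit:
    """Fit ``rate = c · mass^exponent`` by OLS on base-10 logs.

    Both inputs must be positive with equal length ≥ 3; zero variance in
    either logged variable is a degenerate fit and raises
    :class:`~petoscan.data_model.ValidationError`.
    """
    mass = np.asarray(mass, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if mass.shape != rate.shape or mass.ndim != 1:
        raise ValidationError("mass and rate must be 1-D vectors of equal length")
    if mass.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.any(mass <= 0) or np.any(rate <= 0):
        raise ValidationError("mass and rate must be strictly positive")
    x = np.log10(mass)
    y = np.log10(rate)
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in log mass; exponent undefined")
    if np.ptp(y) == 0:
        raise ValidationError("zero variance in log rate; fit degenerate")
    res = stats.linregress(x, y)
    return AllometricFit(
        exponent=float(res.slope),
        exponent_se=float(res.stderr),
        intercept_log10=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=int(mass.size),
    )
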