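"""Dataset-level summaries of a category scan.

Three views of the per-category results: the distribution of correlation
coefficients (mean with a 95% CI), the fraction of categories significant
at a threshold, and the correlation-of-correlations diagnostic — the
Pearson correlation, across categories, between the NOGF–M and NOGF–B_c
correlation vectors.  A strongly negative correlation-of-correlations is
the fingerprint of mass-specific metabolic rate driving apparent
NOGF–body-size associations.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation_scan import CategoryResult, pearson
from .data_model import ValidationError

logger = logging.getLogger("petoscan")

__all__ = [
    "MetaSummary",
    "summarize_r_distribution",
    "significant_fraction",
    "correlation_of_correlations",
    "build_meta_summary",
]


@dataclass(frozen=True)
class MetaSummary:
    """One scan variant's dataset-level numbers."""

    variant: str
    mean_r: float
    ci95_low: float
    ci95_high: float
    n_significant: int
    n_total: int
    frac_significant: float
    meta_corr_r: float
    meta_corr_p: float
    n_excluded: int


def _defined_values(results: list[CategoryResult], attr: str) -> np.ndarray:
    vals = [getattr(r, attr) for r in results if r.defined and math.isfinite(getattr(r, attr))]
    return np.asarray(vals, dtype=float)


def summarize_r_distribution(
    results: list[CategoryResult],
    field: str = "r_M",
    method: str = "normal",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Mean of the chosen correlation field with a 95% CI.

    ``method="normal"``: mean ± 1.96·sd/sqrt(k).  ``method="bootstrap"``:
    percentile interval over ``n_boot`` resamples.  Flagged categories are
    excluded.
    """
    if field not in ("r_M", "r_partial", "r_Bc"):
        raise ValueError(f"unsupported field: {field!r}")
    vals = _defined_values(results, field)
    if vals.size < 2:
        raise ValidationError("need at least 2 defined correlation values")
    mean = float(vals.mean())
    if method == "normal":
        half = 1.96 * float(vals.std(ddof=1)) / math.sqrt(vals.size)
        return mean, (mean - half, mean + half)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
        boot_means = vals[idx].mean(axis=1)
        lo, hi = np.percentile(boot_means, [2.5, 97.5])
        return mean, (float(lo), float(hi))
    raise ValueError(f"unknown CI method: {method!r}")


def significant_fraction(
    results: list[CategoryResult], field: str = "p_M", alpha: float = 0.05
) -> tuple[int, float]:
    """Count and fraction of defined categories with p strictly below alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if field not in ("p_M", "p_partial", "p_Bc"):
        raise ValueError(f"unsupported field: {field!r}")
    vals = _defined_values(results, field)
    if vals.size == 0:
        return 0, 0.0
    count = int((vals < alpha).sum())
    return count, count / vals.size


def correlation_of_correlations(results: list[CategoryResult]) -> tuple[float, float]:
    """Pearson correlation across categories of r_M against r_Bc.

    Categories with undefined correlations are excluded (logged); at least
    three defined categories are required.
    """
    pairs = [
        (r.r_M, r.r_Bc)
        for r in results
        if r.defined and math.isfinite(r.r_M) and math.isfinite(r.r_Bc)
    ]
    n_excluded = len(results) - len(pairs)
    if n_excluded:
        logger.info("correlation_of_correlations: excluded %d undefined categories", n_excluded)
    if len(pairs) < 3:
        raise ValidationError("need at least 3 categories with defined r_M and r_Bc")
    arr = np.asarray(pairs)
    return pearson(arr[:, 0], arr[:, 1])


def build_meta_summary(
    results: list[CategoryResult],
    variant: str = "uncorrected",
    alpha: float = 0.05,
    ci_method: str = "normal",
    seed: int = 0,
) -> MetaSummary:
    """Assemble the full meta summary for one scan variant.

    ``variant="uncorrected"`` summarizes (r_M, p_M); ``"corrected"``
    summarizes (r_partial, p_partial).
    """
    field_r, field_p = {
        "uncorrected": ("r_M", "p_M"),
        "corrected": ("r_partial", "p_partial"),
    }.get(variant, ("r_M", "p_M"))
    mean, (lo, hi) = summarize_r_distribution(results, field_r, method=ci_method, seed=seed)
    count, frac = significant_fraction(results, field_p, alpha)
    meta_r, meta_p = correlation_of_correlations(results)
    n_defined = _defined_values(results, field_r).size
    return MetaSummary(
        variant=variant,
        mean_r=mean,
        ci95_low=lo,
        ci95_high=hi,
        n_significant=count,
        n_total=n_defined,
        frac_significant=frac,
        meta_corr_r=meta_r,
        meta_corr_p=meta_p,
        n_excluded=len(results) - n_defined,
    )


def meta_summaries_to_frame(summaries: list[MetaSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
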