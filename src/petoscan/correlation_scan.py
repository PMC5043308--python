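"""Per-category association of NOGF with body mass and metabolic rate.

For every functional category the scan reports:

* the simple Pearson correlation of the gene count with log10 M (and with
  log10 B_c);
* the first-order partial correlation of count with log10 M given
  log10 B_c — the B_c-corrected association, r_p;
* the standardized partial regression coefficient of log10 M in the
  two-predictor model ``NOGF ~ log10 M + log10 B_c``.

Counts enter untransformed; only M and B_c are log-transformed.  p-values
are two-sided t tests: df = n−2 for simple correlations, n−3 for the
first-order partial.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import FunctionMatrix, Hierarchy, SpeciesTable, ValidationError

logger = logging.getLogger("petoscan")

__all__ = [
    "CategoryResult",
    "pearson",
    "partial_corr",
    "residuals",
    "standardized_partial_regression",
    "scan",
    "results_to_frame",
]


@dataclass
class CategoryResult:
    """Association statistics for one functional category.

    ``defined`` is False for degenerate categories (zero count variance),
    which are reported flagged rather than silently dropped; their numeric
    fields are NaN.
    """

    category_id: str
    upper_category_id: str | None
    r_M: float
    p_M: float
    r_Bc: float
    p_Bc: float
    r_partial: float
    p_partial: float
    beta_M_std: float
    r2_simple: float
    r2_corrected: float
    n: int
    defined: bool = True
    note: str = ""
    variant: str = "tips"


def _corr_p(r: float, df: int) -> float:
    """Two-sided p for a correlation via the t transform at ``df`` degrees
    of freedom."""
    r = min(1.0, max(-1.0, r))
    if df <= 0:
        return float("nan")
    denom = 1.0 - r * r
    if denom <= 0.0:
        return 0.0
    t = r * math.sqrt(df) / math.sqrt(denom)
    return float(2.0 * stats.t.sf(abs(t), df))


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-test p-value (df = n − 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson: inputs must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValidationError("pearson: need n >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = math.sqrt(float(dx @ dx))
    sy = math.sqrt(float(dy @ dy))
    if sx == 0:
        raise ValidationError("pearson: zero variance in x")
    if sy == 0:
        raise ValidationError("pearson: zero variance in y")
    r = float(dx @ dy) / (sx * sy)
    r = min(1.0, max(-1.0, r))
    return r, _corr_p(r, n - 2)


def partial_corr(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> tuple[float, float]:
    """First-order partial correlation of x and y given z.

    r_p = (r_xy − r_xz·r_yz) / sqrt((1 − r_xz²)(1 − r_yz²)); two-sided p
    from t at df = n − 3.  A perfect confound (|r_xz| = 1 or |r_yz| = 1)
    leaves r_p undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValidationError("partial_corr: inputs must be 1-D vectors of equal length")
    if x.size < 4:
        raise ValidationError("partial_corr: need n >= 4")
    r_xy, _ = pearson(x, y)
    r_xz, _ = pearson(x, z)
    r_yz, _ = pearson(y, z)
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise ValidationError(
            "partial_corr: conditioning variable perfectly collinear with x or y"
        )
    r_p = (r_xy - r_xz * r_yz) / math.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    r_p = min(1.0, max(-1.0, r_p))
    return r_p, _corr_p(r_p, x.size - 3)


def residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """OLS residuals of y on x (with intercept): sum to 0, orthogonal to x."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("residuals: inputs must be 1-D vectors of equal length")
    if np.ptp(x) == 0:
        raise ValidationError("residuals: constant predictor")
    dx = x - x.mean()
    slope = float(dx @ (y - y.mean())) / float(dx @ dx)
    intercept = y.mean() - slope * x.mean()
    return y - (intercept + slope * x)


def standardized_partial_regression(
    g: np.ndarray, log_m: np.ndarray, log_bc: np.ndarray
) -> float:
    """Standardized coefficient of log10 M in ``g ~ log10 M + log10 B_c``.

    The raw OLS coefficient of M is rescaled by sd(log M)/sd(g), equivalent
    to z-scoring every variable before the fit.
    """
    g = np.asarray(g, dtype=float)
    log_m = np.asarray(log_m, dtype=float)
    log_bc = np.asarray(log_bc, dtype=float)
    if not (g.shape == log_m.shape == log_bc.shape) or g.ndim != 1:
        raise ValidationError("inputs must be 1-D vectors of equal length")
    n = g.size
    if n < 4:
        raise ValidationError("need n >= 4")
    X = np.column_stack([np.ones(n), log_m, log_bc])
    if np.linalg.matrix_rank(X) < 3:
        raise ValidationError("predictors perfectly collinear; design rank-deficient")
    sd_g = g.std(ddof=1)
    if sd_g == 0:
        raise ValidationError("response has zero variance")
    coef, *_ = np.linalg.lstsq(X, g, rcond=None)
    return float(coef[1] * log_m.std(ddof=1) / sd_g)


def _flagged(category_id: str, upper: str | None, n: int, note: str, variant: str = "tips") -> CategoryResult:
    nan = float("nan")
    return CategoryResult(
        category_id, upper, nan, nan, nan, nan, nan, nan, nan, nan, nan,
        n, defined=False, note=note, variant=variant,
    )


def scan(
    matrix: FunctionMatrix,
    species: SpeciesTable,
    hierarchy: Hierarchy | None = None,
) -> list[CategoryResult]:
    """One :class:`CategoryResult` per category against log10 M and log10 B_c.

    Species are intersected between matrix and table (mismatches are logged,
    mirroring how a species absent from one source is dropped rather than
    fatal); fewer than 4 shared species is an error.  Constant-count
    categories are returned flagged.
    """
    table_ids = set(species.species_ids)
    common = [s for s in matrix.species_ids if s in table_ids]
    n_dropped = (len(matrix.species_ids) - len(common)) + (len(species) - len(common))
    if n_dropped:
        logger.warning("scan: %d species dropped in matrix/table intersection", n_dropped)
    if len(common) < 4:
        raise ValidationError(f"scan: only {len(common)} species shared; need >= 4")
    sub_matrix = matrix.subset_species(common)
    sub_species = species.subset(common)
    log_m = sub_species.log10_mass
    log_bc = sub_species.log10_bc
    n = len(common)

    results: list[CategoryResult] = []
    for j, cat in enumerate(sub_matrix.category_ids):
        g = sub_matrix.counts[:, j].astype(float)
        upper = hierarchy.upper_of(cat) if hierarchy is not None and cat in hierarchy else None
        if np.ptp(g) == 0:
            results.append(_flagged(cat, upper, n, "constant counts; correlations undefined"))
            continue
        r_m, p_m = pearson(g, log_m)
        r_bc, p_bc = pearson(g, log_bc)
        r_p, p_p = partial_corr(g, log_m, log_bc)
        beta = standardized_partial_regression(g, log_m, log_bc)
        results.append(
            CategoryResult(
                category_id=cat,
                upper_category_id=upper,
                r_M=r_m,
                p_M=p_m,
                r_Bc=r_bc,
                p_Bc=p_bc,
                r_partial=r_p,
                p_partial=p_p,
                beta_M_std=beta,
                r2_simple=r_m * r_m,
                r2_corrected=r_p * r_p,
                n=n,
            )
        )
    return results


_COLUMNS = [
    "category_id", "upper_category_id", "r_M", "p_M", "r_Bc", "p_Bc",
    "r_partial", "p_partial", "beta_M_std", "r2_simple", "r2_corrected",
    "n", "defined", "note", "variant",
]


def results_to_frame(results: list[CategoryResult], fdr: bool = False) -> pd.DataFrame:
    """Tabulate results; with ``fdr=True`` append Benjamini–Hochberg adjusted
    p-values for the simple and partial tests (over defined categories)."""
    df = pd.DataFrame([{c: getattr(r, c) for c in _COLUMNS} for r in results])
    if fdr and len(df):
        for col in ("p_M", "p_partial"):
            adj = np.full(len(df), np.nan)
            mask = df["defined"].to_numpy() & np.isfinite(df[col].to_numpy(float))
            if mask.any():
                adj[mask] = stats.false_discovery_control(df.loc[mask, col].to_numpy(float))
            df[col + "_bh"] = adj
    return df
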