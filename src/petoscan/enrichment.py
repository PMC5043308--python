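"""Fisher's-exact-test enrichment of body-size-correlated categories within
second-level functional categories.

For each second-level (upper) category the 2×2 table is

    a = significant categories inside      b = non-significant inside
    c = significant categories outside     d = non-significant outside

where "significant" means p < alpha on the chosen field of the scan
(uncorrected p_M or B_c-corrected p_partial).  Significance is reported as
−log10 of the Fisher p-value; the one-sided (greater) test asks for
over-representation, and the two-sided p follows the R ``fisher.test``
convention (sum of all table probabilities ≤ the observed one, with a
1 + 1e−7 relative guard against ties lost to rounding).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .correlation_scan import CategoryResult
from .data_model import Hierarchy, ValidationError

logger = logging.getLogger("petoscan")

__all__ = ["EnrichmentResult", "fisher_exact_2x2", "enrich", "enrichment_to_frame"]

_R_GAMMA = 1.0 + 1e-7  # relative tie tolerance, as in R's fisher.test


@dataclass(frozen=True)
class EnrichmentResult:
    upper_category_id: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    neg_log10_p: float
    p_greater: float
    p_two_sided: float


def _hypergeom_logpmf_support(N: int, r1: int, c1: int) -> tuple[np.ndarray, int]:
    """Log-pmf of cell ``a`` over its support for fixed margins.

    Margins: row total r1 = a+b, column total c1 = a+c, grand total N.
    Returns (logpmf vector, a_min).
    """
    a_min = max(0, r1 + c1 - N)
    a_max = min(r1, c1)
    a = np.arange(a_min, a_max + 1)
    logpmf = (
        gammaln(r1 + 1) - gammaln(a + 1) - gammaln(r1 - a + 1)
        + gammaln(N - r1 + 1) - gammaln(c1 - a + 1) - gammaln(N - r1 - (c1 - a) + 1)
        - (gammaln(N + 1) - gammaln(c1 + 1) - gammaln(N - c1 + 1))
    )
    return logpmf, a_min


def _fisher_pvalues_for_margins(N: int, r1: int, c1: int, sided: str) -> tuple[np.ndarray, int]:
    """p-values for every value of cell ``a`` compatible with the margins.

    Returns (p vector over the support, a_min).  One pmf evaluation serves
    the whole margin set, which keeps exhaustive verification cheap.
    """
    logpmf, a_min = _hypergeom_logpmf_support(N, r1, c1)
    pmf = np.exp(logpmf - logpmf.max())
    if sided == "greater":
        tail = np.cumsum(pmf[::-1])[::-1]
        p = tail / pmf.sum()
    else:
        # R convention: sum every table whose probability is <= observed,
        # with a (1 + 1e-7) relative guard against ties lost to rounding
        mask = pmf[None, :] <= pmf[:, None] * _R_GAMMA
        p = (mask * pmf[None, :]).sum(axis=1) / pmf.sum()
    return np.minimum(p, 1.0), a_min


def fisher_exact_2x2(a: int, b: int, c: int, d: int, sided: str = "greater") -> float:
    """Exact hypergeometric p-value for the 2×2 table [[a, b], [c, d]].

    ``sided="greater"``: upper tail P(A ≥ a) under odds ratio 1.
    ``sided="two_sided"``: sum of probabilities of all tables with the same
    margins whose probability does not exceed the observed one.
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValidationError(f"cells must be nonnegative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    N = a + b + c + d
    if N < 1:
        raise ValidationError("table total must be >= 1")
    if sided not in ("greater", "two_sided"):
        raise ValueError(f"sided must be 'greater' or 'two_sided', got {sided!r}")
    p, a_min = _fisher_pvalues_for_margins(N, a + b, a + c, sided)
    return float(p[a - a_min])


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio (a·d)/(b·c), Haldane-corrected when any cell is 0."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def enrich(
    results: list[CategoryResult],
    hierarchy: Hierarchy,
    field: str = "p_M",
    alpha: float = 0.05,
    sided: str = "greater",
) -> list[EnrichmentResult]:
    """Per-upper-category enrichment of significant scan results.

    Every defined category must be mapped in the hierarchy (missing ones are
    an error, listed by id).  Flagged (undefined) categories carry no
    p-value and are excluded, with a logged count.  Results are sorted by
    −log10 p descending (ties by upper-category id).
    """
    if field not in ("p_M", "p_partial"):
        raise ValueError(f"unsupported field: {field!r}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    defined = [r for r in results if r.defined and math.isfinite(getattr(r, field))]
    n_excluded = len(results) - len(defined)
    if n_excluded:
        logger.info("enrich: excluded %d categories with undefined p-values", n_excluded)
    missing = [r.category_id for r in defined if r.category_id not in hierarchy]
    if missing:
        raise ValidationError(f"categories missing from hierarchy: {missing}")

    sig = {r.category_id: getattr(r, field) < alpha for r in defined}
    upper_of = {r.category_id: hierarchy.upper_of(r.category_id) for r in defined}
    uppers: dict[str, None] = {}
    for u in upper_of.values():
        uppers.setdefault(u)

    total = len(defined)
    total_sig = sum(sig.values())
    out: list[EnrichmentResult] = []
    for upper in uppers:
        inside = [cid for cid, u in upper_of.items() if u == upper]
        a = sum(sig[cid] for cid in inside)
        b = len(inside) - a
        c = total_sig - a
        d = (total - len(inside)) - c
        p_g = fisher_exact_2x2(a, b, c, d, sided="greater")
        p_2 = fisher_exact_2x2(a, b, c, d, sided="two_sided")
        p = p_g if sided == "greater" else p_2
        out.append(
            EnrichmentResult(
                upper_category_id=upper,
                a=a, b=b, c=c, d=d,
                odds_ratio=_sample_odds_ratio(a, b, c, d),
                p_value=p,
                neg_log10_p=-math.log10(p),
                p_greater=p_g,
                p_two_sided=p_2,
            )
        )
    out.sort(key=lambda r: (-r.neg_log10_p, r.upper_category_id))
    return out


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
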