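"""Felsenstein's phylogenetically independent contrasts (PIC) and
contrast-based association.

Species trait values are not independent draws: close relatives inherit
similar traits.  Under a Brownian-motion model of trait evolution on a
rooted tree with branch lengths, the pruning recursion turns n tip values
into n − 1 standardized contrasts that are independent and identically
distributed.  At each internal node with child values x1, x2 on (noise-
augmented) branches v1, v2:

    contrast   = (x1 − x2) / sqrt(v1 + v2)
    node value = (x1/v1 + x2/v2) / (1/v1 + 1/v2)
    parent branch gains v1·v2 / (v1 + v2)

Contrast signs are arbitrary; here the subtraction order is fixed by the
lexicographically smallest tip label of each child subtree, so outputs are
reproducible.  Contrast pairs are correlated through the origin (contrasts
have no natural mean), with df = k − 1, one fewer again for the partial
correlation.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .correlation_scan import CategoryResult, _corr_p, _flagged
from .data_model import FunctionMatrix, Hierarchy, PhyloTree, SpeciesTable, ValidationError

logger = logging.getLogger("petoscan")

__all__ = [
    "PolytomyError",
    "ContrastSet",
    "compute_contrasts",
    "corr_through_origin",
    "partial_corr_through_origin",
    "pic_scan",
]

#: added to a zero denominator inside the standardization only
DEFAULT_EPSILON = 1e-8


class PolytomyError(ValidationError):
    """The contrasts recursion requires a strictly binary tree."""


@dataclass
class ContrastSet:
    """Standardized contrasts, one per internal node of the (pruned) tree."""

    contrasts: np.ndarray
    node_ids: list[str]
    label: str

    def __post_init__(self) -> None:
        self.contrasts = np.asarray(self.contrasts, dtype=float)
        if self.contrasts.size != len(self.node_ids):
            raise ValidationError("contrasts and node_ids must align")
        if not np.all(np.isfinite(self.contrasts)):
            raise ValidationError("contrasts must be finite")

    def __len__(self) -> int:
        return int(self.contrasts.size)


def compute_contrasts(
    tree: PhyloTree,
    trait: dict[str, float],
    label: str = "trait",
    epsilon: float = DEFAULT_EPSILON,
) -> ContrastSet:
    """Run the pruning recursion on a binary tree.

    Every tip must have a value in ``trait``.  A zero contrast denominator
    (both child branches of length 0) is regularized by ``epsilon`` with a
    logged warning rather than failing.
    """
    tips = tree.tips()
    missing = [t.name for t in tips if t.name not in trait]
    if missing:
        raise ValidationError(f"tips without trait values: {missing}")

    value: dict[int, float] = {}
    var: dict[int, float] = {}
    min_label: dict[int, str] = {}
    contrasts: list[float] = []
    node_ids: list[str] = []

    for node in tree.postorder():
        if node.is_leaf():
            value[id(node)] = float(trait[node.name])
            var[id(node)] = float(node.branch_length or 0.0)
            min_label[id(node)] = node.name
            continue
        if len(node.children) != 2:
            raise PolytomyError(
                f"node with {len(node.children)} children; resolve polytomies first"
            )
        kids = sorted(node.children, key=lambda c: min_label[id(c)])
        (x1, v1), (x2, v2) = ((value[id(k)], var[id(k)]) for k in kids)
        denom = v1 + v2
        if denom == 0.0:
            logger.warning("compute_contrasts: zero branch-length sum; epsilon-regularized")
            denom = epsilon
            v1 = v2 = denom / 2.0
        contrasts.append((x1 - x2) / math.sqrt(denom))
        node_ids.append(f"{min_label[id(kids[0])]}+{min_label[id(kids[1])]}")
        value[id(node)] = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
        var[id(node)] = float(node.branch_length or 0.0) + (v1 * v2) / (v1 + v2)
        min_label[id(node)] = min_label[id(kids[0])]

    return ContrastSet(np.asarray(contrasts), node_ids, label)


def _check_aligned(cx: ContrastSet, cy: ContrastSet) -> None:
    if cx.node_ids != cy.node_ids:
        raise ValidationError("contrast sets come from different trees or prunings")


def corr_through_origin(cx: ContrastSet, cy: ContrastSet) -> tuple[float, float]:
    """Correlation of contrasts constrained through the origin.

    r = Σx·y / sqrt(Σx²·Σy²); two-sided p from t at df = k − 1.
    """
    _check_aligned(cx, cy)
    x, y = cx.contrasts, cy.contrasts
    k = x.size
    if k < 2:
        raise ValidationError("need at least 2 contrasts")
    ssx = float(x @ x)
    ssy = float(y @ y)
    if ssx == 0.0:
        raise ValidationError(f"zero sum of squares in contrasts of {cx.label!r}")
    if ssy == 0.0:
        raise ValidationError(f"zero sum of squares in contrasts of {cy.label!r}")
    r = float(x @ y) / math.sqrt(ssx * ssy)
    r = min(1.0, max(-1.0, r))
    return r, _corr_p(r, k - 1)


def partial_corr_through_origin(
    cg: ContrastSet, cx: ContrastSet, cz: ContrastSet
) -> tuple[float, float]:
    """First-order partial correlation of contrasts cg and cx given cz,
    built from the three through-origin correlations; df = k − 2."""
    r_gx, _ = corr_through_origin(cg, cx)
    r_gz, _ = corr_through_origin(cg, cz)
    r_xz, _ = corr_through_origin(cx, cz)
    if abs(r_gz) >= 1.0 - 1e-12 or abs(r_xz) >= 1.0 - 1e-12:
        raise ValidationError("perfect collinearity among contrast sets")
    r_p = (r_gx - r_gz * r_xz) / math.sqrt((1.0 - r_gz**2) * (1.0 - r_xz**2))
    r_p = min(1.0, max(-1.0, r_p))
    return r_p, _corr_p(r_p, len(cg) - 2)


def _beta_std_through_origin(cg: ContrastSet, cm: ContrastSet, cbc: ContrastSet) -> float:
    """No-intercept two-predictor regression coefficient of the M contrasts,
    scaled to standardized units by the root-sum-of-squares ratio."""
    X = np.column_stack([cm.contrasts, cbc.contrasts])
    if np.linalg.matrix_rank(X) < 2:
        raise ValidationError("contrast predictors perfectly collinear")
    coef, *_ = np.linalg.lstsq(X, cg.contrasts, rcond=None)
    ss_g = float(cg.contrasts @ cg.contrasts)
    ss_m = float(cm.contrasts @ cm.contrasts)
    return float(coef[0]) * math.sqrt(ss_m / ss_g)


def pic_scan(
    matrix: FunctionMatrix,
    species: SpeciesTable,
    tree: PhyloTree,
    hierarchy: Hierarchy | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> list[CategoryResult]:
    """Contrast-based analogue of :func:`petoscan.correlation_scan.scan`.

    Species are intersected across matrix, table, and tree tips; missing
    ones (e.g. a species absent from the tree) are dropped with a logged
    warning.  The tree is pruned to the shared set and must be binary.
    Reported n is the number of contrasts k = tips − 1.
    """
    tip_set = set(tree.leaf_labels)
    table_set = set(species.species_ids)
    common = [s for s in matrix.species_ids if s in table_set and s in tip_set]
    n_dropped = len(set(matrix.species_ids) | table_set | tip_set) - len(common)
    if n_dropped:
        logger.warning("pic_scan: %d species dropped from matrix/table/tree intersection", n_dropped)
    if len(common) < 4:
        raise ValidationError(f"pic_scan: only {len(common)} species shared; need >= 4")

    pruned = tree.prune_to(common)
    if not pruned.is_binary():
        raise PolytomyError("pruned tree contains polytomies; resolve them first")
    sub_matrix = matrix.subset_species(common)
    sub_species = species.subset(common)

    trait_m = dict(zip(common, sub_species.log10_mass))
    trait_bc = dict(zip(common, sub_species.log10_bc))
    cm = compute_contrasts(pruned, trait_m, "log10_M", epsilon)
    cbc = compute_contrasts(pruned, trait_bc, "log10_Bc", epsilon)
    k = len(cm)

    results: list[CategoryResult] = []
    for j, cat in enumerate(sub_matrix.category_ids):
        g = sub_matrix.counts[:, j].astype(float)
        upper = hierarchy.upper_of(cat) if hierarchy is not None and cat in hierarchy else None
        cg = compute_contrasts(pruned, dict(zip(common, g)), cat, epsilon)
        if float(cg.contrasts @ cg.contrasts) == 0.0:
            results.append(_flagged(cat, upper, k, "zero contrast variance", variant="pic"))
            continue
        r_m, p_m = corr_through_origin(cg, cm)
        r_bc, p_bc = corr_through_origin(cg, cbc)
        r_p, p_p = partial_corr_through_origin(cg, cm, cbc)
        beta = _beta_std_through_origin(cg, cm, cbc)
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
                n=k,
                variant="pic",
            )
        )
    return results
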