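"""End-to-end orchestration: load or simulate a cohort, run the scans, and
write a reproducible report bundle of TSV tables plus a YAML manifest."""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allometry import fit_power_law
from .correlation_scan import CategoryResult, results_to_frame, scan
from .data_model import (
    FunctionMatrix,
    Hierarchy,
    SpeciesTable,
    ValidationError,
    parse_newick,
)
from .enrichment import enrich, enrichment_to_frame
from .meta_analysis import build_meta_summary, meta_summaries_to_frame
from .pic import pic_scan
from .synthetic_data import (
    GroundTruth,
    SyntheticConfig,
    generate_function_matrix,
    generate_species,
    generate_tree,
)

logger = logging.getLogger("petoscan")

__all__ = ["RunConfig", "run_full_analysis", "top_table", "confusion_table"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of synthetic mode (``synthetic`` set) or file inputs
    (``species_path`` + ``matrix_path`` [+ hierarchy/tree]) must be active.
    """

    synthetic: SyntheticConfig | None = None
    species_path: str | None = None
    matrix_path: str | None = None
    hierarchy_path: str | None = None
    tree_path: str | None = None
    alpha: float = 0.05
    enrichment_sided: str = "greater"
    ci_method: str = "normal"
    fdr: bool = False
    run_pic: bool = True
    out_dir: str = "petoscan_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        file_mode = self.species_path is not None or self.matrix_path is not None
        if self.synthetic is not None and file_mode:
            raise ValidationError("choose either synthetic mode or file inputs, not both")
        if self.synthetic is None and not file_mode:
            raise ValidationError("no inputs: set synthetic config or input paths")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(synthetic=SyntheticConfig(**syn) if syn is not None else None, **raw)
        return cfg


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic is not None:
        syn = cfg.synthetic
        tree = generate_tree(syn.n_species, syn.seed) if (cfg.run_pic or syn.mass_mode == "bm") else None
        species = generate_species(syn, tree=tree if syn.mass_mode == "bm" else None)
        matrix, truth, hierarchy = generate_function_matrix(species, syn)
        return species, matrix, hierarchy, tree, truth
    species = SpeciesTable.read_tsv(cfg.species_path)
    matrix = FunctionMatrix.read_tsv(cfg.matrix_path)
    hierarchy = Hierarchy.read_tsv(cfg.hierarchy_path) if cfg.hierarchy_path else None
    tree = None
    if cfg.tree_path:
        tree = parse_newick(Path(cfg.tree_path).read_text())
    return species, matrix, hierarchy, tree, None


def top_table(
    results: list[CategoryResult], p_threshold: float = 0.01
) -> pd.DataFrame:
    """Categories with p_partial below threshold, in descending r_partial
    order (ties resolved by category id, so the order is stable)."""
    rows = [
        r for r in results
        if r.defined and np.isfinite(r.p_partial) and r.p_partial < p_threshold
    ]
    rows.sort(key=lambda r: (-r.r_partial, r.category_id))
    return pd.DataFrame(
        [
            {
                "upper_category_id": r.upper_category_id,
                "category_id": r.category_id,
                "r_partial": r.r_partial,
                "p_partial": r.p_partial,
                "r_M": r.r_M,
                "p_M": r.p_M,
            }
            for r in rows
        ]
    )


def confusion_table(
    results: list[CategoryResult], truth: GroundTruth, alpha: float = 0.05
) -> pd.DataFrame:
    """Cross-tabulate generative class against scan significance.

    For each class: how many categories are significant in the uncorrected
    scan (p_M < alpha) and in the B_c-corrected scan (p_partial < alpha).
    """
    by_cat = {r.category_id: r for r in results}
    rows = []
    for class_label, grp in truth.frame.groupby("class", sort=False):
        cats = [by_cat[c] for c in grp["category_id"] if c in by_cat]
        defined = [r for r in cats if r.defined]
        rows.append(
            {
                "class": class_label,
                "n": len(cats),
                "n_defined": len(defined),
                "sig_uncorrected": sum(r.p_M < alpha for r in defined),
                "sig_corrected": sum(r.p_partial < alpha for r in defined),
                "frac_sig_uncorrected": (
                    sum(r.p_M < alpha for r in defined) / len(defined) if defined else float("nan")
                ),
                "frac_sig_corrected": (
                    sum(r.p_partial < alpha for r in defined) / len(defined) if defined else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``cfg.out_dir``.

    Outputs: scan_results.tsv (simple + partial per category),
    pic_results.tsv (if a tree is available and PIC is on),
    meta_summary.tsv, enrichment_{uncorrected,corrected}.tsv,
    allometric_fit.tsv, top_table.tsv, confusion_table.tsv (synthetic runs
    only), and manifest.yaml recording config, seed and versions.
    Deterministic given the seed: rerunning writes byte-identical tables.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        species, matrix, hierarchy, tree, truth = _load_inputs(cfg)
    except Exception as err:
        raise type(err)(f"[input stage] {err}") from err

    bundle: dict = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as err:
            raise type(err)(f"[{name} stage] {err}") from err

    mass = species.frame["body_mass_g"].to_numpy(float)
    fits = stage("allometry", lambda: pd.DataFrame(
        [
            {"response": "B", **fit_power_law(mass, species.frame["metabolic_rate_W"].to_numpy(float)).__dict__}
            if "metabolic_rate_W" in species.frame.columns
            else None,
            {"response": "Bc", **fit_power_law(mass, species.frame["mass_specific_rate_Wg"].to_numpy(float)).__dict__},
        ]
    ).dropna(how="all"))
    bundle["allometric_fit"] = fits

    results = stage("scan", lambda: scan(matrix, species, hierarchy))
    bundle["scan_results"] = results_to_frame(results, fdr=cfg.fdr)

    summaries = stage("meta", lambda: [
        build_meta_summary(results, "uncorrected", cfg.alpha, cfg.ci_method, cfg.seed),
        build_meta_summary(results, "corrected", cfg.alpha, cfg.ci_method, cfg.seed),
    ])
    bundle["meta_summary"] = meta_summaries_to_frame(summaries)

    if hierarchy is not None:
        bundle["enrichment_uncorrected"] = stage(
            "enrichment",
            lambda: enrichment_to_frame(enrich(results, hierarchy, "p_M", cfg.alpha, cfg.enrichment_sided)),
        )
        bundle["enrichment_corrected"] = stage(
            "enrichment",
            lambda: enrichment_to_frame(enrich(results, hierarchy, "p_partial", cfg.alpha, cfg.enrichment_sided)),
        )

    if cfg.run_pic and tree is not None:
        pic_results = stage("pic", lambda: pic_scan(matrix, species, tree, hierarchy))
        bundle["pic_results"] = results_to_frame(pic_results, fdr=cfg.fdr)

    bundle["top_table"] = top_table(results, p_threshold=0.01)

    if truth is not None:
        bundle["confusion_table"] = confusion_table(results, truth, cfg.alpha)
        truth.to_tsv(out / "ground_truth.tsv")
        species.to_tsv(out / "species.tsv")
        matrix.to_tsv(out / "matrix.tsv")
        if hierarchy is not None:
            hierarchy.to_tsv(out / "hierarchy.tsv")
        if tree is not None:
            (out / "tree.nwk").write_text(tree.to_newick() + "\n")

    for name, df in bundle.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)

    manifest = {
        "petoscan_version": __version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "n_species": len(species),
        "n_categories": matrix.n_categories,
        "outputs": sorted(f"{name}.tsv" for name in bundle),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    if d.get("synthetic") is not None:
        d["synthetic"] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d["synthetic"].items()}
    return d
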