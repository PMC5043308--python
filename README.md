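# petoscan

Comparative scans of **gene counts per functional category (NOGF)** against
**body mass**, with explicit correction for the allometry of
**mass-specific metabolic rate** — the statistical toolkit for asking
whether large mammals really carry more cancer-relevant genes (Peto's
paradox and the gene-abundance hypothesis) or whether those associations
are artefacts of metabolism.

## Why metabolic-rate correction

Under Kleiber's law, whole-organism metabolic rate scales as B ∝ M^(3/4),
so the mass-specific rate B_c = B/M falls as M^(−1/4): log B_c and log M
are strongly negatively correlated across species (r ≈ −0.95 in mammals).
Any gene category whose size tracks cellular metabolism will therefore
*look* body-size-dependent. petoscan computes, for every category with
count vector G over n species:

* the simple Pearson correlation r of G with log₁₀ M (p from the t
  transform, df = n−2);
* the first-order **partial correlation** r_p of G with log₁₀ M holding
  log₁₀ B_c constant,
  r_p = (r_GM − r_GBc·r_MBc)/√((1−r_GBc²)(1−r_MBc²)), df = n−3;
* the **standardized partial regression coefficient** of M in
  G ~ log₁₀ M + log₁₀ B_c;
* dataset-level diagnostics (mean r with 95% CI, significant fractions,
  and the correlation across categories between the G–M and G–B_c
  correlation vectors — the confound's fingerprint);
* **Fisher-exact enrichment** of significant categories within
  second-level functional categories, reported as −log₁₀ p;
* the same scan on **phylogenetically independent contrasts**
  (Felsenstein's pruning algorithm, correlations through the origin,
  df = k−1).

It also ships a fully seeded synthetic-data generator (log-uniform masses,
Kleiber-law rates with calibrated lognormal noise, Poisson counts driven
by B_c, by M, or by nothing) so the entire pipeline is testable with known
ground truth, plus readers for species TSVs, count-matrix TSVs, Newick
trees, and KEGG BRITE `.keg` flat files.

## Worked example

```python
from petoscan import (SyntheticConfig, generate_species, generate_function_matrix,
                      fit_power_law, scan, build_meta_summary, top_table)

cfg = SyntheticConfig(seed=1)            # 33 species, 342 categories
sp = generate_species(cfg)
fit = fit_power_law(sp.frame.body_mass_g, sp.frame.mass_specific_rate_Wg)
print(f"exponent={fit.exponent:.3f} se={fit.exponent_se:.3f} r={fit.r:.3f}")

matrix, truth, hierarchy = generate_function_matrix(sp, cfg)
results = scan(matrix, sp, hierarchy)
unc = build_meta_summary(results, "uncorrected")
cor = build_meta_summary(results, "corrected")
print(f"uncorrected: mean r = {unc.mean_r:.3f}, {unc.n_significant}/{unc.n_total} "
      f"significant, meta corr = {unc.meta_corr_r:.3f}")
print(f"corrected:   mean r_p = {cor.mean_r:.3f}, {cor.n_significant}/{cor.n_total} significant")
print(top_table(results, 0.01).head(3).to_string(index=False))
```

prints

```
exponent=-0.255 se=0.013 r=-0.960
uncorrected: mean r = -0.015, 191/342 significant, meta corr = -0.998
corrected:   mean r_p = 0.047, 41/342 significant
upper_category_id category_id  r_partial  p_partial      r_M          p_M
    U_m_driven_03        C196   0.739350   0.000001 0.946664 8.470644e-17
    U_m_driven_01        C172   0.737930   0.000001 0.936531 1.169603e-15
    U_m_driven_03        C203   0.717643   0.000004 0.924390 1.618729e-14
```

Reading the numbers: the fitted allometric exponent of B_c on M is
−0.255 ± 0.013 (the generator's α − 1 = −0.25 with calibrated noise). More
than half the categories correlate "significantly" with body mass before
correction, and the meta correlation of −0.998 says those r values are
almost perfectly mirrored by the categories' B_c correlations — the signal
is metabolic, not body-size-specific. After holding B_c constant only
41/342 categories remain significant, and the top of the corrected table
is occupied by the genuinely mass-driven categories (`U_m_driven_*` upper
categories), exactly the ground truth the generator planted.

The same pipeline runs from the shell:

```sh
petoscan simulate --n-species 33 --n-categories 342 --seed 1 --out data/
petoscan scan   --species data/species.tsv --matrix data/matrix.tsv \
                --hierarchy data/hierarchy.tsv --out scan.tsv
petoscan pic    --species data/species.tsv --matrix data/matrix.tsv \
                --tree data/tree.nwk --out pic.tsv
petoscan all    --seed 1 --out report/     # full bundle + manifest.yaml
```

`petoscan all` writes per-category results (simple + corrected), PIC
results, meta summaries, both enrichment variants, the allometric fit, a
ranked top table, a ground-truth confusion table on synthetic runs, and a
YAML manifest that makes every bundle exactly reproducible from its seed.

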