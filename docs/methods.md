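# Methods

## The problem

Peto's paradox is the observation that cancer incidence does not rise with
body size across species, despite larger bodies containing more cells. One
proposed resolution (the *gene-abundance hypothesis*) is that large animals
carry more cancer-suppressing and fewer cancer-promoting genes; a competing
one (the *metabolic rate hypothesis*) is that the mass-specific metabolic
rate B_c — and with it oxidative mutagenesis — declines with body mass M.
The two are entangled: under Kleiber's law B ∝ M^α with α ≈ 3/4, so
B_c = B/M ∝ M^(α−1) ≈ M^(−1/4), and any gene count that tracks cellular
metabolism will *appear* to track body size.

petoscan implements the statistical machinery for separating the two: it
scans per-category gene counts (NOGF, "number of genes in a functional
category") against log10 M with and without holding log10 B_c constant,
diagnoses metabolically driven spurious correlations at the dataset level,
tests which second-level functional categories are enriched for body-size
associations, and repeats the scan on phylogenetically independent
contrasts.

## Statistical procedure

For each category with count vector g over n species:

* **Simple association** — Pearson r of g with log10 M (and with
  log10 B_c); two-sided p from t = r·√(n−2)/√(1−r²), df = n−2. Counts are
  deliberately left untransformed; only M and B_c are logged.
* **B_c-corrected association** — the first-order partial correlation
  r_p = (r_gM − r_gBc·r_MBc) / √((1−r_gBc²)(1−r_MBc²)), with df = n−3.
  This equals the Pearson correlation of the residuals of g|log B_c with
  the residuals of log M|log B_c (verified as an exact oracle in the test
  suite).
* **Standardized partial regression coefficient** — the coefficient of
  log10 M in OLS of g on [1, log10 M, log10 B_c], rescaled by
  sd(log M)/sd(g); identical to z-scoring all three variables first.
* **R² views** — r_M² (simple) and r_p² (corrected), the quantities whose
  before/after comparison shows how much apparent body-size signal the
  metabolic correction removes.

Categories with zero count variance are reported flagged (`defined=False`)
rather than dropped, so meta-statistics can state their exclusion count.

Dataset-level summaries: the mean of r with a 95% normal-approximation CI
(mean ± 1.96·sd/√k; a bootstrap percentile CI is available by option —
the construction is not identifiable from the reported numbers alone, and
the normal approximation is the conventional default), the fraction of
categories with p strictly below α (default 0.05), and the
*correlation of correlations*: Pearson r across categories between the
r_M vector and the r_Bc vector. When B_c drives the counts, that meta
correlation approaches the B_c–M correlation's sign and is strongly
negative; it is the single-number fingerprint of the confound.

**Enrichment.** For each second-level (upper) category, a 2×2 table of
(inside/outside) × (significant/non-significant at p < α) is tested with
Fisher's exact test and reported as −log10 p. The one-sided (greater)
test is the default, since the question is over-representation; the
two-sided p (R's `fisher.test` convention: sum of all tables with
probability ≤ observed, with a 1+1e−7 relative tie guard) is always
reported alongside. The test is computed from the hypergeometric log-pmf
over the whole support of a margin set at once, which makes exhaustive
verification against integer-arithmetic enumeration cheap. Odds ratios are
sample ORs with a Haldane 0.5 correction when a cell is empty; they are
auxiliary output.

**Phylogenetically independent contrasts.** Felsenstein's pruning
recursion, implemented directly on the tree structure: at an internal node
with child values x1, x2 on noise-augmented branches v1, v2, the
standardized contrast is (x1−x2)/√(v1+v2), the node value is the
precision-weighted mean, and the parent branch is augmented by
v1·v2/(v1+v2). Contrast signs are arbitrary in theory; we fix the
subtraction order by the lexicographically smallest tip label of each
child subtree so output is reproducible (ape::pic agrees with our
contrasts up to these signs, verified in the tests). Contrast pairs are
correlated **through the origin** (contrasts have no natural location),
r = Σxy/√(Σx²Σy²) with df = k−1, and the partial correlation on contrasts
uses the same first-order formula with df = k−2. Polytomies are rejected;
`resolve_polytomies` is an explicit opt-in that inserts zero-length
branches. Species missing from tree, table, or matrix are intersected away
with a logged warning (the platypus situation: present in the count data
but absent from the tree). Note that contrast-based results inherit the
tree's branch-length calibration; with poorly calibrated branch lengths
the standardization, and hence the correlations, shift.

## Synthetic cohort

The generator produces data with the statistical skeleton the analysis
assumes, so every stage is testable without any database access:

* **Species** (default n = 33, the size of a genus-representative mammal
  panel): log10 M ~ Uniform(0, 8) (1 g to 100 t, the mammalian range);
  log10 B = log10(0.02) + α·log10 M + ε with α = 3/4 and
  ε ~ Normal(0, σ_B²); B_c = B/M. The intercept (0.02 W at 1 g) is an
  arbitrary scale constant and cancels from every correlation.
* **Noise calibration**: σ_B is chosen so that the model-implied
  correlation corr(log B_c, log M) = −1/√(1 + σ_B²/((1−α)²·var(log10 M)))
  equals −0.95, the strength of the empirically observed B_c–M
  correlation. Inverting gives σ_B = |α−1|·sd(log10 M)·√(1/ρ²−1) ≈ 0.19
  log-units for the 8-decade default mass range.
* **Tree**: Yule (pure-birth) ultrametric binary tree; tip labels match
  the species table.  An optional mode evolves log10 M by Brownian motion
  on that tree instead of i.i.d. sampling, for contrast-specific tests.
* **Counts**: category j of class c with effect β_j has
  count_ij ~ Poisson(exp(a0 + β_j·z_i)), a0 = log 50, where z is the
  z-scored log10 B_c (`bc_driven`), z-scored log10 M (`m_driven`), or
  absent (`null`, β = 0). Poisson keeps counts integral with realistic
  mild heteroscedasticity and no extra parameters. β_j is drawn
  Normal(0, 0.5²) by default, or ±0.5 with random sign in the
  fixed-magnitude mode used by the recovery checks. The linear predictor
  is clamped to |·| ≤ 30 before exponentiation.
* **Class mix** defaults to (0.5, 0.1, 0.4) for (bc_driven, m_driven,
  null): a majority of metabolically confounded categories, a small
  genuinely mass-linked minority, and a null backstop — the regime in
  which the correction story is informative. Categories are grouped into
  synthetic upper categories that are pure in class (up to 12 categories
  each), so enrichment has a discoverable signal.
* All randomness flows from one master seed through fixed named streams;
  every generator is bit-reproducible.

What the generator does **not** emulate: realistic per-category count
scales and dispersions (no public distributional facts to match), gene
overlap between categories (the source of multi-collinearity that blocks
a joint multivariate model on real data), correlated effects among
categories, and measurement error in M or B_c. Passing tests therefore
demonstrate that the machinery recovers the intended structure when the
model's assumptions hold — not that real KEGG-derived data satisfy them.

## Numerical and design choices

* Base-10 logarithms throughout; exponents are per decade and
  correlations are base-invariant.
* The slope standard error is the standard OLS slope SE; a reported
  "exponent ± x" is read as estimate ± SE.
* "One representative per genus" is resolved by earliest genome completion
  year (most mature annotation), configurable to latest; year ties break
  lexicographically on species id. A contested genus with a missing year
  is an error, not a silent guess.
* KEGG BRITE `.keg` parsing treats only the A/B/C/D line prefixes, strips
  HTML tags from labels, and deduplicates gene identifiers (first
  whitespace token of a D line) within a category — a gene listed twice is
  one gene. Cross-category duplication is intentionally preserved:
  categories genuinely share genes.
* p-versus-α comparisons are strict (<) everywhere. No multiple-testing
  correction is applied by default; Benjamini–Hochberg adjusted columns
  are available by option.
* Zero-length branches are legal input; an ε = 1e−8 is added only when a
  contrast denominator would otherwise be zero, with a logged warning.
* Degenerate inputs fail loudly with the offending entity named: constant
  vectors, rank-deficient designs, perfect confounds (|r| = 1 within
  1e−12), unbalanced Newick at a character offset, a D-line before any
  C-line at a line number.

## Problem sizes used in the checks

The bundled verification uses cohorts of 33 species × 342 categories
(matching the study design the generator emulates), 5000 null categories
for type-I calibration, 50-seed averages for mechanism recovery, and
100–200 seed averages for the calibrated generator quantities; exhaustive
Fisher verification covers every 2×2 table with total ≤ 60. These sizes
give Monte-Carlo standard errors comfortably below the asserted
tolerances.

## Known limitations

* The first-order partial correlation removes the *linear* dependence on
  log B_c. Because the Poisson log-link makes E[count|z] = e^(a0+βz)
  convex in z, a small nonlinear remnant survives correction, so a few
  percent of strongly confounded categories can stay significant after
  correction even in the synthetic world — visible in the recovery tests'
  specificity being below 1.
* Through-origin contrast correlations assume the Brownian model and the
  input branch lengths; neither is checked internally.
* The enrichment test conditions on margins (Fisher); with very few
  significant categories overall its power is limited, exactly as for the
  real analysis.
* No PGLS/Ornstein–Uhlenbeck alternatives, no tree inference, no gene
  ontology input, and no network retrieval: trees, tables, and `.keg`
  files are inputs.
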