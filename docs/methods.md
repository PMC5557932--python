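# Methods

## The analysis model

Methylation is measured as a β-value in [0, 1] (methylated / total signal).
All modelling happens on the M-value scale, `M = log₂(β/(1−β))`, which is
approximately normal and homoscedastic where β is not; the logit base is 2,
the convention of the 450K literature. β-values of exactly 0 or 1 are clamped
to ε = 10⁻⁶ before the transform; synthetic data never reaches the clamp
because it is generated by the inverse map `β = 2^M/(2^M+1)` from finite M.

**Discovery.** For each autosomal CpG, ordinary least squares of M on
intercept + age + five of the six blood cell fractions. One fraction
(granulocyte, the largest) is excluded because the six fractions sum to 1 and
would make the design singular; the adjustment is nevertheless complete,
since the omitted fraction is a linear combination of the others and the
intercept. Constant covariate columns are absorbed into the intercept. Any
rank deficiency beyond these planned exclusions is an error that names the
collinear columns.

Repeated measures make the OLS standard errors naive, so significance is
assessed empirically rather than model-based: the age column is permuted
across *samples* (deliberately breaking within-subject structure — that is
what the null hypothesis of no age association looks like for this design),
the full scan is re-run K times, and each permuted scan's minimum p-value is
recorded. The family-wise error rate of a CpG with observed p is the
fraction of permuted minima *strictly* below it, so FWER values live on the
grid {0, 1/K, …, 1} and are monotone in the observed p. K defaults to 300
and must be at least 20 (the estimator's resolution is 1/K); the discovery
threshold FWER < 0.05 is strict.

**Replication.** Validation cohorts are clustered (twin pairs, or repeated
measures of one individual), so each discovery-significant CpG is refitted
with a linear mixed model: fixed effects intercept + age + five cell
fractions, one random intercept per cluster, REML estimation, Wald two-sided
test for age. The cluster is the twin pair in the cross-sectional cohort and
the individual in the longitudinal cohort (a pair-level effect is omitted
there for parsimony at ~90 subjects). When every cluster holds a single
sample the random intercept is unidentifiable and the fit degenerates to
OLS; on numerical non-convergence the fallback is OLS on cluster means,
flagged in the output. A CpG replicates in a cohort when its slope sign
matches discovery and p < α (strict, α = 0.05); it double-replicates when it
replicates in both cohorts. The subset chain — double-replicated ⊆ each
replicated set ⊆ discovery set — is asserted on every run.

Replication rates are percentages of *testable* discovery CpGs (CpGs absent
from a validation array are excluded from numerator and denominator); the
overlap rate divides the double-replicated count by the smaller cohort's
replicated count. Zero denominators yield NaN ("undefined"), never 0. One
published arithmetic inconsistency is worth recording: an overlap of
5,168/7,238 is 71.4 %, not the 70.4 % that circulated with those counts;
`rate_percent` reports the ratio as computed.

**Characterization.** Gene-region membership is multi-label (a promoter CpG
can sit in TSS200 and 1stExon simultaneously), so a CpG contributes one
count to every region label it carries and region columns need not sum to
the set size; shares of gains/losses therefore divide by the set's total
gains/losses supplied explicitly. The CGI relation is single-label and
partitions the set; open sea is spelled `non-CGI` in all files and outputs
(the Illumina dialect `OpenSea` is rejected rather than silently mapped, to
keep outputs bit-comparable). Two χ² families, both Yates-corrected, 1 df,
upper tail:

* direction bias within a category: the symmetric 2×2 table
  `[[gain, loss], [loss, gain]]`, closed form `8·(max(|g−n/2|−½, 0))²/n`;
* proportionality of a category in the gain (or loss) set against the
  whole-array background: a two-sample 2×2 test against the manifest's
  category counts. Expected cells below 1 flag the p-value unreliable
  (still computed).

The region × CGI cross-tab collapses the six CGI relations to three groups
(island → CGI; both shores and shelves → Shore/Shelf; non-CGI); its
marginals over the three groups reproduce the per-region direction counts by
construction, and this identity is asserted in tests on every input shape.

**Over-representation.** Gene-level, not CpG-level: the universe N is the
set of distinct nearest-gene symbols in the (pipeline-filtered) manifest, m
the genes of the significant CpGs, n the gene-set size after intersection
with the universe, k the overlap. The default tail is the strictly-greater
one, `P(X > k)`, kept exactly as the formula above defines it; note that for
a discrete test this tail is *anti-conservative* (it excludes the observed
outcome), while the conventional inclusive tail `P(X ≥ k)` — available as
`tail="ge"` — is super-uniform under the null. Both are exposed; the tests
verify the conservativeness property on the inclusive tail and the ordering
between the two. Ties in p are broken by larger overlap, then set name, so
output ordering is deterministic. No multiple-testing correction is applied
to enrichment p-values; reporting is a ranked top-T (default 50).

## The synthetic-data generator

Per CpG j, sample i of subject s:

```
M_ij = μ_j(cgi) + b_j·age_i + Σ_c γ_jc·cellfrac_ic + u_js + ε_ij
```

with subject random intercepts u ~ N(0, subject_sd²) drawn independently
*per CpG and subject*, residual noise ε ~ N(0, noise_sd²), per-CpG cell-type
effects γ ~ N(0, cell_effect_sd²), and cell fractions Dirichlet with a
granulocyte-dominated mean (≈ 0.59) mimicking whole blood. A fraction
`frac_affected` (default 0.10) of CpGs carries a true slope b_j; among
affected CpGs 61 % are demethylated (negative slope), matching the
demethylation-dominant direction mix of aging blood. Slope magnitudes are
|N(slope_mean, slope_sd)| with defaults 0.01/0.005 M-units per year — the
effect-size distribution of truly age-associated CpGs is not something the
emulated study reports, so these are calibration choices, stated here as
such. Baseline M depends on the CGI relation (islands hypomethylated at
M ≈ −2, open sea hypermethylated at M ≈ +2, shores/shelves between), which
reproduces the familiar bimodal β distribution.

Noise scales: `noise_sd = 0.15` and `subject_sd = 0.15` M-units. Technical
replicate noise on well-performing 450K probes is of the order of a few
hundredths to ~0.2 M-units and stable between-person differences are of a
comparable scale in blood, so equal moderate components are a reasonable
desk default; `cell_effect_sd = 0.5` makes cell composition a real
confounder so the adjustment is actually exercised.

Annotation: genic region labels are included independently per label with
whole-array probabilities (multi-membership arises naturally; CpGs drawing
no label become intergenic-only); the CGI relation is categorical with the
whole-array composition (island 0.31, shores 0.23, shelves 0.10, open sea
0.36); chromosomes rotate round-robin over 1–22, X, Y, so roughly 1/12 of
probes exercise the sex-chromosome filter; nearest genes come from a shared
pool (~1 gene per 20 CpGs) so several CpGs map to one gene, as on the real
array.

Randomness is organised as counter-based substreams of one global seed: each
CpG owns its own stream, so enlarging the array never changes earlier CpGs,
and the planted truth is a function of the seed alone — the same CpGs are
affected in every cohort simulated from that seed, which is what makes
double replication of planted effects meaningful.

**Cohort presets** (desk scale):

* `discovery_like` — 200 unrelated subjects, baseline ages 70–90, a second
  wave after a six-year follow-up (the follow-up length of the elderly
  birth-cohort design this emulates);
* `cross_sectional_like` — 75 MZ twin pairs (150 subjects), one visit each,
  in two age clusters, 30–37 and 57–74 (twins share the pair's age);
* `longitudinal_like` — 90 elderly twins in mixed MZ/DZ pairs, ages 73–82
  at baseline, a second wave after a ten-year follow-up.

What the generator does **not** emulate: probe-type (Infinium I/II)
chemistry differences, batch and plate effects, SNPs under probes,
cell-composition estimation error (fractions are taken as known), and
non-linear age trajectories. Passing tests therefore demonstrate the
statistical machinery — error control, power at the planted effect sizes,
direction concordance, counting identities — not robustness to array
artefacts, which upstream QC and normalisation are assumed to have handled.

## Problem sizes used by the tests and the acceptance script

Simulation-based checks run at desk scale, chosen so the full suite runs
comfortably on one CPU: family-wise error control uses 200 global-null
datasets of 100 CpGs × 60 samples with K = 100; planted-effect recovery uses
ten seeds of 150 CpGs with the three preset cohorts and K = 100; null
p-value calibration uses 500 CpGs × 80 samples per seed; the hypergeometric
oracle check uses 500 random parameter tuples with N ≤ 60; the worked
pipeline example uses 400 CpGs with K = 100. Headline counts of the emulated
study (tens of thousands of significant CpGs from half a million probes)
require the original cohorts and manifest and are out of reach of synthetic
desk-scale runs by design; the package instead verifies the statistics that
produced them on their published counts, and the pipeline's statistical
properties by simulation.

## Numerical choices and degenerate inputs

* The vectorised scan solves one QR of the design for all CpGs; the
  per-CpG statsmodels fit is an independent route used by the tests.
* Observed p-values are clipped into (0, 1] at the float-tiny end so the
  permutation null's strict inequality is well defined.
* FWER estimation sorts the K permuted minima once and counts by binary
  search; agreement with the exhaustive (CpG × permutation) double loop is
  part of the test suite.
* Empty significant sets short-circuit the pipeline with a warning instead
  of producing empty downstream tables; empty categories yield NaN
  statistics rather than 0.
* Direction ties cannot occur (a slope of exactly 0 is classified "loss" by
  the strict `slope > 0` rule; with continuous data this has probability 0).
* Mixed-model non-convergence falls back to cluster-mean OLS and the output
  row says so; all-singleton clustering is detected up front and fitted as
  plain OLS.

## Known limitations

* The discovery point estimate ignores within-subject correlation by
  design; its standard errors are not interpretable in isolation — only the
  permutation FWER is calibrated. Under strong clustering the observed
  p-values are anti-conservative relative to an exchangeable null, which the
  permutation distribution absorbs.
* The permutation unit is the sample, not the subject; designs where age is
  constant within subject across waves would need a subject-level
  permutation, which is not implemented.
* The proportionality tests compare against the manifest supplied at run
  time; array-version differences in annotation shift the background and
  the resulting χ² values.
* Enrichment p-values are raw; with many gene sets the ranked list is
  exploratory, not inferential.
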