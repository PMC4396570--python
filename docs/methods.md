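# Methods

## Model and procedure

The analysis targets longitudinal methylation drift: CpG sites whose
methylation level changes monotonically with age across repeated blood
samples from the same individuals.  All modelling is on the M scale,
M = log₂(β/(1−β)), because beta values are heteroscedastic near the
boundaries; betas are clipped to [0.001, 0.999] before the logit so the
transform stays finite (clipping constant ε = 0.001, an implementation
choice; the transform pair is exactly inverse away from it).

Quantile normalization precedes the M transform: the normalization target
(mean of order statistics across samples) is well defined on the bounded
beta scale, and normalizing proportions then transforming preserves the
[0,1] range.  Ties within a column receive the mean of the target values
their ranks span; the map is idempotent on tie-free data.

**Step 1 — per-probe linear model.**  Age enters as a categorical factor
(one level per scheduled visit), not as a linear covariate: the inferential
target is a *contrast between the first and last visits*, and a factor
model leaves the trajectory shape free.  Individual enters as fixed
blocks.  Mixed models with a random intercept are the textbook alternative
for repeated measures but are deliberately out of scope: at hundreds of
thousands of probes the fixed-block OLS is a single shared pseudoinverse
(all probes share one design), is exactly reproducible, and absorbs the
strong stable inter-individual differences that dominate methylation data.
An auxiliary F-test of the individual block is reported per probe for
description only; probes with strong individual effects are *not*
excluded — an age effect on top of an individual effect is still an age
effect.

**Step 2 — variance moderation and contrast test.**  Residual variances
are pooled with the standard empirical-Bayes scaled-F model: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess of Var(e_g) over its
sampling component ψ′(d_g/2) identifies ψ′(d₀/2), inverted by Newton
iteration; the mean equation then gives s₀².  If the observed spread does
not exceed the sampling component the prior is degenerate: d₀ = ∞ and
s₀² = mean(s²_g) (every probe then uses the common variance and the t
reference becomes normal).  Limits behave as expected and are tested:
d₀ = 0 reproduces the classical per-probe contrast t exactly; d₀ = ∞ uses
s₀² everywhere.

The contrast standard error is s̃_g · c, where c = √(cᵀ(XᵀX)⁺c) is computed
once from the shared design (with dropouts the design is unbalanced but
still shared, so c is probe-independent).  Two-sided p-values come from
Student t with d₀ + d_g df, Bonferroni-corrected over the tested probes;
the default family-wise α is 0.01.  Degenerate probes (zero residual and
zero posterior variance) get p = 0 if the contrast is nonzero, t = 0
otherwise, and are flagged by direction label.

## Filters, regions, annotation, enrichment

The SNP filter removes a significant probe if *any* in-probe SNP record
has MAF strictly above the threshold (default 0.01); a record exactly at
the threshold is kept.  The cell-type filter removes probes on the
classifier list.  Both operate on the significant set only — the testing
universe and the enrichment universe stay the full manifest — and the two
filters commute.  Sex-chromosome removal exists behind a flag and is off
by default.

Age-modified regions group significant probes by (gene symbol, direction),
using *all* gene annotations of a probe (a two-gene probe can join two
regions), require ≥ 2 distinct probes, and report the probe-coordinate
span with no maximum length.  Intergenic probes never form regions.

Genomic context: gene-structure categories are counted over (probe,
annotation) pairs — the denominator is annotations, because a probe can
legitimately sit in the body of one transcript and the promoter of
another — while island relation, regulatory features, DHS/enhancer flags
and DMR classes are counted over probes.  Nearest-TSS distances are signed
by gene strand (downstream positive), limited to a 1,000 kb window, binned
half-open on absolute distance ([0,5), [5,50), [50,500), [500,1000] kb);
absolute-distance ties break toward the smaller TSS coordinate,
deterministically.  Coordinates are 1-based throughout.

Both Yates-corrected and uncorrected χ² are first-class for 2×2 contrasts
(published 2×2 statistics in this literature mix the two variants; the
pipeline defaults to Yates and always reports Fisher's exact p alongside).
Gene-set enrichment is upper-tail hypergeometric against the manifest gene
universe, BH-adjusted across sets, with the conjunction rule: significant
iff overlap ≥ 5 and p < 0.01 and BH p < 0.05.

## Synthetic cohort: what it emulates and what it does not

Defaults mirror the reference study design: 10 individuals × 7 visits at
3–60 months, ~15% dropout of interior visits (first and last visits are
always kept so the contrast stays estimable per block), 2000 probes, 5%
age-methylated + 5% age-demethylated with |ΔM| = 2 between first and last
visit, 2% SNP-affected, 2% cell-composition-confounded,
σ_resid = σ_individual = 0.5 on the M scale.  The age-effect shape is
linear in log₂(age), normalized to [0,1] over the visit range — methylation
change in infancy is front-loaded, and observed trajectories are smooth
and monotone without a stated functional form.  Residuals are exchangeable
within individual beyond the fixed offset; real serial samples may carry
extra autocorrelation the generator does not model.

Free parameters not fixed by the design were chosen once as plausible
field values: baseline probe means M ~ N(0, 2²); genotype levels 2 M units
apart with heterozygotes midway, genotypes drawn under Hardy–Weinberg at a
per-probe MAF ~ U(0.05, 0.4); granulocyte fraction 0.25 + 0.35·g(age) +
N(0, 0.05) with a ±4 M-unit/fraction coefficient on confounded probes;
manifest category frequencies approximating the 450K array (31% island,
46% of annotations in gene bodies, 12% DHS, 25% enhancer); chromosome
assignment weighted by autosome length.  The generator plants *no*
island/promoter preference in either direction group, so context contrasts
on synthetic data are null — passing tests demonstrate the machinery, not
the biology.  Array chemistry, detection p-values, batch effects and sex
chromosomes are not simulated.

A twentieth of the planted age probes also carry a common in-probe SNP
record, so the MAF filter has genuine work among the significant calls;
the classifier list contains the confounded probes plus null decoys.

## Numerical and design notes

- Rank-deficient designs fall back to the pseudoinverse (flagged);
  all-constant probes keep s²_g = 0.
- Quantile normalization requires complete matrices; the reader rejects
  missing cells unless column-median imputation is explicitly requested
  (the statistical model assumes complete post-QC data).
- Determinism: one integer seed drives manifest, sampling grid, dropout,
  effects and noise; identical seeds give bit-identical outputs, and the
  pipeline records a config hash (path-independent) in its summary.
- Problem sizes in the test suite and the acceptance script (2000 probes,
  ≈60 samples, 5000 variance draws) were chosen as the reference design
  scale; the full-cohort statistics of the original study depend on its
  deposited data and population SNP frequencies and are not reproduced
  here.
- scipy provides the χ²/Fisher/hypergeometric distributions and
  statsmodels the BH adjustment; the moderation machinery, filters, region
  caller and annotation logic are implemented in-package and tested
  against independent brute-force oracles (explicit normal equations,
  exhaustive 2×2 enumeration, direct step-up BH, all-pairs TSS scan,
  exhaustive region grouping).

## Known limitations

- Fixed individual blocks cost degrees of freedom relative to a random-
  intercept model and cannot borrow strength across individuals.
- The first-vs-last contrast ignores intermediate visits for effect
  estimation (they still inform the residual variance); a trend test would
  be more powerful for monotone effects but answers a different question.
- The empirical-Bayes prior assumes exchangeable variances; no
  mean-variance trend or robust down-weighting of variance outliers is
  implemented.
- Enrichment treats gene sets as flat lists: no ontology-graph
  propagation or semantic grouping.
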