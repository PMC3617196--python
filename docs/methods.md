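# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices a maintainer would want to
know. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

The discovery platform measures *relative* protein abundance: each run
labels three patient samples and a pooled reference, and reports, per
run-level protein group, the reporter ratios of each patient channel to
the reference. All statistics operate on the log scale. We parameterise
measurement spread as `cv_log`, **the standard deviation of natural-log
ratios** (default 0.25). The matrix container stores log2 ratios for
readability of fold changes; the two conventions coexist because only
the ratio effect/σ matters to every test, and both effect and σ are kept
in natural-log units wherever power is computed. A config helper
`linear_cv_to_log_sd` converts a linear-scale CV via σ = √log(1+CV²)
for users who estimate CV on the linear scale.

## Protein-group linking (PGCs)

Run-level protein groups are nodes; an edge joins two groups sharing at
least one accession; connected components become protein group codes,
numbered 1, 2, ... by first appearance in input order (reproducible for
a fixed file order; a SHA-1 alias of the member accession set supports
order-independent joins). Any shared accession suffices to merge: a
minimum-overlap threshold would be a second tunable with no principled
default, and the chaining risk it guards against (over-merging isoform
families) is instead *reported* — the QC summary includes the maximum
within-component diameter of the accession-sharing graph. When several
member groups of one PGC appear in one run, their log2 ratios are
combined by the median (robust to one aberrant subgroup; mean and
top-accession-only are available).

## Design: matching and power

One sample per patient preserves independence: the earliest
acute-rejection sample per case patient, and per control patient the
sample nearest the case's week. Matching is greedy 1:ratio — exact week
first, then minimal |Δweek|, ties by |Δage| then sex — because greedy
nearest matching mirrors clinical practice and is transparent; an
exhaustive optimal assignment differs only in contrived tie structures
at these cohort sizes (the test suite checks agreement on separated-week
instances). Mild (1R) samples are excluded from both arms.

Power for the two-group comparison uses the noncentral t: effect
Δ = |ln FC|, noncentrality Δ/(σ√(1/n₁+1/n₂)), df = n₁+n₂−2, two-sided
size α. At FC = 1 the power is exactly α, and power is symmetric in
FC ↔ 1/FC. `required_n` inverts by bisection over the case-group size.

## Detection pre-filter

A PGC is analysed only if observed in at least ⌈⅔·n⌉ samples of the
case group **and** of the control group (4/6 and 10/14 at the default
design). Detection is a per-run event (undersampling), so missingness
arrives in blocks; filtering per group prevents a protein detected only
in one arm from entering the comparison with a spurious advantage.

## Moderated t-tests

Let s_g² be the pooled two-sample variance of row g on d_g = n₁+n₂−2
observed-count degrees of freedom (pairwise-complete: means, variances
and df all use the per-row observed samples; rows with fewer than two
observations in either group are reported but not tested, and no
imputation happens before testing). The empirical-Bayes model takes
s_g² ~ s₀²·F(d_g, d₀); then

    e_g = log s_g² − ψ(d_g/2) + log(d_g/2)

has mean log s₀² + ψ(d₀/2) − log(d₀/2) and variance ψ′(d_g/2) +
ψ′(d₀/2). Matching the two sample moments of e and inverting the
trigamma numerically (Newton, ~50 iterations, relative tolerance 1e-10)
yields (d₀, s₀²); a non-positive excess variance is reported as d₀ = ∞
(pure shrinkage to s₀²). The robust variant winsorizes e at the 5%/5%
tails before matching, bounding the influence of variance outliers; it
trades a small upward bias in d₀ for resistance to contamination.
Degenerate inputs: identical variances return d₀ = ∞ with s₀² equal to
the common value (no sampling correction applies to an exact value);
all-zero variances raise.

The moderated statistic is t_g = Δ̄_g / √(s̃_g²(1/n₁+1/n₂)) with
s̃_g² = (d₀s₀² + d_g s_g²)/(d₀+d_g), referred to t with d₀+d_g df
(normal when d₀ = ∞). d₀ = 0 is an explicit no-shrinkage override and
reproduces the ordinary pooled t exactly. P-values are two-sided and
deliberately **not** multiplicity-adjusted: at these sample sizes and
with corroboration on an independent platform as the false-positive
control, adjustment would trade sensitivity for a guarantee the design
provides elsewhere. Benjamini-Hochberg is available behind a flag.

Fold changes are reported signed: +2^Δ for Δ ≥ 0, −2^(−Δ) otherwise
(positive = more abundant in cases), so |FC| = 2^|Δ|.

Wilcoxon rank-sum tests use the exact null when min(n₁,n₂) ≤ 8 without
ties, otherwise the normal approximation with tie correction; a complete
tie returns p = 1.

## kNN imputation

For a missing level of protein g in sample j: distances to other
proteins are Euclidean over co-observed samples scaled by the
co-observation count (sparse overlaps are not favoured); the k = 10
nearest rows *observed at j* contribute an inverse-distance-weighted
average (neighbours missing at j are skipped and the next nearest used,
keeping k contributors when possible). Ties in distance break by row
order for determinism; a zero distance is floored at 1e-12 before
inversion. Rows missing more than half their entries fall back to the
row mean — a nearly-empty profile has no trustworthy neighbours. k = 10
follows the established kNN-impute convention for expression-style
matrices. Imputation happens once, after testing and before classifier
fitting, so test p-values never see imputed values.

## LDA panel score

w = S⁻¹(μ₁ − μ₀) with S the pooled within-class covariance under the
maximum-likelihood normalisation (denominator n): this makes the fit
invariant to replicating the dataset, which the n−2 convention is not.
The offset c = w·(μ₁+μ₀)/2 − log(π₁/π₀) places score 0 exactly at
posterior probability 0.5 under the training priors; priors default to
the empirical class proportions so the probability-0.5 cut-off and the
sign rule coincide, with equal priors available by argument. The score
is the LDA log-odds, so probability = logistic(score). A singular pooled
covariance (possible when the panel approaches the sample count) falls
back to ridge regularisation S + λI, λ = 1e-6·tr(S)/p, with a warning
each time it is applied.

Cross-validation is class-stratified k-fold (default 6), fold sizes
differing by ≤ 1 per class, deterministic given the seed; folds are
re-drawn (with a warning) in the rare case a training split lacks a
class. One pooled out-of-fold confusion matrix yields sensitivity and
specificity at probability 0.5 — per-fold metrics would be degenerate
with single-case folds — and one pooled AUC, computed as rank
concordance P(score_case > score_control) + ½P(tie) via midranks.
Incremental panels reuse one fold assignment across all nested prefixes
so that performance differences reflect the panel alone. Out-of-fold
scores from each fold's own model are pooled for display without
re-centering; each fold's model is already centered at its own boundary.

Calibration after assay migration refits (w, c) by the same closed form
on the new platform, panel membership and model family unchanged, and
reports old-vs-new weight signs.

## Permutation ANCOVA

Per panel protein, the full model (intercept + covariate + group) is
compared with the reduced model (intercept + covariate); the global
statistic is Σ_g (RSS_red − RSS_full) / Σ_g RSS_full. Protein rows are
standardised first so no single protein's scale dominates the pooled
sums (this also makes the statistic invariant to per-row affine
rescaling). Significance is by permutation — honest at n ≈ 20 where the
asymptotic F reference is doubtful. When the number of distinct
case/control arrangements is at most `n_perm`, the null is enumerated
exactly over label arrangements; otherwise Freedman-Lane: the reduced
model's residual columns are permuted and the statistic recomputed
(applying the statistic to permuted residuals is exact here because
both RSS terms are unchanged by removing the reduced-model fit), with
the add-one convention so Monte-Carlo p-values are never 0 and have
resolution 1/(n_perm+1). The two schemes coincide when the covariate is
constant or absent. Covariates are tested singly, as confounder tables
are conventionally presented; a joint adjustment would change the
question being asked. Samples with a missing covariate are dropped with
a warning; a constant covariate reduces to the unadjusted group test.

The score screen reports plain Pearson r between the classifier score
and each covariate and flags |r| ≥ 0.5; a zero-variance covariate has
undefined r, reported as absent.

## Corroboration

Technical: Spearman correlation per protein over common samples
(monotone platform response curves drop out; r ≤ 0.6 is flagged weak as
a report annotation, never a filter). Statistical: the same moderated
test re-run on the new platform at α = 0.05, with corroboration
requiring both significance and an effect direction matching discovery
— direction agreement is the point of corroboration even though it is
rarely stated as a rule (toggleable). Linear-concentration platforms
are log2-transformed first so directions are comparable with log-ratio
discovery data. The test runs over all rows of the new platform so its
variance prior is fitted on that platform's own rows; with fewer than
10 rows the ordinary t is used instead (with a warning), since the
prior fit would be meaningless. Markers absent from the platform are
reported untestable, not failed.

## Synthetic studies

`simulate_study` emulates: reference-design structure (runs of 3
patient channels, the last run possibly smaller), per-protein baselines
μ_g ~ N(0, 0.5²) (rows differ in abundance, exercising kNN neighbour
selection), natural-log ratio noise with SD `cv_log` = 0.25, planted
class effects of ±ln|FC| with default fold changes +1.28, −1.56, +1.46,
+1.27, −1.31 (the magnitude range of rejection-regulated plasma
proteins), and per-(run, protein) Bernoulli detection — undersampling
happens per run, so a missed protein is missing for exactly that run's
three samples. The default detection probability 0.505 was calibrated
once so that about 14% of proteins survive the two-thirds pre-filter
under the 6-vs-14 design, matching the observed survival fraction in
studies of this type; it is a study condition, not a tuning knob.
Accession sets per run are an anchor accession plus random extras, so
linking is exercised but ground-truth protein identity remains
recoverable. Confounders are drawn independently of class by default
(weight, systolic blood pressure, creatinine at realistic means/SDs); a
leakage mode shifts one covariate by a configurable number of SDs in
cases to test confounder detection. The truth record carries the full
config, planted effects, per-sample latent levels and the detection
pattern, so any stage can be scored against ground truth and the
configuration round-trips exactly.

`simulate_platform_migration` re-measures the planted proteins on a
linear-concentration platform: per-protein affine response (default:
lognormal scale factor, zero intercept — an intercept is supported but
distorts log-scale effects, so it is opt-in) and multiplicative
lognormal measurement noise with log-SD 0.05, a realistic technical CV
for a targeted assay. Chosen effects can be nulled in the freshly drawn
validation cohort, reproducing the scenario where one discovery marker
fails to transfer; the original study samples can be re-measured from
their recorded latents to provide common samples for the correlation
analysis.

What the generator does **not** emulate: peptide-level identity and
spectra, ratio compression of isobaric labelling, batch drift across
runs, non-lognormal heavy tails, informative (abundance-dependent)
missingness, and correlated protein co-regulation beyond planted
effects. Passing tests therefore show that the statistics behave as
designed under the stated model — calibrated nulls, power close to the
analytic prediction, correct recovery of planted structure — not that
real plasma data meet these assumptions.

## Problem sizes and runtime choices

The test suite and acceptance script use the study-scale defaults
(900 proteins × 20 samples, 6 vs 14) for end-to-end checks, 2000-row
null matrices over 200 seeds for calibration, 5000-row draws for prior
recovery, 100 random instances for linking-oracle equivalence, and
499–999 permutations for ANCOVA inference — sizes at which Monte-Carlo
error is small relative to every asserted tolerance while the whole
suite runs in about a minute on one core.

## Known limitations

- Linking merges on any shared accession; heavily chained isoform
  families merge into one code (diameter is reported, not acted on).
- The moderated-test df treats the fitted (d₀, s₀²) as known;
  hyperparameter uncertainty is ignored, as is conventional.
- Greedy matching is not globally optimal for pathological week
  distributions.
- The ANCOVA adjusts one covariate at a time; joint adjustment is
  config-gated and untested against an external reference.
- kNN imputation is O(G²) in the number of proteins; fine at thousands
  of rows, not at hundreds of thousands.
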