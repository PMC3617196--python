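# proteopanel

A computational pipeline for case-control plasma-proteomics biomarker
studies, from untargeted discovery through cross-platform validation to
clinical calibration. It is written for the common, awkward regime of
such studies: a handful of cases, relative quantitation against a pooled
reference channel, protein identities reported as unstable *protein
groups*, and heavy run-to-run missingness from shotgun undersampling.

The motivating application is monitoring acute cardiac allograft
rejection from plasma, where a small panel of rejection-regulated
proteins (immune response, acute-phase inflammation, lipid metabolism)
is combined into a single diagnostic score — but every stage is generic
over a sample manifest, per-run protein-group summaries and optional
second-platform concentration tables.

## What the pipeline computes

**Discovery.**

1. *Protein-group linking.* Per-run protein groups are linked whenever
   they share an accession; connected components define global protein
   group codes (PGCs), so quantities can be compared across runs even
   when group composition drifts (`pgca`).
2. *Design.* 1:2 case-control matching by week post-transplant, age and
   sex, and analytic power for two-group comparisons of log-ratios via
   the noncentral t: with effect Δ = |ln FC|, per-group σ = CV_log and
   groups n₁, n₂, the noncentrality is Δ/(σ·√(1/n₁+1/n₂)) (`design`).
3. *Pre-filter.* Keep PGCs detected in ≥ ⌈⅔·n⌉ samples of **each**
   group — 4 of 6 cases and 10 of 14 controls at the default design
   (`diffstats.prefilter`).
4. *Moderated tests.* Per-PGC empirical-Bayes moderated t-tests: the
   row variance is shrunk as s̃² = (d₀s₀² + d_g s_g²)/(d₀ + d_g), with
   (d₀, s₀²) estimated by digamma/trigamma moment matching of the log
   variances to a scaled F distribution; the robust variant winsorizes
   the log variances before fitting. Candidates are rows with two-sided
   p < 0.01, deliberately unadjusted — corroboration on an independent
   platform controls false positives. Wilcoxon rank-sum tests and signed
   fold changes (±2^|Δlog₂|) accompany the table (`diffstats`).
5. *Imputation.* k-nearest-neighbour imputation (k = 10) with
   co-observation-scaled Euclidean distances and inverse-distance
   weights, applied only before classifier fitting (`imputation`).
6. *Panel score.* A two-class LDA classifier,
   w = S_pooled⁻¹(μ_case − μ_control), centered so that score
   s(x) = w·x − c is zero exactly at posterior probability 0.5; positive
   scores classify as rejection (`classifier`).
7. *Quality and confounding.* Identification QC (peptide counts, unused
   scores, coverage), a permutation-based global ANCOVA per covariate
   (does the panel still separate the groups after adjusting for weight,
   drug dose, blood pressure...?) and a Pearson screen of the score
   against each covariate at |r| ≥ 0.5 (`pgca.qc_summary`, `confound`).

**Validation.** Spearman correlation per protein between platforms on
common samples (r ≤ 0.6 flagged weak); re-testing of candidates on the
new platform at α = 0.05 with a required matching effect direction;
incremental nested panels under stratified 6-fold cross-validation with
shared folds (sensitivity, specificity, AUC as rank concordance); a
locked final model (`corroborate`, `classifier`).

**Clinical calibration.** A locked panel migrated to a new assay keeps
its membership and model form; only the weights and offset are refitted
on the new measurements (`classifier.calibrate_panel`).

**Synthetic studies.** `synthetic.simulate_study` generates the full
input set — run summaries, manifest, run layout, truth record — with
reference-design structure (3 patient channels per run), lognormal
ratio noise (CV 0.25 on the log scale), run-blocked detection, and
planted fold changes of ±1.27–1.56 by default;
`simulate_platform_migration` produces second-platform concentration
tables with chosen effects preserved or nulled. Every stage of the
pipeline is therefore testable against known ground truth with no
external data.

## Worked example

`examples/` holds one short script per capability. From
`examples/02_discovery_stats.py` (discovery statistics at the default
6-vs-14 design, seed 0):

```
fold change 1.15: power  5.9% at alpha 0.01, 6 cases vs 12 controls
fold change 1.30: power 24.5% at alpha 0.01, 6 cases vs 12 controls
fold change 1.50: power 62.9% at alpha 0.01, 6 cases vs 12 controls

variance prior: d0 = inf, s0^2 = 0.1410 (robust fit over 108 rows)
candidate markers at p < 0.01: [338, 492, 502]

planted rows (PGC -> true fold change): {3: 1.28, 492: -1.56, 502: 1.46, 858: 1.27, 51: -1.31}
planted markers recovered among candidates: [492, 502]
```

The two strongest planted effects (−1.56 and +1.46) are recovered and
the weaker ones (±1.27–1.31) are missed — exactly what the power curve
above predicts for a 6-case design — plus one false positive, which is
what the downstream corroboration stage exists to remove.
`examples/05_corroboration_and_calibration.py` then shows four of five
planted markers corroborating on a migrated platform when one effect is
deliberately nulled, and the locked panel being recalibrated.

A thin CLI wraps the same library calls:

```sh
proteopanel simulate --seed 1 --out study/
proteopanel discover --config config.yaml --out results/
```

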