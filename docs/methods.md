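# Methods

## The prediction model

A staged dentition is the vector of Demirjian calcification stages
(0, A–H; 0 = crypt without calcification, H = closed root apex) of the seven
lower-left permanent mandibular teeth, FDI 31–37. A Willems-style score
table maps every (sex, tooth, stage) to a contribution in years, and the
estimated dental age is the plain sum of the seven contributions. Keys
absent from a table score 0: they are the reference levels absorbed during
fitting, so published tables list only stages B–H and leave dashes where a
cell carries no information. Scores may be negative and need not be monotone
in stage (fitted tables routinely are not, because each tooth's column also
soaks up sampling noise and collinearity with the other teeth).

Errors follow the convention `error = chronological age − estimated age`;
negative errors mean overestimation. Estimates are never clamped; a
non-positive estimate triggers a warning, not an exception.

### The packaged Saudi Arabian table

`load_sa_table()` ships a transcription of per-sex coefficients fitted on a
Saudi Arabian reference sample (1146 children aged 4–16). The printed source
runs the stage columns B–H with "−" marking empty (reference) cells, but its
extraction garbled the column alignment of several rows. The transcription
was recovered by requiring every row to parse to exactly seven cells, with
"−" either an empty cell or a minus sign; this constraint turns out to have a
unique solution for every row. Two consistency checks support the result:
the implied all-stage-H sums are 16.191 y (male) and 16.210 y (female) —
complete development landing at the study's 16-year eligibility ceiling —
and the per-stage column sums increase monotonically with stage. Cells whose
placement rests on the seven-cell argument rather than clean spacing are
listed in the table's provenance notes.

## Eligibility

The filter retains records with chronological age strictly below the ceiling
(default 16.0 y; exactly 16.0 is excluded), no unscorable tooth among 31–37,
and not all seven teeth at stage H (a fully developed dentition carries no
age signal below the ceiling). Each excluded record is logged with every
reason it triggered. The filter is idempotent and partitions its input.
Bilateral-absence rules used in radiograph studies need right-side teeth and
are out of scope of a seven-tooth record.

## Fitting country-specific tables

`fit_coefficients` regresses chronological age on seven categorical blocks,
one per tooth, dummy-coded with the lowest *observed* stage per tooth as
reference. After the fit the intercept is folded into every tooth-31 entry
(its reference stage's entry *is* the intercept), teeth 32–37 keep explicit
zeros at their reference stages, and predictions with the folded table equal
the regression's fitted values exactly (checked to 1e-8). Folding is purely
a reparameterisation; it mirrors how published tables put the
largest-magnitude column on the central incisor.

**Weighting.** The historical method is described in the literature only as
"weighted analysis of variance", without a formula. Two reproducible schemes
are built in: `uniform` (OLS) and the default `inv_var_ageband`, a two-pass
feasible WLS — OLS first pass, residual variance per 1-year chronological-age
band, weights equal to inverse band variance, with bands of fewer than two
records or zero variance falling back to the pooled residual variance. The
scheme used is recorded in the `FitResult`.

**Sparse cells and aliasing.** Teeth mature almost in lockstep, so two stage
indicator columns can coincide exactly in finite samples (e.g. every child
with t31 at H also has t32 at H), making the design rank deficient.
`min_cell > 1` first merges any stage observed fewer than `min_cell` times
into the adjacent lower stage (the two then share a score). If the design is
still deficient, `on_deficiency="error"` (library default) raises an error
naming the aliased stage levels, while `"coarsen"` (pipeline/CLI default)
deterministically merges the sparsest aliased group into the stage group
below it within the same tooth until the fit is identifiable; all merges are
reported in the diagnostics. A cohort with no stage variation at all is
rejected as unidentifiable.

**Stratified split.** Train/test splitting is stratified by sex × 1-year age
band; each stratum contributes round-half-up `n × test_fraction` records to
the test set, drawn by a seeded generator, so splits are reproducible.
Singleton strata go to training with a warning. The split fraction has no
canonical value; the default is 0.5.

## Validation statistics

For a set of prediction outcomes: ME = mean signed error, MAE = mean
absolute error, RMSE = √(mean squared error); SDs use n−1. These satisfy
`MAE ≥ |ME|`, `RMSE ≥ MAE` and the decomposition
`RMSE² = ME² + population-variance(error)` (tested to 1e-10).

**RMSE confidence interval.** No standard closed form fits the use case, so
the 95% CI is a subject-level percentile bootstrap, default 2000 resamples,
seeded. Simulation places its coverage near nominal (≈93–96% over 500
cohorts of n=200 with normal errors), and the acceptance suite requires
≥ 90%.

**Wilcoxon signed-rank.** Two-sided; zero differences are dropped (the
classic convention; the count is reported) and ties get midranks. For ≤ 25
non-zero pairs the exact null distribution of the positive-rank sum is built
by dynamic programming over doubled ranks (integers even under midranks) and
p = min(1, 2·min(P(W ≤ w), P(W ≥ w))); beyond that a normal approximation
with continuity and tie corrections is used, which agrees with the exact
path to < 0.02 at n = 12. All-zero differences yield a degenerate result
flagged with p = 1.

**Method comparison** is paired per subject: signed-error differences and
absolute-error differences are averaged per sex and overall, each with a
Wilcoxon p (`p_me` on signed pairs, `p_mae` on absolute pairs), and each
method's RMSE carries its own bootstrap CI. Swapping the two tables negates
every signed difference.

**Calibration slope** is the OLS line of predicted on chronological age
(slope 1, intercept 0 = perfect calibration), reported per sex; the optional
scatter plot needs matplotlib.

**Weighted kappa** is computed on the fixed 9-level ordinal stage scale with
disagreement weights |i−j|/(k−1) (linear, default) or its square
(quadratic); expected disagreement comes from the raters' marginal products.
The weighting used is always recorded. On a two-level scale both weightings
reduce to unweighted Cohen's kappa; a rater without variation makes kappa
undefined (NaN, flagged).

## The synthetic-cohort generator

Each child i gets an age (uniform on the range, or per-band counts to mimic
a study's age table), a sex, a maturation tempo δ_i ~ N(0, σ_child) shared
by all teeth, and per-tooth wobble ε_it ~ N(0, σ_tooth). Tooth t shows the
highest stage whose attainment age μ[sex, t, s] lies at or below
a_i + δ_i + ε_it, else stage 0. This makes stages ordinal, monotone in age
for fixed latents, sex-specific, and correlated within a child — the
features the fitting and validation machinery assume. Gaussian additive
noise on the age axis is a modelling convenience, not a biological claim.

**Calibration.** For ages uniform on (lo, hi) and small noise,
P(stage ≥ s) ≈ (hi − μ_s)/(hi − lo), so `default_params_like_study` inverts
the packaged reference's top-cumulative frequencies:
μ_s = hi − P(stage ≥ s)·(hi − lo), with ties (zero-mass stages) broken by
pushing earlier stages 0.05 y lower to keep μ strictly increasing. The
construction is deterministic. At the defaults the simulated marginals stay
within ~3–4 percentage points of the reference per cell (n = 10000), well
inside the ±10-point acceptance band; the boundary smearing from the latent
noise is the main residual error. The calibration targets the *unfiltered*
cohort; applying the eligibility filter afterwards trims all-H dentitions
and therefore lowers stage-H shares a few points relative to the reference.

**Defaults.** σ_child = 0.7 y and σ_tooth = 0.9 y give a total
stage-attainment SD ≈ 1.14 y and inter-tooth correlation ≈ 0.38, in line
with the spread reported for stage-attainment ages in children and large
enough that adjacent teeth's stage indicators decorrelate (smaller σ_tooth
produced exactly collinear designs at realistic sample sizes). Ages default
to uniform on 4–16 y with an even sex ratio. What the generator does *not*
emulate: secular trends, hypodontia/agenesis, observer mis-staging and
age-distribution spikes; conclusions from passing tests therefore concern
the statistical machinery, not radiographic practice.

**Recovery harness.** `attach_additive_ages` replaces a cohort's ages with
`estimate_age(truth, record) + N(0, σ)`, flooring non-positive results at
0.1 y (counted and warned), so the cohort's generating model is a known
table. With σ = 0 the fit reproduces the truth to ~1e-13. With σ = 0.25 y
and n = 2000 the per-coefficient sampling SE is ≈ 0.25·√(2/n_cell) ≈ 0.03 y,
so the maximum error over the ~112 coefficients concentrates around
0.08–0.15 y even under the most informative (independent uniform stages)
design; the acceptance suite's ±0.05 y bound at that n is therefore not
statistically attainable and that test stays red by design — the recovery
property tests use bounds consistent with the sampling theory instead and
verify that errors shrink with n.

## Pipeline and determinism

`run_pipeline` chains simulate → filter → split → fit → validate → compare,
deriving every stage's seed from the run seed, writing all tables as
delimited text and a JSON manifest (config, library versions, per-stage
counts, failing stage on error) sufficient to re-run any stage in
isolation. Identically configured runs are byte-identical; the manifest
deliberately contains no timestamps. Problem sizes used throughout the test
and acceptance machinery (cohorts of 500–10000, 500 bootstrap-coverage
cohorts, 2000 bootstrap resamples) were chosen as the smallest sizes at
which the checked statistical properties are stable.

## Known limitations

- The packaged table is a transcription; five rows' placement rests on the
  seven-cell alignment argument documented in its provenance notes.
- The original weighting behind "weighted analysis of variance" is not
  specified anywhere accessible; both built-in schemes are documented
  choices, and fitted tables depend (mildly) on which is used.
- Stage-0 vs stage-A handling in the original method is unknowable from the
  source; both are treated as reference (score 0) unless a table says
  otherwise.
- The maturity-score→age percentile conversion of the original Demirjian
  method is supported only through user-supplied tables and is untested.
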