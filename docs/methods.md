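# Methods

## The calibration-transfer model

The package treats the patient's lumbar reference — the arithmetic mean
of trabecular vBMD over the QC-surviving vertebrae L1–L3 — as the
clinical anchor, because the accepted ACR diagnostic cut-offs
(osteoporosis < 80 mg/ml, osteopenia < 120 mg/ml) are defined there.
For every cervicothoracic level ℓ the relationship to the anchor is
modelled as a straight line across patients,

    E[vBMD_ℓ | lumbar] = a_ℓ · lumbar + b_ℓ,

fitted by ordinary least squares over all patients contributing both a
usable vertebra at ℓ and a lumbar reference. The level-specific
diagnostic cut-off for a lumbar cut-off c is the fitted line evaluated
at c:

    threshold_ℓ(c) = a_ℓ · c + b_ℓ.

Two deliberate choices here:

* **Regression direction.** The line predicts the level value *from*
  the lumbar reference. The bundled reference coefficients satisfy
  `threshold = slope · cutoff + intercept` exactly in this direction at
  both cut-offs for all 18 levels, which fixes the convention.
* **Evaluation, not inversion.** Evaluating the line at c and inverting
  the line to find the level value whose predicted lumbar equals c give
  different answers whenever r² < 1; only evaluation reproduces the
  bundled table. The transferred cut-off is therefore "the expected
  level value of a patient sitting exactly at the lumbar cut-off".

Pearson correlations per level are computed twice, with and without the
QC exclusions applied to the level side (the lumbar reference always
honours its own rule), and the two 18-level profiles are compared with
a paired two-sided t test on Fisher z-transformed coefficients. The
z-transform makes correlation differences approximately additive and
variance-stable; a sign-flip permutation p-value is available as an
independent cross-check (`permutation_profile_pvalue`). With 17–18
levels the permutation floor is ≈ 1.5 × 10⁻⁵.

Display rounding is half-up to one decimal (clinical-table convention);
all internal arithmetic and CSV artifacts keep full precision, with a
separate `thresholds_rounded.csv` for display.

## Quality control

Exclusion is flag-based and idempotent: records are never deleted, so
the before/after-exclusion comparison runs on one cohort object.

* Genant fracture grade ≥ 1 → excluded (n reported per level).
* Degeneration grade ≥ 2 (moderate-to-severe) → excluded. Grade 1
  (mild) is retained.
* Both rules can tag the same vertebra; it is counted in both tallies
  and excluded once.
* Grades are mandatory inputs; a missing grade is an error naming the
  patient and level, never assumed 0.

By default the degeneration rule also applies to the L1–L3 reference
region, treating "excluded from further vBMD assessment" as global; a
switch (`use_degeneration_rule_for_reference=False`) preserves the
literal non-fractured-only reading of the reference definition, since
the source material is ambiguous on this point. A patient whose entire
reference region is excluded has no reference and drops out of the
fits (tallied as `n_patients_dropped`).

Group comparisons use Welch's unequal-variance t test (the safer
default when only "unpaired t test" is specified). The sex comparison
first performs deterministic greedy 1:1 nearest-age matching of women
to men within a 5-year caliper, tie-broken by patient id.

## The synthetic cohort generator

The generator exists because the clinical per-vertebra table is not
redistributable. It reproduces the *structure* the analysis assumes,
with defaults emulating the reference study's cohort: 260 patients,
105/260 women, age 59.7 ± 18.3 y truncated to [18, 96], 46/260
contrast-enhanced scans, cervical coverage in 212/260 scans, eight
scanners with the reference sampling weights.

**Latent structure.** A single latent lumbar vBMD per patient drives
everything: latent = sex intercept (at age 18) + sex slope · (age − 18)
+ N(0, σ_between), censored at 0 mg/ml. Defaults: women 215 mg/ml,
−2.8 /y; men 165 mg/ml, −1.1 /y; σ_between = 40 mg/ml. These were
calibrated once, analytically, so the simulated group means sit inside
±25% of the published anchor values (fractured vs non-fractured lumbar
means, age-matched sex means, C4 age-group means) — the anchors are
mutually inconsistent with any single per-sex line, so the defaults sit
inside all the bands rather than on any one anchor. Each level C2–T12
is a_ℓ · latent + b_ℓ + N(0, σ_ℓ) with the bundled reference
coefficients as default couplings; L1–L3 are latent + N(0, 8) each.
Levels are conditionally independent given the latent, the minimal
structure that reproduces a level-wise correlation profile.

**Residual noise.** Per-level σ_ℓ defaults are solved from the bundled
r² profile by inverting

    r_ℓ = a_ℓ σ_L / sqrt(a_ℓ² σ_L² + σ_ℓ²),

where σ_L is the marginal latent sd implied by the age/sex model. That
sd is computed without sampling by integrating the Gaussian-censoring
moment formulas over the truncated-normal age density (64-point
Gauss–Legendre); `expected_level_correlation` exposes the resulting
model-implied r. Censoring the *latent* (rather than each generated
value) keeps the level generation exactly linear, so the zero-noise
configuration (`noiseless_config`) recovers the configured couplings to
machine precision and yields r = 1 at every level — the main structural
self-check of the pipeline.

**Nuisance processes.**

* *Fractures.* P(patient has ≥ 1 fracture) = logistic((75 − latent)/25),
  calibrated so ≈ 23% of patients fracture and their mean lumbar vBMD
  sits near 75–85 mg/ml; a fractured patient carries 1 + Poisson(1.6)
  fractured vertebrae (≈ 2.6 on average), placed regionally with
  probabilities (thoracic 0.65, lumbar 0.34, cervical 0.01), redrawing
  over regions with free imaged levels when a drawn region is full.
  Genant grades over {1, 2, 3} default to uniform (no published
  breakdown exists; this is an explicit assumption). Fractured
  vertebrae receive a positive measured-value bias N(40, 20) mg/ml
  truncated at 0 — compaction/sclerosis inflates the measurement, which
  is what makes the before-exclusion correlation profile visibly worse.
* *Degeneration.* Per-vertebra P(grade ≥ 2) = logistic((age − 90)/10),
  giving ≈ 11% of vertebrae overall; grade 3 with probability 0.3 given
  degeneration; mild grade 1 at rate 0.15 elsewhere. Grade ≥ 2
  vertebrae receive a positive bias N(30, 15) mg/ml truncated at 0.
  Only the direction (increase) is established; the additive Gaussian
  form is a modelling choice.
* *Contrast.* 46/260 scans enhanced; phase venous (0.7) or arterial
  (0.3); one additive scan-level bias per scan, N(20, 8) or N(35, 12)
  mg/ml. The published phase-correction coefficients are not available,
  so these magnitudes are plausible enhancement effects, not calibrated
  values.
* *Scanners.* Eight scanners with plausible phantom-style HU→vBMD
  lines (slopes 0.83–0.90 (mg/ml)/HU) used only to emit raw HU on
  request; measured vBMD is unaffected by scanner identity.

Records carry both the true (unbiased) and measured (bias-applied)
value; downstream analysis sees only the measured value, and tests use
the true value as ground truth.

**What the generator does not emulate.** Real vBMD–age decline is not
exactly linear; level couplings in vivo need not be age-invariant; real
residuals are heteroskedastic and spatially correlated between adjacent
levels; degeneration and fracture co-occur with the *same* vertebra's
density rather than only with age and the patient latent; contrast
enhancement varies by level and perfusion. Passing tests therefore
demonstrate that the pipeline correctly recovers the structure it
assumes — not that the bundled clinical coefficients generalize to any
new population.

## Densitometry

HU→vBMD conversion is `vbmd = slope · hu + intercept`, truncated at the
physical floor 0, with scanner-specific coefficients supplied as
configuration. There are no built-in conversion constants: phantom
calibrations are scanner-specific and unpublished, so a missing
calibration is a hard error naming the scanner. Contrast correction is
a linear map applied after conversion, in vBMD space; phase "none" is
structurally the identity. `fit_contrast_correction` estimates a
correction by OLS from (enhanced, reference) pairs, requiring ≥ 3 pairs
and non-zero variance. The pipeline applies a configured correction per
phase and, when an observed phase has no configured correction, leaves
values uncorrected with a logged warning rather than inventing
coefficients.

## Numerical and policy choices

* OLS and Pearson go through `scipy.stats.linregress` / `pearsonr`;
  test oracles re-derive both from raw sums and normal equations.
* Boundary convention: strict `<` enters the worse category (matching
  the clinical "vBMD < 80 mg/ml" phrasing); equality stays in the
  better category. Verified at one ulp around every bundled threshold.
* Transferred thresholds with a_ℓ ≤ 0 or r² below a configurable floor
  (default 0.3) are emitted but flagged unreliable; the
  osteopenia > osteoporosis ordering is only guaranteed for positive
  slope.
* Levels with fewer than 3 usable patients are omitted from correlation
  maps (with a warning) and refused by the fit; the pipeline fits only
  the levels the cohort covers.
* The rounded regional policy (cervical < 200, thoracic < 100, lumbar
  < 80 mg/ml) distinguishes only osteoporosis vs not-osteoporosis
  unless the user supplies osteopenia constants — no osteopenia
  analogue is published for it. It intentionally disagrees with the
  exact per-level table at some levels (e.g. C7 osteoporosis 153.2
  mg/ml vs the rounded 200); both ship as distinct named policies and
  are not reconciled.
* The L1–L3 cut-offs apply only to the reference levels; L4/L5 are
  representable for input tolerance but are never classified and never
  enter the reference.
* Identity-scale configuration and fail-closed parsing: unknown config
  keys are errors, and every pipeline run writes its resolved
  configuration next to its outputs. All randomness descends from one
  integer seed; two runs with the same configuration produce
  byte-identical CSV artifacts.

## Problem sizes used in the test suite

Structural checks run on cohorts of 260 patients (the emulated study
size); distributional checks (fracture placement, bias recovery,
correlation agreement) use one shared 20 000-patient cohort; parameter
recovery uses 100 seeds at n = 2 000, asserting that ≥ 95% of per-level
fits land within ±0.05 (slope) and ±10 mg/ml (intercept) of the
configured truth and that the seed-averaged per-level r agrees with the
closed form within ±0.03. The per-seed tolerance bands are dominated by
OLS sampling noise at the weakest-coupled level (C2), which is why the
recovery criterion is asserted as a pooled proportion rather than
per seed.

## Known limitations

The bundled coefficients come from a single-centre retrospective cohort
and carry its selection effects; the transfer assumes the level-lumbar
relationship is linear and age-invariant; no fracture-prediction
performance is evaluated (out of scope); Deming/total-least-squares
regression, which treats the lumbar reference as noisy too, is noted as
an alternative but not implemented — with a noisy regressor the OLS
slope is mildly attenuated, which is visible in simulation as a ~1%
shrinkage when the lumbar within-patient noise is large.
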