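# Methods

## Problem setting

Biological-age (BA) clocks map a biomarker panel — clinical chemistry,
proteins, metabolites, or methylation-derived scores — to an age-scale
prediction. When the same people are measured repeatedly, two questions
arise that a single cross-sectional fit cannot answer: how consistent are a
clock's predictions within a person relative to the differences between
people, and when does a prediction deviate enough from the cohort, or move
enough between visits, to be flagged as biologically meaningful rather than
technical noise? This package implements that longitudinal analysis layer,
together with a synthetic-cohort generator that makes every stage testable
against known ground truth.

## Synthetic cohort

The generator emulates a deep-phenotyping design: `n_subjects = 30` (15
male, 15 female), baseline chronological age (CA) uniform on 45–59 years, 13
monthly visits; the clinical panel is measured at every visit, proteomics and
metabolomics bimonthly (visits 1, 3, 5, 7, 9, 11, 13), and a methylation-like
panel at visits 2, 8 and 13. At visit 13 only 20 subjects remain. The
methylation modality carries 16 technical replicates: two at each of its
three visits plus ten retrospective re-assays of the two earlier visits.
With those defaults the modalities contain 380, 200, 200 and 96 samples.

Each sample is driven by a latent biological age

    BA_i(t) = CA_i(t) + δ_i + γ_i (t−1)/12 + w_it,
    δ_i ~ N(0, σ_b²),  w_it ~ N(0, σ_w²),

with CA advancing by one month per visit. Features are linear read-outs,
`x_j = q_j + k_j·BA + N(0, s_j²)`, with per-feature slopes, intercepts and
noise SDs drawn once per cohort from configurable uniform ranges; slopes may
carry either sign, as real biomarkers do.

Defaults `σ_b = 4 y`, `σ_w = 1 y`, `σ_tech = 0.5 y` are a design choice, not
literature estimates: the within-person fluctuation of BA predictions is not
well characterised, and these values put the intraclass correlation of
well-behaved clocks in the 0.85–0.95 region typical of longitudinal
biomarker panels. The per-subject drift γ defaults to 0 (a shared
`drift_rate` constant when set).

A technical replicate shares its biological sample's measured feature vector
and differs by a single BA-scale perturbation `ε ~ N(0, σ_tech²)` mapped
through the feature slopes (`x → x + k_j ε`). Adding independent noise per
feature would let any multi-feature clock average the perturbation away by
`1/√p`, making replicate-derived thresholds vanish with panel size; the
shared-perturbation form keeps "replicate disagreement of a calibrated
clock" at SD `σ_tech` years regardless of panel size, which is the quantity
the thresholds are meant to bound.

Batches: the bimonthly modalities are shipped in four batches by visit block
({1,3}, {5,7}, {9,11}, {13}); an optional per-batch additive feature shift
(`batch_shift_sd`) exercises the median-based batch centering.

What the generator does **not** emulate: assay-specific distributions
(features are Gaussian around a linear age trend), missingness, non-linear
age trajectories, correlated feature noise, seasonal effects, or any real
clock's coefficient structure. Passing tests therefore demonstrate the
correctness and power of the *analysis machinery* under a known model, not
the behaviour of any particular published clock on human data.

## Clocks

**Coefficient-table clocks** are linear scores `intercept + Σ w_j x_j`,
optionally followed by the piecewise log-linear age calibration used by
epigenetic clocks: `age = (1+a)·e^s − 1` for `s ≤ 0`, `(1+a)·s + a`
otherwise, with knot `a = adult_age` (default 20). Inputs absent from a
cohort are imputed with the clock's reference medians, mirroring how
published clocks are applied to panels that lack a variable; a missing input
without a median is a hard error listing the feature ids.

**MLR** regresses CA on the biomarkers by ordinary least squares; **PCA**
standardises the panel, takes the first principal component, orients it to
correlate positively with CA and rescales it to the training-age mean and
SD. Both are emitted as equivalent linear clocks on raw features. Because
they are fit to the cohort itself, their predictions are shrunk towards the
cohort mean — the regression of CA on BA-driven features has slope
`var(CA)/(var(CA)+σ_b²+σ_w²)` even with noiseless features; this is a
property of cohort-trained CA predictors, not a bug.

**Klemera–Doubal (KDM)** regresses each biomarker on CA (`x_j = q_j +
k_j·CA`, residual SD `s_j`) and combines the per-biomarker age estimates by
inverse variance:

    BA_E  = Σ_j (x_j − q_j) k_j/s_j²  /  Σ_j k_j²/s_j²
    BA_EC = (Σ_j (x_j − q_j) k_j/s_j² + CA/s_BA²) / (Σ_j k_j²/s_j² + 1/s_BA²)

`ba_pred` is the CA-anchored `BA_EC`; `BA_E` is kept for diagnostics.
Biomarkers with `|k_j|/SE ≤ 2` are dropped with a warning — near-zero slopes
otherwise receive unstable `1/s_j²` weights. `s_BA²` is estimated as
`var(BA_E − CA)` on training data minus the estimation variance of `BA_E`
(`1/Σ k_j²/s_j²`), floored at 0.25 y²; both the threshold and the floor are
configurable.

**Reference clocks** stand in for published fixed-coefficient predictors: per
modality, the inverse-variance-optimal linear read-out of latent BA derived
from the generative feature parameters (`w_j ∝ k_j/s_j²`). They involve no
cohort-specific fitting, which is exactly the property that distinguishes a
published clock from a cohort-trained one.

**Batch centering** subtracts the per-batch, per-feature median and adds
back the global median, preserving within-batch rank order; batches with
fewer than two samples are left alone with a warning.

## Variability statistics

Technical replicates are excluded from all statistics in this section.

**Variance components** come from one-way random-effects ANOVA with the
unbalanced-group-size correction: with subject sizes `m_i`, `M = Σ m_i`,

    MSW = Σ_ij (y_ij − ȳ_i)² / (M−N),   MSB = Σ_i m_i (ȳ_i − ȳ)² / (N−1),
    n0  = (M − Σ m_i²/M) / (N−1),
    σ̂_w² = MSW,   σ̂_b² = max(0, (MSB − MSW)/n0).

The closed-form moment estimator was chosen over REML deliberately: it is
hand-checkable, exact for the balanced case, and adequate for ≤ 13 visits.
Negative between-subject estimates are truncated at zero. Then
`ICC = σ̂_b²/(σ̂_b²+σ̂_w²)` and `Var_ratio = σ̂_w²/σ̂_b²`; both derive from the
same components, so `ICC = 1/(1+Var_ratio)` holds to machine precision.
`(0,0)` components make the ICC undefined (an error, not a value);
`σ̂_b² = 0` makes the ratio infinite (reported missing with a warning).

**Stability index.** For subject `i`, the raw index is the reciprocal of the
mean *absolute* pairwise difference of their predictions across visits.
Absolute values are used even though a plain difference could be read from
the defining formula: signed pairwise differences of a zig-zag trajectory
cancel towards zero and would send the index to infinity for the least
stable subjects — the opposite of the intended "less fluctuation = higher
index" semantics. Raw indices are min–max normalised to [0, 1] jointly
across every (clock, subject) pair in the run (so clocks are comparable
within a run but not across runs); a subject with identical predictions has
an infinite raw index and maps to 1.0 with a warning. Category scores
average the normalised values over subjects, then over the clocks in the
category.

**Correlation table.** Pearson r of prediction vs CA per clock, pooling all
visits, excluding technical replicates, p-values unadjusted.

## Deviation flagging

**Robust bands.** The spread estimate is the normal-consistent scaled median
absolute deviation, `1.4826 × median|x − median(x)|` — the scaling is what
makes the ±2 and ±3 bands match the 95th/99th standard-normal percentiles
(coverage 95.45% and 99.73%). Unscaled-median and mean-absolute-deviation
variants are available behind a switch. The centre is the per-clock pooled
median over all biological replicates; a per-visit centre is an option. A
zero MAD (degenerate spread) flags every off-centre value at all levels,
with a warning.

The pipeline flags deviations of **age acceleration** (BA − CA) by default
rather than raw predictions (`RunConfig.flag_on`): across a cohort spanning
14 years of CA, the pooled spread of raw predictions is dominated by CA
itself, so raw-value flags mostly mark the chronologically oldest and
youngest subjects. Flagging the acceleration compares like with like; raw
prediction flagging remains available.

**Change thresholds.** Per clock, `T_c = max |Δ| over technical-replicate
pairs + elapsed_max`, where `elapsed_max` is the largest calendar time
between that clock's analysis visits (days/365.25) — a within-person change
is only interesting once it exceeds technical noise plus the age actually
gained. All replicate pairs contribute to one global maximum (a per-pair
elapsed term is a possible refinement; the global maximum is conservative).
Visit-pair changes above `T_c` are flagged with the observed |Δ| reported
alongside.

**Replicate selection.** Among a subject's technical replicates (and the
original), the sample with the highest mean cosine similarity to the
subject's other samples is selected; zero-norm vectors are excluded, ties go
to the lowest replicate id.

**Consistent deviators.** Subjects flagged in ≥ 2 distinct clocks at at
least one shared visit, ranked by total flag count. The power of this
summary is measured by `planted_outlier_trial`: one subject's between-person
offset is fixed at `3σ_b` (= 12 y), reference clocks applied, and recovery
means that subject tops the ranking. Measured power is ~90% over 50
simulated cohorts (93/100 over a wider sweep).

## Numerical and size choices

- All randomness flows from a single integer seed through one
  `numpy.random.Generator`; reruns are byte-identical (JSON keys sorted,
  dates ISO-8601, ages in decimal years).
- Acceptance-scale simulations: MAD coverage at n = 10⁶; ICC recovery with
  200 replicates of a 30-subject × 3-visit design; outlier power over 50
  cohorts of the default 30-subject design. These sizes give Monte-Carlo
  error comfortably below the tolerances being checked.
- Density summaries use a Gaussian KDE with Silverman bandwidth on a fixed
  grid (trapezoid integral within 1e-3 of 1).
- KDM residual SDs are floored at 1e-8 to keep `1/s_j²` finite on noiseless
  fixtures; `s_BA²` floored at 0.25 y².

## Known limitations

- The stability normalisation is run-relative: scores from different runs or
  cohorts are not directly comparable.
- The ANOVA ICC does not adjust for covariates (age trend, sex); a subject
  ageing 1 year over 13 visits inflates σ̂_w² slightly for accurate clocks.
- Published clock coefficients are not shipped; coefficient-table files are
  the interface for users who have them.
- The generator's linear-Gaussian feature model cannot expose failures
  specific to heavy-tailed or non-linear biomarker–age relationships.
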