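# Methods

## Problem and model

Image-based dosimetry for ¹⁷⁷Lu-PSMA-617 therapy requires the
time-integrated activity (TIA) of each volume of interest (VOI) — kidneys,
individual lesions, and a whole-field-of-view tumour burden (TB_FOV) —
because absorbed dose is proportional to TIA through S-values (dose
conversion is out of scope here). The reference protocol images each
therapy cycle at multiple time points (MTP), nominally 24, 48 and 72 h
post injection, and fits each VOI's activity samples with a
monoexponential washout

    A(t) = A0 · 2^(−t / T_eff),

where `A0` (MBq) is the back-extrapolated activity at injection and
`T_eff` (h) the effective half-life combining physical decay and
biological clearance. The reference TIA is the analytic integral

    TIA_ref = A0 · T_eff / ln 2   [MBq·h].

Two single-time-point (STP) alternatives are evaluated against this
reference for the second therapy cycle:

* **STP_prior** uses one measured activity `A(t)` in cycle 2 plus the same
  VOI's cycle-1 fitted half-life `T_prior`:
  `TIA = A(t) · 2^(t/T_prior) · T_prior / ln 2`. It is exact when the
  kinetics do not change between cycles and the sample lies on the curve.
* **STP_H** (Hänscheid) needs no prior: `TIA ≈ A(t) · 2t / ln 2`. On an
  exact monoexponential curve its relative error is
  `2x·2^(−x) − 1` with `x = t / T_eff`: zero at `x = 1` and `x = 2`, a
  maximum of `2/(e·ln 2) − 1 ≈ +6.15%` at `x = 1/ln 2 ≈ 1.44`, and growing
  underestimation outside. The conventional validity window
  `0.75 ≤ x ≤ 2.5` (endpoints inclusive here) has boundary errors of
  −10.81% and −11.61%; we expose the error function itself
  (`stp_h_relative_error`) so tests target the analytic structure rather
  than any heuristic error bound.

## Fitting

The fit is ordinary least squares of `ln A` on `t` (closed form, no
starting values, equivalent to a multiplicative-error model) — the
standard choice for mono-exponential washout and exactly reproducible
across platforms. Whether a nonlinear fit on the linear scale would differ
is second-order at the noise levels considered. Two-point curves are
allowed (exact interpolation); `n_points` is recorded for downstream
filtering. A fitted non-positive decay constant (net-increasing or flat
curve) is flagged — `half_life_eff_h` negative, or −∞ for an exactly flat
curve — never truncated; TIA operations refuse such fits.

## Comparison statistics

The percentage difference `PD = 100·(TIA_STP − TIA_ref)/TIA_ref` is
computed per VOI × method × nominal time, using the *measured* sample
nearest the nominal time (within a ±6 h tolerance, configurable) rather
than a model prediction. Strata pool left/right kidneys. Summaries:

* **Bland–Altman**: mean difference, sample SD (n−1), limits of agreement
  mean ± 1.96·SD. The difference axis defaults to the PD definition
  (reference denominator) so that PD analysis and Bland–Altman share one
  difference; the pair-mean-denominator variant is available via
  `bland_altman_denominator="pair_mean"`.
* **Wilcoxon signed-rank**, two-sided, zero differences dropped (classic
  treatment, not Pratt), mid-ranks for tied magnitudes. For n ≤ 25 the
  exact null distribution is computed by dynamic programming over doubled
  ranks (valid under ties; equivalent to enumerating all 2^n sign
  patterns); larger n uses the normal approximation with tie-corrected
  variance and a 0.5 continuity correction. p-values are reported raw (no
  multiplicity correction), with a 0.05 reporting threshold.
* **Coverage**: fractions of VOIs with |PD| ≤ 10% and ≤ 20% (inclusive
  bounds), and the count/percentage of VOIs whose imaging time lies in the
  Hänscheid window per cycle and time.
* **Half-life change**: per-VOI `100·(T2 − T1)/T1` with the count strictly
  exceeding ±20% (a change of exactly 20% is not counted).

## Synthetic cohort

Clinical per-VOI SPECT data are not redistributable, so the cohort module
generates populations with the same statistical structure: 20 patients ×
2 cycles by default, injected activity 6090 ± 130 MBq, imaging at
24/48/72 h with ±2 h uniform jitter (one session per patient-cycle,
shared by all VOIs), 15% of patients with a single functional kidney, and
0–6 lesions per patient (uniform).

Effective half-lives are drawn from truncated normal distributions on the
natural scale using the printed population parameters as (mean, SD,
min, max) per VOI type and cycle — kidneys 32.5 ± 7.0 (17.8; 51.9) /
31.7 ± 6.4 (21.6; 45.7) h, lesions 69.0 ± 40.0 (20.1; 249.7) /
66.6 ± 34.2 (19.7; 216.2) h, TB_FOV 75.3 ± 41.8 (45.5; 240.0) /
64.8 ± 35.0 (14.5; 192.8) h. (A truncated normal parameterized by the
printed mean has a slightly different distributional mean when the range
is asymmetric; the shift is ≪ 1 SD and accepted in exchange for using the
printed values verbatim.) The same VOI's two cycles are coupled by a
Gaussian copula with ρ = 0.8, calibrated so that ≈46% of lesions change
half-life by more than ±20% between cycles (a 2·10⁵-draw check gives
47.3%); ρ is a parameter and the calibration is documented, not hidden.

Measurement noise is multiplicative lognormal, mean-unbiased on the
linear scale: each sample is `A_true(t)·exp(ε)` with
`ε ~ N(−σ²/2, σ)`, `σ² = ln(1 + cv²)`, default cv = 5%. Per-VOI uptake
fractions (kidney median 2% of injected activity, lesion 0.5%, lognormal
spreads 0.3/0.8, ±15% lognormal cycle-to-cycle variability) are simulator
choices — no per-VOI uptake data are published — chosen to give
kidney-scale A0 of order 100 MBq after a ~6 GBq injection; only relative
quantities (PDs, half-life statistics) are compared against
population-calibrated behaviour. TB_FOV is the sum of the patient's lesion
measurement curves (conservation holds exactly by construction), yet the
pipeline fits TB_FOV curves independently downstream, as the clinical
procedure does; an independent TB_FOV sampling mode exists behind
`tbfov_independent=True`. An optional slow second component produces
biexponential truth while fitting stays monoexponential.

What the generator does **not** emulate: SPECT acquisition and
reconstruction, partial-volume and scatter effects, registration error,
lesion appearance/disappearance between cycles, or progressive-disease
kinetics beyond the copula coupling. Passing tests therefore demonstrate
the estimators' behaviour under clean monoexponential (or mildly
biexponential) kinetics with realistic population spread and measurement
noise — not robustness to image-domain artefacts.

## Phantom path

The voxel-phantom module exercises the image-side steps: axis-aligned
ellipsoids/spheres voxelized with partial-volume fill fractions (4×
subsampling per axis, keeping voxelized volume within ~1% of analytic for
radii ≥ 3 voxels), decayed per-object to each imaging time, written and
read as NIfTI. Segmentation is the 20%-of-maximum fixed threshold: the
26-connected component containing the hottest voxel of the seed region;
connectivity is fixed at 26 (a deliberate choice — upstream clinical
segmentation software is not specified on this point). Body-weight SUV
uses unit-density tissue: `SUV = C[kBq/ml] · BW[g] / A_inj[kBq]`. The
full iterative PSMA lesion-threshold algorithm is out of scope and
replaced by this configurable threshold.

## Numerical and design choices

* Units fixed: MBq, hours, MBq·h; conversions only at the I/O boundary.
* Window endpoints inclusive (boundary cases count as valid).
* The spread/coverage comparisons in the acceptance suite run on a seeded
  200-patient cohort — large enough that orderings (lesion PD spread vs
  kidney, 48 h vs 24 h kidney window coverage) are stable, and small
  enough that the whole suite runs in seconds on one CPU; the half-life
  recovery check uses 1000 VOIs and the noise-calibration check 10⁴
  replicates.
* Report bundles are deterministic: no timestamps, sorted groupings,
  fixed float formatting; identical config + seed ⇒ byte-identical files.
* `stp_prior` takes the prior half-life as a plain argument, so
  population-prior variants (e.g. a cohort-mean half-life) are expressible
  without a separate code path.

## Known limitations

* The Hänscheid window's textbook "less than 10% error" heuristic is
  slightly exceeded at both window edges under pure monoexponential
  kinetics (−10.8% / −11.6%); the package documents the derived values and
  does not enforce the 10% figure.
* Absolute TIA magnitudes from the simulator are not calibrated to
  clinical uptake; only relative statistics are meaningful.
* Monoexponential fitting of biexponential truth biases the effective
  half-life upward; the simulator can generate such truth, but the
  analysis (by design) still fits a single exponential.
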