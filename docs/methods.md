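# Methods

This note documents the models, the processing conventions, the numerical
choices, and what the synthetic-data tests do and do not establish.

## Scope and data model

The package analyses a two-arm (therapy vs control), two-timepoint
(baseline vs follow-up) preclinical tumor MRI experiment consisting of
multi-b-value diffusion-weighted imaging (DWI) with repeated acquisitions
per b-value, and a dynamic contrast-enhanced (DCE) series with an aorta
region of interest for the arterial input function (AIF). Images are
NIfTI-1; masks are inputs, never computed (tumor segmentation is a manual
upstream step). All acquisition metadata — b-values, frame times,
repetition packing, voxel spacing — are declared in the run configuration;
nothing is guessed from headers.

## DWI preprocessing

Order of operations: in-plane motion correction → signal-dropout
detection and exclusion → averaging of surviving repetitions → volumetric
Gaussian smoothing. Smoothing comes last so misaligned or corrupted
repetitions are never blurred into the data. The order is a design
choice; only the individual operations (correction, exclusion, smoothing
at 1.5 mm width) are fixed by the protocol being reproduced.

**Gaussian smoothing.** "Width" is interpreted as full width at half
maximum (FWHM), the common radiological convention; sigma per axis is
`FWHM / (2 sqrt(2 ln 2)) / spacing`, truncated at 3 sigma, reflective
boundary. Defaults: 1.5 mm for DWI, 1.0 mm for DCE. NaN voxels are
handled by normalised convolution.

**Signal-dropout rule.** For each (slice, b-value), a repetition is
excluded when its mean foreground intensity falls below 2/3 (~67%) of the
mean foreground intensity of the brightest ceil(R/2) repetitions.
"Foreground" is defined once per (slice, b-value) as the voxels above the
Otsu threshold of the across-repetition median image, so the same mask
scores every repetition and the mask itself cannot be corrupted by the
dropout being tested. Slices with an empty foreground are flagged
all-excluded with a warning. The threshold fraction (default 2/3) and
the inclusive bright-half convention for odd R are configuration-exposed.

**Registration.** Rigid translation only — bulk motion of an
anaesthetised mouse is small, and the protocol names no deformable
method. The estimator is normalized cross-correlation evaluated on the
true overlap region for every integer displacement in a ±5 voxel window,
refined per axis by quadratic interpolation of the correlation peak
(clamped to ±0.5 voxel). Computing the correlation on overlaps rather
than circularly (FFT) matters: wrap-around artefacts otherwise dominate
for small matrices. DWI slices register onto the repetition with the
highest mean foreground signal per (slice, b-value); DCE frames register
in 3-D onto the mean of the pre-bolus baseline frames. Shift application
uses first-order spline interpolation. Known shifts are recovered within
0.25 voxel in 2-D and 3-D (verified on smoothed random fields and on
phantoms).

## Diffusion models

**Monoexponential ADC.** `S(b) = S0 exp(-b * ADC)`, ADC bounded to
[0, 1e-2] mm²/s, fitted by bounded trust-region least squares initialised
from a log-linear regression on positive signals. On noiseless data the
initialisation is already exact and the optimizer polishes to < 1e-8
relative error.

**Triexponential IVIM.** Three compartments: microcapillary
pseudodiffusion (fraction `f` in %, coefficient `D*`), free water at
fixed `D_water = 3.0e-3 mm²/s` (fitted fraction `f_water` in %), and
tissue diffusion `D`. Bounds: `D` in [0.1, 2.0]e-3 mm²/s, `D*` in
[5e-3, 0.5] mm²/s. Two constraints beyond the boxes are enforced as
penalty residuals: the separation `D* >= 10 D` (prevents compartment
label-swapping, standard IVIM practice) and the fraction budget
`f + f_water <= 100`. Initialisation is two-stage — a monoexponential
fit on b >= 200 s/mm² seeds `D` and the tissue amplitude, the residual
low-b amplitude seeds `f`, `f_water` starts at 2% — expanded into a
deterministic 9-point multistart over `D*` in {15, 50, 150}e-3 and three
fraction seeds; the lowest data residual sum of squares wins.

The default b-grid is
{0, 10, 20, 30, 40, 60, 80, 100, 150, 200, 300, 400, 600, 800} s/mm²:
dense low-b sampling is what makes the perfusion compartment
identifiable. The acquisition's actual b-values are configuration input.

The least-squares objective is Gaussian although magnitude MR noise is
Rician. The resulting bias is characterised rather than corrected: with
this b-range the Rician floor inflates the low-signal high-b points,
flattens the apparent decay, and biases ADC *downward* at low SNR
(measured ≈ -6% at SNR 5, ≈ -1.5% at SNR 10, negligible by SNR 50);
the magnitude of the bias shrinks monotonically with SNR.

Voxel-wise fitting propagates NaN for failed voxels, so ROI means are
means over converged voxels only; a warning fires when more than half
of an ROI fails. Whether to fit voxel-wise then average (default) or fit
the ROI-mean signal is a configuration choice.

## DCE-MRI and the two-compartment exchange model

Contrast concentration is approximated by absolute signal enhancement
`S(t) - S0`, with `S0` the voxel mean over the first `n_baseline`
(default 5) pre-bolus frames. No T1 mapping, relaxivity conversion or
hematocrit correction is applied; consequently plasma flow and plasma
volume are calibrated only up to the common scaling of the tissue and
arterial enhancement — ratios and group contrasts are meaningful, the
absolute scale tracks the AIF normalisation.

The AIF is the ROI-mean enhancement in the aorta mask. Bolus arrival is
the first frame exceeding baseline mean + 5 baseline SDs, sustained for
two consecutive frames (an isolated noise spike cannot trigger arrival).

The 2CXM mass balance, with volume fractions `v_p = PV/100`,
`v_e = ve/100` and rates `F_p = PF/6000 s⁻¹`, `P_S = PS/6000 s⁻¹`:

    v_p dc_p/dt = F_p (c_a(t - t0) - c_p) + P_S (c_e - c_p)
    v_e dc_e/dt = P_S (c_p - c_e)
    C_t = v_p c_p + v_e c_e

The production path is closed-form: the 2x2 compartment matrix is
eigen-decomposed into a biexponential impulse response, convolved exactly
against the piecewise-linear (linearly interpolated) AIF segment by
segment, with series fallbacks where `|lambda dt| < 1e-8`. An
independent stiff ODE integration (Radau, rtol 1e-10, max step one frame
interval) of the same interpolated input serves as the oracle; both
routes agree to better than 1e-6 relative across a 54-point parameter
sweep including the PS = 0 one-compartment limit and fast-exchange
PS = 300 mL/100 mL/min. Degenerate geometries (`v_p = 0` with flow, or
`v_e = 0` with exchange) raise and callers must use the reduced model.

Fitting: bounded least squares over (PF, PV, PS, ve, t0) with the budget
`PV + ve <= 100` as a penalty, the delay t0 free in [0, 10] s, from a
deterministic 12-point multistart grid (PF in {20, 60, 150} x PV in
{5, 15} x PS in {5, 20}); lowest residual sum of squares wins. Noiseless
curves sampled at 1.5 s over 5 min recover PF and PV to machine
precision (well under the 2% design tolerance); with 5%-of-peak Gaussian
noise the median PF/PV errors over 200 replicates are below 15%.
Recovery degrades monotonically as sampling coarsens (tested at
dt = 1 → 8 s) — the temporal resolution of the acquisition is the
binding identifiability constraint.

## Cohort statistics

Group summaries are mean ± sample SD (n−1). Intergroup comparisons use
the two-sided Mann–Whitney U-test (exact enumeration for tie-free data
with min(n1, n2) <= 8, otherwise normal approximation with tie and
continuity corrections; statistic reported as min(U1, U2)). Intragroup
baseline-vs-follow-up comparisons use the two-sided Wilcoxon signed-rank
test after pairwise deletion of incomplete pairs; zero differences are
dropped (Pratt handling available by configuration); exact p for
tie-free n <= 15. The exact/approximate thresholds are chosen so cohorts
of 7–14 per arm exercise both paths, and each result records which path
produced it. Correlations are pairwise-complete Spearman rho with
t-distribution p-values (n − 2 df), rendered as a heatmap with
nonsignificant entries crossed out. p-values are raw throughout: no
multiplicity adjustment is applied anywhere, by design.

The exact implementations are delegated to scipy.stats behind this
module's conventions; the test suite verifies them against independent
brute-force enumeration (all C(n+m, n) labelings for Mann–Whitney, all
2^n sign assignments for Wilcoxon, the 1 − 6Σd²/(n(n²−1)) rank formula
for Spearman) on tie-free data.

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline consumes, with recorded
ground truth and full determinism under (spec, seed):

* **DWI phantoms** — an ellipsoidal tumor (~134 mm³ by default, inside
  the 100–1000 mm³ range such flank tumors span) in a darker uniform
  background, per-voxel mono- or triexponential truth, Rician magnitude
  noise `sqrt((S+n1)² + n2²)`, injected dropout slice-repetitions
  (scale 0.5, safely below the 2/3 threshold) and injected in-plane
  shifts. The Rician mean is verified against the analytic expectation
  `sigma sqrt(pi/2) L_half(-S²/2sigma²)`.
* **DCE phantoms** — a gamma-variate bolus
  `a (t - t0)^alpha exp(-(t-t0)/tau)` (defaults a = 50, alpha = 2,
  tau = 4 s, t0 = 12 s; peak at t0 + alpha tau) carried by an aorta
  region, 2CXM tissue curves in the tumor region, distinct pre-contrast
  baseline intensities per region (so registration has anatomy to lock
  onto), additive Gaussian noise.
* **Cohorts** — subject-level values from truncated normal distributions
  whose per-group, per-timepoint means and SDs default to the reported
  group summaries of the study being reproduced (ADC, D, D*, f, PF, PV,
  volume); within-subject correlation between timepoints 0.5 (assumed —
  the in-vivo value is unreported); baseline missingness 0.35 emulating
  tumors too small to assess (volume itself stays observed).

Not emulated: anatomical realism, coil sensitivity, EPI distortion,
partial-volume mixtures, respiratory motion patterns beyond rigid
translation, or any biological link between immune infiltration and
diffusion. Passing tests therefore establish that the estimators invert
their own forward models at realistic noise levels and that the
statistical layer is exact — they do not certify in-vivo accuracy, where
model mismatch (non-Gaussian residuals, AIF partial volume, T1
nonlinearity) dominates.

The default study design (14 + 14 subjects, the default effect sizes) is
powered: the follow-up ADC Mann–Whitney comparison rejects at
alpha = 0.05 in roughly 90% of seeded replicates.

## Numerical conventions and degenerate inputs

* Missing values are NaN in memory, empty fields in CSV.
* Exactly-at-threshold repetitions survive the dropout rule (strict
  inequality); the comparison is float-sensitive at exact equality, so
  tests probe just above/below the threshold.
* Constant slices register with zero shift and a warning; empty
  foregrounds exclude the slice with a warning, never an exception.
* All-zero paired differences give Wilcoxon p = 1 with a warning;
  constant columns give NaN Spearman rho, flagged.
* Every stochastic step takes an explicit seed; per-subject seeds derive
  from the run seed via `SeedSequence`, and rerunning a configuration
  reproduces all outputs bit-identically.

## Problem sizes

Defaults are chosen so the full test suite and the acceptance script run
on a single CPU in minutes: phantom matrices of 24×24×4 (DWI) and
16×16×3 (DCE), 3–4 repetitions, 200 DCE frames, 100-replicate
detection/power loops, 500-voxel noise characterisations. All sizes are
configuration-scalable to acquisition-realistic matrices; the estimators
are voxel-independent, so accuracy results transfer unchanged.
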