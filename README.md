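# mpmri

Quantitative multiparametric MRI analysis for preclinical tumor studies:
diffusion parameter mapping (monoexponential ADC and triexponential IVIM),
two-compartment exchange model (2CXM) DCE-MRI pharmacokinetics with an
aorta-derived arterial input function, and the nonparametric two-arm
statistics such studies report.

It is written for imaging scientists running small-animal therapy
experiments — two arms (therapy / control), two timepoints (baseline /
follow-up), 7–14 animals per arm — who need a reproducible, testable
pipeline from raw NIfTI series to group statistics, and a synthetic-data
layer that lets every stage be validated against known ground truth
without any in-vivo data.

## Models

**Diffusion.** Voxel-wise signal-vs-b-value decays are fitted with the
monoexponential model

    S(b) = S0 · exp(−b · ADC)

and with a triexponential intravoxel-incoherent-motion (IVIM) model
separating microcapillary pseudodiffusion (fraction *f* in %, coefficient
*D\**), a free-water compartment with fixed D_water = 3.0×10⁻³ mm²/s
(fitted fraction *f*_water), and tissue diffusion *D*:

    S(b) = S0 · [ (f/100) e^(−b·D*) + (f_water/100) e^(−b·D_water)
                  + (1 − f/100 − f_water/100) e^(−b·D) ]

**Perfusion.** DCE tissue curves (absolute enhancement S(t) − S0 as the
concentration proxy) are fitted with the 2CXM

    v_p dc_p/dt = F_p (c_a(t − t0) − c_p) + PS (c_e − c_p)
    v_e dc_e/dt = PS (c_p − c_e),      C_t = v_p c_p + v_e c_e

reported as plasma flow PF (mL/100 mL/min) and plasma volume PV
(mL/100 mL), with the arterial input c_a extracted from an aorta ROI.
The forward model is computed analytically (biexponential residue
convolution) and cross-checked against direct ODE integration to 10⁻⁶.

**Statistics.** Mann–Whitney U between arms, Wilcoxon signed-rank within
arms after pairwise deletion, Spearman correlation matrix; exact
small-sample p-values where tie-free, raw (unadjusted) p throughout.

See `docs/methods.md` for conventions, tolerances and limitations.

## Worked example

Fit the IVIM model to one voxel's noisy decay (Rician noise, SNR ≈ 83)
and the 2CXM to a noiseless synthetic tumor curve:

```python
import numpy as np
from mpmri import dwi, dce, simulate

b = dwi.DEFAULT_B_VALUES                    # 14 b-values, 0–800 s/mm²
sig = dwi.triexp_signal(1000.0, 8.0, 60e-3, 4.0, 0.6e-3, b)
noisy = simulate.rician(sig, 12.0, np.random.default_rng(0))
print(dwi.TriexpIvimModel(noisy, b).fit().summary())

series, (tumor, aorta), truth = simulate.make_dce_phantom(seed=0)
aif = dce.extract_aif(series, aorta, n_baseline=5)
print(dce.TwoCompartmentExchangeModel.from_series(
    series, tumor, aif, 5).fit().summary())
```

```
IvimResults
==========================================================
parameter         estimate       std err           units
----------------------------------------------------------
S0                 1001.96          10.3            a.u.
f                  6.53336          1.35               %
D_star           0.0845644        0.0407          mm^2/s
f_water            12.7745          6.97               %
D              0.000533272      9.56e-05          mm^2/s
----------------------------------------------------------
n obs: 14    rss: 983.086    converged: True

TwoCxmResults
==============================================================
parameter     estimate     std err                   units
--------------------------------------------------------------
PF                  60    3.11e-10           mL/100 mL/min
PV                  13    5.54e-11               mL/100 mL
PS                  10     7.5e-11           mL/100 mL/min
ve                  20    8.35e-11               mL/100 mL
t0          4.2815e-10    3.07e-11                       s
--------------------------------------------------------------
n obs: 200    rss: 3.82913e-18    converged: True
```

The noisy IVIM fit illustrates the identifiability profile of the model:
tissue diffusion D and the total perfusion signal are well determined,
while D\* and the f/f_water split carry large standard errors at a single
voxel — which is why ROI means over voxel-wise maps, not single voxels,
feed the cohort statistics. The noiseless 2CXM fit recovers the phantom
truth (PF = 60, PV = 13, PS = 10, ve = 20, t0 = 0) to machine precision.

End-to-end from a shell:

```sh
mpmri run-all --mode cohort --subjects 14 --seed 42 --out study/
```

writes the cohort table, group summaries (mean ± SD), the Mann–Whitney /
Wilcoxon report, and the Spearman correlation matrix with heatmap into
`study/`. An `--mode imaging` run generates per-subject DWI/DCE phantoms
and drives them through motion correction, signal-dropout exclusion
(threshold 2/3 of the bright-half mean per slice and b-value), repetition
averaging, Gaussian smoothing (FWHM 1.5 mm DWI / 1.0 mm DCE) and
voxel-wise fitting first.

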