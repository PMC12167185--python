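"""Synthetic phantoms and cohorts with known ground truth.

No raw animal images accompany the study this pipeline is built for, so
every stage is exercised on generated data whose truth is recorded:

* DWI phantoms — an ellipsoidal "tumor" inside a uniform background, with
  per-voxel mono- or triexponential diffusion truth, Rician magnitude
  noise, optional injected dropout repetitions (intensity scaled below
  the exclusion threshold) and optional injected in-plane shifts.
* DCE phantoms — an aorta region carrying a gamma-variate bolus and a
  tumor region carrying 2CXM tissue curves, with additive Gaussian noise.
* Cohorts — a two-group (therapy/control) x two-timepoint
  (baseline/follow-up) table of subject-level parameters drawn from
  truncated normal distributions, with within-subject correlation between
  timepoints and baseline missingness emulating tumors too small to
  assess.

Everything is deterministic under (spec, seed): regenerating with the
same arguments is bit-identical, and every injected artifact is recorded
in :class:`PhantomTruth` so detectors can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .dce import AifCurve, twocxm_forward
from .dwi import D_WATER, DEFAULT_B_VALUES, monoexp_signal, triexp_signal
from .exceptions import GeneratorSpecError
from .io import CohortTable, DceSeries, DwiStack, RoiMask

__all__ = [
    "PhantomTruth",
    "CohortDesign",
    "DEFAULT_COHORT_DISTRIBUTIONS",
    "PARAMETER_UNITS",
    "ellipsoid_mask",
    "make_dwi_phantom",
    "make_aif",
    "make_dce_phantom",
    "make_cohort",
    "rician",
]


@dataclasses.dataclass
class PhantomTruth:
    """Ground truth of a generated phantom.

    ``maps`` holds per-voxel truth arrays keyed by parameter name;
    ``dropouts`` lists injected ``(b_index, repetition, z, scale)``;
    ``shifts`` lists injected ``(b_index, repetition, z, (dy, dx))``.
    """

    maps: dict[str, np.ndarray]
    noise_model: str
    noise_sigma: float
    dropouts: list[tuple[int, int, int, float]]
    shifts: list[tuple[int, int, int, tuple[float, ...]]]
    seed: int

    def dropout_set(self) -> set[tuple[int, int, int]]:
        return {(b, r, z) for b, r, z, _ in self.dropouts}


def ellipsoid_mask(shape, center_vox, radii_mm, spacing) -> np.ndarray:
    """Boolean ellipsoid; ``shape``/``center`` are (z, y, x), radii in mm."""
    dz, dy, dx = spacing[2], spacing[1], spacing[0]
    z, y, x = np.ogrid[: shape[0], : shape[1], : shape[2]]
    rz, ry, rx = radii_mm
    return (
        ((z - center_vox[0]) * dz / rz) ** 2
        + ((y - center_vox[1]) * dy / ry) ** 2
        + ((x - center_vox[2]) * dx / rx) ** 2
    ) <= 1.0


def rician(signal: np.ndarray, sigma: float, rng: np.random.Generator
           ) -> np.ndarray:
    """Rician magnitude noise: ``sqrt((S + n1)^2 + n2^2)``, n_i ~ N(0, s²).

    This is the magnitude of a complex signal with independent Gaussian
    noise on both channels; it positively biases low-SNR magnitudes."""
    if sigma == 0:
        return signal.copy()
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2 ** 2)


_DEFAULT_DWI_SPEC = {
    "shape": (4, 24, 24),
    "spacing": (0.5, 0.5, 1.0),          # (dx, dy, dz) mm
    "tumor_center": (2, 12, 12),
    "tumor_radii_mm": (2.0, 4.0, 4.0),   # (rz, ry, rx): ~134 mm³ ellipsoid
    "model": "triexp",
    "S0": 1000.0,               # proton-density-weighted signal in the tumor
    "S0_background": 400.0,     # darker surrounding tissue gives b=0 contrast
    "tumor": {"f": 8.0, "D_star": 60.0e-3, "f_water": 4.0, "D": 0.6e-3},
    "background": {"f": 3.0, "D_star": 20.0e-3, "f_water": 10.0, "D": 1.2e-3},
}


def make_dwi_phantom(
    truth_spec: dict | None = None,
    b_values=None,
    n_repetitions: int = 4,
    noise_sigma: float = 0.0,
    dropout_spec: Sequence[dict] | dict | None = None,
    shift_spec: Sequence[dict] | dict | None = None,
    seed: int = 0,
) -> tuple[DwiStack, PhantomTruth]:
    """Generate a multi-b-value, multi-repetition DWI phantom.

    The noiseless signal comes from the mono- or triexponential model with
    per-region truth from ``truth_spec``; Rician noise of width
    ``noise_sigma`` is applied per repetition.  ``dropout_spec`` entries
    ``{"b_index", "repetition", "z", "scale"}`` scale whole
    slice-repetitions (scale must be < 1, chosen < 2/3 so the exclusion
    rule must catch them); the form ``{"n": k, "scale": s}`` picks k
    slice-repetitions deterministically from the seed.  ``shift_spec``
    entries translate slice-repetitions by known (dy, dx) voxels.  All
    injections are recorded in the returned :class:`PhantomTruth`.
    """
    spec = dict(_DEFAULT_DWI_SPEC)
    spec.update(truth_spec or {})
    b_values = np.asarray(
        DEFAULT_B_VALUES if b_values is None else b_values, dtype=float)
    rng = np.random.default_rng(seed)
    shape = tuple(spec["shape"])
    spacing = tuple(spec["spacing"])
    tumor = ellipsoid_mask(shape, spec["tumor_center"],
                           spec["tumor_radii_mm"], spacing)
    S0 = float(spec["S0"])

    model = spec["model"]
    if model == "triexp":
        keys = ("f", "D_star", "f_water", "D")
    elif model in ("adc", "mono"):
        keys = ("ADC",)
    else:
        raise GeneratorSpecError(f"unknown signal model {model!r}")
    maps = {}
    for key in keys:
        field = np.full(shape, float(spec["background"][key]))
        field[tumor] = float(spec["tumor"][key])
        maps[key] = field
    s0_map = np.full(shape, float(spec.get("S0_background", S0)))
    s0_map[tumor] = S0
    maps["S0"] = s0_map
    maps["tumor_mask"] = tumor

    nb = b_values.size
    clean = np.empty((nb, *shape))
    for i, b in enumerate(b_values):
        if model == "triexp":
            fp = maps["f"] / 100.0
            fw = maps["f_water"] / 100.0
            clean[i] = s0_map * (
                fp * np.exp(-b * maps["D_star"])
                + fw * np.exp(-b * D_WATER)
                + (1.0 - fp - fw) * np.exp(-b * maps["D"])
            )
        else:
            clean[i] = s0_map * np.exp(-b * maps["ADC"])

    volumes = np.empty((nb, n_repetitions, *shape))
    for r in range(n_repetitions):
        volumes[:, r] = rician(clean, noise_sigma, rng)

    dropouts = _resolve_injection(dropout_spec, nb, n_repetitions, shape[0],
                                  rng, kind="dropout")
    for b_i, r_i, z_i, scale in dropouts:
        if scale >= 1.0:
            raise GeneratorSpecError(
                f"dropout scale must be < 1, got {scale}")
        volumes[b_i, r_i, z_i] *= scale

    shifts = _resolve_injection(shift_spec, nb, n_repetitions, shape[0],
                                rng, kind="shift")
    for b_i, r_i, z_i, shift in shifts:
        from scipy import ndimage
        volumes[b_i, r_i, z_i] = ndimage.shift(
            volumes[b_i, r_i, z_i], shift, order=1, mode="nearest")

    stack = DwiStack(volumes, b_values, spacing)
    truth = PhantomTruth(maps, "rician", float(noise_sigma),
                         dropouts, shifts, seed)
    return stack, truth


def _resolve_injection(spec, nb, nrep, nz, rng, kind):
    """Expand an injection spec into explicit per-slice-repetition entries.

    A deterministic draw from ``rng`` resolves the ``{"n": k, ...}`` form;
    the rng is advanced even for n = 0 so phantom noise is unaffected by
    whether injections were requested explicitly or randomly.
    """
    if spec is None:
        return []
    if isinstance(spec, dict):
        k = int(spec.get("n", 1))
        candidates = [(b, r, z) for b in range(nb) for r in range(nrep)
                      for z in range(nz)]
        idx = rng.choice(len(candidates), size=k, replace=False)
        if kind == "dropout":
            scale = float(spec.get("scale", 0.5))
            return [(*candidates[i], scale) for i in sorted(idx)]
        max_s = float(spec.get("max_shift", 2.0))
        return [
            (*candidates[i],
             tuple(rng.uniform(-max_s, max_s, 2).round(2)))
            for i in sorted(idx)
        ]
    out = []
    for entry in spec:
        key = (int(entry["b_index"]), int(entry["repetition"]),
               int(entry["z"]))
        if kind == "dropout":
            out.append((*key, float(entry["scale"])))
        else:
            out.append((*key, tuple(float(s) for s in entry["shift"])))
    return out


# ---------------------------------------------------------------------------
# DCE phantom
# ---------------------------------------------------------------------------

DEFAULT_AIF_PARAMS = {"a": 50.0, "alpha": 2.0, "tau": 4.0, "t0": 12.0}


def make_aif(params: dict | None = None, times=None,
             model: str = "gamma_variate") -> AifCurve:
    """Gamma-variate bolus ``c_a(t) = a (t - t0)^alpha e^{-(t - t0)/tau}``
    for t > t0, zero before; the analytic peak is at ``t0 + alpha * tau``.
    """
    if model != "gamma_variate":
        raise GeneratorSpecError(f"unknown AIF model {model!r}")
    p = dict(DEFAULT_AIF_PARAMS)
    p.update(params or {})
    a, alpha, tau, t0 = (float(p[k]) for k in ("a", "alpha", "tau", "t0"))
    if alpha <= 0 or tau <= 0:
        raise GeneratorSpecError(
            f"gamma-variate needs alpha, tau > 0; got {alpha}, {tau}")
    times = np.asarray(
        np.arange(0.0, 300.0, 1.5) if times is None else times, dtype=float)
    dt = times - t0
    curve = np.where(dt > 0, a * np.maximum(dt, 0.0) ** alpha
                     * np.exp(-np.maximum(dt, 0.0) / tau), 0.0)
    arrival = int(np.searchsorted(times, t0, side="right"))
    return AifCurve(times, curve, min(arrival, times.size - 1))


_DEFAULT_DCE_SPEC = {
    "shape": (3, 16, 16),
    "spacing": (0.5, 0.5, 1.0),
    "tumor_center": (1, 8, 5),
    "tumor_radii_mm": (1.2, 2.5, 2.0),
    "aorta_center": (1, 8, 13),
    "aorta_radii_mm": (1.2, 1.2, 1.2),
    "baseline_signal": 100.0,          # background tissue
    "tumor_baseline_signal": 130.0,    # pre-contrast anatomy: regions differ
    "aorta_baseline_signal": 170.0,
    # truth in reporting units, inside the ranges such tumors show
    "tumor": {"PF": 60.0, "PV": 13.0, "PS": 10.0, "ve": 20.0, "t0": 0.0},
}


def make_dce_phantom(
    truth_spec: dict | None = None,
    aif_params: dict | None = None,
    times=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[DceSeries, tuple[RoiMask, RoiMask], PhantomTruth]:
    """Generate a dynamic series with an aorta bolus and 2CXM tumor curves.

    The aorta region carries the gamma-variate AIF, the tumor region the
    2CXM response to it; both ride on a constant baseline signal.
    Additive Gaussian noise of SD ``noise_sd`` is applied to every voxel.
    Returns the series, the (tumor, aorta) masks and the truth record.
    """
    spec = dict(_DEFAULT_DCE_SPEC)
    spec.update(truth_spec or {})
    rng = np.random.default_rng(seed)
    times = np.asarray(
        np.arange(0.0, 300.0, 1.5) if times is None else times, dtype=float)
    aif = make_aif(aif_params, times)
    shape = tuple(spec["shape"])
    spacing = tuple(spec["spacing"])
    tumor = ellipsoid_mask(shape, spec["tumor_center"],
                           spec["tumor_radii_mm"], spacing)
    aorta = ellipsoid_mask(shape, spec["aorta_center"],
                           spec["aorta_radii_mm"], spacing)
    if (tumor & aorta).any():
        raise GeneratorSpecError("tumor and aorta regions overlap")

    tp = spec["tumor"]
    tissue = twocxm_forward(
        aif, (tp["PF"], tp["PV"], tp["PS"], tp["ve"], tp["t0"]), times)
    base = np.full(shape, float(spec["baseline_signal"]))
    base[tumor] = float(spec["tumor_baseline_signal"])
    base[aorta] = float(spec["aorta_baseline_signal"])
    frames = np.broadcast_to(base, (times.size, *shape)).copy()
    frames[:, aorta] += aif.enhancement[:, None]
    frames[:, tumor] += tissue[:, None]
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)

    maps = {k: np.where(tumor, v, np.nan) for k, v in tp.items()}
    maps["tumor_mask"] = tumor
    maps["aorta_mask"] = aorta
    maps["aif_enhancement"] = aif.enhancement
    truth = PhantomTruth(maps, "gaussian", float(noise_sd), [], [], seed)
    series = DceSeries(frames, times, spacing)
    return series, (RoiMask(tumor, "tumor", spacing),
                    RoiMask(aorta, "aorta", spacing)), truth


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

PARAMETER_UNITS = {
    "volume": "mm^3",
    "ADC": "mm^2/s",
    "D": "mm^2/s",
    "D_star": "mm^2/s",
    "f": "%",
    "PF": "mL/100 mL/min",
    "PV": "mL/100 mL",
}

#: Per-parameter (group, timepoint) -> (mean, SD), with physical truncation
#: ranges.  These defaults are the study conditions the generator emulates:
#: subject-level group summaries of a treated and an untreated arm of a
#: fast-growing flank tumor model at two timepoints five days apart.
DEFAULT_COHORT_DISTRIBUTIONS = {
    "volume": {
        ("control", "baseline"): (160.0, 117.0),
        ("therapy", "baseline"): (121.0, 84.0),
        ("control", "follow_up"): (1009.0, 715.0),
        ("therapy", "follow_up"): (781.0, 447.0),
        "range": (1.0, np.inf),
    },
    "ADC": {
        ("control", "baseline"): (0.759e-3, 0.069e-3),
        ("therapy", "baseline"): (0.786e-3, 0.077e-3),
        ("control", "follow_up"): (0.833e-3, 0.054e-3),
        ("therapy", "follow_up"): (0.754e-3, 0.051e-3),
        "range": (0.1e-3, 3.0e-3),
    },
    "D": {
        ("control", "baseline"): (0.588e-3, 0.060e-3),
        ("therapy", "baseline"): (0.613e-3, 0.080e-3),
        ("control", "follow_up"): (0.633e-3, 0.084e-3),
        ("therapy", "follow_up"): (0.592e-3, 0.067e-3),
        "range": (0.1e-3, 2.0e-3),
    },
    "D_star": {
        ("control", "baseline"): (52.3e-3, 22.7e-3),
        ("therapy", "baseline"): (67.4e-3, 26.7e-3),
        ("control", "follow_up"): (61.0e-3, 20.2e-3),
        ("therapy", "follow_up"): (70.9e-3, 18.6e-3),
        "range": (5.0e-3, 0.5),
    },
    "f": {
        ("control", "baseline"): (5.81, 2.77),
        ("therapy", "baseline"): (4.86, 2.14),
        ("control", "follow_up"): (4.82, 2.07),
        ("therapy", "follow_up"): (5.17, 1.20),
        "range": (0.0, 100.0),
    },
    "PF": {
        ("control", "baseline"): (97.4, 167.9),
        ("therapy", "baseline"): (54.5, 35.6),
        ("control", "follow_up"): (46.9, 28.0),
        ("therapy", "follow_up"): (63.6, 52.2),
        "range": (0.5, 1000.0),
    },
    "PV": {
        ("control", "baseline"): (12.6, 5.8),
        ("therapy", "baseline"): (12.9, 3.4),
        ("control", "follow_up"): (12.4, 5.6),
        ("therapy", "follow_up"): (13.6, 3.7),
        "range": (0.0, 100.0),
    },
}


@dataclasses.dataclass
class CohortDesign:
    """Design of a synthetic two-arm, two-timepoint cohort.

    ``distributions`` maps parameter -> {(group, timepoint): (mean, SD),
    "range": (lo, hi)}.  ``baseline_missing_prob`` is the chance a subject
    has no baseline measurement (tumor too small to assess);
    ``timepoint_correlation`` is the assumed within-subject correlation
    between baseline and follow-up values (unreported in vivo; 0.5 by
    assumption).
    """

    n_therapy: int = 14
    n_control: int = 14
    distributions: dict = dataclasses.field(
        default_factory=lambda: DEFAULT_COHORT_DISTRIBUTIONS)
    baseline_missing_prob: float = 0.35
    timepoint_correlation: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_therapy < 1 or self.n_control < 1:
            raise GeneratorSpecError("need at least one subject per group")
        if not 0 <= self.baseline_missing_prob < 1:
            raise GeneratorSpecError("baseline_missing_prob must be in [0, 1)")
        if not -1 < self.timepoint_correlation < 1:
            raise GeneratorSpecError("timepoint correlation must be in (-1, 1)")
        for param, dist in self.distributions.items():
            lo, hi = dist.get("range", (-np.inf, np.inf))
            for key, val in dist.items():
                if key == "range":
                    continue
                mean, sd = val
                if sd < 0:
                    raise GeneratorSpecError(
                        f"negative SD for {param} {key}")
                if not lo <= mean <= hi:
                    raise GeneratorSpecError(
                        f"mean of {param} {key} outside its range")


def _truncated_bivariate(rng, means, sds, corr, lo, hi, max_tries=1000):
    """One correlated (baseline, follow-up) pair inside [lo, hi]."""
    cov = np.array([[1.0, corr], [corr, 1.0]])
    chol = np.linalg.cholesky(cov)
    for _ in range(max_tries):
        z = chol @ rng.standard_normal(2)
        vals = np.asarray(means) + np.asarray(sds) * z
        if np.all((vals >= lo) & (vals <= hi)):
            return vals
    raise GeneratorSpecError(
        f"truncation to [{lo}, {hi}] infeasible for means {means}, SDs {sds}")


def make_cohort(design: CohortDesign | None = None) -> tuple[CohortTable, dict]:
    """Draw a synthetic cohort table plus its subject-level truth.

    Values come from truncated normals with the design's per-cell means
    and SDs, correlated within subject across timepoints.  Baseline
    missingness is applied per subject and parameter family (imaging
    parameters share the subject's missingness; volume is always
    observed).  Returns the table and a truth dict with the realized
    missingness pattern.
    """
    design = design or CohortDesign()
    rng = np.random.default_rng(design.seed)
    records = []
    missing_baseline: dict[str, bool] = {}
    groups = [("therapy", design.n_therapy), ("control", design.n_control)]
    for group, n in groups:
        for i in range(1, n + 1):
            sid = f"{group}_{i:02d}"
            missing_baseline[sid] = bool(
                rng.random() < design.baseline_missing_prob)
            for param, dist in design.distributions.items():
                lo, hi = dist.get("range", (-np.inf, np.inf))
                mb, sb = dist[(group, "baseline")]
                mf, sf = dist[(group, "follow_up")]
                vals = _truncated_bivariate(
                    rng, (mb, mf), (sb, sf),
                    design.timepoint_correlation, lo, hi)
                for tp, val in zip(("baseline", "follow_up"), vals):
                    hidden = (tp == "baseline" and missing_baseline[sid]
                              and param != "volume")
                    records.append({
                        "subject_id": sid,
                        "group": group,
                        "timepoint": tp,
                        "parameter": param,
                        "value": np.nan if hidden else float(val),
                        "units": PARAMETER_UNITS.get(param, ""),
                    })
    table = CohortTable.from_records(records)
    truth = {"missing_baseline": missing_baseline, "seed": design.seed}
    return table, truth
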