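"""Dynamic contrast-enhanced MRI: enhancement conversion, arterial input
function extraction and two-compartment exchange model (2CXM) fitting.

Contrast-agent concentration is approximated by the absolute signal
enhancement ``S(t) - S0`` (no T1 mapping, relaxivity conversion or
hematocrit correction), so plasma flow and plasma volume are calibrated
only up to the common scaling of tissue and arterial enhancement.

The 2CXM describes tracer exchange between a plasma compartment (fraction
``v_p``, fed by plasma flow ``F_p`` from the arterial input ``c_a``) and an
interstitial compartment (fraction ``v_e``) across a permeability-surface
product ``PS``::

    v_p dc_p/dt = F_p (c_a(t - t0) - c_p) + PS (c_e - c_p)
    v_e dc_e/dt = PS (c_p - c_e)
    C_t        = v_p c_p + v_e c_e

Internally flows are s⁻¹ and volumes are fractions; the API reports the
conventional units PF in mL/100 mL/min, PV and ve in mL/100 mL, PS in
mL/100 mL/min.

The tissue curve is computed by two independent routes that must agree to
1e-6 relative: a closed-form biexponential residue-function convolution
(eigen-decomposition of the 2x2 compartment matrix, exact convolution
against the piecewise-linear AIF) and direct stiff ODE integration.  The
analytic route is the production path; the ODE route is the oracle.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .exceptions import FitError, InputError, NoBolusError, ParameterError
from .io import DceSeries, RoiMask

__all__ = [
    "AifCurve",
    "signal_enhancement",
    "extract_aif",
    "twocxm_forward",
    "TwoCompartmentExchangeModel",
    "TwoCxmResults",
    "fit_2cxm",
    "dce_map_fit",
]

#: Reporting-unit conversions: PF [mL/100 mL/min] -> F_p [1/s], etc.
PER_MIN_PER_100ML_TO_PER_S = 1.0 / (100.0 * 60.0)

T0_BOUNDS = (0.0, 10.0)  # bolus delay, s


@dataclasses.dataclass
class AifCurve:
    """Arterial input: ROI-mean enhancement over time with bolus arrival."""

    times: np.ndarray
    enhancement: np.ndarray
    bolus_arrival_index: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.enhancement = np.asarray(self.enhancement, dtype=float)
        if self.times.shape != self.enhancement.shape or self.times.ndim != 1:
            raise InputError("AIF times and enhancement must match in length")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("AIF times must be strictly increasing")

    def __call__(self, t) -> np.ndarray:
        """Linear interpolation; zero before the first sample."""
        return np.interp(np.asarray(t, float), self.times, self.enhancement,
                         left=0.0)


def signal_enhancement(series: DceSeries, n_baseline: int) -> DceSeries:
    """Per-voxel absolute enhancement ``S(t) - S0``.

    ``S0`` is the voxel mean over the first ``n_baseline`` (pre-bolus)
    frames.  Enhancement may be negative where noise fluctuates below
    baseline.
    """
    if not 1 <= n_baseline < series.n_frames:
        raise ParameterError(
            f"n_baseline must be in [1, {series.n_frames - 1}], got {n_baseline}"
        )
    s0 = series.frames[:n_baseline].mean(axis=0)
    return DceSeries(series.frames - s0[None], series.times, series.spacing)


def extract_aif(
    series: DceSeries, aorta_mask: RoiMask, n_baseline: int, k: float = 5.0
) -> AifCurve:
    """ROI-mean enhancement curve from the aorta with bolus-arrival detection.

    Arrival is the first frame whose ROI-mean enhancement exceeds the
    baseline mean by ``k`` baseline standard deviations (default 5),
    sustained for two consecutive frames so an isolated noise spike
    cannot masquerade as the bolus.  A
    noiseless baseline (SD = 0) falls back to any strictly positive
    excursion.  Raises :class:`NoBolusError` when nothing exceeds the
    threshold.
    """
    if aorta_mask.mask.shape != series.frames.shape[1:]:
        raise InputError("aorta mask shape does not match the series")
    enh = signal_enhancement(series, n_baseline)
    curve = enh.frames[:, aorta_mask.mask].mean(axis=1)
    base = curve[:n_baseline]
    thr = base.mean() + k * base.std(ddof=0)
    if base.std(ddof=0) == 0:
        thr = base.mean() + max(1e-12, 1e-9 * np.abs(curve).max())
    over = curve > thr
    over[:n_baseline] = False
    # spike guard: arrival must be sustained for two consecutive frames
    sustained = over & np.r_[over[1:], True]
    above = np.nonzero(sustained)[0]
    if above.size == 0:
        raise NoBolusError(
            f"no frame exceeds baseline mean + {k} SD; is there a bolus?"
        )
    return AifCurve(series.times, curve, int(above[0]))


# ---------------------------------------------------------------------------
# 2CXM forward model
# ---------------------------------------------------------------------------

def _internal_rates(PF, PV, PS, ve):
    """Reporting units -> (F_p [1/s], v_p, P_S [1/s], v_e) fractions."""
    return (
        PF * PER_MIN_PER_100ML_TO_PER_S,
        PV / 100.0,
        PS * PER_MIN_PER_100ML_TO_PER_S,
        ve / 100.0,
    )


def _check_params(PF, PV, PS, ve, t0):
    if PF <= 0:
        raise ParameterError(f"plasma flow must be positive, got {PF}")
    if not 0 <= PV <= 100:
        raise ParameterError(f"PV must be in [0, 100] mL/100 mL, got {PV}")
    if PS < 0:
        raise ParameterError(f"PS must be non-negative, got {PS}")
    if not 0 <= ve <= 100 - PV + 1e-9:
        raise ParameterError(
            f"ve must be in [0, 100 - PV]; got ve={ve}, PV={PV}"
        )
    if not T0_BOUNDS[0] <= t0 <= T0_BOUNDS[1]:
        raise ParameterError(f"t0 must be in {T0_BOUNDS} s, got {t0}")


def _impulse_terms(Fp, vp, ps, ve):
    """Exponential terms (amplitude, rate) of the impulse response
    ``h(t) = sum_i A_i exp(lambda_i t)`` with ``C_t = (h * c_a)``.

    Derived from the eigen-decomposition of the 2x2 compartment matrix.
    Degenerate geometries reduce to the one-compartment limit.
    """
    if vp <= 0:
        if ps > 0 or Fp > 0:
            raise ParameterError(
                "plasma volume of zero with nonzero flow is degenerate; "
                "use a reduced model"
            )
        return [(0.0, 0.0)]
    if ve <= 0 or ps == 0:
        if ve <= 0 and ps > 0:
            raise ParameterError(
                "interstitial volume of zero with nonzero PS is degenerate; "
                "use a reduced model"
            )
        # one-compartment plasma limit: h(t) = Fp exp(-Fp t / vp)
        return [(Fp, -Fp / vp)]
    M = np.array([[-(Fp + ps) / vp, ps / vp],
                  [ps / ve, -ps / ve]])
    lam, V = np.linalg.eig(M)
    coeff = np.linalg.solve(V, np.array([Fp / vp, 0.0]))
    w = np.array([vp, ve])
    amps = (w @ V) * coeff
    return [(float(np.real(a)), float(np.real(l))) for a, l in zip(amps, lam)]


def _exp_convolve(times: np.ndarray, g: np.ndarray, lam: float) -> np.ndarray:
    """Exact ``y(t) = ∫_0^t e^{lam (t - tau)} g(tau) dtau`` for piecewise-
    linear ``g`` sampled at ``times``."""
    y = np.zeros_like(g)
    dt = np.diff(times)
    x = lam * dt
    e = np.exp(x)
    small = np.abs(x) < 1e-8
    with np.errstate(divide="ignore", invalid="ignore"):
        I0 = np.where(small, dt * (1 + x / 2 + x * x / 6), (e - 1.0) / lam)
        I1 = np.where(small, dt * dt * (0.5 + x / 3 + x * x / 8),
                      (e - 1.0 - x) / (lam * lam))
    for k in range(dt.size):
        g0, g1 = g[k], g[k + 1]
        slope = (g1 - g0) / dt[k]
        y[k + 1] = y[k] * e[k] + g0 * I0[k] + slope * I1[k]
    return y


def twocxm_forward(
    aif: AifCurve,
    params: dict | tuple,
    times,
    method: str = "conv",
) -> np.ndarray:
    """Tissue enhancement curve from the 2CXM.

    ``params`` is ``(PF, PV, PS, ve, t0)`` in reporting units or a dict
    with those keys.  The delayed AIF ``c_a(t - t0)`` is resampled onto the
    output grid by linear interpolation; both implementations then see the
    same piecewise-linear input, so they agree to solver precision.

    ``method='conv'`` (default) uses the closed-form biexponential
    residue-function convolution; ``method='ode'`` integrates the
    mass-balance system directly (Radau, tight tolerances) and exists as
    an independent cross-check.
    """
    if isinstance(params, dict):
        PF, PV, PS, ve, t0 = (params[k] for k in ("PF", "PV", "PS", "ve", "t0"))
    else:
        PF, PV, PS, ve, t0 = params
    _check_params(PF, PV, PS, ve, t0)
    times = np.asarray(times, dtype=float)
    ca = aif(times - t0)
    Fp, vp, ps, vef = _internal_rates(PF, PV, PS, ve)

    if method == "conv":
        terms = _impulse_terms(Fp, vp, ps, vef)
        out = np.zeros_like(times)
        for amp, lam in terms:
            if amp == 0.0:
                continue
            out += amp * _exp_convolve(times, ca, lam)
        return out
    if method == "ode":
        return _twocxm_ode(times, ca, Fp, vp, ps, vef)
    raise ParameterError(f"method must be 'conv' or 'ode', got {method!r}")


def _twocxm_ode(times, ca_samples, Fp, vp, ps, vef) -> np.ndarray:
    """Stiff-safe direct integration of the compartment ODEs."""
    if vp <= 0:
        if ps > 0 or Fp > 0:
            raise ParameterError("degenerate: vp = 0 with nonzero flow")
        return np.zeros_like(times)
    if vef <= 0 and ps > 0:
        raise ParameterError("degenerate: ve = 0 with nonzero PS")

    def ca_t(t):
        return np.interp(t, times, ca_samples)

    two_compartment = vef > 0

    def rhs(t, x):
        cp = x[0]
        dcp = (Fp * (ca_t(t) - cp)) / vp
        if two_compartment:
            ce = x[1]
            dcp += ps * (ce - cp) / vp
            dce = ps * (cp - ce) / vef
            return [dcp, dce]
        return [dcp]

    x0 = [0.0, 0.0] if two_compartment else [0.0]
    scale = max(np.abs(ca_samples).max(), 1.0)
    sol = solve_ivp(
        rhs, (times[0], times[-1]), x0, method="Radau", t_eval=times,
        rtol=1e-10, atol=1e-12 * scale,
        max_step=float(np.diff(times).min()),
    )
    if not sol.success:
        raise FitError(f"ODE integration failed: {sol.message}")
    cp = sol.y[0]
    ct = vp * cp
    if two_compartment:
        ct = ct + vef * sol.y[1]
    return ct


# ---------------------------------------------------------------------------
# 2CXM fitting
# ---------------------------------------------------------------------------

class TwoCxmResults:
    """2CXM fit results: ``(PF, PV, PS, ve, t0)`` with reporting units.

    PF and PV are the quantities of interest; PS, ve and the bolus delay
    t0 are internal nuisance parameters of the exchange model.
    """

    param_names = ("PF", "PV", "PS", "ve", "t0")
    param_units = ("mL/100 mL/min", "mL/100 mL", "mL/100 mL/min",
                   "mL/100 mL", "s")

    def __init__(self, params, cov, rss, nobs, converged, model):
        self.params = np.asarray(params, dtype=float)
        self.cov_params = cov
        self.rss = float(rss)
        self.nobs = int(nobs)
        self.converged = bool(converged)
        self.model = model

    PF = property(lambda self: float(self.params[0]))
    PV = property(lambda self: float(self.params[1]))
    PS = property(lambda self: float(self.params[2]))
    ve = property(lambda self: float(self.params[3]))
    t0 = property(lambda self: float(self.params[4]))

    @property
    def bse(self):
        d = np.diag(self.cov_params)
        return np.sqrt(np.where(d >= 0, d, np.nan))

    def predict(self, times=None) -> np.ndarray:
        times = self.model.times if times is None else np.asarray(times, float)
        return twocxm_forward(self.model.aif, tuple(self.params), times)

    @property
    def resid(self) -> np.ndarray:
        return self.model.curve - self.predict()

    def summary(self) -> str:
        lines = [
            "TwoCxmResults",
            "=" * 62,
            f"{'parameter':<10}{'estimate':>12}{'std err':>12}{'units':>24}",
            "-" * 62,
        ]
        for name, val, se, unit in zip(self.param_names, self.params,
                                       self.bse, self.param_units):
            lines.append(f"{name:<10}{val:>12.5g}{se:>12.3g}{unit:>24}")
        lines += [
            "-" * 62,
            f"n obs: {self.nobs}    rss: {self.rss:.6g}    "
            f"converged: {self.converged}",
        ]
        return "\n".join(lines)


class TwoCompartmentExchangeModel:
    """2CXM fitted to one tissue enhancement curve against a measured AIF.

    Constrained nonlinear least squares over ``(PF, PV, PS, ve, t0)`` from
    a deterministic multistart grid (12 starts); the start with the lowest
    residual sum of squares wins.  The constraint ``ve <= 100 - PV`` is a
    penalty residual; everything else is a box bound.
    """

    #: Deterministic multistart grid in reporting units (PF, PV, PS, ve, t0).
    START_GRID = [
        (PF0, PV0, PS0, 20.0, 0.5)
        for PF0 in (20.0, 60.0, 150.0)
        for PV0 in (5.0, 15.0)
        for PS0 in (5.0, 20.0)
    ]

    BOUNDS_LO = (1e-3, 0.0, 0.0, 0.0, T0_BOUNDS[0])
    BOUNDS_HI = (1000.0, 100.0, 500.0, 100.0, T0_BOUNDS[1])

    def __init__(self, curve, times, aif: AifCurve):
        self.curve = np.asarray(curve, dtype=float)
        self.times = np.asarray(times, dtype=float)
        if self.curve.shape != self.times.shape:
            raise InputError("curve and times must match in length")
        if self.times.size < 30:
            raise InputError("2CXM fitting needs at least 30 frames")
        self.aif = aif
        self._scale = float(max(np.abs(self.curve).max(),
                                np.abs(aif.enhancement).max(), 1e-12))

    @classmethod
    def from_series(cls, series: DceSeries, tumor_mask: RoiMask,
                    aif: AifCurve, n_baseline: int
                    ) -> "TwoCompartmentExchangeModel":
        """ROI-mean tissue curve from a raw dynamic series."""
        enh = signal_enhancement(series, n_baseline)
        curve = enh.frames[:, tumor_mask.mask].mean(axis=1)
        return cls(curve, series.times, aif)

    def _residuals(self, x):
        PF, PV, PS, ve, t0 = x
        model = twocxm_forward(self.aif, (PF, PV, min(PS, 500.0),
                                          min(ve, 100.0 - PV), t0), self.times)
        data = model - self.curve
        budget = max(0.0, PV + ve - 100.0) / 100.0
        return np.concatenate([data, [1e3 * self._scale * budget]])

    def fit(self) -> TwoCxmResults:
        if not np.any(np.abs(self.curve) > 0):
            raise FitError("tissue curve is identically zero; nothing to fit")
        best = None
        for x0 in self.START_GRID:
            try:
                res = least_squares(
                    self._residuals, np.asarray(x0, float),
                    bounds=(self.BOUNDS_LO, self.BOUNDS_HI), method="trf",
                    x_scale=[50.0, 10.0, 10.0, 20.0, 1.0],
                    xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=300,
                )
            except (ParameterError, FitError):
                continue
            rss = float(np.sum(res.fun[: self.times.size] ** 2))
            if best is None or rss < best[1]:
                best = (res, rss)
        if best is None:
            raise FitError("no multistart point converged")
        res, rss = best
        jac = res.jac[: self.times.size]
        dof = max(self.times.size - 5, 1)
        s2 = rss / dof
        jtj = jac.T @ jac
        try:
            cov = s2 * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov = s2 * np.linalg.pinv(jtj)
        return TwoCxmResults(res.x, cov, rss, self.times.size,
                             res.status > 0, self)


def fit_2cxm(tissue_curve, aif: AifCurve, config: dict | None = None
             ) -> TwoCxmResults:
    """Fit the 2CXM to one tissue enhancement curve (functional wrapper)."""
    times = (config or {}).get("times", aif.times)
    return TwoCompartmentExchangeModel(tissue_curve, times, aif).fit()


def dce_map_fit(
    series: DceSeries,
    tumor_mask: RoiMask,
    aif: AifCurve,
    n_baseline: int = 5,
):
    """Voxel-wise 2CXM fitting inside the tumor ROI.

    Returns a :class:`mpmri.dwi.MapFitResult` with PF and PV maps (plus
    PS, ve, t0) and their ROI means over successfully fitted voxels.
    """
    from .dwi import MapFitResult, ParameterMap  # local import, no cycle

    if tumor_mask.mask.shape != series.frames.shape[1:]:
        raise InputError("tumor mask shape does not match the series")
    enh = signal_enhancement(series, n_baseline)
    names = TwoCxmResults.param_names
    units = TwoCxmResults.param_units
    shape = tumor_mask.mask.shape
    maps = {
        n: ParameterMap(np.full(shape, np.nan), n, u, series.spacing)
        for n, u in zip(names, units)
    }
    coords = np.argwhere(tumor_mask.mask)
    n_failed = 0
    for z, y, x in coords:
        curve = enh.frames[:, z, y, x]
        try:
            fit = TwoCompartmentExchangeModel(curve, series.times, aif).fit()
        except (FitError, InputError):
            n_failed += 1
            continue
        for n, v in zip(names, fit.params):
            maps[n].data[z, y, x] = v
    roi_means = {n: maps[n].roi_mean(tumor_mask.mask) for n in names}
    return MapFitResult(maps, roi_means, int(coords.shape[0]), n_failed)
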