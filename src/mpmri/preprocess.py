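"""DWI/DCE preprocessing: smoothing, motion correction, dropout exclusion.

The preprocessing chain for diffusion data is, in order: in-plane rigid
motion correction, signal-dropout detection and exclusion, averaging of the
surviving repetitions, and volumetric Gaussian smoothing.  Smoothing is
applied last so that it never blurs misaligned repetitions together.
Dynamic contrast-enhanced data are motion corrected in 3-D against a
pre-bolus baseline and smoothed the same way.

The signal-dropout rule drops an individual slice-repetition when its mean
foreground intensity falls below a fixed fraction (default 2/3 ≈ 67%) of
the mean foreground intensity of the brightest half of all repetitions of
the same slice and b-value.  "Foreground" is defined once per (slice,
b-value) as the voxels above the Otsu threshold of the median image across
repetitions, so that the same mask scores every repetition — a mask
computed per repetition would itself be corrupted by the dropout being
tested.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .exceptions import ParameterError
from .io import DceSeries, DwiStack, VoxelGrid3D

__all__ = [
    "FWHM_TO_SIGMA",
    "gaussian_smooth",
    "foreground_mask",
    "detect_signal_dropout",
    "DropoutReport",
    "inplane_motion_correct",
    "volume_motion_correct",
    "average_repetitions",
]

#: FWHM = sigma * 2*sqrt(2*ln 2); radiological filter widths are FWHM.
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

DEFAULT_DROPOUT_FRACTION = 2.0 / 3.0


def gaussian_smooth(grid: VoxelGrid3D, width_mm: float) -> VoxelGrid3D:
    """Volumetric Gaussian smoothing with FWHM ``width_mm`` in physical units.

    The kernel width is specified as full width at half maximum in mm and
    converted per axis to a sigma in voxels using the grid spacing, so the
    smoothing is isotropic in physical space even on anisotropic grids.
    The kernel is truncated at 3 sigma with reflective boundaries; the
    total image sum is preserved (to within truncation error) for
    interior-supported images.  NaN voxels are handled by normalised
    convolution: they do not contaminate their neighbourhood and remain NaN.
    """
    if width_mm <= 0:
        raise ParameterError(f"smoothing width must be positive, got {width_mm}")
    dx, dy, dz = grid.spacing
    sigma_vox = (
        width_mm * FWHM_TO_SIGMA / dz,  # array axis 0 = z
        width_mm * FWHM_TO_SIGMA / dy,
        width_mm * FWHM_TO_SIGMA / dx,
    )
    data = grid.data
    nan_mask = np.isnan(data)
    if nan_mask.any():
        filled = np.where(nan_mask, 0.0, data)
        weight = (~nan_mask).astype(float)
        num = ndimage.gaussian_filter(filled, sigma_vox, mode="reflect", truncate=3.0)
        den = ndimage.gaussian_filter(weight, sigma_vox, mode="reflect", truncate=3.0)
        with np.errstate(invalid="ignore"):
            out = num / den
        out[nan_mask] = np.nan
    else:
        out = ndimage.gaussian_filter(data, sigma_vox, mode="reflect", truncate=3.0)
    return VoxelGrid3D(out, grid.spacing, grid.origin)


def foreground_mask(slices: np.ndarray) -> np.ndarray:
    """Foreground of a (repetition, y, x) slice group via Otsu thresholding.

    The threshold is computed on the voxel-wise median across repetitions.
    Returns a boolean (y, x) mask; all-False when the slice is constant
    (Otsu undefined) or nothing exceeds the threshold.
    """
    median_img = np.median(slices, axis=0)
    finite = median_img[np.isfinite(median_img)]
    if finite.size == 0 or np.ptp(finite) == 0:
        return np.zeros(median_img.shape, dtype=bool)
    thr = threshold_otsu(finite)
    return median_img > thr


class DropoutReport:
    """Per (b_index, repetition, slice) record of the dropout decision.

    ``entries`` is a DataFrame with columns ``b_index, repetition, z,
    mean_foreground_signal, threshold, excluded``; ``excluded`` is exactly
    ``mean_foreground_signal < threshold``.
    """

    def __init__(self, entries: pd.DataFrame):
        self.entries = entries.reset_index(drop=True)

    def excluded_set(self) -> set[tuple[int, int, int]]:
        sel = self.entries[self.entries["excluded"]]
        return {
            (int(r.b_index), int(r.repetition), int(r.z))
            for r in sel.itertuples(index=False)
        }

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def detect_signal_dropout(
    stack: DwiStack, fraction: float = DEFAULT_DROPOUT_FRACTION
) -> DropoutReport:
    """Flag slice-repetitions whose foreground signal dropped out.

    For each (slice z, b-value): a single foreground mask is computed from
    the across-repetition median image; ``m_r`` is the mean foreground
    intensity of repetition r; ``B`` is the mean of the brightest
    ``ceil(R/2)`` of the ``m_r``; repetition r is excluded iff
    ``m_r < fraction * B``.  The flags are written into ``stack.excluded``
    in place and returned as a :class:`DropoutReport`.

    A slice with an empty foreground mask is flagged all-excluded with a
    warning rather than raising.
    """
    if stack.n_repetitions < 2:
        raise ParameterError("dropout detection needs at least 2 repetitions")
    if not 0 <= fraction:
        raise ParameterError(f"dropout fraction must be >= 0, got {fraction}")
    R = stack.n_repetitions
    n_top = math.ceil(R / 2)
    rows = []
    for b in range(stack.n_b):
        for z in range(stack.n_slices):
            group = stack.volumes[b, :, z]  # (R, y, x)
            fg = foreground_mask(group)
            if not fg.any():
                warnings.warn(
                    f"empty foreground for slice z={z}, b-index {b}; "
                    "flagging all repetitions excluded"
                )
                for r in range(R):
                    rows.append((b, r, z, np.nan, np.nan, True))
                    stack.excluded[b, r, z] = True
                continue
            m = group[:, fg].mean(axis=1)
            bright = np.sort(m)[::-1][:n_top]
            threshold = fraction * bright.mean()
            for r in range(R):
                excl = bool(m[r] < threshold)
                rows.append((b, r, z, float(m[r]), float(threshold), excl))
                stack.excluded[b, r, z] = excl
    entries = pd.DataFrame(
        rows,
        columns=["b_index", "repetition", "z", "mean_foreground_signal",
                 "threshold", "excluded"],
    )
    return DropoutReport(entries)


# ---------------------------------------------------------------------------
# Rigid translation registration (normalized cross-correlation, subpixel)
# ---------------------------------------------------------------------------

def _overlap_slices(shape, offset):
    """Index slices of moving/reference for candidate displacement ``offset``.

    ``moving(n)`` is compared against ``reference(n - offset)`` on the
    region where both are valid.
    """
    mov, ref = [], []
    for n, d in zip(shape, offset):
        lo, hi = max(0, d), n + min(0, d)
        if hi - lo < 2:
            return None
        mov.append(slice(lo, hi))
        ref.append(slice(lo - d, hi - d))
    return tuple(mov), tuple(ref)


def _ncc_surface(moving: np.ndarray, reference: np.ndarray, max_shift: int) -> np.ndarray:
    """True normalized cross-correlation on a ±``max_shift`` window.

    For each integer displacement the Pearson correlation is computed on
    the actual overlap region (no circular wrap-around), so a pure
    translation of identical content scores exactly 1 at the true offset.
    """
    ndim = moving.ndim
    window = range(-max_shift, max_shift + 1)
    cc = np.full((2 * max_shift + 1,) * ndim, -np.inf)
    for idx in np.ndindex(*cc.shape):
        offset = tuple(i - max_shift for i in idx)
        sl = _overlap_slices(moving.shape, offset)
        if sl is None:
            continue
        a = moving[sl[0]].ravel()
        b = reference[sl[1]].ravel()
        a = a - a.mean()
        b = b - b.mean()
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        cc[idx] = (a @ b) / (na * nb) if na > 0 and nb > 0 else 0.0
    return cc


def _quadratic_peak_offset(c_m, c_0, c_p) -> float:
    """Subpixel offset of a 1-D quadratic through three points around a peak."""
    denom = c_m - 2.0 * c_0 + c_p
    if denom >= 0 or not np.isfinite(denom):
        return 0.0
    off = 0.5 * (c_m - c_p) / denom
    return float(np.clip(off, -0.5, 0.5))


def estimate_shift(
    moving: np.ndarray, reference: np.ndarray, max_shift: int = 5
) -> np.ndarray:
    """Estimate the rigid translation taking ``moving`` onto ``reference``.

    Integer search over a ±``max_shift`` voxel window on the normalized
    cross-correlation surface, refined per axis by quadratic interpolation
    of the peak.  Returns the displacement of ``moving`` relative to
    ``reference`` (so applying ``-shift`` aligns it).  Constant images give
    a zero shift with a warning.
    """
    if np.ptp(moving) == 0 or np.ptp(reference) == 0:
        warnings.warn("constant image in registration; assuming zero shift")
        return np.zeros(moving.ndim)
    cc = _ncc_surface(moving, reference, max_shift)
    peak = np.unravel_index(np.argmax(cc), cc.shape)
    shift = np.array(peak, dtype=float) - max_shift
    for ax, p in enumerate(peak):
        if 0 < p < cc.shape[ax] - 1:
            idx_m = list(peak); idx_m[ax] = p - 1
            idx_p = list(peak); idx_p[ax] = p + 1
            shift[ax] += _quadratic_peak_offset(
                cc[tuple(idx_m)], cc[peak], cc[tuple(idx_p)]
            )
    return shift


def apply_shift(image: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Translate an image by a (possibly subpixel) shift, spline order 1."""
    if np.allclose(shift, 0):
        return image.copy()
    return ndimage.shift(image, shift, order=1, mode="nearest")


def inplane_motion_correct(
    stack: DwiStack, max_shift: int = 5
) -> tuple[DwiStack, pd.DataFrame]:
    """Rigidly align each 2-D slice-repetition onto its reference repetition.

    For every (slice, b-value) the reference is the repetition with the
    highest mean foreground signal; every other repetition is translated
    onto it.  Returns the corrected stack and a log of applied shifts
    (columns ``b_index, repetition, z, shift_y, shift_x``).
    """
    out = stack.copy()
    rows = []
    for b in range(stack.n_b):
        for z in range(stack.n_slices):
            group = stack.volumes[b, :, z]
            fg = foreground_mask(group)
            means = group[:, fg].mean(axis=1) if fg.any() else group.mean(axis=(1, 2))
            ref_idx = int(np.argmax(means))
            ref = group[ref_idx]
            for r in range(stack.n_repetitions):
                if r == ref_idx:
                    rows.append((b, r, z, 0.0, 0.0))
                    continue
                shift = estimate_shift(group[r], ref, max_shift)
                out.volumes[b, r, z] = apply_shift(group[r], -shift)
                rows.append((b, r, z, float(shift[0]), float(shift[1])))
    log = pd.DataFrame(rows, columns=["b_index", "repetition", "z",
                                      "shift_y", "shift_x"])
    return out, log


def volume_motion_correct(
    series: DceSeries, n_baseline: int, max_shift: int = 5
) -> tuple[DceSeries, pd.DataFrame]:
    """Rigidly align each 3-D frame onto the mean of the baseline frames.

    ``n_baseline`` frames (all pre-bolus) are averaged into the reference.
    Returns the corrected series and the per-frame shift log.
    """
    if not 1 <= n_baseline < series.n_frames:
        raise ParameterError(
            f"n_baseline must be in [1, {series.n_frames - 1}], got {n_baseline}"
        )
    ref = series.frames[:n_baseline].mean(axis=0)
    out = series.copy()
    rows = []
    for t in range(series.n_frames):
        shift = estimate_shift(series.frames[t], ref, max_shift)
        out.frames[t] = apply_shift(series.frames[t], -shift)
        rows.append((t, float(shift[0]), float(shift[1]), float(shift[2])))
    log = pd.DataFrame(rows, columns=["frame", "shift_z", "shift_y", "shift_x"])
    return out, log


def average_repetitions(
    stack: DwiStack,
) -> tuple[list[VoxelGrid3D], np.ndarray]:
    """Average non-excluded repetitions per b-value.

    Returns one :class:`VoxelGrid3D` per b-value (voxel-wise mean over the
    repetitions not flagged in ``stack.excluded``) and a count map of shape
    ``(n_b, n_slices)`` giving the number of repetitions averaged per
    slice.  Slices where every repetition was excluded become NaN with a
    warning.
    """
    grids = []
    counts = np.zeros((stack.n_b, stack.n_slices), dtype=int)
    for b in range(stack.n_b):
        vol = np.empty(stack.volumes.shape[2:])
        for z in range(stack.n_slices):
            keep = ~stack.excluded[b, :, z]
            counts[b, z] = keep.sum()
            if counts[b, z] == 0:
                warnings.warn(
                    f"all repetitions excluded for slice z={z}, b-index {b}; "
                    "slice set to NaN"
                )
                vol[z] = np.nan
            else:
                vol[z] = stack.volumes[b, keep, z].mean(axis=0)
        grids.append(VoxelGrid3D(vol, stack.spacing))
    return grids, counts
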