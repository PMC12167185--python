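"""Spatial/temporal data containers and NIfTI-1 / CSV input-output.

The containers defined here are the shared currency of the pipeline:

* :class:`VoxelGrid3D` — a single 3-D scalar volume with physical spacing,
  indexed ``(z, y, x)``.
* :class:`DwiStack` — a multi-b-value, multi-repetition diffusion series,
  indexed ``(b_index, repetition, z, y, x)``, carrying its b-values and an
  ``excluded`` flag array written by the signal-dropout rule.
* :class:`DceSeries` — a dynamic contrast-enhanced series indexed
  ``(t_index, z, y, x)`` with frame times in seconds.
* :class:`RoiMask` — a boolean 3-D region of interest (tumor or aorta).
* :class:`CohortTable` — the long-format subject x group x timepoint x
  parameter table feeding the statistics layer.

Images are read and written as NIfTI-1 via nibabel.  NIfTI stores arrays in
``(x, y, z, ...)`` order; this module transposes so that in-memory arrays
are ``(..., z, y, x)``, the natural order for slice-wise processing.  DICOM
is deliberately unsupported: scanner export is upstream of this pipeline
and NIfTI is the interchange standard.

How 4-D/5-D files map onto :class:`DwiStack` and :class:`DceSeries` is never
guessed from headers — the caller declares the layout (b-values, frame
times, repetition packing) explicitly, typically from the YAML run config.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import EmptyRoiError, FormatError, IntegrityError, LayoutError

__all__ = [
    "VoxelGrid3D",
    "DwiStack",
    "DceSeries",
    "RoiMask",
    "CohortTable",
    "read_nifti",
    "write_nifti",
    "compute_roi_volume",
    "write_cohort_csv",
    "read_cohort_csv",
    "COHORT_COLUMNS",
]

GROUPS = ("therapy", "control")
TIMEPOINTS = ("baseline", "follow_up")
COHORT_COLUMNS = ["subject_id", "group", "timepoint", "parameter", "value", "units"]


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive lengths in mm, got {spacing}")
    return spacing


@dataclasses.dataclass
class VoxelGrid3D:
    """A 3-D scalar volume with voxel spacing and origin in mm.

    ``data`` is indexed ``(z, y, x)``; ``spacing`` is ``(dx, dy, dz)``.
    Missing voxels are NaN.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"expected a 3-D array, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclasses.dataclass
class DwiStack:
    """Diffusion-weighted series: ``volumes[b_index, repetition, z, y, x]``.

    ``b_values`` (s/mm²) must be strictly increasing, non-negative, and
    include at least one value below 50 s/mm² to anchor S0.  ``excluded``
    flags slice-repetitions dropped by the motion/signal-dropout rule; it is
    all-False on construction.
    """

    volumes: np.ndarray
    b_values: np.ndarray
    spacing: tuple[float, float, float]
    excluded: np.ndarray | None = None

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=np.float64)
        if self.volumes.ndim != 5:
            raise ValueError(
                f"expected (b, repetition, z, y, x) 5-D array, got shape {self.volumes.shape}"
            )
        self.b_values = np.asarray(self.b_values, dtype=np.float64)
        nb = self.volumes.shape[0]
        if self.b_values.shape != (nb,):
            raise LayoutError(
                f"{nb} b-indices in data but {self.b_values.size} b-values declared"
            )
        if np.any(self.b_values < 0) or np.any(np.diff(self.b_values) <= 0):
            raise ValueError("b-values must be non-negative and strictly increasing")
        if self.b_values[0] >= 50:
            raise ValueError("need at least one b-value < 50 s/mm² as a b≈0 anchor")
        if self.volumes.shape[1] < 1:
            raise ValueError("at least one repetition required")
        self.spacing = _check_spacing(self.spacing)
        shape_ex = (nb, self.n_repetitions, self.n_slices)
        if self.excluded is None:
            self.excluded = np.zeros(shape_ex, dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
            if self.excluded.shape != shape_ex:
                raise LayoutError(
                    f"excluded has shape {self.excluded.shape}, expected {shape_ex}"
                )

    @property
    def n_b(self) -> int:
        return self.volumes.shape[0]

    @property
    def n_repetitions(self) -> int:
        return self.volumes.shape[1]

    @property
    def n_slices(self) -> int:
        return self.volumes.shape[2]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.volumes.shape[3:]

    def copy(self) -> "DwiStack":
        return DwiStack(
            self.volumes.copy(), self.b_values.copy(), self.spacing, self.excluded.copy()
        )


@dataclasses.dataclass
class DceSeries:
    """Dynamic series ``frames[t_index, z, y, x]`` with frame times in s."""

    frames: np.ndarray
    times: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 4:
            raise ValueError(f"expected (t, z, y, x) 4-D array, got {self.frames.shape}")
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.shape != (self.frames.shape[0],):
            raise LayoutError(
                f"{self.frames.shape[0]} frames but {self.times.size} times declared"
            )
        if self.frames.shape[0] < 8:
            raise ValueError("a dynamic series needs at least 8 frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        self.spacing = _check_spacing(self.spacing)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def copy(self) -> "DceSeries":
        return DceSeries(self.frames.copy(), self.times.copy(), self.spacing)


@dataclasses.dataclass
class RoiMask:
    """Boolean 3-D region of interest; ``label`` is 'tumor' or 'aorta'."""

    mask: np.ndarray
    label: str
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {self.mask.shape}")
        if not self.mask.any():
            raise EmptyRoiError(f"ROI '{self.label}' contains no voxels")
        if self.label not in ("tumor", "aorta"):
            raise ValueError(f"label must be 'tumor' or 'aorta', got {self.label!r}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


class CohortTable:
    """Long-format cohort table: one row per (subject, timepoint, parameter).

    Backed by a pandas DataFrame with columns
    ``subject_id, group, timepoint, parameter, value, units``.  The key
    ``(subject_id, timepoint, parameter)`` must be unique; missing
    measurements are NaN values (the study reported none when a tumor was
    too small to segment).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise IntegrityError(f"cohort table missing columns {missing}")
        df = df[COHORT_COLUMNS]
        bad_group = set(df["group"]) - set(GROUPS)
        if bad_group:
            raise IntegrityError(f"unknown group labels {sorted(bad_group)}")
        bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise IntegrityError(f"unknown timepoints {sorted(bad_tp)}")
        key = ["subject_id", "timepoint", "parameter"]
        if df.duplicated(key).any():
            dupes = df[df.duplicated(key, keep=False)][key].drop_duplicates()
            raise IntegrityError(f"duplicate key rows: {dupes.values.tolist()}")
        df["value"] = pd.to_numeric(df["value"], errors="coerce").astype(float)
        if np.isinf(df["value"].to_numpy()).any():
            raise IntegrityError("infinite values in cohort table")
        self.df = df.sort_values(key, kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        a, b = self.df, other.df
        if len(a) != len(b):
            return False
        same_meta = (a.drop(columns="value").reset_index(drop=True)
                     == b.drop(columns="value").reset_index(drop=True)).all().all()
        av, bv = a["value"].to_numpy(), b["value"].to_numpy()
        same_val = np.all((av == bv) | (np.isnan(av) & np.isnan(bv))) if len(a) else True
        return bool(same_meta and same_val)

    def parameters(self) -> list[str]:
        return sorted(self.df["parameter"].unique())

    def values_for(self, group: str, timepoint: str, parameter: str,
                   dropna: bool = True) -> np.ndarray:
        sel = self.df[
            (self.df["group"] == group)
            & (self.df["timepoint"] == timepoint)
            & (self.df["parameter"] == parameter)
        ]["value"].to_numpy()
        return sel[~np.isnan(sel)] if dropna else sel

    def paired_values(self, group: str, parameter: str) -> pd.DataFrame:
        """Baseline/follow-up values per subject (NaN where missing)."""
        sel = self.df[(self.df["group"] == group) & (self.df["parameter"] == parameter)]
        wide = sel.pivot(index="subject_id", columns="timepoint", values="value")
        for tp in TIMEPOINTS:
            if tp not in wide.columns:
                wide[tp] = np.nan
        return wide[list(TIMEPOINTS)]

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "CohortTable":
        return cls(pd.DataFrame.from_records(records, columns=COHORT_COLUMNS))

    @classmethod
    def empty(cls) -> "CohortTable":
        return cls(pd.DataFrame(columns=COHORT_COLUMNS))


# ---------------------------------------------------------------------------
# NIfTI input/output
# ---------------------------------------------------------------------------

def _load(path) -> nib.Nifti1Image:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise FormatError(f"cannot read {path} as NIfTI-1: {exc}") from exc
    return img


def read_nifti(path, layout: dict | None = None):
    """Read a NIfTI-1 file into the container declared by ``layout``.

    ``layout`` declares the meaning of the trailing axes; it is never
    inferred from the header:

    * ``None`` or ``{"kind": "volume"}`` — a plain 3-D volume
      (:class:`VoxelGrid3D`).
    * ``{"kind": "mask", "label": ...}`` — an ROI; nonzero voxels are true.
    * ``{"kind": "dce", "times": [...]}`` — a 4-D dynamic series; the 4th
      axis is time and ``times`` gives the frame times in seconds.
    * ``{"kind": "dwi", "b_values": [...], "n_repetitions": R}`` — either a
      5-D file with axes (x, y, z, b, repetition) or a 4-D file whose 4th
      axis packs b-major blocks of R repetitions (repetition fastest).

    Returns the container; spacing comes from the header ``pixdim``.
    """
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    spacing = tuple(float(z) for z in zooms)
    kind = (layout or {}).get("kind", "volume")

    if kind == "volume":
        if data.ndim != 3:
            raise LayoutError(f"declared 3-D volume but file has shape {data.shape}")
        return VoxelGrid3D(data.T, spacing)
    if kind == "mask":
        if data.ndim != 3:
            raise LayoutError(f"declared mask but file has shape {data.shape}")
        return RoiMask(data.T > 0, layout.get("label", "tumor"), spacing)
    if kind == "dce":
        times = layout.get("times")
        if times is None:
            raise LayoutError("DCE layout requires frame 'times'")
        if data.ndim != 4:
            raise LayoutError(f"declared DCE but file has shape {data.shape}")
        if len(times) != data.shape[3]:
            raise LayoutError(
                f"{data.shape[3]} frames in file but {len(times)} times declared"
            )
        frames = np.transpose(data, (3, 2, 1, 0))  # (t, z, y, x)
        return DceSeries(frames, np.asarray(times, float), spacing)
    if kind == "dwi":
        b_values = layout.get("b_values")
        if b_values is None:
            raise LayoutError("DWI layout requires 'b_values'")
        nb = len(b_values)
        if data.ndim == 5:
            if data.shape[3] != nb:
                raise LayoutError(
                    f"axis 3 has length {data.shape[3]} but {nb} b-values declared"
                )
            vols = np.transpose(data, (3, 4, 2, 1, 0))  # (b, rep, z, y, x)
        elif data.ndim == 4:
            nrep = int(layout.get("n_repetitions", 1))
            if data.shape[3] != nb * nrep:
                raise LayoutError(
                    f"axis 3 has length {data.shape[3]}, expected "
                    f"{nb} b-values x {nrep} repetitions = {nb * nrep}"
                )
            vols = np.transpose(data, (3, 2, 1, 0))  # (b*rep, z, y, x)
            vols = vols.reshape(nb, nrep, *vols.shape[1:])
        else:
            raise LayoutError(f"declared DWI but file has shape {data.shape}")
        return DwiStack(vols, np.asarray(b_values, float), spacing)
    raise LayoutError(f"unknown layout kind {kind!r}")


def write_nifti(obj, path) -> None:
    """Write a container to NIfTI-1 (float32; masks as uint8).

    Round trip is bit-exact for float32 payloads: data are cast to float32
    on write, and :func:`read_nifti` returns exactly the stored values.
    """
    path = Path(path)
    if isinstance(obj, VoxelGrid3D):
        arr = obj.data.T.astype(np.float32)
        spacing = obj.spacing
    elif isinstance(obj, RoiMask):
        arr = obj.mask.T.astype(np.uint8)
        spacing = obj.spacing
    elif isinstance(obj, DceSeries):
        arr = np.transpose(obj.frames, (3, 2, 1, 0)).astype(np.float32)
        spacing = obj.spacing
    elif isinstance(obj, DwiStack):
        arr = np.transpose(obj.volumes, (4, 3, 2, 0, 1)).astype(np.float32)
        spacing = obj.spacing
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms((*spacing, *([1.0] * (arr.ndim - 3))))
    nib.save(img, str(path))


def compute_roi_volume(mask: RoiMask) -> float:
    """ROI volume in mm³: true-voxel count times the voxel volume."""
    if not mask.mask.any():  # defensive; RoiMask forbids this on construction
        raise EmptyRoiError("cannot compute volume of an empty ROI")
    dx, dy, dz = mask.spacing
    return float(mask.mask.sum()) * dx * dy * dz


# ---------------------------------------------------------------------------
# Cohort CSV
# ---------------------------------------------------------------------------

def write_cohort_csv(table: CohortTable, path) -> None:
    """Write a cohort table as CSV with a stable row order.

    Rows are sorted by (subject_id, timepoint, parameter); missing values
    become empty fields.
    """
    table.df.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> CohortTable:
    df = pd.read_csv(path, dtype={"subject_id": str, "units": str})
    if df.empty and not set(COHORT_COLUMNS) <= set(df.columns):
        raise FormatError(f"{path} is not a cohort CSV")
    return CohortTable(df)
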