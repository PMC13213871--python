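"""Data model and I/O for 4D-flow velocity datasets, masks, annotations and tables.

On-disk layout
--------------
A velocity dataset is three 4D NIfTI files (one per velocity component,
time on the last axis) plus a JSON sidecar carrying acquisition metadata
(keys ``venc_cm_s``, ``frame_duration_ms``, ``units``).  Masks are 4D NIfTI
with any value > 0 read as blood pool.  Annotations are JSON.  Force traces
and cohort tables are CSV.

Units
-----
In-memory velocity values are always m/s regardless of the on-disk unit
declared in the sidecar; metadata fields carry their unit in the field name
(``spacing_mm``, ``frame_duration_ms``, ``venc_cm_s``) and SI accessors
(``spacing_m`` ...) are what computations use.  All unit conversion happens
here, at the I/O boundary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError, GeometryError

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids a cycle with hdf
    from .hdf import ForceTrace

__all__ = [
    "Grid",
    "VelocityField",
    "Mask4D",
    "Annotation",
    "SubjectRecord",
    "read_velocity_dataset",
    "write_velocity_dataset",
    "read_mask",
    "write_mask",
    "read_annotation",
    "write_annotation",
    "write_force_trace",
    "read_force_trace",
    "write_cohort_table",
    "read_cohort_table",
]

_UNIT_TO_M_S = {"m/s": 1.0, "cm/s": 0.01, "mm/s": 0.001}


@dataclass(frozen=True)
class Grid:
    """Spatial sampling of a volume in a fixed right-handed patient frame.

    Voxel (i, j, k) sits at ``origin_mm + orientation @ (spacing_mm * (i,j,k))``.
    ``orientation`` columns are the unit vectors of the grid axes.
    """

    shape: tuple[int, int, int]
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "spacing_mm", np.asarray(self.spacing_mm, float))
        object.__setattr__(self, "origin_mm", np.asarray(self.origin_mm, float))
        object.__setattr__(self, "orientation", np.asarray(self.orientation, float))
        if np.any(self.spacing_mm <= 0):
            raise GeometryError("voxel spacing must be positive")

    @property
    def affine_mm(self) -> np.ndarray:
        """4x4 voxel-index -> patient-space (mm) affine."""
        aff = np.eye(4)
        aff[:3, :3] = self.orientation * self.spacing_mm[np.newaxis, :]
        aff[:3, 3] = self.origin_mm
        return aff

    def voxel_centers_mm(self) -> np.ndarray:
        """Patient-space coordinates of all voxel centers, shape (*shape, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        ).astype(float)
        return idx @ (self.orientation * self.spacing_mm[np.newaxis, :]).T + self.origin_mm


def _default_grid_fields(shape, spacing_mm, origin_mm, orientation):
    spacing_mm = np.asarray(spacing_mm, float)
    origin_mm = np.zeros(3) if origin_mm is None else np.asarray(origin_mm, float)
    orientation = np.eye(3) if orientation is None else np.asarray(orientation, float)
    return spacing_mm, origin_mm, orientation


@dataclass
class VelocityField:
    """Periodic, time-resolved 3-component blood velocity on a voxel grid.

    ``values`` has shape (n_frames, nx, ny, nz, 3) in m/s.  The time axis is
    cyclic: retrospective ECG gating reconstructs one representative cardiac
    cycle, so frame ``n_frames`` wraps to frame 0.  ``venc_cm_s`` is the
    velocity-encoding limit of the acquisition; raw (pre-unwrap) values lie
    in [-venc, +venc).
    """

    values: np.ndarray
    spacing_mm: np.ndarray
    frame_duration_ms: float
    venc_cm_s: float
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.spacing_mm = np.asarray(self.spacing_mm, float)
        self.orientation = np.asarray(self.orientation, float)
        self.origin_mm = np.asarray(self.origin_mm, float)
        if self.values.ndim != 5 or self.values.shape[-1] != 3:
            raise FormatError(
                f"velocity values must have shape (t, x, y, z, 3), got {self.values.shape}"
            )
        if self.n_frames < 2:
            raise DataError("a velocity field needs at least 2 time frames")
        if np.any(self.spacing_mm <= 0) or self.frame_duration_ms <= 0 or self.venc_cm_s <= 0:
            raise ConfigError("spacing, frame_duration and venc must all be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:4]

    @property
    def grid(self) -> Grid:
        return Grid(self.grid_shape, self.spacing_mm, self.origin_mm, self.orientation)

    @property
    def spacing_m(self) -> np.ndarray:
        return self.spacing_mm * 1e-3

    @property
    def frame_duration_s(self) -> float:
        return self.frame_duration_ms * 1e-3

    @property
    def period_s(self) -> float:
        """Duration of the reconstructed cardiac cycle (R-R interval)."""
        return self.n_frames * self.frame_duration_s

    @property
    def venc_m_s(self) -> float:
        return self.venc_cm_s * 1e-2

    @property
    def voxel_volume_m3(self) -> float:
        return float(np.prod(self.spacing_m))

    def copy_with(self, values: np.ndarray) -> "VelocityField":
        return VelocityField(
            values=np.asarray(values, float),
            spacing_mm=self.spacing_mm.copy(),
            frame_duration_ms=self.frame_duration_ms,
            venc_cm_s=self.venc_cm_s,
            orientation=self.orientation.copy(),
            origin_mm=self.origin_mm.copy(),
        )


@dataclass
class Mask4D:
    """Time-resolved binary ventricular blood-pool mask on the velocity grid."""

    values: np.ndarray
    label: str = "LV"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 4:
            raise FormatError(f"mask must have shape (t, x, y, z), got {self.values.shape}")
        if self.label not in ("LV", "RV"):
            raise ConfigError(f"mask label must be 'LV' or 'RV', got {self.label!r}")
        if not self.values.any():
            raise DataError("mask contains no voxels in any frame")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def volume_ml(self, spacing_mm: np.ndarray) -> np.ndarray:
        """Blood-pool volume per frame in mL (1 mm^3 = 1e-3 mL)."""
        voxel_mm3 = float(np.prod(np.asarray(spacing_mm, float)))
        return self.values.reshape(self.n_frames, -1).sum(axis=1) * voxel_mm3 * 1e-3


@dataclass
class Annotation:
    """Anatomical annotation anchoring the force-decomposition axes.

    ``av_point_mm`` is a point on the atrioventricular valve plane at end
    diastole, ``av_normal`` the plane normal (oriented apex -> base),
    ``lvot_dir`` points along the left ventricular outflow tract, and
    ``es_frame`` is the end-systolic frame index.
    """

    av_point_mm: np.ndarray
    av_normal: np.ndarray
    lvot_dir: np.ndarray
    es_frame: int

    def __post_init__(self) -> None:
        self.av_point_mm = np.asarray(self.av_point_mm, float)
        self.av_normal = np.asarray(self.av_normal, float)
        self.lvot_dir = np.asarray(self.lvot_dir, float)
        n1, n2 = np.linalg.norm(self.av_normal), np.linalg.norm(self.lvot_dir)
        if n1 == 0 or n2 == 0:
            raise GeometryError("annotation direction vectors must be non-zero")
        cosang = abs(float(self.av_normal @ self.lvot_dir) / (n1 * n2))
        if cosang >= 0.99:
            raise GeometryError(
                f"AV normal and LVOT direction are near-parallel (|cos|={cosang:.4f})"
            )


@dataclass
class SubjectRecord:
    """One subject at one visit: demographics plus derived metrics.

    Volumetric and force metrics are filled downstream; ``metrics`` holds a
    flat name -> value mapping (e.g. ``lv_rms_apex_base_systole``).
    """

    id: str
    group: str  # control | patient
    visit: str  # baseline | followup
    age: Optional[float] = None
    sex: Optional[str] = None
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    heart_rate_bpm: Optional[float] = None
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("height_cm", "weight_kg", "heart_rate_bpm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DataError(f"{name} must be positive when present, got {v}")

    def to_row(self) -> dict:
        row = {
            "id": self.id,
            "group": self.group,
            "visit": self.visit,
            "age": self.age,
            "sex": self.sex,
            "height_cm": self.height_cm,
            "weight_kg": self.weight_kg,
            "heart_rate_bpm": self.heart_rate_bpm,
        }
        row.update(self.metrics)
        return row


# ---------------------------------------------------------------------------
# NIfTI readers / writers


def _load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def _grid_from_affine(affine: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lin = affine[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    orientation = lin / spacing[np.newaxis, :]
    return spacing, affine[:3, 3].copy(), orientation


def read_velocity_dataset(
    component_paths: Sequence, sidecar_path
) -> VelocityField:
    """Read a three-component 4D-flow velocity dataset into SI units.

    Parameters
    ----------
    component_paths
        Three NIfTI paths (x, y, z velocity components), each (nx, ny, nz, nt)
        on identical grids.
    sidecar_path
        JSON sidecar with keys ``venc_cm_s``, ``frame_duration_ms`` and
        ``units`` (one of m/s, cm/s, mm/s; defaults to m/s).
    """
    if len(component_paths) != 3:
        raise FormatError(f"expected 3 component files, got {len(component_paths)}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    if "venc_cm_s" not in sidecar:
        raise ConfigError(f"sidecar {sidecar_path} is missing required key 'venc_cm_s'")
    if "frame_duration_ms" not in sidecar:
        raise ConfigError(f"sidecar {sidecar_path} is missing required key 'frame_duration_ms'")
    units = sidecar.get("units", "m/s")
    if units not in _UNIT_TO_M_S:
        raise ConfigError(f"unknown velocity unit {units!r} (expected one of {list(_UNIT_TO_M_S)})")
    scale = _UNIT_TO_M_S[units]

    comps, affine0 = [], None
    for p in component_paths:
        data, affine = _load_nifti(p)
        if data.ndim != 4:
            raise FormatError(f"{p}: expected a 4D volume (x, y, z, t), got shape {data.shape}")
        if comps and data.shape != comps[0].shape:
            raise FormatError(
                f"component grids disagree: {comps[0].shape} vs {data.shape} ({p})"
            )
        if affine0 is None:
            affine0 = affine
        comps.append(data)

    # NIfTI stores time last; internal layout is time-major.
    values = np.stack(comps, axis=-1)  # (x, y, z, t, 3)
    values = np.moveaxis(values, 3, 0) * scale
    if "spacing_mm" in sidecar:
        # NIfTI headers hold the affine in float32; the sidecar carries the
        # grid geometry at full precision when this package wrote the file.
        spacing = np.asarray(sidecar["spacing_mm"], float)
        origin = np.asarray(sidecar.get("origin_mm", [0.0, 0.0, 0.0]), float)
        orientation = np.asarray(sidecar.get("orientation", np.eye(3).tolist()), float)
    else:
        spacing, origin, orientation = _grid_from_affine(affine0)
    return VelocityField(
        values=values,
        spacing_mm=spacing,
        frame_duration_ms=float(sidecar["frame_duration_ms"]),
        venc_cm_s=float(sidecar["venc_cm_s"]),
        orientation=orientation,
        origin_mm=origin,
    )


def write_velocity_dataset(vel: VelocityField, directory, stem: str = "vel") -> dict:
    """Write a velocity field as three NIfTI components plus a JSON sidecar.

    Values are written in m/s.  Returns a dict with the created paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = vel.grid.affine_mm
    paths = []
    for ci, name in enumerate("xyz"):
        comp = np.moveaxis(vel.values[..., ci], 0, -1)  # (x, y, z, t)
        p = directory / f"{stem}_v{name}.nii"
        nib.save(nib.Nifti1Image(comp, affine), str(p))
        paths.append(p)
    sidecar = {
        "venc_cm_s": vel.venc_cm_s,
        "frame_duration_ms": vel.frame_duration_ms,
        "units": "m/s",
        "spacing_mm": vel.spacing_mm.tolist(),
        "origin_mm": vel.origin_mm.tolist(),
        "orientation": vel.orientation.tolist(),
    }
    sidecar_path = directory / f"{stem}_sidecar.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return {"components": paths, "sidecar": sidecar_path}


def read_mask(path, label: str = "LV") -> Mask4D:
    """Read a 4D NIfTI mask; any voxel value > 0 is blood pool."""
    data, _ = _load_nifti(path)
    if data.ndim == 3:  # static mask: treat as single frame
        data = data[..., np.newaxis]
    if data.ndim != 4:
        raise FormatError(f"{path}: expected 3D or 4D mask, got shape {data.shape}")
    values = np.moveaxis(data > 0, 3, 0)
    if not values.any():
        raise DataError(f"{path}: mask is empty in every frame")
    empty = np.where(~values.reshape(values.shape[0], -1).any(axis=1))[0]
    if empty.size:
        warnings.warn(f"{path}: mask frames {empty.tolist()} contain no voxels", stacklevel=2)
    return Mask4D(values=values, label=label)


def write_mask(mask: Mask4D, path, grid: Optional[Grid] = None) -> None:
    affine = grid.affine_mm if grid is not None else np.eye(4)
    data = np.moveaxis(mask.values.astype(np.uint8), 0, -1)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_annotation(path) -> Annotation:
    with open(path) as fh:
        d = json.load(fh)
    try:
        return Annotation(
            av_point_mm=d["av_point"],
            av_normal=d["av_normal"],
            lvot_dir=d["lvot_dir"],
            es_frame=int(d["es_frame"]),
        )
    except KeyError as exc:
        raise ConfigError(f"annotation {path} is missing key {exc}") from exc


def write_annotation(ann: Annotation, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "av_point": ann.av_point_mm.tolist(),
                "av_normal": ann.av_normal.tolist(),
                "lvot_dir": ann.lvot_dir.tolist(),
                "es_frame": int(ann.es_frame),
            },
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# CSV writers / readers


def write_force_trace(trace: "ForceTrace", path) -> None:
    """Write a force trace as CSV: one row per frame, components in Newton.

    Columns are ``time_fraction`` plus the three anatomical direction labels
    of the trace (LV: apex_base, lateral_septal, inferior_anterior; RV:
    apex_base, septum_free_wall, diaphragm_rvot).  The decomposed trace is
    written if present, the reference-cycle trace if the trace was resampled.
    """
    comp = trace.reference if trace.reference is not None else trace.decomposed
    if comp is None:
        comp = trace.raw
        labels = ("fx", "fy", "fz")
    else:
        labels = trace.labels
    frac = np.arange(comp.shape[0]) / comp.shape[0]
    df = pd.DataFrame({"time_fraction": frac})
    for i, lab in enumerate(labels):
        df[lab] = comp[:, i]
    df.to_csv(path, index=False, float_format="%.12g")


def read_force_trace(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cohort_table(table: pd.DataFrame | Sequence[SubjectRecord], path) -> None:
    """Write a cohort table (one row per subject-visit) to CSV."""
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame([r.to_row() for r in table])
    table.to_csv(path, index=False, float_format="%.12g")


def read_cohort_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
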