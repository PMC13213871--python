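"""Anatomical axes, mask resampling and ventricular volumetrics.

The force decomposition axes form a right-handed orthonormal triad anchored
to two manual landmarks: the atrioventricular (AV) valve plane normal gives
the apical-basal axis, and the left ventricular outflow tract (LVOT)
direction, orthogonalized against it, gives the transverse axis.  The right
ventricle uses the *same* spatial directions; only the anatomical labels
change (septum-free wall, diaphragm-RVOT).

Volumetrics follow standard CMR planimetry: volume(t) is the voxel count of
the blood-pool mask times the voxel volume; end diastole / end systole are
the volume-curve extrema; indexed quantities divide by the Mosteller body
surface area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import DataError, GeometryError
from .io import Annotation, Grid, Mask4D

__all__ = [
    "AXIS_LABELS",
    "AxesTriad",
    "Volumetrics",
    "build_axes",
    "resample_mask_to_flow",
    "compute_volumes",
    "mosteller_bsa",
    "derived_indices",
]

#: Anatomical names of the three force components, per ventricle.
AXIS_LABELS = {
    "LV": ("apex_base", "lateral_septal", "inferior_anterior"),
    "RV": ("apex_base", "septum_free_wall", "diaphragm_rvot"),
}


@dataclass(frozen=True)
class AxesTriad:
    """Right-handed orthonormal direction set in patient space.

    ``e1`` is apical-basal (apex -> base, along the AV-plane normal), ``e2``
    the LVOT-aligned transverse direction, ``e3 = e1 x e2``.
    """

    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray
    ventricle: str = "LV"

    def __post_init__(self) -> None:
        for name in ("e1", "e2", "e3"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if self.ventricle not in AXIS_LABELS:
            raise GeometryError(f"ventricle must be LV or RV, got {self.ventricle!r}")

    @property
    def labels(self) -> tuple[str, str, str]:
        return AXIS_LABELS[self.ventricle]

    @property
    def matrix(self) -> np.ndarray:
        """Rows are e1, e2, e3; ``matrix @ f`` decomposes a patient-space vector."""
        return np.stack([self.e1, self.e2, self.e3])

    def relabel(self, ventricle: str) -> "AxesTriad":
        return AxesTriad(self.e1, self.e2, self.e3, ventricle=ventricle)


@dataclass
class Volumetrics:
    """Global ventricular volumes and derived clinical indices.

    edv/esv/sv in mL, ef in %, indexed quantities in mL/m^2, cardiac index
    in L/min/m^2, qp_qs dimensionless.
    """

    edv: float
    esv: float
    sv: float
    ef: float
    bsa: Optional[float] = None
    edvi: Optional[float] = None
    svi: Optional[float] = None
    cardiac_index: Optional[float] = None
    qp_qs: Optional[float] = None

    def __post_init__(self) -> None:
        if self.esv > self.edv + 1e-9:
            raise DataError(f"ESV ({self.esv}) exceeds EDV ({self.edv})")
        if not (0.0 <= self.ef <= 100.0):
            raise DataError(f"ejection fraction out of [0, 100]: {self.ef}")


def build_axes(annotation: Annotation, ventricle: str = "LV") -> AxesTriad:
    """Construct the anatomical decomposition triad from an annotation.

    e1 is the normalized AV-plane normal (positive sense apex -> base); e2 is
    the component of the LVOT direction orthogonal to e1 (Gram-Schmidt),
    normalized; e3 = e1 x e2.  The RV triad is the identical set of vectors
    carrying RV labels.
    """
    e1 = annotation.av_normal / np.linalg.norm(annotation.av_normal)
    lvot = annotation.lvot_dir / np.linalg.norm(annotation.lvot_dir)
    resid = lvot - (lvot @ e1) * e1
    norm = np.linalg.norm(resid)
    # Annotation already rejects |cos| >= 0.99, but guard against numerics.
    if norm < 1e-12:
        raise GeometryError("LVOT direction is parallel to the AV-plane normal")
    e2 = resid / norm
    e3 = np.cross(e1, e2)
    return AxesTriad(e1, e2, e3, ventricle=ventricle)


def resample_mask_to_flow(
    mask_on_cine_grid: Mask4D,
    cine_geometry: Grid,
    flow_geometry: Grid,
    n_flow_frames: int,
) -> Mask4D:
    """Resample a cine-grid delineation onto the 4D-flow grid.

    Spatially: the 0/1 mask is trilinearly interpolated at the flow voxel
    centers (both grids live in the same patient frame) and thresholded at
    0.5.  Temporally: flow frame ``k`` takes cine frame
    ``round(n_cine * k / n_flow) mod n_cine`` — nearest normalized cycle
    fraction.

    Raises
    ------
    GeometryError
        If the two fields of view do not overlap.
    """
    if tuple(mask_on_cine_grid.values.shape[1:]) != tuple(cine_geometry.shape):
        raise GeometryError("mask grid does not match the declared cine geometry")

    # Flow voxel centers in cine voxel-index coordinates.
    centers = flow_geometry.voxel_centers_mm().reshape(-1, 3)
    lin_inv = np.linalg.inv(cine_geometry.orientation * cine_geometry.spacing_mm[np.newaxis, :])
    cine_idx = (centers - cine_geometry.origin_mm) @ lin_inv.T  # (nvox, 3)

    shape = np.asarray(cine_geometry.shape, float)
    inside = np.all((cine_idx > -0.5) & (cine_idx < shape - 0.5), axis=1)
    if not inside.any():
        raise GeometryError("cine and flow fields of view do not overlap")

    n_cine = mask_on_cine_grid.n_frames
    out = np.zeros((n_flow_frames, *flow_geometry.shape), dtype=bool)
    coords = cine_idx.T  # (3, nvox) for map_coordinates
    for k in range(n_flow_frames):
        src = int(round(n_cine * k / n_flow_frames)) % n_cine
        interp = map_coordinates(
            mask_on_cine_grid.values[src].astype(float),
            coords,
            order=1,
            mode="constant",
            cval=0.0,
        )
        out[k] = (interp >= 0.5).reshape(flow_geometry.shape)
    return Mask4D(values=out, label=mask_on_cine_grid.label)


def compute_volumes(mask: Mask4D, spacing_mm: np.ndarray) -> tuple[np.ndarray, Volumetrics]:
    """Volume curve (mL per frame) and global volumetrics from a mask.

    EDV is the volume-curve maximum over frames, ESV the minimum; SV and EF
    follow by definition (EF in %, 0 for a flat curve).
    """
    curve = mask.volume_ml(spacing_mm)
    edv, esv = float(curve.max()), float(curve.min())
    sv = edv - esv
    ef = 100.0 * sv / edv if edv > 0 else 0.0
    return curve, Volumetrics(edv=edv, esv=esv, sv=sv, ef=ef)


def mosteller_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2) by Mosteller: sqrt(height_cm * weight_kg / 3600)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise DataError("height and weight must be positive")
    return float(np.sqrt(height_cm * weight_kg / 3600.0))


def derived_indices(
    volumetrics: Volumetrics,
    bsa: float,
    heart_rate_bpm: Optional[float] = None,
    lv_sv: Optional[float] = None,
    rv_sv: Optional[float] = None,
) -> Volumetrics:
    """Complete a Volumetrics with BSA-indexed and shunt quantities.

    edvi = EDV/BSA, svi = SV/BSA (mL/m^2); cardiac index = SVi x HR / 1000
    (L/min/m^2); planimetric Qp/Qs = RV SV / LV SV, the ratio of pulmonic to
    systemic stroke output.
    """
    if bsa <= 0:
        raise DataError("BSA must be positive")
    volumetrics.bsa = bsa
    volumetrics.edvi = volumetrics.edv / bsa
    volumetrics.svi = volumetrics.sv / bsa
    if heart_rate_bpm is not None:
        if heart_rate_bpm <= 0:
            raise DataError("heart rate must be positive")
        volumetrics.cardiac_index = volumetrics.svi * heart_rate_bpm / 1000.0
    if rv_sv is not None and lv_sv is not None:
        if lv_sv <= 0:
            raise DataError("LV stroke volume must be positive for Qp/Qs")
        volumetrics.qp_qs = rv_sv / lv_sv
    return volumetrics
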