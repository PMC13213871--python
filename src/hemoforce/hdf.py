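"""Hemodynamic force computation from 4D-flow velocity fields.

The intraventricular pressure-gradient field is evaluated from the
Navier-Stokes momentum balance,

    grad p = -rho * (dv/dt + (v . grad) v) + mu * laplacian(v),

with the temporal acceleration dv/dt taken by cyclic central differences
over the periodic cardiac cycle, and spatial derivatives by central
differences on the voxel grid (one-sided at the grid boundary).  Absolute
pressure never enters: only the time-varying gradients that drive filling
and ejection are computed.

Integrating the gradient over the ventricular blood pool at each frame
yields the global hemodynamic force

    F(t) = integral over V(t) of grad p dV     [Newton],

a 3-component vector exchanged between the blood and the surrounding
myocardium.  F(t) is decomposed onto the anatomical triad, resampled to a
reference cardiac cycle with end systole anchored at 40% of the R-R
interval, and summarized as per-direction RMS and peak values in systole
and diastole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigError, DataError
from .geometry import AxesTriad
from .io import Mask4D, VelocityField

__all__ = [
    "FluidConstants",
    "GradientField",
    "ForceTrace",
    "PhaseMetrics",
    "ES_FRACTION",
    "pressure_gradient_field",
    "integrate_force",
    "decompose_force",
    "resample_to_reference",
    "phase_metrics",
    "compute_hdf",
]

#: Reference-cycle fraction at which end systole is anchored.
ES_FRACTION = 0.40

#: Default number of samples on the reference cardiac cycle; a multiple of
#: 1/ES_FRACTION so the systole/diastole boundary falls exactly on a sample.
DEFAULT_N_REF = 100


@dataclass(frozen=True)
class FluidConstants:
    """Blood density (kg/m^3) and dynamic viscosity (Pa s).

    Defaults are standard values for whole blood at body temperature.
    """

    rho: float = 1060.0
    mu: float = 4.0e-3

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ConfigError("rho and mu must be positive")


@dataclass
class GradientField:
    """Pressure gradient per voxel per frame (Pa/m, 3 components).

    ``terms`` optionally keeps the three contributions (temporal,
    convective, viscous) separately; they sum to ``values``.
    """

    values: np.ndarray  # (t, x, y, z, 3)
    spacing_mm: np.ndarray
    terms: Optional[dict] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.spacing_mm = np.asarray(self.spacing_mm, float)
        if not np.all(np.isfinite(self.values)):
            raise DataError("pressure-gradient field contains non-finite values")


@dataclass
class ForceTrace:
    """Global hemodynamic force over the cardiac cycle.

    ``raw`` is the patient-space force per frame (Newton); ``decomposed``
    its projection on the anatomical triad; ``reference`` the decomposed
    trace resampled onto ``n_ref`` uniform samples of the reference cycle
    [0, 1) with end systole at ``es_fraction``.
    """

    raw: np.ndarray  # (n_frames, 3), N, patient space
    frame_duration_ms: float
    decomposed: Optional[np.ndarray] = None
    reference: Optional[np.ndarray] = None
    labels: tuple = ("fx", "fy", "fz")
    es_fraction: float = ES_FRACTION
    ventricle: Optional[str] = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, float)
        if self.raw.ndim != 2 or self.raw.shape[1] != 3:
            raise DataError(f"force trace must have shape (n_frames, 3), got {self.raw.shape}")

    @property
    def n_frames(self) -> int:
        return self.raw.shape[0]


@dataclass
class PhaseMetrics:
    """Per-direction RMS and peak force (Newton) in systole and diastole.

    Systole is the reference-cycle interval [0, es_fraction), diastole
    [es_fraction, 1).  ``rms`` and ``peak`` map direction label ->
    {"systole": value, "diastole": value}.
    """

    rms: dict
    peak: dict
    es_fraction: float = ES_FRACTION
    ventricle: Optional[str] = None

    def to_flat_dict(self, prefix: str = "") -> dict:
        out = {}
        for label, phases in self.rms.items():
            for phase, v in phases.items():
                out[f"{prefix}rms_{label}_{phase}"] = v
        for label, phases in self.peak.items():
            for phase, v in phases.items():
                out[f"{prefix}peak_{label}_{phase}"] = v
        return out


# ---------------------------------------------------------------------------
# Discrete differential operators


def _temporal_derivative(values: np.ndarray, dt: float) -> np.ndarray:
    """Cyclic central difference along the (periodic) time axis."""
    return (np.roll(values, -1, axis=0) - np.roll(values, 1, axis=0)) / (2.0 * dt)


def _spatial_gradient(values: np.ndarray, spacing_m: np.ndarray) -> list[np.ndarray]:
    """First derivatives along x, y, z; central interior, one-sided at edges.

    ``values`` is (t, x, y, z, c); returns one array per spatial axis.
    """
    return [
        np.gradient(values, spacing_m[ax], axis=1 + ax, edge_order=1)
        for ax in range(3)
    ]


def _second_derivative(values: np.ndarray, h: float, axis: int) -> np.ndarray:
    """Second central difference along ``axis``, one-sided at the boundary.

    The boundary uses the shifted three-point stencil (f0 - 2 f1 + f2)/h^2,
    so the operator stays exact on quadratic profiles everywhere.
    """
    n = values.shape[axis]
    out = np.zeros_like(values)
    if n < 3:
        return out
    v = np.moveaxis(values, axis, 0)
    o = np.moveaxis(out, axis, 0)
    o[1:-1] = (v[2:] - 2.0 * v[1:-1] + v[:-2]) / h**2
    o[0] = (v[0] - 2.0 * v[1] + v[2]) / h**2
    o[-1] = (v[-1] - 2.0 * v[-2] + v[-3]) / h**2
    return out


def _laplacian(values: np.ndarray, spacing_m: np.ndarray) -> np.ndarray:
    lap = np.zeros_like(values)
    for ax in range(3):
        lap += _second_derivative(values, spacing_m[ax], axis=1 + ax)
    return lap


# ---------------------------------------------------------------------------
# Operations


def pressure_gradient_field(
    vel: VelocityField,
    constants: FluidConstants = FluidConstants(),
    keep_terms: bool = False,
) -> GradientField:
    """Navier-Stokes pressure gradient per voxel per frame.

    grad p = -rho (dv/dt + (v . grad) v) + mu laplacian(v), evaluated on the
    full acquired field (voxels outside any ventricular mask participate in
    the spatial stencils).  The input should be preprocessed (unwrapped and
    background-corrected).

    Raises
    ------
    DataError
        If the field has fewer than 3 frames (central time differences need
        distinct neighbors).
    """
    if vel.n_frames < 3:
        raise DataError("temporal central differences require at least 3 frames")
    rho, mu = constants.rho, constants.mu
    v = vel.values
    spacing = vel.spacing_m

    temporal = -rho * _temporal_derivative(v, vel.frame_duration_s)

    grads = _spatial_gradient(v, spacing)  # dv_c/dx_ax, each (t,x,y,z,3)
    convective = np.zeros_like(v)
    for ax in range(3):
        convective += v[..., ax : ax + 1] * grads[ax]
    convective *= -rho

    viscous = mu * _laplacian(v, spacing)

    total = temporal + convective + viscous
    terms = (
        {"temporal": temporal, "convective": convective, "viscous": viscous}
        if keep_terms
        else None
    )
    return GradientField(values=total, spacing_mm=vel.spacing_mm, terms=terms)


def integrate_force(
    grad: GradientField,
    mask: Mask4D,
    spacing_mm: Optional[np.ndarray] = None,
    frame_duration_ms: float = 1.0,
) -> ForceTrace:
    """Integrate the pressure gradient over the (time-varying) blood pool.

    F(t) = sum over masked voxels of grad p * voxel volume, in Newton.  An
    empty mask frame yields zero force for that frame with a warning.
    """
    spacing_mm = np.asarray(grad.spacing_mm if spacing_mm is None else spacing_mm, float)
    if grad.values.shape[:4] != mask.values.shape:
        raise DataError(
            f"gradient grid {grad.values.shape[:4]} and mask grid {mask.values.shape} disagree"
        )
    voxel_m3 = float(np.prod(spacing_mm * 1e-3))
    n = grad.values.shape[0]
    force = np.zeros((n, 3))
    for t in range(n):
        m = mask.values[t]
        if not m.any():
            warnings.warn(f"mask frame {t} is empty; force set to 0", stacklevel=2)
            continue
        force[t] = grad.values[t][m].sum(axis=0) * voxel_m3
    return ForceTrace(raw=force, frame_duration_ms=frame_duration_ms, ventricle=mask.label)


def decompose_force(trace: ForceTrace, triad: AxesTriad) -> ForceTrace:
    """Project the patient-space force onto the anatomical triad.

    component_i(t) = F(t) . e_i; with an orthonormal triad the squared
    components sum to |F|^2 (energy preserved).
    """
    trace.decomposed = trace.raw @ triad.matrix.T
    trace.labels = triad.labels
    trace.ventricle = triad.ventricle
    return trace


def resample_to_reference(
    trace: ForceTrace,
    es_frame: int,
    n_ref: int = DEFAULT_N_REF,
    es_fraction: float = ES_FRACTION,
) -> ForceTrace:
    """Resample a force trace onto the reference cardiac cycle.

    A piecewise-linear time warp maps [0, t_ES] -> [0, es_fraction] and
    [t_ES, RR] -> [es_fraction, 1]; the (decomposed, else raw) signal is then
    linearly interpolated at ``n_ref`` uniform reference fractions
    j/n_ref, j = 0..n_ref-1.  The reference sample at fraction
    ``es_fraction`` equals the original end-systolic frame value, and a
    trace whose ES already sits at ``es_fraction`` with n_ref = n_frames
    passes through unchanged.
    """
    n = trace.n_frames
    if not 0 < es_frame < n:
        raise DataError(f"es_frame must be in (0, {n}), got {es_frame}")
    if not 0.0 < es_fraction < 1.0:
        raise ConfigError("es_fraction must lie in (0, 1)")

    signal = trace.decomposed if trace.decomposed is not None else trace.raw
    # Periodic extension: frame n is frame 0 again.
    t_orig = np.arange(n + 1, dtype=float)  # in frame units; RR = n
    sig_ext = np.vstack([signal, signal[:1]])

    u = np.arange(n_ref, dtype=float) / n_ref
    t_es = float(es_frame)
    t_warped = np.where(
        u <= es_fraction,
        u * t_es / es_fraction,
        t_es + (u - es_fraction) * (n - t_es) / (1.0 - es_fraction),
    )
    ref = np.column_stack(
        [np.interp(t_warped, t_orig, sig_ext[:, c]) for c in range(3)]
    )
    trace.reference = ref
    trace.es_fraction = es_fraction
    return trace


def phase_metrics(trace: ForceTrace) -> PhaseMetrics:
    """RMS and peak |component| per direction, in systole and in diastole.

    Operates on the reference-cycle trace; systole is [0, es_fraction),
    diastole [es_fraction, 1).
    """
    if trace.reference is None:
        raise DataError("phase metrics require a reference-cycle trace; resample first")
    ref = trace.reference
    frac = np.arange(ref.shape[0], dtype=float) / ref.shape[0]
    systole = frac < trace.es_fraction
    rms, peak = {}, {}
    for i, label in enumerate(trace.labels):
        comp = ref[:, i]
        rms[label] = {
            "systole": float(np.sqrt(np.mean(comp[systole] ** 2))),
            "diastole": float(np.sqrt(np.mean(comp[~systole] ** 2))),
        }
        peak[label] = {
            "systole": float(np.max(np.abs(comp[systole]))),
            "diastole": float(np.max(np.abs(comp[~systole]))),
        }
    return PhaseMetrics(rms=rms, peak=peak, es_fraction=trace.es_fraction, ventricle=trace.ventricle)


def compute_hdf(
    vel: VelocityField,
    mask: Mask4D,
    triad: AxesTriad,
    es_frame: int,
    constants: FluidConstants = FluidConstants(),
    n_ref: int = DEFAULT_N_REF,
) -> tuple[ForceTrace, PhaseMetrics]:
    """Full force pipeline: gradients -> integration -> decomposition ->
    reference-cycle resampling -> phase metrics."""
    grad = pressure_gradient_field(vel, constants)
    trace = integrate_force(grad, mask, frame_duration_ms=vel.frame_duration_ms)
    trace = decompose_force(trace, triad)
    trace = resample_to_reference(trace, es_frame=es_frame, n_ref=n_ref)
    return trace, phase_metrics(trace)
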