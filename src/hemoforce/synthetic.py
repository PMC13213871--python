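"""Analytic 4D-flow phantoms, corruption injectors and cohort simulation.

No patient data ships with this package.  Every pipeline stage is instead
exercised by phantoms whose hemodynamic force is known in closed form (or by
an independent brute-force sum), generated at the acquisition scale of a
clinical pediatric protocol: 32^3-ish grids at 2.2 x 2.2 x 2.5 mm, 25
reconstructed time phases, VENC 150 cm/s.

Phantom kinds
-------------
``uniform_oscillation``
    Spatially uniform v(t) = A sin(2 pi t / T) along z.  Convective and
    viscous terms vanish identically; the force over a mask of volume V is
    F_z(t_k) = -rho V A (2 pi / T) cos(2 pi k / n) * sinc_n, where
    sinc_n = sin(2 pi / n) / (2 pi / n) is the attenuation of the cyclic
    central difference at the sampling rate.
``poiseuille``
    Steady parabolic pipe flow v_z = v_max (1 - r^2/R^2) inside a cylinder.
    On the eroded interior the pressure gradient is exactly the viscous term
    -4 mu v_max / R^2 along z (central second differences are exact on
    quadratics), so F_z = -4 mu v_max / R^2 * V_mask.
``solid_rotation``
    Rigid rotation about the cylinder axis.  The centripetal pressure
    gradient field is radially symmetric, so the net force over a centered
    mask cancels to ~0 while the integrated |grad p| stays finite.
``contracting_blob``
    Uniform oscillatory velocity inside an ellipsoid whose semi-axes vary
    sinusoidally over the cycle — exercises time-varying-mask integration.
    Its oracle is the brute-force voxel sum, not a closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .hdf import FluidConstants
from .io import Annotation, Mask4D, VelocityField
from .preprocess import _monomial_basis, _normalized_coords

__all__ = [
    "PhantomSpec",
    "OracleRecord",
    "CohortSpec",
    "make_phantom",
    "inject_corruptions",
    "simulate_cohort",
    "CONTROL_MEDIANS",
    "PREOP_MEDIANS",
    "POSTOP_MEDIANS",
]

PHANTOM_KINDS = ("uniform_oscillation", "poiseuille", "solid_rotation", "contracting_blob")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of an analytic flow phantom.

    Defaults mirror a clinical pediatric 4D-flow protocol (grid scale,
    25 phases, VENC 150 cm/s) so that discretization tolerances quoted in
    the tests are realistic.
    """

    kind: str = "uniform_oscillation"
    grid: tuple = (32, 32, 32)
    spacing_mm: tuple = (2.2, 2.2, 2.5)
    n_frames: int = 25
    period_s: float = 1.0
    venc_cm_s: float = 150.0
    amplitude_m_s: float = 0.5  # uniform_oscillation / contracting_blob
    v_max_m_s: float = 1.0  # poiseuille
    radius_m: float = 0.01  # poiseuille / solid_rotation cylinder radius
    angular_rate_rad_s: float = 10.0  # solid_rotation
    mask_volume_ml: float = 100.0  # uniform_oscillation target mask volume
    constants: FluidConstants = field(default_factory=FluidConstants)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ConfigError(f"unknown phantom kind {self.kind!r}")
        if min(self.grid) < 4 or self.n_frames < 3:
            raise ConfigError("phantom grid must be >= 4 per axis with >= 3 frames")
        for name in ("period_s", "venc_cm_s", "amplitude_m_s", "v_max_m_s",
                     "radius_m", "angular_rate_rad_s", "mask_volume_ml"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass
class OracleRecord:
    """Ground truth attached to a phantom.

    ``force_trace_n`` is the closed-form per-frame force (Newton, patient
    space) where one exists; for the contracting blob it is None and the
    oracle is an independent brute-force sum.  ``gradient_pa_m`` is the
    constant interior pressure gradient for the Poiseuille phantom.
    """

    kind: str
    force_trace_n: Optional[np.ndarray]
    peak_force_n: Optional[float]
    gradient_pa_m: Optional[np.ndarray] = None
    mask_volume_m3: Optional[float] = None
    notes: str = ""


def _voxel_centers_m(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coordinates of voxel centers (m) relative to the grid center."""
    sp = np.asarray(spec.spacing_mm, float) * 1e-3
    axes = [(np.arange(n) - (n - 1) / 2.0) * sp[i] for i, n in enumerate(spec.grid)]
    return tuple(np.meshgrid(*axes, indexing="ij"))


def _sinc_factor(n_frames: int) -> float:
    """Amplitude attenuation of the cyclic central difference on a sampled
    sinusoid: sin(2 pi / n) / (2 pi / n)."""
    w = 2.0 * np.pi / n_frames
    return float(np.sin(w) / w)


def _dilate_box(mask: np.ndarray, margin: int) -> np.ndarray:
    """Axis-aligned bounding box of ``mask`` grown by ``margin`` voxels."""
    out = np.zeros_like(mask)
    idx = np.where(mask)
    slices = tuple(
        slice(max(0, int(i.min()) - margin), min(n, int(i.max()) + 1 + margin))
        for i, n in zip(idx, mask.shape)
    )
    out[slices] = True
    return out


def _centered_box_mask(spec: PhantomSpec) -> np.ndarray:
    """Centered cuboid with voxel count approximating mask_volume_ml."""
    voxel_ml = float(np.prod(spec.spacing_mm)) * 1e-3
    n_target = max(1, int(round(spec.mask_volume_ml / voxel_ml)))
    # Cap the box so a zero-velocity shell (>= 4 voxels per side) always
    # surrounds the flow region: it stands in for stationary tissue.
    cap = [max(1, n - 8) for n in spec.grid]
    a = max(1, int(round(n_target ** (1.0 / 3.0))))
    a = min(a, cap[0], cap[1])
    nz = min(max(1, int(round(n_target / (a * a)))), cap[2])
    mask = np.zeros(spec.grid, dtype=bool)
    sx = (spec.grid[0] - a) // 2
    sy = (spec.grid[1] - a) // 2
    sz = (spec.grid[2] - nz) // 2
    mask[sx : sx + a, sy : sy + a, sz : sz + nz] = True
    return mask


def _default_annotation(spec: PhantomSpec) -> Annotation:
    half_z_mm = spec.grid[2] * spec.spacing_mm[2] / 2.0
    return Annotation(
        av_point_mm=np.array([0.0, 0.0, half_z_mm]),
        av_normal=np.array([0.0, 0.0, 1.0]),
        lvot_dir=np.array([1.0, 0.0, 1.0]) / np.sqrt(2.0),
        es_frame=int(round(0.4 * spec.n_frames)),
    )


def make_phantom(
    spec: PhantomSpec,
) -> tuple[VelocityField, Mask4D, Annotation, OracleRecord]:
    """Sample an analytic phantom and its ground-truth force oracle."""
    nt = spec.n_frames
    dt = spec.period_s / nt
    x, y, z = _voxel_centers_m(spec)
    rho, mu = spec.constants.rho, spec.constants.mu
    voxel_m3 = float(np.prod(np.asarray(spec.spacing_mm) * 1e-3))
    values = np.zeros((nt, *spec.grid, 3))
    phases = 2.0 * np.pi * np.arange(nt) / nt

    if spec.kind == "uniform_oscillation":
        if spec.amplitude_m_s >= 2.0 * spec.venc_cm_s * 1e-2:
            raise ConfigError("amplitude >= 2*VENC cannot be unwrapped; reduce amplitude")
        mask3 = _centered_box_mask(spec)
        # Flow confined to a region 3 voxels wider than the mask: the
        # surrounding zero-velocity shell plays the role of stationary
        # tissue, and the mask stays clear of the velocity discontinuity so
        # the closed-form oracle remains exact on every stencil it touches.
        flow_region = _dilate_box(mask3, 3)
        for k in range(nt):
            values[k, ..., 2] = np.where(
                flow_region, spec.amplitude_m_s * np.sin(phases[k]), 0.0
            )
        mask = np.broadcast_to(mask3, (nt, *spec.grid)).copy()
        v_mask = float(mask3.sum()) * voxel_m3
        fz = (
            -rho * v_mask * spec.amplitude_m_s * (2.0 * np.pi / spec.period_s)
            * np.cos(phases) * _sinc_factor(nt)
        )
        oracle = OracleRecord(
            kind=spec.kind,
            force_trace_n=np.column_stack([np.zeros(nt), np.zeros(nt), fz]),
            peak_force_n=float(np.max(np.abs(fz))),
            mask_volume_m3=v_mask,
            notes="closed form: F_z = -rho V A (2pi/T) cos * discrete-derivative factor",
        )

    elif spec.kind == "poiseuille":
        r2 = x**2 + y**2
        profile = np.where(r2 <= spec.radius_m**2,
                           spec.v_max_m_s * (1.0 - r2 / spec.radius_m**2), 0.0)
        values[:, ..., 2] = profile[np.newaxis]
        # Eroded interior: every spatial stencil point stays inside the
        # quadratic region, so the discrete Laplacian is exact there.
        margin = 2.0 * max(spec.spacing_mm[0], spec.spacing_mm[1]) * 1e-3
        interior = r2 <= (spec.radius_m - margin) ** 2
        if not interior.any():
            raise ConfigError("poiseuille radius too small for the grid spacing")
        mask = np.broadcast_to(interior, (nt, *spec.grid)).copy()
        v_mask = float(interior.sum()) * voxel_m3
        gz = -4.0 * mu * spec.v_max_m_s / spec.radius_m**2
        trace = np.zeros((nt, 3))
        trace[:, 2] = gz * v_mask
        oracle = OracleRecord(
            kind=spec.kind,
            force_trace_n=trace,
            peak_force_n=float(abs(gz) * v_mask),
            gradient_pa_m=np.array([0.0, 0.0, gz]),
            mask_volume_m3=v_mask,
            notes="steady viscous gradient -4 mu v_max / R^2 on the eroded interior",
        )

    elif spec.kind == "solid_rotation":
        omega = spec.angular_rate_rad_s
        r_cyl = 2.0 * spec.radius_m  # rotating region radius
        inside = (x**2 + y**2) <= r_cyl**2
        values[:, ..., 0] = np.where(inside, -omega * y, 0.0)[np.newaxis]
        values[:, ..., 1] = np.where(inside, omega * x, 0.0)[np.newaxis]
        margin = 2.0 * max(spec.spacing_mm[0], spec.spacing_mm[1]) * 1e-3
        interior = (x**2 + y**2) <= (r_cyl - margin) ** 2
        mask = np.broadcast_to(interior, (nt, *spec.grid)).copy()
        v_mask = float(interior.sum()) * voxel_m3
        oracle = OracleRecord(
            kind=spec.kind,
            force_trace_n=np.zeros((nt, 3)),
            peak_force_n=0.0,
            mask_volume_m3=v_mask,
            notes="centripetal gradient cancels by symmetry over the centered mask",
        )

    else:  # contracting_blob
        # Ellipsoid with sinusoidally varying semi-axes; minimum volume
        # (end systole) lands at 40% of the cycle.
        nx, ny, nz = spec.grid
        sp = np.asarray(spec.spacing_mm, float) * 1e-3
        a0 = np.array([0.28 * nx * sp[0], 0.28 * ny * sp[1], 0.32 * nz * sp[2]])
        es_phase = 2.0 * np.pi * 0.4
        mask = np.zeros((nt, *spec.grid), dtype=bool)
        for k in range(nt):
            scale = 1.0 - 0.15 * np.cos(phases[k] - es_phase)
            ax = a0 * scale
            mask[k] = (x / ax[0]) ** 2 + (y / ax[1]) ** 2 + (z / ax[2]) ** 2 <= 1.0
        # Flow region: largest ellipsoid plus margin; outside is stationary.
        ax_flow = a0 * (1.15 + 0.15)
        flow_region = (x / ax_flow[0]) ** 2 + (y / ax_flow[1]) ** 2 + (z / ax_flow[2]) ** 2 <= 1.0
        for k in range(nt):
            values[k, ..., 2] = np.where(
                flow_region, spec.amplitude_m_s * np.sin(phases[k]), 0.0
            )
        oracle = OracleRecord(
            kind=spec.kind,
            force_trace_n=None,
            peak_force_n=None,
            notes="oracle is the independent brute-force voxel sum",
        )

    vel = VelocityField(
        values=values,
        spacing_mm=np.asarray(spec.spacing_mm, float),
        frame_duration_ms=dt * 1e3,
        venc_cm_s=spec.venc_cm_s,
    )
    ann = _default_annotation(spec)
    return vel, Mask4D(values=mask, label="LV"), ann, oracle


def inject_corruptions(
    vel: VelocityField,
    offset_poly_coeffs: Optional[np.ndarray] = None,
    wrap: bool = False,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[VelocityField, dict]:
    """Corrupt a clean field the way a scanner would.

    ``offset_poly_coeffs`` has shape (n_coef, 3): coefficients of the 3D
    monomial basis (total degree inferred from the count: 4 -> linear,
    10 -> quadratic, 20 -> cubic) on voxel coordinates normalized to [-1, 1],
    one column per velocity component.  The offset is added to every frame.
    If ``wrap``, values are rewrapped into [-VENC, +VENC).  Gaussian noise of
    SD ``noise_sd`` (m/s) is added last.  Returns the corrupted field and a
    report with the wrapped-sample count.
    """
    values = vel.values.copy()
    if offset_poly_coeffs is not None:
        coeffs = np.asarray(offset_poly_coeffs, float)
        n_coef = coeffs.shape[0]
        order = {4: 1, 10: 2, 20: 3}.get(n_coef)
        if order is None:
            raise ConfigError(
                f"offset coefficient count {n_coef} does not match degree 1, 2 or 3"
            )
        basis = _monomial_basis(_normalized_coords(vel.grid_shape), order)
        offset = (basis @ coeffs).reshape(*vel.grid_shape, 3)
        values = values + offset[np.newaxis]
    n_wrapped = 0
    if wrap:
        venc = vel.venc_m_s
        if np.any(np.abs(values) >= 2.0 * venc):
            raise DataError("|v| >= 2*VENC would wrap twice and be unrecoverable")
        wrapped = np.mod(values + venc, 2.0 * venc) - venc
        n_wrapped = int(np.sum(~np.isclose(wrapped, values, rtol=0.0, atol=1e-12)))
        values = wrapped
    if noise_sd < 0:
        raise ConfigError("noise_sd must be nonnegative")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    report = {"n_wrapped": n_wrapped, "noise_sd": noise_sd, "seed": seed}
    return vel.copy_with(values), report


# ---------------------------------------------------------------------------
# Cohort simulation

#: Group-typical values (medians of each variable) used as simulation
#: centers.  HDF entries are RMS forces in Newton; volumetric entries are
#: BSA-indexed (mL/m^2), EF in %, Qp/Qs dimensionless.
CONTROL_MEDIANS = {
    "age": 10, "height_cm": 142, "weight_kg": 32, "heart_rate_bpm": 75,
    "lv_edvi": 83, "lv_svi": 49, "lv_ef": 57,
    "rv_edvi": 88, "rv_svi": 50, "rv_ef": 57, "qp_qs": 1.03,
    "lv_rms_apex_base_systole": 0.147, "lv_rms_lateral_septal_systole": 0.086,
    "lv_rms_inferior_anterior_systole": 0.031,
    "lv_rms_apex_base_diastole": 0.091, "lv_rms_lateral_septal_diastole": 0.020,
    "lv_rms_inferior_anterior_diastole": 0.022,
    "rv_rms_apex_base_systole": 0.097, "rv_rms_septum_free_wall_systole": 0.038,
    "rv_rms_diaphragm_rvot_systole": 0.125,
    "rv_rms_apex_base_diastole": 0.060, "rv_rms_septum_free_wall_diastole": 0.022,
    "rv_rms_diaphragm_rvot_diastole": 0.026,
}

PREOP_MEDIANS = {
    "age": 8, "height_cm": 138, "weight_kg": 30, "heart_rate_bpm": 83,
    "lv_edvi": 63, "lv_svi": 39, "lv_ef": 60,
    "rv_edvi": 129, "rv_svi": 72, "rv_ef": 58, "qp_qs": 1.79,
    "lv_rms_apex_base_systole": 0.104, "lv_rms_lateral_septal_systole": 0.067,
    "lv_rms_inferior_anterior_systole": 0.024,
    "lv_rms_apex_base_diastole": 0.067, "lv_rms_lateral_septal_diastole": 0.019,
    "lv_rms_inferior_anterior_diastole": 0.026,
    "rv_rms_apex_base_systole": 0.146, "rv_rms_septum_free_wall_systole": 0.064,
    "rv_rms_diaphragm_rvot_systole": 0.169,
    "rv_rms_apex_base_diastole": 0.128, "rv_rms_septum_free_wall_diastole": 0.041,
    "rv_rms_diaphragm_rvot_diastole": 0.050,
}

POSTOP_MEDIANS = {
    "age": 10, "height_cm": 153, "weight_kg": 38, "heart_rate_bpm": 77,
    "lv_edvi": 76, "lv_svi": 47, "lv_ef": 59,
    "rv_edvi": 90, "rv_svi": 49, "rv_ef": 49, "qp_qs": 1.04,
    "lv_rms_apex_base_systole": 0.127, "lv_rms_lateral_septal_systole": 0.092,
    "lv_rms_inferior_anterior_systole": 0.028,
    "lv_rms_apex_base_diastole": 0.089, "lv_rms_lateral_septal_diastole": 0.023,
    "lv_rms_inferior_anterior_diastole": 0.031,
    "rv_rms_apex_base_systole": 0.095, "rv_rms_septum_free_wall_systole": 0.038,
    "rv_rms_diaphragm_rvot_systole": 0.098,
    "rv_rms_apex_base_diastole": 0.071, "rv_rms_septum_free_wall_diastole": 0.026,
    "rv_rms_diaphragm_rvot_diastole": 0.037,
}

HDF_METRICS = [k for k in CONTROL_MEDIANS if k.startswith(("lv_rms", "rv_rms"))]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the simulated pre/post-intervention cohort.

    ``coupling`` is the target correlation between (log) ventricular EDV and
    (log) force metrics of the same ventricle; ``cv_volume`` / ``cv_force``
    are lognormal coefficients of variation; ``paired_shift`` scales the
    baseline -> follow-up change toward the follow-up group centers (1.0
    reproduces the full printed shift, 0.0 removes it for null simulations).
    """

    n_controls: int = 11
    n_patients: int = 21
    missing_follow_up: int = 5
    coupling: float = 0.8
    cv_volume: float = 0.18
    cv_force: float = 0.35
    paired_shift: float = 1.0
    followup_tracking: float = 0.7  # subject-level persistence baseline -> follow-up
    seed: int = 0
    male_controls: int = 6
    male_patients: int = 6

    def __post_init__(self) -> None:
        if self.n_controls < 2 or self.n_patients < 2:
            raise ConfigError("cohort sizes must be >= 2")
        if not 0 <= self.missing_follow_up <= self.n_patients:
            raise ConfigError("missing_follow_up must be in [0, n_patients]")
        if not 0.0 <= self.coupling < 1.0:
            raise ConfigError("coupling must be in [0, 1)")
        if self.cv_volume < 0 or self.cv_force < 0:
            raise ConfigError("coefficients of variation must be nonnegative")


def _subject_rows(rng, sid, group, visit, medians, spec: CohortSpec, z_state=None):
    """One subject-visit row; z_state carries per-ventricle latent volume
    scores so follow-up rows track their baseline."""
    if z_state is None:
        z_vol = {"lv": rng.standard_normal(), "rv": rng.standard_normal()}
    else:
        t = spec.followup_tracking
        z_vol = {
            v: t * z_state[v] + np.sqrt(1.0 - t**2) * rng.standard_normal()
            for v in ("lv", "rv")
        }
    row = {"id": sid, "group": group, "visit": visit}
    row["age"] = max(1.0, medians["age"] + rng.normal(0, 3))
    row["height_cm"] = max(60.0, medians["height_cm"] * np.exp(rng.normal(0, 0.10)))
    row["weight_kg"] = max(8.0, medians["weight_kg"] * np.exp(rng.normal(0, 0.25)))
    row["heart_rate_bpm"] = max(40.0, medians["heart_rate_bpm"] + rng.normal(0, 8))
    for vent in ("lv", "rv"):
        row[f"{vent}_edvi"] = medians[f"{vent}_edvi"] * np.exp(spec.cv_volume * z_vol[vent])
        row[f"{vent}_svi"] = medians[f"{vent}_svi"] * np.exp(
            spec.cv_volume * (0.9 * z_vol[vent] + 0.44 * rng.standard_normal())
        )
        row[f"{vent}_ef"] = float(np.clip(medians[f"{vent}_ef"] + rng.normal(0, 4), 20, 80))
    row["qp_qs"] = max(0.5, medians["qp_qs"] * np.exp(rng.normal(0, 0.10)))
    r = spec.coupling
    for name in HDF_METRICS:
        vent = name[:2]
        z = r * z_vol[vent] + np.sqrt(1.0 - r**2) * rng.standard_normal()
        row[name] = medians[name] * np.exp(spec.cv_force * z)
    return row, z_vol


def simulate_cohort(spec: CohortSpec = CohortSpec()) -> pd.DataFrame:
    """Simulate a control group plus a paired pre/post patient cohort.

    Patients each get a baseline row; all but ``missing_follow_up`` of them
    also get a follow-up row whose group centers move toward the follow-up
    medians by ``paired_shift`` and whose latent volume score tracks the
    baseline.  Force metrics are generated from the same latent volume score
    as the volumetrics, so volume-force correlations are tunable via
    ``coupling``.  Fixed seed => byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(spec.n_controls):
        row, _ = _subject_rows(rng, f"C{i+1:02d}", "control", "baseline",
                               CONTROL_MEDIANS, spec)
        row["sex"] = "m" if i < spec.male_controls else "f"
        rows.append(row)

    followup_ids = set(range(spec.missing_follow_up, spec.n_patients))
    fu_medians = {
        k: PREOP_MEDIANS[k] + spec.paired_shift * (POSTOP_MEDIANS[k] - PREOP_MEDIANS[k])
        for k in PREOP_MEDIANS
    }
    for i in range(spec.n_patients):
        sid = f"P{i+1:02d}"
        base, z = _subject_rows(rng, sid, "patient", "baseline", PREOP_MEDIANS, spec)
        base["sex"] = "m" if i < spec.male_patients else "f"
        rows.append(base)
        if i in followup_ids:
            fu, _ = _subject_rows(rng, sid, "patient", "followup", fu_medians, spec,
                                  z_state=z)
            fu["sex"] = base["sex"]
            rows.append(fu)

    df = pd.DataFrame(rows)
    implied = df.select_dtypes("number")
    if (implied[[c for c in implied.columns if c.endswith(("_edvi", "_svi"))]] <= 0).any().any():
        raise DataError("simulated volumetrics include non-positive values; check spec")
    return df
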