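"""Phase-contrast velocity corrections: VENC aliasing and background offsets.

Phase-contrast MRI encodes velocity in signal phase, so two artifacts
corrupt the velocity field before any force computation is meaningful:

* **Aliasing (wrapping)** — velocities beyond the encoding limit +/-VENC wrap
  around by multiples of 2*VENC.  ``unwrap_phase`` undoes this by temporal
  unwrapping: within each voxel, a jump between successive cardiac frames
  larger than VENC in magnitude is implausible for a periodic flow sampled at
  clinical frame rates and is taken to be a wrap.
* **Residual background phase offsets** — eddy currents and concomitant
  fields leave a spatially smooth, temporally constant velocity offset.
  ``correct_background_phase`` estimates it as a low-order 3D polynomial
  fitted to voxels that contain stationary tissue and subtracts it from
  every frame.

The intended order is unwrap first, then background correction: offsets are
small relative to VENC, while wraps are VENC-scale and would wreck the
polynomial fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np

from .errors import ConfigError, PreprocessingError
from .io import VelocityField

__all__ = [
    "StaticTissueMask",
    "detect_static_tissue",
    "correct_background_phase",
    "unwrap_phase",
    "DEFAULT_STATIC_THRESHOLD_M_S",
    "DEFAULT_POLY_ORDER",
]

#: Temporal-SD threshold below which a voxel counts as stationary tissue.
#: Chosen so that truly static phantom shells are reliably flagged while
#: voxels carrying pulsatile flow (SD of order 0.1 m/s and up) are not.
DEFAULT_STATIC_THRESHOLD_M_S = 0.02

#: Default total degree of the background-offset polynomial.  Scanner
#: background offsets are smooth; a quadratic captures the usual linear plus
#: mildly curved spatial profiles without overfitting sparse static regions.
DEFAULT_POLY_ORDER = 2


@dataclass
class StaticTissueMask:
    """Time-invariant mask of voxels judged to contain stationary tissue."""

    values: np.ndarray  # (nx, ny, nz) bool
    fraction_static: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)


def detect_static_tissue(
    vel: VelocityField, std_threshold_m_s: float = DEFAULT_STATIC_THRESHOLD_M_S
) -> StaticTissueMask:
    """Flag voxels whose velocity barely varies over the cardiac cycle.

    A voxel is static iff the temporal standard deviation of *each* of its
    three velocity components is below ``std_threshold_m_s``.  Blood voxels
    carry pulsatile flow and fail this for at least one component.

    Raises
    ------
    PreprocessingError
        If no voxel qualifies — background correction is then impossible.
    """
    if std_threshold_m_s <= 0:
        raise ConfigError("std_threshold_m_s must be positive")
    sd = vel.values.std(axis=0)  # (nx, ny, nz, 3), population SD over frames
    static = np.all(sd < std_threshold_m_s, axis=-1)
    n_static = int(static.sum())
    if n_static == 0:
        raise PreprocessingError(
            "no static-tissue voxels found below the SD threshold; "
            "background correction is impossible"
        )
    return StaticTissueMask(values=static, fraction_static=n_static / static.size)


def _monomial_basis(coords: np.ndarray, order: int) -> np.ndarray:
    """Design matrix of 3D monomials x^i y^j z^k with total degree <= order.

    ``coords`` is (n, 3) and should be pre-scaled to roughly [-1, 1] for
    conditioning.
    """
    cols = [np.ones(coords.shape[0])]
    for deg in range(1, order + 1):
        for combo in combinations_with_replacement(range(3), deg):
            col = np.ones(coords.shape[0])
            for axis in combo:
                col = col * coords[:, axis]
            cols.append(col)
    return np.column_stack(cols)


def _normalized_coords(shape: tuple[int, int, int]) -> np.ndarray:
    """Voxel-index coordinates mapped to [-1, 1] per axis, shape (nvox, 3)."""
    axes = [
        np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape
    ]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return grid.reshape(-1, 3)


def correct_background_phase(
    vel: VelocityField,
    static_mask: StaticTissueMask,
    poly_order: int = DEFAULT_POLY_ORDER,
) -> tuple[VelocityField, dict]:
    """Fit and subtract a smooth spatial velocity offset per component.

    For each velocity component independently, a 3D polynomial of total
    degree <= ``poly_order`` is least-squares fitted to the *time-averaged*
    velocity over static voxels and subtracted from every frame.  After
    correction the mean static-voxel velocity is ~0.

    Returns the corrected field and a report dict with the fitted
    coefficients (on normalized [-1, 1] voxel coordinates).

    Raises
    ------
    ConfigError
        If ``poly_order`` is not in {1, 2, 3}.
    PreprocessingError
        If there are fewer static voxels than polynomial coefficients.
    """
    if poly_order not in (1, 2, 3):
        raise ConfigError(f"poly_order must be 1, 2 or 3, got {poly_order}")
    static = static_mask.values
    if static.shape != vel.grid_shape:
        raise PreprocessingError("static mask grid does not match the velocity grid")

    coords = _normalized_coords(vel.grid_shape)
    basis_all = _monomial_basis(coords, poly_order)
    flat_static = static.ravel()
    n_static, n_coef = int(flat_static.sum()), basis_all.shape[1]
    if n_static < n_coef:
        raise PreprocessingError(
            f"{n_static} static voxels cannot determine {n_coef} polynomial coefficients"
        )

    tmean = vel.values.mean(axis=0).reshape(-1, 3)  # (nvox, 3)
    a = basis_all[flat_static]
    coeffs, *_ = np.linalg.lstsq(a, tmean[flat_static], rcond=None)
    offset = (basis_all @ coeffs).reshape(*vel.grid_shape, 3)

    corrected = vel.copy_with(vel.values - offset[np.newaxis])
    report = {
        "poly_order": poly_order,
        "n_static_voxels": n_static,
        "coefficients": coeffs.T.tolist(),  # per component
        "residual_static_mean_m_s": (
            corrected.values.mean(axis=0).reshape(-1, 3)[flat_static].mean(axis=0).tolist()
        ),
    }
    return corrected, report


def unwrap_phase(vel: VelocityField) -> tuple[VelocityField, dict]:
    """Undo VENC aliasing by temporal unwrapping, voxel by voxel.

    Successive frame differences with magnitude > VENC trigger addition of
    the multiple of 2*VENC that restores continuity.  This recovers the true
    velocity wherever |v_true| < 2*VENC and the true inter-frame change stays
    below VENC; a dataset with no super-VENC excursion passes through
    unchanged.

    Returns the unwrapped field and a wrap-count report.
    """
    venc = vel.venc_m_s
    unwrapped = np.unwrap(vel.values, axis=0, period=2.0 * venc)
    changed = ~np.isclose(unwrapped, vel.values, rtol=0.0, atol=1e-12)
    report = {
        "venc_m_s": venc,
        "n_samples_changed": int(changed.sum()),
        "fraction_changed": float(changed.mean()),
    }
    return vel.copy_with(unwrapped), report
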