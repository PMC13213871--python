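"""Navier-Stokes force computation against closed-form and brute-force oracles."""

import numpy as np
import pytest

from hemoforce import (
    Annotation,
    FluidConstants,
    ForceTrace,
    Mask4D,
    VelocityField,
    build_axes,
    decompose_force,
    integrate_force,
    phase_metrics,
    pressure_gradient_field,
    resample_to_reference,
)
from hemoforce.errors import DataError
from hemoforce.synthetic import PhantomSpec, _sinc_factor, make_phantom


def _brute_force_sum(grad_values, mask_values, voxel_m3):
    """Independent naive triple-loop volume integral."""
    nt = grad_values.shape[0]
    out = np.zeros((nt, 3))
    for t in range(nt):
        for i in range(grad_values.shape[1]):
            for j in range(grad_values.shape[2]):
                for k in range(grad_values.shape[3]):
                    if mask_values[t, i, j, k]:
                        out[t] += grad_values[t, i, j, k] * voxel_m3
    return out


class TestPressureGradientField:
    def test_uniform_sinusoid_matches_cyclic_difference_closed_form(self):
        # spatially uniform v(t) = A sin(2 pi t / T) x-hat: convective and
        # viscous terms vanish; the cyclic central difference of a sampled
        # sinusoid carries the sin(w)/w attenuation factor.
        A, T, nt, n = 0.4, 1.0, 25, 8
        rho = 1060.0
        values = np.zeros((nt, n, n, n, 3))
        phases = 2 * np.pi * np.arange(nt) / nt
        values[..., 0] = A * np.sin(phases)[:, None, None, None]
        vel = VelocityField(values, [2.2, 2.2, 2.5], T / nt * 1e3, 150.0)
        grad = pressure_gradient_field(vel, FluidConstants(rho=rho), keep_terms=True)
        expected = -rho * A * (2 * np.pi / T) * np.cos(phases) * _sinc_factor(nt)
        np.testing.assert_allclose(
            grad.values[..., 0],
            np.broadcast_to(expected[:, None, None, None], grad.values[..., 0].shape),
            rtol=1e-10,
        )
        np.testing.assert_allclose(grad.values[..., 1:], 0.0, atol=1e-12)
        np.testing.assert_allclose(grad.terms["convective"], 0.0, atol=1e-12)
        np.testing.assert_allclose(grad.terms["viscous"], 0.0, atol=1e-12)

    def test_poiseuille_interior_gradient_is_exact(self, poiseuille_phantom):
        # central second differences are exact on the quadratic profile, so
        # the interior z-gradient equals -4 mu v_max / R^2 to round-off
        vel, mask, _, oracle = poiseuille_phantom
        grad = pressure_gradient_field(vel, FluidConstants())
        interior = mask.values[0]
        gz = grad.values[0][interior][:, 2]
        np.testing.assert_allclose(gz, oracle.gradient_pa_m[2], rtol=1e-9)
        np.testing.assert_allclose(grad.values[0][interior][:, :2], 0.0, atol=1e-9)

    def test_constant_field_gives_zero_gradient(self):
        values = np.full((5, 6, 6, 6, 3), 0.3)
        vel = VelocityField(values, [2, 2, 2], 40.0, 150.0)
        grad = pressure_gradient_field(vel)
        np.testing.assert_allclose(grad.values, 0.0, atol=1e-12)

    def test_fewer_than_three_frames_rejected(self):
        vel = VelocityField(np.zeros((2, 4, 4, 4, 3)), [2, 2, 2], 40.0, 150.0)
        with pytest.raises(DataError):
            pressure_gradient_field(vel)


class TestIntegrateForce:
    def test_uniform_oscillation_peak_matches_closed_form(self, oscillation_phantom):
        vel, mask, _, oracle = oscillation_phantom
        grad = pressure_gradient_field(vel)
        trace = integrate_force(grad, mask)
        peak = np.abs(trace.raw).max()
        assert peak == pytest.approx(oracle.peak_force_n, rel=0.005)
        # closed-form magnitude at the acquisition scale: ~0.33 N per 100 mL
        assert oracle.peak_force_n == pytest.approx(
            1060 * oracle.mask_volume_m3 * 0.5 * 2 * np.pi * _sinc_factor(25), rel=1e-12
        )

    def test_matches_brute_force_triple_loop(self, rng):
        values = rng.normal(0, 0.2, size=(4, 6, 6, 6, 3))
        vel = VelocityField(values, [2.0, 2.0, 2.5], 40.0, 150.0)
        mask = Mask4D(rng.random((4, 6, 6, 6)) < 0.5)
        grad = pressure_gradient_field(vel)
        trace = integrate_force(grad, mask)
        oracle = _brute_force_sum(grad.values, mask.values, vel.voxel_volume_m3)
        np.testing.assert_allclose(trace.raw, oracle, rtol=1e-10, atol=1e-18)

    def test_mask_additivity_is_exact(self, rng):
        values = rng.normal(0, 0.2, size=(3, 8, 8, 8, 3))
        vel = VelocityField(values, [2.0, 2.0, 2.5], 40.0, 150.0)
        grad = pressure_gradient_field(vel)
        whole = rng.random((3, 8, 8, 8)) < 0.6
        whole[:, 4, 4, 4] = True
        whole[:, 4, 4, 5] = True
        part = rng.random((3, 8, 8, 8)) < 0.5
        part[:, 4, 4, 4] = True
        part[:, 4, 4, 5] = False
        a = whole & part
        b = whole & ~part
        fa = integrate_force(grad, Mask4D(a)).raw
        fb = integrate_force(grad, Mask4D(b)).raw
        fw = integrate_force(grad, Mask4D(whole)).raw
        np.testing.assert_allclose(fa + fb, fw, rtol=0, atol=1e-15)

    def test_solid_rotation_force_cancels(self, rotation_phantom):
        vel, mask, _, _ = rotation_phantom
        grad = pressure_gradient_field(vel)
        trace = integrate_force(grad, mask)
        abs_integral = np.array(
            [
                np.linalg.norm(grad.values[t], axis=-1)[mask.values[t]].sum()
                * vel.voxel_volume_m3
                for t in range(vel.n_frames)
            ]
        )
        assert (np.linalg.norm(trace.raw, axis=1) < 0.01 * abs_integral).all()

    def test_poiseuille_force_matches_viscous_closed_form(self, poiseuille_phantom):
        vel, mask, _, oracle = poiseuille_phantom
        grad = pressure_gradient_field(vel)
        trace = integrate_force(grad, mask)
        # F_z = -4 mu v_max / R^2 * V on the eroded interior
        expected = -4 * 4e-3 * 1.0 / 0.01**2 * oracle.mask_volume_m3
        np.testing.assert_allclose(trace.raw[:, 2], expected, rtol=0.05)
        np.testing.assert_allclose(trace.raw[:, 2], oracle.force_trace_n[:, 2], rtol=1e-9)

    def test_temporal_linearity_on_oscillation_phantom(self):
        spec = PhantomSpec(kind="uniform_oscillation", grid=(16, 16, 16),
                           mask_volume_ml=20.0)
        vel, mask, _, _ = make_phantom(spec)
        double = vel.copy_with(2.0 * vel.values)
        f1 = integrate_force(pressure_gradient_field(vel), mask).raw
        f2 = integrate_force(pressure_gradient_field(double), mask).raw
        np.testing.assert_allclose(f2, 2.0 * f1, rtol=1e-12, atol=1e-15)

    def test_grid_refinement_converges_to_continuum_force(self):
        """Peak-force error vs the continuum closed form (target mask volume,
        no discrete-derivative factor in the volume) shrinks monotonically
        as the grid is refined at fixed field of view."""
        errors = []
        for n, sp in [(16, (4.4, 4.4, 5.0)), (32, (2.2, 2.2, 2.5)),
                      (64, (1.1, 1.1, 1.25))]:
            spec = PhantomSpec(kind="uniform_oscillation", grid=(n, n, n),
                               spacing_mm=sp, mask_volume_ml=100.0)
            vel, mask, _, _ = make_phantom(spec)
            trace = integrate_force(pressure_gradient_field(vel), mask)
            continuum = 1060 * 100e-6 * 0.5 * 2 * np.pi * _sinc_factor(25)
            errors.append(abs(np.abs(trace.raw).max() - continuum) / continuum)
        assert errors[0] > errors[1] > errors[2]

    def test_empty_mask_frame_zero_force_with_warning(self, rng):
        values = rng.normal(0, 0.1, size=(3, 6, 6, 6, 3))
        vel = VelocityField(values, [2, 2, 2], 40.0, 150.0)
        m = np.ones((3, 6, 6, 6), dtype=bool)
        m[1] = False
        grad = pressure_gradient_field(vel)
        with pytest.warns(UserWarning, match="frame 1"):
            trace = integrate_force(grad, Mask4D(m))
        np.testing.assert_array_equal(trace.raw[1], 0.0)

    def test_noisy_phantom_peak_recovered_within_10pct(self):
        # SNR 20 dB: noise SD one tenth of the velocity amplitude
        vel, mask, _, oracle = make_phantom(PhantomSpec(kind="uniform_oscillation"))
        noisy = vel.copy_with(
            vel.values + np.random.default_rng(11).normal(0, 0.05, vel.values.shape)
        )
        trace = integrate_force(pressure_gradient_field(noisy), mask)
        peak = np.abs(trace.raw).max()
        assert peak == pytest.approx(oracle.peak_force_n, rel=0.10)


class TestDecomposeForce:
    def _triad(self):
        return build_axes(Annotation([0, 0, 0], [0, 0, 1], [1, 0, 1], 10), "LV")

    def test_canonical_decomposition(self):
        triad = build_axes(Annotation([0, 0, 0], [1, 0, 0], [0, 1, 0], 10), "LV")
        trace = ForceTrace(raw=np.array([[3.0, 4.0, 0.0]]), frame_duration_ms=40.0)
        trace = decompose_force(trace, triad)
        np.testing.assert_allclose(trace.decomposed, [[3.0, 4.0, 0.0]])
        assert np.linalg.norm(trace.decomposed) == pytest.approx(5.0)

    def test_rotated_triad_moves_component(self):
        # triad rotated 90 degrees about z: x-force appears on the second axis
        triad = build_axes(Annotation([0, 0, 0], [0, 0, 1], [1, 0, 0], 10), "LV")
        trace = ForceTrace(raw=np.array([[1.0, 0.0, 0.0]]), frame_duration_ms=40.0)
        trace = decompose_force(trace, triad)
        np.testing.assert_allclose(trace.decomposed, [[0.0, 1.0, 0.0]], atol=1e-12)

    def test_energy_conserved_for_random_triads(self, rng):
        for _ in range(1000):
            n, l = rng.normal(size=3), rng.normal(size=3)
            denom = np.linalg.norm(n) * np.linalg.norm(l)
            if denom == 0 or abs(n @ l) / denom >= 0.99:
                continue
            triad = build_axes(Annotation([0, 0, 0], n, l, 5))
            f = rng.normal(size=(4, 3))
            trace = decompose_force(ForceTrace(raw=f, frame_duration_ms=40.0), triad)
            np.testing.assert_allclose(
                (trace.decomposed**2).sum(axis=1), (f**2).sum(axis=1), rtol=1e-12
            )


class TestResampleToReference:
    def _trace(self, signal):
        return ForceTrace(raw=np.asarray(signal, float), frame_duration_ms=40.0)

    def test_identity_when_es_already_at_40pct(self):
        n = 25
        sig = np.column_stack(
            [np.sin(2 * np.pi * np.arange(n) / n), np.zeros(n), np.zeros(n)]
        )
        out = resample_to_reference(self._trace(sig), es_frame=10, n_ref=25)
        np.testing.assert_allclose(out.reference, sig, atol=1e-12)

    def test_constant_signal_stays_constant(self):
        out = resample_to_reference(self._trace(np.full((20, 3), 0.3)), es_frame=5,
                                    n_ref=100)
        np.testing.assert_allclose(out.reference, 0.3, atol=1e-14)

    def test_es_sample_lands_at_fraction_040(self):
        n = 25
        rng = np.random.default_rng(4)
        sig = rng.normal(size=(n, 3))
        es = 5  # end systole at 20% of the original cycle
        out = resample_to_reference(self._trace(sig), es_frame=es, n_ref=100)
        np.testing.assert_allclose(out.reference[40], sig[es], atol=1e-12)

    def test_out_of_range_es_frame_rejected(self):
        with pytest.raises(DataError):
            resample_to_reference(self._trace(np.zeros((10, 3))), es_frame=10)


class TestPhaseMetrics:
    def _ref_trace(self, reference, labels=("apex_base", "lateral_septal",
                                            "inferior_anterior")):
        t = ForceTrace(raw=np.zeros((5, 3)), frame_duration_ms=40.0)
        t.reference = np.asarray(reference, float)
        t.labels = labels
        return t

    def test_constant_signal_metrics(self):
        ref = np.zeros((100, 3))
        ref[:, 0] = 0.1
        m = phase_metrics(self._ref_trace(ref))
        assert m.rms["apex_base"]["systole"] == pytest.approx(0.1)
        assert m.rms["apex_base"]["diastole"] == pytest.approx(0.1)
        assert m.peak["apex_base"]["systole"] == pytest.approx(0.1)

    def test_sinusoid_rms_approaches_a_over_sqrt2(self):
        # 5 cycles per reference cycle: integer periods in both phases
        n_ref, A = 1000, 0.2
        u = np.arange(n_ref) / n_ref
        ref = np.zeros((n_ref, 3))
        ref[:, 1] = A * np.sin(2 * np.pi * 5 * u)
        m = phase_metrics(self._ref_trace(ref))
        assert m.rms["lateral_septal"]["systole"] == pytest.approx(A / np.sqrt(2), rel=0.01)
        assert m.rms["lateral_septal"]["diastole"] == pytest.approx(A / np.sqrt(2), rel=0.01)

    def test_signal_confined_to_systole(self):
        ref = np.zeros((100, 3))
        ref[:40, 2] = 0.05
        m = phase_metrics(self._ref_trace(ref))
        assert m.rms["inferior_anterior"]["diastole"] == 0.0
        assert m.rms["inferior_anterior"]["systole"] == pytest.approx(0.05)
        assert m.peak["inferior_anterior"]["systole"] >= m.rms["inferior_anterior"]["systole"]
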