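"""Axis construction, mask resampling and volumetrics."""

import numpy as np
import pytest

from hemoforce import (
    Annotation,
    GeometryError,
    Grid,
    Mask4D,
    build_axes,
    compute_volumes,
    derived_indices,
    mosteller_bsa,
    resample_mask_to_flow,
)
from hemoforce.errors import DataError
from hemoforce.geometry import AXIS_LABELS


class TestBuildAxes:
    def test_gram_schmidt_on_canonical_vectors(self):
        ann = Annotation([0, 0, 0], [0, 0, 1], [1, 0, 1], 10)
        triad = build_axes(ann, "LV")
        np.testing.assert_allclose(triad.e1, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(triad.e2, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(triad.e3, [0, 1, 0], atol=1e-12)

    def test_orthogonal_lvot_passes_through(self):
        ann = Annotation([0, 0, 0], [0, 0, 1], [0, 2, 0], 10)
        triad = build_axes(ann)
        np.testing.assert_allclose(triad.e2, [0, 1, 0], atol=1e-12)

    def test_parallel_inputs_raise_geometry_error(self):
        with pytest.raises(GeometryError):
            Annotation([0, 0, 0], [0, 0, 1], [0, 0, -1], 10)

    def test_rv_uses_same_vectors_different_labels(self):
        ann = Annotation([0, 0, 0], [0, 0, 1], [1, 0, 1], 10)
        lv, rv = build_axes(ann, "LV"), build_axes(ann, "RV")
        np.testing.assert_array_equal(lv.matrix, rv.matrix)
        assert lv.labels == AXIS_LABELS["LV"]
        assert rv.labels == ("apex_base", "septum_free_wall", "diaphragm_rvot")

    def test_orthonormal_right_handed_for_random_annotations(self, rng):
        """Property: 1000 random valid annotations all yield an exact
        right-handed orthonormal triad."""
        count = 0
        while count < 1000:
            n, l = rng.normal(size=3), rng.normal(size=3)
            nn = np.linalg.norm(n) * np.linalg.norm(l)
            if nn == 0 or abs(n @ l) / nn >= 0.99:
                continue
            triad = build_axes(Annotation([0, 0, 0], n, l, 5))
            m = triad.matrix
            np.testing.assert_allclose(m @ m.T, np.eye(3), atol=1e-10)
            np.testing.assert_allclose(np.cross(triad.e1, triad.e2), triad.e3, atol=1e-12)
            count += 1


class TestResampleMask:
    def _cuboid_mask(self, shape, lo, hi, n_frames=4):
        values = np.zeros((n_frames, *shape), dtype=bool)
        values[:, lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        return Mask4D(values)

    def test_identity_resampling(self):
        g = Grid((16, 16, 16), [2.0, 2.0, 2.0], [0, 0, 0], np.eye(3))
        mask = self._cuboid_mask((16, 16, 16), (4, 4, 4), (12, 12, 12))
        out = resample_mask_to_flow(mask, g, g, 4)
        np.testing.assert_array_equal(out.values, mask.values)

    def test_upsampling_preserves_cuboid_volume_within_5pct(self):
        coarse = Grid((16, 16, 16), [4.0, 4.0, 4.0], [0, 0, 0], np.eye(3))
        # cell-centered alignment: fine voxel centers offset half a fine
        # voxel so the 0.5 level set does not sit exactly on sample points
        fine = Grid((32, 32, 32), [2.0, 2.0, 2.0], [1.0, 1.0, 1.0], np.eye(3))
        mask = self._cuboid_mask((16, 16, 16), (4, 4, 4), (12, 12, 12), n_frames=2)
        out = resample_mask_to_flow(mask, coarse, fine, 2)
        analytic_ml = (8 * 4.0) ** 3 * 1e-3  # cuboid edge 8 coarse voxels
        vol = out.volume_ml(fine.spacing_mm)[0]
        assert abs(vol - analytic_ml) / analytic_ml < 0.05

    def test_temporal_nearest_cycle_fraction_rule(self):
        g = Grid((4, 4, 4), [1, 1, 1], [0, 0, 0], np.eye(3))
        n_cine, n_flow = 30, 25
        values = np.zeros((n_cine, 4, 4, 4), dtype=bool)
        for k in range(n_cine):  # frame index encoded in voxel count
            values[k, 0, 0, : (k % 4) + 1] = True
        values[:, 3, 3, 3] = True  # keep every frame non-empty
        mask = Mask4D(values)
        out = resample_mask_to_flow(mask, g, g, n_flow)
        for k in range(n_flow):
            src = int(round(n_cine * k / n_flow)) % n_cine
            np.testing.assert_array_equal(out.values[k], mask.values[src])

    def test_disjoint_fov_raises(self):
        a = Grid((8, 8, 8), [1, 1, 1], [0, 0, 0], np.eye(3))
        b = Grid((8, 8, 8), [1, 1, 1], [1000, 1000, 1000], np.eye(3))
        mask = self._cuboid_mask((8, 8, 8), (2, 2, 2), (6, 6, 6))
        with pytest.raises(GeometryError):
            resample_mask_to_flow(mask, a, b, 4)


class TestVolumetrics:
    def test_flat_curve_gives_zero_sv_and_ef(self):
        values = np.zeros((5, 12, 12, 12), dtype=bool)
        values[:, :10, :10, :10] = True  # 1000 voxels every frame
        curve, vol = compute_volumes(Mask4D(values), np.array([2.0, 2.0, 2.5]))
        np.testing.assert_allclose(curve, 10.0)
        assert vol.sv == 0.0 and vol.ef == 0.0

    def test_edv_esv_derivations(self):
        # EDV 100 mL / ESV 40 mL built from voxel counts at 10 mm^3 each
        values = np.zeros((2, 25, 25, 25), dtype=bool)
        values[0].ravel()[:10000] = True
        values[1].ravel()[:4000] = True
        curve, vol = compute_volumes(Mask4D(values), np.array([2.0, 2.0, 2.5]))
        assert vol.edv == pytest.approx(100.0)
        assert vol.esv == pytest.approx(40.0)
        assert vol.sv == pytest.approx(60.0)
        assert vol.ef == pytest.approx(60.0)

    def test_random_mask_matches_counting_oracle(self, rng):
        values = rng.random((6, 9, 9, 9)) < 0.3
        values[:, 4, 4, 4] = True
        curve, vol = compute_volumes(Mask4D(values), np.array([2.0, 2.0, 2.5]))
        # independent brute-force voxel count, 10 mm^3 per voxel
        for t in range(6):
            n = sum(
                1
                for i in range(9)
                for j in range(9)
                for k in range(9)
                if values[t, i, j, k]
            )
            assert curve[t] == pytest.approx(n * 10.0 * 1e-3)
        assert vol.edv - vol.esv - vol.sv == 0.0

    def test_volume_conservation_and_index_round_trip(self):
        values = np.zeros((2, 10, 10, 10), dtype=bool)
        values[0, :6, :6, :6] = True
        values[1, :4, :4, :4] = True
        _, vol = compute_volumes(Mask4D(values), np.array([2.0, 2.0, 2.5]))
        vol = derived_indices(vol, bsa=1.3)
        assert vol.edv - vol.esv - vol.sv == 0.0
        assert vol.edvi * vol.bsa == pytest.approx(vol.edv, rel=1e-12)


class TestMostellerAndIndices:
    @pytest.mark.parametrize(
        "height,weight,expected",
        [(180.0, 80.0, 2.00), (142.0, 32.0, 1.12), (138.0, 30.0, 1.07)],
    )
    def test_mosteller_worked_examples(self, height, weight, expected):
        assert mosteller_bsa(height, weight) == pytest.approx(expected, abs=0.005)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(DataError):
            mosteller_bsa(-1.0, 50.0)

    def test_cardiac_index_worked_example(self):
        vol = _vol(sv=49.0, edv=90.0)
        vol = derived_indices(vol, bsa=1.0, heart_rate_bpm=75.0)
        assert vol.cardiac_index == pytest.approx(3.7, abs=0.05)

    @pytest.mark.parametrize("rv,lv,expected", [(50.0, 50.0, 1.0), (90.0, 45.0, 2.0)])
    def test_qp_qs(self, rv, lv, expected):
        vol = derived_indices(_vol(), bsa=1.0, lv_sv=lv, rv_sv=rv)
        assert vol.qp_qs == pytest.approx(expected)

    def test_qp_qs_scale_invariant(self):
        a = derived_indices(_vol(), bsa=1.0, lv_sv=45.0, rv_sv=90.0).qp_qs
        b = derived_indices(_vol(), bsa=1.0, lv_sv=4.5, rv_sv=9.0).qp_qs
        assert a == pytest.approx(b, rel=1e-12)


def _vol(sv=50.0, edv=100.0):
    from hemoforce import Volumetrics

    return Volumetrics(edv=edv, esv=edv - sv, sv=sv, ef=100.0 * sv / edv)
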