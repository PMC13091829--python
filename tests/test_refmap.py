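import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from renaldwi.directions import DIRECTIONS_12
from renaldwi.io import AcquisitionScheme, DwiSeries
from renaldwi.ivim import STATUS_FAILED, signal_model
from renaldwi.refmap import (
    compute_fa,
    fit_per_direction,
    fit_tensor,
    project_pseudodiffusion,
    refmap_maps,
)
from renaldwi.synthetic import PhantomConfig, make_phantom, synthesize_dwi

B_STUDY = np.array([0, 10, 30, 50, 70, 80, 100, 120, 200, 400, 600, 800]) / 1000.0


def axisym_projections(evals, axis, dirs):
    evals = np.asarray(evals, dtype=float)
    frame = np.linalg.qr(np.column_stack([axis, np.eye(3)[:, :2]]))[0]
    return ((dirs @ frame) ** 2) @ evals, frame


class TestComputeFa:
    @pytest.mark.parametrize(
        "lam, expected",
        [((2.0, 2.0, 2.0), 0.0), ((1.0, 0.0, 0.0), 1.0), ((2.44, 1.61, 1.61), 0.2487)],
    )
    def test_closed_forms(self, lam, expected):
        assert compute_fa(*lam) == pytest.approx(expected, abs=5e-4)

    def test_scale_invariance(self):
        assert compute_fa(2.44, 1.61, 1.61) == pytest.approx(
            compute_fa(24.4, 16.1, 16.1), abs=1e-12
        )

    def test_all_zero_flagged(self):
        assert np.isnan(compute_fa(0.0, 0.0, 0.0))


class TestFitTensor:
    def test_isotropic(self):
        tf = fit_tensor(np.full(12, 2.0), DIRECTIONS_12)
        assert tf.MD == pytest.approx(2.0, abs=1e-12)
        assert tf.FA == pytest.approx(0.0, abs=1e-9)
        assert tf.Dtax == pytest.approx(2.0, abs=1e-9)
        assert tf.Dtrad == pytest.approx(2.0, abs=1e-9)

    def test_exact_anisotropic_recovery(self):
        d_j, _ = axisym_projections([2.44, 1.61, 1.61], np.array([0.0, 0, 1]), DIRECTIONS_12)
        tf = fit_tensor(d_j, DIRECTIONS_12)
        np.testing.assert_allclose(tf.evals, [2.44, 1.61, 1.61], atol=1e-10)
        assert tf.FA == pytest.approx(0.2487, abs=5e-4)
        # MD identity holds to machine precision
        assert tf.MD == pytest.approx((tf.Dtax + 2 * tf.Dtrad) / 3, abs=1e-15)

    def test_residual_zero_on_tensor_consistent_input(self, rng):
        A = rng.normal(size=(3, 3))
        D = A @ A.T / 3
        d_j = np.einsum("ji,jk,ki->i", DIRECTIONS_12.T, D, DIRECTIONS_12.T)
        tf = fit_tensor(d_j, DIRECTIONS_12)
        recon = np.einsum("ji,jk,ki->i", DIRECTIONS_12.T, tf.tensor, DIRECTIONS_12.T)
        np.testing.assert_allclose(recon, d_j, atol=1e-10)

    def test_rotation_equivariance(self, rng):
        R = Rotation.from_rotvec([0.3, -0.5, 0.9]).as_matrix()
        d_j, frame = axisym_projections([2.5, 1.4, 1.0], np.array([0.0, 0, 1]), DIRECTIONS_12)
        tf = fit_tensor(d_j, DIRECTIONS_12)
        # rotate directions and the underlying tensor together
        d_rot = ((DIRECTIONS_12 @ R.T @ frame) ** 2) @ np.array([2.5, 1.4, 1.0])
        tf_rot = fit_tensor(d_rot, DIRECTIONS_12 @ R.T)
        np.testing.assert_allclose(tf.evals, tf_rot.evals, atol=1e-9)
        assert tf.FA == pytest.approx(tf_rot.FA, abs=1e-9)

    def test_insufficient_directions_invalid(self):
        tf = fit_tensor(np.full(5, 2.0), DIRECTIONS_12[:5])
        assert not tf.valid

    def test_negative_eigenvalue_clamped(self):
        d_j, _ = axisym_projections([2.0, 0.5, -0.2], np.array([0.0, 0, 1]), DIRECTIONS_12)
        tf = fit_tensor(d_j, DIRECTIONS_12)
        assert tf.clamped
        assert np.all(tf.evals >= 0)


class TestProjectPseudodiffusion:
    def test_isotropic_constant(self):
        dp_ax, dp_rad, dp = project_pseudodiffusion(
            np.full(12, 33.0), DIRECTIONS_12, np.eye(3)
        )
        assert dp_ax == pytest.approx(33.0, abs=1e-9)
        assert dp_rad == pytest.approx(33.0, abs=1e-9)
        assert dp == pytest.approx(33.0, abs=1e-9)

    def test_exact_amplitude_recovery(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        dp_j = ((DIRECTIONS_12 @ q) ** 2) @ np.array([60.0, 20.0, 20.0])
        dp_ax, dp_rad, dp = project_pseudodiffusion(dp_j, DIRECTIONS_12, q)
        assert dp_ax == pytest.approx(60.0, abs=1e-9)
        assert dp_rad == pytest.approx(20.0, abs=1e-9)
        assert dp == pytest.approx((60 + 2 * 20) / 3, abs=1e-9)

    def test_minor_axis_permutation_invariance(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        dp_j = ((DIRECTIONS_12 @ q) ** 2) @ np.array([55.0, 30.0, 12.0])
        _, rad_a, _ = project_pseudodiffusion(dp_j, DIRECTIONS_12, q)
        q_perm = q[:, [0, 2, 1]]
        _, rad_b, _ = project_pseudodiffusion(dp_j, DIRECTIONS_12, q_perm)
        assert rad_a == pytest.approx(rad_b, abs=1e-9)

    def test_too_few_defined_directions(self):
        dp_j = np.full(12, np.nan)
        dp_j[:4] = 30.0
        out = project_pseudodiffusion(dp_j, DIRECTIONS_12, np.eye(3))
        assert all(np.isnan(v) for v in out)


class TestPerDirection:
    @staticmethod
    def _series_from_voxel(signals_per_direction):
        """1-voxel series from per-direction signal curves (11 b + shared b0)."""
        sch = AcquisitionScheme.study_scheme("bipolar", "diastole")
        data = np.zeros((1, 1, 1, len(sch)))
        b = sch.b_ms_um2
        data[0, 0, 0, b == 0] = 1000.0
        for j, g in enumerate(DIRECTIONS_12):
            sel = (b > 0) & np.all(np.abs(sch.bvecs - g) < 1e-12, axis=1)
            data[0, 0, 0, sel] = signals_per_direction[j][np.argsort(b[sel])]
        return DwiSeries(data, sch)

    def test_isotropic_voxel_uniform_dt(self):
        bnz = np.sort(B_STUDY[B_STUDY > 0])
        sig = [signal_model(bnz, 1000.0, 0.15, 2.0, 30.0) for _ in range(12)]
        series = self._series_from_voxel(sig)
        out, dirs = fit_per_direction(series, np.ones((1, 1, 1), bool))
        dt = out["Dt_j"][0, 0, 0]
        assert np.all(np.abs(dt - dt.mean()) < 1e-6)

    def test_tensor_consistent_dt_per_direction(self):
        d_g, _ = axisym_projections([2.44, 1.61, 1.61], np.array([0.0, 0, 1]), DIRECTIONS_12)
        bnz = np.sort(B_STUDY[B_STUDY > 0])
        sig = [signal_model(bnz, 1000.0, 0.15, d_g[j], 40.0) for j in range(12)]
        series = self._series_from_voxel(sig)
        out, dirs = fit_per_direction(series, np.ones((1, 1, 1), bool))
        # map back to the test's direction order
        for j, g in enumerate(DIRECTIONS_12):
            k = int(np.argmin(np.linalg.norm(dirs - g, axis=1)))
            assert out["Dt_j"][0, 0, 0, k] == pytest.approx(d_g[j], rel=1e-3)

    def test_corrupted_direction_isolated(self):
        bnz = np.sort(B_STUDY[B_STUDY > 0])
        sig = [signal_model(bnz, 1000.0, 0.15, 2.0, 30.0) for _ in range(12)]
        sig[3] = np.zeros_like(bnz)
        series = self._series_from_voxel(sig)
        out, dirs = fit_per_direction(series, np.ones((1, 1, 1), bool))
        k = int(np.argmin(np.linalg.norm(dirs - DIRECTIONS_12[3], axis=1)))
        status = out["status_j"][0, 0, 0]
        assert status[k] == STATUS_FAILED
        assert np.sum(status == STATUS_FAILED) == 1


class TestRefmapMaps:
    def test_noiseless_round_trip(self, small_phantom, noiseless_series):
        _, maps_truth = small_phantom
        ms = maps_truth.mask_set()
        mask = ms.tissue("cortex") | ms.tissue("medulla")
        out, qc = refmap_maps(noiseless_series, mask)
        q = maps_truth.quadrants[("bipolar", "diastole")]
        truth = {
            "MD": q.md(),
            "FA": q.fa(),
            "Dtax": q.evals[..., 0],
            "Dtrad": q.evals[..., 1:].mean(-1),
            "f": q.fp,
            "Dp": q.pevals.mean(-1),
            "Dpax": q.pevals[..., 0],
            "Dprad": q.pevals[..., 1:].mean(-1),
        }
        for name, tr in truth.items():
            rel = np.abs(out[name][mask] - tr[mask]) / np.abs(tr[mask])
            assert np.nanmax(rel) < 1e-2, name

    def test_deterministic(self, noiseless_series, small_phantom):
        _, maps_truth = small_phantom
        mask = maps_truth.mask_set().tissue("medulla")
        a, _ = refmap_maps(noiseless_series, mask)
        b, _ = refmap_maps(noiseless_series, mask)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_exact_identities_hold(self, small_phantom, noiseless_series):
        _, maps_truth = small_phantom
        mask = maps_truth.mask_set().tissue("medulla")
        out, _ = refmap_maps(noiseless_series, mask)
        ok = np.isfinite(out["Dp"])
        np.testing.assert_allclose(
            out["MD"][mask], (out["Dtax"] + 2 * out["Dtrad"])[mask] / 3, atol=1e-12
        )
        np.testing.assert_allclose(
            out["Dp"][ok], (out["Dpax"] + 2 * out["Dprad"])[ok] / 3, atol=1e-12
        )

    def test_cortex_fa_below_medulla_fa_default_phantom(self):
        cfg = PhantomConfig(shape=(20, 20, 1), semi_axes=(8.5, 6.0), seed=8)
        truth = make_phantom(cfg)
        sch = AcquisitionScheme.study_scheme("bipolar", "diastole")
        series = synthesize_dwi(truth, sch, 0.0)
        ms = truth.mask_set()
        out, _ = refmap_maps(series, ms.tissue("cortex") | ms.tissue("medulla"))
        fa_c = np.nanmean(out["FA"][ms.tissue("cortex")])
        fa_m = np.nanmean(out["FA"][ms.tissue("medulla")])
        assert fa_c < fa_m
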