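"""Reconstruction operators, calibration, coil compression, ADMM solver."""

import numpy as np
import pytest

import xdflow as x
from xdflow.containers import AcquisitionTable
from xdflow.gating import BinSpec, WeightedBinnedData
from xdflow.recon import (BinnedOperator, FiniteDifference, ReconConfig,
                          WaveletTransform, calibrate_sensitivities,
                          coil_compress, espirit_maps, fft2c,
                          fit_coil_compressor, lowres_maps, objective,
                          project_calibration, solve)


def _binned(ky, kz, values, weights, grid=(16, 16), n_t=1, n_c=1, n_r=1,
            bins=None):
    m = len(ky)
    bt = np.zeros(m, int) if bins is None else np.asarray(bins[0])
    bc = np.zeros(m, int) if bins is None else np.asarray(bins[1])
    br = np.zeros(m, int) if bins is None else np.asarray(bins[2])
    return WeightedBinnedData(
        bin_t=bt, bin_c=bc, bin_r=br, echo=np.zeros(m, int),
        ky=np.asarray(ky), kz=np.asarray(kz),
        values=np.asarray(values, complex), weights=np.asarray(weights, float),
        spec=BinSpec(n_t=n_t, n_c=n_c, n_r=n_r),
        attrs={"grid": list(grid)})


def _full_grid(n):
    yy, zz = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return yy.ravel(), zz.ravel()


class TestOperators:
    def test_adjoint_identity(self, rng):
        n, n_coil = 16, 4
        maps = x.generate_coil_maps((n, n), n_coil)
        ky, kz = _full_grid(n)
        sel = rng.choice(n * n, 90, replace=False)
        binned = _binned(ky[sel], kz[sel],
                         rng.standard_normal((90, n_coil)) + 0j,
                         rng.uniform(0.1, 1, 90), grid=(n, n))
        op = BinnedOperator(binned, maps)
        u = rng.standard_normal(op.shape) + 1j * rng.standard_normal(op.shape)
        v = [rng.standard_normal((90, n_coil)) * (1 + 1j)]
        lhs = np.vdot(np.concatenate([a.ravel() for a in op.forward(u)]),
                      np.concatenate([b.ravel() for b in v]))
        rhs = np.vdot(u, op.adjoint(v))
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_identity_maps_full_sampling_is_unitary(self, rng):
        n = 12
        maps = np.ones((1, n, n), complex)
        ky, kz = _full_grid(n)
        binned = _binned(ky, kz, np.zeros((n * n, 1), complex),
                         np.ones(n * n), grid=(n, n))
        op = BinnedOperator(binned, maps)
        u = rng.standard_normal(op.shape) + 1j * rng.standard_normal(op.shape)
        out = op.forward(u)[0]
        assert np.linalg.norm(out) == pytest.approx(np.linalg.norm(u))

    def test_zero_image_gives_zero_samples(self):
        n = 8
        ky, kz = _full_grid(n)
        binned = _binned(ky, kz, np.zeros((n * n, 2), complex),
                         np.ones(n * n), grid=(n, n))
        op = BinnedOperator(binned, x.generate_coil_maps((n, n), 2))
        out = op.forward(np.zeros(op.shape, complex))
        assert np.abs(out[0]).max() == 0.0

    def test_wavelet_orthonormal_roundtrip(self, rng):
        w = WaveletTransform((1, 1, 1, 32, 32))
        u = rng.standard_normal((1, 1, 1, 32, 32)) \
            + 1j * rng.standard_normal((1, 1, 1, 32, 32))
        c = w.forward(u)
        assert np.linalg.norm(c) == pytest.approx(np.linalg.norm(u))
        back = w.adjoint(c)
        assert np.linalg.norm(back - u) / np.linalg.norm(u) < 1e-10

    @pytest.mark.parametrize("cyclic", [True, False])
    def test_finite_difference_adjoint_and_constant_nullspace(self, rng, cyclic):
        fd = FiniteDifference(axis=1, cyclic=cyclic)
        shape = (2, 5, 3, 4, 4)
        u = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        v = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        lhs = np.vdot(fd.forward(u), v)
        rhs = np.vdot(u, fd.adjoint(v))
        assert abs(lhs - rhs) / abs(lhs) < 1e-12
        const = np.ones(shape, complex)
        assert np.abs(fd.forward(const)).max() == 0.0


class TestCalibration:
    def test_espirit_recovers_known_maps(self, small_phantom):
        n = 48
        maps = x.generate_coil_maps((n, n), 6)
        img = small_phantom.image(0.0)
        ksp = fft2c(maps * img[None])
        cs = 24
        calib = ksp[:, n // 2 - cs // 2:n // 2 + cs // 2,
                    n // 2 - cs // 2:n // 2 + cs // 2]
        sm = espirit_maps(calib, (n, n))
        supp = np.abs(img) > 0.1
        est, tru = sm.maps[:, supp], maps[:, supp]
        align = np.sum(est * np.conj(tru), axis=0)
        align /= np.maximum(np.abs(align), 1e-12)
        est = est * np.conj(align)[None]
        corr = np.abs(np.vdot(est, tru)) / (
            np.linalg.norm(est) * np.linalg.norm(tru))
        assert corr > 0.99

    def test_uniform_single_coil_gives_constant_map(self):
        n = 32
        img = np.zeros((n, n), complex)
        img[8:24, 8:24] = 1.0
        ksp = fft2c(img[None])
        calib = ksp[:, n // 2 - 8:n // 2 + 8, n // 2 - 8:n // 2 + 8]
        sm = espirit_maps(calib, (n, n))
        mags = np.abs(sm.maps[0][np.abs(sm.maps[0]) > 0])
        assert mags.std() < 0.01 * mags.mean()

    def test_deterministic(self, small_acquisition):
        a = calibrate_sensitivities(small_acquisition, calib_size=16)
        b = calibrate_sensitivities(small_acquisition, calib_size=16)
        np.testing.assert_array_equal(a.maps, b.maps)

    def test_incomplete_calibration_region_names_extent(self):
        tab = AcquisitionTable(
            kspace=np.ones((4, 2), complex), ky=np.array([0, 1, 2, 3]),
            kz=np.array([0, 1, 2, 3]), echo=np.zeros(4, int),
            time_ms=np.zeros(4), cardiac_phase=np.zeros(4),
            navigator=np.zeros((4, 2, 1, 1), complex),
            attrs={"grid": [16, 16]})
        with pytest.raises(ValueError, match="calibration region"):
            project_calibration(tab, calib_size=8)


class TestCoilCompression:
    def test_identity_when_keeping_all_coils(self, small_acquisition):
        out, energy = coil_compress(small_acquisition, small_acquisition.n_coils)
        assert energy == pytest.approx(1.0)
        # unitary rotation preserves per-sample norms
        np.testing.assert_allclose(
            np.linalg.norm(out.kspace, axis=1),
            np.linalg.norm(small_acquisition.kspace, axis=1), rtol=1e-10)

    def test_rank2_mixing_lossless_at_two_virtual_coils(self, rng):
        base = rng.standard_normal((500, 2)) + 1j * rng.standard_normal((500, 2))
        mixing = rng.standard_normal((2, 6)) + 1j * rng.standard_normal((2, 6))
        data = base @ mixing
        comp, energy = fit_coil_compressor(data, 2)
        assert energy == pytest.approx(1.0)
        back = (data @ comp) @ comp.conj().T
        np.testing.assert_allclose(back, data, atol=1e-10)

    def test_retained_energy_matches_svd_oracle(self, rng):
        base = rng.standard_normal((300, 2)) + 1j * rng.standard_normal((300, 2))
        mixing = rng.standard_normal((2, 4)) + 1j * rng.standard_normal((2, 4))
        data = base @ mixing
        s = np.linalg.svd(data, compute_uv=False)
        _, energy = fit_coil_compressor(data, 1)
        assert energy == pytest.approx(s[0] ** 2 / np.sum(s ** 2))


class TestSolver:
    def test_fully_sampled_lambda0_equals_inverse_fft(self, rng):
        n = 16
        img = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        k = fft2c(img[None])[0]
        ky, kz = _full_grid(n)
        binned = _binned(ky, kz, k[ky, kz][:, None], np.ones(n * n),
                         grid=(n, n))
        cfg = ReconConfig(lambda_x=0, lambda_t=0, lambda_c=0, lambda_r=0)
        out = solve(binned, np.ones((1, n, n), complex), cfg)
        nrmse = np.linalg.norm(out.data[0, 0, 0, 0] - img) / np.linalg.norm(img)
        assert nrmse < 1e-6

    def test_huge_temporal_tv_flattens_time(self, rng):
        # lambda_t -> large forces the solution constant along t
        n = 12
        maps = x.generate_coil_maps((n, n), 3)
        imgs = [rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
                for _ in range(2)]
        ky, kz = _full_grid(n)
        rows, vals, bins_t = [], [], []
        for t, im in enumerate(imgs):
            k = fft2c(maps * im[None])
            rows.append((ky, kz))
            vals.append(k[:, ky, kz].T)
            bins_t.append(np.full(n * n, t))
        binned = _binned(np.concatenate([r[0] for r in rows]),
                         np.concatenate([r[1] for r in rows]),
                         np.concatenate(vals),
                         np.ones(2 * n * n), grid=(n, n), n_t=2,
                         bins=(np.concatenate(bins_t),
                               np.zeros(2 * n * n, int),
                               np.zeros(2 * n * n, int)))
        # rho of the same order as lambda keeps the dual ascent fast in the
        # hard-constraint regime
        cfg = ReconConfig(lambda_x=0, lambda_t=50.0, lambda_c=0, lambda_r=0,
                          max_iters=60, admm_rho=25.0, tolerance=1e-8)
        out = solve(binned, maps, cfg)
        diff = np.linalg.norm(out.data[0, 1] - out.data[0, 0])
        scale = np.linalg.norm(out.data[0, 0])
        assert diff / scale < 0.02

    def test_objective_non_increasing(self, rng):
        n = 16
        maps = x.generate_coil_maps((n, n), 4)
        img = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        k = fft2c(maps * img[None])
        ky, kz = _full_grid(n)
        sel = rng.choice(n * n, n * n // 2, replace=False)
        binned = _binned(ky[sel], kz[sel], k[:, ky[sel], kz[sel]].T,
                         np.ones(len(sel)), grid=(n, n))
        cfg = ReconConfig(lambda_x=1e-3, lambda_t=0, lambda_c=0, lambda_r=0,
                          max_iters=15)
        out = solve(binned, maps, cfg)
        obj = out.provenance["log"][0]["objective"]
        assert len(obj) > 2
        tol = 1e-6 * obj[0] + 1e-12
        assert all(b <= a + max(0.02 * a, tol) for a, b in zip(obj, obj[1:]))

    def test_undersampled_noiseless_recovery(self, rng):
        # 2x undersampling, 8 coils, oracle maps, small wavelet penalty
        n = 32
        maps = x.generate_coil_maps((n, n), 8)
        cfg_ph = x.PhantomConfig(grid_size=n, n_coils=8)
        img = x.Phantom(cfg_ph).image(0.0)
        k = fft2c(maps * img[None])
        ky, kz = _full_grid(n)
        rng2 = np.random.default_rng(3)
        sel = rng2.choice(n * n, n * n // 2, replace=False)
        binned = _binned(ky[sel], kz[sel], k[:, ky[sel], kz[sel]].T,
                         np.ones(len(sel)), grid=(n, n))
        cfg = ReconConfig(lambda_x=1e-4, lambda_t=0, lambda_c=0, lambda_r=0,
                          max_iters=40, tolerance=1e-7)
        out = solve(binned, maps, cfg)
        nrmse = np.linalg.norm(out.data[0, 0, 0, 0] - img) / np.linalg.norm(img)
        assert nrmse < 0.05

    def test_all_zero_weights_rejected(self):
        n = 8
        ky, kz = _full_grid(n)
        binned = _binned(ky, kz, np.ones((n * n, 1), complex),
                         np.zeros(n * n), grid=(n, n))
        with pytest.raises(ValueError):
            solve(binned, np.ones((1, n, n), complex), ReconConfig())

    def test_map_grid_mismatch_rejected(self):
        n = 8
        ky, kz = _full_grid(n)
        binned = _binned(ky, kz, np.ones((n * n, 1), complex),
                         np.ones(n * n), grid=(n, n))
        with pytest.raises(ValueError):
            solve(binned, np.ones((1, 4, 4), complex), ReconConfig())
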