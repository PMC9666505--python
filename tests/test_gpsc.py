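"""Direct Inversion, TV initializer, support generation and GP loop."""


import numpy as np
import pytest

from tpmphantom import (
    OpticalConfig,
    RIVolume,
    direct_inversion,
    gpsc_reconstruct,
    make_support,
    ri_error_metrics,
    simulate_projection_set,
    total_variation,
    tv_initial_reconstruction,
)
from tpmphantom.gpsc import SupportMask


def _fwhm(profile, pitch):
    x = np.arange(len(profile)) * pitch
    xf = np.linspace(x[0], x[-1], 4000)
    pf = np.interp(xf, x, profile)
    above = np.where(pf >= pf.max() / 2)[0]
    return xf[above[-1]] - xf[above[0]]


class TestDirectInversion:
    def test_no_scattering_gives_zero_dn(self):
        vol = RIVolume(np.full((32, 32, 32), 1.5123), [0.25] * 3, 0.0)
        cfg = OpticalConfig(n_projections=12, azimuth_step_deg=30.0)
        rec, _ = direct_inversion(simulate_projection_set(vol, cfg))
        assert np.abs(rec.values - 1.5123).max() < 1e-6

    def test_weak_sphere_recovered_from_born_fields(self, born_sphere_recovery):
        """Peak Δn within 20% and centroid within one voxel of truth."""
        vol, dn_true, rec, _ = born_sphere_recovery
        dn = rec.values - 1.5123
        assert dn.max() == pytest.approx(dn_true, rel=0.2)
        w = np.clip(dn, 0, None) ** 2
        n = vol.shape[0]
        for axis in range(3):
            other = tuple(a for a in range(3) if a != axis)
            marg = w.sum(axis=other)
            com = (np.arange(n) * marg).sum() / marg.sum()
            assert abs(com - n // 2) <= 1.0

    def test_circular_scan_has_missing_cone(self, di_noisy):
        """47° circular scan: coverage < 1 with an empty double cone
        around the axial frequency axis."""
        _, cov = di_noisy
        assert cov.filled_fraction < 1.0
        nz = cov.filled_mask.shape[2]
        # axial axis (K_perp = 0) empty away from DC
        axial = cov.filled_mask[0, 0]
        assert not axial[2 : nz // 2].any()
        assert not axial[nz // 2 + 1 : -1].any()

    def test_coverage_invariants(self, di_noisy):
        _, cov = di_noisy
        assert np.all(cov.weights[cov.filled_mask] >= 1)
        assert np.all(cov.accumulated_spectrum[~cov.filled_mask] == 0)

    def test_point_feature_axially_elongated(self):
        """Missing cone symptom: axial FWHM exceeds lateral FWHM."""
        n, pitch = 48, 0.2
        c = (np.arange(n) - n // 2 + 0.0) * pitch
        X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
        v = np.full((n, n, n), 1.5123)
        v[X**2 + Y**2 + Z**2 <= 0.5**2] += 2e-3
        vol = RIVolume(v, [pitch] * 3, 0.0)
        cfg = OpticalConfig(zenith_deg=47.0, n_projections=40, azimuth_step_deg=9.0)
        rec, _ = direct_inversion(simulate_projection_set(vol, cfg))
        dn = rec.values - 1.5123
        i0 = np.unravel_index(np.argmax(dn), dn.shape)
        lat = _fwhm(dn[:, i0[1], i0[2]], pitch)
        ax = _fwhm(dn[i0[0], i0[1], :], pitch)
        assert ax / lat > 1.0


class TestBornOracleAgreement:
    def test_msbp_matches_born_for_weak_blob(self, born_blob_pair):
        """MSBP and the brute-force first-Born integral agree to ≤1% RMS
        of the scattered field for a weak band-limited object."""
        _, d_born, d_msbp = born_blob_pair
        s_born, s_msbp = d_born - 1.0, d_msbp - 1.0
        rel = np.linalg.norm(s_msbp - s_born) / np.linalg.norm(s_born)
        assert rel <= 0.01


class TestTvInitialReconstruction:
    def test_zero_weight_matches_direct_inversion(self, pset_noisy, di_noisy):
        di, cov = di_noisy
        out = tv_initial_reconstruction(
            pset_noisy, tv_weight=0.0, n_iter=200, coverage=cov, di_volume=di
        )
        num = np.linalg.norm(out.values - di.values)
        den = np.linalg.norm(di.values - 1.5123)
        assert num / den < 0.05

    def test_strong_weight_reduces_total_variation(self, pset_noisy, di_noisy):
        di, cov = di_noisy
        out = tv_initial_reconstruction(
            pset_noisy, tv_weight=1e-2, coverage=cov, di_volume=di
        )
        assert total_variation(out.values) < total_variation(di.values)

    def test_zero_data_gives_zero_volume(self, pset_noisy, di_noisy):
        di, cov = di_noisy
        flat = RIVolume(
            np.full_like(di.values, 1.5123), di.voxel_pitch, di.origin
        )
        out = tv_initial_reconstruction(
            pset_noisy, tv_weight=1e-3, n_iter=30, coverage=cov, di_volume=flat
        )
        assert np.abs(out.values - 1.5123).max() < 1e-10


class TestMakeSupport:
    def test_truth_volume_full_recall_with_closing(self, strong_phantom):
        spec, truth = strong_phantom
        support = make_support(truth, dilation=2, closing=6)
        obj = truth.values > spec.n_background + 1e-12
        assert np.all(support.mask[obj])

    def test_binary_two_level_input_exact_mask(self):
        vals = np.full((16, 16, 16), 1.5123)
        vals[4:9, 5:10, 6:11] = 1.54
        vol = RIVolume(vals, [0.25] * 3, 0.0)
        support = make_support(vol, dilation=0)
        np.testing.assert_array_equal(support.mask, vals > 1.5123)

    def test_constant_volume_rejected(self):
        vol = RIVolume(np.full((8, 8, 8), 1.5123), [0.25] * 3, 0.0)
        with pytest.raises(ValueError, match="no object"):
            make_support(vol)

    def test_empty_mask_type_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SupportMask(np.zeros((4, 4, 4), dtype=bool))


class TestGpscReconstruct:
    def test_consistent_input_terminates_with_fixed_point(self, pset_noisy):
        """An iterate satisfying all constraints and the data is a fixed
        point: dynamics 0, immediate stop, volume unchanged."""
        from tpmphantom.gpsc import FrequencyCoverage

        cfg = pset_noisy.config
        n = 32
        c = (np.arange(n) - n // 2) * 0.25
        X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
        x0 = 0.01 * np.exp(-(X**2 + Y**2 + Z**2) / 2.0)
        support = SupportMask(x0 > 1e-6)
        x0[~support.mask] = 0.0
        k0 = 2 * np.pi / cfg.wavelength_um
        scale = 2.0 * cfg.n_immersion * k0**2 * 0.25**3
        spectrum = np.fft.fftn(np.fft.ifftshift(x0)) * scale
        mask = np.random.default_rng(0).random((n, n, n)) < 0.3
        cov = FrequencyCoverage(
            mask, np.where(mask, spectrum, 0.0), mask.astype(int)
        )
        init = RIVolume(cfg.n_immersion + x0, [0.25] * 3, 0.0)
        rec, hist = gpsc_reconstruct(
            pset_noisy, support, eps=0.02, init=init, coverage=cov
        )
        assert hist.n_iter == 10  # stopping window fills, then stops
        assert all(d == 0.0 for d in hist.dynamics)
        assert np.abs(rec.values - init.values).max() < 1e-8

    def test_replenishment_idempotent(self, di_noisy):
        _, cov = di_noisy
        X = np.fft.fftn(np.random.default_rng(0).normal(size=cov.filled_mask.shape))
        D = cov.averaged
        m = cov.filled_mask
        X1 = X.copy()
        X1[m] = D[m]
        X2 = X1.copy()
        X2[m] = D[m]
        np.testing.assert_array_equal(X1, X2)

    def test_final_iterate_satisfies_signal_constraints(self, gpsc_noisy, support_noisy):
        rec, _ = gpsc_noisy
        dn = rec.values - 1.5123
        assert dn.min() >= -1e-12
        assert np.abs(dn[~support_noisy.mask]).max() <= 1e-12

    def test_misfit_non_increasing(self, gpsc_noisy):
        _, hist = gpsc_noisy
        mis = np.asarray(hist.misfit)
        assert np.all(np.diff(mis) <= 1e-9 * mis[0])

    def test_improves_on_direct_inversion_inside_object(self, weak_phantom, sim_config):
        """Noise-free data, envelope support: GP iterations reduce the
        RI error inside the object relative to Direct Inversion."""
        spec, truth = weak_phantom
        pset = simulate_projection_set(truth, sim_config)
        obj = truth.values > spec.n_background + 1e-12
        di, cov = direct_inversion(pset)
        support = make_support(truth, dilation=2, closing=6)
        rec, _ = gpsc_reconstruct(pset, support, eps=0.02, init=di, coverage=cov)
        rmse_gp, _ = ri_error_metrics(rec, truth, obj)
        rmse_di, _ = ri_error_metrics(di, truth, obj)
        assert rmse_gp <= rmse_di
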