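"""BOLD cleaning: detrending, filtering, nuisance regression, geometry."""

import numpy as np
import pytest

from gastricnet import bold as bp


def make_vs(data, tr=2.0, voxel_mm=3.0, mask=None):
    data = np.asarray(data, dtype=float)
    affine = np.diag([voxel_mm] * 3 + [1.0])
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return bp.VolumeSeries(data=data, tr_s=tr, affine=affine, mask=mask)


def single_voxel_series(x, grid=(3, 3, 3), loc=(1, 1, 1)):
    data = np.zeros(grid + (len(x),))
    data[loc] = x
    return make_vs(data)


class TestDetrendBandpass:
    def test_quadratic_drift_removed(self):
        t = np.linspace(-1, 1, 450)
        vs = single_voxel_series(3.0 + 2.0 * t + 5.0 * t**2)
        out = bp.detrend_and_bandpass(vs)
        assert np.max(np.abs(out.data)) < 1e-6

    def test_passband_kept_stopband_attenuated(self):
        t = np.arange(450) * 2.0
        keep = np.sin(2 * np.pi * 0.05 * t)
        kill = np.sin(2 * np.pi * 0.2 * t)
        core = slice(50, -50)
        out_keep = bp.detrend_and_bandpass(single_voxel_series(keep)).data[1, 1, 1]
        out_kill = bp.detrend_and_bandpass(single_voxel_series(kill)).data[1, 1, 1]
        assert np.std(out_keep[core]) == pytest.approx(np.std(keep[core]), rel=0.1)
        assert 20 * np.log10(np.std(kill[core]) / np.std(out_kill[core])) >= 20

    def test_output_zero_mean(self, rng):
        vs = make_vs(rng.standard_normal((3, 3, 3, 200)))
        out = bp.detrend_and_bandpass(vs)
        assert np.allclose(out.data.mean(axis=-1), 0.0, atol=1e-8)

    def test_band_vs_nyquist_validated(self):
        vs = single_voxel_series(np.zeros(100), grid=(2, 2, 2), loc=(0, 0, 0))
        with pytest.raises(ValueError, match="Nyquist"):
            bp.detrend_and_bandpass(vs, band_hz=(0.01, 0.3))  # TR 2 s -> Nyquist 0.25


class TestSphereRegressor:
    def test_single_voxel_sphere(self, rng):
        data = rng.standard_normal((5, 5, 5, 50))
        vs = make_vs(data)
        # 4-mm diameter around the center of voxel (2,2,2) = 6 mm world
        series = bp.sphere_regressor(vs, (6.0, 6.0, 6.0), diameter_mm=4.0)
        assert np.allclose(series, data[2, 2, 2])

    def test_homogeneous_volume(self, rng):
        x = rng.standard_normal(50)
        data = np.broadcast_to(x, (5, 5, 5, 50)).copy()
        vs = make_vs(data)
        series = bp.sphere_regressor(vs, (6.0, 6.0, 6.0), diameter_mm=9.0)
        assert np.allclose(series, x)

    def test_empty_intersection_names_center(self):
        vs = make_vs(np.zeros((3, 3, 3, 10)))
        with pytest.raises(ValueError, match="200"):
            bp.sphere_regressor(vs, (200.0, 200.0, 200.0), diameter_mm=4.0)


class TestRetroicor:
    def test_volume_at_rpeak_phase_zero(self):
        nuis = bp.retroicor_cardiac([0.0, 1.0, 2.0], [1.0])
        assert np.allclose(nuis.regressors[0], [1, 0, 1, 0, 1, 0], atol=1e-12)

    def test_mid_diastole_row(self):
        nuis = bp.retroicor_cardiac([0.0, 1.0], [0.5])
        assert np.allclose(nuis.regressors[0], [-1, 0, 1, 0, -1, 0], atol=1e-12)

    def test_planted_pulsation_variance_reduced(self, rng):
        # beat-locked pulsation sampled at TR 2 s; the Fourier set should
        # absorb >=80% of the variance at the aliased cardiac frequency
        tr, n_vol = 2.0, 300
        vol_times = np.arange(n_vol) * tr
        rpeaks = np.cumsum(np.full(700, 0.9))
        rpeaks = np.concatenate([[0.0], rpeaks])
        theta = 2 * np.pi * ((vol_times % 0.9) / 0.9)
        puls = np.cos(theta) + 0.4 * np.sin(2 * theta)
        data = np.zeros((2, 2, 2, n_vol))
        data[:] = puls
        data += 0.1 * rng.standard_normal(data.shape)
        vs = make_vs(data, tr=tr)
        nuis = bp.retroicor_cardiac(rpeaks, vol_times)
        out = bp.regress_out(vs, nuis)
        before = np.var(data[0, 0, 0])
        after = np.var(out.data[0, 0, 0])
        assert after < 0.2 * before


class TestRegressOut:
    def test_voxel_equal_to_regressor_zeroed(self, rng):
        x = rng.standard_normal(80)
        vs = single_voxel_series(x, grid=(2, 2, 2), loc=(0, 0, 0))
        out = bp.regress_out(vs, bp.NuisanceSet(regressors=x[:, None], labels=["x"]))
        assert np.max(np.abs(out.data[0, 0, 0])) < 1e-10

    def test_orthogonal_voxel_unchanged_up_to_mean(self):
        n = 100
        t = np.arange(n)
        vox = np.sin(2 * np.pi * 5 * t / n)
        reg = np.cos(2 * np.pi * 10 * t / n)
        vs = single_voxel_series(vox, grid=(2, 2, 2), loc=(0, 0, 0))
        out = bp.regress_out(vs, bp.NuisanceSet(regressors=reg[:, None], labels=["r"]))
        assert np.allclose(out.data[0, 0, 0], vox - vox.mean(), atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        n = 60
        design = rng.standard_normal((n, 3))
        vs = make_vs(rng.standard_normal((3, 3, 2, n)))
        out = bp.regress_out(vs, bp.NuisanceSet(regressors=design, labels=list("abc")))
        resid = out.data.reshape(-1, n)
        assert np.max(np.abs(resid @ design)) < 1e-8

    def test_dependent_column_dropped_with_warning(self, rng):
        n = 50
        r = rng.standard_normal(n)
        design = np.column_stack([r, 2 * r])
        vs = make_vs(rng.standard_normal((2, 2, 2, n)))
        with pytest.warns(UserWarning, match="dependent"):
            bp.regress_out(vs, bp.NuisanceSet(regressors=design, labels=["r", "r2"]))


class TestSmoothing:
    def test_impulse_fwhm_matches_request(self):
        data = np.zeros((15, 15, 15, 1))
        data[7, 7, 7, 0] = 1.0
        out = bp.smooth_gaussian(make_vs(data), fwhm_mm=3.0).data[:, :, :, 0]
        profile = out[:, 7, 7]
        half = profile.max() / 2
        above = np.where(profile >= half)[0]
        width_mm = (above[-1] - above[0] + 1) * 3.0
        assert 2.0 <= width_mm <= 4.5  # 3-mm FWHM at 3-mm voxels

    def test_constant_volume_unchanged(self):
        data = np.full((8, 8, 8, 2), 4.2)
        out = bp.smooth_gaussian(make_vs(data))
        assert np.allclose(out.data, 4.2, atol=1e-6)

    def test_linearity_two_impulses(self):
        a = np.zeros((12, 12, 12, 1)); a[3, 3, 3, 0] = 1.0
        b = np.zeros((12, 12, 12, 1)); b[8, 8, 8, 0] = 1.0
        sa = bp.smooth_gaussian(make_vs(a)).data
        sb = bp.smooth_gaussian(make_vs(b)).data
        sab = bp.smooth_gaussian(make_vs(a + b)).data
        assert np.allclose(sab, sa + sb, atol=1e-10)


class TestNarrowbandTrim:
    def test_450_volumes_trim_to_420(self, rng):
        vs = make_vs(rng.standard_normal((4, 4, 2, 450)))
        out = bp.narrowband_and_trim(vs, f0=0.05)
        assert out.n_volumes == 420
        assert out.n_volumes * out.tr_s == 840.0

    def test_trim_zero_is_identity_on_time_axis(self, rng):
        vs = make_vs(rng.standard_normal((2, 2, 2, 450)))
        out = bp.narrowband_and_trim(vs, f0=0.05, trim_volumes=0)
        assert out.n_volumes == 450

    def test_too_few_volumes_raises(self, rng):
        vs = make_vs(rng.standard_normal((2, 2, 2, 31)))
        with pytest.raises(ValueError):
            bp.narrowband_and_trim(vs, f0=0.05)


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        series, mean = bp.framewise_displacement(np.zeros((50, 6)))
        assert np.all(series == 0) and mean == 0

    def test_translation_step(self):
        mp = np.zeros((10, 6))
        mp[5:, 0] = 1.0
        series, _ = bp.framewise_displacement(mp)
        assert series[5] == 1.0 and series.sum() == 1.0

    def test_rotation_arc_length(self):
        mp = np.zeros((10, 6))
        mp[5:, 3] = 0.01
        series, _ = bp.framewise_displacement(mp)
        assert series[5] == pytest.approx(0.5)

    def test_wrong_column_count(self):
        with pytest.raises(ValueError, match="6"):
            bp.framewise_displacement(np.zeros((10, 5)))
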