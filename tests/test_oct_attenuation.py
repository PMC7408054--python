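"""Attenuation estimator, surface detection/flattening, ROI and en-face ops."""

import numpy as np
import pytest

from fioct import oct_attenuation as oa
from fioct import synthetic_data as sd
from fioct.errors import EmptyROIError, InvalidParameterError, SurfaceNotFoundError


def closed_form_mu_hat(mu: float, delta: float) -> float:
    """Estimator fixed point on an infinite noiseless exponential A-line."""
    return (np.exp(2.0 * mu * delta) - 1.0) / (2.0 * delta)


class TestEstimateAttenuation:
    def test_matches_geometric_series_closed_form(self):
        # complete tail: mu_hat = (e^{2 mu delta} - 1) / (2 delta) to 1e-9
        mu, delta = 3.0, 0.001
        aline = sd.simulate_ascan(mu, 6000, delta, speckle=False)
        amap = oa.estimate_attenuation(
            oa.OCMVolume(aline[None, None, :], axial_pixel_mm=delta))
        est = amap.mu[0, 0, :2000]
        expected = closed_form_mu_hat(mu, delta)
        assert np.all(np.abs(est - expected) / expected < 1e-9)
        assert expected == pytest.approx(3.009, abs=5e-4)

    def test_scale_equivariance(self, rng):
        # the estimator is a ratio: scaling a column leaves mu_hat unchanged
        aline = sd.simulate_ascan(3.0, 300, speckle=True, rng=rng)
        base = oa.estimate_attenuation(oa.OCMVolume(aline[None, None, :]))
        for scale in (1e-3, 7.3, 1e4):
            scaled = oa.estimate_attenuation(
                oa.OCMVolume(scale * aline[None, None, :]))
            assert np.allclose(scaled.mu[scaled.valid], base.mu[base.valid])

    def test_monotone_in_true_mu_noiseless(self):
        lines = [sd.simulate_ascan(mu, 500, speckle=False) for mu in (2.0, 3.5, 5.0)]
        maps = [oa.estimate_attenuation(oa.OCMVolume(a[None, None, :]))
                for a in lines]
        v = maps[0].valid[0, 0]
        assert np.all(maps[0].mu[0, 0, v] < maps[1].mu[0, 0, v])
        assert np.all(maps[1].mu[0, 0, v] < maps[2].mu[0, 0, v])

    def test_all_zero_column_fully_invalid(self):
        amap = oa.estimate_attenuation(oa.OCMVolume(np.zeros((2, 2, 50))))
        assert not amap.valid.any()

    def test_tail_guard_masks_deepest_fraction(self):
        aline = sd.simulate_ascan(3.0, 100, speckle=False)
        amap = oa.estimate_attenuation(oa.OCMVolume(aline[None, None, :]),
                                       tail_guard=0.2)
        assert not amap.valid[0, 0, 80:].any()

    @pytest.mark.parametrize("mu_true", [2.90, 3.20, 4.35])
    def test_preset_recovery_with_speckle(self, mu_true):
        # cohort presets recovered within 5% from 200 averaged A-scans
        spec = sd.uniform_spec(mu_true, shape=(20, 10, 1200), surface=8, seed=7)
        volume, _ = sd.simulate_volume(spec)
        flat = oa.flatten_volume(volume, oa.detect_surface(volume))
        profile, valid = oa.attenuation_profile_from_roi(flat)
        assert np.median(profile[valid]) == pytest.approx(mu_true, rel=0.05)


class TestDetectSurface:
    def test_noiseless_flat_surface_exact(self):
        spec = sd.uniform_spec(3.0, shape=(12, 12, 64), surface=10, speckle=False)
        volume, _ = sd.simulate_volume(spec)
        surf = oa.detect_surface(volume)
        assert np.all(surf.depth == 10)

    def test_tilted_speckled_within_one_pixel(self):
        shape = (48, 48, 256)
        surface = sd.tilted_surface(shape, z0=10, slope=0.05)
        spec = sd.uniform_spec(3.2, shape=shape, surface=surface, seed=3)
        volume, truth = sd.simulate_volume(spec)
        surf = oa.detect_surface(volume)
        frac = np.mean(np.abs(surf.depth - truth.surface_map) <= 1)
        assert frac >= 0.95

    def test_all_zero_volume_raises(self):
        with pytest.raises(SurfaceNotFoundError):
            oa.detect_surface(oa.OCMVolume(np.zeros((4, 4, 32))))


class TestFlattenVolume:
    def test_flat_zero_surface_is_identity(self):
        vol = oa.OCMVolume(np.random.default_rng(0).exponential(1, (4, 4, 16)))
        flat = oa.flatten_volume(vol, oa.SurfaceMap(np.zeros((4, 4), int)))
        assert np.array_equal(flat.intensity, vol.intensity)
        assert flat.valid.all()

    def test_residual_tilt_at_most_one_pixel(self):
        shape = (48, 48, 256)
        surface = sd.tilted_surface(shape, z0=10, slope=0.05)
        spec = sd.uniform_spec(3.2, shape=shape, surface=surface, seed=3)
        volume, _ = sd.simulate_volume(spec)
        thr = oa.noise_threshold(volume)
        flat = oa.flatten_volume(volume, oa.detect_surface(volume))
        resurf = oa.detect_surface(flat, threshold=thr)
        assert np.ptp(resurf.depth) <= 1

    def test_idempotent_after_first_application(self):
        shape = (16, 16, 128)
        surface = sd.tilted_surface(shape, z0=8, slope=0.1)
        spec = sd.uniform_spec(3.0, shape=shape, surface=surface, speckle=False)
        volume, truth = sd.simulate_volume(spec)
        thr = oa.noise_threshold(volume)
        flat1 = oa.flatten_volume(volume, oa.detect_surface(volume))
        flat2 = oa.flatten_volume(flat1, oa.detect_surface(flat1, threshold=thr))
        assert np.array_equal(flat1.intensity, flat2.intensity)

    def test_wrapped_voxels_marked_invalid(self):
        vol = oa.OCMVolume(np.ones((2, 2, 10)))
        flat = oa.flatten_volume(vol, oa.SurfaceMap(np.full((2, 2), 3)))
        assert flat.valid[:, :, :7].all() and not flat.valid[:, :, 7:].any()


class TestRoiStats:
    def test_uniform_map_median_and_zero_spread(self):
        amap = oa.AttenuationMap(mu=np.full((4, 4, 20), 3.0),
                                 valid=np.ones((4, 4, 20), bool))
        out = oa.mean_attenuation_roi(amap, oa.ROISelection())
        assert out["median_mm1"] == 3.0 and out["std_mm1"] == 0.0

    def test_roi_spans_requested_bscans(self):
        amap = oa.AttenuationMap(mu=np.ones((120, 8, 20)),
                                 valid=np.ones((120, 8, 20), bool))
        out = oa.mean_attenuation_roi(amap, oa.ROISelection(bscan_range=(10, 110)))
        assert out["n_bscans"] == 100

    def test_two_region_median_between_values(self):
        mu = np.full((8, 8, 10), 2.9)
        mu[4:] = 4.35
        amap = oa.AttenuationMap(mu=mu, valid=np.ones_like(mu, bool))
        out = oa.mean_attenuation_roi(amap, oa.ROISelection())
        assert 2.9 <= out["median_mm1"] <= 4.35

    def test_empty_valid_set_raises(self):
        amap = oa.AttenuationMap(mu=np.ones((4, 4, 8)),
                                 valid=np.zeros((4, 4, 8), bool))
        with pytest.raises(EmptyROIError):
            oa.mean_attenuation_roi(amap, oa.ROISelection())


class TestEnfaceProjection:
    def test_uniform_map_gives_uniform_image(self):
        amap = oa.AttenuationMap(mu=np.full((6, 5, 30), 3.3),
                                 valid=np.ones((6, 5, 30), bool))
        enf = oa.enface_projection(amap, (0, 30))
        assert np.allclose(enf, 3.3)

    def test_mean_median_agree_on_constant_columns(self, rng):
        mu = np.repeat(rng.uniform(2.5, 4.5, (8, 8))[:, :, None], 40, axis=2)
        amap = oa.AttenuationMap(mu=mu, valid=np.ones_like(mu, bool))
        a = oa.enface_projection(amap, (0, 40), reducer="mean")
        b = oa.enface_projection(amap, (0, 40), reducer="median")
        assert np.allclose(a, b, rtol=1e-12)

    def test_two_region_segmentation_within_5pct(self):
        shape = (48, 48, 1024)
        surface = sd.tilted_surface(shape, z0=10, slope=0.05)
        spec = sd.two_region_spec(shape=shape, mu_left=4.35, mu_right=2.90,
                                  surface=surface, seed=3)
        volume, _ = sd.simulate_volume(spec)
        flat = oa.flatten_volume(volume, oa.detect_surface(volume))
        amap = oa.estimate_attenuation(flat)
        enf = oa.enface_projection(amap, depth_range=(5, 200), reducer="mean")
        assert np.nanmean(enf[:24]) == pytest.approx(4.35, rel=0.05)
        assert np.nanmean(enf[24:]) == pytest.approx(2.90, rel=0.05)

    def test_empty_window_rejected(self):
        amap = oa.AttenuationMap(mu=np.ones((4, 4, 8)),
                                 valid=np.ones((4, 4, 8), bool))
        with pytest.raises(InvalidParameterError):
            oa.enface_projection(amap, (5, 5))


def test_db_conversion_linearizes():
    linear = np.random.default_rng(0).exponential(1.0, (3, 3, 10))
    vol = oa.OCMVolume.from_db(10.0 * np.log10(linear))
    assert np.allclose(vol.intensity, linear, rtol=1e-10)
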