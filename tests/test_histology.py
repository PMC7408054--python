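"""Color deconvolution, Phansalkar thresholding, counting, density maps."""

import numpy as np
import pytest

from fioct import histology_density as hd
from fioct import synthetic_data as sd
from fioct.errors import InvalidParameterError


def brute_force_phansalkar(gray, radius, k=0.25, p=2.0, q=10.0, r=0.5):
    """Literal per-pixel evaluation of the threshold formula (reflect pad)."""
    h, w = gray.shape
    padded = np.pad(gray, radius, mode="symmetric")
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            win = padded[i:i + 2 * radius + 1, j:j + 2 * radius + 1]
            m, s = win.mean(), win.std()
            t = m * (1 + p * np.exp(-q * m) + k * (s / r - 1))
            out[i, j] = gray[i, j] > t
    return out


class TestColorDeconvolve:
    def test_white_pixel_zero_od(self):
        rgb = np.full((2, 2, 3), 255, dtype=np.uint8)
        od, h8 = hd.color_deconvolve(rgb)
        assert np.all(np.abs(od) < 1e-3)

    def test_pure_hematoxylin_recovered(self):
        od_h = np.full((4, 4), 1.0)
        rgb = sd.render_od_to_rgb(od_h, np.zeros_like(od_h))
        od, _ = hd.color_deconvolve(rgb)
        assert od[:, :, 0] == pytest.approx(1.0, rel=0.01)
        assert np.all(np.abs(od[:, :, 1]) < 0.01)

    def test_round_trip_under_one_percent(self, rng):
        # render -> deconvolve over 1000 random in-gamut stain mixes
        od_h, od_e = sd.sample_ingamut_stain_mixes(1000, rng)
        rgb = sd.render_od_to_rgb(od_h.reshape(1, -1), od_e.reshape(1, -1))
        od, _ = hd.color_deconvolve(rgb)
        assert np.abs(od[0, :, 0] - od_h).max() < 0.01
        assert np.abs(od[0, :, 1] - od_e).max() < 0.01

    def test_mixture_od_is_additive(self, rng):
        # deconvolution linearity: OD of a two-stain mix = sum of parts
        od_h = rng.uniform(0.1, 0.5, 50)
        od_e = rng.uniform(0.05, 0.3, 50)
        mix, _ = hd.color_deconvolve(
            sd.render_od_to_rgb(od_h.reshape(1, -1), od_e.reshape(1, -1)))
        pure_h, _ = hd.color_deconvolve(
            sd.render_od_to_rgb(od_h.reshape(1, -1), np.zeros((1, 50))))
        pure_e, _ = hd.color_deconvolve(
            sd.render_od_to_rgb(np.zeros((1, 50)), od_e.reshape(1, -1)))
        total = pure_h[0, :, :2] + pure_e[0, :, :2]
        assert np.abs(mix[0, :, :2] - total).max() < 0.01

    def test_agrees_with_skimage_separate_stains(self, rng):
        # independent oracle: same stain matrix through skimage's unmixer
        from skimage.color import separate_stains

        od_h = rng.uniform(0.1, 0.6, 64).reshape(8, 8)
        od_e = rng.uniform(0.05, 0.3, 64).reshape(8, 8)
        rgb = sd.render_od_to_rgb(od_h, od_e)
        ours, _ = hd.color_deconvolve(rgb)
        conv = np.linalg.inv(hd.StainMatrix.he_default().rows)
        # skimage normalizes OD by log10(1e-6): rescale to physical OD units
        theirs = separate_stains(rgb, conv) * (-np.log10(1e-6))
        assert np.abs(ours - theirs).max() < 0.02

    def test_singular_matrix_rejected(self):
        rows = np.array([[1, 0, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        with pytest.raises(InvalidParameterError):
            hd.StainMatrix(rows)


class TestPhansalkarThreshold:
    def test_uniform_half_image_all_foreground(self):
        # t = 0.5 (1 + 2 e^-5 - 0.25) ~ 0.3817 < 0.5 everywhere
        gray = np.full((20, 20), 0.5)
        t_expected = 0.5 * (1 + 2 * np.exp(-5.0) - 0.25)
        assert t_expected == pytest.approx(0.3817, abs=2e-4)
        assert hd.phansalkar_threshold(gray, radius=3).all()

    def test_all_zero_image_empty_foreground(self):
        assert not hd.phansalkar_threshold(np.zeros((16, 16)), radius=3).any()

    def test_bright_disk_on_dark_ground(self):
        gray = np.zeros((32, 32))
        yy, xx = np.mgrid[0:32, 0:32]
        disk = (yy - 16) ** 2 + (xx - 16) ** 2 <= 36
        gray[disk] = 0.9
        mask = hd.phansalkar_threshold(gray, radius=2)
        assert mask[16, 16]
        assert not mask[2, 2]

    @pytest.mark.parametrize("radius", [2, 5])
    def test_equals_brute_force_formula(self, radius, rng):
        gray = rng.uniform(0, 1, (64, 64))
        fast = hd.phansalkar_threshold(gray, radius=radius)
        slow = brute_force_phansalkar(gray, radius)
        assert np.array_equal(fast, slow)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            hd.phansalkar_threshold(np.full((8, 8), 2.0))


class TestCountCells:
    def test_empty_mask_zero_cells(self):
        _, n = hd.count_cells(np.zeros((32, 32), bool))
        assert n == 0

    def test_25_disks_counted_exactly(self, rng):
        mask = np.zeros((300, 300), bool)
        yy, xx = np.mgrid[0:300, 0:300]
        centers = [(30 + 60 * i, 30 + 60 * j) for i in range(5) for j in range(5)]
        for cy, cx in centers:
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= 36
        _, n = hd.count_cells(mask)
        assert n == 25

    def test_bridged_disks_split_by_watershed(self):
        mask = np.zeros((64, 64), bool)
        yy, xx = np.mgrid[0:64, 0:64]
        mask |= (yy - 32) ** 2 + (xx - 20) ** 2 <= 64
        mask |= (yy - 32) ** 2 + (xx - 40) ** 2 <= 64
        mask[31:33, 20:40] = True  # 2-px bridge
        _, n_split = hd.count_cells(mask, split_touching=True, opening_radius=0)
        _, n_merged = hd.count_cells(mask, split_touching=False, opening_radius=0)
        assert n_merged == 1
        assert n_split == 2

    def test_min_area_filters_debris(self):
        mask = np.zeros((64, 64), bool)
        mask[10:30, 10:30] = True  # one real object
        mask[50:52, 50:52] = True  # 4-px debris
        _, n = hd.count_cells(mask, min_area=20, opening_radius=0,
                              split_touching=False)
        assert n == 1


class TestDensityMap:
    def test_single_cell_unit_conversion(self):
        # 1 cell in a 100 um x 100 um tile (0.01 mm^2) -> 100 cells/mm^2
        dmap = hd.density_map(np.array([[50.0, 50.0]]), (200, 200),
                              tile_size_um=100.0, pixel_size_um=1.0)
        assert dmap[0, 0] == pytest.approx(100.0)

    def test_uniform_density_recovered(self, rng):
        # 500 cells over 1 mm^2 -> area-weighted mean density 500 / mm^2
        pts = rng.uniform(0, 2000, size=(500, 2))  # 2000 px * 0.5 um = 1 mm
        dmap = hd.density_map(pts, (2000, 2000), tile_size_um=100.0,
                              pixel_size_um=0.5)
        areas = hd.tile_areas_mm2((2000, 2000), 100.0, 0.5)
        assert (dmap * areas).sum() / areas.sum() == pytest.approx(500.0)

    def test_no_centroids_zero_map(self):
        dmap = hd.density_map(np.empty((0, 2)), (100, 100))
        assert np.all(dmap == 0)

    def test_conservation_exact(self, rng):
        # sum over tiles of density x true tile area == total count
        pts = rng.uniform(0, 333, size=(137, 2))
        dmap = hd.density_map(pts, (333, 333), tile_size_um=50.0,
                              pixel_size_um=0.5)
        areas = hd.tile_areas_mm2((333, 333), 50.0, 0.5)
        assert (dmap * areas).sum() == pytest.approx(137.0, abs=1e-9)


class TestFullPipeline:
    def test_recovers_500_nuclei_within_2pct(self, he_slide_500):
        _, rgb, truth = he_slide_500
        result = hd.cell_density_pipeline(rgb)
        assert abs(result.total_count - 500) / 500 <= 0.02
        assert result.total_count == len(result.centroids)

    def test_blank_slide_zero_detections(self):
        rgb, _ = sd.simulate_he_image(sd.HESlideSpec(shape=(256, 256), n_nuclei=0))
        assert hd.cell_density_pipeline(rgb).total_count == 0
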