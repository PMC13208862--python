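"""Segmentation workflow: thresholding, particle analysis, porosity."""

import numpy as np
import pytest

from printbench.imageops import (BinaryMask, DEFAULT_PORE_FILTER, ParticleFilter,
                                 binarize, filter_particles, label_particles,
                                 porosity, to_grayscale)
from printbench.patterns import GridParams, grid_toolpath
from printbench.render import DepositionModel, RasterImage, render_topview


def _flood_fill_components(mask: np.ndarray, connectivity: int):
    """Brute-force labeling oracle: BFS flood fill, returns frozensets of
    pixel coordinates per component."""
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                comp = []
                while stack:
                    rr, cc = stack.pop()
                    comp.append((rr, cc))
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] \
                                and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(frozenset(comp))
    return set(comps)


def _otsu_exhaustive(pixels: np.ndarray) -> int:
    """Independent Otsu oracle: exhaustive 256-bin between-class variance."""
    hist = np.bincount(pixels.ravel(), minlength=256).astype(float)
    total = hist.sum()
    best_t, best_var = 0, -1.0
    levels = np.arange(256)
    for t in range(255):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (levels[: t + 1] * hist[: t + 1]).sum() / w0
        mu1 = (levels[t + 1 :] * hist[t + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestGrayscale:
    def test_grayscale_input_is_identity(self):
        arr = np.arange(100, dtype=np.uint8).reshape(10, 10)
        assert np.array_equal(to_grayscale(arr), arr)

    def test_red_and_blue_map_to_distinct_luminances(self):
        red = np.zeros((2, 2, 3), dtype=np.uint8)
        red[..., 0] = 200
        blue = np.zeros((2, 2, 3), dtype=np.uint8)
        blue[..., 2] = 200
        assert to_grayscale(red)[0, 0] != to_grayscale(blue)[0, 0]

    def test_constant_rgb_maps_to_itself(self):
        arr = np.full((4, 4, 3), 77, dtype=np.uint8)
        assert np.all(to_grayscale(arr) == 77)

    def test_unsupported_channel_count_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4, 5), dtype=np.uint8))


class TestBinarize:
    def test_fixed_threshold_selects_bright_pixels(self):
        px = np.array([[50, 200], [200, 50]], dtype=np.uint8)
        img = RasterImage(px, scale=10)
        mask = binarize(img, "fixed", threshold=128, polarity="bright")
        assert np.array_equal(mask.mask, px == 200)
        assert mask.provenance == {"method": "fixed", "threshold": 128.0,
                                   "polarity": "bright"}

    def test_otsu_threshold_lies_between_bimodal_modes(self):
        rng = np.random.default_rng(0)
        px = np.concatenate([rng.normal(60, 10, 3000), rng.normal(190, 10, 3000)])
        px = np.clip(np.round(px), 0, 255).astype(np.uint8).reshape(60, 100)
        img = RasterImage(px, scale=10)
        mask = binarize(img, "otsu")
        thr = mask.provenance["threshold"]
        assert 80 < thr < 170
        assert abs(thr - _otsu_exhaustive(px)) <= 1.0

    def test_all_background_image_gives_empty_mask(self):
        px = np.full((10, 10), 30, dtype=np.uint8)
        px[0, 0] = 200  # one bright speck so Otsu separates
        mask = binarize(RasterImage(px, scale=10), "otsu")
        assert mask.mask.sum() == 1

    def test_otsu_on_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            binarize(RasterImage(np.full((5, 5), 99, dtype=np.uint8), scale=10))

    def test_dark_polarity_selects_ink(self):
        px = np.array([[50, 200]], dtype=np.uint8)
        mask = binarize(RasterImage(px, scale=10), "fixed", threshold=128,
                        polarity="dark")
        assert np.array_equal(mask.mask, px == 50)


class TestLabelParticles:
    def test_solid_square_area_in_mm2(self):
        m = np.zeros((30, 30), dtype=bool)
        m[5:15, 5:15] = True
        recs = label_particles(BinaryMask(m, scale=10))
        assert len(recs) == 1
        assert recs[0].area == pytest.approx(1.0)
        assert recs[0].area_px == 100

    def test_square_perimeter_within_2_percent(self):
        m = np.zeros((30, 30), dtype=bool)
        m[5:15, 5:15] = True
        recs = label_particles(BinaryMask(m, scale=10))
        assert recs[0].perimeter == pytest.approx(4.0, rel=0.02)

    def test_disk_circularity_near_one(self):
        yy, xx = np.mgrid[0:120, 0:120]
        disk = (xx - 60) ** 2 + (yy - 60) ** 2 <= 40**2  # r = 2 mm at 20 px/mm
        recs = label_particles(BinaryMask(disk, scale=20))
        assert recs[0].circularity == pytest.approx(1.0, abs=0.03)

    def test_square_circularity_near_pi_over_four(self):
        m = np.zeros((120, 120), dtype=bool)
        m[20:100, 20:100] = True
        recs = label_particles(BinaryMask(m, scale=20))
        assert recs[0].circularity == pytest.approx(np.pi / 4, abs=0.03)

    def test_hydraulic_radius_identity_for_every_record(self):
        rng = np.random.default_rng(3)
        mask = rng.random((64, 64)) > 0.6
        for rec in label_particles(BinaryMask(mask, scale=10)):
            assert rec.hydraulic_radius == pytest.approx(rec.area / rec.perimeter,
                                                         rel=1e-12)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_labeling_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(5):
            mask = rng.random((64, 64)) > 0.55
            recs = label_particles(BinaryMask(mask, scale=10),
                                   connectivity=connectivity)
            oracle = _flood_fill_components(mask, connectivity)
            assert len(recs) == len(oracle)
            oracle_sizes = sorted(len(c) for c in oracle)
            assert sorted(r.area_px for r in recs) == oracle_sizes

    def test_border_touching_flag(self):
        m = np.zeros((20, 20), dtype=bool)
        m[0:5, 0:5] = True  # touches border
        m[10:15, 10:15] = True  # interior
        recs = label_particles(BinaryMask(m, scale=10))
        assert sorted(r.touches_border for r in recs) == [False, True]

    def test_empty_mask_gives_empty_list(self):
        assert label_particles(BinaryMask(np.zeros((8, 8), bool), scale=10)) == []

    def test_scale_equivariance_for_convex_particles(self):
        # the same 4 mm disk measured at 20 and 40 px/mm agrees within 2%
        results = {}
        for scale in (20, 40):
            r_px = int(2.0 * scale)
            n = 6 * scale
            yy, xx = np.mgrid[0:n, 0:n]
            disk = (xx - n // 2) ** 2 + (yy - n // 2) ** 2 <= r_px**2
            results[scale] = label_particles(BinaryMask(disk, scale=scale))[0]
        assert results[20].area == pytest.approx(results[40].area, rel=0.02)
        assert results[20].perimeter == pytest.approx(results[40].perimeter, rel=0.02)


class TestFilterParticles:
    def _records(self):
        m = np.zeros((40, 40), dtype=bool)
        m[0:3, 0:3] = True  # border blob
        m[10:20, 10:20] = True  # square
        m[30, 30] = True  # single-pixel speck
        return label_particles(BinaryMask(m, scale=10))

    def test_min_area_px_removes_specks(self):
        kept = filter_particles(self._records(),
                                ParticleFilter(min_area_px=2.5, exclude_border=False))
        assert all(r.area_px >= 2.5 for r in kept)
        assert len(kept) == 2

    def test_permissive_filter_is_identity(self):
        recs = self._records()
        kept = filter_particles(recs, ParticleFilter(min_area=0.0,
                                                     circularity_range=(0, 1.05),
                                                     exclude_border=False))
        assert kept == recs

    def test_border_exclusion(self):
        kept = filter_particles(self._records(),
                                ParticleFilter(exclude_border=True, min_area_px=2.5))
        assert len(kept) == 1
        assert not kept[0].touches_border

    def test_inverted_circularity_range_rejected(self):
        with pytest.raises(ValueError):
            ParticleFilter(circularity_range=(0.9, 0.1))

    def test_ideal_grid_keeps_exactly_36_pores(self):
        img = render_topview(grid_toolpath(GridParams()), DepositionModel(), scale=20)
        mask = binarize(img, "otsu", polarity="bright")
        kept = filter_particles(label_particles(mask), DEFAULT_PORE_FILTER)
        assert len(kept) == 36


class TestPorosity:
    def test_quarter_foreground_is_25_percent(self):
        m = np.zeros((20, 20), dtype=bool)
        m[:10, :10] = True
        assert porosity(BinaryMask(m, scale=10)) == pytest.approx(25.0)

    def test_empty_and_full(self):
        assert porosity(BinaryMask(np.zeros((5, 5), bool), scale=10)) == 0.0
        assert porosity(BinaryMask(np.ones((5, 5), bool), scale=10)) == 100.0

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            porosity(BinaryMask(np.ones((5, 5), bool), scale=10), roi=(0, 0, 0, 0))

    @pytest.mark.parametrize("width", [0.41, 0.6, 0.8])
    def test_grid_porosity_matches_strip_union_closed_form(self, width):
        # 7+7 strips of width w on a 30 mm square, boundary strips half
        # inside the ROI: ink area = 2*6*30*w - 36 w^2
        t = grid_toolpath(GridParams(commanded_line_width=width, n_layers=1))
        img = render_topview(t, DepositionModel(), scale=20)
        mask = binarize(img, "otsu", polarity="bright")
        measured = porosity(mask, roi=(0, 0, 30, 30))
        expected = 100 * (900 - (360 * width - 36 * width**2)) / 900
        assert measured == pytest.approx(expected, abs=1.5)
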