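"""Segmentation, QC filtering and peak statistics against brute-force oracles."""
from collections import deque
from pathlib import Path

import numpy as np
import pytest

from flimcyto import (AcquisitionConfig, DEFAULT_GROUP_PROFILES, LifetimeMaps,
                      inject_artifacts, otsu_segment, peak_statistics,
                      qc_qualify, refine_mask, render_cell_layout,
                      simulate_tcspc_image, smooth_maps)
from flimcyto.preprocess import QCConfig, SegmentationError

DATA = Path(__file__).parent / "data"


def brute_force_otsu_foreground(image):
    """Exhaustive between-class-variance search over 256 histogram bins."""
    counts, edges = np.histogram(image.ravel(), bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    best_var, best_thr = -1.0, None
    for i in range(1, 256):
        w0, w1 = counts[:i].sum(), counts[i:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:i] * centers[:i]).sum() / w0
        m1 = (counts[i:] * centers[i:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_thr = var, centers[i - 1]
    return image > best_thr


def flood_fill_holes(mask):
    """Reference hole filling: everything not reachable from the border."""
    ny, nx = mask.shape
    outside = np.zeros_like(mask, dtype=bool)
    queue = deque()
    for iy in range(ny):
        for ix in range(nx):
            if (iy in (0, ny - 1) or ix in (0, nx - 1)) and not mask[iy, ix]:
                outside[iy, ix] = True
                queue.append((iy, ix))
    while queue:
        iy, ix = queue.popleft()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            jy, jx = iy + dy, ix + dx
            if (0 <= jy < ny and 0 <= jx < nx and not mask[jy, jx]
                    and not outside[jy, jx]):
                outside[jy, jx] = True
                queue.append((jy, jx))
    return ~outside


def maps_from_arrays(tm, a2, intensity, valid=None):
    tm = np.asarray(tm, dtype=float)
    valid = np.ones_like(tm, dtype=bool) if valid is None else valid
    return LifetimeMaps(tm_ps=tm, a2_frac=np.asarray(a2, dtype=float),
                        t2_ps=np.zeros_like(tm),
                        intensity=np.asarray(intensity, dtype=float),
                        valid=valid)


class TestOtsu:
    def test_bimodal_image_separates_levels(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.random((50, 50)) < 0.8, 10, 200)
        fg = otsu_segment(img)
        np.testing.assert_array_equal(fg, img == 200)

    def test_matches_exhaustive_variance_search(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 16, size=(40, 40)).astype(float)
        np.testing.assert_array_equal(otsu_segment(img),
                                      brute_force_otsu_foreground(img))

    def test_constant_image_raises(self):
        with pytest.raises(SegmentationError):
            otsu_segment(np.full((10, 10), 7.0))


class TestRefineMask:
    def test_square_dilation_matches_brute_force(self):
        binary = np.zeros((9, 9), dtype=bool)
        binary[3:6, 3:6] = True
        out = refine_mask(binary, min_area_px=1)
        # brute-force radius-1 disk (city-block plus) dilation
        ref = np.zeros_like(binary)
        for iy, ix in np.argwhere(binary):
            for dy, dx in ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)):
                ref[iy + dy, ix + dx] = True
        np.testing.assert_array_equal(out.mask, ref)
        assert out.area == 21

    def test_small_components_dropped(self):
        binary = np.zeros((60, 60), dtype=bool)
        binary[2:7, 2:12] = True            # 50 px
        binary[20:44, 20:45] = True         # 600 px
        out = refine_mask(binary, min_area_px=100, dilate_radius_px=0)
        assert out.n_components == 1
        assert not out.mask[2:7, 2:12].any()
        assert out.mask[20:44, 20:45].all()

    def test_ring_hole_filled(self):
        ring = np.zeros((16, 16), dtype=bool)
        ring[3:13, 3:13] = True
        ring[6:10, 6:10] = False
        out = refine_mask(ring, min_area_px=1, dilate_radius_px=0)
        np.testing.assert_array_equal(out.mask, flood_fill_holes(ring))
        assert out.area == 100

    def test_empty_result_is_empty_mask_not_error(self):
        binary = np.zeros((20, 20), dtype=bool)
        binary[0, 0] = True
        out = refine_mask(binary, min_area_px=50)
        assert out.area == 0 and out.n_components == 0

    def test_golden_mask_regression(self):
        """Fixed-seed phantom through Otsu -> dilate -> filter -> fill must
        reproduce the stored golden mask byte for byte."""
        cfg = AcquisitionConfig(image_size_px=64, n_time_bins=32)
        _, maps = render_cell_layout(3, DEFAULT_GROUP_PROFILES["normal"],
                                     cfg, 2024)
        img = simulate_tcspc_image(maps, cfg, 2025)
        mask = refine_mask(otsu_segment(img.intensity()), min_area_px=30)
        got = "\n".join("".join("1" if v else "0" for v in row)
                        for row in mask.mask) + "\n"
        assert got == (DATA / "golden_mask.txt").read_text()


class TestSmoothMaps:
    def test_constant_map_unchanged(self):
        maps = maps_from_arrays(np.full((8, 8), 900.0),
                                np.full((8, 8), 0.9), np.ones((8, 8)))
        mask = refine_mask(np.ones((8, 8), dtype=bool), min_area_px=1,
                           dilate_radius_px=0)
        out = smooth_maps(maps, mask)
        np.testing.assert_array_equal(out.tm_ps, maps.tm_ps)

    def test_single_outlier_replaced(self):
        tm = np.full((5, 5), 900.0)
        tm[2, 2] = 5000.0
        maps = maps_from_arrays(tm, np.full((5, 5), 0.9), np.ones((5, 5)))
        mask = refine_mask(np.ones((5, 5), dtype=bool), min_area_px=1,
                           dilate_radius_px=0)
        out = smooth_maps(maps, mask)
        assert out.tm_ps[2, 2] == 900.0

    def test_matches_brute_force_masked_median(self):
        rng = np.random.default_rng(3)
        tm = rng.uniform(400, 1400, size=(7, 7))
        mask_arr = rng.random((7, 7)) < 0.7
        maps = maps_from_arrays(tm, tm / 2000.0, np.ones((7, 7)))
        mask = refine_mask(mask_arr, min_area_px=1, dilate_radius_px=0)
        # hole filling may add pixels; use the refined mask as reference
        m = mask.mask
        out = smooth_maps(maps, mask)
        for iy in range(7):
            for ix in range(7):
                if not m[iy, ix]:
                    assert out.tm_ps[iy, ix] == tm[iy, ix]
                    continue
                window = [tm[jy, jx]
                          for jy in range(max(iy - 1, 0), min(iy + 2, 7))
                          for jx in range(max(ix - 1, 0), min(ix + 2, 7))
                          if m[jy, jx]]
                assert out.tm_ps[iy, ix] == pytest.approx(np.median(window))

    def test_intensity_untouched(self, small_image):
        image, _, maps_gt = small_image
        from flimcyto import FitConfig, fit_image
        maps = fit_image(image, FitConfig())
        mask = refine_mask(otsu_segment(maps.intensity), min_area_px=30)
        out = smooth_maps(maps, mask)
        np.testing.assert_array_equal(out.intensity, maps.intensity)


class TestQCQualify:
    def _mask_of(self, arr):
        return refine_mask(arr, min_area_px=1, dilate_radius_px=0)

    def test_clean_image_qualifies(self):
        intensity = np.ones((40, 40)) * 2.0
        intensity[10:30, 10:30] = 100.0
        m = np.zeros((40, 40), dtype=bool)
        m[10:30, 10:30] = True
        maps = maps_from_arrays(np.full((40, 40), 900.0),
                                np.full((40, 40), 0.9), intensity)
        ok, reasons = qc_qualify(maps, self._mask_of(m),
                                 QCConfig(min_cell_pixels=100))
        assert ok and reasons == []

    def test_bright_noncell_region_rejected(self):
        intensity = np.ones((40, 40)) * 2.0
        intensity[10:30, 10:30] = 100.0
        intensity[0:5, 0:5] = 1000.0          # debris outside the mask
        m = np.zeros((40, 40), dtype=bool)
        m[10:30, 10:30] = True
        maps = maps_from_arrays(np.full((40, 40), 900.0),
                                np.full((40, 40), 0.9), intensity)
        ok, reasons = qc_qualify(maps, self._mask_of(m),
                                 QCConfig(min_cell_pixels=100))
        assert not ok
        assert any("non-cell intensity" in r for r in reasons)

    def test_empty_mask_rejected_for_size(self):
        maps = maps_from_arrays(np.zeros((20, 20)), np.zeros((20, 20)),
                                np.zeros((20, 20)))
        ok, reasons = qc_qualify(maps, self._mask_of(np.zeros((20, 20),
                                                              dtype=bool)))
        assert not ok
        assert any("cell area" in r for r in reasons)

    def test_debris_injection_round_trip(self, small_image):
        image, _, gt = small_image
        cell = gt["cell_label"] > 0
        dirty = inject_artifacts(image, "bright_debris", 0.8, seed=6)
        maps = maps_from_arrays(np.full(cell.shape, 900.0),
                                np.full(cell.shape, 0.9), dirty.intensity())
        ok, reasons = qc_qualify(maps, self._mask_of(cell),
                                 QCConfig(min_cell_pixels=50))
        assert not ok
        assert any("non-cell intensity" in r for r in reasons)

    def test_rejection_monotone_in_severity(self, small_image):
        image, _, gt = small_image
        cell = gt["cell_label"] > 0
        flags = []
        for severity in (0.0, 0.25, 0.5, 0.75, 1.0):
            dirty = inject_artifacts(image, "bright_debris", severity, seed=6)
            maps = maps_from_arrays(np.full(cell.shape, 900.0),
                                    np.full(cell.shape, 0.9),
                                    dirty.intensity())
            ok, _ = qc_qualify(maps, self._mask_of(cell),
                               QCConfig(min_cell_pixels=50))
            flags.append(ok)
        # once rejected, higher severity must never re-qualify
        first_bad = flags.index(False) if False in flags else len(flags)
        assert all(not f for f in flags[first_bad:])


class TestPeakStatistics:
    def _full_mask(self, shape):
        return refine_mask(np.ones(shape, dtype=bool), min_area_px=1,
                           dilate_radius_px=0)

    def test_uniform_map_peaks_at_value(self):
        maps = maps_from_arrays(np.full((10, 10), 900.0),
                                np.full((10, 10), 0.934), np.ones((10, 10)))
        s = peak_statistics(maps, self._full_mask((10, 10)))
        assert abs(s.peak_tm_ps - 900.0) <= 10.0       # half a 20-ps bin
        assert abs(s.peak_a2_pct - 93.4) <= 0.5        # half a 1% bin

    def test_bimodal_map_takes_majority_mode(self):
        tm = np.full((10, 10), 650.0)
        tm[:3, :] = 930.0                              # 30% minority mass
        maps = maps_from_arrays(tm, np.full((10, 10), 0.5),
                                np.ones((10, 10)))
        s = peak_statistics(maps, self._full_mask((10, 10)))
        assert 640.0 <= s.peak_tm_ps <= 660.0

    def test_mode_tie_goes_to_lower_bin(self):
        tm = np.concatenate([np.full(50, 650.0), np.full(50, 930.0)])
        maps = maps_from_arrays(tm.reshape(10, 10), np.full((10, 10), 0.5),
                                np.ones((10, 10)))
        s = peak_statistics(maps, self._full_mask((10, 10)))
        assert s.peak_tm_ps == pytest.approx(650.0, abs=10.0)

    def test_no_valid_pixels_raises(self):
        maps = maps_from_arrays(np.zeros((5, 5)), np.zeros((5, 5)),
                                np.zeros((5, 5)),
                                valid=np.zeros((5, 5), dtype=bool))
        with pytest.raises(SegmentationError):
            peak_statistics(maps, self._full_mask((5, 5)))

    def test_synthetic_image_peak_in_group_range(self, small_image):
        from flimcyto import FitConfig, fit_image
        from scipy import stats as st
        image, _, _ = small_image
        maps = fit_image(image, FitConfig())
        mask = refine_mask(otsu_segment(maps.intensity), min_area_px=30)
        s = peak_statistics(maps, mask)
        prof = DEFAULT_GROUP_PROFILES["normal"]
        lo, hi = st.norm.ppf([0.005, 0.995], loc=prof.tm_mean_ps,
                             scale=prof.tm_sd_ps)
        assert lo - 20 <= s.peak_tm_ps <= hi + 20
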