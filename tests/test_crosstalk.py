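import dataclasses

import numpy as np
import pytest

from cytoorder.correlation import Correlogram, correlate_fft
from cytoorder.crosstalk import (
    InscribedCircle,
    central_peak_excess,
    clip_to_circle,
    disc_overlap_normalization,
    largest_inscribed_circle,
    peak_and_background,
    random_pair_null,
    same_cell_crosstalk,
)
from cytoorder.segmentation import BinaryMask
from cytoorder.synthetic import FiberSpec, elliptical_cell_mask, generate_paired


def mask_of(arr):
    return BinaryMask(np.asarray(arr, dtype=bool), 112.0)


def disc_mask(n, center, radius):
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return mask_of((yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2)


PAIR_SPEC = FiberSpec(
    n_fibers=40, length_px=60, width_px=3, image_size=(192, 192),
    orientations_deg=((0.0, 1.0),), angle_jitter_sd_deg=60.0, seed=0,
)


class TestLargestInscribedCircle:
    def test_filled_disc(self):
        m = disc_mask(101, (50, 50), 30)
        c = largest_inscribed_circle(m)
        assert abs(c.center[0] - 50) <= 1 and abs(c.center[1] - 50) <= 1
        assert abs(c.radius_px - 30) <= 1

    def test_filled_rectangle_half_short_side(self):
        v = np.zeros((60, 60), dtype=bool)
        v[10:50, 15:35] = True  # 40 x 20 rectangle
        c = largest_inscribed_circle(mask_of(v))
        assert abs(c.radius_px - 10) <= 1

    def test_l_shape_matches_bruteforce(self):
        v = np.zeros((40, 40), dtype=bool)
        v[5:35, 5:15] = True
        v[25:35, 5:35] = True
        c = largest_inscribed_circle(mask_of(v))
        # oracle: exhaustive feasibility scan over all centers and radii
        best_r = -1
        yy, xx = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        for cy in range(40):
            for cx in range(40):
                if not v[cy, cx]:
                    continue
                for r in range(0, 20):
                    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
                    if (disc & ~v).any():
                        break
                    best_r = max(best_r, r)
        assert c.radius_px == best_r
        disc = (yy - c.center[0]) ** 2 + (xx - c.center[1]) ** 2 <= c.radius_px**2
        assert not (disc & ~v).any()  # returned disc actually fits

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            largest_inscribed_circle(mask_of(np.zeros((5, 5))))


class TestClipToCircle:
    def test_full_mask_clips_to_disc(self):
        m = mask_of(np.ones((41, 41)))
        out = clip_to_circle(m, InscribedCircle((20, 20), 10))
        assert out.shape == (21, 21)
        yy, xx = np.meshgrid(np.arange(-10, 11), np.arange(-10, 11), indexing="ij")
        np.testing.assert_array_equal(out.values, yy**2 + xx**2 <= 100)

    def test_subpixel_circle_errors(self):
        m = mask_of(np.ones((5, 5)))
        with pytest.raises(ValueError):
            clip_to_circle(m, InscribedCircle((2, 2), 0))

    def test_idempotent_for_concentric(self):
        m = mask_of(np.random.default_rng(0).random((41, 41)) < 0.5)
        c = InscribedCircle((20, 20), 10)
        once = clip_to_circle(m, c)
        twice = clip_to_circle(once, InscribedCircle((10, 10), 10))
        np.testing.assert_array_equal(once.values, twice.values)

    def test_never_increases_set_pixels(self):
        m = mask_of(np.random.default_rng(1).random((41, 41)) < 0.5)
        out = clip_to_circle(m, InscribedCircle((20, 20), 12))
        assert out.values.sum() <= m.values.sum()


class TestPeakAndBackground:
    def test_flat_correlogram(self):
        c = Correlogram(np.full((81, 81), 0.3), 112.0)
        pk = peak_and_background(c, 9, (27, 36))
        assert pk.peak_height == pytest.approx(0.0)
        assert pk.background == pytest.approx(0.3)

    def test_central_spike_over_constant(self):
        v = np.full((81, 81), 0.2)
        v[40, 40] += 0.05
        pk = peak_and_background(Correlogram(v, 112.0), 9, (27, 36))
        assert pk.peak_height == pytest.approx(0.05)
        assert pk.background == pytest.approx(0.2)
        assert pk.peak_lag == (0, 0)

    def test_window_exceeding_extent_errors(self):
        c = Correlogram(np.zeros((21, 21)), 112.0)
        with pytest.raises(ValueError):
            peak_and_background(c, 9, (27, 36))


class TestSameCellCrosstalk:
    def test_identical_masks_have_positive_peak(self, rng):
        m = mask_of(rng.random((96, 96)) < 0.2)
        _, pk = same_cell_crosstalk([(m, m)], max_lag=40)
        assert pk.peak_height > 0
        assert pk.peak_lag == (0, 0)

    def test_independent_masks_no_peak(self):
        # averaged over cells, independent networks show no central peak:
        # the central-window excess over off-center control windows is zero
        # within its empirical spread across seeds
        excesses = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            cells = [
                (mask_of(r.random((96, 96)) < 0.2), mask_of(r.random((96, 96)) < 0.2))
                for _ in range(4)
            ]
            avg, _ = same_cell_crosstalk(cells, max_lag=40)
            c = Correlogram(avg.mean, 112.0, "overlap", "cross")
            excesses.append(central_peak_excess(c))
        excesses = np.array(excesses)
        assert abs(excesses.mean()) < 3 * excesses.std(ddof=1)

    def test_peak_monotone_in_shared_fraction(self):
        peaks = []
        for f in (0.0, 0.25, 0.5, 1.0):
            per_seed = []
            for seed in range(5):
                spec = dataclasses.replace(PAIR_SPEC, seed=seed)
                ia, ib, ta, tb = generate_paired(spec, f, displacement_sd_px=1.0)
                _, pk = same_cell_crosstalk([(ta, tb)], max_lag=40)
                per_seed.append(pk.peak_height)
            peaks.append(np.mean(per_seed))
        assert peaks == sorted(peaks)

    def test_inscribed_circle_exceeds_full_for_central_colocalization(self):
        # networks co-localized only near the cell center: restricting the
        # analysis to the inscribed circle raises the measured peak
        rng = np.random.default_rng(3)
        support = elliptical_cell_mask((192, 192), (90, 60))
        centre = elliptical_cell_mask((192, 192), (40, 40))
        full_peaks, circ_peaks = [], []
        for seed in range(5):
            spec = dataclasses.replace(
                PAIR_SPEC, seed=seed, n_fibers=30, length_px=30
            )
            _, _, ta, _ = generate_paired(spec, 0.0, support=centre)
            # channel B shares the central fibers and adds peripheral ones
            _, _, tb0, _ = generate_paired(
                dataclasses.replace(spec, seed=seed + 100), 0.0, support=support
            )
            tb = dataclasses.replace(tb0, values=tb0.values | ta.values)
            _, pf = same_cell_crosstalk([(ta, tb, support)], region="full")
            _, pc = same_cell_crosstalk([(ta, tb, support)], region="inscribed_circle")
            full_peaks.append(pf.peak_height)
            circ_peaks.append(pc.peak_height)
        assert np.mean(circ_peaks) > np.mean(full_peaks)

    def test_region_restriction_never_adds_pixels(self):
        m = disc_mask(101, (50, 50), 40)
        fiber = mask_of(np.random.default_rng(0).random((101, 101)) < 0.3)
        fiber = dataclasses.replace(fiber, values=fiber.values & m.values)
        circ = largest_inscribed_circle(m)
        clipped = clip_to_circle(fiber, circ)
        assert clipped.values.sum() <= fiber.values.sum()


class TestRandomPairNull:
    def _cells(self, n, seed0=0, colocalized=True):
        cellsA, cellsB = [], []
        for k in range(n):
            spec = dataclasses.replace(PAIR_SPEC, seed=seed0 + k)
            ia, ib, ta, tb = generate_paired(spec, 0.8 if colocalized else 0.0, 1.0)
            cellsA.append(ta)
            cellsB.append(tb)
        return cellsA, cellsB

    def test_single_cell_errors(self):
        a, b = self._cells(1)
        with pytest.raises(ValueError):
            random_pair_null(a, b, seed=0)

    def test_no_central_peak_for_independent_networks(self):
        excesses = []
        for seed in range(20):
            a, b = self._cells(4, seed0=1000 + 10 * seed, colocalized=False)
            sup = [elliptical_cell_mask((192, 192))] * 4
            avg = random_pair_null(a, b, seed=seed, supportsA=sup, supportsB=sup)
            c = Correlogram(avg.mean, 112.0, "overlap", "cross")
            excesses.append(central_peak_excess(c))
        excesses = np.array(excesses)
        assert abs(excesses.mean()) < 3 * excesses.std(ddof=1)

    def test_same_cell_peak_dominates_null_peak(self):
        a, b = self._cells(6, colocalized=True)
        sup = [elliptical_cell_mask((192, 192))] * 6
        _, pk_same = same_cell_crosstalk(list(zip(a, b)), max_lag=40)
        avg = random_pair_null(a, b, seed=5, supportsA=sup, supportsB=sup)
        c = Correlogram(avg.mean, 112.0, "overlap", "cross")
        lag = c.max_lag
        pk_null = peak_and_background(c, 9, (min(27, lag - 1), min(36, lag)))
        assert pk_same.peak_height > pk_null.peak_height

    def test_cloned_mask_still_peaks_in_null(self):
        # pathological input: every cell identical, so even the derangement
        # pairing correlates a mask with its own copy
        m = disc_mask(101, (50, 50), 45)
        fibers = np.random.default_rng(2).random((101, 101)) < 0.25
        fm = mask_of(fibers & m.values)
        a = [fm] * 3
        avg = random_pair_null(a, a, seed=0, supportsA=[m] * 3, supportsB=[m] * 3)
        c = Correlogram(avg.mean, 112.0, "overlap", "cross")
        lag = c.max_lag
        pk = peak_and_background(c, 9, (min(27, lag - 1), min(36, lag)))
        assert pk.peak_height > 0.05

    def test_derangement_never_pairs_cell_with_itself(self):
        from cytoorder.crosstalk import _random_derangement

        rng = np.random.default_rng(0)
        for n in (2, 3, 5, 11):
            for _ in range(20):
                perm = _random_derangement(n, rng)
                assert not np.any(perm == np.arange(n))
                assert sorted(perm) == list(range(n))


class TestDiscOverlapNormalization:
    def test_removes_cross_artifact_for_isotropic_disc_content(self):
        # rectangle normalization under-weights diagonal lags of a disc
        # region; the circle-overlap normalization restores isotropy
        rng = np.random.default_rng(4)
        r = 45
        m = disc_mask(2 * r + 1, (r, r), r)
        noise = mask_of((rng.random((2 * r + 1, 2 * r + 1)) < 0.4) & m.values)
        c = correlate_fft(noise, noise, 30)
        fixed = disc_overlap_normalization(c, r)
        lag = 20
        axis_vals = [c.at_lag(lag, 0), c.at_lag(0, lag)]
        diag = int(round(lag / np.sqrt(2)))
        diag_vals = [c.at_lag(diag, diag), c.at_lag(-diag, diag)]
        rect_ratio = np.mean(diag_vals) / np.mean(axis_vals)
        axis_f = [fixed.at_lag(lag, 0), fixed.at_lag(0, lag)]
        diag_f = [fixed.at_lag(diag, diag), fixed.at_lag(-diag, diag)]
        circ_ratio = np.mean(diag_f) / np.mean(axis_f)
        assert abs(circ_ratio - 1.0) < 0.05
        assert abs(circ_ratio - 1.0) < abs(rect_ratio - 1.0)
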