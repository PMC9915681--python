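"""Dendrite tracking: row maxima, closing/skeleton, binning, interpolation."""

import dataclasses

import numpy as np
import pytest

from cepquant.blebs import enhance
from cepquant.io import PixelCalibration
from cepquant.phantom import PhantomSpec, render
from cepquant.region import DendriteCrop, find_dendrite_region
from cepquant.tracking import (
    DendriteTrack,
    TrackSet,
    bin_to_dendrites,
    close_and_skeletonize,
    interpolate_and_smooth,
    rowwise_maxima,
    track_dendrites,
)

CAL1 = PixelCalibration(1.0)  # 1 µm/px so physical == pixel distances


def make_crop(rows, cols, cell_body_side="bottom", pixel_size=1.0):
    return DendriteCrop(
        intensities=np.zeros((rows, cols)),
        calibration=PixelCalibration(pixel_size),
        bit_depth=16,
        rotation_angle=0.0,
        offset=(0, 0),
        cell_body_side=cell_body_side,
    )


def gaussian_row(cols, centers, amp=1.0, sigma=1.5):
    x = np.arange(cols, dtype=float)
    row = np.zeros(cols)
    for c, a in centers:
        row += a * np.exp(-((x - c) ** 2) / (2 * sigma**2))
    return row


class TestRowwiseMaxima:
    def test_four_separated_peaks_found_at_centers(self):
        centers = [(10, 1.0), (30, 1.0), (50, 1.0), (70, 1.0)]
        img = np.tile(gaussian_row(90, centers), (20, 1))
        mask = rowwise_maxima(img, noise_estimate=0.01, calibration=CAL1, min_sep_um=5)
        for r in range(20):
            cols = np.nonzero(mask[r])[0]
            assert len(cols) == 4
            for c, _ in centers:
                assert np.min(np.abs(cols - c)) <= 1

    def test_flat_rows_yield_no_points(self):
        img = np.vstack([np.zeros((5, 60)), np.tile(gaussian_row(60, [(30, 1.0)]), (5, 1))])
        mask = rowwise_maxima(img, 0.01, CAL1, min_sep_um=5)
        assert mask[:5].sum() == 0
        assert mask[5:].sum() == 5

    def test_six_peaks_keep_four_most_intense(self):
        centers = [(10, 0.5), (22, 1.0), (34, 0.6), (46, 0.95), (58, 0.9), (70, 0.99)]
        img = np.tile(gaussian_row(85, centers), (4, 1))
        mask = rowwise_maxima(img, 0.01, CAL1, min_sep_um=5)
        expected = sorted([22, 46, 58, 70])
        for r in range(4):
            cols = sorted(np.nonzero(mask[r])[0])
            assert len(cols) == 4
            for c_exp, c_got in zip(expected, cols):
                assert abs(c_exp - c_got) <= 1

    def test_nonpositive_separation_rejected(self):
        with pytest.raises(ValueError):
            rowwise_maxima(np.zeros((4, 4)), 0.01, CAL1, min_sep_um=0)


class TestCloseAndSkeletonize:
    def test_dotted_line_with_small_gaps_becomes_one_segment(self):
        pts = np.zeros((40, 20), dtype=bool)
        pts[::3, 10] = True  # 2-px gaps
        labels = close_and_skeletonize(pts, CAL1, gap_um=5)
        assert labels.max() == 1

    def test_gaps_beyond_element_not_bridged(self):
        pts = np.zeros((40, 20), dtype=bool)
        pts[2:6, 10] = True
        pts[26:30, 10] = True  # 20 px between the two bars
        labels = close_and_skeletonize(pts, CAL1, gap_um=5)
        assert labels.max() == 2

    def test_phantom_points_give_four_segments(self, suite):
        _, img, _ = suite["clean"]
        crop = find_dendrite_region(img)
        enh = enhance(crop)
        mask = rowwise_maxima(enh.contrast_crop, enh.noise_estimate, crop.calibration)
        labels = close_and_skeletonize(mask, crop.calibration)
        assert labels.max() == 4

    def test_track_ends_at_border_not_eroded(self):
        pts = np.zeros((30, 9), dtype=bool)
        pts[:, 4] = True  # full-height line
        labels = close_and_skeletonize(pts, CAL1, gap_um=8)
        rows = np.nonzero(labels.any(axis=1))[0]
        assert rows.min() == 0 and rows.max() == 29


class TestBinToDendrites:
    def test_four_parallel_strands_indexed_left_to_right(self):
        seg = np.zeros((50, 100), dtype=int)
        for i, c in enumerate([20, 40, 60, 80]):
            seg[5:45, c] = i + 1
        crop = make_crop(50, 100)
        ts = bin_to_dendrites(seg, crop, min_sep_um=5)
        assert [t.index for t in ts.tracks] == [1, 2, 3, 4]
        means = [np.nanmean(t.x_of_row) for t in ts.tracks]
        assert means == sorted(means)
        np.testing.assert_allclose(means, [20, 40, 60, 80])

    def test_duplicate_claims_keep_nearer_point(self):
        # two strands converging: at the meeting rows only one point per
        # index may survive
        seg = np.zeros((40, 60), dtype=int)
        for r in range(40):
            seg[r, 20] = 1
            seg[r, max(21, 40 - r // 2)] = 2
        crop = make_crop(40, 60)
        ts = bin_to_dendrites(seg, crop, min_sep_um=3)
        assert len(ts.tracks) <= 4
        for r in range(40):
            xs = [t.x_of_row[r] for t in ts.tracks if not np.isnan(t.x_of_row[r])]
            assert len(xs) == len(set(xs))  # distinct x per row

    def test_five_strands_capped_at_four(self):
        seg = np.zeros((60, 130), dtype=int)
        for i, c in enumerate([15, 40, 65, 90, 115]):
            seg[5:55, c] = i + 1
        crop = make_crop(60, 130)
        ts = bin_to_dendrites(seg, crop, min_sep_um=5)
        assert len(ts.tracks) <= 4
        for r in range(60):
            n = sum(1 for t in ts.tracks if not np.isnan(t.x_of_row[r]))
            assert n <= 4

    def test_matches_greedy_assignment_oracle_on_small_grid(self):
        """Independent re-derivation of the binning rule on a small scene."""
        rng = np.random.default_rng(5)
        true_cols = [8.0, 20.0, 32.0]
        seg = np.zeros((30, 44), dtype=int)
        pts_by_row = {}
        for r in range(30):
            cols = [int(round(c + rng.normal(0, 0.5))) for c in true_cols]
            pts_by_row[r] = sorted(cols)
            for k, c in enumerate(cols):
                seg[r, c] = 1  # label value irrelevant to binning
        crop = make_crop(30, 44)
        ts = bin_to_dendrites(seg, crop, min_sep_um=2)
        # oracle: greedy nearest-EMA sweep, lowest index wins ties
        alpha = 1 / 25
        emas = None
        oracle = {r: {} for r in range(30)}
        for r in range(30):
            pts = pts_by_row[r]
            if emas is None:
                emas = [float(p) for p in pts]
                for j, p in enumerate(pts):
                    oracle[r][j] = p
                continue
            claims = {}
            for p in pts:
                d = [abs(p - m) for m in emas]
                j = int(np.argmin(d))
                if j not in claims or d[j] < abs(claims[j] - emas[j]):
                    claims[j] = p
            for j, p in claims.items():
                oracle[r][j] = p
                emas[j] = (1 - alpha) * emas[j] + alpha * p
        for r in range(30):
            got = {
                t.index - 1: t.x_of_row[r]
                for t in ts.tracks
                if t.observed_rows[r]
            }
            assert got == oracle[r]


class TestInterpolateAndSmooth:
    def _track_with_hole(self, rows=60, col=10.0, hole=(20, 30)):
        x = np.full(rows, col)
        obs = np.ones(rows, dtype=bool)
        x[hole[0] : hole[1]] = np.nan
        obs[hole[0] : hole[1]] = False
        x[:5] = np.nan
        obs[:5] = False
        return DendriteTrack(index=1, x_of_row=x, observed_rows=obs)

    def test_hole_filled_with_constant_and_length_matches(self):
        t = self._track_with_hole()
        crop = make_crop(60, 20, pixel_size=0.5)
        ts = interpolate_and_smooth(TrackSet(tracks=[t], crop_ref=crop))
        out = ts.tracks[0]
        s0, s1 = out.span
        assert np.allclose(out.x_of_row[s0:s1], 10.0)
        assert out.length == pytest.approx((s1 - s0 - 1) * 0.5)
        # interpolated rows stay flagged as unobserved
        assert not out.observed_rows[20:30].any()

    def test_sinusoid_arc_length_close_to_analytic(self):
        rows = 200
        rr = np.arange(rows, dtype=float)
        x = 30 + 8 * np.sin(2 * np.pi * rr / 120)
        t = DendriteTrack(index=1, x_of_row=x.copy(), observed_rows=np.ones(rows, bool))
        crop = make_crop(rows, 60, pixel_size=1.0)
        ts = interpolate_and_smooth(TrackSet(tracks=[t], crop_ref=crop), smoothing_um=1.0)
        # dense numeric arc length of the analytic curve
        rf = np.linspace(0, rows - 1, 20000)
        xf = 30 + 8 * np.sin(2 * np.pi * rf / 120)
        analytic = np.hypot(np.diff(rf), np.diff(xf)).sum()
        assert ts.tracks[0].length == pytest.approx(analytic, rel=0.02)

    def test_smoothing_is_fixed_point_on_straight_line(self):
        rows = 50
        x = np.full(rows, 7.0)
        t = DendriteTrack(index=1, x_of_row=x.copy(), observed_rows=np.ones(rows, bool))
        crop = make_crop(rows, 20, pixel_size=0.2)
        ts = interpolate_and_smooth(TrackSet(tracks=[t], crop_ref=crop))
        np.testing.assert_allclose(ts.tracks[0].x_of_row, 7.0)


class TestEndToEndTracking:
    def _tracks(self, suite, name):
        _, img, gt = suite[name]
        crop = find_dendrite_region(img)
        enh = enhance(crop)
        return crop, gt, track_dendrites(crop, enh.contrast_crop, enh.noise_estimate)

    def test_break_free_phantom_mad_within_1_5_px(self, suite):
        crop, gt, ts = self._tracks(suite, "clean")
        assert crop.rotation_angle == 0.0
        assert len(ts.tracks) == 4
        r0, c0 = crop.offset
        for i, t in enumerate(ts.tracks):
            s0, s1 = t.span
            errs = [
                abs(t.x_of_row[r] + c0 - gt.true_tracks[i, r + r0])
                for r in range(s0, s1)
                if not np.isnan(gt.true_tracks[i, r + r0])
            ]
            assert np.mean(errs) <= 1.5

    def test_at_most_four_tracks_and_indices_per_row(self, suite):
        for name in ("clean", "five_strand", "broken_50", "hairpin"):
            _, _, ts = self._tracks(suite, name)
            assert len(ts.tracks) <= 4
            n_rows = len(ts.tracks[0].x_of_row)
            for r in range(n_rows):
                n = sum(1 for t in ts.tracks if not np.isnan(t.x_of_row[r]))
                assert n <= 4

    def test_mirror_equivariance(self, suite):
        crop, _, ts = self._tracks(suite, "clean")
        flipped = dataclasses.replace(crop, intensities=crop.intensities[:, ::-1].copy())
        enh_f = enhance(flipped)
        ts_f = track_dendrites(flipped, enh_f.contrast_crop, enh_f.noise_estimate)
        assert len(ts_f.tracks) == len(ts.tracks)
        cols = crop.shape[1]
        for t, t_f in zip(ts.tracks, reversed(ts_f.tracks)):
            both = ~np.isnan(t.x_of_row) & ~np.isnan(t_f.x_of_row)
            assert both.sum() > 0.9 * t.n_rows()
            diff = np.abs((cols - 1 - t_f.x_of_row[both]) - t.x_of_row[both])
            assert np.median(diff) <= 1.0

    def test_hairpin_is_smoothed_through_not_followed(self, suite):
        """Documented limitation: turns >= 90 deg are interpolated across."""
        spec, _, _ = suite["hairpin"]
        crop, gt, ts = self._tracks(suite, "hairpin")
        kinked = ts.tracks[1]
        s0, s1 = kinked.span
        xs = kinked.x_of_row[s0:s1]
        # the 3 µm sideways excursion is not reproduced: the recovered path
        # stays close to the main strand column
        assert np.nanmax(np.abs(np.diff(xs))) < spec.kinks[0].depth_um / crop.pixel_size / 2
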