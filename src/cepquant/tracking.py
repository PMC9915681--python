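"""Trace up to four dendrites through the cropped image.

The tracker works on the crop-scale contrast-enhanced image:

1. per row, up to four local intensity maxima above a noise floor and
   mutually separated by a physical minimum distance;
2. morphological closing with a vertical line bridges small vertical gaps in
   the resulting point mask, and skeletonization thins the result back to
   1-px-wide segments;
3. sweeping rows from the distal end toward the cell body, each segment point
   is binned to the dendrite whose exponentially weighted running-average
   column is nearest; duplicate assignments in a row keep the nearer point;
4. each track is interpolated over missing rows within its observed span and
   smoothed with a physical-length moving average.

A hard cap of four tracks reflects the anatomy (four CEP dendrites).  The
tracker does not follow turns of 90 degrees or more -- a hairpin is smoothed
through and interpolated, a known and documented limitation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage import measure
from skimage.morphology import skeletonize

from .io import PixelCalibration, to_pixels
from .region import DendriteCrop

__all__ = [
    "DendriteTrack",
    "TrackSet",
    "rowwise_maxima",
    "close_and_skeletonize",
    "bin_to_dendrites",
    "interpolate_and_smooth",
    "track_dendrites",
]

MAX_TRACKS = 4
MIN_SEP_UM = 1.5
PROMINENCE_GAIN = 2.0  # prominence floor = gain * noise estimate
CLOSING_GAP_UM = 4.0
SMOOTHING_WINDOW_UM = 3.0
EMA_MEMORY_ROWS = 25
NEW_TRACK_FACTOR = 3.0  # open a new track beyond factor * min_sep from all EMAs
ANCHOR_RUN_ROWS = 5  # a track end must sit on this many consecutive observed rows
MIN_SEGMENT_PX = 3  # skeleton fragments below this are discarded as noise


@dataclasses.dataclass
class DendriteTrack:
    """One traced dendrite.

    ``x_of_row[r]`` is the (continuous) column position at crop row ``r`` or
    NaN where the track is absent; ``observed_rows`` flags rows supported by
    a true detected maximum rather than interpolation.
    """

    index: int  # 1-4
    x_of_row: np.ndarray  # float, NaN = absent
    observed_rows: np.ndarray  # bool
    length: float = 0.0  # µm along the smoothed path
    mean_intensity: float = float("nan")  # original camera units
    break_intervals: list[tuple[int, int]] = dataclasses.field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        rows = np.where(~np.isnan(self.x_of_row))[0]
        if len(rows) == 0:
            return (0, 0)
        return int(rows.min()), int(rows.max()) + 1

    def n_rows(self) -> int:
        s0, s1 = self.span
        return s1 - s0


@dataclasses.dataclass
class TrackSet:
    tracks: list[DendriteTrack]
    crop_ref: DendriteCrop

    def __post_init__(self) -> None:
        if len(self.tracks) > MAX_TRACKS:
            raise ValueError("more than four dendrite tracks")
        idx = [t.index for t in self.tracks]
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate track indices")


def rowwise_maxima(
    img: np.ndarray,
    noise_estimate: float,
    calibration: PixelCalibration,
    k: int = MAX_TRACKS,
    min_sep_um: float = MIN_SEP_UM,
) -> np.ndarray:
    """Per-row local maxima point mask: up to ``k`` peaks per row.

    Peaks must exceed a prominence floor (``PROMINENCE_GAIN x noise``), rise
    above the image's global Otsu level (background noise in a
    contrast-equalized image has high local prominence but stays below the
    foreground level), and be mutually separated by at least ``min_sep_um``.
    Rows inside breaks yield fewer than ``k`` points; flat rows yield none.
    """
    if min_sep_um <= 0:
        raise ValueError("min_sep must be positive")
    sep = to_pixels(min_sep_um, calibration)
    floor = max(PROMINENCE_GAIN * noise_estimate, 1e-6)
    if img.max() > img.min():
        from skimage.filters import threshold_otsu

        height = float(threshold_otsu(img))
    else:
        height = np.inf
    mask = np.zeros(img.shape, dtype=bool)
    for r in range(img.shape[0]):
        peaks, props = find_peaks(img[r], distance=sep, prominence=floor, height=height)
        if len(peaks) > k:
            order = np.argsort(img[r][peaks])[::-1][:k]
            peaks = peaks[order]
        mask[r, peaks] = True
    return mask


def close_and_skeletonize(
    points: np.ndarray, calibration: PixelCalibration, gap_um: float = CLOSING_GAP_UM
) -> np.ndarray:
    """Bridge vertical gaps below ``gap_um`` and thin to 1-px segments.

    Returns a labeled integer array of connected skeleton segments.
    """
    if gap_um <= 0:
        raise ValueError("gap must be positive")
    length = to_pixels(gap_um, calibration)
    structure = np.ones((length, 1), dtype=bool)
    # pad vertically so the dilation half of the closing has room past the
    # image border; otherwise track ends within `length/2` rows of the edge
    # are eroded away
    padded = np.pad(points, ((length, length), (0, 0)))
    closed = ndimage.binary_closing(padded, structure=structure)[length:-length]
    skel = skeletonize(closed)
    labels = measure.label(skel, connectivity=2)
    # segments of a couple of pixels are isolated noise points, not dendrite
    # evidence; drop and relabel
    for p in measure.regionprops(labels):
        if p.area < MIN_SEGMENT_PX:
            labels[labels == p.label] = 0
    return measure.label(labels > 0, connectivity=2)


def bin_to_dendrites(
    segments: np.ndarray,
    crop: DendriteCrop,
    min_sep_um: float = MIN_SEP_UM,
) -> TrackSet:
    """Assign skeleton points to at most four dendrite tracks.

    Sweeps rows from the distal end toward the cell body, matching each
    point to the nearest exponentially weighted running-average column.
    Ties go to the lower track index; conflicting points in a row keep the
    nearer one; a point farther than ``NEW_TRACK_FACTOR x min_sep`` from all
    running averages opens a new track while fewer than four exist.  If more
    than four column clusters appear, the four with the most supporting rows
    are kept.
    """
    rows, cols = segments.shape
    sep_px = to_pixels(min_sep_um, crop.calibration)
    open_radius = NEW_TRACK_FACTOR * sep_px
    alpha = 1.0 / EMA_MEMORY_ROWS

    # sweep direction: distal -> cell body
    if crop.cell_body_side == "bottom":
        row_order = range(rows)
    else:
        row_order = range(rows - 1, -1, -1)

    emas: list[float] = []
    xs: list[dict[int, float]] = []  # per-track {row: x}
    support: list[int] = []

    for r in row_order:
        pts = np.nonzero(segments[r])[0]
        if len(pts) == 0:
            continue
        # candidate assignment: nearest EMA per point
        claims: dict[int, tuple[float, float]] = {}  # track -> (dist, x)
        unassigned: list[float] = []
        for x in sorted(pts):
            if emas:
                d = [abs(x - m) for m in emas]
                j = int(np.argmin(d))  # argmin takes the first = lowest index on ties
                if d[j] <= open_radius:
                    if j not in claims or d[j] < claims[j][0]:
                        claims[j] = (d[j], float(x))
                    continue
            unassigned.append(float(x))
        for j, (_, x) in claims.items():
            xs[j][r] = x
            emas[j] = (1 - alpha) * emas[j] + alpha * x
            support[j] += 1
        for x in unassigned:
            emas.append(x)
            xs.append({r: x})
            support.append(1)

    if len(emas) > MAX_TRACKS:
        keep = sorted(
            np.argsort(support)[::-1][:MAX_TRACKS]
        )  # the four longest-supported
    else:
        keep = list(range(len(emas)))

    # order indices 1..4 left to right by mean column
    keep.sort(key=lambda j: np.mean(list(xs[j].values())))
    tracks = []
    for i, j in enumerate(keep):
        x_of_row = np.full(rows, np.nan)
        observed = np.zeros(rows, dtype=bool)
        for r, x in xs[j].items():
            x_of_row[r] = x
            observed[r] = True
        _trim_unanchored_ends(x_of_row, observed)
        if not observed.any():
            continue
        tracks.append(DendriteTrack(index=i + 1, x_of_row=x_of_row, observed_rows=observed))
    for i, t in enumerate(tracks):  # reindex if a track vanished entirely
        t.index = i + 1
    return TrackSet(tracks=tracks, crop_ref=crop)


def _trim_unanchored_ends(x_of_row: np.ndarray, observed: np.ndarray) -> None:
    """Drop isolated observed rows at the track ends (in place).

    A real dendrite end yields maxima on contiguous rows; sporadic noise
    points binned near the ends would otherwise stretch the span and read
    as breaks.  Rows are trimmed from each end until the end sits on a run
    of at least ``ANCHOR_RUN_ROWS`` consecutive observed rows.
    """
    obs = np.where(observed)[0]
    if len(obs) == 0:
        return
    runs = np.split(obs, np.where(np.diff(obs) > 1)[0] + 1)
    while runs and len(runs[0]) < ANCHOR_RUN_ROWS:
        drop = runs.pop(0)
        x_of_row[drop] = np.nan
        observed[drop] = False
    while runs and len(runs[-1]) < ANCHOR_RUN_ROWS:
        drop = runs.pop()
        x_of_row[drop] = np.nan
        observed[drop] = False


def interpolate_and_smooth(
    trackset: TrackSet, smoothing_um: float = SMOOTHING_WINDOW_UM
) -> TrackSet:
    """Fill missing rows inside each track's span and smooth the x path.

    Interpolation is piecewise linear over rows; smoothing is a moving
    average with a physical window. ``observed_rows`` flags are preserved,
    so interpolated rows remain identifiable. Track length is the polyline
    arc length in µm; mean intensity is sampled from the original crop
    along the track.
    """
    crop = trackset.crop_ref
    px = crop.pixel_size
    win = max(1, to_pixels(smoothing_um, crop.calibration))
    out_tracks = []
    for t in trackset.tracks:
        s0, s1 = t.span
        if s1 - s0 == 0:
            out_tracks.append(t)
            continue
        rows = np.arange(s0, s1)
        known = ~np.isnan(t.x_of_row[s0:s1])
        x = np.interp(rows, rows[known], t.x_of_row[s0:s1][known])
        if win > 1 and len(x) > win:
            kernel = np.ones(win) / win
            # reflect-pad so the smoother is a fixed point on straight lines
            pad = win // 2
            xp = np.pad(x, pad, mode="reflect")
            x = np.convolve(xp, kernel, mode="same")[pad : pad + len(rows)]
        x_of_row = np.full_like(t.x_of_row, np.nan)
        x_of_row[s0:s1] = x
        d = np.hypot(np.diff(rows.astype(float)), np.diff(x))
        length = float(d.sum() * px)
        cols_i = np.clip(np.round(x).astype(int), 0, crop.shape[1] - 1)
        mean_int = float(crop.intensities[rows, cols_i].mean())
        out_tracks.append(
            DendriteTrack(
                index=t.index,
                x_of_row=x_of_row,
                observed_rows=t.observed_rows.copy(),
                length=length,
                mean_intensity=mean_int,
                break_intervals=list(t.break_intervals),
            )
        )
    return TrackSet(tracks=out_tracks, crop_ref=crop)


def track_dendrites(
    crop: DendriteCrop,
    contrast_img: np.ndarray,
    noise_estimate: float,
    min_sep_um: float = MIN_SEP_UM,
) -> TrackSet:
    """Full tracking stage: maxima, closing/skeleton, binning, smoothing."""
    pts = rowwise_maxima(contrast_img, noise_estimate, crop.calibration, min_sep_um=min_sep_um)
    segments = close_and_skeletonize(pts, crop.calibration)
    raw = bin_to_dendrites(segments, crop, min_sep_um=min_sep_um)
    return interpolate_and_smooth(raw)
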