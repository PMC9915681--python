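"""Break detection, feature-to-dendrite matching, the 19-metric report, and
the 0-4 categorical degeneration score.

Break detection compares each dendrite track, row by row, against an
Otsu-binarized image of the dendrites: a row whose probe window around the
track position contains no foreground is a break row, and
``dendrite_remaining`` is the fraction of track rows that are not breaks.

The categorical score bins each dendrite from ``dendrite_remaining`` and
``feature_count`` alone:

====  ==========================================------------------
 0    more than 85% dendrite remaining and no blebs
 1    fewer than 5 blebs (remaining > 85%)
 2    5 or more blebs (remaining > 85%)
 3    between 50% and 85% dendrite remaining
 4    50% or less dendrite remaining
====  ==========================================------------------

Rules are evaluated in precedence order 4 -> 3 -> 0 -> 2 -> 1, so breakage
grades outrank blebbing grades, mirroring manual scales where loss of the
dendrite is the more severe phenotype.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from skimage.filters import threshold_otsu

from .blebs import BlebFeature
from .region import DendriteCrop, global_contrast
from .tracking import DendriteTrack, TrackSet

__all__ = [
    "METRIC_NAMES",
    "DegenerationScore",
    "binarize_dendrites",
    "detect_breaks",
    "match_features",
    "compute_report",
    "categorize",
]

PROBE_HALF_WIDTH_UM = 0.75  # break probe: +/- one dendrite width around the track
MATCH_RADIUS_UM = 3.0  # max centroid-to-track distance for feature matching
MIN_BREAK_LENGTH_UM = 1.0  # shorter gaps are binarization-edge jitter, not breaks

# category boundaries (config-exposed)
REMAINING_SEVERE = 0.50
REMAINING_MODERATE = 0.85
BLEB_MANY = 5

#: The 19 degeneration metrics reported per dendrite, in canonical order.
METRIC_NAMES: tuple[str, ...] = (
    "dendrite_length",
    "dendrite_remaining",
    "break_count",
    "total_break_length",
    "dendrite_mean_intensity",
    "feature_count",
    "feature_count_per_length",
    "weighted_feature_count",
    "mean_feature_area",
    "mean_feature_circularity",
    "mean_feature_extent",
    "mean_feature_eccentricity",
    "mean_feature_min_caliper",
    "mean_feature_max_caliper",
    "mean_feature_intensity",
    "mean_feature_norm_location",
    "feature_location_dispersion",
    "mean_feature_distance_from_cell_body",
    "degeneration_category",
)


@dataclasses.dataclass(frozen=True)
class DegenerationScore:
    category: int
    basis: str

    def __post_init__(self) -> None:
        if self.category not in (0, 1, 2, 3, 4):
            raise ValueError(f"category must be 0-4, got {self.category}")


def binarize_dendrites(crop: DendriteCrop) -> np.ndarray:
    """Otsu binarization of the contrast-adjusted crop (dendrite foreground)."""
    norm = crop.normalized()
    if norm.max() <= norm.min():
        return np.zeros(norm.shape, dtype=bool)
    adj = global_contrast(norm)
    return adj > threshold_otsu(adj)


def detect_breaks(
    track: DendriteTrack,
    dendrite_mask: np.ndarray,
    crop: DendriteCrop,
    probe_half_width_um: float = PROBE_HALF_WIDTH_UM,
) -> tuple[list[tuple[int, int]], float]:
    """Break intervals for one track, plus the fraction of dendrite remaining.

    A track row is a break row when a horizontal probe window of physical
    half-width ``probe_half_width_um`` centred on the track position contains
    no foreground in ``dendrite_mask``. Maximal runs of break rows become
    half-open intervals; runs shorter than ``MIN_BREAK_LENGTH_UM`` are
    discarded as binarization-edge jitter. ``remaining = 1 - break_rows /
    track_rows``.
    """
    from .io import to_pixels

    s0, s1 = track.span
    if s1 - s0 == 0:
        return [], 0.0
    w = to_pixels(probe_half_width_um, crop.calibration)
    cols = dendrite_mask.shape[1]
    break_rows = np.zeros(s1 - s0, dtype=bool)
    for i, r in enumerate(range(s0, s1)):
        x = track.x_of_row[r]
        if math.isnan(x):
            break_rows[i] = True
            continue
        c = int(round(x))
        lo, hi = max(c - w, 0), min(c + w + 1, cols)
        if not dendrite_mask[r, lo:hi].any():
            break_rows[i] = True

    min_rows = to_pixels(MIN_BREAK_LENGTH_UM, crop.calibration)
    intervals: list[tuple[int, int]] = []
    in_run = False
    for i, b in enumerate(break_rows):
        if b and not in_run:
            start = s0 + i
            in_run = True
        elif not b and in_run:
            intervals.append((start, s0 + i))
            in_run = False
    if in_run:
        intervals.append((start, s1))
    kept = [(a, b) for a, b in intervals if b - a >= min_rows]
    n_break = sum(b - a for a, b in kept)
    remaining = 1.0 - n_break / len(break_rows)
    return kept, float(remaining)


def _arc_from_cell_body(track: DendriteTrack, crop: DendriteCrop) -> np.ndarray:
    """Cumulative arc length (px) from the cell-body end, indexed by crop row."""
    s0, s1 = track.span
    rows = np.arange(s0, s1)
    x = track.x_of_row[s0:s1]
    seg = np.hypot(np.diff(rows.astype(float)), np.diff(x))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if crop.cell_body_side == "bottom":
        cum = cum[-1] - cum
    arc = np.full(len(track.x_of_row), np.nan)
    arc[s0:s1] = cum
    return arc


def match_features(
    features: list[BlebFeature],
    trackset: TrackSet,
    match_radius_um: float = MATCH_RADIUS_UM,
) -> tuple[list[BlebFeature], list[BlebFeature]]:
    """Assign each feature to the nearest track at its centroid row.

    A feature matches the track minimizing the horizontal distance between
    its centroid and the track position at that row, within a physical
    radius; ties break to the lower track index. Returns (matched,
    unmatched); unmatched features are reported separately, never silently
    dropped.
    """
    crop = trackset.crop_ref
    px = crop.pixel_size
    arcs = {t.index: _arc_from_cell_body(t, crop) for t in trackset.tracks}
    matched: list[BlebFeature] = []
    unmatched: list[BlebFeature] = []
    for f in features:
        r = int(round(f.centroid[0]))
        best: tuple[float, DendriteTrack] | None = None
        for t in trackset.tracks:  # ascending index: first-wins ties
            s0, s1 = t.span
            rr = min(max(r, s0), s1 - 1) if s1 > s0 else None
            if rr is None or math.isnan(t.x_of_row[rr]):
                continue
            d = abs(f.centroid[1] - t.x_of_row[rr]) * px
            if d <= match_radius_um and (best is None or d < best[0]):
                best = (d, t)
        if best is None:
            unmatched.append(f)
            continue
        _, t = best
        s0, s1 = t.span
        rr = min(max(r, s0), s1 - 1)
        arc_px = arcs[t.index][rr]
        dist_um = float(arc_px * px)
        norm = dist_um / t.length if t.length > 0 else 0.0
        matched.append(
            dataclasses.replace(
                f,
                dendrite_index=t.index,
                norm_location=float(np.clip(norm, 0.0, 1.0)),
                distance_from_cell_body=dist_um,
            )
        )
    return matched, unmatched


def categorize(dendrite_remaining: float, feature_count: int) -> DegenerationScore:
    """Bin one dendrite into the 0-4 categorical degeneration score."""
    if dendrite_remaining <= REMAINING_SEVERE:
        return DegenerationScore(4, "remaining <= 50%")
    if dendrite_remaining <= REMAINING_MODERATE:
        return DegenerationScore(3, "50% < remaining <= 85%")
    if feature_count == 0:
        return DegenerationScore(0, "remaining > 85%, no blebs")
    if feature_count >= BLEB_MANY:
        return DegenerationScore(2, ">= 5 blebs")
    return DegenerationScore(1, "1-4 blebs")


def _feature_stats(feats: list[BlebFeature]) -> dict[str, float]:
    """Per-dendrite means of feature descriptors; NaN markers when empty."""
    if not feats:
        keys = (
            "mean_feature_area", "mean_feature_circularity", "mean_feature_extent",
            "mean_feature_eccentricity", "mean_feature_min_caliper",
            "mean_feature_max_caliper", "mean_feature_intensity",
            "mean_feature_norm_location", "feature_location_dispersion",
            "mean_feature_distance_from_cell_body",
        )
        return {k: float("nan") for k in keys}
    return {
        "mean_feature_area": float(np.mean([f.area for f in feats])),
        "mean_feature_circularity": float(np.mean([f.circularity for f in feats])),
        "mean_feature_extent": float(np.mean([f.extent for f in feats])),
        "mean_feature_eccentricity": float(np.mean([f.eccentricity for f in feats])),
        "mean_feature_min_caliper": float(np.mean([f.min_caliper for f in feats])),
        "mean_feature_max_caliper": float(np.mean([f.max_caliper for f in feats])),
        "mean_feature_intensity": float(np.mean([f.mean_intensity for f in feats])),
        "mean_feature_norm_location": float(np.mean([f.norm_location for f in feats])),
        "feature_location_dispersion": float(np.std([f.norm_location for f in feats])),
        "mean_feature_distance_from_cell_body": float(
            np.mean([f.distance_from_cell_body for f in feats])
        ),
    }


def compute_report(
    trackset: TrackSet,
    matched_features: list[BlebFeature],
    image_id: str = "",
) -> list[dict]:
    """The 19 degeneration metrics per dendrite, plus a per-image aggregate.

    Each returned dict carries ``image_id``, ``dendrite_index`` and the
    metrics of :data:`METRIC_NAMES`. The aggregate row (``dendrite_index =
    'all'``) holds the mean over dendrites (NaN-aware for feature metrics).
    """
    crop = trackset.crop_ref
    px = crop.pixel_size
    rows_out: list[dict] = []
    for t in trackset.tracks:
        feats = [f for f in matched_features if f.dendrite_index == t.index]
        n_rows = t.n_rows()
        break_rows = sum(b - a for a, b in t.break_intervals)
        remaining = 1.0 - break_rows / n_rows if n_rows else 0.0
        rec = {
            "image_id": image_id,
            "dendrite_index": t.index,
            "dendrite_length": t.length,
            "dendrite_remaining": remaining,
            "break_count": len(t.break_intervals),
            "total_break_length": break_rows * px,
            "dendrite_mean_intensity": t.mean_intensity,
            "feature_count": len(feats),
            "feature_count_per_length": len(feats) / t.length if t.length > 0 else float("nan"),
            "weighted_feature_count": (
                len(feats) / remaining if remaining > 0 else float("inf") if feats else 0.0
            ),
        }
        rec.update(_feature_stats(feats))
        rec["degeneration_category"] = categorize(remaining, len(feats)).category
        rows_out.append(rec)

    if rows_out:
        agg = {"image_id": image_id, "dendrite_index": "all"}
        for name in METRIC_NAMES:
            vals = [r[name] for r in rows_out]
            finite = [v for v in vals if np.isfinite(v)]
            agg[name] = float(np.mean(finite)) if finite else float("nan")
        rows_out.append(agg)
    return rows_out
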