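# Methods

## The measurement problem

The four CEP dopaminergic dendrites of *C. elegans* degenerate in two
visually distinct modes: **blebbing** (roughly circular swellings that
protrude from the strand, "beads on a string") and **breakage** (gaps in the
strand). `cepquant` turns a maximum-projection image of these neurons plus a
camera pixel size into 19 per-dendrite metrics and a categorical 0–4 score.
Every size-dependent operation takes its size in µm and converts it through
the calibration (`to_pixels`, half-up rounding, floored at 1 px so
structuring elements never degenerate at coarse pixel sizes), which is what
makes one parameter set portable across imaging setups.

A single convention runs through all modules: row 0 at the image top,
`(row, col)` indexing, 0-based, half-open ranges. The crop records which
vertical end adjoined the cell bodies (`cell_body_side`), and all
along-dendrite positions (arc distance, normalized location) are measured
from that end.

## Pipeline stages and their parameters

### Dendrite region

Cell bodies are the brightest objects in a GFP image. After a global
contrast adjustment (linear rescale of the 1st–99.9th percentile range), the
mask of pixels above the **99.5th percentile** marks soma cores; each core is
grown by morphological reconstruction to the surrounding
near-soma-intensity region (≥ 0.75 of the threshold) so the centroid and
bounding box reflect the full cell bodies rather than a noise-biased
subsample. A constant image, or a threshold catching more than 30 % of
pixels, is rejected with an explicit error.

The rotation angle comes from the second-order central moments of the
soma+dendrite foreground. Plain Otsu tends to isolate only the bright somas
(whose cluster is perpendicular to the dendrites and would flip the angle by
90°), so the foreground is taken above the lower threshold of a 3-class
multi-Otsu. Rotations below 2° are skipped: interpolation costs more than
such a tilt is worth.

The image is split at the cell-body bounding box; each half is Otsu-binarized
and described by its connected components. "Circular" means circularity
(4πA/P²) > 0.6; "dendrite-like" means major axis > 4× minor and orientation
within 30° of vertical. The half with fewer circular objects wins; ties go to
the greater summed dendrite-like major-axis length. Border removal is
shape-aware: compact components touching any border are dropped (residual
soma fragments, edge clutter) while elongated vertical ones are kept —
dendrites necessarily touch the soma-adjacent border, so removing everything
that touches a border would delete the object of interest. The crop is the
tight bounding box of what remains plus a **2 µm** margin.

### Bleb detection

The crop is CLAHE-equalized with a clip limit that decreases as the
background noise rises (noise = 1.4826 × MAD of below-Otsu pixels; clip =
max(0.005, 0.03/(1+50·noise))) — noisy images get gentler equalization so
noise is not amplified into fake structure. The result is upsampled 4×
(bicubic) and background-subtracted. The background is a 5 µm-radius grey
opening computed at crop scale and upsampled; when the radius exceeds 15 px
the opening runs on a proportionally downscaled image instead — the
background is smooth at that scale, and this keeps the cost independent of
resolution.

Candidates come from a global threshold, Otsu **plus one robust noise
spread of the enhanced image itself** — local equalization inflates
background noise, especially in near-empty regions, so the noise term must be
measured after enhancement — followed by erosion with a horizontal line of
**2 × the expected dendrite width** (default width 0.75 µm): thin vertical
dendrites vanish, wider protrusions survive. Seeds under 2 px² are discarded.

Each seed is refined by morphological Chan–Vese segmentation in a window of
3× its bounding box, initialized from the seed. The iteration budget (50 at
the 0.2 µm/px reference) scales inversely with pixel size because the
morphological front advances about one pixel per iteration. Two
post-conditions keep the contour honest: an isotropic opening at ~1.25× the
expected dendrite width cuts the thin dendrite tails the contour grows
along (the same "features are wider than dendrites" premise as the erosion),
and a collapsed contour falls back to the seed's pre-erosion component
*restricted to the refinement window*, so a bleb connected to its dendrite
is not replaced by the whole strand. Overlapping refined masks merge into
one feature.

Measurements: area (µm²), circularity, extent (area / bounding-box area),
eccentricity, min/max Feret calipers (projection sweep at 3° steps), and
mean intensity sampled from the **original, unenhanced** crop under the
downscaled mask.

### Dendrite tracking

Tracking runs on the crop-scale CLAHE image. Per row, up to four peaks
(`scipy.signal.find_peaks`) with minimum separation **1.5 µm**, prominence
above 2× the crop noise, and height above the image's global Otsu level —
the height floor matters because equalized background noise has high local
prominence but stays below the foreground level. The point mask is closed
with a vertical line of **4 µm** (the mask is zero-padded first so closing
does not erode track ends at the image border), skeletonized, and fragments
under 3 px dropped.

Points are swept from the distal end toward the cell body and binned to the
nearest exponentially weighted running-average column (memory 25 rows).
Duplicate claims on one track in a row keep the nearer point; a point farther
than 3× the separation from every average opens a new track while fewer than
four exist; beyond four, the four longest-supported columns are kept, and
indices 1–4 are assigned left to right. Track ends must sit on a run of at
least 5 consecutive observed rows — sporadic noise points near the ends
would otherwise stretch the span and read as breaks. Tracks are then
linearly interpolated over missing rows inside their span (interpolated rows
stay flagged) and smoothed with a **3 µm** moving average; length is the
polyline arc length.

The tracker cannot follow turns of ≥ 90°: a hairpin is smoothed through and
interpolated. This is deliberate and documented, not fixed; the phantom
battery includes a hairpin fixture asserting exactly this behavior.

### Breaks, matching, report, category

Break detection probes, for each track row, a horizontal window of ± one
dendrite width (0.75 µm) around the track position against the
Otsu-binarized crop; rows with no foreground are break rows. Runs shorter
than **1 µm** are discarded as binarization-edge jitter — without that floor,
1–2 row slivers at track ends register as breaks on perfectly continuous
dendrites. `dendrite_remaining` is the fraction of track rows that are not
break rows.

Features are matched to the track minimizing horizontal distance at the
centroid row, within **3 µm**; ties go to the lower index; unmatched features
are reported in a side list, never silently dropped. Normalized location is
arc distance from the cell-body end divided by track length.

The categorical score uses only `dendrite_remaining` and `feature_count`,
with rules evaluated in precedence order 4 → 3 → 0 → 2 → 1 so breakage
outranks blebbing (mirroring manual scales, where loss of the dendrite is
the more severe phenotype). Boundaries: ≤ 0.50 → 4; (0.50, 0.85] → 3; then
0 blebs → 0, ≥ 5 blebs → 2, else 1. The boundary conventions make the scale
exhaustive (the verbal rules leave "exactly 5 blebs" and the endpoints
unstated).

### Group statistics

Each dendrite is one observation. z-scores use the control group's standard
deviation only — the score then reads "how many control-SDs the treatment
mean moved", and its sign encodes direction. One-way ANOVA is the classical
between/within mean-square F (via `scipy.stats.f_oneway`). Multiple
comparisons: Bonferroni (`min(1, m·p)`), or a many-to-one Dunnett-style
correction approximated by a seeded label permutation of the max-|t|
statistic over treatments vs control (add-one p estimator). Given only
p-values (no raw data), the Dunnett route degrades to the Šidák bound
`1−(1−p)^m`, its independent-comparison limit. Tests cross-check the
permutation approximation against the exact multivariate-t implementation
and verify family-wise error ≤ 0.06 at α = 0.05 over 2,000 simulated null
datasets, and ANOVA type-I error within [0.035, 0.065] over 2,000 nulls.

## The phantom model

Phantoms emulate the validation imagery: four (configurably 1–5)
near-vertical strands with sinusoidal column paths, rendered by integrating
an isotropic Gaussian profile (σ = 0.25 µm) along the path so a straight
strand has an exact Gaussian cross-section with peak 0.30 of full scale;
bright soma disks (radius 2 µm, 0.85 of full scale) at the proximal end
(image bottom pre-rotation); blebs as isotropic Gaussian bumps whose
diameter is the full width at half maximum (gain 1.2 × dendrite intensity —
brighter than the strand, dimmer than the somas, as in real images); breaks
as zeroed arc intervals whose exact remaining fraction is recorded; a
multiplicative linear illumination gradient; additive Gaussian noise
(default SD 0.01 of full scale, i.e. SNR 30; the low-SNR fixture uses 0.06,
SNR 5); optional whole-image rotation. Rendering is bitwise-deterministic
given spec + seed.

The default battery (`default_suite`) covers: clean; sparse (3) and dense
(12) blebs; 20/50/80 % loss; combined; 30° and 90° rotations; a five-strand
stressor; a hairpin; and low SNR — 12 fixtures, each rendering at 0.1 and
0.325 µm/px as well.

What the phantoms do **not** model: worm-body autofluorescence, depth-varying
blur from the projection, Poisson photon statistics (the noise hook is
config-extendable), motion artifacts, and dendrites that leave the frame.
Passing the phantom suite therefore demonstrates the pipeline's geometric
and quantitative correctness under controlled conditions, not robustness to
every real-world artifact.

## Problem sizes and runtime

Default phantoms are 256 × 192 px at 0.2 µm/px (a ~51 × 38 µm field with
~42 µm dendrites) — large enough that every stage operates at realistic
physical scales, small enough that the full 12-fixture battery runs the
complete pipeline in well under a minute. Statistical calibrations use 2,000
replicates with 199-permutation Dunnett nulls, vectorized.

## Known limitations

- **Feature contour sizes are not resolution-covariant to better than
  ~5–15 %.** The candidate threshold is noise-adaptive by design, and the
  converged Chan–Vese balance depends on the window's noise texture; both
  change when the same scene is sampled on a different pixel grid.
  Dendrite-geometry metrics (length, break length, remaining, arc
  positions) agree across a 2× pixel-size change to within a few percent;
  calipers and areas should be compared across resolutions only with this
  caveat in mind.
- Mirror symmetry of feature sizes holds to ~10 % (CLAHE tile grids are not
  mirror-symmetric).
- One worm per frame; all four dendrites must be visible. Overlapping
  dendrites are flagged by the QC check (overlap > 20 % of rows) because
  overlap reads as breakage.
- Blebs dimmer than the detection threshold or narrower than the erosion
  length (≈ 1.5 µm with defaults) are missed; a 1.5 µm bleb sits at the
  detection margin and its measured size is biased low.
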