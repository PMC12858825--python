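# Methods

This note documents the models and numerical choices behind the pipeline,
what the synthetic fixtures do and do not emulate, and the known limits of
the approach.

## Video model and quality gating

Videos are normalised to a `(T, m, n, c)` tensor and split into
single-channel stacks. Axis assignment trusts container metadata first
(TIFF axis tags `T/I/Z` time-like, `C/S` channel-like; a lone untagged axis
is taken as time), then a smallest-axis-is-channel heuristic (an axis of
size ≤ 8 among the leading axes), then an explicit caller hint; genuinely
ambiguous layouts raise an error naming the candidates rather than
guessing. Integer data use the dtype maximum as the dynamic-range ceiling;
for float data the observed global maximum plays that role, and every
range-relative rule applies unchanged.

Two per-channel quality flags gate the dataset: *low intensity* (time-mean
intensity below 1% of the dynamic range — severe photobleaching or failed
illumination makes the distribution shape untrustworthy because the dim
tail drops below the noise floor) and *saturated* (more than 1% of pixels
pinned at the ceiling — clipping distorts every moment). Both thresholds
are explicit parameters; flagged channels are excluded from the dataset
array by default but always processed, logged and recoverable with
`--include-flagged`. The flags are order-statistics of the pixel multiset
and therefore invariant to frame permutation.

## Binarization branch

The threshold is *mean-relative*: pixel > mean(frame) × (1 + %I/100).
Because each frame is thresholded against its own mean, a global
multiplicative fade (photobleaching) does not change the binary mask; a
constant frame produces an all-zero mask for any positive offset.
Binarization happens at full resolution; the binary mask is then pooled
over *p×p* windows with a ≥ 0.5 majority rule (the symmetric choice for
fractional window means; trailing partial windows average over the pixels
actually present). Region statistics are computed on the pooled analysis
stack, with the pooling factor recorded in provenance.

Islands use 8-connectivity — filamentous networks genuinely touch
diagonally — and voids 4-connectivity, the standard dual pairing that
prevents both phases percolating through the same diagonal contact.
Percolation is tested per axis (left↔right or top↔bottom) on the analysis
stack. All "maximum" metrics are robustified as the mean of the top 10% of
per-frame values (⌈·⌉ with a floor of one sample), which suppresses
single-frame segmentation flukes. Change metrics `dI`, `dV` are ratios of
the final-window mean to the initial-window mean over the first/last
max(1, ⌈X%·N⌉) evaluated frames; a zero initial mean makes the ratio
undefined and is reported as an empty CSV cell plus a flag column, never as
infinity, keeping dataset tables finite and machine-readable.

## Intensity branch

Shape statistics use population moments over the full-resolution pixel
multiset of each evaluated frame (no spatial pooling — pooling is a local
mean and biases every central moment toward zero). The sign convention is
S = (mean − central tendency)/σ, so a pronounced bright tail — bundling,
aggregation, condensation — is positive for both skewness variants.
Closed forms anchor the scale: an exponential field gives S1 → 1 − ln 2,
S2 → 1, K → 6; a symmetric two-point field attains the analytic kurtosis
floor K = −2 exactly.

Mode estimation is exact value-counting for integer frames (the natural
estimator for discrete camera data; ties break toward the lowest
intensity). For float frames the 256-bin histogram's raw argmax is an
unacceptable estimator — on a flat-topped distribution the argmax wanders
several bins under Poisson count noise, contributing mode errors of order
0.1 σ — so the binned counts are Gaussian-smoothed (σ = 4 bins) and the
peak refined by parabolic interpolation of the three surrounding bins.
The estimator remains fully deterministic; measured against the Gaussian
closed form it keeps |S2| error below 0.01 at 10⁶ pixels. Frames with
σ = 0 contribute zero-valued statistics with a degeneracy flag rather than
being dropped, so frame indexing stays aligned across branches.

Because mean, median, mode and σ all scale together under a positive
affine intensity map, S1, S2 and K are invariant to such maps (up to mode
binning granularity), which is what makes the branch blind to
multiplicative photobleaching while remaining sensitive to genuine
restructuring.

## Flow branch

Dense per-pixel displacement between consecutive evaluated frames is
estimated with scikit-image's pyramidal iterative Lucas–Kanade solver
(`optical_flow_ilk`; radius 7, 10 warps, prefilter on — all recorded in
provenance). The pyramid handles the 0.5–8 px/frame displacements typical
of this application; on band-limited test textures rigid shifts of
0.5–4 px are recovered to well under 1%. Displacements are block-averaged
per *p×p* window (default *p* = 8) and divided by the raw-frame gap
between the evaluated pair, so constant motion reports the same velocity
at any evaluation stride; with both µm/pixel and s/frame calibration the
unit becomes µm/s.

Angles use θ = atan2(−Δrow, Δcol): +π/2 is "up" on screen, bounds are
(−π, π] with −π folded onto +π. Direction statistics are circular: each
vector contributes its unit direction (magnitude-unweighted), the
resultant length R of the mean unit vector gives
σθ = sqrt(−2 ln max(R, 10⁻⁹)) (capped near 6.44 rad), and the circular
mean is atan2 of the mean components — two directions just either side of
the ±π boundary therefore average to ±π, never to zero. Zero-magnitude
vectors carry no direction and are excluded from direction pooling; an
optional minimum-magnitude mask (default off) can additionally exclude
sub-noise vectors. θ and σθ pool all vectors of all fields by default; a
config switch (`direction_pool="fields"`) instead summarises the per-field
mean directions. Near-constant frames are detected (relative intensity
spread < 10⁻⁶) and yield a zero field with a low-texture flag instead of
amplified solver noise.

## Barcode assembly and rendering

The 17 slots are fixed in order (7 IB + 6 ID + 4 OF) with ASCII-safe
column names; undefined values propagate as empty CSV cells with companion
flag columns. Floats are written with 17 significant digits and re-read
with round-trip parsing, so the CSV is a lossless archive. The SVG
heat-strip uses the plasma colormap with per-metric min→max normalisation
across the dataset (optionally fixed bounds for bounded metrics, for
cross-dataset comparability); a metric constant across the dataset renders
at the scale midpoint and undefined cells render as hatched neutral gray.
Rendering is plain deterministic text assembly: identical arrays produce
byte-identical documents.

## Batch orchestration

`run_batch` discovers inputs lexicographically, mirrors the input tree in
the output tree, writes four RDS CSVs per channel (binarization record,
intensity record, flow per-field summary, flow long-format vector table),
quarantines per-file failures in the run log without aborting, and records
the full effective configuration in the log so any run can be reproduced
from it. Rows are sorted by the configured key (default: speed `v`)
before writing, making outputs independent of processing order.

## Synthetic fixtures: what they emulate and what they do not

The generators produce the controlled conditions the pipeline is validated
against, each with analytic ground truth: rigid advection of a
band-limited texture (flow targets; textures are smoothed seeded noise
because dense flow is undefined on white noise, and shifting is done by
Fourier phase ramp for exact periodic subpixel motion), a stripe that
percolates in a chosen fraction of frames (connectivity and area targets
exact from geometry), amplitude-compensated contracting Gaussian blobs
(growing voids, sharpening bright tail, approximately conserved mean),
i.i.d. distribution fields (moment closed forms; the two-point field
places exactly half the pixels at each level so its closed forms are exact
rather than asymptotic), and exponential photobleaching over a static
structure with a fixed additive noise floor.

These fixtures validate the *measurement* chain, not the biology: they
contain no spatially varying background, no depth sectioning, no motion
blur, no camera shot noise model, and only rigid or affine-like dynamics.
Passing tests therefore certify that the metrics equal their definitions
on known inputs and that the conventions (ratio vs difference, sign,
angle) are honoured — not that the defaults are optimal for any particular
microscope or material.

## Problem sizes and defaults

Default screening parameters: %I = 10, k = 10, p = 4 (binarization, from
the useful 2–8 range), p = 8 (flow), X = 5, top fraction 10%. The test
suite and the acceptance script validate closed forms on 1024×1024 fields
(10⁶ pixels, where sampling noise sits comfortably below the asserted
tolerances), flow recovery on 96×96 five-frame clips in 8 directions at
0.5–4 px/frame, region statistics against an exhaustive flood-fill oracle
on all 2¹⁶ binary 4×4 frames plus seeded 32×32 frames, and compression on
a four-video, ~109 MB uint8 set.

## Known limitations

* The binarization assumes minimal spatial variation in background
  intensity; no illumination correction is applied.
* Mode skewness of near-symmetric float distributions is the least stable
  metric (mode estimation is intrinsically harder than median/moments);
  its binning granularity (~bin width/σ) bounds the attainable precision.
* Optical flow reports apparent motion: intensity fluctuations without
  material transport (blinking, bleaching gradients) can register as flow;
  the low-texture guard only catches the degenerate constant-frame case.
* Displacements larger than the pyramid capture range (roughly an eighth
  of the frame per evaluated gap) alias; choose k accordingly for fast
  samples.
* Only multi-page TIFF is read natively; other containers (e.g. .nd2)
  plug in through the reader registry.
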