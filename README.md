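# barcode-screen

High-throughput screening of time-lapse microscopy videos of active and
non-equilibrium materials — motor-driven cytoskeletal networks, migrating
cell monolayers, reconstituted biomaterial composites — into a compact
**1×17 structural-and-dynamical fingerprint ("barcode") per channel**.

Large video datasets (hundreds of GB) are hard to share, compare and mine.
This package reduces each single-channel video to 17 interpretable metrics
computed by three independent branches, archives richer per-branch reduced
data structures (RDS) as CSV for downstream analysis, and renders whole
datasets as color-coded barcode arrays (CSV + SVG), shrinking dataset size
by roughly four orders of magnitude.

## The 17 metrics

A video is modelled as a `(T, m, n, c)` array (frames × rows × columns ×
channels); each channel is analysed independently, evaluating every *k*-th
frame (default *k* = 10).

**Image binarization (IB) — 7 metrics.** Each frame is thresholded at a
percentage offset %I above its own mean intensity (default %I = 10; the
per-frame threshold tracks photobleaching) and pooled over *p×p* windows
(default *p* = 4). Connected white regions ("islands", 8-connected) and
black regions ("voids", 4-connected) give, as fractions of the field of
view:

| symbol | meaning |
|---|---|
| `C` | fraction of frames with an island percolating edge-to-edge along an axis |
| `I`, `V` | robust maxima of island / void area (mean of the top 10% of per-frame maxima) |
| `dI`, `dV` | final/initial area *ratios* over the first and last *X*% of frames (default *X* = 5); > 1 means growth |
| `I01`, `I02` | mean largest and second-largest island area in the initial window |

**Intensity distribution (ID) — 6 metrics.** Population statistics of the
pixel-intensity multiset per frame, a proxy for mass density:
median skewness `S1 = (mean − median)/σ`, mode skewness
`S2 = (mean − mode)/σ`, excess kurtosis `K = μ₄/σ⁴ − 3` (positive for a
pronounced bright tail / clustering), reported as robust maxima `K, S1, S2`
and initial-to-final *differences* `dK, dS1, dS2`. All three are σ-normalised,
so multiplicative photobleaching leaves them unchanged.

**Optical flow (OF) — 4 metrics.** Dense pyramidal Lucas–Kanade flow
between consecutive evaluated frames, block-averaged over *p×p* windows
(default *p* = 8) and normalised per frame interval (µm/s when calibrated):
mean speed `v`, speed change `dv`, and the circular mean direction `theta`
∈ (−π, π] (+π/2 = up) with circular standard deviation
`sigma_theta = sqrt(−2 ln R)` over all vectors — correct at the ±π boundary.

Dim and saturated channels are flagged (defaults: mean < 1% of dynamic
range, > 1% of pixels at the ceiling) and excluded from the dataset array
unless overridden.

## Worked example

Generate two synthetic videos — a texture drifting rightward at 2 px/frame
and a field of contracting clusters — then screen them:

```bash
barcode fixtures make translating_texture --out videos/drift.tif \
    --frames 20 --size 96 --seed 7 --param dx=2
barcode fixtures make contracting_clusters --out videos/aggregate.tif \
    --frames 20 --size 96 --seed 7
barcode run --input videos --output out --stride 2 --pool-ib 1
```

```
2 barcode row(s); 0 excluded; 0 failure(s)
```

Selected columns of `out/dataset_barcodes.csv` (rows sorted by speed `v`):

```
  source_path  C     I     V    dV     K    S2   dS2     v  theta  sigma_theta
aggregate.tif  0 0.132 0.725 1.149 2.582 0.985 0.465 0.224 -0.489        3.807
    drift.tif  0 0.069 0.626 0.996 0.111 0.037 0.000 1.998  0.001        0.041
```

The aggregating video shows growing voids (`dV = 1.149 > 1`), a sharpening
bright tail (`K = 2.58`, `dS2 = 0.465 > 0`) and slow, isotropic motion
(`v ≈ 0.22`, `sigma_theta ≈ 3.8`). The drifting texture is recovered at
`v = 1.998 ≈ 2` px/frame, direction `theta ≈ 0` (rightward) and almost no
directional spread (`sigma_theta = 0.04`), with no restructuring
(`dV ≈ 1`, `dS2 = 0`). `out/` also holds the four per-channel RDS CSVs,
the rendered `dataset_barcodes.svg` and a reproducible `run_log.txt`.

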