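"""Intensity-distribution (ID) branch.

The pixel-intensity histogram of each evaluated frame serves as a proxy for
the spatial mass distribution.  Three shape statistics are computed per
frame with population moments over the full-resolution pixel multiset:

* median skewness  S1 = (mean - median) / sigma
* mode skewness    S2 = (mean - mode) / sigma
* excess kurtosis  K  = mu4 / sigma^4 - 3

The sign convention makes a pronounced high-intensity tail positive, so
bundling/aggregation (bright dense regions plus dark depleted regions)
drives S1, S2 and K up.  Because every statistic is normalised by sigma,
a multiplicative intensity decay (photobleaching) leaves all three
unchanged.  The branch reduces the per-frame series to 6 metrics: robust
maxima K, S1, S2 and initial-to-final differences dK, dS1, dS2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d as _gaussian_filter1d

from .binarization import robust_max, _n_window
from .errors import ParameterError, PipelineError
from .video_io import VideoTensor, select_evaluated_frames

N_HISTOGRAM_BINS = 256


@dataclass
class IntensityFrameStats:
    """Distribution statistics for one frame."""

    frame_index: int
    mean: float
    median: float
    mode: float
    sigma: float
    S1_i: float
    S2_i: float
    K_i: float
    mu4: float
    histogram: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    degenerate: bool = False  # sigma == 0: shape stats reported as 0


@dataclass
class IDMetrics:
    """The 6 intensity-branch barcode entries."""

    K: float
    S1: float
    S2: float
    delta_K: float
    delta_S1: float
    delta_S2: float
    all_degenerate: bool = False


# histogram-smoothing scale (bins) for the float-frame mode estimator; a raw
# argmax over 256 bins wanders several bins on flat-topped distributions
_MODE_SMOOTH_BINS = 4.0


def _mode(values: np.ndarray, hist_range: Optional[tuple[float, float]]) -> tuple[float, np.ndarray]:
    """Most frequent intensity and the RDS histogram.

    Integer frames use exact value counts (the natural estimator for
    discrete camera data).  Float frames bin into 256 equal-width bins over
    [min, max]; to keep the estimate stable on flat-topped distributions the
    binned counts are Gaussian-smoothed before the peak is located and the
    peak position is refined by parabolic interpolation of the three bins
    around it.  Everything is deterministic; ties break toward the lowest
    intensity (argmax returns the first maximal bin).
    """
    lo, hi = hist_range if hist_range is not None else (float(values.min()), float(values.max()))
    if hi <= lo:
        hi = lo + 1.0
    if values.dtype.kind in "ui":
        counts = np.bincount(values.ravel().astype(np.int64))
        mode = float(np.argmax(counts))
        hist, _ = np.histogram(values, bins=N_HISTOGRAM_BINS, range=(lo, hi))
        return mode, hist
    vlo, vhi = float(values.min()), float(values.max())
    if vhi <= vlo:
        hist, _ = np.histogram(values, bins=N_HISTOGRAM_BINS, range=(lo, hi))
        return vlo, hist
    hist, edges = np.histogram(values, bins=N_HISTOGRAM_BINS, range=(vlo, vhi))
    smooth = _gaussian_filter1d(hist.astype(np.float64), _MODE_SMOOTH_BINS)
    b = int(np.argmax(smooth))
    center = 0.5 * (edges[b] + edges[b + 1])
    if 0 < b < N_HISTOGRAM_BINS - 1:
        y0, y1, y2 = smooth[b - 1], smooth[b], smooth[b + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # proper local maximum: sub-bin refinement
            center += 0.5 * (y0 - y2) / denom * (edges[1] - edges[0])
    if hist_range is not None:
        hist, _ = np.histogram(values, bins=N_HISTOGRAM_BINS, range=(lo, hi))
    return float(center), hist


def frame_intensity_stats(
    frame: np.ndarray,
    frame_index: int = 0,
    hist_range: Optional[tuple[float, float]] = None,
) -> IntensityFrameStats:
    """Population shape statistics of one frame's pixel-intensity multiset.

    A constant (sigma = 0) frame gets S1 = S2 = K = 0 with a degenerate flag
    rather than NaNs, so a dead frame cannot poison the branch reduction.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ParameterError("frame is empty")
    x = frame.astype(np.float64, copy=False).ravel()
    mean = float(x.mean())
    median = float(np.median(x))
    d = x - mean
    var = float(np.mean(d * d))
    sigma = math.sqrt(var)
    mu4 = float(np.mean(d ** 4))
    mode, hist = _mode(frame, hist_range)
    if sigma == 0.0:
        return IntensityFrameStats(frame_index, mean, median, mode, 0.0,
                                   0.0, 0.0, 0.0, mu4, hist, degenerate=True)
    return IntensityFrameStats(
        frame_index=frame_index,
        mean=mean,
        median=median,
        mode=mode,
        sigma=sigma,
        S1_i=(mean - median) / sigma,
        S2_i=(mean - mode) / sigma,
        K_i=mu4 / var ** 2 - 3.0,
        mu4=mu4,
        histogram=hist,
    )


def compile_id_metrics(stats: Sequence[IntensityFrameStats], X: float = 5.0,
                       top_frac: float = 10.0) -> IDMetrics:
    """Reduce per-frame shape statistics to the 6 ID metrics.

    Maxima use the same mean-of-top-``top_frac``% rule as the IB branch;
    change metrics are plain differences (final window mean minus initial
    window mean) — antisymmetric under time reversal.
    """
    if not stats:
        raise PipelineError("compile_id_metrics needs at least one frame record")
    if not (0 < X <= 100):
        raise ParameterError("change window X must lie in (0, 100]")
    if all(s.degenerate for s in stats):
        return IDMetrics(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, all_degenerate=True)
    n_x = _n_window(len(stats), X)
    K = np.array([s.K_i for s in stats])
    S1 = np.array([s.S1_i for s in stats])
    S2 = np.array([s.S2_i for s in stats])
    return IDMetrics(
        K=robust_max(K, top_frac),
        S1=robust_max(S1, top_frac),
        S2=robust_max(S2, top_frac),
        delta_K=float(K[-n_x:].mean() - K[:n_x].mean()),
        delta_S1=float(S1[-n_x:].mean() - S1[:n_x].mean()),
        delta_S2=float(S2[-n_x:].mean() - S2[:n_x].mean()),
    )


def run_id_branch(video: VideoTensor, k: int = 10, X: float = 5.0,
                  top_frac: float = 10.0):
    """Run the full ID branch on one channel: full-resolution statistics for
    every k-th frame (no spatial pooling — pooling distorts moments).

    Returns ``(IDMetrics, list[IntensityFrameStats])``.
    """
    idx = select_evaluated_frames(video.n_frames, k)
    rng = (0.0, float(video.max_representable)) if video.max_representable > 0 else None
    stats = [frame_intensity_stats(video.frames[i], frame_index=i, hist_range=rng)
             for i in idx]
    return compile_id_metrics(stats, X=X, top_frac=top_frac), stats
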