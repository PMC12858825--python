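"""Image-binarization (IB) branch.

Each evaluated frame is thresholded at a percentage offset above its own
mean intensity — a per-frame threshold that tracks photobleaching — then
optionally pooled over p x p windows.  Connected white regions ("islands",
where material resides) and black regions ("voids", material-free) are
measured as fractions of the field of view, and a frame is "connected"
when a white component percolates edge to edge along at least one axis.

The branch reduces a stack of per-frame records to 7 metrics:
C (fraction of percolating frames), I and V (robust maxima of island and
void area), dI and dV (final/initial area ratios), and I01, I02 (initial
largest and second-largest island areas).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage import measure

from ._blocks import block_mean
from .errors import ParameterError, PipelineError
from .video_io import VideoTensor, select_evaluated_frames


@dataclass
class BinaryFrameRecord:
    """Region statistics for one binarized frame (areas as FOV fractions)."""

    frame_index: int
    connected: int
    max_island_area: float
    second_island_area: float
    max_void_area: float
    island_count: int
    void_count: int
    threshold_used: float = float("nan")


@dataclass
class IBMetrics:
    """The 7 binarization-branch barcode entries."""

    C: float
    I: float
    V: float
    delta_I: float  # NaN when initial island area is 0 (flagged)
    delta_V: float
    I01: float
    I02: float
    delta_I_undefined: bool = False
    delta_V_undefined: bool = False


def binarize_frame(frame: np.ndarray, percent_offset: float = 10.0):
    """Threshold a frame at ``mean * (1 + %I/100)``.

    Returns ``(binary, threshold)``.  The threshold is mean-relative, making
    the output invariant to a global intensity rescale.  A constant frame
    yields an all-zero mask for any positive offset.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ParameterError("frame is empty")
    if percent_offset < 0:
        raise ParameterError("percent offset %I must be >= 0")
    threshold = float(frame.mean()) * (1.0 + percent_offset / 100.0)
    return frame > threshold, threshold


def downsample_binary(stack: np.ndarray, p: int) -> np.ndarray:
    """Pool a binary stack over p x p windows with a majority (>= 0.5) rule.

    Trailing partial windows are averaged over the pixels present.  ``p=1``
    is the identity.
    """
    stack = np.asarray(stack)
    single = stack.ndim == 2
    if single:
        stack = stack[None]
    m, n = stack.shape[1:]
    if p < 1 or p > min(m, n):
        raise ParameterError(f"pooling window p={p} invalid for {m}x{n} frames")
    if p == 1:
        out = stack.astype(bool)
    else:
        out = np.stack([block_mean(f, p) >= 0.5 for f in stack])
    return out[0] if single else out


def region_stats(binary_frame: np.ndarray, frame_index: int = 0,
                 threshold_used: float = float("nan")) -> BinaryFrameRecord:
    """Island/void areas and edge-to-edge percolation for one binary frame.

    Islands use 8-connectivity (filamentous structures touch diagonally),
    voids 4-connectivity — the standard dual pair that avoids both phases
    percolating through the same diagonal contact.  ``connected`` is 1 when
    a single white component touches both left and right edges, or both top
    and bottom edges.
    """
    bf = np.asarray(binary_frame).astype(bool)
    area = bf.size

    islands = measure.label(bf, connectivity=2)
    voids = measure.label(~bf, connectivity=1)
    island_sizes = np.bincount(islands.ravel())[1:]  # drop background label 0
    void_sizes = np.bincount(voids.ravel())[1:]

    top2 = np.sort(island_sizes)[::-1][:2] if island_sizes.size else np.array([])
    max_island = float(top2[0]) / area if top2.size else 0.0
    second_island = float(top2[1]) / area if top2.size > 1 else 0.0
    max_void = float(void_sizes.max()) / area if void_sizes.size else 0.0

    connected = 0
    if island_sizes.size:
        left, right = islands[:, 0], islands[:, -1]
        top, bottom = islands[0, :], islands[-1, :]
        lr = np.intersect1d(left[left > 0], right[right > 0])
        tb = np.intersect1d(top[top > 0], bottom[bottom > 0])
        connected = int(lr.size > 0 or tb.size > 0)

    return BinaryFrameRecord(
        frame_index=frame_index,
        connected=connected,
        max_island_area=max_island,
        second_island_area=second_island,
        max_void_area=max_void,
        island_count=int(island_sizes.size),
        void_count=int(void_sizes.size),
        threshold_used=threshold_used,
    )


def _n_window(n_records: int, percent: float) -> int:
    return max(1, math.ceil(percent / 100.0 * n_records))


def robust_max(values: Sequence[float], top_frac: float = 10.0) -> float:
    """Mean of the highest ``top_frac``% of values (at least one value).

    The robustified "maximum" used for every maximum-type barcode metric.
    """
    v = np.sort(np.asarray(values, dtype=float))[::-1]
    if v.size == 0:
        raise PipelineError("robust_max of an empty sequence")
    return float(v[: _n_window(v.size, top_frac)].mean())


def compile_ib_metrics(records: Sequence[BinaryFrameRecord], X: float = 5.0,
                       top_frac: float = 10.0) -> IBMetrics:
    """Reduce per-frame records to the 7 IB metrics.

    ``X`` is the percentage of frames defining the initial and final change
    windows; change metrics dI, dV are final/initial *ratios* (values > 1
    mean growth).  A zero initial-window mean makes the ratio undefined; it
    is reported as NaN with a flag rather than infinity.
    """
    if not records:
        raise PipelineError("compile_ib_metrics needs at least one frame record")
    if not (0 < X <= 100):
        raise ParameterError("change window X must lie in (0, 100]")
    n = len(records)
    n_x = _n_window(n, X)
    islands = np.array([r.max_island_area for r in records])
    seconds = np.array([r.second_island_area for r in records])
    vmax = np.array([r.max_void_area for r in records])
    conn = np.array([r.connected for r in records])

    init_I, fin_I = islands[:n_x].mean(), islands[-n_x:].mean()
    init_V, fin_V = vmax[:n_x].mean(), vmax[-n_x:].mean()
    dI_undef, dV_undef = init_I == 0.0, init_V == 0.0

    return IBMetrics(
        C=float(conn.mean()),
        I=robust_max(islands, top_frac),
        V=robust_max(vmax, top_frac),
        delta_I=float("nan") if dI_undef else float(fin_I / init_I),
        delta_V=float("nan") if dV_undef else float(fin_V / init_V),
        I01=float(islands[:n_x].mean()),
        I02=float(seconds[:n_x].mean()),
        delta_I_undefined=bool(dI_undef),
        delta_V_undefined=bool(dV_undef),
    )


def run_ib_branch(video: VideoTensor, percent_offset: float = 10.0, k: int = 10,
                  p: int = 4, X: float = 5.0, top_frac: float = 10.0,
                  keep_stacks: bool = False):
    """Run the full IB branch on one channel.

    Returns ``(IBMetrics, list[BinaryFrameRecord])`` — the records are the
    branch's reduced data structure.  With ``keep_stacks`` the pooled binary
    stack is returned as a third element (for optional TIFF export).
    """
    idx = select_evaluated_frames(video.n_frames, k)
    records, frames = [], []
    for i in idx:
        binary, thr = binarize_frame(video.frames[i], percent_offset)
        pooled = downsample_binary(binary, p)
        records.append(region_stats(pooled, frame_index=i, threshold_used=thr))
        if keep_stacks:
            frames.append(pooled)
    metrics = compile_ib_metrics(records, X=X, top_frac=top_frac)
    if keep_stacks:
        return metrics, records, np.stack(frames)
    return metrics, records
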