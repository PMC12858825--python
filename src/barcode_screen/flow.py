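"""Optical-flow (OF) branch.

Dense per-pixel motion between consecutive evaluated frames is estimated
with a pyramidal iterative Lucas–Kanade solver, block-averaged over p x p
windows into a downsampled velocity-vector grid, and normalised by the
frame gap so the reported unit is pixels per (raw) frame interval — or
micrometres per second when the tensor carries physical calibration.

Angle convention: theta = atan2(-delta_row, delta_col), i.e. +pi/2 is "up"
on screen and angles live in (-pi, pi].  Directions are summarised with
circular statistics — the resultant length R of the unit direction vectors
gives the circular standard deviation sigma_theta = sqrt(-2 ln R) — which
handles motion near the +-pi boundary correctly (two directions just either
side of the boundary average to +-pi, never to 0).

The branch reduces the per-field series to 4 metrics: mean speed v, speed
change dv (final minus initial window), and the pooled direction summary
(theta, sigma_theta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.registration import optical_flow_ilk

from ._blocks import block_mean
from .errors import ParameterError, PipelineError
from .video_io import VideoTensor, select_evaluated_frames

# resultant-length floor: caps sigma_theta near sqrt(-2 ln 1e-9) ~ 6.44 rad
R_EPSILON = 1e-9

#: Fixed dense-flow solver parameters, recorded in provenance.
DEFAULT_FLOW_PARAMS = {"radius": 7, "num_warp": 10, "gaussian": False, "prefilter": True}

# frames whose intensity spread is below this fraction of their mean are
# treated as textureless: flow on them is noise
_LOW_TEXTURE_REL_STD = 1e-6


@dataclass
class FlowField:
    """A downsampled velocity-vector grid for one evaluated frame pair.

    ``vectors[..., 0]`` is vx (+x = rightward columns) and
    ``vectors[..., 1]`` is vy (+y = up the screen, i.e. decreasing rows),
    in pixels per frame interval (or um/s when calibrated).
    """

    field_index: int
    frame_pair: tuple[int, int]
    vectors: np.ndarray
    v_i: float
    theta_i: float
    sigma_theta_i: float
    resultant_length: float
    low_texture: bool = False
    degenerate_direction: bool = False


@dataclass
class OFMetrics:
    """The 4 optical-flow barcode entries."""

    v: float
    delta_v: float
    theta: float
    sigma_theta: float
    undefined: bool = False  # fewer than two evaluated frames


def circular_summary(vectors: np.ndarray,
                     min_magnitude: float = 0.0) -> tuple[float, float, float]:
    """Circular mean direction, circular standard deviation and resultant
    length of a collection of (vx, vy) vectors.

    Each vector contributes its unit direction (magnitude-unweighted);
    zero-magnitude vectors carry no direction and are always excluded, and
    ``min_magnitude`` optionally masks sub-noise vectors as well.  Returns
    ``(theta, sigma_theta, R)``; an all-excluded collection returns
    ``(0.0, 0.0, 0.0)`` — the degenerate no-motion case.
    """
    v = np.asarray(vectors, dtype=float).reshape(-1, 2)
    if v.shape[0] == 0:
        raise ParameterError("circular_summary needs at least one vector")
    mag = np.hypot(v[:, 0], v[:, 1])
    moving = mag > max(min_magnitude, 0.0)
    if not moving.any():
        return 0.0, 0.0, 0.0
    u = v[moving] / mag[moving, None]
    cbar, sbar = float(u[:, 0].mean()), float(u[:, 1].mean())
    R = min(math.hypot(cbar, sbar), 1.0)  # guard float rounding above 1
    theta = math.atan2(sbar, cbar)
    if theta <= -math.pi:  # fold -pi onto +pi: bounds are (-pi, pi]
        theta = math.pi
    sigma = math.sqrt(-2.0 * math.log(max(R, R_EPSILON)))
    return theta, sigma, R


def compute_flow_field(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    p: int = 8,
    flow_params: Optional[dict] = None,
    frame_gap: int = 1,
    field_index: int = 0,
    frame_pair: Optional[tuple[int, int]] = None,
    velocity_scale: float = 1.0,
) -> FlowField:
    """Estimate the window-averaged velocity field between two frames.

    The dense displacement field is block-averaged per ``p x p`` window and
    divided by ``frame_gap`` (number of raw frames between the pair), so
    constant motion reports the same velocity regardless of the evaluation
    stride.  ``velocity_scale`` converts px/frame to physical units when
    calibration is available.
    """
    a = np.asarray(frame_a, dtype=np.float32)
    b = np.asarray(frame_b, dtype=np.float32)
    if a.shape != b.shape:
        raise PipelineError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if p < 1 or p > min(a.shape):
        raise ParameterError(f"pooling window p={p} invalid for {a.shape} frames")
    if frame_gap < 1:
        raise ParameterError("frame_gap must be >= 1")
    params = dict(DEFAULT_FLOW_PARAMS)
    if flow_params:
        params.update(flow_params)

    low_texture = False
    mean_scale = max(abs(float(a.mean())), abs(float(b.mean())), 1.0)
    if float(a.std()) < _LOW_TEXTURE_REL_STD * mean_scale or \
       float(b.std()) < _LOW_TEXTURE_REL_STD * mean_scale:
        low_texture = True
        d_row = np.zeros((math.ceil(a.shape[0] / p), math.ceil(a.shape[1] / p)))
        d_col = np.zeros_like(d_row)
    else:
        flow = optical_flow_ilk(a, b, **params)  # (2, m, n): (d_row, d_col)
        d_row = block_mean(flow[0], p)
        d_col = block_mean(flow[1], p)

    scale = velocity_scale / frame_gap
    vx = d_col * scale
    vy = -d_row * scale  # screen-up positive
    vectors = np.stack([vx, vy], axis=-1)
    speed = float(np.hypot(vx, vy).mean())
    theta, sigma, R = circular_summary(vectors)
    return FlowField(
        field_index=field_index,
        frame_pair=frame_pair if frame_pair is not None else (0, frame_gap),
        vectors=vectors,
        v_i=speed,
        theta_i=theta,
        sigma_theta_i=sigma,
        resultant_length=R,
        low_texture=low_texture,
        degenerate_direction=R == 0.0,
    )


def compile_of_metrics(fields: Sequence[FlowField], X: float = 5.0,
                       pool: str = "vectors",
                       min_magnitude: float = 0.0) -> OFMetrics:
    """Reduce the flow-field series to the 4 OF metrics.

    ``v`` is the plain mean of per-field mean speeds (every field weighted
    equally); ``dv`` the final-minus-initial window difference.  ``theta``
    and ``sigma_theta`` pool the unit directions of all vectors of all
    fields by default; ``pool="fields"`` instead takes the circular summary
    of the per-field mean directions.
    """
    if not fields:
        return OFMetrics(float("nan"), float("nan"), float("nan"), float("nan"),
                         undefined=True)
    if not (0 < X <= 100):
        raise ParameterError("change window X must lie in (0, 100]")
    from .binarization import _n_window

    v_i = np.array([f.v_i for f in fields])
    n_x = _n_window(len(fields), X)
    if pool == "vectors":
        allv = np.concatenate([f.vectors.reshape(-1, 2) for f in fields])
        theta, sigma, _ = circular_summary(allv, min_magnitude=min_magnitude)
    elif pool == "fields":
        dirs = np.array([[math.cos(f.theta_i), math.sin(f.theta_i)]
                         for f in fields if not f.degenerate_direction])
        theta, sigma, _ = circular_summary(dirs) if dirs.size else (0.0, 0.0, 0.0)
    else:
        raise ParameterError(f"unknown direction pooling mode {pool!r}")
    return OFMetrics(
        v=float(v_i.mean()),
        delta_v=float(v_i[-n_x:].mean() - v_i[:n_x].mean()),
        theta=theta,
        sigma_theta=sigma,
    )


def run_of_branch(video: VideoTensor, k: int = 10, p: int = 8, X: float = 5.0,
                  flow_params: Optional[dict] = None, pool: str = "vectors"):
    """Run the full OF branch on one channel.

    Velocity fields are computed between consecutive evaluated frames and
    normalised per raw frame interval; with both ``pixel_size_um`` and
    ``frame_interval_s`` set on the tensor, velocities are in um/s.

    Returns ``(OFMetrics, list[FlowField])``.  A single-frame video yields
    undefined (NaN) metrics with a flag and an empty field list.
    """
    idx = select_evaluated_frames(video.n_frames, k)
    if len(idx) < 2:
        return compile_of_metrics([], X=X), []
    scale = 1.0
    if video.pixel_size_um is not None and video.frame_interval_s is not None:
        scale = video.pixel_size_um / video.frame_interval_s
    fields = []
    for j in range(len(idx) - 1):
        a, b = idx[j], idx[j + 1]
        fields.append(
            compute_flow_field(
                video.frames[a], video.frames[b], p=p, flow_params=flow_params,
                frame_gap=b - a, field_index=j, frame_pair=(a, b),
                velocity_scale=scale,
            )
        )
    return compile_of_metrics(fields, X=X, pool=pool), fields
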