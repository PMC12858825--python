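"""Video loading and the canonical (T, m, n, c) tensor model.

Multi-channel time-lapse stacks are normalised into per-channel
:class:`VideoTensor` objects with shape (T, m, n).  Axis order is resolved
from container metadata first, a smallest-axis-is-channel heuristic second,
and an explicit caller hint third.  A reader registry lets other container
formats plug in without touching the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import tifffile

from .errors import AxisAmbiguityError, MalformedVideoError, ParameterError, VideoReadError

# Axis characters used by TIFF metadata: time-like, channel-like, spatial.
# 'Q' is tifffile's "unknown" tag: trusted as time only when it is the single
# non-spatial axis.
_TIME_AXES = set("TIZ")
_CHANNEL_AXES = set("CS")
_MAX_PLAUSIBLE_CHANNELS = 8


@dataclass
class VideoTensor:
    """A single-channel grayscale frame stack.

    Attributes
    ----------
    frames : ndarray, shape (T, m, n)
        Scalar intensities, all >= 0.
    dtype_kind : str
        Numpy-style kind+bits tag of the source data, e.g. ``"u8"``, ``"u16"``,
        ``"f32"``.
    max_representable : float
        Dynamic-range ceiling: the dtype maximum for integer data, the
        observed global maximum for float data.
    pixel_size_um, frame_interval_s : float or None
        Optional physical calibration (micrometres per pixel, seconds per frame).
    source_path : str
        Origin of the data, for provenance.
    channel_index : int
        Which channel of the source container this tensor is.
    """

    frames: np.ndarray
    dtype_kind: str
    max_representable: float
    pixel_size_um: Optional[float] = None
    frame_interval_s: Optional[float] = None
    source_path: str = ""
    channel_index: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise MalformedVideoError(
                f"VideoTensor frames must be (T, m, n); got shape {self.frames.shape}"
            )
        T, m, n = self.frames.shape
        if m < 8 or n < 8:
            raise MalformedVideoError(f"frame size {m}x{n} below the 8x8 minimum")
        if T < 1:
            raise MalformedVideoError("video must contain at least one frame")
        if self.pixel_size_um is not None and self.pixel_size_um < 0:
            raise ParameterError("pixel_size_um must be >= 0")
        if self.frame_interval_s is not None and self.frame_interval_s <= 0:
            raise ParameterError("frame_interval_s must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape  # type: ignore[return-value]

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def save_tiff(self, path) -> None:
        """Write the stack as a multi-page grayscale TIFF (bit-exact round trip)."""
        tifffile.imwrite(str(path), self.frames, photometric="minisblack",
                         metadata={"axes": "TYX"})


@dataclass
class QualityFlags:
    """Per-channel usability flags.

    Videos whose time-averaged mean intensity sits below a small fraction of
    the dynamic range are flagged as too dim to trust the distribution-shape
    metrics; videos with a substantial fraction of pixels pinned at the
    dynamic-range ceiling are flagged as saturated.
    """

    low_intensity: bool
    saturated: bool
    fraction_saturated_pixels: float
    mean_intensity_fraction: float

    @property
    def any(self) -> bool:
        return self.low_intensity or self.saturated


def _dtype_tag(dtype: np.dtype) -> str:
    return f"{dtype.kind}{dtype.itemsize * 8}"


def _max_representable(arr: np.ndarray) -> float:
    if arr.dtype.kind in "ui":
        return float(np.iinfo(arr.dtype).max)
    # float data: dynamic-range rules are relative to the observed global max
    return float(arr.max()) if arr.size else 0.0


def _tensors_from_tcyx(
    arr: np.ndarray, path: str, pixel_size_um=None, frame_interval_s=None
) -> list[VideoTensor]:
    """Split a (T, C, Y, X) array into per-channel tensors."""
    maxrep = _max_representable(arr)
    tag = _dtype_tag(arr.dtype)
    out = []
    for c in range(arr.shape[1]):
        out.append(
            VideoTensor(
                frames=np.ascontiguousarray(arr[:, c]),
                dtype_kind=tag,
                max_representable=maxrep,
                pixel_size_um=pixel_size_um,
                frame_interval_s=frame_interval_s,
                source_path=path,
                channel_index=c,
            )
        )
    return out


def _normalize_axes(arr: np.ndarray, axes: str | None, hint: Optional[int]) -> np.ndarray:
    """Return the array transposed to (T, C, Y, X).

    ``axes`` is the container's axis string (e.g. ``"TYX"``, ``"TCYX"``) when
    trustworthy; ``hint`` is the caller's channel-axis index in the raw array.
    """
    if arr.ndim == 2:
        return arr[None, None]

    if axes is not None and len(axes) == arr.ndim and "Y" in axes and "X" in axes:
        y, x = axes.index("Y"), axes.index("X")
        chan = [i for i, a in enumerate(axes) if a in _CHANNEL_AXES]
        time = [i for i, a in enumerate(axes) if a in _TIME_AXES and i not in (y, x)]
        unknown = [i for i in range(arr.ndim)
                   if i not in (y, x) and i not in chan and i not in time]
        if len(unknown) == 1 and not time:
            time = unknown  # a lone untagged axis can only be time
        elif unknown:
            time = []
            chan = []  # metadata unusable: fall through to heuristics
        if len(chan) <= 1 and len(chan) + len(time) + 2 == arr.ndim:
            order_t = time
            if len(order_t) > 1:
                # collapse multiple time-like axes (e.g. Z+T) into one
                perm = order_t + chan + [y, x]
                arr = arr.transpose(perm)
                tshape = arr.shape[: len(order_t)]
                arr = arr.reshape((int(np.prod(tshape)),) + arr.shape[len(order_t):])
                if not chan:
                    arr = arr[:, None]
                return arr
            perm = (order_t or []) + chan + [y, x]
            arr = arr.transpose(perm)
            if not order_t:
                arr = arr[None]
            if not chan:
                arr = arr[:, None]
            return arr

    # metadata unusable: fall back to heuristics / hint
    if arr.ndim == 3:
        if hint is not None:
            # hint names the channel axis; the two remaining axes are spatial (T=1)
            return np.moveaxis(arr, hint, 0)[None]
        sizes = arr.shape
        # a trailing tiny axis is a channel axis (TYXC-style RGB/sample data)
        if sizes[2] <= _MAX_PLAUSIBLE_CHANNELS < sizes[0]:
            raise AxisAmbiguityError(
                f"3-D array of shape {sizes}: trailing axis of size {sizes[2]} could be "
                "channels (interpretation (T=1, Y, X, C)) or columns ((T, Y, X)); "
                "pass channel_axis_hint to disambiguate"
            )
        return arr[:, None]
    if arr.ndim == 4:
        if hint is not None:
            arr = np.moveaxis(arr, hint, 1)
            return arr
        candidates = [i for i in range(2) if arr.shape[i] <= _MAX_PLAUSIBLE_CHANNELS]
        if arr.shape[3] <= _MAX_PLAUSIBLE_CHANNELS and arr.shape[3] < min(arr.shape[1], arr.shape[2]):
            # TYXC dialect
            if not candidates:
                return np.moveaxis(arr, 3, 1)
            raise AxisAmbiguityError(
                f"4-D array of shape {arr.shape}: both axis {candidates[0]} and axis 3 "
                "are plausible channel axes; pass channel_axis_hint"
            )
        if len(candidates) == 1:
            return np.moveaxis(arr, candidates[0], 1)
        if len(candidates) == 2:
            if arr.shape[0] == arr.shape[1]:
                raise AxisAmbiguityError(
                    f"4-D array of shape {arr.shape}: axes 0 and 1 have equal plausible-"
                    "channel sizes; pass channel_axis_hint naming the channel axis"
                )
            # smaller of the two leading axes is the channel axis
            c = 0 if arr.shape[0] < arr.shape[1] else 1
            return np.moveaxis(arr, c, 1)
        raise AxisAmbiguityError(
            f"4-D array of shape {arr.shape}: no axis small enough to be a channel axis"
        )
    raise MalformedVideoError(f"cannot interpret {arr.ndim}-D array as a video")


def _read_tiff(path: str, channel_axis_hint: Optional[int]):
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            arr = series.asarray()
            axes = series.axes
    except (tifffile.TiffFileError, FileNotFoundError, OSError) as exc:
        raise VideoReadError(f"cannot read TIFF {path!r}: {exc}") from exc
    if arr.ndim >= 3 and axes is not None and set(axes) <= {"Q", "Y", "X"} and arr.ndim != len(axes):
        axes = None
    return arr, axes


# --- reader registry -------------------------------------------------------

_READERS: dict[str, Callable] = {}


def register_reader(extension: str, reader: Callable) -> None:
    """Register ``reader(path, channel_axis_hint) -> (array, axes_string|None)``
    for a file extension (with leading dot).  Lets third-party plug-ins add
    container formats (e.g. a native .nd2 reader) without modifying this module.
    """
    _READERS[extension.lower()] = reader


register_reader(".tif", _read_tiff)
register_reader(".tiff", _read_tiff)


def load_video(
    path,
    channel_axis_hint: Optional[int] = None,
    n_interleaved_channels: Optional[int] = None,
    pixel_size_um: Optional[float] = None,
    frame_interval_s: Optional[float] = None,
) -> list[VideoTensor]:
    """Load a video container into one :class:`VideoTensor` per channel.

    Parameters
    ----------
    path : path-like
        Multi-page TIFF (or any registered container format).
    channel_axis_hint : int, optional
        Index of the channel axis in the raw array, needed only when container
        metadata and size heuristics cannot disambiguate the axes.
    n_interleaved_channels : int, optional
        For page-interleaved stacks whose metadata records no channel axis:
        deinterleave a (c*T, m, n) stack into c channels of T frames each
        (channel index varies fastest, the common acquisition layout).

    Returns
    -------
    list of VideoTensor
        Channel order preserved; axis order normalised to (T, m, n).
    """
    p = Path(path)
    ext = p.suffix.lower()
    reader = _READERS.get(ext)
    if reader is None:
        raise VideoReadError(
            f"no reader registered for {ext!r} (registered: {sorted(_READERS)})"
        )
    arr, axes = reader(str(p), channel_axis_hint)
    arr = np.asarray(arr)
    if arr.dtype.kind not in "uif":
        raise MalformedVideoError(f"unsupported pixel dtype {arr.dtype}")
    if n_interleaved_channels is not None and arr.ndim == 3:
        c = int(n_interleaved_channels)
        if c < 1 or arr.shape[0] % c:
            raise MalformedVideoError(
                f"{arr.shape[0]} pages do not deinterleave into {c} channels"
            )
        arr = arr.reshape(arr.shape[0] // c, c, *arr.shape[1:])
        axes = "TCYX"
    tcyx = _normalize_axes(arr, axes, channel_axis_hint)
    if tcyx.shape[0] == 1:
        warnings.warn(
            f"{p.name}: single frame — optical-flow and change metrics will be undefined",
            stacklevel=2,
        )
    return _tensors_from_tcyx(
        tcyx, str(p), pixel_size_um=pixel_size_um, frame_interval_s=frame_interval_s
    )


def evaluate_quality(
    video: VideoTensor, low_frac: float = 0.01, sat_frac: float = 0.01
) -> QualityFlags:
    """Flag unusably dim or saturated channels.

    ``low_intensity`` is set when the time-averaged mean intensity falls below
    ``low_frac`` of the dynamic range; ``saturated`` when more than
    ``sat_frac`` of all pixels (over all frames) sit at the representable
    maximum.  Both checks are invariant to frame order.
    """
    if not (0 < low_frac < 1) or not (0 < sat_frac < 1):
        raise ParameterError("low_frac and sat_frac must lie in (0, 1)")
    maxrep = video.max_representable
    mean_frac = float(video.frames.mean()) / maxrep if maxrep > 0 else 0.0
    sat = float(np.count_nonzero(video.frames >= maxrep)) / video.frames.size if maxrep > 0 else 0.0
    return QualityFlags(
        low_intensity=mean_frac < low_frac,
        saturated=sat > sat_frac,
        fraction_saturated_pixels=sat,
        mean_intensity_fraction=mean_frac,
    )


def select_evaluated_frames(T: int, k: int) -> list[int]:
    """Indices of every k-th frame: {0, k, 2k, ...} < T (always includes 0)."""
    if k < 1:
        raise ParameterError(f"frame stride k must be >= 1, got {k}")
    if T < 1:
        raise ParameterError(f"frame count T must be >= 1, got {T}")
    return list(range(0, T, k))
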