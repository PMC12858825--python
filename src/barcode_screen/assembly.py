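"""Barcode assembly and dataset rendering.

The three branch outputs are concatenated into an ordered 1x17 fingerprint
per channel — 7 binarization metrics, 6 intensity-distribution metrics,
4 optical-flow metrics — and whole datasets of barcodes are written as a
CSV table and rendered as a color-coded SVG heat-strip array (plasma
colorscale, per-metric min-to-max normalisation by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import matplotlib
import numpy as np
import pandas as pd

from .binarization import IBMetrics
from .errors import ParameterError, PipelineError
from .flow import OFMetrics
from .intensity import IDMetrics
from .video_io import QualityFlags

#: The fixed metric order of every barcode (ASCII-safe symbols).
METRIC_NAMES = (
    "C", "I", "V", "dI", "dV", "I01", "I02",          # binarization branch
    "K", "S1", "S2", "dK", "dS1", "dS2",              # intensity branch
    "v", "dv", "theta", "sigma_theta",                # optical-flow branch
)

FLAG_NAMES = (
    "flag_dI_undefined", "flag_dV_undefined", "flag_id_degenerate",
    "flag_of_undefined", "flag_low_intensity", "flag_saturated",
)

PROVENANCE_COLUMNS = ("source_path", "channel")


@dataclass
class Barcode17:
    """One channel's ordered 17-metric fingerprint plus provenance and flags."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (17,):
            raise PipelineError(f"a barcode has exactly 17 slots, got {self.values.shape}")

    def __getitem__(self, name: str) -> float:
        return float(self.values[METRIC_NAMES.index(name)])

    def as_dict(self) -> dict:
        return dict(zip(METRIC_NAMES, (float(v) for v in self.values)))


@dataclass
class DatasetBarcodeArray:
    """An ordered collection of barcodes with rendering configuration."""

    rows: list
    sort_key: Optional[str] = None
    color_bounds: Optional[dict] = None  # metric -> (min, max); dataset-relative if None

    def sorted_by(self, key: str) -> "DatasetBarcodeArray":
        """Stable-sorted copy (undefined values last); metric values unchanged."""
        if key not in METRIC_NAMES:
            raise ParameterError(f"unknown sort key {key!r}")
        i = METRIC_NAMES.index(key)

        def keyfun(bc):
            v = float(bc.values[i])
            return (1, 0.0) if math.isnan(v) else (0, v)

        return DatasetBarcodeArray(
            rows=sorted(self.rows, key=keyfun),
            sort_key=key,
            color_bounds=self.color_bounds,
        )

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for bc in self.rows:
            rec = {c: bc.provenance.get(c, "") for c in PROVENANCE_COLUMNS}
            for key, val in bc.provenance.items():
                if key not in PROVENANCE_COLUMNS:
                    rec[key] = val
            rec.update(bc.as_dict())
            for f in FLAG_NAMES:
                rec[f] = int(bool(bc.flags.get(f.removeprefix("flag_"), False)))
            recs.append(rec)
        return pd.DataFrame(recs)


def assemble_barcode(
    ib: IBMetrics,
    idm: IDMetrics,
    of: OFMetrics,
    provenance: Optional[dict] = None,
    quality: Optional[QualityFlags] = None,
) -> Barcode17:
    """Concatenate the three branch outputs into one ordered barcode.

    All branches must have been run on the same evaluated-frame schedule;
    if the provenance records per-branch strides they are checked for
    consistency.  Undefined branch values (NaN sentinels) propagate with
    their flags.
    """
    prov = dict(provenance or {})
    strides = {key: prov[key] for key in ("k_ib", "k_id", "k_of") if key in prov}
    if len(set(strides.values())) > 1:
        raise PipelineError(f"branches ran with different frame strides: {strides}")
    values = np.array([
        ib.C, ib.I, ib.V, ib.delta_I, ib.delta_V, ib.I01, ib.I02,
        idm.K, idm.S1, idm.S2, idm.delta_K, idm.delta_S1, idm.delta_S2,
        of.v, of.delta_v, of.theta, of.sigma_theta,
    ], dtype=float)
    flags = {
        "dI_undefined": ib.delta_I_undefined,
        "dV_undefined": ib.delta_V_undefined,
        "id_degenerate": idm.all_degenerate,
        "of_undefined": of.undefined,
        "low_intensity": bool(quality.low_intensity) if quality else False,
        "saturated": bool(quality.saturated) if quality else False,
    }
    return Barcode17(values=values, provenance=prov, flags=flags)


def write_dataset_csv(array: DatasetBarcodeArray, path) -> None:
    """Write the dataset barcode table.

    Undefined metrics are emitted as empty cells with their companion flag
    column set; floats are formatted with 17 significant digits, so
    re-reading the CSV reproduces every value bit-for-bit.
    """
    df = array.to_dataframe()
    try:
        df.to_csv(path, index=False, na_rep="", float_format="%.17g")
    except OSError as exc:
        raise PipelineError(f"cannot write dataset CSV to {path}: {exc}") from exc


def read_dataset_csv(path) -> pd.DataFrame:
    """Re-read a dataset barcode CSV (empty metric cells become NaN)."""
    return pd.read_csv(path, float_precision="round_trip")


# --- SVG rendering ---------------------------------------------------------

_CELL_W, _CELL_H = 28, 22
_LABEL_W = 170
_HEADER_H = 26
_UNDEFINED_FILL = "#bdbdbd"


def _hex_color(cmap, x: float) -> str:
    r, g, b, _ = cmap(float(np.clip(x, 0.0, 1.0)))
    return "#{:02x}{:02x}{:02x}".format(round(r * 255), round(g * 255), round(b * 255))


def colorize_array(
    array: DatasetBarcodeArray,
    colormap: str = "plasma",
    fixed_bounds: Optional[dict] = None,
) -> str:
    """Render the dataset as an SVG heat-strip array; returns the SVG text.

    Each cell is colored by (value - min) / (max - min) for its metric,
    with min/max taken across the dataset (or from ``fixed_bounds`` for
    metrics listed there).  A metric constant across the dataset renders at
    the colorscale midpoint; undefined values render neutral gray with
    hatching.  Output is deterministic: identical arrays give identical text.
    """
    if not array.rows:
        raise ParameterError("cannot render an empty barcode array")
    try:
        cmap = matplotlib.colormaps[colormap]
    except KeyError as exc:
        raise ParameterError(f"unknown colormap {colormap!r}") from exc

    values = np.array([bc.values for bc in array.rows])  # (R, 17)
    bounds = dict(fixed_bounds or {})
    if array.color_bounds:
        bounds = {**array.color_bounds, **bounds}

    n_rows = len(array.rows)
    width = _LABEL_W + 17 * _CELL_W
    height = _HEADER_H + n_rows * _CELL_H
    out = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        '<defs><pattern id="undef" width="6" height="6" patternUnits="userSpaceOnUse" '
        'patternTransform="rotate(45)"><rect width="6" height="6" fill="' + _UNDEFINED_FILL
        + '"/><line x1="0" y1="0" x2="0" y2="6" stroke="#757575" stroke-width="2"/></pattern></defs>',
    ]
    for j, name in enumerate(METRIC_NAMES):
        x = _LABEL_W + j * _CELL_W + _CELL_W / 2
        out.append(
            f'<text x="{x}" y="{_HEADER_H - 8}" font-size="11" font-family="sans-serif" '
            f'text-anchor="middle">{name}</text>'
        )
    for i, bc in enumerate(array.rows):
        y = _HEADER_H + i * _CELL_H
        label = f"{bc.provenance.get('source_path', '')}:c{bc.provenance.get('channel', 0)}"
        out.append(
            f'<text x="{_LABEL_W - 6}" y="{y + _CELL_H - 7}" font-size="10" '
            f'font-family="sans-serif" text-anchor="end">{label}</text>'
        )
        for j, name in enumerate(METRIC_NAMES):
            v = values[i, j]
            x = _LABEL_W + j * _CELL_W
            if math.isnan(v):
                fill = "url(#undef)"
            else:
                col = values[:, j]
                if name in bounds:
                    lo, hi = bounds[name]
                else:
                    finite = col[~np.isnan(col)]
                    lo, hi = float(finite.min()), float(finite.max())
                frac = 0.5 if hi <= lo else (v - lo) / (hi - lo)
                fill = _hex_color(cmap, frac)
            out.append(
                f'<rect x="{x}" y="{y}" width="{_CELL_W}" height="{_CELL_H}" '
                f'fill="{fill}" stroke="#ffffff" stroke-width="0.5"/>'
            )
    out.append("</svg>")
    return "\n".join(out) + "\n"
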