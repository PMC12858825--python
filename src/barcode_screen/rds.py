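"""Reduced-data-structure (RDS) archives: one CSV per branch per channel.

The RDS files hold substantially more information than the 17-entry barcode
itself and are the entry point for downstream, hypothesis-driven analysis.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .binarization import BinaryFrameRecord
from .flow import FlowField
from .intensity import IntensityFrameStats, N_HISTOGRAM_BINS


def write_ib_rds(records: Sequence[BinaryFrameRecord], path) -> None:
    """Per-frame binarization statistics."""
    pd.DataFrame(
        {
            "frame_index": [r.frame_index for r in records],
            "threshold": [r.threshold_used for r in records],
            "C_i": [r.connected for r in records],
            "I_i": [r.max_island_area for r in records],
            "I2_i": [r.second_island_area for r in records],
            "V_i": [r.max_void_area for r in records],
            "island_count": [r.island_count for r in records],
            "void_count": [r.void_count for r in records],
        }
    ).to_csv(path, index=False)


def write_binary_stack_tiff(stack: np.ndarray, path) -> None:
    """Optional pixel-level archive of the pooled binarized stack as a
    1-bit multi-page TIFF."""
    tifffile.imwrite(str(path), np.asarray(stack).astype(bool),
                     photometric="minisblack", metadata={"axes": "TYX"})


def write_id_rds(stats: Sequence[IntensityFrameStats], path) -> None:
    """Per-frame distribution statistics followed by the 256-bin histogram."""
    base = {
        "frame_index": [s.frame_index for s in stats],
        "mean": [s.mean for s in stats],
        "median": [s.median for s in stats],
        "mode": [s.mode for s in stats],
        "sigma": [s.sigma for s in stats],
        "S1_i": [s.S1_i for s in stats],
        "S2_i": [s.S2_i for s in stats],
        "K_i": [s.K_i for s in stats],
    }
    hists = np.array([
        s.histogram if s.histogram.size == N_HISTOGRAM_BINS
        else np.zeros(N_HISTOGRAM_BINS, dtype=np.int64)
        for s in stats
    ])
    for b in range(N_HISTOGRAM_BINS):
        base[f"hist_{b}"] = hists[:, b]
    pd.DataFrame(base).to_csv(path, index=False)


def write_of_rds(fields: Sequence[FlowField], vector_path, summary_path) -> None:
    """Long-format vector table plus a per-field summary table."""
    rows = []
    for f in fields:
        gm, gn, _ = f.vectors.shape
        rr, cc = np.meshgrid(np.arange(gm), np.arange(gn), indexing="ij")
        rows.append(
            pd.DataFrame(
                {
                    "field_index": f.field_index,
                    "frame_a": f.frame_pair[0],
                    "frame_b": f.frame_pair[1],
                    "row": rr.ravel(),
                    "col": cc.ravel(),
                    "vx": f.vectors[..., 0].ravel(),
                    "vy": f.vectors[..., 1].ravel(),
                }
            )
        )
    long = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["field_index", "frame_a", "frame_b", "row", "col", "vx", "vy"]
    )
    long.to_csv(vector_path, index=False)
    pd.DataFrame(
        {
            "field_index": [f.field_index for f in fields],
            "v_i": [f.v_i for f in fields],
            "theta_i": [f.theta_i for f in fields],
            "sigma_theta_i": [f.sigma_theta_i for f in fields],
            "R": [f.resultant_length for f in fields],
        }
    ).to_csv(summary_path, index=False)
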