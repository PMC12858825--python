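"""Batch orchestration: run the three-branch pipeline over folder trees.

``run_batch`` walks a hierarchical input tree, pushes every channel of
every video through the binarization, intensity and flow branches, writes
the three per-channel RDS CSVs mirroring the input tree, and consolidates
all retained barcodes into the dataset CSV + SVG.  Per-file failures are
quarantined in the run log; identical config + inputs give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import time
import traceback
from configparser import ConfigParser
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import rds
from .assembly import DatasetBarcodeArray, assemble_barcode, colorize_array, write_dataset_csv
from .binarization import run_ib_branch
from .errors import BarcodeError
from .flow import DEFAULT_FLOW_PARAMS, run_of_branch
from .intensity import run_id_branch
from .video_io import evaluate_quality, load_video


@dataclass
class RunConfig:
    """Effective parameter set of one batch run (defaults are the validated
    screening defaults: %I = 10, k = 10, IB pooling p = 4 from the useful
    2–8 range, OF pooling p = 8, change window X = 5%)."""

    input_root: str = "."
    output_root: str = "barcode_out"
    percent_offset: float = 10.0
    stride: int = 10
    p_ib: int = 4
    p_of: int = 8
    change_window: float = 5.0
    top_frac: float = 10.0
    flow_params: dict = field(default_factory=lambda: dict(DEFAULT_FLOW_PARAMS))
    channels: str = "all"  # "all" or comma-separated indices
    low_frac: float = 0.01
    sat_frac: float = 0.01
    include_flagged: bool = False
    colormap: str = "plasma"
    sort_key: str = "v"
    direction_pool: str = "vectors"
    pattern: str = "*.tif*"
    seed: int = 0  # reserved for stochastic extensions; the pipeline itself is deterministic

    def selected_channels(self, n: int) -> list[int]:
        if self.channels == "all":
            return list(range(n))
        want = [int(c) for c in str(self.channels).split(",") if c != ""]
        return [c for c in want if 0 <= c < n]

    # -- lossless INI round trip -------------------------------------------
    def to_ini(self, path) -> None:
        cp = ConfigParser()
        cp["barcode"] = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "flow_params":
                v = ",".join(f"{key}={val}" for key, val in sorted(v.items()))
            cp["barcode"][f.name] = str(v)
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_ini(cls, path) -> "RunConfig":
        cp = ConfigParser()
        cp.read(path)
        sec = cp["barcode"]
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in sec:
                continue
            raw = sec[f.name]
            if f.name == "flow_params":
                fp = {}
                for item in raw.split(","):
                    key, val = item.split("=")
                    fp[key] = val in ("True", "true") if val in ("True", "False", "true", "false") \
                        else (int(val) if val.lstrip("-").isdigit() else float(val))
                kwargs[f.name] = fp
            elif f.type in ("int", int):
                kwargs[f.name] = int(raw)
            elif f.type in ("float", float):
                kwargs[f.name] = float(raw)
            elif f.type in ("bool", bool):
                kwargs[f.name] = raw in ("True", "true", "1")
            else:
                kwargs[f.name] = raw
        return cls(**kwargs)


def discover_videos(input_root, patterns: Sequence[str] = ("*.tif", "*.tiff")) -> list[Path]:
    """Deterministic (lexicographic) recursive listing of matching files."""
    root = Path(input_root)
    if not root.exists():
        raise BarcodeError(f"input root {root} does not exist")
    found = set()
    for pat in patterns:
        found.update(p for p in root.rglob(pat) if p.is_file())
    return sorted(found, key=lambda p: str(p.relative_to(root)))


@dataclass
class BatchResult:
    array: DatasetBarcodeArray
    log_lines: list
    excluded: list
    failures: list

    @property
    def ok(self) -> bool:
        return not self.failures


def process_channel(video, cfg: RunConfig):
    """Run all three branches on one channel; returns (barcode, rds_bundle)."""
    quality = evaluate_quality(video, cfg.low_frac, cfg.sat_frac)
    ib, ib_records = run_ib_branch(
        video, percent_offset=cfg.percent_offset, k=cfg.stride, p=cfg.p_ib,
        X=cfg.change_window, top_frac=cfg.top_frac,
    )
    idm, id_stats = run_id_branch(
        video, k=cfg.stride, X=cfg.change_window, top_frac=cfg.top_frac,
    )
    of, of_fields = run_of_branch(
        video, k=cfg.stride, p=cfg.p_of, X=cfg.change_window,
        flow_params=cfg.flow_params, pool=cfg.direction_pool,
    )
    provenance = {
        "source_path": video.source_path,
        "channel": video.channel_index,
        "percent_offset": cfg.percent_offset,
        "k": cfg.stride,
        "p_ib": cfg.p_ib,
        "p_of": cfg.p_of,
        "X": cfg.change_window,
        "top_frac": cfg.top_frac,
        "flow_params": ";".join(f"{a}={b}" for a, b in sorted(cfg.flow_params.items())),
    }
    barcode = assemble_barcode(ib, idm, of, provenance, quality)
    return barcode, (ib_records, id_stats, of_fields), quality


def run_batch(cfg: RunConfig) -> BatchResult:
    """Execute the pipeline over every discovered video.

    Writes, under ``cfg.output_root`` (mirroring the input tree): three RDS
    CSVs per channel, ``dataset_barcodes.csv``, ``dataset_barcodes.svg``,
    and ``run_log.txt``.  Flagged (dim/saturated) channels are excluded from
    the dataset array by default but always logged.
    """
    in_root, out_root = Path(cfg.input_root), Path(cfg.output_root)
    out_root.mkdir(parents=True, exist_ok=True)
    log: list[str] = ["# effective config"]
    for f in dataclasses.fields(cfg):
        log.append(f"#   {f.name} = {getattr(cfg, f.name)}")
    manifest = discover_videos(in_root, patterns=cfg.pattern.split(";"))
    if not manifest:
        log.append("WARNING: empty manifest — no videos matched")
    barcodes, excluded, failures = [], [], []
    for path in manifest:
        rel = path.relative_to(in_root)
        t0 = time.perf_counter()
        try:
            channels = load_video(path)
            for c in cfg.selected_channels(len(channels)):
                video = channels[c]
                barcode, (ib_r, id_s, of_f), quality = process_channel(video, cfg)
                stem = out_root / rel.parent / f"{rel.stem}_c{c}"
                stem.parent.mkdir(parents=True, exist_ok=True)
                rds.write_ib_rds(ib_r, f"{stem}_ib.csv")
                rds.write_id_rds(id_s, f"{stem}_id.csv")
                rds.write_of_rds(of_f, f"{stem}_of_vectors.csv", f"{stem}_of.csv")
                if quality.any and not cfg.include_flagged:
                    excluded.append((str(rel), c, quality))
                    log.append(
                        f"EXCLUDED {rel}:c{c} low_intensity={quality.low_intensity} "
                        f"saturated={quality.saturated}"
                    )
                else:
                    barcodes.append(barcode)
            log.append(f"OK {rel} ({len(channels)} channel(s), "
                       f"{time.perf_counter() - t0:.2f}s)")
        except Exception as exc:  # quarantine; the batch must not abort
            failures.append((str(rel), exc))
            log.append(f"FAILED {rel}: {type(exc).__name__}: {exc}")
            log.extend("#   " + ln for ln in traceback.format_exc().splitlines()[-3:])

    array = DatasetBarcodeArray(rows=barcodes).sorted_by(cfg.sort_key)
    if barcodes:
        write_dataset_csv(array, out_root / "dataset_barcodes.csv")
        (out_root / "dataset_barcodes.svg").write_text(
            colorize_array(array, colormap=cfg.colormap)
        )
    if excluded:
        log.append("# exclusion summary: " + ", ".join(f"{r}:c{c}" for r, c, _ in excluded))
    (out_root / "run_log.txt").write_text("\n".join(log) + "\n")
    return BatchResult(array=array, log_lines=log, excluded=excluded, failures=failures)
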