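"""File formats: indexed-PNG label masks, gap-table CSVs, JSON sidecars,
vector-dataset bundles, and overlay rendering.

All text artifacts are UTF-8 with LF newlines and '.' decimals; CSVs
start with a ``#`` comment line carrying the config hash and seed so any
output can be traced back to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .quantify import GapRecord, SpineCurve, validate_mask

# label index -> RGB palette for indexed PNGs (body sky blue, normal gap
# white, narrowed gap purple, matching the annotation convention)
_PALETTE = {0: (0, 0, 0), 1: (135, 206, 235), 2: (255, 255, 255), 3: (128, 0, 128)}

GAP_CSV_COLUMNS = [
    "gap_index",
    "start_row",
    "end_row",
    "width_px",
    "ratio_to_mean",
    "label",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config."""
    blob = json.dumps(config, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _provenance_line(run_hash: str | None, seed: int | None) -> str:
    return f"# config_hash={run_hash or 'none'} seed={'none' if seed is None else seed}\n"


def write_mask_png(path, mask: np.ndarray) -> None:
    """8-bit indexed PNG with the label palette."""
    arr = validate_mask(mask).astype(np.uint8)
    img = Image.fromarray(arr, mode="P")
    palette = [0] * 768
    for idx, rgb in _PALETTE.items():
        palette[3 * idx : 3 * idx + 3] = rgb
    img.putpalette(palette)
    img.save(path)


def read_mask_png(path) -> np.ndarray:
    """Read an indexed PNG/TIFF back into an integer label mask."""
    with Image.open(path) as img:
        if img.mode not in ("P", "L", "I", "I;16"):
            raise ValueError(f"{path}: expected an indexed/grayscale image, got {img.mode}")
        arr = np.asarray(img, dtype=np.int64)
    return validate_mask(arr)


def write_gap_csv(
    path,
    gaps: Iterable[GapRecord],
    run_hash: str | None = None,
    seed: int | None = None,
    extra_columns: dict[str, Sequence] | None = None,
) -> None:
    records = [
        {
            "gap_index": g.gap_index,
            "start_row": g.start_row,
            "end_row": g.end_row,
            "width_px": g.width_px,
            "ratio_to_mean": g.ratio_to_mean,
            "label": g.label,
        }
        for g in gaps
    ]
    frame = pd.DataFrame.from_records(records, columns=GAP_CSV_COLUMNS)
    if extra_columns:
        for name, values in extra_columns.items():
            frame[name] = list(values)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_provenance_line(run_hash, seed))
        frame.to_csv(fh, index=False, lineterminator="\n")


def read_gap_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_truth_csv(path, truth, run_hash: str | None = None, seed: int | None = None) -> None:
    """Ground-truth gap table: gap_index,start_row,end_row,width_px,label."""
    frame = pd.DataFrame.from_records(
        [
            {
                "gap_index": g.gap_index,
                "start_row": g.start_row,
                "end_row": g.end_row,
                "width_px": g.width_px,
                "label": g.label,
            }
            for g in truth.gaps
        ],
        columns=["gap_index", "start_row", "end_row", "width_px", "label"],
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_provenance_line(run_hash, seed))
        frame.to_csv(fh, index=False, lineterminator="\n")


def write_curve_json(
    path, curve: SpineCurve | Sequence[float], run_hash: str | None = None
) -> None:
    if isinstance(curve, SpineCurve):
        payload = {
            "coeffs": list(curve.coeffs),
            "rss": curve.rss,
            "n_points": curve.n_points,
        }
    else:
        payload = {"coeffs": list(curve)}
    if run_hash:
        payload["config_hash"] = run_hash
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def write_vector_dataset(path, vectors, labels, manifest: dict) -> None:
    """Array bundle (NPZ) plus an embedded JSON manifest."""
    np.savez_compressed(
        path,
        vectors=np.stack(vectors),
        labels=np.stack(labels),
        __manifest__=np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8),
    )


def read_vector_dataset(path):
    with np.load(path) as data:
        manifest = json.loads(bytes(data["__manifest__"]).decode())
        return data["vectors"].copy(), data["labels"].copy(), manifest


def write_overlay_png(path, mask: np.ndarray, curve: SpineCurve, gaps: Sequence[GapRecord]) -> None:
    """RGB rendering: mask in gray, centerline green, gaps red/lime by label."""
    arr = validate_mask(mask)
    h, w = arr.shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    rgb[arr > 0] = (90, 90, 90)
    colors = {"narrowed": (255, 60, 60), "normal": (120, 255, 120), "unassigned": (255, 200, 60)}
    for g in gaps:
        rgb[g.start_row : g.end_row, :] = np.maximum(
            rgb[g.start_row : g.end_row, :], np.array(colors[g.label], dtype=np.uint8) // 3
        )
    ys = np.arange(h)
    xs = np.round(np.asarray(curve(ys.astype(float)))).astype(int)
    ok = (xs >= 0) & (xs < w)
    rgb[ys[ok], xs[ok]] = (0, 255, 0)
    Image.fromarray(rgb, mode="RGB").save(path)
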