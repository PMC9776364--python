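"""Color-coded overlay rendering and result tables.

Overlay color semantics: green = accepted, red = double-counted,
yellow = small, blue = invisible, gray = cell block.  Only mask boundary
pixels are recolored; all other pixels keep their grayscale value.

Measurement tables are comma-separated UTF-8 CSV with a header row and
"." decimals.  The per-nucleus file carries one ``mask`` row per segmented
object followed by ``summary`` rows (per-status counts, removed and final
counts) so the bookkeeping round-trips through the file.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .postprocess import DoubleCountPair
from .stack_model import (
    ConsistencyError,
    NucleusMask,
    QuantResult,
    Status,
    SubstackProjection,
)

DEFAULT_COLORS: dict[Status, tuple[int, int, int]] = {
    Status.ACCEPTED: (0, 255, 0),  # #00FF00
    Status.DOUBLE_COUNTED: (255, 0, 0),  # #FF0000
    Status.SMALL: (255, 255, 0),  # #FFFF00
    Status.INVISIBLE: (0, 0, 255),  # #0000FF
    Status.BIG: (128, 128, 128),  # #808080
}

MEASUREMENT_COLUMNS = [
    "row_type",
    "sequence_id",
    "substack_index",
    "label_id",
    "area_px",
    "mean_intensity",
    "status",
    "estimated_count",
    "partner_substack",
    "partner_label",
    "value",
]


@dataclass(frozen=True)
class OverlayStyle:
    """Status-to-color map and outline thickness for overlay rendering."""

    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    thickness: int = 1


def mask_boundary(mask: NucleusMask, shape: tuple[int, int]) -> list[tuple[int, int]]:
    """Mask pixels with at least one 4-neighbor outside the mask (or the frame)."""
    pts = mask.pixel_set
    boundary = []
    h, w = shape
    for r, c in sorted(pts):
        if not (0 <= r < h and 0 <= c < w):
            raise ConsistencyError(
                f"mask {mask.label_id} pixel ({r}, {c}) outside image {shape}"
            )
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = r + dr, c + dc
            if not (0 <= nr < h and 0 <= nc < w) or (nr, nc) not in pts:
                boundary.append((r, c))
                break
    return boundary


def render_overlay(
    projection: SubstackProjection,
    masks: list[NucleusMask],
    style: OverlayStyle | None = None,
) -> np.ndarray:
    """Grayscale projection replicated to RGB with status-colored outlines."""
    style = style or OverlayStyle()
    rgb = np.repeat(projection.pixels[:, :, None], 3, axis=2).astype(np.uint8)
    for mask in masks:
        color = style.colors[mask.status]
        for r, c in mask_boundary(mask, projection.pixels.shape):
            rgb[r, c] = color
    return rgb


def write_overlay_png(path: Path | str, overlay: np.ndarray) -> Path:
    path = Path(path)
    iio.imwrite(path, overlay)
    return path


def _pair_index(result: QuantResult) -> dict[tuple[int, int], tuple[int, int]]:
    index: dict[tuple[int, int], tuple[int, int]] = {}
    for pair in result.double_count_pairs:
        if isinstance(pair, DoubleCountPair):
            e = pair.eliminated
            s = pair.survivor
            index[(e.substack_index, e.label_id)] = (s.substack_index, s.label_id)
            index[(s.substack_index, s.label_id)] = (e.substack_index, e.label_id)
    return index


def write_measurements(result: QuantResult, out_path: Path | str) -> Path:
    """Write the per-nucleus measurement table plus summary rows."""
    out_path = Path(out_path)
    partners = _pair_index(result)
    with open(out_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=MEASUREMENT_COLUMNS)
        writer.writeheader()
        for masks in result.substack_masks:
            for m in masks:
                partner = partners.get((m.substack_index, m.label_id))
                writer.writerow(
                    {
                        "row_type": "mask",
                        "sequence_id": result.sequence_id,
                        "substack_index": m.substack_index,
                        "label_id": m.label_id,
                        "area_px": m.area_px,
                        "mean_intensity": f"{m.mean_intensity:.3f}",
                        "status": m.status.value,
                        "estimated_count": m.estimated_count,
                        "partner_substack": "" if partner is None else partner[0],
                        "partner_label": "" if partner is None else partner[1],
                        "value": "",
                    }
                )
        for status in Status:
            writer.writerow(
                {
                    "row_type": "summary",
                    "sequence_id": result.sequence_id,
                    "status": status.value,
                    "value": result.counts_by_status[status],
                }
            )
        for name, value in (
            ("removed_count", result.removed_count),
            ("final_count", result.final_count),
        ):
            writer.writerow(
                {"row_type": "summary", "sequence_id": result.sequence_id,
                 "status": name, "value": value}
            )
    return out_path


def read_measurement_summary(path: Path | str) -> dict[str, int]:
    """Re-read the summary rows of a measurement file (round-trip check)."""
    summary: dict[str, int] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            if row["row_type"] == "summary":
                summary[row["status"]] = int(row["value"])
    return summary


BATCH_COLUMNS = [
    "sequence_id",
    "raw_count",
    "accepted",
    "double_counted",
    "small",
    "invisible",
    "big",
    "removed_count",
    "final_count",
    "error",
]


def write_batch_summary(
    results: list[QuantResult],
    out_path: Path | str,
    failures: list[tuple[str, str]] | None = None,
) -> Path:
    """One row per sequence; failed sequences are flagged, not dropped."""
    out_path = Path(out_path)
    with open(out_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=BATCH_COLUMNS)
        writer.writeheader()
        rows = [
            {
                "sequence_id": r.sequence_id,
                "raw_count": r.raw_count,
                "accepted": r.counts_by_status[Status.ACCEPTED],
                "double_counted": r.counts_by_status[Status.DOUBLE_COUNTED],
                "small": r.counts_by_status[Status.SMALL],
                "invisible": r.counts_by_status[Status.INVISIBLE],
                "big": r.counts_by_status[Status.BIG],
                "removed_count": r.removed_count,
                "final_count": r.final_count,
                "error": "",
            }
            for r in results
        ] + [
            {col: "" for col in BATCH_COLUMNS} | {"sequence_id": sid, "error": msg}
            for sid, msg in (failures or [])
        ]
        for row in sorted(rows, key=lambda r: r["sequence_id"]):
            writer.writerow(row)
    return out_path


def read_batch_summary(path: Path | str) -> list[dict]:
    """Rows of a batch summary CSV (used by the stats command)."""
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))
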