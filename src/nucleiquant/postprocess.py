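"""Rule-based post-processing of segmented nucleus masks.

Four stages run in fixed order on the masks of one sequence:

1. double-count elimination — colocalization analysis between adjacent
   substacks: when two masks overlap by more than the intersection
   threshold (percent of the smaller mask's area by default), the smaller
   mask is marked ``double_counted``;
2. small-nucleus elimination — ``area < small_nucleus_area_limit``;
3. invisible-nucleus elimination — strictly more than 50% of a mask's
   pixels darker than the visibility limit;
4. cell-block detection — a surviving mask larger than the big-nucleus
   limit whose pixels are mostly brighter than the brightness limit is a
   fused cluster; its cell count is estimated as area / average nucleus
   area (rounded half-up, floored at 1).

Each mask ends with exactly one status; a mask eliminated by an earlier
stage is not considered by later ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .stack_model import (
    ConfigurationError,
    ConsistencyError,
    NucleusMask,
    PipelineParams,
    QuantResult,
    Status,
)


@dataclass(frozen=True)
class DoubleCountPair:
    """One resolved double-count: the kept mask and the discarded copy."""

    survivor: NucleusMask
    eliminated: NucleusMask
    shared_area_px: int
    intersection_pct: float


def intersection_percent(
    a: NucleusMask, b: NucleusMask, denominator: str = "min"
) -> float:
    """Shared area of two masks as a percent in [0, 100].

    With the default ``min`` denominator the overlap is relative to the
    smaller mask's area, so a nucleus fully contained in a larger one scores
    100%.  ``union`` gives intersection-over-union instead.
    """
    shared = len(a.pixel_set & b.pixel_set)
    if shared == 0:
        return 0.0
    if denominator == "min":
        denom = min(a.area_px, b.area_px)
    elif denominator == "union":
        denom = len(a.pixel_set | b.pixel_set)
    else:
        raise ConfigurationError(f"unknown denominator {denominator!r}")
    return 100.0 * shared / denom


def find_double_counts(
    masks_by_substack: list[list[NucleusMask]],
    threshold_pct: float,
    denominator: str = "min",
) -> list[DoubleCountPair]:
    """Mark double-counted masks across adjacent substack pairs.

    Pairs of substacks (0,1), (1,2), ... are processed in ascending order;
    within a pair, overlapping candidates are examined in descending
    shared-area order (ties broken by label ids).  When the overlap percent
    strictly exceeds the threshold, the smaller-area mask is marked
    ``double_counted`` (area tie: the copy from the higher substack is
    eliminated).  A mask already marked participates in no further
    comparisons, which stops eliminations from cascading along chains of
    three or more substacks.
    """
    pairs: list[DoubleCountPair] = []
    for i in range(len(masks_by_substack) - 1):
        lower, upper = masks_by_substack[i], masks_by_substack[i + 1]
        candidates = []
        for a in lower:
            for b in upper:
                shared = len(a.pixel_set & b.pixel_set)
                if shared > 0:
                    candidates.append((shared, a, b))
        candidates.sort(key=lambda t: (-t[0], t[1].label_id, t[2].label_id))
        for shared, a, b in candidates:
            if a.status is Status.DOUBLE_COUNTED or b.status is Status.DOUBLE_COUNTED:
                continue
            pct = intersection_percent(a, b, denominator)
            if pct <= threshold_pct:
                continue
            if a.area_px < b.area_px:
                survivor, eliminated = b, a
            elif b.area_px < a.area_px:
                survivor, eliminated = a, b
            else:  # tie: drop the copy from the higher substack
                survivor, eliminated = a, b
            eliminated.status = Status.DOUBLE_COUNTED
            pairs.append(DoubleCountPair(survivor, eliminated, shared, pct))
    return pairs


def eliminate_small(mask: NucleusMask, limit: int) -> Status:
    """Mark a surviving mask ``small`` iff its area is strictly below limit."""
    if mask.status is Status.ACCEPTED and mask.area_px < limit:
        mask.status = Status.SMALL
    return mask.status


def eliminate_invisible(
    mask: NucleusMask, image: np.ndarray, visibility_limit: int
) -> Status:
    """Mark a mask ``invisible`` iff >50% of its pixels are below the limit.

    Both inequalities are strict: a pixel at exactly the visibility limit is
    visible, and a mask with exactly half its pixels dark is kept.
    """
    if mask.status is not Status.ACCEPTED:
        return mask.status
    vals = mask.intensities(image)
    dark = int(np.count_nonzero(vals < visibility_limit))
    if dark / mask.area_px > PipelineParams.INVISIBLE_FRACTION:
        mask.status = Status.INVISIBLE
    return mask.status


def detect_block(
    mask: NucleusMask,
    image: np.ndarray,
    big_limit: int,
    bright_limit: int,
    average_area: int,
) -> Status:
    """Classify a surviving mask as a cell block and estimate its cell count.

    A block must exceed the big-nucleus area limit AND have strictly more
    than 50% of its pixels brighter than the brightness limit; its count is
    ``round_half_up(area / average_area)``, at least 1.
    """
    if average_area <= 0:
        raise ConfigurationError("average_nucleus_area must be positive")
    if mask.status is not Status.ACCEPTED:
        return mask.status
    if mask.area_px > big_limit:
        vals = mask.intensities(image)
        bright = int(np.count_nonzero(vals > bright_limit))
        if bright / mask.area_px > 0.5:
            mask.status = Status.BIG
            mask.estimated_count = max(1, math.floor(mask.area_px / average_area + 0.5))
    return mask.status


def apply_postprocessing(
    masks_by_substack: list[list[NucleusMask]],
    substack_images: list[np.ndarray],
    params: PipelineParams,
    sequence_id: str = "",
) -> QuantResult:
    """Run all four stages in order and assemble the sequence bookkeeping."""
    if len(masks_by_substack) != len(substack_images):
        raise ConsistencyError(
            f"{len(masks_by_substack)} mask lists vs "
            f"{len(substack_images)} substack images"
        )
    for masks, image in zip(masks_by_substack, substack_images):
        for m in masks:
            rows, cols = m.coords()
            if rows.size and (
                rows.max() >= image.shape[0] or cols.max() >= image.shape[1]
            ):
                raise ConsistencyError(
                    f"mask {m.label_id} in substack {m.substack_index} "
                    "lies outside its image"
                )

    pairs = find_double_counts(
        masks_by_substack, params.intersection_percent, params.intersection_denominator
    )
    tally = {"double_counted": len(pairs), "small": 0, "invisible": 0, "big": 0}
    for masks, image in zip(masks_by_substack, substack_images):
        for m in masks:
            if eliminate_small(m, params.small_nucleus_area_limit) is Status.SMALL:
                tally["small"] += 1
        for m in masks:
            if eliminate_invisible(m, image, params.visibility_limit) is Status.INVISIBLE:
                tally["invisible"] += 1
        for m in masks:
            status = detect_block(
                m,
                image,
                params.big_nucleus_area_limit,
                PipelineParams.BRIGHT_INTENSITY_LIMIT,
                params.average_nucleus_area,
            )
            if status is Status.BIG:
                tally["big"] += 1

    return QuantResult.from_masks(
        sequence_id=sequence_id,
        substack_masks=masks_by_substack,
        params=params,
        removed_by_stage=tally,
        double_count_pairs=pairs,
    )
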