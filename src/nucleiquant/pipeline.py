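"""End-to-end orchestration: stack -> substacks -> masks -> counts."""

from __future__ import annotations

import logging

from .postprocess import apply_postprocessing
from .projection import make_substacks
from .segmentation import SegmentationBackend, conventional_count, segment
from .stack_model import (
    PipelineParams,
    ProjectionSpec,
    QuantResult,
    SubstackProjection,
    ZStack,
)

logger = logging.getLogger("nucleiquant")


def quantify_stack(
    stack: ZStack,
    projection: ProjectionSpec | None = None,
    params: PipelineParams | None = None,
    sequence_id: str = "",
) -> tuple[QuantResult, list[SubstackProjection]]:
    """Run the full quantification pipeline on one Z-stack.

    Returns the sequence bookkeeping plus the substack projections (for
    overlay rendering).  Identical inputs give identical outputs.
    """
    projection = projection or ProjectionSpec()
    params = params or PipelineParams()
    sequence_id = sequence_id or stack.site_label
    substacks = make_substacks(stack, projection)
    backend = SegmentationBackend(params.backend, params.backend_params)
    masks_by_substack = [segment(sub, backend) for sub in substacks]
    raw = sum(len(m) for m in masks_by_substack)
    result = apply_postprocessing(
        masks_by_substack,
        [sub.pixels for sub in substacks],
        params,
        sequence_id=sequence_id,
    )
    logger.info(
        "%s: raw=%d removed(double=%d, small=%d, invisible=%d) blocks=%d final=%d",
        sequence_id,
        raw,
        result.removed_by_stage.get("double_counted", 0),
        result.removed_by_stage.get("small", 0),
        result.removed_by_stage.get("invisible", 0),
        result.removed_by_stage.get("big", 0),
        result.final_count,
    )
    return result, substacks


def conventional_quantify(
    stack: ZStack,
    projection: ProjectionSpec | None = None,
    params: PipelineParams | None = None,
) -> int:
    """Total count of the conventional comparator over all substacks.

    Threshold + watershed + particle analysis per substack projection, with
    no double-count handling or elimination rules — the baseline the
    rule-based pipeline is compared against.
    """
    projection = projection or ProjectionSpec()
    params = params or PipelineParams()
    total = 0
    for sub in make_substacks(stack, projection):
        count, _ = conventional_count(
            sub.pixels,
            min_area=params.conventional_min_area,
            circularity_range=params.conventional_circularity,
        )
        total += count
    return total
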