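"""Z-projection algorithms and substack partitioning.

Six per-pixel reductions (maximum, minimum, mean, median, standard
deviation, sum) and three partitioning schemes (complete, split5, split2).
All projections live on the 8-bit scale: mean/median/stdev are rounded
half-up to integers and every result is clipped to [0, 255], so a sum
projection saturates rather than rescales — the downstream intensity rules
(visibility 16, brightness 127) are defined on this scale.
"""

from __future__ import annotations

import warnings

import numpy as np

from .stack_model import (
    PipelineError,
    PlaneImage,
    ProjectionAlgorithm,
    ProjectionSpec,
    StackingScheme,
    SubstackProjection,
    ZStack,
)

_SCHEME_WIDTH = {StackingScheme.SPLIT5: 5, StackingScheme.SPLIT2: 2}


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def project_planes(
    planes: list[PlaneImage] | np.ndarray,
    algorithm: ProjectionAlgorithm | str,
) -> np.ndarray:
    """Reduce a non-empty list of equally shaped planes to one 2-D image.

    Standard deviation is the population form (divisor n); the median of an
    even plane count is the rounded average of the two middle values.
    """
    algorithm = ProjectionAlgorithm(algorithm)
    if isinstance(planes, np.ndarray):
        volume = planes.astype(np.float64)
    else:
        if len(planes) == 0:
            raise PipelineError("cannot project an empty plane list")
        volume = np.stack([p.pixels for p in planes]).astype(np.float64)
    if volume.ndim != 3 or volume.shape[0] == 0:
        raise PipelineError("cannot project an empty plane list")

    if algorithm is ProjectionAlgorithm.MAXIMUM:
        out = volume.max(axis=0)
    elif algorithm is ProjectionAlgorithm.MINIMUM:
        out = volume.min(axis=0)
    elif algorithm is ProjectionAlgorithm.MEAN:
        out = _round_half_up(volume.mean(axis=0))
    elif algorithm is ProjectionAlgorithm.MEDIAN:
        out = _round_half_up(np.median(volume, axis=0))
    elif algorithm is ProjectionAlgorithm.STDEV:
        out = _round_half_up(volume.std(axis=0, ddof=0))
    else:  # SUM
        out = volume.sum(axis=0)
    return np.clip(out, 0, 255).astype(np.uint8)


def partition_scheme(
    n_planes: int, scheme: StackingScheme | str
) -> list[tuple[int, int]]:
    """Half-open plane intervals for a scheme; contiguous, covering, disjoint.

    If ``n_planes`` is not a multiple of the substack width the final
    interval is shorter (ragged) and a warning is emitted.
    """
    scheme = StackingScheme(scheme)
    if n_planes < 1:
        raise PipelineError("n_planes must be >= 1")
    if scheme is StackingScheme.COMPLETE:
        return [(0, n_planes)]
    width = _SCHEME_WIDTH[scheme]
    intervals = [
        (start, min(start + width, n_planes)) for start in range(0, n_planes, width)
    ]
    if n_planes % width != 0:
        warnings.warn(
            f"{n_planes} planes are not divisible by the substack width {width}; "
            f"the final substack covers only {intervals[-1][1] - intervals[-1][0]} plane(s)",
            stacklevel=2,
        )
    return intervals


def make_substacks(stack: ZStack, spec: ProjectionSpec) -> list[SubstackProjection]:
    """Project each partition interval of a stack into one SubstackProjection."""
    volume = stack.as_array()
    substacks = []
    for idx, (start, end) in enumerate(partition_scheme(stack.n_planes, spec.scheme)):
        pixels = project_planes(volume[start:end], spec.algorithm)
        substacks.append(
            SubstackProjection(pixels=pixels, source_range=(start, end), substack_index=idx)
        )
    return substacks
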