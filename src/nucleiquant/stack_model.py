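"""Shared domain types and conventions for confocal Z-stack quantification.

All images are single-channel 8-bit grayscale (DAPI-like nuclear stain).
Coordinates are row-major, origin top-left, 0-based ``(row, col)``.
Intensity thresholds throughout the pipeline (visibility limit 16, brightness
limit 127) are defined on the 8-bit scale; 16-bit acquisitions are down-scaled
on load, never the thresholds up-scaled.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class PipelineError(Exception):
    """Base class for errors raised by this package."""


class FormatError(PipelineError, ValueError):
    """Input data does not meet the format contract (bit depth, shape, ...)."""


class ConfigurationError(PipelineError, ValueError):
    """Invalid parameter value or unknown backend/preset name."""


class ConsistencyError(PipelineError, ValueError):
    """Internally inconsistent inputs (e.g. mask outside its image)."""


class Status(str, enum.Enum):
    """Post-processing status of a segmented nucleus mask."""

    ACCEPTED = "accepted"
    DOUBLE_COUNTED = "double_counted"
    SMALL = "small"
    INVISIBLE = "invisible"
    BIG = "big"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ProjectionAlgorithm(str, enum.Enum):
    """Per-pixel reduction applied across the planes of a substack."""

    MAXIMUM = "maximum"
    MINIMUM = "minimum"
    MEAN = "mean"
    MEDIAN = "median"
    STDEV = "stdev"
    SUM = "sum"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class StackingScheme(str, enum.Enum):
    """How the Z-planes of a sequence are partitioned into substacks.

    ``complete`` collapses all planes into one projection; ``split5`` forms
    substacks of five consecutive planes (two substacks for a canonical
    10-plane scan); ``split2`` forms substacks of two consecutive planes
    (five substacks for a 10-plane scan).
    """

    COMPLETE = "complete"
    SPLIT5 = "split5"
    SPLIT2 = "split2"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def normalize_to_8bit(raw: np.ndarray) -> np.ndarray:
    """Normalize an acquired plane to the canonical 8-bit intensity range.

    8-bit input is returned unchanged.  16-bit input is scaled by integer
    division by 257, so 0 maps to 0 and 65535 maps to 255; the map is
    monotone non-decreasing and idempotent on its own output.

    Raises
    ------
    FormatError
        If the dtype is neither 8-bit nor 16-bit unsigned integer.
    """
    arr = np.asarray(raw)
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return (arr // 257).astype(np.uint8)
    raise FormatError(
        f"unsupported bit depth: {arr.dtype} (expected uint8 or uint16)"
    )


@dataclass
class PlaneImage:
    """One 2-D confocal plane with its position in the Z-order."""

    pixels: np.ndarray
    plane_index: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FormatError("plane must be a non-empty 2-D image")
        if self.pixels.dtype != np.uint8:
            raise FormatError(
                f"plane must be 8-bit after normalization, got {self.pixels.dtype}"
            )
        if self.plane_index < 0:
            raise FormatError("plane_index must be >= 0")

    @classmethod
    def from_raw(cls, raw: np.ndarray, plane_index: int) -> "PlaneImage":
        """Build a plane from raw 8- or 16-bit data, normalizing intensity."""
        return cls(pixels=normalize_to_8bit(raw), plane_index=plane_index)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class ZStack:
    """An ordered sequence of equally sized planes from one confocal scan site."""

    planes: list[PlaneImage]
    site_label: str = ""
    z_spacing_um: Optional[float] = None
    z_range_um: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.planes:
            raise FormatError("a ZStack needs at least one plane")
        shape = self.planes[0].pixels.shape
        for i, plane in enumerate(self.planes):
            if plane.pixels.shape != shape:
                raise FormatError(
                    f"plane {i} has shape {plane.pixels.shape}, expected {shape}"
                )
            if plane.plane_index != i:
                raise FormatError(
                    f"plane_index values must be consecutive 0..n-1; "
                    f"plane {i} carries index {plane.plane_index}"
                )

    @property
    def n_planes(self) -> int:
        return len(self.planes)

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes[0].pixels.shape  # type: ignore[return-value]

    def as_array(self) -> np.ndarray:
        """Planes stacked into a (n_planes, height, width) uint8 array."""
        return np.stack([p.pixels for p in self.planes], axis=0)

    @classmethod
    def from_array(
        cls, volume: np.ndarray, site_label: str = "", **meta: Optional[float]
    ) -> "ZStack":
        """Build a stack from a (n, h, w) array, normalizing each plane."""
        volume = np.asarray(volume)
        if volume.ndim != 3:
            raise FormatError("expected a (n_planes, height, width) array")
        planes = [PlaneImage.from_raw(volume[i], i) for i in range(volume.shape[0])]
        return cls(planes=planes, site_label=site_label, **meta)


@dataclass(frozen=True)
class ProjectionSpec:
    """Choice of projection algorithm and substack partitioning scheme."""

    algorithm: ProjectionAlgorithm = ProjectionAlgorithm.SUM
    scheme: StackingScheme = StackingScheme.SPLIT2

    def __post_init__(self) -> None:
        object.__setattr__(self, "algorithm", ProjectionAlgorithm(self.algorithm))
        object.__setattr__(self, "scheme", StackingScheme(self.scheme))


@dataclass
class SubstackProjection:
    """One 2-D image produced by projecting a contiguous range of planes."""

    pixels: np.ndarray
    source_range: tuple[int, int]
    substack_index: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise FormatError("projection pixels must be uint8")
        start, end = self.source_range
        if not (0 <= start < end):
            raise FormatError(f"source_range {self.source_range} must be non-empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class NucleusMask:
    """One segmented object on one substack projection.

    ``pixel_set`` holds ``(row, col)`` coordinates; ``estimated_count`` is 1
    for every status except ``big``, where it carries the cell-block estimate.
    """

    label_id: int
    pixel_set: frozenset[tuple[int, int]]
    area_px: int
    mean_intensity: float
    substack_index: int
    status: Status = Status.ACCEPTED
    estimated_count: int = 1

    def __post_init__(self) -> None:
        if self.label_id <= 0:
            raise ConsistencyError("label_id must be positive")
        if self.area_px != len(self.pixel_set) or self.area_px == 0:
            raise ConsistencyError("area_px must equal |pixel_set| and be > 0")
        if self.status is not Status.BIG and self.estimated_count != 1:
            raise ConsistencyError("estimated_count must be 1 unless status is big")

    @classmethod
    def from_coords(
        cls,
        label_id: int,
        rows: np.ndarray,
        cols: np.ndarray,
        image: np.ndarray,
        substack_index: int,
    ) -> "NucleusMask":
        """Build a mask from coordinate arrays, reading intensities from image."""
        pixel_set = frozenset(zip((int(r) for r in rows), (int(c) for c in cols)))
        return cls(
            label_id=label_id,
            pixel_set=pixel_set,
            area_px=len(pixel_set),
            mean_intensity=float(np.mean(image[rows, cols])),
            substack_index=substack_index,
        )

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Mask pixels as (rows, cols) index arrays in raster order."""
        pts = sorted(self.pixel_set)
        rows = np.fromiter((p[0] for p in pts), dtype=np.intp, count=len(pts))
        cols = np.fromiter((p[1] for p in pts), dtype=np.intp, count=len(pts))
        return rows, cols

    def intensities(self, image: np.ndarray) -> np.ndarray:
        rows, cols = self.coords()
        return image[rows, cols]


@dataclass
class PipelineParams:
    """Tunable parameters of the post-processing rules and backends.

    Defaults reproduce the published configuration: intersection threshold
    60%, small-nucleus limit 100 px, visibility limit 16, brightness limit
    127, average single-nucleus area 400 px.  The big-nucleus limit defaults
    to 800 px (twice the average area) so that a cell block must plausibly
    contain at least two average nuclei; it is a package choice, configurable.
    Setting ``intersection_percent`` above 100 disables double-count
    elimination (no overlap percentage can strictly exceed 100).
    The 50% fractions in the invisibility and brightness rules are fixed by
    the rule definitions and deliberately not configurable.
    """

    intersection_percent: float = 60.0
    small_nucleus_area_limit: int = 100
    visibility_limit: int = 16
    big_nucleus_area_limit: int = 800
    average_nucleus_area: int = 400
    backend: str = "reference"
    backend_params: dict = field(default_factory=dict)
    conventional_min_area: int = 20
    conventional_circularity: tuple[float, float] = (0.0, 1.0)
    intersection_denominator: str = "min"  # "min" or "union"

    INVISIBLE_FRACTION = 0.5  # fixed: "> 50% of pixels" rules
    BRIGHT_INTENSITY_LIMIT = 127  # fixed: cell-block brightness rule

    def __post_init__(self) -> None:
        if self.intersection_percent <= 0:
            raise ConfigurationError("intersection_percent must be > 0")
        for name in (
            "small_nucleus_area_limit",
            "visibility_limit",
            "big_nucleus_area_limit",
            "average_nucleus_area",
            "conventional_min_area",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.small_nucleus_area_limit >= self.big_nucleus_area_limit:
            raise ConfigurationError(
                "small_nucleus_area_limit must be < big_nucleus_area_limit"
            )
        if self.intersection_denominator not in ("min", "union"):
            raise ConfigurationError(
                "intersection_denominator must be 'min' or 'union'"
            )


@dataclass
class QuantResult:
    """Bookkeeping of one quantified sequence.

    Invariants (enforced by :meth:`from_masks`):
    ``final_count = counts_by_status[accepted] + sum(estimated_count of big)``,
    ``removed_count = double_counted + small + invisible`` and the per-status
    counts sum to the raw mask count.
    """

    sequence_id: str
    substack_masks: list[list[NucleusMask]]
    counts_by_status: dict[Status, int]
    removed_count: int
    final_count: int
    params_used: PipelineParams
    removed_by_stage: dict[str, int] = field(default_factory=dict)
    double_count_pairs: list = field(default_factory=list)

    @property
    def raw_count(self) -> int:
        return sum(len(masks) for masks in self.substack_masks)

    @classmethod
    def from_masks(
        cls,
        sequence_id: str,
        substack_masks: list[list[NucleusMask]],
        params: PipelineParams,
        removed_by_stage: Optional[dict[str, int]] = None,
        double_count_pairs: Optional[list] = None,
    ) -> "QuantResult":
        counts = {status: 0 for status in Status}
        final = 0
        for masks in substack_masks:
            for m in masks:
                counts[m.status] += 1
                if m.status is Status.ACCEPTED:
                    final += 1
                elif m.status is Status.BIG:
                    final += m.estimated_count
        removed = (
            counts[Status.DOUBLE_COUNTED]
            + counts[Status.SMALL]
            + counts[Status.INVISIBLE]
        )
        result = cls(
            sequence_id=sequence_id,
            substack_masks=substack_masks,
            counts_by_status=counts,
            removed_count=removed,
            final_count=final,
            params_used=params,
            removed_by_stage=removed_by_stage or {},
            double_count_pairs=double_count_pairs or [],
        )
        assert sum(counts.values()) == result.raw_count
        return result
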