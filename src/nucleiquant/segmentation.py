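"""Segmentation backends for substack projections.

Three backends share one contract — a pure function of ``(image, params)``
returning an integer label map with background 0:

* ``reference`` — deterministic classical segmenter (Li threshold, connected
  components, marker-based watershed splitting of fused components).  Used
  by the test suite and as the default; needs no model download.
* ``conventional`` — the Fiji-macro-style comparator: Li threshold, binary
  watershed, particle analysis with a minimum area and a circularity window.
* ``cellpose`` — thin optional adapter around the Cellpose generalist
  neural segmenter (cytoplasm-style model, flow threshold 0.6, mask
  threshold 0.0 by default).  Requires the ``cellpose`` package.

Label numbering is canonical: labels 1..k are assigned in raster order of
each object's topmost-leftmost pixel, so mask lists are comparable across
runs and rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_li
from skimage.morphology import local_maxima
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .stack_model import (
    ConfigurationError,
    NucleusMask,
    PipelineParams,
    SubstackProjection,
)

BackendFn = Callable[[np.ndarray, dict], np.ndarray]


@dataclass(frozen=True)
class SegmentationBackend:
    """Named backend plus its opaque parameter set."""

    name: str
    params: dict = field(default_factory=dict)


def canonical_relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..k in raster order of each object's first pixel."""
    out = np.zeros_like(labels, dtype=np.int32)
    flat = labels.ravel()
    ids = np.unique(flat)
    ids = ids[ids != 0]
    first_pixel = {lid: np.argmax(flat == lid) for lid in ids}
    for new_id, lid in enumerate(sorted(ids, key=lambda i: first_pixel[i]), start=1):
        out[labels == lid] = new_id
    return out


# An image whose brightest pixel is not distinguishable from black holds no
# segmentable signal; thresholding below this would only segment noise.
SIGNAL_FLOOR = 16


def _threshold(image: np.ndarray, params: dict) -> np.ndarray:
    """Binary foreground via Li's minimum cross-entropy threshold.

    Li's iteration is started from the intensity midrange rather than the
    image mean: on sparse images the mean sits inside the noise floor and
    the iteration converges to a split of the background noise.  A numeric
    ``threshold`` in params overrides Li; this supports emulating an
    over-sensitive detector that also picks up very dim structures.
    """
    thr = params.get("threshold", "li")
    if thr == "li":
        lo, hi = int(image.min()), int(image.max())
        if hi < SIGNAL_FLOOR or hi == lo:
            return np.zeros_like(image, dtype=bool)
        thr = threshold_li(image, initial_guess=(lo + hi) / 2.0)
    binary = image > thr
    min_size = int(params.get("min_size", 5))
    if min_size > 1:
        lab = cc_label(binary, connectivity=2)
        counts = np.bincount(lab.ravel())
        drop = counts < min_size
        drop[0] = False
        binary = binary & ~drop[lab]
    return binary


def _split_watershed(binary: np.ndarray, min_peak_distance: int) -> np.ndarray:
    """Label a binary mask, splitting fused components by watershed.

    Watershed markers are the connected plateau regions of the distance
    transform's regional maxima, so a single elongated object (whose ridge
    is one connected plateau) is never shattered, while a dumbbell of two
    fused nuclei (two separate maxima) is split.  Within one component,
    maxima plateaus whose centroids lie closer than ``min_peak_distance``
    are merged into one marker.  All operations are morphological, so the
    construction is deterministic and equivariant under 90-degree rotation.
    """
    labels = cc_label(binary, connectivity=2)
    if labels.max() == 0:
        return labels.astype(np.int32)
    dist = ndi.distance_transform_edt(binary)
    maxima = local_maxima(dist, connectivity=2) & binary
    plateau_labels, n_plateaus = ndi.label(maxima, structure=np.ones((3, 3)))
    if n_plateaus == 0:  # pragma: no cover - nonempty masks always have maxima
        return labels.astype(np.int32)
    centroids = ndi.center_of_mass(maxima, plateau_labels, range(1, n_plateaus + 1))
    component_of = ndi.labeled_comprehension(
        labels, plateau_labels, range(1, n_plateaus + 1), lambda v: v[0], int, 0
    )

    parent = list(range(n_plateaus))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n_plateaus):
        for j in range(i + 1, n_plateaus):
            if component_of[i] != component_of[j]:
                continue
            di = centroids[i][0] - centroids[j][0]
            dj = centroids[i][1] - centroids[j][1]
            if di * di + dj * dj < min_peak_distance**2:
                parent[find(i)] = find(j)

    marker_id = {}
    markers = np.zeros_like(labels, dtype=np.int32)
    for i in range(n_plateaus):
        root = find(i)
        if root not in marker_id:
            marker_id[root] = len(marker_id) + 1
        markers[plateau_labels == i + 1] = marker_id[root]
    return watershed(-dist, markers, mask=binary).astype(np.int32)


def reference_segment(image: np.ndarray, params: dict | None = None) -> np.ndarray:
    """Deterministic reference segmenter.

    Li threshold -> connected components (8-connectivity) -> watershed split
    of components with multiple distance-transform maxima (default minimum
    peak separation 5 px).  Identical inputs give identical label maps.
    """
    params = params or {}
    binary = _threshold(image, params)
    labels = _split_watershed(binary, int(params.get("min_peak_distance", 5)))
    return canonical_relabel(labels)


def conventional_segment(image: np.ndarray, params: dict | None = None) -> np.ndarray:
    """Label map of the conventional comparator (before particle filtering)."""
    params = dict(params or {})
    params.setdefault("min_size", 1)  # the particle filter does the size gating
    binary = _threshold(image, params)
    labels = _split_watershed(binary, int(params.get("min_peak_distance", 5)))
    return canonical_relabel(labels)


def circularity(area: float, perimeter: float) -> float:
    """4*pi*area/perimeter^2, clipped to 1.0 (discrete perimeters overshoot)."""
    if perimeter <= 0:
        return 1.0
    return min(1.0, 4.0 * np.pi * area / perimeter**2)


def conventional_count(
    image: np.ndarray,
    min_area: int = 20,
    circularity_range: tuple[float, float] = (0.0, 1.0),
    params: dict | None = None,
) -> tuple[int, list[NucleusMask]]:
    """Threshold + watershed + particle analysis, ImageJ-macro style.

    Keeps objects with ``area >= min_area`` (px^2) and Crofton circularity
    inside ``circularity_range``; returns the kept-object count and masks.
    """
    labels = conventional_segment(image, params)
    lo, hi = circularity_range
    masks: list[NucleusMask] = []
    kept = 0
    for region in regionprops(labels):
        if region.area < min_area:
            continue
        circ = circularity(region.area, region.perimeter_crofton)
        if not (lo <= circ <= hi):
            continue
        kept += 1
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        masks.append(NucleusMask.from_coords(kept, rr, cc, image, substack_index=0))
    return kept, masks


def _cellpose_segment(image: np.ndarray, params: dict) -> np.ndarray:
    """Adapter around the Cellpose generalist segmenter (optional extra)."""
    try:
        from cellpose import models
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ConfigurationError(
            "the 'cellpose' backend requires the cellpose package "
            "(pip install nucleiquant[cellpose])"
        ) from exc
    model = models.Cellpose(model_type=params.get("model_type", "cyto"))
    masks, *_ = model.eval(
        image,
        diameter=params.get("diameter"),
        flow_threshold=params.get("flow_threshold", 0.6),
        cellprob_threshold=params.get("mask_threshold", 0.0),
        channels=[0, 0],
    )
    return canonical_relabel(np.asarray(masks, dtype=np.int32))


BACKENDS: dict[str, BackendFn] = {
    "reference": reference_segment,
    "conventional": conventional_segment,
    "cellpose": _cellpose_segment,
}


def get_backend(name: str) -> BackendFn:
    try:
        return BACKENDS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown segmentation backend {name!r}; "
            f"registered: {sorted(BACKENDS)}"
        ) from None


def segment(
    projection: SubstackProjection,
    backend: SegmentationBackend | PipelineParams,
) -> list[NucleusMask]:
    """Segment one substack projection into a list of nucleus masks.

    Masks are pairwise disjoint, numbered 1..k in raster order of their
    topmost-leftmost pixel, and start life with status ``accepted`` and
    ``estimated_count`` 1.
    """
    if isinstance(backend, PipelineParams):
        backend = SegmentationBackend(backend.backend, backend.backend_params)
    fn = get_backend(backend.name)
    labels = fn(projection.pixels, dict(backend.params))
    objects = ndi.find_objects(labels)
    masks: list[NucleusMask] = []
    for lid in range(1, labels.max() + 1):
        sl = objects[lid - 1]
        if sl is None:  # pragma: no cover - canonical labels are gapless
            continue
        rr, cc = np.nonzero(labels[sl] == lid)
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        masks.append(
            NucleusMask.from_coords(
                lid, rr, cc, projection.pixels, projection.substack_index
            )
        )
    return masks
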