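"""Reading image sequences from disk and discovering them for batch runs.

A sequence is either one multi-page TIFF (page order = Z order) or a
directory of single-plane images whose filenames sort into Z order with
natural (numeric-aware) sorting, so ``z10`` follows ``z2``.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .stack_model import FormatError, PlaneImage, ZStack

IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


class SequenceKind(str, enum.Enum):
    MULTI_PAGE_FILE = "multi_page_file"
    PLANE_FILE_SET = "plane_file_set"


@dataclass(frozen=True)
class SequenceLocator:
    """Where one image sequence lives and how to read it."""

    path: Path
    kind: SequenceKind
    sequence_id: str


def natural_key(name: str) -> tuple:
    """Sort key treating digit runs as numbers: z2 < z10."""
    return tuple(
        int(part) if part.isdigit() else part.lower()
        for part in re.split(r"(\d+)", name)
    )


def _read_pages(path: Path) -> list[np.ndarray]:
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            return [page.asarray() for page in tf.pages]
    return [iio.imread(path)]


def _to_gray(arr: np.ndarray, origin: str) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise FormatError(f"{origin}: color images are not supported")
    if arr.ndim != 2:
        raise FormatError(f"{origin}: expected a 2-D plane, got shape {arr.shape}")
    return arr


def load_sequence(locator: SequenceLocator) -> ZStack:
    """Load one sequence as a ZStack with planes in ascending Z order.

    Every plane is normalized to 8-bit.  Raises :class:`FormatError` when
    planes disagree in shape or no readable plane is found.
    """
    raw_planes: list[np.ndarray] = []
    if locator.kind is SequenceKind.MULTI_PAGE_FILE:
        for arr in _read_pages(locator.path):
            raw_planes.append(_to_gray(arr, str(locator.path)))
    else:
        files = sorted(
            (
                f
                for f in locator.path.iterdir()
                if f.is_file() and f.suffix.lower() in IMAGE_SUFFIXES
            ),
            key=lambda f: natural_key(f.name),
        )
        for f in files:
            for arr in _read_pages(f):
                raw_planes.append(_to_gray(arr, str(f)))
    if not raw_planes:
        raise FormatError(f"{locator.path}: no readable planes")
    shape = raw_planes[0].shape
    for i, arr in enumerate(raw_planes):
        if arr.shape != shape:
            raise FormatError(
                f"{locator.path}: plane {i} has shape {arr.shape}, expected {shape}"
            )
    planes = [PlaneImage.from_raw(arr, i) for i, arr in enumerate(raw_planes)]
    return ZStack(planes=planes, site_label=locator.sequence_id)


def discover_sequences(root_path: Path | str) -> list[SequenceLocator]:
    """Find all sequences under a directory, in deterministic name order.

    Multi-page image files and immediate subdirectories containing image
    files each become one locator; other files are ignored.  The result is
    sorted by sequence_id, so it does not depend on directory listing order.
    """
    root = Path(root_path)
    if not root.is_dir():
        raise FormatError(f"{root}: not a readable directory")
    locators: list[SequenceLocator] = []
    for entry in root.iterdir():
        if entry.is_file() and entry.suffix.lower() in IMAGE_SUFFIXES:
            locators.append(
                SequenceLocator(entry, SequenceKind.MULTI_PAGE_FILE, entry.stem)
            )
        elif entry.is_dir():
            has_images = any(
                f.is_file() and f.suffix.lower() in IMAGE_SUFFIXES
                for f in entry.iterdir()
            )
            if has_images:
                locators.append(
                    SequenceLocator(entry, SequenceKind.PLANE_FILE_SET, entry.name)
                )
    return sorted(locators, key=lambda loc: loc.sequence_id)


def save_stack_tiff(stack: ZStack, path: Path | str) -> Path:
    """Write a ZStack as an 8-bit multi-page TIFF (lossless round-trip)."""
    path = Path(path)
    tifffile.imwrite(path, stack.as_array(), photometric="minisblack")
    return path
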