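"""Image containers and TIFF input/output.

A microscopic field is three co-registered fluorescence channels on a
12-bit grayscale: sarcolemma (membrane, for partitioning fibers),
carbonyl groups, and HNE adducts.  On disk a field is one multi-page
TIFF (page order: membrane, carbonyl, HNE) in a 16-bit container; the
pixel size in micrometres is stored in the ImageJ-style resolution tags.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

MAX_GSU = 4095  # 2**12 - 1, full scale of the 12-bit camera

PAGE_ORDER = ("membrane", "carbonyl", "hne")


@dataclass
class ImageStack:
    """One microscopic field: three co-registered channels plus pixel size.

    Channels are 2-D float arrays in grayscale units (gsu) on the 12-bit
    scale [0, 4095]; ``pixel_size_um`` is the side of one pixel in µm.
    """

    membrane: np.ndarray
    carbonyl: np.ndarray
    hne: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        shapes = {self.membrane.shape, self.carbonyl.shape, self.hne.shape}
        if len(shapes) != 1:
            raise ValueError(f"channel dimensions differ: {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.membrane.shape

    def channels(self) -> dict[str, np.ndarray]:
        return {"membrane": self.membrane, "carbonyl": self.carbonyl, "hne": self.hne}


def write_image_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a field as a 3-page 16-bit TIFF (membrane, carbonyl, HNE).

    Intensities are rounded to the nearest integer and clipped to the
    12-bit range before storage.
    """
    path = Path(path)
    data = np.stack(
        [np.clip(np.rint(c), 0, MAX_GSU).astype(np.uint16) for c in
         (stack.membrane, stack.carbonyl, stack.hne)]
    )
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / stack.pixel_size_um, 1.0 / stack.pixel_size_um),
        metadata={"unit": "um", "axes": "CYX"},
    )
    return path


def read_image_stack(path: str | Path, pixel_size_um: float | None = None) -> ImageStack:
    """Read a 3-page field TIFF written by :func:`write_image_stack`.

    ``pixel_size_um`` overrides the value recorded in the TIFF tags;
    it must be given for files that carry no resolution information.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        if pixel_size_um is None:
            pixel_size_um = _pixel_size_from_tags(tif)
    if pixel_size_um is None:
        raise ValueError(f"{path}: no pixel size in TIFF tags; pass pixel_size_um")
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[0] != 3:
        raise ValueError(f"{path}: expected 3 channel pages, got shape {arr.shape}")
    mem, carb, hne = (arr[i].astype(float) for i in range(3))
    return ImageStack(mem, carb, hne, pixel_size_um)


def _pixel_size_from_tags(tif: "tifffile.TiffFile") -> float | None:
    page = tif.pages[0]
    tag = page.tags.get("XResolution")
    if tag is None:
        return None
    num, den = tag.value
    if num == 0:
        return None
    return den / num


def write_label_map(labels, path: str | Path,
                    excluded_mask: np.ndarray | None = None) -> Path:
    """Write a fiber label image as a 16-bit TIFF.

    Accepts a plain label array or a ``segment.LabelMap``.  If an
    excluded-fiber mask is available it is stored as a second page
    (0/1), so that downstream background estimation can keep excluded
    fiber pixels out of the extracellular pool after a round-trip.
    """
    if hasattr(labels, "labels"):  # LabelMap without importing segment
        excluded_mask = labels.excluded_mask if excluded_mask is None else excluded_mask
        labels = labels.labels
    path = Path(path)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as uint16")
    pages = [labels.astype(np.uint16)]
    if excluded_mask is not None:
        pages.append(excluded_mask.astype(np.uint16))
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
    return path


def read_label_map(path: str | Path):
    """Read a label TIFF; returns ``(labels, excluded_mask_or_None)``."""
    arr = tifffile.imread(Path(path))
    if arr.ndim == 3:
        return arr[0].astype(np.int32), arr[1].astype(bool)
    return arr.astype(np.int32), None
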