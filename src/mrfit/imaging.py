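"""Image-based shrinkage measurement.

A drying slice is photographed from above at regular intervals; each frame is
reduced to a binary foreground mask and the slice area is the foreground
pixel count.  Shrinkage at frame ``k`` is the area ratio
``S(k) = A(k) / A(1)`` against the first frame.  The pipeline per frame:

    color -> grayscale -> threshold -> fill holes -> filter particles -> count

Conventions chosen for reproducibility: ITU-R 601 luma weights
(0.299/0.587/0.114) for the grayscale step, Otsu's criterion as the default
threshold with a strict ``>`` comparison (bright slice on dark background;
``invert=True`` flips polarity), 4-connectivity for the hole-filling
background and 8-connectivity for particle components.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "to_grayscale",
    "binarize",
    "fill_holes",
    "filter_particles",
    "mask_area",
    "shrinkage",
    "process_series",
    "load_frames",
]

_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse a 3-channel image to single-channel luminance.

    Uses fixed ITU-R 601 weights so masks are bit-reproducible across
    platforms; integer inputs stay integer (rounded), float inputs stay
    float.  Grayscale input is returned unchanged.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        gray = image.astype(float) @ _LUMA
        if np.issubdtype(image.dtype, np.integer):
            return np.rint(gray).astype(image.dtype)
        return gray
    raise ValueError(f"expected HxW or HxWx3 raster, got shape {image.shape}")


def binarize(
    gray: np.ndarray,
    threshold: float | None = None,
    invert: bool = False,
) -> np.ndarray:
    """Threshold a grayscale frame into a boolean foreground mask.

    ``threshold=None`` selects the Otsu threshold.  Foreground is strictly
    above the threshold (below-or-equal with ``invert=True``).  A constant
    image has no Otsu separation: a warning is emitted and the mask is empty
    (or full under inversion).
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("binarize expects a single-channel image")
    if threshold is None:
        if gray.min() == gray.max():
            warnings.warn("constant image: threshold is degenerate", stacklevel=2)
            threshold = gray.flat[0]
        else:
            threshold = threshold_otsu(gray)
    mask = gray > threshold
    return ~mask if invert else mask


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not 4-connected to the raster border.

    Never removes foreground, so the area can only grow; idempotent.
    """
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))


def filter_particles(
    mask: np.ndarray, min_area: int = 50, keep_largest: bool = True
) -> np.ndarray:
    """Drop small spurious 8-connected foreground components.

    Components below ``min_area`` pixels are removed; with ``keep_largest``
    only the single largest surviving component remains (area ties broken by
    the component encountered first in raster scan order).  An empty mask
    passes through unchanged.
    """
    if min_area < 0:
        raise ValueError("min_area must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())[1:]  # skip background label 0
    keep = np.nonzero(areas >= min_area)[0] + 1
    if keep.size == 0:
        return np.zeros_like(mask)
    if keep_largest:
        # labels are assigned in raster scan order, so argmax's first-hit
        # tie-break keeps the first-encountered component
        keep = np.array([keep[np.argmax(areas[keep - 1])]])
    return np.isin(labels, keep)


def mask_area(mask: np.ndarray) -> int:
    """Foreground pixel count of a boolean mask."""
    return int(np.count_nonzero(mask))


def shrinkage(area_t: float, area_0: float) -> float:
    """Area ratio ``A(t) / A(0)``; the dimensionless shrinkage measure."""
    if area_0 <= 0:
        raise ValueError("reference area must be positive")
    if area_t < 0:
        raise ValueError("area cannot be negative")
    return area_t / area_0


def segment(
    image: np.ndarray,
    threshold: float | None = None,
    invert: bool = False,
    min_area: int = 50,
    keep_largest: bool = True,
    roi: tuple[int, int, int, int] | None = None,
) -> np.ndarray:
    """Full single-frame pipeline: grayscale, threshold, fill, filter.

    ``roi`` is an optional ``(row0, row1, col0, col1)`` crop applied first.
    """
    image = np.asarray(image)
    if roi is not None:
        r0, r1, c0, c1 = roi
        image = image[r0:r1, c0:c1]
    gray = to_grayscale(image)
    mask = binarize(gray, threshold=threshold, invert=invert)
    mask = fill_holes(mask)
    return filter_particles(mask, min_area=min_area, keep_largest=keep_largest)


def process_series(
    images,
    threshold: float | None = None,
    invert: bool = False,
    min_area: int = 50,
    keep_largest: bool = True,
    roi: tuple[int, int, int, int] | None = None,
) -> pd.DataFrame:
    """Measure the shrinkage trajectory of an ordered frame sequence.

    The first frame defines the reference area, so ``S(1) = 1`` whenever its
    mask is non-empty.  A frame segmenting to an empty mask is recorded with
    ``S = 0`` under a warning and processing continues.  Returns a DataFrame
    with columns ``k``, ``area_px``, ``shrinkage``.
    """
    images = list(images)
    if not images:
        raise ValueError("need at least one frame")
    rows = []
    area0 = None
    for k, image in enumerate(images, start=1):
        mask = segment(
            image,
            threshold=threshold,
            invert=invert,
            min_area=min_area,
            keep_largest=keep_largest,
            roi=roi,
        )
        area = mask_area(mask)
        if area == 0:
            warnings.warn(f"frame {k}: empty mask, recording shrinkage 0", stacklevel=2)
        if k == 1:
            area0 = area if area > 0 else None
        s = shrinkage(area, area0) if area0 else 0.0
        rows.append({"k": k, "area_px": area, "shrinkage": s})
    return pd.DataFrame(rows)


def load_frames(source, manifest: str | Path | None = None) -> list[np.ndarray]:
    """Load an image series from a directory (lexicographic filename order)
    or from a manifest CSV with ``k,filename`` columns."""
    import imageio.v3 as iio

    if manifest is not None:
        table = pd.read_csv(manifest)
        if not {"k", "filename"} <= set(table.columns):
            raise ValueError("manifest must have k,filename columns")
        base = Path(manifest).parent
        paths = [base / f for f in table.sort_values("k")["filename"]]
    else:
        directory = Path(source)
        paths = sorted(
            p for p in directory.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not paths:
            raise ValueError(f"no PNG/TIFF frames found in {directory}")
    return [iio.imread(p) for p in paths]
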