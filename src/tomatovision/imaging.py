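"""Image I/O and preprocessing: denoising, segmentation, binarization.

Images are plain numpy arrays throughout: RGB rasters are ``(H, W, 3)`` uint8,
grayscale rasters ``(H, W)`` uint8, and binary images / masks ``(H, W)`` bool.
Coordinates are row-major with the origin at the top-left.

The preprocessing chain mirrors a controlled acquisition chamber: a sample is
photographed against a stationary dark background, impulse/blur noise from the
camera is suppressed with a rank-order filter, and the fruit region is
recovered by differencing the sample frame against an empty background frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .exceptions import ImageIOError, ParameterError, ShapeError

__all__ = [
    "ForegroundMask",
    "SegmentedSample",
    "read_image",
    "write_image",
    "denoise_rank_order",
    "segment_frame_difference",
    "binarize",
    "postprocess_mask",
]

_READABLE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForegroundMask:
    """Boolean foreground map produced by frame differencing.

    Attributes
    ----------
    pixels : (H, W) bool array, True where the per-pixel channel-summed
        absolute frame difference exceeded ``threshold``.
    threshold : the intensity-difference threshold that produced the mask.
    """

    pixels: np.ndarray
    threshold: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class SegmentedSample:
    """A sample frame restricted to its foreground: background pixels zeroed."""

    image: np.ndarray  # (H, W, 3) uint8, zero outside the mask
    mask: ForegroundMask

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.pixels.shape:
            raise ShapeError(
                f"image {self.image.shape[:2]} and mask {self.mask.pixels.shape} differ"
            )


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image from a PNG/TIFF/JPEG file.

    Grayscale files are replicated to three channels; an alpha channel is
    dropped. Raises :class:`ImageIOError` for missing or unreadable files.
    """
    path = Path(path)
    if not path.is_file():
        raise ImageIOError(f"no such image file: {path}")
    if path.suffix.lower() not in _READABLE_SUFFIXES:
        raise ImageIOError(f"unsupported image format {path.suffix!r}: {path}")
    if path.suffix.lower() in (".jpg", ".jpeg"):
        logger.warning("reading lossy JPEG %s; prefer PNG/TIFF for analysis", path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of backend errors
        raise ImageIOError(f"could not read image {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageIOError(f"unsupported channel layout {arr.shape} in {path}")
    return arr


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write an RGB, grayscale, or binary raster to disk.

    Binary (bool) images are encoded as {0, 255} single-channel rasters.
    PNG/TIFF round-trip bit-exactly.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise ImageIOError(f"directory does not exist: {path.parent}")
    if image.dtype == bool:
        image = image.astype(np.uint8) * 255
    elif image.dtype != np.uint8:
        image = np.clip(image, 0, 255).astype(np.uint8)
    try:
        iio.imwrite(path, image)
    except Exception as exc:
        raise ImageIOError(f"could not write image {path}: {exc}") from exc


def denoise_rank_order(
    image: np.ndarray, rank: int = 5, window: int = 3
) -> np.ndarray:
    """Rank-order filter: each pixel becomes the ``rank``-th smallest value in
    its ``window``×``window`` neighborhood (per channel for RGB input).

    ``rank`` is 1-based in [1, window²]; rank ⌈window²/2⌉ is the median filter.
    Borders use reflect (edge-symmetric) padding so dimensions are preserved.
    Higher ranks are brighter: the filter output is non-decreasing in rank.
    """
    if window % 2 == 0 or window < 1:
        raise ParameterError(f"window must be odd and positive, got {window}")
    if not 1 <= rank <= window * window:
        raise ParameterError(f"rank must be in [1, {window * window}], got {rank}")
    if image.ndim == 3:
        size = (window, window, 1)
    elif image.ndim == 2:
        size = (window, window)
    else:
        raise ShapeError(f"expected 2-D or 3-D image, got shape {image.shape}")
    return ndimage.rank_filter(image, rank - 1, size=size, mode="reflect")


def segment_frame_difference(
    background: np.ndarray, sample: np.ndarray, threshold: float = 30.0
) -> SegmentedSample:
    """Foreground segmentation by two-frame differencing.

    A pixel is foreground iff the sum over the three channels of the absolute
    intensity difference between the sample frame (object present) and the
    background frame (empty chamber) strictly exceeds ``threshold``. The
    returned sample image has background pixels zeroed.
    """
    if background.shape != sample.shape:
        raise ShapeError(
            f"frame shapes differ: {background.shape} vs {sample.shape}"
        )
    if threshold < 0:
        raise ParameterError(f"threshold must be non-negative, got {threshold}")
    diff = np.abs(sample.astype(np.int32) - background.astype(np.int32))
    if diff.ndim == 3:
        diff = diff.sum(axis=2)
    fg = diff > threshold
    segmented = np.where(fg[..., None] if sample.ndim == 3 else fg, sample, 0)
    return SegmentedSample(image=segmented.astype(np.uint8),
                           mask=ForegroundMask(pixels=fg, threshold=threshold))


def binarize(
    image: np.ndarray, method: str = "otsu", fixed_threshold: float | None = None
) -> np.ndarray:
    """Hard-threshold a grayscale image to a boolean raster (on iff > t).

    ``method='otsu'`` picks the threshold maximizing between-class variance;
    ``method='fixed'`` uses ``fixed_threshold``.
    """
    if image.ndim != 2:
        raise ShapeError(f"binarize expects a grayscale image, got {image.shape}")
    if method == "fixed":
        if fixed_threshold is None:
            raise ParameterError("method='fixed' requires fixed_threshold")
        t = fixed_threshold
    elif method == "otsu":
        if np.all(image == image.flat[0]):
            t = float(image.flat[0])  # constant image: nothing exceeds it
        else:
            t = threshold_otsu(image)
    else:
        raise ParameterError(f"unknown binarization method {method!r}")
    return image > t


def postprocess_mask(
    mask: ForegroundMask, min_component_area: int = 64
) -> ForegroundMask:
    """Remove speckle from a foreground mask.

    Drops 8-connected components smaller than ``min_component_area`` pixels
    and keeps only the largest surviving component (the fruit). An empty mask
    is returned unchanged.
    """
    if min_component_area < 0:
        raise ParameterError("min_component_area must be >= 0")
    labels, n = ndimage.label(mask.pixels, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    keep = np.flatnonzero(sizes >= min_component_area) + 1
    if keep.size == 0:
        return ForegroundMask(np.zeros_like(mask.pixels), mask.threshold)
    largest = keep[np.argmax(sizes[keep - 1])]
    return ForegroundMask(labels == largest, mask.threshold)
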