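"""Image preprocessing: marker localization, ROI cropping, tensor preparation.

The raw input is a pressure-topography raster spanning 60 s of recording, with
a pure-white full-height vertical line marking the swallow onset.  The chain
is:

1. binarize the grayscale image at threshold 128;
2. locate the marker as the column with the most white pixels;
3. crop the swallow region of interest to the right of the marker (input to
   the swallow-pattern classifier);
4. crop the IRP region of interest — the bottom band of rows over the first
   10 s after the marker (input to the IRP classifier);
5. resize bilinearly to the classifier input shape (299×299×3 for the IRP
   task, 224×224×3 for the pattern task) and rescale pixels to [-1, 1].

Coordinates are 0-based, origin top-left; crops are half-open intervals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = [
    "HRMImage",
    "BinaryMask",
    "SwallowROI",
    "IRPROI",
    "NormalizedTensor",
    "ClassifierTarget",
    "MarkerNotFoundError",
    "binarize",
    "locate_marker",
    "crop_swallow",
    "extract_irp_roi",
    "prepare_tensor",
]

DEFAULT_DURATION_S = 60.0


class MarkerNotFoundError(ValueError):
    """Raised when no white marker pixel exists in the binarized image."""


class ClassifierTarget(enum.Enum):
    IRP = "irp"
    PATTERN = "pattern"


#: Classifier input edge length, pixels, per task.
TARGET_SIZE = {ClassifierTarget.IRP: 299, ClassifierTarget.PATTERN: 224}


@dataclass(frozen=True)
class HRMImage:
    """An RGB pressure-topography raster of one 60 s recording window."""

    pixels: np.ndarray  # H x W x 3, uint8
    seconds_per_pixel: float = 0.0  # 0 -> derived as 60 s / width

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 pixels, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one row and column")
        object.__setattr__(self, "pixels", px.astype(np.uint8))
        if self.seconds_per_pixel <= 0:
            object.__setattr__(
                self, "seconds_per_pixel", DEFAULT_DURATION_S / px.shape[1]
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def open(cls, path, seconds_per_pixel: float = 0.0) -> "HRMImage":
        with Image.open(path) as im:
            return cls(np.asarray(im.convert("RGB")), seconds_per_pixel)

    def save(self, path) -> None:
        Image.fromarray(self.pixels, mode="RGB").save(path)


@dataclass(frozen=True)
class BinaryMask:
    mask: np.ndarray  # H x W bool

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError(f"expected 2-D mask, got shape {m.shape}")
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class SwallowROI:
    pixels: np.ndarray
    origin_x: int
    origin_y: int


@dataclass(frozen=True)
class IRPROI:
    pixels: np.ndarray
    origin_x: int
    origin_y: int


@dataclass(frozen=True)
class NormalizedTensor:
    """Classifier-ready array with values in [-1, 1]."""

    values: np.ndarray  # target_h x target_w x 3, float32
    source: ClassifierTarget


def binarize(image: HRMImage, threshold: float = 128) -> BinaryMask:
    """Threshold the grayscale image (mean of RGB) at ``threshold``.

    A pixel is white when its gray value is >= threshold, so the pure-white
    onset marker (gray 255) always survives.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must lie in [0, 255], got {threshold}")
    gray = image.pixels.astype(np.float64).mean(axis=2)
    return BinaryMask(gray >= threshold)


def locate_marker(mask: BinaryMask) -> int:
    """Column index with the greatest white-pixel count; ties -> smallest index."""
    counts = mask.mask.sum(axis=0)
    if counts.max(initial=0) == 0:
        raise MarkerNotFoundError("no white pixels: marker not found")
    return int(np.argmax(counts))  # argmax returns the first maximum


def crop_swallow(
    image: HRMImage,
    marker_x: int,
    *,
    top: int = 0,
    bottom: int = 0,
    marker_offset: int = 2,
) -> SwallowROI:
    """Crop the swallow ROI: columns right of the marker, margin rows removed.

    ``marker_offset`` (default = the marker thickness) excludes the white
    line itself from the crop.
    """
    x0 = marker_x + marker_offset
    y0, y1 = top, image.height - bottom
    if x0 >= image.width:
        raise ValueError(
            f"marker at {marker_x} + offset {marker_offset} leaves no columns "
            f"(width {image.width})"
        )
    if y0 >= y1:
        raise ValueError(f"margins top={top}, bottom={bottom} leave no rows")
    return SwallowROI(image.pixels[y0:y1, x0:], origin_x=x0, origin_y=y0)


def extract_irp_roi(
    image: HRMImage,
    marker_x: int,
    *,
    window_s: float = 10.0,
    les_band_fraction: float = 0.25,
) -> IRPROI:
    """Crop the IRP ROI: bottom band of rows over the post-onset window.

    The temporal width is ``round(window_s / seconds_per_pixel)`` columns
    starting at the marker; the spatial band is the bottom
    ``les_band_fraction`` of rows (the LES / esophago-gastric junction).
    """
    if not 0 < les_band_fraction <= 1:
        raise ValueError(f"les_band_fraction must lie in (0, 1], got {les_band_fraction}")
    width = round(window_s / image.seconds_per_pixel)
    if width < 1:
        raise ValueError("IRP window narrower than one pixel")
    if marker_x + width > image.width:
        raise ValueError(
            f"IRP window [{marker_x}, {marker_x + width}) exceeds image width "
            f"{image.width}"
        )
    band = round(image.height * les_band_fraction)
    y0 = image.height - max(band, 1)
    return IRPROI(
        image.pixels[y0:, marker_x : marker_x + width], origin_x=marker_x, origin_y=y0
    )


def prepare_tensor(roi, target: ClassifierTarget) -> NormalizedTensor:
    """Bilinear-resize a ROI to its classifier input shape and scale to [-1, 1]."""
    if not isinstance(target, ClassifierTarget):
        try:
            target = ClassifierTarget(target)
        except ValueError:
            raise ValueError(f"unknown classifier target {target!r}") from None
    pixels = np.asarray(roi.pixels if hasattr(roi, "pixels") else roi, dtype=np.uint8)
    if pixels.size == 0:
        raise ValueError("empty ROI")
    size = TARGET_SIZE[target]
    im = Image.fromarray(pixels, mode="RGB").resize((size, size), Image.BILINEAR)
    values = np.asarray(im, dtype=np.float32) / 127.5 - 1.0
    # bilinear interpolation of 8-bit values cannot leave [0, 255], so the
    # rescaled tensor stays in [-1, 1]; clip guards against float round-off
    return NormalizedTensor(np.clip(values, -1.0, 1.0), source=target)
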