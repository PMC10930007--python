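"""Phantom detection and circular ROI construction.

The phantom is segmented on each Signal image by thresholding (Otsu by
default), filling holes and keeping the largest connected component.
The phantom center is the midpoint of the component's horizontal and
vertical extents, and the analysis ROI is a circle at that center with
diameter 90% of the phantom width.  Coordinates are 0-based (row, col)
with pixel centers at integer positions; circle membership is by
Euclidean distance of pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import GeometryError, NoPhantomError

#: ROI diameter as a fraction of the detected phantom width
ROI_DIAMETER_FRACTION = 0.9


@dataclass(frozen=True)
class PhantomGeometry:
    """Detected phantom mask plus axis-aligned center and extents (px)."""

    mask: np.ndarray
    center: tuple[float, float]
    width: float
    height: float

    def __post_init__(self) -> None:
        if not np.any(self.mask):
            raise GeometryError("phantom mask is empty")
        if self.width < 8 or self.height < 8:
            raise GeometryError(
                f"phantom extent {self.width}x{self.height} px is below the 8 px minimum"
            )


@dataclass(frozen=True)
class CircularRoi:
    """Circle of ``radius`` px around ``center`` (row, col); membership is
    pixel-center distance <= radius."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GeometryError("ROI radius must be positive")


def detect_phantom(signal_pixels: np.ndarray, threshold: str | float = "otsu") -> PhantomGeometry:
    """Segment the phantom on a Signal image.

    ``threshold`` is ``"otsu"`` (default) or a fraction of the image
    maximum (e.g. ``0.25``).  Raises :class:`NoPhantomError` when the
    image is flat or the foreground is implausibly small or large.
    """
    img = np.asarray(signal_pixels, dtype=np.float64)
    if img.ndim != 2:
        raise NoPhantomError("expected a 2-D image")
    if img.max() == img.min():
        raise NoPhantomError("image is constant; no phantom to segment")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        thr = threshold_otsu(img)
    else:
        thr = float(threshold) * img.max()
    fg = img > thr
    frac = fg.mean()
    if frac > 0.95:
        raise NoPhantomError(f"foreground covers {frac:.0%} of the image")
    fg = ndimage.binary_fill_holes(fg)
    labels = measure.label(fg)
    if labels.max() == 0:
        raise NoPhantomError("no foreground component found")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    if mask.mean() < 0.01:
        raise NoPhantomError(f"largest component covers {mask.mean():.1%} of the image")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    rmin, rmax = int(rows[0]), int(rows[-1])
    cmin, cmax = int(cols[0]), int(cols[-1])
    return PhantomGeometry(
        mask=mask,
        center=((rmin + rmax) / 2.0, (cmin + cmax) / 2.0),
        width=float(cmax - cmin + 1),
        height=float(rmax - rmin + 1),
    )


def build_combined_roi(
    geometry: PhantomGeometry, fraction: float = ROI_DIAMETER_FRACTION
) -> CircularRoi:
    """Circular analysis ROI: diameter ``fraction`` (default 90%) of the
    phantom width, centered at the phantom center."""
    roi = CircularRoi(center=geometry.center, radius=fraction / 2.0 * geometry.width)
    _check_bounds(roi, geometry.mask.shape)
    return roi


def _check_bounds(roi: CircularRoi, shape: tuple[int, ...]) -> None:
    r0, c0 = roi.center
    if (
        r0 - roi.radius < -0.5
        or c0 - roi.radius < -0.5
        or r0 + roi.radius > shape[0] - 0.5
        or c0 + roi.radius > shape[1] - 0.5
    ):
        raise GeometryError(
            f"ROI (center {roi.center}, radius {roi.radius:.1f}) exceeds image bounds {shape}"
        )


def circle_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def roi_pixels(image: np.ndarray, roi: CircularRoi) -> np.ndarray:
    """Values of exactly the ROI member pixels, as a 1-D array."""
    image = np.asarray(image)
    _check_bounds(roi, image.shape)
    return image[circle_mask(image.shape, roi.center, roi.radius)]
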