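"""Per-element analysis of "save uncombined" series.

For every coil element and slice, noise is measured as the SD inside the
circular ROI transferred from the sum-of-squares combined by-product
series, and signal as the mean of a small (5 px radius, 5.86 mm at
FOV 300 / matrix 256) ROI centered on the intensity maximum of the
box-smoothed Signal image.  Smoothing plus restriction of the peak
search to an eroded phantom mask keeps the signal ROI fully inside the
phantom even when the true maximum sits on the phantom edge.

Per-element peak SNR is summarized over the three slices where SNR peaks
(+110/+130/+150 mm for superior "...P" groups, the negated locations for
inferior "...S" groups), giving the longitudinal QA statistic.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .combined import AnalysisConfig, compute_snr
from .dicom_io import ImagePair
from .errors import AlignmentError, CoverageError, GeometryError
from .segmentation import CircularRoi, build_combined_roi, detect_phantom, roi_pixels

_GROUP_RE = re.compile(r"^([A-Z]{2,})(\d+)$")

#: |slice locations| (mm) used for the peak-SNR summary
PEAK_SLICE_MAGNITUDES = (110.0, 130.0, 150.0)

#: coarse angular sectors reported by position derivation, counterclockwise
OCTANT_LABELS = ("E", "NE", "N", "NW", "W", "SW", "S", "SE")

#: channel tables per coil type; "absent" channels exist in the data stream
#: but have no physical receive element behind them
COIL_TABLES: dict[str, dict] = {
    "torso": {
        "groups": ("VAP", "VAS", "VPP", "VPS"),
        "channels": tuple(f"{g}{n}" for g in ("VAP", "VAS", "VPP", "VPS") for n in (1, 2, 3)),
        "absent": frozenset(),
    },
    "headneck": {
        "groups": ("VAP", "VAS", "VPP", "VPS"),
        "channels": tuple(f"{g}{n}" for g in ("VAP", "VAS", "VPP", "VPS") for n in (1, 2, 3)),
        "absent": frozenset({"VAP3", "VPP3"}),
    },
    "body": {"groups": (), "channels": (), "absent": frozenset()},
}


@dataclass(frozen=True)
class ElementSliceMetrics:
    """Noise, peak signal and SNR of one element at one slice."""

    element_label: str
    slice_location: float
    noise_sd: float
    peak_center: tuple[int, int]
    mean_peak_signal: float
    snr: float
    phantom_center: tuple[float, float]
    roi: CircularRoi


@dataclass(frozen=True)
class ElementSummary:
    """Peak-SNR summary of one element over its three best slices."""

    element_label: str
    group: str
    peak_snr_mean: float
    peak_snr_sd: float
    slices_used: tuple[float, float, float]


def smooth_signal(signal_pixels: np.ndarray, window: int = 10) -> np.ndarray:
    """Uniform (box) mean filter of ``window`` x ``window`` pixels with
    replicate boundary handling.  For even windows the footprint is
    anchored with a one-pixel offset toward the top-left: the window at
    pixel i covers rows i - window//2 .. i + (window-1)//2.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    return ndimage.uniform_filter(
        np.asarray(signal_pixels, dtype=np.float64), size=window, mode="nearest"
    )


def locate_peak_roi(
    signal_pixels: np.ndarray,
    phantom_mask: np.ndarray,
    roi_radius: float = 5.0,
    smoothing_window: int = 10,
) -> tuple[tuple[int, int], CircularRoi]:
    """Find the in-phantom intensity peak and build the signal ROI there.

    The argmax is taken on the smoothed image restricted to the phantom
    mask eroded by a disc of ``roi_radius``, which guarantees the ROI of
    ``roi_radius`` px on the *original* image lies entirely inside the
    phantom.  Ties are broken by smallest (row, col) in lexicographic
    order.
    """
    smoothed = smooth_signal(signal_pixels, smoothing_window)
    eroded = ndimage.binary_erosion(phantom_mask, structure=disk(int(math.ceil(roi_radius))))
    if not eroded.any():
        raise GeometryError("phantom too small to contain the peak ROI")
    masked = np.where(eroded, smoothed, -np.inf)
    peak = np.unravel_index(int(np.argmax(masked)), masked.shape)  # first = lexicographic min
    center = (int(peak[0]), int(peak[1]))
    return center, CircularRoi(center=center, radius=roi_radius)


def analyze_element_series(
    uncombined: dict[str, list[ImagePair]],
    sos_combined: list[ImagePair],
    config: AnalysisConfig | None = None,
) -> dict[str, list[ElementSliceMetrics]]:
    """Per element and slice: transferred-ROI noise SD, peak-ROI mean
    signal and their ratio.

    The circular ROI and phantom mask come from the sum-of-squares
    combined Signal image of the matching slice, so the noise statistic
    of all elements of one slice is computed on identical pixels.
    """
    config = config or AnalysisConfig()
    sos_by_loc = {p.meta.slice_location: p for p in sos_combined}
    for label, pairs in uncombined.items():
        locs = {p.meta.slice_location for p in pairs}
        if locs != set(sos_by_loc):
            raise AlignmentError(
                f"element {label}: slice locations differ from the sum-of-squares series"
            )

    # per-slice geometry from the SOS series, shared by all elements
    slice_geometry: dict[float, tuple] = {}
    for loc, pair in sos_by_loc.items():
        geom = detect_phantom(pair.signal_pixels, threshold=config.threshold)
        roi = build_combined_roi(geom, fraction=config.roi_fraction)
        slice_geometry[loc] = (geom, roi)

    out: dict[str, list[ElementSliceMetrics]] = {}
    for label, pairs in uncombined.items():
        metrics = []
        for pair in sorted(pairs, key=lambda p: p.meta.slice_location):
            loc = pair.meta.slice_location
            geom, roi = slice_geometry[loc]
            noise_sd = float(roi_pixels(pair.noise_pixels, roi).astype(np.float64).std(ddof=1))
            peak, peak_roi = locate_peak_roi(
                pair.signal_pixels,
                geom.mask,
                roi_radius=config.peak_roi_radius,
                smoothing_window=config.smoothing_window,
            )
            mean_peak = float(roi_pixels(pair.signal_pixels, peak_roi).astype(np.float64).mean())
            metrics.append(
                ElementSliceMetrics(
                    element_label=label,
                    slice_location=loc,
                    noise_sd=noise_sd,
                    peak_center=peak,
                    mean_peak_signal=mean_peak,
                    snr=compute_snr(mean_peak, noise_sd, config.snr_correction),
                    phantom_center=geom.center,
                    roi=peak_roi,
                )
            )
        out[label] = metrics
    return out


def element_group(label: str) -> str:
    m = _GROUP_RE.match(label)
    if not m:
        raise ValueError(f"element label {label!r} does not look like GROUP<number>")
    return m.group(1)


def peak_slice_locations(group: str) -> tuple[float, float, float]:
    """Summary slice locations for a coil group: groups whose name ends in
    P sit superiorly (+110/+130/+150 mm), groups ending in S inferiorly."""
    side = group[-1]
    if side == "P":
        return PEAK_SLICE_MAGNITUDES
    if side == "S":
        return tuple(-m for m in PEAK_SLICE_MAGNITUDES)  # type: ignore[return-value]
    raise ValueError(f"group {group!r} must end in P (superior) or S (inferior)")


def summarize_peak_snr(
    metrics: dict[str, list[ElementSliceMetrics]],
    coil_type: str = "torso",
    tolerance_mm: float = 1.0,
) -> list[ElementSummary]:
    """Mean and SD of element SNR over the three peak-SNR slices."""
    out = []
    for label in sorted(metrics):
        group = element_group(label)
        targets = peak_slice_locations(group)
        by_loc = {m.slice_location: m for m in metrics[label]}
        snrs, used = [], []
        for target in targets:
            nearest = min(by_loc, key=lambda loc: abs(loc - target))
            if abs(nearest - target) > tolerance_mm:
                raise CoverageError(
                    f"element {label}: no slice within {tolerance_mm} mm of {target:+.0f} mm"
                )
            snrs.append(by_loc[nearest].snr)
            used.append(nearest)
        arr = np.asarray(snrs, dtype=np.float64)
        out.append(
            ElementSummary(
                element_label=label,
                group=group,
                peak_snr_mean=float(arr.mean()),
                peak_snr_sd=float(arr.std(ddof=1)),
                slices_used=tuple(used),  # type: ignore[arg-type]
            )
        )
    return out


def derive_element_position(
    metrics: list[ElementSliceMetrics], snr_floor: float = 5.0
) -> tuple[str, int | None]:
    """Coarse physical position of an element from its image statistics.

    Returns ``(axial_sign, octant)`` where ``axial_sign`` is "superior"
    or "inferior" from the sign of the slice location of maximal peak
    signal, and ``octant`` indexes the 45-degree sector (0 = "E" = image
    right, counterclockwise; see :data:`OCTANT_LABELS`) of the peak
    position relative to the phantom center at that slice.  Elements
    whose SNR never exceeds ``snr_floor`` are reported
    ``("undetectable", None)``.
    """
    if not metrics:
        return "undetectable", None
    if max(m.snr for m in metrics) < snr_floor:
        return "undetectable", None
    best = max(metrics, key=lambda m: m.mean_peak_signal)
    axial = "superior" if best.slice_location >= 0 else "inferior"
    dr = best.phantom_center[0] - best.peak_center[0]  # "up" is positive
    dc = best.peak_center[1] - best.phantom_center[1]
    angle = math.degrees(math.atan2(dr, dc)) % 360.0
    octant = int(((angle + 22.5) % 360.0) // 45.0)
    return axial, octant
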