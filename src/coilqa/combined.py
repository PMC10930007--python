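"""Per-slice SNR and percent image uniformity of combined-element series.

For each slice the phantom is segmented on the Signal image, a circular
ROI of 90% of the phantom width is built, and:

* ``mean_signal`` = mean pixel intensity inside the Signal-image ROI,
* ``noise_sd``    = sample SD (n-1) of the same ROI applied to the Noise image,
* ``snr``         = correction * mean_signal / noise_sd,
* ``piu``         = 100 * (1 - (S_max - S_min) / (S_max + S_min)),

with S_max/S_min the raw (unsmoothed) extremes inside the Signal-image
ROI.  The SNR correction defaults to 1.0 (plain mean/SD ratio); a
Rayleigh-statistics factor of 0.655 can be selected for strict
normal-equivalent noise scaling — note that switching it rescales all
stored baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dicom_io import ImagePair
from .errors import CoilQaError, UndefinedPiuError, ZeroNoiseError
from .segmentation import CircularRoi, build_combined_roi, detect_phantom, roi_pixels

#: mean/SD -> amplitude/sigma correction for Rayleigh-distributed noise pixels
RAYLEIGH_CORRECTION = 0.655


@dataclass(frozen=True)
class AnalysisConfig:
    """Shared analysis knobs for combined and per-element metrics."""

    snr_correction: float = 1.0
    roi_fraction: float = 0.9
    threshold: str | float = "otsu"
    peak_roi_radius: float = 5.0
    smoothing_window: int = 10


@dataclass(frozen=True)
class SliceMetrics:
    """Metrics of one combined-element slice."""

    slice_location: float
    mean_signal: float
    noise_sd: float
    snr: float
    s_max: float
    s_min: float
    piu: float
    roi: CircularRoi


def compute_snr(mean_signal: float, noise_sd: float, correction: float = 1.0) -> float:
    """SNR = correction * mean_signal / noise_sd; noise_sd must be positive."""
    if noise_sd <= 0:
        raise ZeroNoiseError(
            f"noise SD {noise_sd} is not positive — the Noise image appears corrupt"
        )
    return correction * mean_signal / noise_sd


def compute_piu(s_max: float, s_min: float) -> float:
    """Percent image uniformity; 100 = perfectly uniform."""
    if not s_max >= s_min >= 0:
        raise UndefinedPiuError(f"require s_max >= s_min >= 0, got {s_max}, {s_min}")
    if s_max == 0:
        raise UndefinedPiuError("PIU undefined: maximum signal is zero")
    return 100.0 * (1.0 - (s_max - s_min) / (s_max + s_min))


def analyze_combined_series(
    pairs: list[ImagePair], config: AnalysisConfig | None = None
) -> list[SliceMetrics]:
    """One :class:`SliceMetrics` per pair, ordered by slice location."""
    if not pairs:
        raise CoilQaError("empty series")
    config = config or AnalysisConfig()
    out: list[SliceMetrics] = []
    for pair in sorted(pairs, key=lambda p: p.meta.slice_location):
        loc = pair.meta.slice_location
        try:
            geom = detect_phantom(pair.signal_pixels, threshold=config.threshold)
            roi = build_combined_roi(geom, fraction=config.roi_fraction)
            sig = roi_pixels(pair.signal_pixels, roi).astype(np.float64)
            noi = roi_pixels(pair.noise_pixels, roi).astype(np.float64)
            mean_signal = float(sig.mean())
            noise_sd = float(noi.std(ddof=1))
            s_max, s_min = float(sig.max()), float(sig.min())
            snr = compute_snr(mean_signal, noise_sd, config.snr_correction)
            piu = compute_piu(s_max, s_min)
        except CoilQaError as exc:
            raise type(exc)(f"slice {loc:+.1f} mm: {exc}") from exc
        out.append(
            SliceMetrics(
                slice_location=loc,
                mean_signal=mean_signal,
                noise_sd=noise_sd,
                snr=snr,
                s_max=s_max,
                s_min=s_min,
                piu=piu,
                roi=roi,
            )
        )
    return out
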