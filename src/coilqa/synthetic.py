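"""Synthetic phantom acquisitions with known ground truth.

Emulates the statistical structure of a multi-slice spin-echo QA
acquisition of a cylindrical phantom: an 18-slice axial stack with 100%
gap spanning ±170 mm, a ~13.5 cm circular phantom cross-section in a
300 mm / 256 px field of view, per-element receive sensitivities peaking
on the phantom rim near ±90 mm axially, magnitude (Rayleigh/Rician)
noise that is elevated within ±30 mm of isocenter, and injectable
element faults (dead: flat signal + 3x noise; noisy: mildly elevated
noise).  Every generated series carries its generating parameters as
ground truth so downstream estimators can be validated against analytic
expectations.

The generator works in image space only — there is no Bloch, coil-field
or k-space simulation.  Pixels are stored as 16-bit unsigned magnitude
values, matching scanner output conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Literal

import numpy as np
from scipy import stats

from .dicom_io import AcquisitionMeta, ImagePair
from .errors import InvalidDesignError

Distribution = Literal["rayleigh", "gaussian-magnitude"]
Fault = Literal["none", "dead", "noisy"]

#: residual flat in-phantom signal of a dead element (a.u.)
DEAD_FLAT_SIGNAL = 10.0
#: noise multiplier of a dead element
DEAD_NOISE_FACTOR = 3.0
#: noise multiplier of a degraded ("noisy") element
NOISY_NOISE_FACTOR = 1.25
#: in-plane exponential decay length of element sensitivity (mm)
ELEMENT_DECAY_MM = 45.0


@dataclass(frozen=True)
class AcquisitionDesign:
    """Geometry of the synthetic acquisition.

    Defaults reproduce the QA protocol geometry: 18 axial 10 mm slices
    with 100% gap (center-to-center spacing 20 mm, centers ±170 mm),
    FOV 300 mm at matrix 256 (pixel spacing 1.171875 mm), and a 135 mm
    diameter phantom centered in-plane.
    """

    n_slices: int = 18
    slice_thickness: float = 10.0
    gap_fraction: float = 1.0
    fov: float = 300.0
    matrix: int = 256
    phantom_diameter: float = 135.0
    center_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise InvalidDesignError("n_slices must be >= 1")
        if self.slice_thickness <= 0:
            raise InvalidDesignError("slice_thickness must be positive")
        if self.gap_fraction < 0:
            raise InvalidDesignError("gap_fraction must be >= 0")
        if self.matrix < 16:
            raise InvalidDesignError("matrix must be >= 16 px")
        if self.fov <= 0:
            raise InvalidDesignError("fov must be positive")
        if not 0 < self.phantom_diameter <= self.fov:
            raise InvalidDesignError("phantom must fit inside the FOV")

    @property
    def pixel_spacing(self) -> float:
        return self.fov / self.matrix


@dataclass(frozen=True)
class NoiseModel:
    """Magnitude-noise law of the receiver chain.

    ``base_sigma`` is the per-channel Gaussian sigma; magnitude pixels are
    Rayleigh (two i.i.d. Gaussian channels) by default, or a folded
    Gaussian when ``distribution="gaussian-magnitude"`` (analytically
    simpler for exact tests).  Noise is boosted by ``central_boost``
    for slice locations within ``boost_extent`` of isocenter, emulating
    the elevated noise observed at the central slices of a split-magnet
    system.
    """

    base_sigma: float = 22.0
    central_boost: float = 1.3
    boost_extent: float = 30.0
    distribution: Distribution = "rayleigh"

    def __post_init__(self) -> None:
        if self.base_sigma <= 0:
            raise InvalidDesignError("base_sigma must be positive")
        if self.central_boost < 1:
            raise InvalidDesignError("central_boost must be >= 1")

    def boost_at(self, slice_location: float) -> float:
        return self.central_boost if abs(slice_location) <= self.boost_extent else 1.0

    def sigma_at(self, slice_location: float) -> float:
        return self.base_sigma * self.boost_at(slice_location)


@dataclass(frozen=True)
class ElementModel:
    """One receive-coil element of a phased array.

    The sensitivity is separable: an exponential in-plane falloff from a
    point on the phantom rim at ``in_plane_angle`` (degrees, 0 = image
    right, counterclockwise with "up" = decreasing row), times a Gaussian
    axial profile centered at ``axial_center`` (mm from isocenter).  A
    ``sensitivity_scale`` of 0 models a physically absent channel that
    still records noise.
    """

    label: str
    axial_center: float = 95.0
    in_plane_angle: float = 270.0
    sensitivity_scale: float = 550.0
    axial_width: float = 110.0
    noise_sigma: float = 10.0
    fault: Fault = "none"

    def __post_init__(self) -> None:
        if self.sensitivity_scale < 0:
            raise InvalidDesignError("sensitivity_scale must be >= 0")
        if self.noise_sigma <= 0:
            raise InvalidDesignError("noise_sigma must be positive")

    @property
    def noise_factor(self) -> float:
        return {"none": 1.0, "dead": DEAD_NOISE_FACTOR, "noisy": NOISY_NOISE_FACTOR}[self.fault]


def slice_positions(design: AcquisitionDesign) -> np.ndarray:
    """Slice-center locations (mm from isocenter), ascending.

    Spacing is ``slice_thickness * (1 + gap_fraction)`` and the stack is
    symmetric about isocenter, e.g. 18 slices of 10 mm at 100% gap give
    centers -170, -150, ..., +150, +170 mm (center span 340 mm).
    """
    spacing = design.slice_thickness * (1.0 + design.gap_fraction)
    idx = np.arange(design.n_slices, dtype=np.float64) - (design.n_slices - 1) / 2.0
    return idx * spacing


@lru_cache(maxsize=32)
def _grid(design: AcquisitionDesign) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(phantom disc mask, X mm, Y mm) on pixel centers; Y grows downward."""
    m, ps = design.matrix, design.pixel_spacing
    coords = (np.arange(m) - (m - 1) / 2.0) * ps
    X, Y = np.meshgrid(coords, coords)  # X varies along columns, Y along rows
    ox, oy = design.center_offset
    r = design.phantom_diameter / 2.0
    mask = (X - ox) ** 2 + (Y - oy) ** 2 <= r**2
    return mask, X, Y


def phantom_disc(design: AcquisitionDesign) -> np.ndarray:
    """Boolean in-plane phantom mask on the image grid."""
    return _grid(design)[0]


# --- magnitude statistics ----------------------------------------------------

def magnitude_sample(
    rng: np.random.Generator,
    amplitude: np.ndarray | float,
    sigma: float,
    distribution: Distribution = "rayleigh",
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Draw a magnitude image around noise-free amplitude ``amplitude``."""
    if shape is None:
        shape = np.shape(amplitude)
    if distribution == "rayleigh":
        return np.hypot(amplitude + rng.normal(0.0, sigma, shape), rng.normal(0.0, sigma, shape))
    return np.abs(amplitude + rng.normal(0.0, sigma, shape))


def magnitude_mean(amplitude: float, sigma: float, distribution: Distribution = "rayleigh") -> float:
    """Exact mean of a magnitude pixel with true amplitude ``amplitude``."""
    if distribution == "rayleigh":
        return float(stats.rice.mean(amplitude / sigma, scale=sigma))
    return float(stats.foldnorm.mean(amplitude / sigma, scale=sigma))


def magnitude_noise_sd(sigma: float, distribution: Distribution = "rayleigh") -> float:
    """Exact SD of a noise-only magnitude pixel (zero amplitude)."""
    if distribution == "rayleigh":
        return sigma * math.sqrt(2.0 - math.pi / 2.0)
    return sigma * math.sqrt(1.0 - 2.0 / math.pi)


def _quantize(img: np.ndarray, quantize: bool) -> np.ndarray:
    if quantize:
        return np.clip(np.round(img), 0, 65535).astype(np.uint16)
    return np.maximum(img, 0.0).astype(np.float64)


# --- combined-element series -------------------------------------------------

@dataclass(frozen=True)
class CombinedTruth:
    """Generating parameters of a combined series, for validation.

    ``signal_levels[i]`` is the noise-free in-phantom intensity of slice
    ``i`` (uniform in-plane unless an in-plane modulation was applied);
    ``sigmas[i]`` the per-channel noise sigma.  ``true_roi_mean`` /
    ``true_noise_sd`` / ``true_snr`` give the exact expectations of the
    measured Signal-ROI mean, Noise-ROI SD and their ratio (quantization
    to integer intensities is ignored; its bias is negligible at the
    default noise scale).
    """

    design: AcquisitionDesign
    slice_locations: tuple[float, ...]
    signal_levels: tuple[float, ...]
    sigmas: tuple[float, ...]
    distribution: Distribution
    seed: int

    def true_roi_mean(self, index: int) -> float:
        return magnitude_mean(self.signal_levels[index], self.sigmas[index], self.distribution)

    def true_noise_sd(self, index: int) -> float:
        return magnitude_noise_sd(self.sigmas[index], self.distribution)

    def true_snr(self, index: int) -> float:
        return self.true_roi_mean(index) / self.true_noise_sd(index)

    def to_json(self) -> dict:
        return {
            "kind": "combined",
            "design": vars(self.design) | {"center_offset": list(self.design.center_offset)},
            "slice_locations": list(self.slice_locations),
            "signal_levels": list(self.signal_levels),
            "sigmas": list(self.sigmas),
            "distribution": self.distribution,
            "seed": self.seed,
        }


def make_combined_series(
    design: AcquisitionDesign,
    signal_profile: Callable[[float], float],
    noise: NoiseModel,
    seed: int,
    *,
    filter_label: str = "unfiltered",
    inplane: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    noiseless_signal: bool = False,
    quantize: bool = True,
    series_kind: str = "combined",
) -> tuple[list[ImagePair], CombinedTruth]:
    """Generate one Signal + one Noise image per slice (2 x n_slices images).

    The Signal image is a disc of intensity ``signal_profile(z)`` (times
    an optional in-plane modulation) plus magnitude noise; the Noise
    image is magnitude noise alone.  Deterministic given ``seed``.
    """
    mask, X, Y = _grid(design)
    locs = slice_positions(design)
    levels = np.array([float(signal_profile(z)) for z in locs])
    if np.any(levels < 0):
        raise InvalidDesignError("signal_profile must be >= 0 at every slice location")
    rng = np.random.default_rng(seed)
    pairs: list[ImagePair] = []
    for i, z in enumerate(locs):
        sigma = noise.sigma_at(z)
        amp = levels[i] * mask.astype(np.float64)
        if inplane is not None:
            amp = amp * np.clip(inplane(X, Y), 0.0, None)
        if noiseless_signal:
            sig = amp.copy()
        else:
            sig = magnitude_sample(rng, amp, sigma, noise.distribution)
        noi = magnitude_sample(rng, 0.0, sigma, noise.distribution, shape=mask.shape)
        meta = AcquisitionMeta(
            slice_location=float(z),
            pixel_spacing=(design.pixel_spacing, design.pixel_spacing),
            matrix=(design.matrix, design.matrix),
            series_kind=series_kind,  # type: ignore[arg-type]
            filter_label=filter_label,
        )
        pairs.append(ImagePair(_quantize(sig, quantize), _quantize(noi, quantize), meta))
    truth = CombinedTruth(
        design=design,
        slice_locations=tuple(float(z) for z in locs),
        signal_levels=tuple(levels),
        sigmas=tuple(noise.sigma_at(z) for z in locs),
        distribution=noise.distribution,
        seed=seed,
    )
    return pairs, truth


# --- uncombined (per-element) series ----------------------------------------

@lru_cache(maxsize=256)
def _rim_falloff(design: AcquisitionDesign, angle_deg: float) -> np.ndarray:
    """In-plane sensitivity: exp(-d/decay) from the rim point at angle_deg."""
    mask, X, Y = _grid(design)
    ox, oy = design.center_offset
    r = design.phantom_diameter / 2.0
    theta = math.radians(angle_deg)
    px = ox + r * math.cos(theta)
    py = oy - r * math.sin(theta)  # image Y grows downward; angle measured "up"
    d = np.hypot(X - px, Y - py)
    out = np.exp(-d / ELEMENT_DECAY_MM)
    out.setflags(write=False)
    return out


def element_amplitude(
    design: AcquisitionDesign, element: ElementModel, slice_location: float
) -> np.ndarray:
    """Noise-free Signal-image amplitude of one element at one slice."""
    mask = phantom_disc(design).astype(np.float64)
    if element.fault == "dead":
        return DEAD_FLAT_SIGNAL * mask
    if element.sensitivity_scale == 0:
        return np.zeros_like(mask)
    axial = math.exp(-(((slice_location - element.axial_center) / element.axial_width) ** 2))
    return element.sensitivity_scale * axial * _rim_falloff(design, element.in_plane_angle) * mask


@dataclass(frozen=True)
class ElementTruth:
    """Generating parameters of an uncombined acquisition."""

    design: AcquisitionDesign
    slice_locations: tuple[float, ...]
    elements: tuple[ElementModel, ...]
    noise: NoiseModel
    seed: int

    def element_sigma(self, element: ElementModel, slice_location: float) -> float:
        return element.noise_sigma * self.noise.boost_at(slice_location) * element.noise_factor

    def true_element_noise_sd(self, element: ElementModel, slice_location: float) -> float:
        return magnitude_noise_sd(self.element_sigma(element, slice_location), self.noise.distribution)

    def peak_position_px(self, element: ElementModel) -> tuple[float, float]:
        """Ground-truth in-plane sensitivity maximum (row, col), fractional px."""
        d = self.design
        ox, oy = d.center_offset
        r = d.phantom_diameter / 2.0
        theta = math.radians(element.in_plane_angle)
        x = ox + r * math.cos(theta)
        y = oy - r * math.sin(theta)
        half = (d.matrix - 1) / 2.0
        return (half + y / d.pixel_spacing, half + x / d.pixel_spacing)

    def to_json(self) -> dict:
        return {
            "kind": "uncombined",
            "design": vars(self.design) | {"center_offset": list(self.design.center_offset)},
            "slice_locations": list(self.slice_locations),
            "noise": vars(self.noise),
            "elements": [vars(e) for e in self.elements],
            "seed": self.seed,
        }


def make_element_series(
    design: AcquisitionDesign,
    elements: list[ElementModel],
    noise: NoiseModel,
    seed: int,
    *,
    quantize: bool = True,
) -> tuple[dict[str, list[ImagePair]], list[ImagePair], ElementTruth]:
    """Generate a "save uncombined" acquisition plus its sum-of-squares by-product.

    Returns ``(element_label -> pairs, sos_combined_pairs, truth)``.  With
    the default 18-slice design and 12 elements the uncombined series
    holds 432 images and the combined by-product 36.  The sum-of-squares
    Signal (Noise) image is the root-sum-of-squares of the element Signal
    (Noise) images, so with a single noiseless element it equals that
    element's image exactly.
    """
    if not elements:
        raise InvalidDesignError("at least one element is required")
    labels = [e.label for e in elements]
    if len(set(labels)) != len(labels):
        raise InvalidDesignError(f"duplicate element labels in {labels}")
    locs = slice_positions(design)
    rng = np.random.default_rng(seed)
    uncombined: dict[str, list[ImagePair]] = {e.label: [] for e in elements}
    sos_pairs: list[ImagePair] = []
    truth = ElementTruth(
        design=design,
        slice_locations=tuple(float(z) for z in locs),
        elements=tuple(elements),
        noise=noise,
        seed=seed,
    )
    ps = (design.pixel_spacing, design.pixel_spacing)
    shape = (design.matrix, design.matrix)
    for z in locs:
        sos_sig_sq = np.zeros(shape)
        sos_noi_sq = np.zeros(shape)
        for element in elements:
            sigma = truth.element_sigma(element, z)
            amp = element_amplitude(design, element, z)
            sig = magnitude_sample(rng, amp, sigma, noise.distribution)
            noi = magnitude_sample(rng, 0.0, sigma, noise.distribution, shape=shape)
            sos_sig_sq += sig**2
            sos_noi_sq += noi**2
            meta = AcquisitionMeta(
                slice_location=float(z),
                pixel_spacing=ps,
                matrix=shape,
                series_kind="uncombined",
                element_label=element.label,
                filter_label="unfiltered",
            )
            uncombined[element.label].append(
                ImagePair(_quantize(sig, quantize), _quantize(noi, quantize), meta)
            )
        sos_meta = AcquisitionMeta(
            slice_location=float(z),
            pixel_spacing=ps,
            matrix=shape,
            series_kind="combined_sos",
            filter_label="unfiltered",
        )
        sos_pairs.append(
            ImagePair(
                _quantize(np.sqrt(sos_sig_sq), quantize),
                _quantize(np.sqrt(sos_noi_sq), quantize),
                sos_meta,
            )
        )
    return uncombined, sos_pairs, truth


# --- presets -----------------------------------------------------------------

def combined_signal_profile(coil_type: str, filter_label: str = "unfiltered") -> Callable[[float], float]:
    """Axial signal profile of a combined series for a coil preset.

    Unfiltered receive-only coils peak near +90 mm (torso) or -90 mm
    (head/neck); prescan normalization replaces the axial shape with a
    body-coil-like bell centered at isocenter (an emulation of the
    filter's effect, not a physics model); the integrated body coil has
    a taller bell and 5x the noise.
    """
    if filter_label == "prescan":
        return lambda z: 600.0 * math.exp(-((z / 170.0) ** 2))
    if coil_type == "torso":
        return lambda z: 650.0 * math.exp(-(((z - 90.0) / 280.0) ** 2))
    if coil_type == "headneck":
        return lambda z: 650.0 * math.exp(-(((z + 90.0) / 280.0) ** 2))
    if coil_type == "body":
        return lambda z: 1050.0 * math.exp(-((z / 160.0) ** 2))
    raise InvalidDesignError(f"unknown coil type {coil_type!r}")


def default_noise_model(coil_type: str) -> NoiseModel:
    if coil_type == "body":
        return NoiseModel(base_sigma=105.0)  # ~5x the array-coil noise
    return NoiseModel()


def default_inplane(coil_type: str, filter_label: str = "unfiltered", design: AcquisitionDesign | None = None):
    """In-plane intensity modulation: a vertical gradient for unfiltered
    surface-coil images (uniformity ~75%), removed by prescan filtering."""
    if filter_label == "prescan" or coil_type == "body":
        return None
    radius = (design or AcquisitionDesign()).phantom_diameter / 2.0
    return lambda X, Y: 1.0 - 0.18 * Y / radius


def default_elements(coil_type: str) -> list[ElementModel]:
    """Element layout of a coil preset.

    Twelve channels in four groups of three: VAP/VAS on the bottom coil
    half, VPP/VPS on the top; third letter P = superior (+95 mm axial
    center), S = inferior (-95 mm).  The Head/Neck set exposes the same
    12 channels but VAP3 and VPP3 are physically absent: they are modeled
    as zero-sensitivity channels with low receiver noise.
    """
    if coil_type == "body":
        return []
    bottom = {"1": 220.0, "2": 270.0, "3": 320.0}
    top = {"1": 140.0, "2": 90.0, "3": 40.0}
    out: list[ElementModel] = []
    for group, angles, axial in (
        ("VAP", bottom, +95.0),
        ("VAS", bottom, -95.0),
        ("VPP", top, +95.0),
        ("VPS", top, -95.0),
    ):
        for num, angle in angles.items():
            label = f"{group}{num}"
            if coil_type == "headneck" and label in ("VAP3", "VPP3"):
                out.append(
                    ElementModel(label=label, axial_center=axial, in_plane_angle=angle,
                                 sensitivity_scale=0.0, noise_sigma=3.0)
                )
            else:
                out.append(ElementModel(label=label, axial_center=axial, in_plane_angle=angle))
    return out


def apply_fault(elements: list[ElementModel], label: str, fault: Fault) -> list[ElementModel]:
    """Return a copy of ``elements`` with ``fault`` injected on ``label``."""
    if label not in {e.label for e in elements}:
        raise InvalidDesignError(f"no element named {label!r}")
    return [replace(e, fault=fault) if e.label == label else e for e in elements]
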