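"""Reading and writing of phantom-QA DICOM series.

A QA acquisition produces, for every slice location (and, in "save
uncombined" mode, every coil element), two magnitude images: a *Signal*
image acquired normally and a *Noise* image acquired with the RF
transmitter off.  This module reads a directory of such single-frame MR
images, groups them by slice location and element label, classifies the
members of each group into Signal and Noise, and returns validated
:class:`ImagePair` objects sorted by slice location.

Three series kinds are handled:

``combined``
    one image pair per slice, all elements combined (adaptive combine),
    with or without prescan-normalization filtering;
``uncombined``
    one image pair per slice *and* coil element;
``combined_sos``
    the sum-of-squares combined by-product of an uncombined acquisition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.errors import InvalidDicomError
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid

from .errors import InconsistentSeriesError, MissingPairError

SeriesKind = Literal["combined", "uncombined", "combined_sos"]

#: fallback regex applied to SeriesDescription when no coil-name tag is set
_LABEL_RE = re.compile(r"\b([A-Z]{2,}\d+)\b")


@dataclass(frozen=True)
class AcquisitionMeta:
    """Header facts needed by the analysis, decoupled from DICOM tags.

    ``slice_location`` is the signed axial distance from isocenter in mm;
    ``acquisition_index`` is the ordinal of the image within its
    slice/element group (InstanceNumber order) and is used as the
    tie-break when Signal/Noise classification by intensity is ambiguous.
    """

    slice_location: float
    pixel_spacing: tuple[float, float]
    matrix: tuple[int, int]
    series_kind: SeriesKind
    element_label: str | None = None
    filter_label: str = "unknown"
    acquisition_index: int = 0

    def __post_init__(self) -> None:
        if min(self.pixel_spacing) <= 0:
            raise InconsistentSeriesError(f"non-positive pixel spacing {self.pixel_spacing}")
        if min(self.matrix) < 16:
            raise InconsistentSeriesError(f"matrix {self.matrix} smaller than 16 px")


@dataclass
class ImagePair:
    """One slice's (or slice+element's) Signal and Noise pixel arrays."""

    signal_pixels: np.ndarray
    noise_pixels: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.signal_pixels = np.asarray(self.signal_pixels)
        self.noise_pixels = np.asarray(self.noise_pixels)
        if self.signal_pixels.shape != self.noise_pixels.shape:
            raise InconsistentSeriesError(
                f"signal/noise shape mismatch at slice {self.meta.slice_location}"
            )


@dataclass
class DicomConfig:
    """Tag-layout knobs for scanners whose private layout differs.

    The element label is looked up in the standard Receive Coil Name tag
    (0018,1250) first, then in ``element_private_tag`` if configured, and
    finally extracted from SeriesDescription with ``label_regex``.
    """

    element_private_tag: tuple[int, int] | None = None
    label_regex: str = _LABEL_RE.pattern
    slice_rounding_mm: float = 0.1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DicomConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        tag = raw.get("element_private_tag")
        if tag is not None:
            tag = (int(str(tag[0]), 16), int(str(tag[1]), 16)) if isinstance(tag, (list, tuple)) else None
        return cls(
            element_private_tag=tag,
            label_regex=raw.get("label_regex", _LABEL_RE.pattern),
            slice_rounding_mm=float(raw.get("slice_rounding_mm", 0.1)),
        )


def assign_signal_noise(
    image_a: np.ndarray, image_b: np.ndarray, order: tuple[int, int] = (0, 1)
) -> tuple[np.ndarray, np.ndarray]:
    """Classify two same-shape images of one group into (Signal, Noise).

    The image with the larger maximum intensity is the Signal image.  On
    an exact tie the known acquisition order decides: the first-acquired
    image (smaller ``order`` entry) is taken as Signal.
    """
    max_a, max_b = float(np.max(image_a)), float(np.max(image_b))
    if max_a > max_b:
        return image_a, image_b
    if max_b > max_a:
        return image_b, image_a
    return (image_a, image_b) if order[0] <= order[1] else (image_b, image_a)


def _slice_location(ds: pydicom.Dataset) -> float:
    if "SliceLocation" in ds:
        return float(ds.SliceLocation)
    return float(ds.ImagePositionPatient[2])


def _element_label(ds: pydicom.Dataset, config: DicomConfig) -> str | None:
    name = getattr(ds, "ReceiveCoilName", None)
    if name:
        return str(name)
    if config.element_private_tag is not None and config.element_private_tag in ds:
        value = ds[config.element_private_tag].value
        if value:
            return str(value)
    desc = str(getattr(ds, "SeriesDescription", ""))
    m = re.search(config.label_regex, desc)
    return m.group(1) if m else None


def _filter_label(ds: pydicom.Dataset) -> str:
    desc = str(getattr(ds, "SeriesDescription", "")).lower()
    if "prescan" in desc:
        return "prescan"
    if "unfiltered" in desc or "none" in desc:
        return "unfiltered"
    return "unknown"


def load_series(
    directory: str | Path,
    expected_kind: SeriesKind,
    config: DicomConfig | None = None,
) -> list[ImagePair] | dict[str, list[ImagePair]]:
    """Read one QA series directory into grouped, validated image pairs.

    Returns a list of pairs sorted by slice location for combined kinds,
    or a mapping ``element_label -> sorted pairs`` for ``uncombined``.
    The result is independent of filesystem enumeration order: grouping
    keys are header values, and within each group images are ordered by
    InstanceNumber.
    """
    config = config or DicomConfig()
    directory = Path(directory)
    records = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except (InvalidDicomError, OSError):
            continue
        spacing = tuple(float(v) for v in ds.PixelSpacing)
        pixels = ds.pixel_array.astype(np.float64)
        loc = round(_slice_location(ds) / config.slice_rounding_mm) * config.slice_rounding_mm
        label = _element_label(ds, config) if expected_kind == "uncombined" else None
        records.append(
            {
                "loc": round(loc, 6),
                "label": label,
                "instance": int(getattr(ds, "InstanceNumber", 0)),
                "pixels": pixels,
                "spacing": spacing,
                "shape": pixels.shape,
                "filter": _filter_label(ds),
            }
        )
    if not records:
        raise MissingPairError(f"no readable DICOM images in {directory}")

    spacings = {r["spacing"] for r in records}
    shapes = {r["shape"] for r in records}
    if len(spacings) > 1 or len(shapes) > 1:
        raise InconsistentSeriesError(
            f"mixed pixel spacing {spacings} or matrix {shapes} in {directory}"
        )

    groups: dict[tuple[float, str | None], list[dict]] = {}
    for r in records:
        groups.setdefault((r["loc"], r["label"]), []).append(r)

    pairs: dict[str | None, list[ImagePair]] = {}
    for (loc, label), members in sorted(groups.items(), key=lambda kv: (str(kv[0][1]), kv[0][0])):
        if len(members) != 2:
            who = f"element {label}, " if label else ""
            raise MissingPairError(
                f"{who}slice {loc:+.1f} mm has {len(members)} image(s); expected a Signal/Noise pair"
            )
        members.sort(key=lambda r: r["instance"])
        signal, noise = assign_signal_noise(
            members[0]["pixels"], members[1]["pixels"], order=(0, 1)
        )
        meta = AcquisitionMeta(
            slice_location=loc,
            pixel_spacing=members[0]["spacing"],
            matrix=members[0]["shape"],
            series_kind=expected_kind,
            element_label=label,
            filter_label=members[0]["filter"],
            acquisition_index=members[0]["instance"],
        )
        pairs.setdefault(label, []).append(ImagePair(signal, noise, meta))

    for plist in pairs.values():
        plist.sort(key=lambda p: p.meta.slice_location)

    if expected_kind == "uncombined":
        if None in pairs:
            raise InconsistentSeriesError(
                "uncombined series contains images without an element label"
            )
        return {str(k): v for k, v in pairs.items()}
    if len(pairs) != 1:
        raise InconsistentSeriesError(
            f"combined series contains multiple element labels: {sorted(map(str, pairs))}"
        )
    return next(iter(pairs.values()))


# --- writing -----------------------------------------------------------------

def _make_dataset(
    pixels: np.ndarray,
    meta: AcquisitionMeta,
    *,
    is_signal: bool,
    instance_number: int,
    series_uid: str,
    study_uid: str,
    series_number: int,
    series_description: str,
) -> FileDataset:
    arr = np.clip(np.round(np.asarray(pixels, dtype=np.float64)), 0, 65535).astype(np.uint16)
    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = MRImageStorage
    file_meta.MediaStorageSOPInstanceUID = generate_uid(
        entropy_srcs=[series_uid, str(instance_number)]
    )
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(None, {}, file_meta=file_meta, preamble=b"\0" * 128)
    ds.SOPClassUID = MRImageStorage
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.Modality = "MR"
    ds.PatientName = "PHANTOM^QA"
    ds.PatientID = "COILQA"
    ds.StudyDate = ds.SeriesDate = ds.ContentDate = "20200101"
    ds.StudyTime = ds.SeriesTime = ds.ContentTime = "000000"
    ds.SeriesNumber = series_number
    ds.InstanceNumber = instance_number
    ds.SeriesDescription = series_description
    ds.ImageType = ["DERIVED", "PRIMARY", "M"]
    ds.ImageComments = "SIGNAL" if is_signal else "NOISE"
    if meta.element_label:
        ds.ReceiveCoilName = meta.element_label
    loc = float(round(meta.slice_location, 4))
    ds.SliceLocation = loc
    ds.ImagePositionPatient = [0.0, 0.0, loc]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [float(meta.pixel_spacing[0]), float(meta.pixel_spacing[1])]
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = arr.tobytes()
    return ds


def write_series(
    pairs: list[ImagePair],
    directory: str | Path,
    *,
    entropy: str = "coilqa",
    series_number: int = 1,
) -> list[Path]:
    """Write image pairs as classic single-frame MR DICOM files.

    The Signal image of every pair receives the lower InstanceNumber
    (Signal acquired first), slice location goes to both SliceLocation
    and ImagePositionPatient[2], and the element label (if any) to
    Receive Coil Name and SeriesDescription.  UIDs are derived
    deterministically from ``entropy`` so identical inputs produce
    byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study_uid = generate_uid(entropy_srcs=[entropy, "study"])
    series_uid = generate_uid(entropy_srcs=[entropy, "series", str(series_number)])
    paths = []
    instance = 1
    for pair in pairs:
        label = pair.meta.element_label or "comb"
        desc = f"coilqa {pair.meta.series_kind} {pair.meta.filter_label} {label}"
        for pixels, is_signal, tag in (
            (pair.signal_pixels, True, "S"),
            (pair.noise_pixels, False, "N"),
        ):
            ds = _make_dataset(
                pixels,
                pair.meta,
                is_signal=is_signal,
                instance_number=instance,
                series_uid=series_uid,
                study_uid=study_uid,
                series_number=series_number,
                series_description=desc,
            )
            name = f"{pair.meta.series_kind}_{label}_{pair.meta.slice_location:+08.1f}_{tag}.dcm"
            path = directory / name
            ds.save_as(path, enforce_file_format=True)
            paths.append(path)
            instance += 1
    return paths
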