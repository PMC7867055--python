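"""Study input/output: slice containers, DICOM / PNG+JSON readers and writers.

A study is a stack of short-axis end-diastole grayscale slices with the
acquisition geometry (slice thickness, inter-slice gap, in-plane pixel
spacing) needed to turn pixel counts into areas and volumes.  The canonical
in-memory order is apical-first; :func:`normalize_order` detects and undoes
stacks stored base-to-apex.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid
from PIL import Image
from scipy import stats
from skimage.filters import threshold_otsu


class StudyFormatError(ValueError):
    """Raised when an input study directory cannot be read consistently."""


@dataclass(frozen=True)
class SliceImage:
    """One grayscale short-axis frame plus its pixel geometry.

    Parameters
    ----------
    pixels : ndarray
        2-D intensity grid (any integer or float dtype).
    pixel_spacing : tuple of float
        (row mm/px, col mm/px); both strictly positive.
    instance_index : int
        Acquisition instance number (1-based in DICOM convention).
    slice_location : float or None
        Out-of-plane position in mm, if known.
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]
    instance_index: int
    slice_location: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise StudyFormatError("pixels: expected a 2-D grid")
        if min(px.shape) < 64:
            raise StudyFormatError(
                f"pixels: minimum side is 64 px, got shape {px.shape}"
            )
        rs, cs = self.pixel_spacing
        if rs <= 0 or cs <= 0:
            raise StudyFormatError(
                f"pixel_spacing: components must be > 0, got {self.pixel_spacing}"
            )

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_spacing[0] * self.pixel_spacing[1])


@dataclass
class StudyStack:
    """Ordered slice collection with through-plane geometry.

    ``slices`` are apical-first once :func:`normalize_order` has run;
    ``source_order`` records what was detected on disk.
    """

    slices: list[SliceImage]
    slice_thickness: float
    slice_gap: float
    source_order: str = "unknown"

    def __post_init__(self) -> None:
        if self.slice_thickness <= 0:
            raise StudyFormatError("slice_thickness: must be > 0")
        if self.slice_gap < 0:
            raise StudyFormatError("slice_gap: must be >= 0")
        if not self.slices:
            raise StudyFormatError("slices: stack is empty")
        sp0 = self.slices[0].pixel_spacing
        shape0 = self.slices[0].pixels.shape
        for s in self.slices[1:]:
            if s.pixels.shape != shape0:
                raise StudyFormatError(
                    f"slices: mixed dimensions {shape0} vs {s.pixels.shape}"
                )
            if not np.allclose(s.pixel_spacing, sp0):
                raise StudyFormatError(
                    f"slices: conflicting pixel_spacing {sp0} vs {s.pixel_spacing}"
                )

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def slice_interval(self) -> float:
        """Through-plane extent attributed to each slice (thickness + gap), mm."""
        return self.slice_thickness + self.slice_gap

    @property
    def pixel_spacing(self) -> tuple[float, float]:
        return self.slices[0].pixel_spacing


def window_normalize(pixels: np.ndarray, plow: float = 1.0, phigh: float = 99.0) -> np.ndarray:
    """Rescale a slice to [0, 1] by its robust (1st-99th percentile) window.

    Patient stacks from different scanners carry very different absolute gray
    levels; every thresholding step downstream operates on this windowed scale.
    """
    px = np.asarray(pixels, dtype=np.float64)
    lo, hi = np.percentile(px, [plow, phigh])
    if hi <= lo:
        return np.zeros_like(px)
    return np.clip((px - lo) / (hi - lo), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Readers


def read_study(path: str | Path) -> StudyStack:
    """Read a study from a directory of DICOM files or a PNG + ``meta.json`` fixture.

    Slices are sorted by SliceLocation when present, else by instance number.
    Thickness must be present (no silent default); a missing inter-slice gap is
    derived from consecutive slice locations minus the thickness.
    """
    path = Path(path)
    if not path.is_dir():
        raise StudyFormatError(f"not a directory: {path}")
    dicoms = sorted(path.glob("*.dcm"))
    if dicoms:
        return _read_dicom_series(dicoms)
    if (path / "meta.json").exists():
        return _read_png_fixture(path)
    raise StudyFormatError(f"no DICOM series or PNG fixture found in {path}")


def _read_dicom_series(files: list[Path]) -> StudyStack:
    slices: list[SliceImage] = []
    thickness = None
    gap = None
    for f in files:
        ds = pydicom.dcmread(f)
        if "SliceThickness" not in ds or ds.SliceThickness is None:
            raise StudyFormatError(f"{f.name}: missing SliceThickness tag")
        t = float(ds.SliceThickness)
        if thickness is not None and abs(t - thickness) > 1e-6:
            raise StudyFormatError("conflicting SliceThickness across files")
        thickness = t
        if "SpacingBetweenSlices" in ds and ds.SpacingBetweenSlices is not None:
            # DICOM stores center-to-center spacing; the gap is that minus thickness
            g = float(ds.SpacingBetweenSlices) - t
            gap = max(g, gap) if gap is not None else g
        loc = float(ds.SliceLocation) if "SliceLocation" in ds else None
        inst = int(ds.InstanceNumber) if "InstanceNumber" in ds else len(slices) + 1
        rs, cs = (float(v) for v in ds.PixelSpacing)
        slices.append(
            SliceImage(
                pixels=ds.pixel_array.astype(np.float64),
                pixel_spacing=(rs, cs),
                instance_index=inst,
                slice_location=loc,
            )
        )
    if gap is None:
        locs = [s.slice_location for s in slices]
        if len(slices) > 1 and all(l is not None for l in locs):
            step = float(np.median(np.abs(np.diff(sorted(locs)))))
            gap = step - thickness
        else:
            gap = 0.0
    if gap < 0:
        warnings.warn("derived slice gap negative; clamping to 0", stacklevel=2)
        gap = 0.0
    slices = _sort_slices(slices)
    return StudyStack(slices=slices, slice_thickness=thickness, slice_gap=gap)


def _read_png_fixture(path: Path) -> StudyStack:
    meta = json.loads((path / "meta.json").read_text())
    for key in ("slice_thickness", "slice_gap", "pixel_spacing", "instances"):
        if key not in meta:
            raise StudyFormatError(f"meta.json: missing field '{key}'")
    rs, cs = (float(v) for v in meta["pixel_spacing"])
    slices = []
    for rec in meta["instances"]:
        arr = np.asarray(Image.open(path / rec["file"]), dtype=np.float64)
        slices.append(
            SliceImage(
                pixels=arr,
                pixel_spacing=(rs, cs),
                instance_index=int(rec["instance_number"]),
                slice_location=rec.get("slice_location"),
            )
        )
    slices = _sort_slices(slices)
    return StudyStack(
        slices=slices,
        slice_thickness=float(meta["slice_thickness"]),
        slice_gap=float(meta["slice_gap"]),
    )


def _sort_slices(slices: list[SliceImage]) -> list[SliceImage]:
    if all(s.slice_location is not None for s in slices):
        return sorted(slices, key=lambda s: (s.slice_location, s.instance_index))
    return sorted(slices, key=lambda s: s.instance_index)


# ---------------------------------------------------------------------------
# Order normalization


def _blood_pool_area(s: SliceImage) -> float:
    """Bright-pixel count in a centered half-side ROI (LV blood pool proxy)."""
    win = window_normalize(s.pixels)
    h, w = win.shape
    roi = win[h // 4 : h - h // 4, w // 4 : w - w // 4]
    if roi.max() <= roi.min():
        return 0.0
    thr = threshold_otsu(roi)
    return float(np.count_nonzero(roi > thr))


def normalize_order(stack: StudyStack, min_trend: float = 0.6) -> StudyStack:
    """Return the stack in canonical apical-first order.

    The LV cross-section tapers toward the apex, so the blood-pool area trend
    along the stored order identifies the direction: increasing area means the
    stack is already apical-first, decreasing means it was stored base-first and
    is reversed.  An undecidable trend (|Spearman rho| < ``min_trend``) keeps
    the original order and flags it.  Idempotent.
    """
    if len(stack) == 1:
        return replace(stack, source_order="single")
    areas = [_blood_pool_area(s) for s in stack.slices]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input -> nan rho
        rho = stats.spearmanr(np.arange(len(areas)), areas).statistic
    if not np.isfinite(rho) or abs(rho) < min_trend:
        warnings.warn(
            "slice order undecidable from blood-pool trend; keeping stored order",
            stacklevel=2,
        )
        return replace(stack, source_order="unknown")
    if rho > 0:
        return replace(stack, source_order="apical_to_basal")
    return replace(
        stack, slices=list(reversed(stack.slices)), source_order="basal_to_apical"
    )


# ---------------------------------------------------------------------------
# Writers (used by the phantom generator and the CLI)


def write_study_dicom(stack: StudyStack, out_dir: str | Path, series_tag: str = "lvtrab") -> list[Path]:
    """Write the stack as a minimal uncompressed DICOM series (one file per slice)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid(entropy_srcs=[series_tag, "series"])
    paths = []
    for i, s in enumerate(stack.slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = MRImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(
            entropy_srcs=[series_tag, f"slice{i}"]
        )
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "MR"
        ds.SliceThickness = stack.slice_thickness
        # center-to-center spacing = thickness + gap
        ds.SpacingBetweenSlices = stack.slice_thickness + stack.slice_gap
        ds.PixelSpacing = [s.pixel_spacing[0], s.pixel_spacing[1]]
        ds.InstanceNumber = s.instance_index
        if s.slice_location is not None:
            ds.SliceLocation = s.slice_location
        px = np.clip(np.rint(s.pixels), 0, 65535).astype(np.uint16)
        ds.Rows, ds.Columns = px.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = px.tobytes()
        p = out_dir / f"slice_{i:03d}.dcm"
        ds.save_as(p, enforce_file_format=True)
        paths.append(p)
    return paths


def write_study_png(stack: StudyStack, out_dir: str | Path) -> list[Path]:
    """Write the stack as 16-bit grayscale PNGs plus a ``meta.json`` sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    instances = []
    paths = []
    for i, s in enumerate(stack.slices):
        name = f"slice_{i:03d}.png"
        px = np.clip(np.rint(s.pixels), 0, 65535).astype(np.uint16)
        Image.fromarray(px).save(out_dir / name)
        instances.append(
            {
                "file": name,
                "instance_number": s.instance_index,
                "slice_location": s.slice_location,
            }
        )
        paths.append(out_dir / name)
    meta = {
        "slice_thickness": stack.slice_thickness,
        "slice_gap": stack.slice_gap,
        "pixel_spacing": list(stack.pixel_spacing),
        "instances": instances,
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=2))
    return paths
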