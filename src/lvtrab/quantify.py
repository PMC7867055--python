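"""Areas, volumes, masses and the trabeculated-myocardium percentage (TM%).

Per slice, the trabecular area At and compact area Ac come straight from the
segmentation masks; the slice TM% is 100*At/(At+Ac).  Per patient, each
slice's area is extruded over the slice interval (thickness + gap) and summed
into the trabecular volume VT and compact-zone volume VCZ; the patient TM% is
100*VT/(VT+VCZ) — a volume-weighted quantity, not a mean of slice
percentages.  Masses are volumes times the myocardial tissue density
(1.05 g/mL by default).  A patient is labeled LVNC when TM% reaches the
27.4% cutoff (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .segmentation import SegmentationResult
from .studyio import StudyStack

TM_PCT_CUTOFF = 27.4  # patient-level LVNC threshold on TM%, percent
MYOCARDIAL_DENSITY = 1.05  # g/mL

LVNC = "LVNC"
NON_LVNC = "non-LVNC"


class QuantificationError(ValueError):
    pass


@dataclass(frozen=True)
class SliceQuant:
    """Per-slice areas (mm^2) and trabeculation percentage.

    ``tm_pct_slice`` is None (undefined) when both areas are zero — an empty
    slice carries no evidence either way and must not masquerade as 0%.
    """

    area_trabecular: float
    area_compact: float
    tm_pct_slice: Optional[float]

    @classmethod
    def from_areas(cls, at: float, ac: float) -> "SliceQuant":
        if at < 0 or ac < 0:
            raise QuantificationError("areas must be >= 0")
        tm = 100.0 * at / (at + ac) if at + ac > 0 else None
        return cls(area_trabecular=at, area_compact=ac, tm_pct_slice=tm)


@dataclass(frozen=True)
class PatientQuant:
    """Patient-level volumes (mL), TM%, masses (g) and the LVNC label."""

    vt: float
    vcz: float
    tm_pct: float
    mass_trabecular: float
    mass_compact: float
    density: float
    lvnc_label: str
    n_slices_used: int


def quantify_slice(
    seg: SegmentationResult, pixel_spacing: tuple[float, float]
) -> SliceQuant:
    """Convert a slice segmentation into physical areas and slice TM%."""
    px_area = float(pixel_spacing[0]) * float(pixel_spacing[1])
    at = float(seg.trabecular_mask.sum()) * px_area
    ac = float(seg.compact_mask.sum()) * px_area
    return SliceQuant.from_areas(at, ac)


def quantify_patient(
    slices: list[SliceQuant],
    stack: StudyStack,
    density: float = MYOCARDIAL_DENSITY,
) -> PatientQuant:
    """Sum slice areas into volumes, masses, TM% and the LVNC label.

    Each usable slice contributes area * slice_interval (mm^3, converted to
    mL).  Order independent: a reversed stack gives the identical result.
    """
    usable = [s for s in slices if s.tm_pct_slice is not None]
    if not usable:
        raise QuantificationError("no usable slices to quantify")
    if density <= 0:
        raise QuantificationError("density must be > 0")
    interval = stack.slice_interval  # mm
    vt = sum(s.area_trabecular for s in usable) * interval / 1000.0  # mm^3 -> mL
    vcz = sum(s.area_compact for s in usable) * interval / 1000.0
    tm_pct = 100.0 * vt / (vt + vcz) if vt + vcz > 0 else 0.0
    return PatientQuant(
        vt=vt,
        vcz=vcz,
        tm_pct=tm_pct,
        mass_trabecular=vt * density,
        mass_compact=vcz * density,
        density=density,
        lvnc_label=classify_lvnc(tm_pct),
        n_slices_used=len(usable),
    )


def classify_lvnc(tm_pct: float, cutoff: float = TM_PCT_CUTOFF) -> str:
    """LVNC iff the trabeculated-myocardium percentage reaches the cutoff."""
    if not 0.0 <= tm_pct <= 100.0:
        raise QuantificationError(f"tm_pct out of range [0, 100]: {tm_pct}")
    return LVNC if tm_pct >= cutoff else NON_LVNC
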