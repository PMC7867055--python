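"""Patient-level orchestration: segment a stack, quantify, profile FD, report.

Parallel execution (over slices) is contractually bit-identical to serial:
each slice is a pure function of its pixels and the configuration, and
results are assembled by slice index, so the worker count can never change
the output.
"""

from __future__ import annotations

import json
import logging
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image

from .fractal import FDProfile, box_count_fd, extract_border, fd_profile, split_thirds
from .quantify import (
    MYOCARDIAL_DENSITY,
    PatientQuant,
    SliceQuant,
    quantify_patient,
    quantify_slice,
)
from .segmentation import (
    SegmentationConfig,
    SegmentationError,
    SegmentationResult,
    segment_slice,
)
from .studyio import SliceImage, StudyStack, normalize_order, read_study

log = logging.getLogger("lvtrab")


@dataclass(frozen=True)
class RunConfig:
    """Everything a patient run needs, with the clinically relevant knobs."""

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    density: float = MYOCARDIAL_DENSITY
    workers: int = 1
    seed: int = 0
    write_overlays: bool = True

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("workers: must be >= 1")
        if self.density <= 0:
            raise ValueError("density: must be > 0")


@dataclass
class PatientReport:
    """Everything computed for one patient."""

    stack: StudyStack
    segmentations: list[Optional[SegmentationResult]]
    slice_quants: list[Optional[SliceQuant]]
    patient: PatientQuant
    fd: FDProfile
    failed_slices: list[int]

    def to_dict(self) -> dict:
        per_slice = []
        for i, (q, f) in enumerate(zip(self.slice_quants, self.fd.per_slice_fd)):
            per_slice.append(
                {
                    "slice": i,
                    "area_trabecular_mm2": None if q is None else round(q.area_trabecular, 3),
                    "area_compact_mm2": None if q is None else round(q.area_compact, 3),
                    "tm_pct_slice": None
                    if q is None or q.tm_pct_slice is None
                    else round(q.tm_pct_slice, 3),
                    "fd": None if f is None else round(f, 4),
                    "failed": i in self.failed_slices,
                }
            )
        p = self.patient
        return {
            "per_slice": per_slice,
            "patient": {
                "vt_ml": round(p.vt, 4),
                "vcz_ml": round(p.vcz, 4),
                "tm_pct": round(p.tm_pct, 3),
                "mass_trabecular_g": round(p.mass_trabecular, 4),
                "mass_compact_g": round(p.mass_compact, 4),
                "density_g_per_ml": p.density,
                "lvnc_label": p.lvnc_label,
                "n_slices_used": p.n_slices_used,
            },
            "fd": {
                "global_fd": round(self.fd.global_fd, 4),
                "global_label": self.fd.global_label,
                "max_fd_basal": _round_opt(self.fd.max_fd_basal),
                "max_fd_mid": _round_opt(self.fd.max_fd_mid),
                "max_fd_apical": _round_opt(self.fd.max_fd_apical),
                "third_labels": list(self.fd.third_labels),
            },
            "failed_slices": self.failed_slices,
            "source_order": self.stack.source_order,
        }


def _round_opt(v: Optional[float], nd: int = 4) -> Optional[float]:
    return None if v is None else round(v, nd)


def _segment_one(args: tuple[SliceImage, SegmentationConfig]):
    image, config = args
    try:
        return segment_slice(image, config)
    except SegmentationError as exc:
        return exc


def segment_stack(
    stack: StudyStack, config: SegmentationConfig, workers: int = 1
) -> list[Optional[SegmentationResult]]:
    """Segment every slice; failed slices yield None (and a log line).

    With ``workers`` > 1, slices are distributed over processes; the assembly
    is by index and each slice is independent, so output is identical to the
    serial run.
    """
    jobs = [(s, config) for s in stack.slices]
    if workers == 1 or len(jobs) == 1:
        raw = [_segment_one(j) for j in jobs]
    else:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            raw = list(pool.map(_segment_one, jobs))
    out: list[Optional[SegmentationResult]] = []
    for i, r in enumerate(raw):
        if isinstance(r, Exception):
            log.warning("slice %d failed: %s", i, r)
            out.append(None)
        else:
            out.append(r)
    return out


def process_stack(stack: StudyStack, config: RunConfig = RunConfig()) -> PatientReport:
    """Normalize order, segment, quantify and FD-profile one patient stack."""
    stack = normalize_order(stack)
    t0 = time.perf_counter()
    segs = segment_stack(stack, config.segmentation, config.workers)
    log.info(
        "segmented %d slices in %.2f s", len(stack), time.perf_counter() - t0
    )
    failed = [i for i, s in enumerate(segs) if s is None]
    quants = [
        None if s is None else quantify_slice(s, stack.pixel_spacing) for s in segs
    ]
    usable = [q for q in quants if q is not None]
    if not usable:
        raise SegmentationError("all slices failed segmentation")
    patient = quantify_patient(usable, stack, config.density)

    fds: list[Optional[float]] = []
    for s in segs:
        if s is None:
            fds.append(None)
        else:
            fds.append(box_count_fd(extract_border(s)))
    profile = fd_profile(fds, split_thirds(len(stack), apical_first=True))
    return PatientReport(
        stack=stack,
        segmentations=segs,
        slice_quants=quants,
        patient=patient,
        fd=profile,
        failed_slices=failed,
    )


def run_patient(
    input_path: str | Path, out_dir: str | Path, config: RunConfig = RunConfig()
) -> PatientReport:
    """Read a study directory, process it, and write all report artifacts."""
    stack = read_study(input_path)
    report = process_stack(stack, config)
    write_report(report, out_dir, overlays=config.write_overlays)
    return report


def write_report(
    report: PatientReport, out_dir: str | Path, overlays: bool = True
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = report.to_dict()
    (out / "patient.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    pd.DataFrame(payload["per_slice"]).to_csv(out / "slices.csv", index=False)
    pd.DataFrame([payload["patient"]]).to_csv(out / "patient.csv", index=False)
    _write_fd_report(report, out / "fd_report.csv")
    if overlays:
        for i, seg in enumerate(report.segmentations):
            if seg is None:
                continue
            img = render_overlay(report.stack.slices[i], seg)
            Image.fromarray(img).save(out / f"overlay_{i:03d}.png")
    for i, seg in enumerate(report.segmentations):
        if seg is None:
            continue
        (out / f"slice_{i:03d}.json").write_text(
            json.dumps(_slice_record(report, i), indent=2, sort_keys=True)
        )


def _slice_record(report: PatientReport, i: int) -> dict:
    seg = report.segmentations[i]
    q = report.slice_quants[i]
    assert seg is not None and q is not None
    return {
        "slice": i,
        "area_trabecular_mm2": round(q.area_trabecular, 3),
        "area_compact_mm2": round(q.area_compact, 3),
        "tm_pct_slice": _round_opt(q.tm_pct_slice, 3),
        "lv_centroid_px": [round(v, 3) for v in seg.lv_cavity.centroid_px],
        "external_polygon": np.round(seg.external_polygon, 3).tolist(),
        "rv_present": seg.rv_cavity is not None,
        "fd": _round_opt(report.fd.per_slice_fd[i]),
    }


def _write_fd_report(report: PatientReport, path: Path) -> None:
    thirds = split_thirds(len(report.stack), apical_first=True)
    names = {}
    for name, idx in (("basal", thirds.basal), ("mid", thirds.mid), ("apical", thirds.apical)):
        for i in idx:
            names[i] = name
    rows = [
        {"slice": i, "third": names[i], "fd": _round_opt(f)}
        for i, f in enumerate(report.fd.per_slice_fd)
    ]
    df = pd.DataFrame(rows)
    summary = pd.DataFrame(
        [
            {
                "slice": "global",
                "third": "",
                "fd": round(report.fd.global_fd, 4),
            }
        ]
    )
    pd.concat([df, summary], ignore_index=True).to_csv(path, index=False)


def render_overlay(image: SliceImage, seg: SegmentationResult) -> np.ndarray:
    """RGB rendering: external layer gray, trabecular contour blue, cavity red."""
    from .studyio import window_normalize
    from scipy.ndimage import binary_erosion

    base = (window_normalize(image.pixels) * 255).astype(np.uint8)
    rgb = np.stack([base] * 3, axis=-1)

    def contour(mask: np.ndarray) -> np.ndarray:
        return mask & ~binary_erosion(mask, structure=np.ones((3, 3), bool))

    h, w = base.shape
    ext = np.round(seg.external_polygon).astype(int)
    ext = ext[(ext[:, 0] >= 0) & (ext[:, 0] < h) & (ext[:, 1] >= 0) & (ext[:, 1] < w)]
    rgb[ext[:, 0], ext[:, 1]] = (160, 160, 160)
    tz = contour(seg.trabecular_mask)
    rgb[tz] = (40, 80, 255)
    cav = contour(seg.lv_cavity.mask())
    rgb[cav] = (255, 40, 40)
    return rgb
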