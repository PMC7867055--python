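"""Head-to-head comparison of the TM% and fractal-dimension diagnostic rules.

Given a per-patient table of (global FD, TM%), both inclusive thresholds are
applied — FD >= 1.26 and TM% >= 27.4 — and agreement, disagreement and
accuracy against a supplied ground-truth labeling are tabulated.  A slice
variant applies the per-third FD threshold (1.30) and the same TM% cutoff to
individual slices.

A 27-patient reference cohort (all carrying an established LVNC diagnosis)
ships with the package as ``data/cohort_global.csv`` and, for the patients
the two rules disagree on, per-slice values in ``data/cohort_slices.csv``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .fractal import THIRD_FD_THRESHOLD, classify_fd_global
from .quantify import LVNC, NON_LVNC, TM_PCT_CUTOFF, classify_lvnc


class ComparisonError(ValueError):
    pass


@dataclass(frozen=True)
class ComparisonRow:
    patient_id: str
    global_fd: float
    tm_pct: float
    fd_label: str
    tm_label: str
    agree: bool


@dataclass(frozen=True)
class ComparisonReport:
    rows: tuple[ComparisonRow, ...]
    n_fd_non_lvnc: int
    fd_accuracy_pct: int
    tm_accuracy_pct: int
    per_slice_disagreements: Optional[pd.DataFrame] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


def load_reference_cohort() -> pd.DataFrame:
    """Packaged 27-patient (FD, TM%) table."""
    with resources.as_file(
        resources.files("lvtrab.data").joinpath("cohort_global.csv")
    ) as p:
        return pd.read_csv(p)


def load_reference_slices() -> pd.DataFrame:
    """Packaged per-slice (FD, TM%) values for the disagreement patients."""
    with resources.as_file(
        resources.files("lvtrab.data").joinpath("cohort_slices.csv")
    ) as p:
        return pd.read_csv(p)


def compare_methods(
    table: list[tuple[str, float, float]],
    truth: dict[str, str],
) -> ComparisonReport:
    """Apply both diagnostic rules and score them against the truth labels.

    ``table`` holds (patient_id, global_fd, tm_pct) rows; ``truth`` maps every
    patient to LVNC / non-LVNC.  Accuracy is correct/total rounded to the
    nearest integer percent.
    """
    if not table:
        raise ComparisonError("empty comparison table")
    ids = [t[0] for t in table]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ComparisonError(f"duplicate patient_id: {dup}")
    missing = [i for i in ids if i not in truth]
    if missing:
        raise ComparisonError(f"truth labels missing for: {missing}")

    rows = []
    fd_correct = tm_correct = 0
    for pid, fd, tm in table:
        fd_label = classify_fd_global(fd)
        tm_label = classify_lvnc(tm)
        rows.append(
            ComparisonRow(
                patient_id=pid,
                global_fd=fd,
                tm_pct=tm,
                fd_label=fd_label,
                tm_label=tm_label,
                agree=fd_label == tm_label,
            )
        )
        fd_correct += fd_label == truth[pid]
        tm_correct += tm_label == truth[pid]
    n = len(rows)
    return ComparisonReport(
        rows=tuple(rows),
        n_fd_non_lvnc=sum(r.fd_label == NON_LVNC for r in rows),
        fd_accuracy_pct=round(100.0 * fd_correct / n),
        tm_accuracy_pct=round(100.0 * tm_correct / n),
    )


def compare_slices(
    per_slice: list[tuple[str, float, float]],
) -> pd.DataFrame:
    """Slice-level labels: FD >= 1.30 vs TM% >= 27.4, with agreement flags.

    Returns a frame with one row per (slice_id, fd, tm_pct) input.
    """
    recs = []
    for sid, fd, tm in per_slice:
        if not 0.0 < fd <= 2.0:
            raise ComparisonError(f"{sid}: FD {fd} outside (0, 2]")
        if not 0.0 <= tm <= 100.0:
            raise ComparisonError(f"{sid}: TM% {tm} outside [0, 100]")
        fd_label = LVNC if fd >= THIRD_FD_THRESHOLD else NON_LVNC
        tm_label = LVNC if tm >= TM_PCT_CUTOFF else NON_LVNC
        recs.append(
            {
                "slice_id": sid,
                "fd": fd,
                "tm_pct": tm,
                "fd_label": fd_label,
                "tm_label": tm_label,
                "agree": fd_label == tm_label,
            }
        )
    return pd.DataFrame(recs)


def compare_from_csv(
    table_path: str | Path,
    truth: str | dict[str, str] = "all-lvnc",
    slice_table_path: Optional[str | Path] = None,
) -> ComparisonReport:
    """Run the patient comparison from a CSV (patient_id, global_fd, tm_pct).

    ``truth`` is either an explicit per-patient mapping or the shorthand
    "all-lvnc" / "all-non-lvnc".
    """
    df = pd.read_csv(table_path)
    required = {"patient_id", "global_fd", "tm_pct"}
    if not required <= set(df.columns):
        raise ComparisonError(
            f"table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    for i, row in df.iterrows():
        if row.isna().any():
            raise ComparisonError(f"malformed row {i + 1}: {row.to_dict()}")
    table = [
        (str(r.patient_id), float(r.global_fd), float(r.tm_pct))
        for r in df.itertuples()
    ]
    if isinstance(truth, str):
        label = {"all-lvnc": LVNC, "all-non-lvnc": NON_LVNC}.get(truth)
        if label is None:
            raise ComparisonError(f"unknown truth shorthand: {truth!r}")
        truth = {pid: label for pid, _, _ in table}
    report = compare_methods(table, truth)
    if slice_table_path is not None:
        sdf = pd.read_csv(slice_table_path)
        per_slice = [
            (f"{r.patient_id}:{r.slice_id}", float(r.fd), float(r.tm_pct))
            for r in sdf.itertuples()
        ]
        slices = compare_slices(per_slice)
        report = ComparisonReport(
            rows=report.rows,
            n_fd_non_lvnc=report.n_fd_non_lvnc,
            fd_accuracy_pct=report.fd_accuracy_pct,
            tm_accuracy_pct=report.tm_accuracy_pct,
            per_slice_disagreements=slices[~slices.agree].reset_index(drop=True),
        )
    return report
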