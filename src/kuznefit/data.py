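"""Reading, cleaning and normalizing per-patient lesion time series.

Input is a long-format CSV of target-lesion longest diameters (LD, mm)
with measurement times in days relative to treatment start (negative =
pre-treatment scans).  Cleaning removes null and repeated measurements;
patients with fewer than seven net measurements are dropped so that at
least three points remain for fitting after holding out the final two or
three visits.  LD is converted to a tumor cell count assuming a spherical
lesion of which tumor cells occupy a packing fraction, then normalized by
the tumor-cell scale T0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import ScaleConstants

__all__ = [
    "PatientRecord",
    "Cohort",
    "REQUIRED_COLUMNS",
    "read_cohort",
    "write_cohort",
    "clean",
    "filter_cohort",
    "ld_to_cells",
    "cells_to_ld",
    "normalize",
]

REQUIRED_COLUMNS = ("patient_id", "study", "arm", "treatment", "time_days", "ld_mm")


class SchemaError(ValueError):
    """Input file does not provide the required columns."""


@dataclass
class PatientRecord:
    """One patient's LD time series, optionally cleaned and normalized.

    ``time_days`` and ``ld_mm`` are parallel arrays (NaN marks a null LD
    before cleaning).  After :func:`normalize`, ``tau`` holds dimensionless
    times and ``y`` normalized tumor-cell numbers; ``y[0]`` is the fitting
    initial condition y1.
    """

    patient_id: str
    study_id: str = ""
    arm_id: str = ""
    treatment: str = ""
    time_days: np.ndarray = field(default_factory=lambda: np.empty(0))
    ld_mm: np.ndarray = field(default_factory=lambda: np.empty(0))
    tau: np.ndarray | None = None
    y: np.ndarray | None = None
    cleaned: bool = False
    cleaning_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_days = np.asarray(self.time_days, dtype=float)
        self.ld_mm = np.asarray(self.ld_mm, dtype=float)
        if len(self.time_days) != len(self.ld_mm):
            raise ValueError("time_days and ld_mm must have equal length")

    def __len__(self) -> int:
        return len(self.time_days)

    @property
    def normalized(self) -> bool:
        return self.tau is not None and self.y is not None


@dataclass
class Cohort:
    """A set of patient records with unique ids, plus provenance."""

    records: list[PatientRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("patient_id must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, patient_id: str) -> PatientRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(patient_id)


def read_cohort(path: str | Path, column_map: Mapping[str, str] | None = None) -> Cohort:
    """Read a long-format cohort CSV into one record per patient.

    ``column_map`` maps file column names to the canonical schema
    (patient_id, study, arm, treatment, time_days, ld_mm).  Rows keep their
    file order; no cleaning is applied.  Null LD is an empty field or NA.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    def to_num(col: str, allow_null: bool) -> np.ndarray:
        raw = df[col].str.strip()
        null_mask = (raw == "") | raw.str.upper().isin({"NA", "NAN", "NULL"})
        num = pd.to_numeric(raw.mask(null_mask), errors="coerce")
        bad = num.isna() & ~null_mask
        if bad.any():
            rows = ", ".join(str(i) for i in df.index[bad][:10])
            raise ValueError(f"unparseable numeric in column {col!r} at row(s) {rows}")
        if not allow_null and null_mask.any():
            rows = ", ".join(str(i) for i in df.index[null_mask][:10])
            raise ValueError(f"null not allowed in column {col!r} at row(s) {rows}")
        return num.to_numpy(dtype=float)

    df["_time"] = to_num("time_days", allow_null=False)
    df["_ld"] = to_num("ld_mm", allow_null=True)

    records = []
    for pid, grp in df.groupby("patient_id", sort=False):
        records.append(
            PatientRecord(
                patient_id=str(pid),
                study_id=str(grp["study"].iloc[0]),
                arm_id=str(grp["arm"].iloc[0]),
                treatment=str(grp["treatment"].iloc[0]),
                time_days=grp["_time"].to_numpy(),
                ld_mm=grp["_ld"].to_numpy(),
            )
        )
    return Cohort(records=records, provenance={"source": str(path)})


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to the canonical long-format CSV dialect."""
    rows = []
    for r in cohort:
        for t, ld in zip(r.time_days, r.ld_mm):
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "study": r.study_id,
                    "arm": r.arm_id,
                    "treatment": r.treatment,
                    "time_days": t,
                    "ld_mm": "" if np.isnan(ld) else ld,
                }
            )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def clean(record: PatientRecord) -> PatientRecord:
    """Remove null and repeated measurements from one record.

    Rules: rows with null LD are dropped; exact duplicate (time, LD) rows
    collapse to one; when two rows share a time with different LD the first
    occurrence wins.  The result has strictly increasing times.  Dropped
    rows are noted in the cleaning log.  Idempotent.
    """
    log: list[str] = []
    t, ld = record.time_days, record.ld_mm

    keep = ~np.isnan(ld)
    n_null = int((~keep).sum())
    if n_null:
        log.append(f"{record.patient_id}: dropped {n_null} null LD row(s)")
    t, ld = t[keep], ld[keep]

    # stable sort by time so the first occurrence at each time is kept
    order = np.argsort(t, kind="stable")
    t, ld = t[order], ld[order]
    seen_times: dict[float, float] = {}
    keep_idx = []
    for i, (ti, li) in enumerate(zip(t, ld)):
        if ti in seen_times:
            if seen_times[ti] == li:
                log.append(f"{record.patient_id}: dropped duplicate row (t={ti}, ld={li})")
            else:
                log.append(
                    f"{record.patient_id}: conflicting LD at t={ti} "
                    f"(kept {seen_times[ti]}, dropped {li})"
                )
            continue
        seen_times[ti] = li
        keep_idx.append(i)

    return replace(
        record,
        time_days=t[keep_idx],
        ld_mm=ld[keep_idx],
        tau=None,
        y=None,
        cleaned=True,
        cleaning_log=record.cleaning_log + log,
    )


def filter_cohort(cohort: Cohort, min_net: int = 7) -> Cohort:
    """Keep only records with at least ``min_net`` net measurements."""
    kept = [r for r in cohort if len(r) >= min_net]
    prov = dict(cohort.provenance)
    prov["min_net"] = min_net
    prov["n_before_filter"] = len(cohort)
    return Cohort(records=kept, provenance=prov)


def ld_to_cells(ld_mm, scales: ScaleConstants = ScaleConstants()):
    """Convert lesion longest diameter (mm) to a tumor cell count.

    Assumes a spherical lesion of diameter LD with tumor cells occupying
    ``packing_fraction`` of the volume at ``cell_volume`` mm^3 per cell:
    cells = packing_fraction * (pi/6) * LD^3 / cell_volume.
    """
    ld = np.asarray(ld_mm, dtype=float)
    if np.any(ld < 0):
        raise ValueError("ld_mm must be >= 0")
    cells = scales.packing_fraction * (np.pi / 6.0) * ld**3 / scales.cell_volume
    return float(cells) if np.isscalar(ld_mm) else cells


def cells_to_ld(cells, scales: ScaleConstants = ScaleConstants()):
    """Inverse of :func:`ld_to_cells`."""
    c = np.asarray(cells, dtype=float)
    if np.any(c < 0):
        raise ValueError("cells must be >= 0")
    ld = (6.0 * c * scales.cell_volume / (scales.packing_fraction * np.pi)) ** (1.0 / 3.0)
    return float(ld) if np.isscalar(cells) else ld


def normalize(record: PatientRecord, scales: ScaleConstants = ScaleConstants()) -> PatientRecord:
    """Fill the dimensionless (tau, y) pairs used for fitting.

    tau = time_scale * time_days (tau may be negative for pre-treatment
    scans; times are never re-zeroed) and y = cells / T0.
    """
    if not record.cleaned:
        raise ValueError("record must be cleaned before normalization")
    if len(record) == 0:
        raise ValueError("cannot normalize an empty record")
    tau = scales.time_scale * record.time_days
    y = ld_to_cells(record.ld_mm, scales) / scales.T0
    return replace(record, tau=tau, y=y)


def truncate(record: PatientRecord, n_keep: int) -> PatientRecord:
    """First ``n_keep`` measurements of a record (for held-out fitting)."""
    if n_keep < 1 or n_keep > len(record):
        raise ValueError(f"n_keep must be in [1, {len(record)}], got {n_keep}")
    return replace(
        record,
        time_days=record.time_days[:n_keep],
        ld_mm=record.ld_mm[:n_keep],
        tau=None if record.tau is None else record.tau[:n_keep],
        y=None if record.y is None else record.y[:n_keep],
    )
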