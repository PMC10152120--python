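"""CSV ingestion and serialization of per-VOI time–activity tables.

The reproducible interface to the analysis is a tidy CSV with one row per
measurement: ``patient_id, cycle, voi_id, voi_type, time_h, activity_MBq``.
Image-to-activity conversion (reconstruction, calibration, registration)
happens upstream of this boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tac import VOI_TYPES, TimeActivityCurve, curve_from_arrays

TAC_COLUMNS = ["patient_id", "cycle", "voi_id", "voi_type", "time_h",
               "activity_MBq"]


def curves_to_frame(curves: Iterable[TimeActivityCurve]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": c.patient_id,
            "cycle": c.cycle,
            "voi_id": c.voi_id,
            "voi_type": c.voi_type,
            "time_h": s.time_h,
            "activity_MBq": s.activity_MBq,
        }
        for c in curves
        for s in c.samples
    ]
    return pd.DataFrame(rows, columns=TAC_COLUMNS)


def frame_to_curves(frame: pd.DataFrame) -> list[TimeActivityCurve]:
    """Group a tidy measurement table into validated, time-sorted curves."""
    missing = [c for c in TAC_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    curves = []
    for (pid, cycle, voi_id, voi_type), sub in frame.groupby(
        ["patient_id", "cycle", "voi_id", "voi_type"], sort=True
    ):
        curves.append(
            curve_from_arrays(
                str(pid), int(cycle), str(voi_id), str(voi_type),
                sub["time_h"].to_numpy(), sub["activity_MBq"].to_numpy(),
            )
        )
    return curves


def read_tac_csv(path) -> list[TimeActivityCurve]:
    """Read and validate a time–activity CSV.

    Malformed rows are reported with their file line numbers (header is
    line 1). Raises :class:`ValidationError` listing all offending lines,
    or a schema error when a required column is absent.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"patient_id": str, "voi_id": str,
                                     "voi_type": str})
    missing = [c for c in TAC_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")

    problems: list[str] = []
    lines = frame.index.to_numpy() + 2  # +1 header, +1 zero-based
    time = pd.to_numeric(frame["time_h"], errors="coerce")
    act = pd.to_numeric(frame["activity_MBq"], errors="coerce")
    cyc = pd.to_numeric(frame["cycle"], errors="coerce")
    for ln in lines[time.isna() | ~(time > 0)]:
        problems.append(f"line {ln}: time_h must be a positive number")
    for ln in lines[act.isna() | (act < 0)]:
        problems.append(f"line {ln}: activity_MBq must be a non-negative number")
    for ln in lines[cyc.isna() | ~cyc.isin([1, 2])]:
        problems.append(f"line {ln}: cycle must be 1 or 2")
    for ln in lines[~frame["voi_type"].isin(VOI_TYPES)]:
        problems.append(f"line {ln}: voi_type must be one of {VOI_TYPES}")
    dup = frame.duplicated(subset=["patient_id", "cycle", "voi_id", "time_h"],
                           keep=False)
    for ln in lines[dup.to_numpy()]:
        problems.append(f"line {ln}: duplicate (patient, cycle, voi, time) row")
    if problems:
        raise ValidationError(
            f"{path.name}: {len(problems)} invalid row(s):\n  "
            + "\n  ".join(problems)
        )

    frame = frame.assign(time_h=time, activity_MBq=act, cycle=cyc.astype(int))
    return frame_to_curves(frame)


def write_tac_csv(curves: Iterable[TimeActivityCurve], path) -> None:
    """Write curves to CSV with full float precision (lossless round trip)."""
    frame = curves_to_frame(curves)
    frame.to_csv(path, index=False, float_format="%.17g")
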