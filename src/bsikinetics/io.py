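"""Reading and writing the pipeline's delimited-text formats.

Two measurement dialects are accepted, distinguished by their header:

* relative dialect — columns ``patient_id, biomarker, day, value,
  below_lod`` with ``day`` already counted from the index blood culture;
* calendar dialect — columns ``patient_id, biomarker, specimen_date,
  value, below_lod`` (ISO dates), which requires a patient table with
  columns ``patient_id, group, index_date`` to convert dates to relative
  days.

All files are UTF-8 CSV with a header row.
"""
from __future__ import annotations

import dataclasses
import json

import pandas as pd

from .broken_stick import BrokenStickFit
from .datatypes import Biomarker, Measurement, MicrobialGroup, PatientRecord
from .preprocess import assign_relative_day

__all__ = ["read_cohort", "write_cohort", "write_patients",
           "fit_to_record", "write_fits"]

_RELATIVE_COLS = {"patient_id", "biomarker", "day", "value"}
_CALENDAR_COLS = {"patient_id", "biomarker", "specimen_date", "value"}


def read_cohort(measurements_path, patients_path=None) -> list[PatientRecord]:
    """Assemble patient records from a measurement table (+ patient table).

    The relative dialect works without a patient table (groups default to
    ``unknown``); the calendar dialect requires one for the index dates.
    """
    df = pd.read_csv(measurements_path)
    cols = set(df.columns)
    pat = None
    if patients_path is not None:
        pat = pd.read_csv(patients_path, dtype={"patient_id": str})
        pat = pat.set_index("patient_id")
    if _RELATIVE_COLS <= cols:
        df["day"] = df["day"].astype(int)
    elif _CALENDAR_COLS <= cols:
        if pat is None or "index_date" not in pat.columns:
            raise ValueError(
                "calendar-dated measurements require a patient table with "
                "an index_date column"
            )
        index_dates = pat["index_date"]
        df["day"] = [
            assign_relative_day(s, index_dates[str(pid)])
            for pid, s in zip(df["patient_id"], df["specimen_date"])
        ]
    else:
        raise ValueError(
            "unrecognised measurement columns: expected "
            f"{sorted(_RELATIVE_COLS)} or {sorted(_CALENDAR_COLS)}, got {sorted(cols)}"
        )
    if "below_lod" not in df.columns:
        df["below_lod"] = False
    df["below_lod"] = df["below_lod"].astype(bool)

    groups: dict[str, MicrobialGroup] = {}
    if pat is not None and "group" in pat.columns:
        groups = {pid: MicrobialGroup(g) for pid, g in pat["group"].items()}

    records: dict[str, PatientRecord] = {}
    ids = pat.index if pat is not None else pd.unique(df["patient_id"].astype(str))
    for pid in ids:
        pid = str(pid)
        records[pid] = PatientRecord(pid, groups.get(pid, MicrobialGroup.UNKNOWN))
    for row in df.itertuples(index=False):
        pid = str(row.patient_id)
        rec = records.setdefault(pid, PatientRecord(pid))
        rec.measurements.append(
            Measurement(pid, Biomarker(row.biomarker), int(row.day),
                        float(row.value), bool(row.below_lod))
        )
    return list(records.values())


def write_cohort(patients, path) -> None:
    """Write measurements in the relative dialect."""
    rows = [
        (p.patient_id, m.biomarker.value, m.relative_day, m.value, m.below_lod)
        for p in patients
        for m in p.measurements
    ]
    pd.DataFrame(
        rows, columns=["patient_id", "biomarker", "day", "value", "below_lod"]
    ).to_csv(path, index=False)


def write_patients(patients, path) -> None:
    """Write the patient table (id and microbial group)."""
    pd.DataFrame(
        [(p.patient_id, p.microbial_group.value) for p in patients],
        columns=["patient_id", "group"],
    ).to_csv(path, index=False)


def fit_to_record(fit: BrokenStickFit, **extra) -> dict:
    """Machine-readable record of one fit (JSON-serialisable)."""
    d = dataclasses.asdict(fit)
    d.update(extra)
    return d


def write_fits(records: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)
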