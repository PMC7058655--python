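"""Raw measurement tables -> analysis-ready cohort.

Stages, in the order the pipeline applies them: relative-day indexing,
windowing to days [-30, 1], detection-limit imputation for CRP,
implausible-value exclusion for albumin, eligibility filtering, and
daily-mean aggregation (the broken-stick fitting target).
"""
from __future__ import annotations

import dataclasses
import datetime
import logging
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    WINDOW,
    Biomarker,
    DailySeries,
    Measurement,
    PatientRecord,
)

__all__ = [
    "assign_relative_day",
    "impute_below_lod",
    "exclude_implausible_pa",
    "window_measurements",
    "select_cohort",
    "select_cohort_both",
    "daily_means",
    "patient_day_matrices",
]

logger = logging.getLogger(__name__)

CRP_LOD = 10.0  # mg/l, assay limit of detection
PA_FLOOR = 11.0  # g/l, below this albumin is treated as implausible


def _as_date(d) -> datetime.date:
    if isinstance(d, datetime.datetime):
        return d.date()
    if isinstance(d, datetime.date):
        return d
    return datetime.date.fromisoformat(str(d))


def assign_relative_day(specimen_date, index_date) -> int:
    """Whole-day difference ``specimen_date - index_date``.

    Day 0 is the day the index blood culture is drawn; time of day is
    never considered. Dates may be ``datetime.date`` or ISO-8601 strings.
    """
    return (_as_date(specimen_date) - _as_date(index_date)).days


def impute_below_lod(
    measurements: Iterable[Measurement],
    lod: float = CRP_LOD,
    rng: np.random.Generator | int | None = None,
    mode: str = "discrete",
) -> list[Measurement]:
    """Replace below-detection-limit CRP values by random sub-LOD draws.

    Flagged values are replaced by an independent draw from the discrete
    uniform on {0, 1, ..., 9} mg/l (``mode="discrete"``, the default) or
    the continuous uniform on [0, lod) (``mode="continuous"``). Values at
    or above the limit pass through untouched. Reproducible under a fixed
    seed.

    Raises
    ------
    ValueError
        If any measurement is not CRP — no albumin detection-limit rule
        exists.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if mode not in ("discrete", "continuous"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    out: list[Measurement] = []
    for m in measurements:
        if m.biomarker is not Biomarker.CRP:
            raise ValueError(
                f"impute_below_lod applies to CRP only, got {m.biomarker.value}"
            )
        if m.below_lod:
            if mode == "discrete":
                value = float(rng.integers(0, 10))
            else:
                value = float(rng.uniform(0.0, lod))
            out.append(dataclasses.replace(m, value=value, below_lod=False))
        else:
            out.append(m)
    return out


def exclude_implausible_pa(
    measurements: Iterable[Measurement], floor: float = PA_FLOOR
) -> list[Measurement]:
    """Drop albumin values strictly below ``floor`` (default 11 g/l).

    The boundary is strict: a value exactly at the floor survives. The
    number of removals is logged.
    """
    measurements = list(measurements)
    kept = [m for m in measurements if m.value >= floor]
    n_removed = len(measurements) - len(kept)
    if n_removed:
        logger.info("excluded %d implausible albumin values (< %g g/l)",
                    n_removed, floor)
    return kept


def window_measurements(
    patients: Sequence[PatientRecord], window: tuple[int, int] = WINDOW
) -> list[PatientRecord]:
    """Restrict every patient's series to relative days within ``window``."""
    lo, hi = window
    return [
        PatientRecord(
            p.patient_id,
            p.microbial_group,
            [m for m in p.measurements if lo <= m.relative_day <= hi],
        )
        for p in patients
    ]


def _eligible(p: PatientRecord, biomarker: Biomarker) -> bool:
    days = {m.relative_day for m in p.measurements if m.biomarker == biomarker}
    return any(-30 <= d <= -1 for d in days) and any(d in (0, 1) for d in days)


def select_cohort(
    patients: Sequence[PatientRecord], biomarker: Biomarker
) -> list[PatientRecord]:
    """Patients with >=1 measurement in days [-30, -1] and >=1 at day 0 or 1.

    Both requirements apply to the given biomarker; patients measured for
    only the other biomarker are dropped here but remain eligible for its
    own analysis. Idempotent and order-preserving.
    """
    return [p for p in patients if _eligible(p, biomarker)]


def select_cohort_both(patients: Sequence[PatientRecord]) -> list[PatientRecord]:
    """The intersection cohort eligible for both CRP and albumin."""
    return [
        p for p in patients
        if _eligible(p, Biomarker.CRP) and _eligible(p, Biomarker.PA)
    ]


def daily_means(
    patients: Sequence[PatientRecord],
    biomarker: Biomarker,
    statistic: str = "mean",
) -> DailySeries:
    """Pooled per-day mean concentration across all patients.

    Every specimen counts once — multiple same-day specimens from one
    patient each contribute — and days without specimens are absent.
    ``statistic="median"`` substitutes the per-day median.
    """
    rows = [
        (m.relative_day, m.value)
        for p in patients
        for m in p.measurements
        if m.biomarker == biomarker
    ]
    if not rows:
        return DailySeries(biomarker, np.array([], int), np.array([]), np.array([], int))
    df = pd.DataFrame(rows, columns=["day", "value"])
    agg = df.groupby("day")["value"].agg([statistic, "count"]).sort_index()
    return DailySeries(
        biomarker,
        agg.index.to_numpy(),
        agg[statistic].to_numpy(),
        agg["count"].to_numpy(),
    )


def patient_day_matrices(
    patients: Sequence[PatientRecord],
    biomarker: Biomarker,
    window: tuple[int, int] = WINDOW,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-patient per-day value sums and counts on the full day grid.

    Returns ``(days, sums, counts)`` where ``sums`` and ``counts`` are
    ``(n_patients, n_days)`` arrays. Resampling patients with replacement
    then reduces daily means to one vectorised sum — the workhorse of the
    patient-level bootstrap.
    """
    lo, hi = window
    days = np.arange(lo, hi + 1)
    sums = np.zeros((len(patients), len(days)))
    counts = np.zeros((len(patients), len(days)), dtype=int)
    for i, p in enumerate(patients):
        for m in p.measurements:
            if m.biomarker == biomarker and lo <= m.relative_day <= hi:
                j = m.relative_day - lo
                sums[i, j] += m.value
                counts[i, j] += 1
    return days, sums, counts
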