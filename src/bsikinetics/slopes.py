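"""Per-patient two-window slope analysis.

For each patient with at least two specimens in both a fixed early window
and a fixed late window, an ordinary least-squares line of concentration
on day is fitted within each window using that patient's specimens only.
The default windows follow the cohort analysis: for CRP, days −30..−4
(early) and −3..1 (late); for albumin, −30..−2 and −1..1 — the late
windows are the whole-day renderings of the cohort-level change-points.
The summary reports the share of patients whose late slope points in the
biomarker's acute direction (CRP rising, albumin falling).
"""
from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .datatypes import Biomarker, MicrobialGroup, PatientRecord

__all__ = [
    "SlopePair",
    "SlopeExclusion",
    "SlopePatternSummary",
    "DEFAULT_WINDOWS",
    "compute_slope_pairs",
    "summarize_slope_patterns",
]

#: (early, late) windows per biomarker, inclusive day ranges.
DEFAULT_WINDOWS: dict[Biomarker, tuple[tuple[int, int], tuple[int, int]]] = {
    Biomarker.CRP: ((-30, -4), (-3, 1)),
    Biomarker.PA: ((-30, -2), (-1, 1)),
}


@dataclass(frozen=True)
class SlopePair:
    patient_id: str
    biomarker: Biomarker
    slope_early: float  # units/day in the early window
    slope_late: float  # units/day in the late window
    n_early: int
    n_late: int
    group: MicrobialGroup

    def __post_init__(self) -> None:
        if self.n_early < 2 or self.n_late < 2:
            raise ValueError("slope pairs require >= 2 specimens per window")
        if not (np.isfinite(self.slope_early) and np.isfinite(self.slope_late)):
            raise ValueError("slopes must be finite")


@dataclass(frozen=True)
class SlopeExclusion:
    patient_id: str
    reason: str


@dataclass(frozen=True)
class SlopePatternSummary:
    """Cohort summary of individual slope pairs.

    ``proportion_acute`` is the share of included patients whose late
    slope is strictly in the acute direction: positive for CRP (rising
    inflammation marker), negative for albumin (falling). Quartiles of
    both slopes are given per microbial group.
    """

    biomarker: Biomarker
    n: int
    proportion_acute: float
    direction: str  # "rise" or "fall"
    quartiles: dict[str, dict[str, tuple[float, float, float]]]


def _ols_slope(days: np.ndarray, values: np.ndarray) -> float:
    days = days.astype(float)
    xc = days - days.mean()
    return float(np.dot(xc, values) / np.dot(xc, xc))


def compute_slope_pairs(
    patients: Sequence[PatientRecord],
    biomarker: Biomarker,
    window_early: tuple[int, int] | None = None,
    window_late: tuple[int, int] | None = None,
) -> tuple[list[SlopePair], list[SlopeExclusion]]:
    """Per-patient OLS slopes in the early and late windows.

    A patient is included only with >=2 specimens in each window, spread
    over >=2 distinct days (otherwise the within-window slope is
    undefined). Same-day duplicate specimens both enter the regression.
    Excluded patients are returned with the reason; exclusions are data,
    not errors.
    """
    we = window_early or DEFAULT_WINDOWS[biomarker][0]
    wl = window_late or DEFAULT_WINDOWS[biomarker][1]
    if we[0] > we[1] or wl[0] > wl[1]:
        raise ValueError("windows must satisfy start <= end")
    if we[1] >= wl[0]:
        raise ValueError("early and late windows must be disjoint and ordered")

    pairs: list[SlopePair] = []
    excluded: list[SlopeExclusion] = []
    for p in patients:
        sel = p.series(biomarker)
        early = [(m.relative_day, m.value) for m in sel if we[0] <= m.relative_day <= we[1]]
        late = [(m.relative_day, m.value) for m in sel if wl[0] <= m.relative_day <= wl[1]]
        reason = None
        if len(early) < 2:
            reason = "insufficient early specimens"
        elif len(late) < 2:
            reason = "insufficient late specimens"
        elif len({d for d, _ in early}) < 2:
            reason = "early specimens on a single day"
        elif len({d for d, _ in late}) < 2:
            reason = "late specimens on a single day"
        if reason is not None:
            excluded.append(SlopeExclusion(p.patient_id, reason))
            continue
        de, ve = map(np.array, zip(*early))
        dl, vl = map(np.array, zip(*late))
        pairs.append(
            SlopePair(
                patient_id=p.patient_id,
                biomarker=biomarker,
                slope_early=_ols_slope(de, ve),
                slope_late=_ols_slope(dl, vl),
                n_early=len(early),
                n_late=len(late),
                group=p.microbial_group,
            )
        )
    return pairs, excluded


def summarize_slope_patterns(
    pairs: Sequence[SlopePair],
    biomarker: Biomarker,
    threshold: float = 0.0,
) -> SlopePatternSummary:
    """Share of patients changing in the acute direction, plus quartiles.

    The classifier is a strict sign rule by default: ``slope_late >
    threshold`` for CRP, ``slope_late < -threshold`` for albumin (with
    ``threshold`` = 0). A positive ``threshold`` demands a minimum
    magnitude of change.
    """
    if not pairs:
        raise ValueError("cannot summarise an empty collection of slope pairs")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    late = np.array([p.slope_late for p in pairs])
    if biomarker is Biomarker.CRP:
        acute, direction = late > threshold, "rise"
    else:
        acute, direction = late < -threshold, "fall"
    quartiles: dict[str, dict[str, tuple[float, float, float]]] = {}
    df = pd.DataFrame(
        {
            "group": [p.group.value for p in pairs],
            "slope_early": [p.slope_early for p in pairs],
            "slope_late": [p.slope_late for p in pairs],
        }
    )
    for g, sub in df.groupby("group"):
        quartiles[g] = {
            which: tuple(np.percentile(sub[which], [25, 50, 75]))
            for which in ("slope_early", "slope_late")
        }
    return SlopePatternSummary(
        biomarker=biomarker,
        n=len(pairs),
        proportion_acute=float(acute.mean()),
        direction=direction,
        quartiles=quartiles,
    )


def slope_pairs_to_frame(pairs: Sequence[SlopePair]) -> pd.DataFrame:
    """One row per included patient, ready for export or plotting."""
    return pd.DataFrame(
        [
            (p.patient_id, p.biomarker.value, p.group.value, p.slope_early,
             p.slope_late, p.n_early, p.n_late)
            for p in pairs
        ],
        columns=["patient_id", "biomarker", "group", "slope_early",
                 "slope_late", "n_early", "n_late"],
    )
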