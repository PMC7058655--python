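"""Core domain types for biomarker kinetics before bloodstream infection.

Conventions used throughout the package:

* Relative day 0 ("D0") is the day the index blood culture is drawn;
  negative days precede it. The analysis window is ``[-30, 1]``.
* CRP (C-reactive protein) is measured in mg/l, plasma albumin (PA) in g/l.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Analysis window in relative days, inclusive on both ends.
WINDOW: tuple[int, int] = (-30, 1)


class Biomarker(str, enum.Enum):
    """Biomarkers tracked by the analysis."""

    CRP = "CRP"  # C-reactive protein, mg/l (positive acute-phase protein)
    PA = "PA"  # plasma albumin, g/l (negative acute-phase protein)


class MicrobialGroup(str, enum.Enum):
    """Microbial aetiology of the bloodstream infection."""

    GRAM_POS = "gram_pos"  # monomicrobial Gram-positive
    GRAM_NEG = "gram_neg"  # monomicrobial Gram-negative
    POLYMICROBIAL = "polymicrobial"
    UNKNOWN = "unknown"


#: Canonical ordering used for deterministic group-keyed random streams.
GROUP_ORDER: tuple[MicrobialGroup, ...] = (
    MicrobialGroup.GRAM_POS,
    MicrobialGroup.GRAM_NEG,
    MicrobialGroup.POLYMICROBIAL,
    MicrobialGroup.UNKNOWN,
)


@dataclass(frozen=True)
class Measurement:
    """One biomarker value for one patient on one relative day.

    ``below_lod`` marks CRP values reported below the assay detection
    limit; for such rows ``value`` holds the detection limit itself until
    :func:`bsikinetics.preprocess.impute_below_lod` replaces it.
    """

    patient_id: str
    biomarker: Biomarker
    relative_day: int
    value: float
    below_lod: bool = False

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"measurement value must be >= 0, got {self.value}")


@dataclass
class PatientRecord:
    """A patient's microbial group label and measurement series."""

    patient_id: str
    microbial_group: MicrobialGroup = MicrobialGroup.UNKNOWN
    measurements: list[Measurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.measurements:
            if m.patient_id != self.patient_id:
                raise ValueError(
                    f"measurement patient_id {m.patient_id!r} does not match "
                    f"record {self.patient_id!r}"
                )

    def series(self, biomarker: Biomarker) -> list[Measurement]:
        """Measurements of one biomarker, sorted by relative day."""
        sel = [m for m in self.measurements if m.biomarker == biomarker]
        return sorted(sel, key=lambda m: m.relative_day)


@dataclass(frozen=True)
class DailySeries:
    """Per-relative-day mean concentration and specimen count, all patients pooled.

    Days with zero specimens are absent. This is the fitting target of the
    broken-stick regression: one point per day, the arithmetic mean over
    every specimen drawn that day.
    """

    biomarker: Biomarker
    days: np.ndarray  # int, strictly increasing
    means: np.ndarray  # float, same length as days
    counts: np.ndarray  # int >= 1, same length as days

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        means = np.asarray(self.means, dtype=float)
        counts = np.asarray(self.counts, dtype=int)
        if not (len(days) == len(means) == len(counts)):
            raise ValueError("days, means and counts must have equal length")
        if len(days) and np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(counts < 1):
            raise ValueError("every day present must have count >= 1")
        if not np.all(np.isfinite(means)):
            raise ValueError("daily means must be finite")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return len(self.days)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "biomarker": self.biomarker.value,
                "day": self.days,
                "mean": self.means,
                "count": self.counts,
            }
        )


def measurements_to_frame(patients: list[PatientRecord]) -> pd.DataFrame:
    """Flatten patient records into a tidy long-format table."""
    rows = [
        (p.patient_id, p.microbial_group.value, m.biomarker.value,
         m.relative_day, m.value, m.below_lod)
        for p in patients
        for m in p.measurements
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "group", "biomarker", "day", "value", "below_lod"]
    )
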