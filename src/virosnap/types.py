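"""Participant-level data model for a two-arm long-acting vs oral HIV switch trial.

All timing is expressed in integer study days with randomization at day 0;
nominal week ``w`` corresponds to day ``7 * w``.  Viral loads censored at the
lower limit of quantification ("<50") are stored with ``below_lloq=True`` and
``copies_per_ml=0`` so that threshold comparisons never rely on a sentinel
value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

DAYS_PER_WEEK = 7


class Arm(str, enum.Enum):
    LONG_ACTING = "long_acting"
    ORAL = "oral"


class Stratum(str, enum.Enum):
    """Third-drug class at screening (the randomization stratification factor)."""

    INSTI = "INSTI"
    NNRTI = "NNRTI"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class DoseKind(str, enum.Enum):
    INJECTION = "injection"
    ORAL_DISPENSE = "oral_dispense"
    ORAL_BRIDGE = "oral_bridge"


class ChangeReason(str, enum.Enum):
    VIROLOGICAL_FAILURE = "virological_failure"
    ADVERSE_EVENT = "adverse_event"
    OTHER = "other"


class Gene(str, enum.Enum):
    RT = "RT"
    IN = "IN"


class Timepoint(str, enum.Enum):
    BASELINE = "baseline"
    FAILURE = "failure"


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    arm: Arm
    stratum: Stratum
    randomization_day: int = 0
    withdrawal_day: Optional[int] = None
    death_day: Optional[int] = None
    oral_lead_in: bool = False
    sex: Sex = Sex.FEMALE
    baseline_bmi: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("withdrawal_day", "death_day"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def followup_end_day(self) -> Optional[int]:
        """Day follow-up terminated (earlier of withdrawal and death), if any."""
        days = [d for d in (self.withdrawal_day, self.death_day) if d is not None]
        return min(days) if days else None


@dataclass(frozen=True)
class VLMeasurement:
    """A censoring-aware viral-load observation on the study-day axis."""

    participant_id: str
    study_day: int
    nominal_week: int
    copies_per_ml: int
    below_lloq: bool = False

    def __post_init__(self) -> None:
        if self.study_day < 0:
            raise ValueError("study_day must be >= 0")
        if self.copies_per_ml < 0:
            raise ValueError("copies_per_ml must be non-negative")
        if self.below_lloq and self.copies_per_ml >= 50:
            raise ValueError("below_lloq implies copies_per_ml < 50")

    def at_or_above(self, threshold: int) -> bool:
        """True when the measured value is >= threshold copies/ml."""
        if self.below_lloq:
            return False
        return self.copies_per_ml >= threshold


@dataclass(frozen=True)
class DoseEvent:
    participant_id: str
    kind: DoseKind
    target_day: int
    actual_day: Optional[int] = None  # absent = missed
    missed_oral_days: int = 0
    bridge_start_day: Optional[int] = None
    bridge_end_day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.missed_oral_days < 0:
            raise ValueError("missed_oral_days must be >= 0")
        if self.kind is DoseKind.INJECTION and self.missed_oral_days != 0:
            raise ValueError("missed_oral_days must be 0 for injections")
        if (self.bridge_start_day is None) != (self.bridge_end_day is None):
            raise ValueError("bridge interval needs both start and end")
        if self.bridge_start_day is not None and self.bridge_end_day < self.bridge_start_day:
            raise ValueError("bridge interval must be well ordered")


@dataclass(frozen=True)
class RegimenChange:
    participant_id: str
    start_day: int
    end_day: Optional[int] = None  # open-ended if absent
    within_class: bool = False
    reason: ChangeReason = ChangeReason.OTHER
    to_long_acting_oral_forms: bool = False

    def __post_init__(self) -> None:
        if self.end_day is not None and self.end_day < self.start_day:
            raise ValueError("end_day must be >= start_day")

    @property
    def duration_days(self) -> Optional[int]:
        if self.end_day is None:
            return None
        return self.end_day - self.start_day


@dataclass(frozen=True)
class AdverseEvent:
    participant_id: str
    onset_day: int
    grade: int
    serious: bool = False
    related: bool = False
    injection_site: bool = False
    led_to_discontinuation: bool = False

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3, 4):
            raise ValueError("grade must be in 1..4")


# Amino-acid alphabet for aligned sequences.  A position holds either a single
# residue, '*' for a stop codon, 'X' for no call, or a bracketed mixture such
# as '[NS]' occupying one reference position.
AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")
STOP = "*"
NOCALL = "X"


@dataclass(frozen=True)
class SequenceRecord:
    """An aligned amino-acid sequence in reference numbering.

    ``residues`` is a compact aligned string: one character per reference
    position, with mixtures written as bracketed sets (``[NS]``) that occupy a
    single position.
    """

    participant_id: str
    timepoint: Timepoint
    gene: Gene
    residues: str

    def positions(self) -> list[frozenset]:
        """Expand the aligned string to a per-position list of residue sets."""
        out: list[frozenset] = []
        i = 0
        s = self.residues
        while i < len(s):
            c = s[i]
            if c == "[":
                j = s.index("]", i)
                group = s[i + 1 : j]
                if not group:
                    raise ValueError(f"empty mixture at offset {i}")
                bad = set(group) - AA_LETTERS - {STOP}
                if bad:
                    raise ValueError(f"invalid residues {bad} at offset {i}")
                out.append(frozenset(group))
                i = j + 1
            elif c in AA_LETTERS or c in (STOP, NOCALL):
                out.append(frozenset(c))
                i += 1
            else:
                raise ValueError(f"invalid residue {c!r} at offset {i}")
        return out

    @property
    def fasta_id(self) -> str:
        return f"{self.participant_id}|{self.timepoint.value}|{self.gene.value}"


def week_to_day(week: int) -> int:
    return DAYS_PER_WEEK * week


def day_to_week(day: int) -> float:
    return day / DAYS_PER_WEEK
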