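"""Modified FDA snapshot classification of the week-96 virologic outcome.

Each participant is classified into ``suppressed`` / ``nonsuppressed`` /
``no_data`` from the viral load selected inside the analysis window
(weeks 84-102, days 588-714 inclusive, nominal day 672), with three
modifications to the plain snapshot treatment-switch rule: temporary regimen
changes lasting no more than 31 days, oral bridging of the long-acting drugs
with a subsequent return to injections, and within-class drug changes in the
oral arm are *not* treatment switches.  A participant who switched regimens
for virological failure before the end of their window is assigned
``nonsuppressed`` regardless of any in-window measurement.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .io import TrialDataset
from .types import (
    Arm,
    ChangeReason,
    ParticipantRecord,
    RegimenChange,
    VLMeasurement,
    week_to_day,
)


class SnapshotCategory(str, enum.Enum):
    SUPPRESSED = "suppressed"
    NONSUPPRESSED = "nonsuppressed"
    NO_DATA = "no_data"


class SnapshotReason(str, enum.Enum):
    OBSERVED_VL = "observed_vl"
    ASSIGNED_FAILURE_SWITCH = "assigned_failure_switch"
    DEATH = "death"
    WITHDRAWAL = "withdrawal"
    MISSING_IN_WINDOW = "missing_in_window"


@dataclass(frozen=True)
class SnapshotConfig:
    threshold: int = 50                  # copies/ml; 50 for the primary outcome
    window_start_week: int = 84
    window_end_week: int = 102
    nominal_week: int = 96
    temporary_change_max_days: int = 31
    window_extensions: dict[str, int] = field(default_factory=dict)  # pid -> end week

    def __post_init__(self) -> None:
        if not (self.window_start_week < self.nominal_week < self.window_end_week):
            raise ValueError("window must bracket the nominal week")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def window_days(self, participant_id: str) -> tuple[int, int]:
        end_week = self.window_extensions.get(participant_id, self.window_end_week)
        return week_to_day(self.window_start_week), week_to_day(end_week)

    @property
    def nominal_day(self) -> int:
        return week_to_day(self.nominal_week)


@dataclass(frozen=True)
class SnapshotResult:
    participant_id: str
    category: SnapshotCategory
    reason: SnapshotReason
    vl_used: Optional[VLMeasurement] = None

    def __post_init__(self) -> None:
        if self.category is SnapshotCategory.SUPPRESSED and self.reason is not SnapshotReason.OBSERVED_VL:
            raise ValueError("suppressed implies reason observed_vl")
        if self.category is SnapshotCategory.NO_DATA and self.vl_used is not None:
            raise ValueError("no_data implies no vl_used")


def is_disqualifying_switch(
    changes: Sequence[RegimenChange],
    arm: Arm,
    config: SnapshotConfig = SnapshotConfig(),
) -> tuple[bool, Optional[RegimenChange]]:
    """Return whether any regimen change counts as a treatment switch.

    A change is *not* a switch when it is temporary (lasting no more than
    ``temporary_change_max_days``), when it is oral dosing of the long-acting
    drugs with a later return to injections (bridging), or when it is a
    within-class change in the oral arm.  Returns the first qualifying change.
    """
    disqualifying = _disqualifying_switches(changes, arm, config)
    if disqualifying:
        return True, disqualifying[0]
    return False, None


def _disqualifying_switches(
    changes: Sequence[RegimenChange], arm: Arm, config: SnapshotConfig
) -> list[RegimenChange]:
    open_ended = [c for c in changes if c.end_day is None]
    if len(open_ended) > 1:
        raise ValueError(
            f"overlapping open-ended regimen changes for "
            f"{open_ended[0].participant_id}"
        )
    out = []
    for change in sorted(changes, key=lambda c: c.start_day):
        dur = change.duration_days
        if dur is not None and dur <= config.temporary_change_max_days:
            continue  # temporary change
        if change.to_long_acting_oral_forms and change.end_day is not None:
            continue  # oral bridging with return to injectable therapy
        if arm is Arm.ORAL and change.within_class:
            continue  # within-class change in the oral arm
        out.append(change)
    return out


def _select_window_vl(
    vls: Sequence[VLMeasurement], config: SnapshotConfig, participant_id: str
) -> Optional[VLMeasurement]:
    lo, hi = config.window_days(participant_id)
    in_window = [v for v in vls if lo <= v.study_day <= hi]
    if not in_window:
        return None
    nominal = config.nominal_day
    # closest to the nominal day; ties broken toward the later measurement
    return min(in_window, key=lambda v: (abs(v.study_day - nominal), -v.study_day))


def classify_snapshot(
    participant: ParticipantRecord,
    vls: Sequence[VLMeasurement],
    changes: Sequence[RegimenChange],
    config: SnapshotConfig = SnapshotConfig(),
) -> SnapshotResult:
    """Classify one participant's week-96 virologic outcome."""
    pid = participant.participant_id
    _, window_end = config.window_days(pid)

    if any(
        c.reason is ChangeReason.VIROLOGICAL_FAILURE and c.start_day <= window_end
        for c in _disqualifying_switches(changes, participant.arm, config)
    ):
        return SnapshotResult(pid, SnapshotCategory.NONSUPPRESSED,
                              SnapshotReason.ASSIGNED_FAILURE_SWITCH)

    chosen = _select_window_vl(vls, config, pid)
    if chosen is not None:
        if chosen.at_or_above(config.threshold):
            return SnapshotResult(pid, SnapshotCategory.NONSUPPRESSED,
                                  SnapshotReason.OBSERVED_VL, chosen)
        return SnapshotResult(pid, SnapshotCategory.SUPPRESSED,
                              SnapshotReason.OBSERVED_VL, chosen)

    # no in-window measurement: disposition-derived reason, death taking
    # precedence over withdrawal, then missing-in-window
    if participant.death_day is not None:
        reason = SnapshotReason.DEATH
    elif participant.withdrawal_day is not None:
        reason = SnapshotReason.WITHDRAWAL
    else:
        reason = SnapshotReason.MISSING_IN_WINDOW
    return SnapshotResult(pid, SnapshotCategory.NO_DATA, reason)


def classify_all(dataset: TrialDataset, config: SnapshotConfig = SnapshotConfig()) -> pd.DataFrame:
    """Per-participant snapshot classification table."""
    if not config.window_extensions and len(dataset.window_extensions):
        config = SnapshotConfig(
            threshold=config.threshold,
            window_start_week=config.window_start_week,
            window_end_week=config.window_end_week,
            nominal_week=config.nominal_week,
            temporary_change_max_days=config.temporary_change_max_days,
            window_extensions=dataset.extension_map(),
        )
    rows = []
    vls_by = dataset.vls_by_participant()
    changes_by = dataset.changes_by_participant()
    for p in dataset.participant_records():
        pid = p.participant_id
        res = classify_snapshot(p, vls_by[pid], changes_by[pid], config)
        rows.append({
            "participant_id": pid,
            "arm": p.arm.value,
            "stratum": p.stratum.value,
            "category": res.category.value,
            "reason": res.reason.value,
            "vl_day": res.vl_used.study_day if res.vl_used else pd.NA,
        })
    return pd.DataFrame(rows, columns=["participant_id", "arm", "stratum",
                                       "category", "reason", "vl_day"])


def snapshot_table(dataset: TrialDataset, config: SnapshotConfig = SnapshotConfig()) -> pd.DataFrame:
    """Per-arm (suppressed, nonsuppressed, no_data) counts.

    The three counts per arm always sum to the arm's size.
    """
    per = classify_all(dataset, config)
    rows = []
    for arm in (Arm.LONG_ACTING, Arm.ORAL):
        sub = per[per["arm"] == arm.value]
        rows.append({
            "arm": arm.value,
            "n": len(sub),
            "suppressed": int((sub["category"] == "suppressed").sum()),
            "nonsuppressed": int((sub["category"] == "nonsuppressed").sum()),
            "no_data": int((sub["category"] == "no_data").sum()),
        })
    return pd.DataFrame(rows)
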