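"""Analysis-population derivation: ITT-exposed, per-protocol and complete case.

ITT-E is everyone who received at least one dose of the assigned
intervention.  The per-protocol population further excludes, in precedence
order, participants who withdrew or died before week 96, participants with an
injection given more than 14 days after its target date once bridged days are
subtracted, and participants who missed more than 7 days of oral treatment at
one or more visits.  Complete case is ITT-E restricted to participants with a
viral load inside the snapshot window.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .io import TrialDataset
from .snapshot import SnapshotConfig
from .types import Arm, DoseEvent, DoseKind, week_to_day

#: widest plausible early-administration window (days); an injection recorded
#: earlier than this before its target is treated as a data problem
EARLY_VISIT_WINDOW_DAYS = 7


class PpExclusionReason(str, enum.Enum):
    WITHDREW_OR_DIED = "withdrew_or_died"
    INJECTION_DELAY_GT14_NO_BRIDGE = "injection_delay_gt14_no_bridge"
    MISSED_ORAL_GT7 = "missed_oral_gt7"


@dataclass(frozen=True)
class PopulationFlags:
    participant_id: str
    itt_e: bool
    per_protocol: bool
    complete_case: bool
    pp_exclusion_reason: Optional[PpExclusionReason] = None

    def __post_init__(self) -> None:
        if self.per_protocol and not self.itt_e:
            raise ValueError("per_protocol implies itt_e")
        if self.complete_case and not self.itt_e:
            raise ValueError("complete_case implies itt_e")


def injection_delay(dose: DoseEvent, bridges: Sequence[DoseEvent] = ()) -> int:
    """Delay of one injection in days, excluding days covered by oral bridging.

    The delay interval runs from the target day to the actual administration
    day; any oral-bridge days overlapping that interval are subtracted.
    """
    if dose.kind is not DoseKind.INJECTION:
        raise ValueError("injection_delay requires an injection DoseEvent")
    if dose.actual_day is None:
        raise ValueError("injection_delay requires actual_day")
    raw = dose.actual_day - dose.target_day
    if raw < -EARLY_VISIT_WINDOW_DAYS:
        warnings.warn(
            f"injection for {dose.participant_id} recorded {-raw} days before "
            f"target; treating delay as 0",
            stacklevel=2,
        )
        return 0
    if raw <= 0:
        return 0
    bridged = 0
    for b in bridges:
        if b.bridge_start_day is None:
            continue
        lo = max(b.bridge_start_day, dose.target_day)
        hi = min(b.bridge_end_day, dose.actual_day)
        if hi > lo:
            bridged += hi - lo
    return max(0, raw - bridged)


def derive_populations(
    dataset: TrialDataset,
    snapshot_config: SnapshotConfig = SnapshotConfig(),
    week96_day: int = week_to_day(96),
) -> pd.DataFrame:
    """Population flags for every participant.

    Returns a table with columns ``participant_id``, ``arm``, ``itt_e``,
    ``per_protocol``, ``complete_case`` and ``pp_exclusion_reason``.
    """
    if not snapshot_config.window_extensions and len(dataset.window_extensions):
        snapshot_config = SnapshotConfig(
            threshold=snapshot_config.threshold,
            window_start_week=snapshot_config.window_start_week,
            window_end_week=snapshot_config.window_end_week,
            nominal_week=snapshot_config.nominal_week,
            temporary_change_max_days=snapshot_config.temporary_change_max_days,
            window_extensions=dataset.extension_map(),
        )
    rows = []
    doses_by = dataset.doses_by_participant()
    vls_by = dataset.vls_by_participant()
    for p in dataset.participant_records():
        pid = p.participant_id
        doses = doses_by[pid]
        bridges = [d for d in doses if d.kind is DoseKind.ORAL_BRIDGE]

        itt_e = any(d.actual_day is not None for d in doses)

        reason: Optional[PpExclusionReason] = None
        end = p.followup_end_day
        if end is not None and end < week96_day:
            reason = PpExclusionReason.WITHDREW_OR_DIED
        elif any(
            injection_delay(d, bridges) > 14
            for d in doses
            if d.kind is DoseKind.INJECTION and d.actual_day is not None
        ):
            reason = PpExclusionReason.INJECTION_DELAY_GT14_NO_BRIDGE
        elif any(
            d.missed_oral_days > 7
            for d in doses
            if d.kind in (DoseKind.ORAL_DISPENSE, DoseKind.ORAL_BRIDGE)
        ):
            reason = PpExclusionReason.MISSED_ORAL_GT7

        per_protocol = itt_e and reason is None

        lo, hi = snapshot_config.window_days(pid)
        has_window_vl = any(lo <= v.study_day <= hi for v in vls_by[pid])
        complete_case = itt_e and has_window_vl

        rows.append({
            "participant_id": pid,
            "arm": p.arm.value,
            "itt_e": itt_e,
            "per_protocol": per_protocol,
            "complete_case": complete_case,
            "pp_exclusion_reason": reason.value if (itt_e and reason) else pd.NA,
        })
    return pd.DataFrame(rows)


def population_summary(flags: pd.DataFrame) -> pd.DataFrame:
    """Per-arm population sizes and per-protocol exclusion counts by reason."""
    rows = []
    for arm in (Arm.LONG_ACTING, Arm.ORAL):
        sub = flags[flags["arm"] == arm.value]
        row = {
            "arm": arm.value,
            "itt_e": int(sub["itt_e"].sum()),
            "per_protocol": int(sub["per_protocol"].sum()),
            "complete_case": int(sub["complete_case"].sum()),
        }
        for reason in PpExclusionReason:
            row[f"excl_{reason.value}"] = int(
                (sub["pp_exclusion_reason"] == reason.value).sum()
            )
        rows.append(row)
    return pd.DataFrame(rows)
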