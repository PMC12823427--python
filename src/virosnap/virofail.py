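"""Arm-specific viral-load monitoring and confirmed-virological-failure (CVF)
detection.

A long-acting-arm result at or above 200 copies/ml prompts a repeat test 4-6
weeks later; the oral arm uses a higher 1,000 copies/ml trigger with a repeat
10-16 weeks later (allowing adherence counselling).  Confirmed virological
failure is two consecutive measurements in a participant's series both at or
above 200 copies/ml, irrespective of their spacing: the retest windows govern
when measurements are generated, not how failure is defined.  A single
qualifying value with an explicit adjudication record (for example death
before the repeat test) is an adjudicated, unconfirmed failure that the
pipeline counts only when configured to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .io import TrialDataset
from .types import Arm, VLMeasurement, week_to_day


@dataclass(frozen=True)
class MonitoringRule:
    arm: Arm
    trigger_threshold: int
    retest_weeks_lo: int
    retest_weeks_hi: int
    confirm_threshold: int = 200

    def __post_init__(self) -> None:
        if self.trigger_threshold <= 0 or self.confirm_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.retest_weeks_lo > self.retest_weeks_hi:
            raise ValueError("retest window must be well ordered")


LONG_ACTING_RULE = MonitoringRule(Arm.LONG_ACTING, trigger_threshold=200,
                                  retest_weeks_lo=4, retest_weeks_hi=6)
ORAL_RULE = MonitoringRule(Arm.ORAL, trigger_threshold=1000,
                           retest_weeks_lo=10, retest_weeks_hi=16)


def rule_for(arm: Arm) -> MonitoringRule:
    return LONG_ACTING_RULE if arm is Arm.LONG_ACTING else ORAL_RULE


@dataclass(frozen=True)
class CvfStatus:
    participant_id: str
    confirmed: bool
    adjudicated_unconfirmed: bool = False
    failure_day: Optional[int] = None
    qualifying_pair: Optional[tuple[VLMeasurement, VLMeasurement]] = None

    def __post_init__(self) -> None:
        if self.confirmed and self.adjudicated_unconfirmed:
            raise ValueError("confirmed excludes adjudicated_unconfirmed")
        if self.confirmed and self.qualifying_pair is None:
            raise ValueError("confirmed requires a qualifying pair")


def retest_due(vl: VLMeasurement, rule: MonitoringRule) -> Optional[tuple[int, int]]:
    """Retest day interval triggered by one measurement, if any."""
    if not vl.at_or_above(rule.trigger_threshold):
        return None
    return (
        vl.study_day + week_to_day(rule.retest_weeks_lo),
        vl.study_day + week_to_day(rule.retest_weeks_hi),
    )


def detect_cvf(
    series: Sequence[VLMeasurement],
    rule: MonitoringRule,
    adjudicated_days: Sequence[int] = (),
) -> CvfStatus:
    """Scan a day-sorted series for the first consecutive pair >= 200 copies/ml.

    ``adjudicated_days`` are study days of single qualifying measurements for
    which a clinical adjudication record exists (never inferred from the data).
    """
    pid = series[0].participant_id if series else ""
    prev: Optional[VLMeasurement] = None
    for vl in series:
        if prev is not None and prev.at_or_above(rule.confirm_threshold) and vl.at_or_above(rule.confirm_threshold):
            return CvfStatus(pid, confirmed=True, failure_day=prev.study_day,
                             qualifying_pair=(prev, vl))
        prev = vl
    for vl in series:
        if vl.at_or_above(rule.confirm_threshold) and vl.study_day in set(adjudicated_days):
            return CvfStatus(pid, confirmed=False, adjudicated_unconfirmed=True,
                             failure_day=vl.study_day)
    return CvfStatus(pid, confirmed=False)


def cvf_statuses(dataset: TrialDataset) -> pd.DataFrame:
    """Per-participant CVF status table."""
    adj_by: dict[str, list[int]] = {}
    for r in dataset.adjudications.itertuples():
        adj_by.setdefault(r.participant_id, []).append(int(r.study_day))
    rows = []
    vls_by = dataset.vls_by_participant()
    for p in dataset.participant_records():
        pid = p.participant_id
        status = detect_cvf(vls_by[pid], rule_for(p.arm), adj_by.get(pid, ()))
        rows.append({
            "participant_id": pid,
            "arm": p.arm.value,
            "stratum": p.stratum.value,
            "confirmed": status.confirmed,
            "adjudicated_unconfirmed": status.adjudicated_unconfirmed,
            "failure_day": status.failure_day if status.failure_day is not None else pd.NA,
        })
    return pd.DataFrame(rows)


def cvf_table(dataset: TrialDataset, count_adjudicated: bool = True) -> pd.DataFrame:
    """Per-arm failure counts over ITT-E.

    ``count_adjudicated`` controls whether adjudicated unconfirmed failures
    count as failures.
    """
    per = cvf_statuses(dataset)
    failed = per["confirmed"] | (per["adjudicated_unconfirmed"] if count_adjudicated else False)
    rows = []
    for arm in (Arm.LONG_ACTING, Arm.ORAL):
        sub = per["arm"] == arm.value
        rows.append({
            "arm": arm.value,
            "n": int(sub.sum()),
            "failures": int((failed & sub).sum()),
        })
    return pd.DataFrame(rows)
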