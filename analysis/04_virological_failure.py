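#!/usr/bin/env python
"""Confirmed virological failure and its noninferiority interval.

Detects confirmed failure (two consecutive viral loads >= 200 copies/ml) per
participant, counts the single adjudicated unconfirmed failure when enabled,
and computes the unstratified Miettinen-Nurminen 95% CI for the risk
difference.  On the reference fixture: 4/255 vs 0/257 failures, difference
1.6 percentage points.
"""

from pathlib import Path

from virosnap.io import read_trial_dataset
from virosnap.stats import Bound, TwoByTwo, mn_score_ci, noninferiority_decision
from virosnap.virofail import cvf_statuses, cvf_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ds = read_trial_dataset(RESULTS / "data" / "reference")
    cvf_statuses(ds).to_csv(RESULTS / "cvf_participants_reference.csv", index=False)
    for adjudicated in (True, False):
        table = cvf_table(ds, count_adjudicated=adjudicated).set_index("arm")
        label = "with" if adjudicated else "without"
        print(f"failures {label} the adjudicated case: "
              f"{table.loc['long_acting', 'failures']}/{table.loc['long_acting', 'n']} "
              f"vs {table.loc['oral', 'failures']}/{table.loc['oral', 'n']}")
    table = cvf_table(ds, count_adjudicated=True).set_index("arm")
    t = TwoByTwo(int(table.loc["long_acting", "failures"]),
                 int(table.loc["long_acting", "n"]),
                 int(table.loc["oral", "failures"]),
                 int(table.loc["oral", "n"]))
    ci = mn_score_ci(t)
    decision = noninferiority_decision(ci, margin=4.0, bound_used=Bound.UPPER)
    print(f"risk difference {ci.estimate:.1f} pp "
          f"(95% MN CI {ci.lower:.1f} to {ci.upper:.1f}); "
          f"4 pp upper-bound criterion {'met' if decision.met else 'not met'}")
    with open(RESULTS / "cvf_interval_reference.txt", "w") as fh:
        fh.write(f"{ci.estimate:.4f} {ci.lower:.4f} {ci.upper:.4f} "
                 f"met={decision.met}\n")


if __name__ == "__main__":
    main()
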