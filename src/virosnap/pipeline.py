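"""End-to-end report pipeline tying the analysis stages together.

``run_pipeline`` executes snapshot classification, population derivation,
confirmed-virological-failure detection, the APOBEC-aware resistance summary
and the noninferiority statistics on one dataset, writes the report tables as
CSV plus a human-readable summary, and returns everything in memory.  Outputs
are a deterministic function of the dataset and configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .io import TrialDataset
from .populations import derive_populations, population_summary
from .resistance import MutationLists, default_mutation_lists, load_drm_list, load_signatures, resistance_prevalence
from .snapshot import SnapshotConfig, classify_all, snapshot_table
from .stats import (
    Bound,
    DiffCI,
    StratumCounts,
    TwoByTwo,
    cmh_mn_ci,
    mn_score_ci,
    noninferiority_decision,
    round_half_away,
    wald_ci,
)
from .types import Arm, Stratum
from .virofail import cvf_statuses, cvf_table


@dataclass(frozen=True)
class PipelineConfig:
    snapshot: SnapshotConfig = field(default_factory=SnapshotConfig)
    suppression_margin: float = 10.0   # percentage points, lower bound
    cvf_margin: float = 4.0            # percentage points, upper bound
    alpha: float = 0.05
    count_adjudicated_cvf: bool = True
    drm_list_path: Optional[str] = None
    signature_list_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.suppression_margin <= 0 or self.cvf_margin <= 0:
            raise ValueError("margins must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        snap_raw = raw.pop("snapshot", {})
        snapshot = SnapshotConfig(**snap_raw)
        return cls(snapshot=snapshot, **raw)

    def mutation_lists(self) -> MutationLists:
        if self.drm_list_path is None and self.signature_list_path is None:
            return default_mutation_lists()
        base = default_mutation_lists()
        drm = load_drm_list(self.drm_list_path) if self.drm_list_path else base.ias_drm_list
        if self.signature_list_path:
            rt, in_ = load_signatures(self.signature_list_path)
        else:
            rt, in_ = base.apobec_signatures_rt, base.apobec_signatures_in
        return MutationLists(ias_drm_list=drm, apobec_signatures_rt=rt,
                             apobec_signatures_in=in_)

    def digest(self) -> str:
        payload = {
            "threshold": self.snapshot.threshold,
            "window": [self.snapshot.window_start_week, self.snapshot.window_end_week],
            "suppression_margin": self.suppression_margin,
            "cvf_margin": self.cvf_margin,
            "alpha": self.alpha,
            "count_adjudicated_cvf": self.count_adjudicated_cvf,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _ci_row(label: str, ci: DiffCI, decision=None) -> dict:
    row = {
        "outcome": label,
        "method": ci.method.value,
        "estimate_pp": round_half_away(ci.estimate, 2),
        "lower_pp": round_half_away(ci.lower, 2),
        "upper_pp": round_half_away(ci.upper, 2),
    }
    if decision is not None:
        row["margin_pp"] = decision.margin
        row["bound_used"] = decision.bound_used.value
        row["noninferior"] = decision.met
    return row


def _arm_counts(table: pd.DataFrame, column: str) -> TwoByTwo:
    la = table[table["arm"] == Arm.LONG_ACTING.value].iloc[0]
    orl = table[table["arm"] == Arm.ORAL.value].iloc[0]
    return TwoByTwo(int(la[column]), int(la["n"]), int(orl[column]), int(orl["n"]))


def _stratified_counts(per: pd.DataFrame, predicate: pd.Series) -> list[StratumCounts]:
    out = []
    for stratum in (Stratum.INSTI, Stratum.NNRTI):
        sub = per[per["stratum"] == stratum.value]
        if not len(sub):
            continue
        la = sub[sub["arm"] == Arm.LONG_ACTING.value]
        orl = sub[sub["arm"] == Arm.ORAL.value]
        if not len(la) or not len(orl):
            continue
        out.append(StratumCounts(stratum.value, TwoByTwo(
            int(predicate[la.index].sum()), len(la),
            int(predicate[orl.index].sum()), len(orl),
        )))
    return out


def run_pipeline(
    dataset: TrialDataset,
    config: PipelineConfig = PipelineConfig(),
    output_dir: Optional[str | Path] = None,
    seed: Optional[int] = None,
) -> dict[str, pd.DataFrame]:
    """Run every stage and assemble the report bundle."""
    # (a) snapshot outcome and noninferiority statistics
    per = classify_all(dataset, config.snapshot)
    snap = snapshot_table(dataset, config.snapshot)

    stat_rows = []
    suppressed = per["category"] == "suppressed"
    strata = _stratified_counts(per, suppressed)
    t_sup = _arm_counts(snap, "suppressed")
    ci_sup = cmh_mn_ci(strata, config.alpha) if len(strata) > 1 else mn_score_ci(t_sup, config.alpha)
    dec_sup = noninferiority_decision(ci_sup, config.suppression_margin, Bound.LOWER)
    stat_rows.append(_ci_row(f"suppressed_lt{config.snapshot.threshold}", ci_sup, dec_sup))

    t_non = _arm_counts(snap, "nonsuppressed")
    stat_rows.append(_ci_row(f"nonsuppressed_ge{config.snapshot.threshold}",
                             mn_score_ci(t_non, config.alpha)))

    # (b) confirmed virological failure
    cvf = cvf_table(dataset, config.count_adjudicated_cvf)
    t_cvf = _arm_counts(cvf, "failures")
    ci_cvf = mn_score_ci(t_cvf, config.alpha)
    dec_cvf = noninferiority_decision(ci_cvf, config.cvf_margin, Bound.UPPER)
    stat_rows.append(_ci_row("confirmed_virological_failure", ci_cvf, dec_cvf))

    # (c) populations
    flags = derive_populations(dataset, config.snapshot)
    pops = population_summary(flags)

    # (d) adverse-event summary with Wald CIs
    ae = dataset.adverse_events
    arm_n = {a.value: int((dataset.participants["arm"] == a.value).sum())
             for a in (Arm.LONG_ACTING, Arm.ORAL)}
    arm_of = dict(zip(dataset.participants["participant_id"], dataset.participants["arm"]))
    ae_rows = []
    masks = {
        "grade3_or_higher": ae["grade"] >= 3,
        "grade3_or_higher_related": (ae["grade"] >= 3) & ae["related"],
        "serious": ae["serious"],
        "any_grade": ae["grade"] >= 1,
        "led_to_discontinuation": ae["led_to_discontinuation"],
        "injection_site": ae["injection_site"],
    }
    for label, mask in masks.items():
        pids = set(ae[mask]["participant_id"])
        x = {a: sum(1 for p in pids if arm_of[p] == a) for a in arm_n}
        if min(arm_n.values()) == 0:
            continue
        t = TwoByTwo(x["long_acting"], arm_n["long_acting"], x["oral"], arm_n["oral"])
        ci = wald_ci(t, config.alpha)
        ae_rows.append({
            "event": label,
            "long_acting": t.x1, "n_long_acting": t.n1,
            "oral": t.x2, "n_oral": t.n2,
            "diff_pp": round_half_away(ci.estimate, 1),
            "lower_pp": round_half_away(ci.lower, 1),
            "upper_pp": round_half_away(ci.upper, 1),
        })
    ae_summary = pd.DataFrame(ae_rows)

    # (e) resistance prevalence with and without the APOBEC filter
    lists = config.mutation_lists()
    res_rows = []
    if len(dataset.sequences):
        for drug in sorted({d for (_, _, _, d) in lists.ias_drm_list.entries}):
            for arm in (Arm.LONG_ACTING, Arm.ORAL):
                filt_num, den = resistance_prevalence(dataset, lists, drug, True, arm=arm.value)
                raw_num, _ = resistance_prevalence(dataset, lists, drug, False, arm=arm.value)
                if den == 0:
                    continue
                res_rows.append({
                    "drug": drug, "arm": arm.value,
                    "with_filter": filt_num, "without_filter": raw_num,
                    "denominator": den,
                    "prevalence_filtered_pct": round_half_away(100 * filt_num / den, 1),
                    "prevalence_unfiltered_pct": round_half_away(100 * raw_num / den, 1),
                })
    resistance = pd.DataFrame(res_rows)

    bundle = {
        "snapshot_participants": per,
        "snapshot_table": snap,
        "statistics": pd.DataFrame(stat_rows),
        "cvf_table": cvf,
        "cvf_participants": cvf_statuses(dataset),
        "population_flags": flags,
        "population_summary": pops,
        "ae_summary": ae_summary,
        "resistance_summary": resistance,
    }

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in bundle.items():
            df.to_csv(out / f"{name}.csv", index=False)
        lines = [
            f"config digest: {config.digest()}",
            f"seed: {seed if seed is not None else 'n/a (deterministic input)'}",
            f"participants: {len(dataset.participants)}",
            "",
            "snapshot table:", snap.to_string(index=False), "",
            "noninferiority statistics (percentage points):",
            bundle["statistics"].to_string(index=False), "",
            "populations:", pops.to_string(index=False),
        ]
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
        (out / "run.log").write_text(
            f"config digest {config.digest()}\nseed {seed}\n"
            f"stages: snapshot, populations, cvf, resistance, stats\n"
        )
    return bundle
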