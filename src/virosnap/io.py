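"""Reading and writing the participant-level trial dataset.

The on-disk form is a directory of comma-separated UTF-8 tables with header
rows (``participants.csv``, ``viral_loads.csv``, ``doses.csv``,
``regimen_changes.csv``, ``adverse_events.csv`` plus the optional
``mutation_calls.csv``, ``adjudications.csv`` and ``window_extensions.csv``)
and a FASTA file ``sequences.fasta`` whose record ids are
``participant_id|timepoint|gene``.  Reading is strict: a missing column is a
:class:`SchemaError` naming the column, and a row referencing an unknown
participant is an :class:`IntegrityError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    AdverseEvent,
    Arm,
    ChangeReason,
    DoseEvent,
    DoseKind,
    Gene,
    ParticipantRecord,
    RegimenChange,
    SequenceRecord,
    Sex,
    Stratum,
    Timepoint,
    VLMeasurement,
)


class SchemaError(ValueError):
    """A table does not match the documented schema."""


class IntegrityError(ValueError):
    """A row references a participant that does not exist."""


_SCHEMAS: dict[str, list[str]] = {
    "participants": [
        "participant_id", "arm", "stratum", "randomization_day",
        "withdrawal_day", "death_day", "oral_lead_in", "sex", "baseline_bmi",
    ],
    "viral_loads": [
        "participant_id", "study_day", "nominal_week", "copies_per_ml", "below_lloq",
    ],
    "doses": [
        "participant_id", "kind", "target_day", "actual_day",
        "missed_oral_days", "bridge_start_day", "bridge_end_day",
    ],
    "regimen_changes": [
        "participant_id", "start_day", "end_day", "within_class",
        "reason", "to_long_acting_oral_forms",
    ],
    "adverse_events": [
        "participant_id", "onset_day", "grade", "serious", "related",
        "injection_site", "led_to_discontinuation",
    ],
    "mutation_calls": ["participant_id", "timepoint", "gene", "call"],
    "adjudications": ["participant_id", "study_day", "note"],
    "window_extensions": ["participant_id", "extended_end_week"],
    "sequences": ["participant_id", "timepoint", "gene", "residues"],
}

_INT_COLS = {
    "randomization_day", "study_day", "nominal_week", "copies_per_ml",
    "target_day", "start_day", "onset_day", "grade", "missed_oral_days",
    "extended_end_week",
}
_OPT_INT_COLS = {
    "withdrawal_day", "death_day", "actual_day", "bridge_start_day",
    "bridge_end_day", "end_day",
}
_BOOL_COLS = {
    "oral_lead_in", "below_lloq", "within_class", "to_long_acting_oral_forms",
    "serious", "related", "injection_site", "led_to_discontinuation",
}
_FLOAT_COLS = {"baseline_bmi"}

# keys used to reject duplicate rows deterministically
_UNIQUE_KEYS = {
    "participants": ["participant_id"],
    "viral_loads": ["participant_id", "study_day"],
    "doses": ["participant_id", "target_day", "kind"],
    "window_extensions": ["participant_id"],
}


def _empty(table: str) -> pd.DataFrame:
    return _coerce(pd.DataFrame(columns=_SCHEMAS[table]), table)


def _coerce(df: pd.DataFrame, table: str) -> pd.DataFrame:
    df = df.copy()
    for col in _SCHEMAS[table]:
        if col not in df.columns:
            raise SchemaError(f"{table}: missing column '{col}'")
        if col in _INT_COLS:
            df[col] = pd.to_numeric(df[col]).astype("int64") if len(df) else df[col].astype("int64")
        elif col in _OPT_INT_COLS:
            df[col] = pd.to_numeric(df[col]).astype("Int64") if len(df) else df[col].astype("Int64")
        elif col in _BOOL_COLS:
            if len(df):
                df[col] = df[col].map(
                    {True: True, False: False, "True": True, "False": False,
                     "true": True, "false": False, 1: True, 0: False, "1": True, "0": False}
                )
                if df[col].isna().any():
                    raise SchemaError(f"{table}: non-boolean value in column '{col}'")
            df[col] = df[col].astype(bool) if len(df) else df[col].astype(bool)
        elif col in _FLOAT_COLS:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("float64")
        else:
            df[col] = df[col].astype(str) if len(df) else df[col].astype(str)
    key = _UNIQUE_KEYS.get(table)
    if key and len(df) and df.duplicated(subset=key).any():
        dup = df[df.duplicated(subset=key)].iloc[0]
        raise SchemaError(f"{table}: duplicate row for key {tuple(dup[k] for k in key)}")
    return df[_SCHEMAS[table]]


@dataclass
class TrialDataset:
    """All trial tables, keyed by ``participant_id``."""

    participants: pd.DataFrame
    viral_loads: pd.DataFrame = field(default_factory=lambda: _empty("viral_loads"))
    doses: pd.DataFrame = field(default_factory=lambda: _empty("doses"))
    regimen_changes: pd.DataFrame = field(default_factory=lambda: _empty("regimen_changes"))
    adverse_events: pd.DataFrame = field(default_factory=lambda: _empty("adverse_events"))
    sequences: pd.DataFrame = field(default_factory=lambda: _empty("sequences"))
    mutation_calls: pd.DataFrame = field(default_factory=lambda: _empty("mutation_calls"))
    adjudications: pd.DataFrame = field(default_factory=lambda: _empty("adjudications"))
    window_extensions: pd.DataFrame = field(default_factory=lambda: _empty("window_extensions"))

    def __post_init__(self) -> None:
        self.participants = _coerce(self.participants, "participants")
        self.viral_loads = _coerce(self.viral_loads, "viral_loads")
        self.doses = _coerce(self.doses, "doses")
        self.regimen_changes = _coerce(self.regimen_changes, "regimen_changes")
        self.adverse_events = _coerce(self.adverse_events, "adverse_events")
        self.sequences = _coerce(self.sequences, "sequences")
        self.mutation_calls = _coerce(self.mutation_calls, "mutation_calls")
        self.adjudications = _coerce(self.adjudications, "adjudications")
        self.window_extensions = _coerce(self.window_extensions, "window_extensions")
        known = set(self.participants["participant_id"])
        for name in ("viral_loads", "doses", "regimen_changes", "adverse_events",
                     "sequences", "mutation_calls", "adjudications", "window_extensions"):
            tbl = getattr(self, name)
            orphans = set(tbl["participant_id"]) - known
            if orphans:
                raise IntegrityError(
                    f"{name}: unknown participant_id(s) {sorted(orphans)[:5]}"
                )

    # ---- typed accessors -------------------------------------------------

    def participant_ids(self, arm: Optional[Arm] = None) -> list[str]:
        df = self.participants
        if arm is not None:
            df = df[df["arm"] == arm.value]
        return list(df["participant_id"])

    def participant(self, pid: str) -> ParticipantRecord:
        row = self.participants.set_index("participant_id").loc[pid]
        return ParticipantRecord(
            participant_id=pid,
            arm=Arm(row["arm"]),
            stratum=Stratum(row["stratum"]),
            randomization_day=int(row["randomization_day"]),
            withdrawal_day=None if pd.isna(row["withdrawal_day"]) else int(row["withdrawal_day"]),
            death_day=None if pd.isna(row["death_day"]) else int(row["death_day"]),
            oral_lead_in=bool(row["oral_lead_in"]),
            sex=Sex(row["sex"]),
            baseline_bmi=None if pd.isna(row["baseline_bmi"]) else float(row["baseline_bmi"]),
        )

    def vls_for(self, pid: str) -> list[VLMeasurement]:
        df = self.viral_loads
        rows = df[df["participant_id"] == pid].sort_values("study_day")
        return [
            VLMeasurement(pid, int(r.study_day), int(r.nominal_week),
                          int(r.copies_per_ml), bool(r.below_lloq))
            for r in rows.itertuples()
        ]

    def doses_for(self, pid: str) -> list[DoseEvent]:
        df = self.doses
        rows = df[df["participant_id"] == pid].sort_values("target_day")
        out = []
        for r in rows.itertuples():
            out.append(DoseEvent(
                pid, DoseKind(r.kind), int(r.target_day),
                None if pd.isna(r.actual_day) else int(r.actual_day),
                int(r.missed_oral_days),
                None if pd.isna(r.bridge_start_day) else int(r.bridge_start_day),
                None if pd.isna(r.bridge_end_day) else int(r.bridge_end_day),
            ))
        return out

    def changes_for(self, pid: str) -> list[RegimenChange]:
        df = self.regimen_changes
        rows = df[df["participant_id"] == pid].sort_values("start_day")
        return [
            RegimenChange(
                pid, int(r.start_day),
                None if pd.isna(r.end_day) else int(r.end_day),
                bool(r.within_class), ChangeReason(r.reason),
                bool(r.to_long_acting_oral_forms),
            )
            for r in rows.itertuples()
        ]

    def sequences_for(self, pid: str, timepoint: Optional[Timepoint] = None) -> list[SequenceRecord]:
        df = self.sequences
        rows = df[df["participant_id"] == pid]
        if timepoint is not None:
            rows = rows[rows["timepoint"] == timepoint.value]
        return [
            SequenceRecord(pid, Timepoint(r.timepoint), Gene(r.gene), str(r.residues))
            for r in rows.itertuples()
        ]

    # bulk variants of the accessors above: one pass over each table instead
    # of one filter per participant

    def vls_by_participant(self) -> dict[str, list[VLMeasurement]]:
        out: dict[str, list[VLMeasurement]] = {pid: [] for pid in self.participants["participant_id"]}
        for r in self.viral_loads.sort_values("study_day").itertuples():
            out[r.participant_id].append(VLMeasurement(
                r.participant_id, int(r.study_day), int(r.nominal_week),
                int(r.copies_per_ml), bool(r.below_lloq)))
        return out

    def doses_by_participant(self) -> dict[str, list[DoseEvent]]:
        out: dict[str, list[DoseEvent]] = {pid: [] for pid in self.participants["participant_id"]}
        for r in self.doses.sort_values("target_day").itertuples():
            out[r.participant_id].append(DoseEvent(
                r.participant_id, DoseKind(r.kind), int(r.target_day),
                None if pd.isna(r.actual_day) else int(r.actual_day),
                int(r.missed_oral_days),
                None if pd.isna(r.bridge_start_day) else int(r.bridge_start_day),
                None if pd.isna(r.bridge_end_day) else int(r.bridge_end_day)))
        return out

    def changes_by_participant(self) -> dict[str, list[RegimenChange]]:
        out: dict[str, list[RegimenChange]] = {pid: [] for pid in self.participants["participant_id"]}
        for r in self.regimen_changes.sort_values("start_day").itertuples():
            out[r.participant_id].append(RegimenChange(
                r.participant_id, int(r.start_day),
                None if pd.isna(r.end_day) else int(r.end_day),
                bool(r.within_class), ChangeReason(r.reason),
                bool(r.to_long_acting_oral_forms)))
        return out

    def participant_records(self) -> list[ParticipantRecord]:
        out = []
        for r in self.participants.itertuples():
            out.append(ParticipantRecord(
                r.participant_id, Arm(r.arm), Stratum(r.stratum),
                int(r.randomization_day),
                None if pd.isna(r.withdrawal_day) else int(r.withdrawal_day),
                None if pd.isna(r.death_day) else int(r.death_day),
                bool(r.oral_lead_in), Sex(r.sex),
                None if pd.isna(r.baseline_bmi) else float(r.baseline_bmi)))
        return out

    def extension_map(self) -> dict[str, int]:
        """participant_id -> extended window end week."""
        return dict(zip(self.window_extensions["participant_id"],
                        self.window_extensions["extended_end_week"].astype(int)))

    def equals(self, other: "TrialDataset") -> bool:
        for name in _TABLE_FILES:
            a = getattr(self, name).reset_index(drop=True)
            b = getattr(other, name).reset_index(drop=True)
            if not a.equals(b):
                return False
        return True


_TABLE_FILES = [
    "participants", "viral_loads", "doses", "regimen_changes",
    "adverse_events", "mutation_calls", "adjudications", "window_extensions",
]


def write_trial_dataset(dataset: TrialDataset, directory: str | Path) -> list[Path]:
    """Write all tables (and sequences as FASTA) under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in _TABLE_FILES:
        path = directory / f"{name}.csv"
        getattr(dataset, name).to_csv(path, index=False)
        written.append(path)
    seqs = dataset.sequences
    # metadata travels in the FASTA ids; only write the file when records exist
    fasta = directory / "sequences.fasta"
    records = [
        SeqRecord(Seq(str(r.residues)),
                  id=f"{r.participant_id}|{r.timepoint}|{r.gene}", description="")
        for r in seqs.itertuples()
    ]
    if records:
        SeqIO.write(records, fasta, "fasta")
        written.append(fasta)
    return written


def read_trial_dataset(directory: str | Path) -> TrialDataset:
    """Read a dataset directory written by :func:`write_trial_dataset`."""
    directory = Path(directory)
    tables: dict[str, pd.DataFrame] = {}
    for name in _TABLE_FILES:
        path = directory / f"{name}.csv"
        if not path.exists():
            if name == "participants":
                raise FileNotFoundError(path)
            tables[name] = _empty(name)
            continue
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        raw = raw.replace({"": None})
        tables[name] = _coerce(raw, name) if len(raw) else _empty(name)
    fasta = directory / "sequences.fasta"
    seq_rows = []
    if fasta.exists():
        for rec in SeqIO.parse(str(fasta), "fasta"):
            pid, timepoint, gene = rec.id.split("|")
            seq_rows.append(
                {"participant_id": pid, "timepoint": timepoint,
                 "gene": gene, "residues": str(rec.seq)}
            )
    sequences = pd.DataFrame(seq_rows, columns=_SCHEMAS["sequences"]) if seq_rows else _empty("sequences")
    return TrialDataset(sequences=sequences, **tables)


def dataset_from_records(
    participants: Iterable[ParticipantRecord],
    vls: Iterable[VLMeasurement] = (),
    doses: Iterable[DoseEvent] = (),
    changes: Iterable[RegimenChange] = (),
    aes: Iterable[AdverseEvent] = (),
    sequences: Iterable[SequenceRecord] = (),
    mutation_calls: Iterable[tuple[str, str, str, str]] = (),
    adjudications: Iterable[tuple[str, int, str]] = (),
    window_extensions: Iterable[tuple[str, int]] = (),
) -> TrialDataset:
    """Assemble a :class:`TrialDataset` from typed records."""

    def opt(v):
        return pd.NA if v is None else v

    p_rows = [
        {
            "participant_id": p.participant_id, "arm": p.arm.value,
            "stratum": p.stratum.value, "randomization_day": p.randomization_day,
            "withdrawal_day": opt(p.withdrawal_day), "death_day": opt(p.death_day),
            "oral_lead_in": p.oral_lead_in, "sex": p.sex.value,
            "baseline_bmi": float("nan") if p.baseline_bmi is None else p.baseline_bmi,
        }
        for p in participants
    ]
    vl_rows = [
        {"participant_id": v.participant_id, "study_day": v.study_day,
         "nominal_week": v.nominal_week, "copies_per_ml": v.copies_per_ml,
         "below_lloq": v.below_lloq}
        for v in vls
    ]
    dose_rows = [
        {"participant_id": d.participant_id, "kind": d.kind.value,
         "target_day": d.target_day, "actual_day": opt(d.actual_day),
         "missed_oral_days": d.missed_oral_days,
         "bridge_start_day": opt(d.bridge_start_day),
         "bridge_end_day": opt(d.bridge_end_day)}
        for d in doses
    ]
    change_rows = [
        {"participant_id": c.participant_id, "start_day": c.start_day,
         "end_day": opt(c.end_day), "within_class": c.within_class,
         "reason": c.reason.value,
         "to_long_acting_oral_forms": c.to_long_acting_oral_forms}
        for c in changes
    ]
    ae_rows = [
        {"participant_id": a.participant_id, "onset_day": a.onset_day,
         "grade": a.grade, "serious": a.serious, "related": a.related,
         "injection_site": a.injection_site,
         "led_to_discontinuation": a.led_to_discontinuation}
        for a in aes
    ]
    seq_rows = [
        {"participant_id": s.participant_id, "timepoint": s.timepoint.value,
         "gene": s.gene.value, "residues": s.residues}
        for s in sequences
    ]
    call_rows = [
        {"participant_id": pid, "timepoint": tp, "gene": gene, "call": call}
        for pid, tp, gene, call in mutation_calls
    ]
    adj_rows = [
        {"participant_id": pid, "study_day": day, "note": note}
        for pid, day, note in adjudications
    ]
    ext_rows = [
        {"participant_id": pid, "extended_end_week": wk}
        for pid, wk in window_extensions
    ]

    def frame(rows, table):
        return pd.DataFrame(rows, columns=_SCHEMAS[table]) if rows else _empty(table)

    return TrialDataset(
        participants=frame(p_rows, "participants"),
        viral_loads=frame(vl_rows, "viral_loads"),
        doses=frame(dose_rows, "doses"),
        regimen_changes=frame(change_rows, "regimen_changes"),
        adverse_events=frame(ae_rows, "adverse_events"),
        sequences=frame(seq_rows, "sequences"),
        mutation_calls=frame(call_rows, "mutation_calls"),
        adjudications=frame(adj_rows, "adjudications"),
        window_extensions=frame(ext_rows, "window_extensions"),
    )
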