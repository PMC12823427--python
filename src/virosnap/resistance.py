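"""Drug-resistance mutation (DRM) parsing and APOBEC-context filtering.

Host APOBEC3 enzymes hypermutate proviral DNA (G-to-A editing), which can
create amino-acid changes that look like drug-resistance mutations but sit on
defective, non-replicating genomes.  A curated set of 14 such APOBEC-context
DRMs in reverse transcriptase (RT) and integrase (IN) is therefore disregarded
whenever the carrying sequence shows evidence of APOBEC activity - at least
one signature APOBEC mutation, or at least one stop codon.  All other listed
DRMs are retained regardless of APOBEC evidence.

The signature-mutation reference lists (154 RT / 95 IN positions in the public
Stanford resistance database) are user-supplied data files; the file shipped
with the package (``data/apobec_signatures_synthetic.csv``) is a synthetic
stand-in used by the simulator and tests, so the filtering algorithm is
correct independently of any particular transcription of the reference lists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io import TrialDataset
from .types import AA_LETTERS, STOP, Gene, SequenceRecord, Timepoint

#: the 14 APOBEC-context DRMs in RT/IN (gene, position, mutant amino acid)
APOBEC_CONTEXT_DRMS: frozenset[tuple[str, int, str]] = frozenset({
    ("RT", 67, "N"), ("RT", 138, "K"), ("RT", 184, "I"),
    ("RT", 190, "E"), ("RT", 190, "S"), ("RT", 230, "I"),
    ("IN", 118, "R"), ("IN", 138, "K"), ("IN", 140, "R"),
    ("IN", 140, "S"), ("IN", 163, "K"), ("IN", 163, "R"),
    ("IN", 232, "N"), ("IN", 263, "K"),
})

DEFAULT_GENE_LENGTHS = {Gene.RT: 300, Gene.IN: 288}


class MutationParseError(ValueError):
    def __init__(self, text: str, offset: int, message: str):
        super().__init__(f"{message} in {text!r} at offset {offset}")
        self.offset = offset


@dataclass(frozen=True)
class MutationCall:
    gene: Gene
    position: int
    reference_aa: Optional[str]
    observed_aas: frozenset[str]
    drug_classes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if not self.observed_aas:
            raise ValueError("observed_aas must be non-empty")

    def key(self) -> tuple[str, int, frozenset[str]]:
        return (self.gene.value, self.position, self.observed_aas)


_CALL_RE = re.compile(r"^([A-Z])?(\d+)([A-Z*](?:/[A-Z*])*)$")


def parse_mutation(text: str, gene: Gene,
                   drm_list: Optional["DrmList"] = None) -> MutationCall:
    """Parse mutation-call notation like ``K103N/S`` or ``M230M/L``.

    The grammar is an optional reference residue, a 1-based position, and one
    or more observed residues separated by ``/``.  A reference residue
    repeated inside the mixture (``M230M/L``) is dropped from the mutant set.
    """
    token = text.strip()
    m = _CALL_RE.match(token)
    if m is None:
        offset = 0
        for i, c in enumerate(token):
            if not (c.isalnum() or c in "/*"):
                offset = i
                break
        raise MutationParseError(text, offset, "malformed mutation call")
    ref, pos_s, obs_s = m.groups()
    position = int(pos_s)
    observed = set(obs_s.split("/"))
    for aa in observed:
        if aa not in AA_LETTERS and aa != STOP:
            raise MutationParseError(text, token.index(aa), f"invalid residue {aa!r}")
    if ref is not None:
        observed.discard(ref)
    if not observed:
        raise MutationParseError(text, 0, "call lists only the reference residue")
    drugs: frozenset[str] = frozenset()
    if drm_list is not None:
        drugs = frozenset(
            drug
            for aa in observed
            for drug in drm_list.drugs_for(gene, position, aa)
        )
    return MutationCall(gene, position, ref, frozenset(observed), drugs)


@dataclass(frozen=True)
class DrmList:
    """A curated (gene, position, mutant, drug) resistance-mutation list."""

    entries: frozenset[tuple[str, int, str, str]]

    def drugs_for(self, gene: Gene, position: int, aa: str) -> set[str]:
        return {d for g, p, a, d in self.entries
                if g == gene.value and p == position and a == aa}

    def mutants(self, drug: Optional[str] = None) -> set[tuple[str, int, str]]:
        return {(g, p, a) for g, p, a, d in self.entries
                if drug is None or d == drug}


@dataclass(frozen=True)
class MutationLists:
    """All reference data the filter needs."""

    ias_drm_list: DrmList
    apobec_context_drms: frozenset[tuple[str, int, str]] = APOBEC_CONTEXT_DRMS
    apobec_signatures_rt: frozenset[tuple[int, str]] = frozenset()
    apobec_signatures_in: frozenset[tuple[int, str]] = frozenset()
    stop_codon_symbol: str = STOP

    def signatures(self, gene: Gene) -> frozenset[tuple[int, str]]:
        return self.apobec_signatures_rt if gene is Gene.RT else self.apobec_signatures_in


@dataclass(frozen=True)
class FilterResult:
    retained: tuple[MutationCall, ...]
    disregarded: tuple[MutationCall, ...]
    apobec_evidence: bool
    evidence_kind: str  # signature_mutation | stop_codon | none

    def __post_init__(self) -> None:
        if self.disregarded and not self.apobec_evidence:
            raise ValueError("calls can only be disregarded with APOBEC evidence")


def has_apobec_evidence(seq: SequenceRecord, lists: MutationLists) -> tuple[bool, str]:
    """Evidence of APOBEC activity on an aligned sequence.

    Signature mutations take precedence over stop codons in the reported
    evidence kind; either alone is sufficient evidence.
    """
    positions = seq.positions()
    sigs = lists.signatures(seq.gene)
    for pos, aa in sigs:
        if pos <= len(positions) and aa in positions[pos - 1]:
            return True, "signature_mutation"
    for residues in positions:
        if lists.stop_codon_symbol in residues:
            return True, "stop_codon"
    return False, "none"


def filter_drms(
    calls: Sequence[MutationCall],
    seq: Optional[SequenceRecord],
    lists: MutationLists,
) -> FilterResult:
    """Disregard APOBEC-context DRMs on sequences with APOBEC evidence.

    A call is disregarded iff any of its observed mutants at its (gene,
    position) is in the APOBEC-context set *and* the sequence shows evidence
    of APOBEC activity; every other call is retained.
    """
    evidence, kind = (False, "none") if seq is None else has_apobec_evidence(seq, lists)
    retained, disregarded = [], []
    for call in calls:
        in_context = any(
            (call.gene.value, call.position, aa) in lists.apobec_context_drms
            for aa in call.observed_aas
        )
        if in_context and evidence:
            disregarded.append(call)
        else:
            retained.append(call)
    return FilterResult(tuple(retained), tuple(disregarded), evidence, kind)


def load_drm_list(path: str | Path) -> DrmList:
    df = pd.read_csv(path)
    entries = frozenset(
        (str(r.gene), int(r.position), str(r.mutant), str(r.drug))
        for r in df.itertuples()
    )
    return DrmList(entries)


def load_signatures(path: str | Path) -> tuple[frozenset, frozenset]:
    df = pd.read_csv(path)
    rt = frozenset((int(r.position), str(r.mutant))
                   for r in df.itertuples() if r.gene == "RT")
    in_ = frozenset((int(r.position), str(r.mutant))
                    for r in df.itertuples() if r.gene == "IN")
    return rt, in_


def default_mutation_lists() -> MutationLists:
    """Lists built from the packaged data files.

    The DRM list is a working subset of the public curated lists covering the
    mutations this analysis encounters; the signature list is synthetic (see
    module docstring) and should be replaced with the full reference lists for
    production use.
    """
    data = resources.files("virosnap") / "data"
    drm = load_drm_list(str(data / "drm_list.csv"))
    rt, in_ = load_signatures(str(data / "apobec_signatures_synthetic.csv"))
    return MutationLists(ias_drm_list=drm, apobec_signatures_rt=rt,
                         apobec_signatures_in=in_)


def participant_filter_results(
    dataset: TrialDataset,
    lists: MutationLists,
    timepoint: Timepoint = Timepoint.BASELINE,
) -> pd.DataFrame:
    """Apply the APOBEC filter to every (participant, gene) with calls or a
    sequence; one row per mutation call plus sequence-level evidence."""
    calls_df = dataset.mutation_calls
    calls_df = calls_df[calls_df["timepoint"] == timepoint.value]
    rows = []
    seq_index = {
        (r.participant_id, r.gene): SequenceRecord(
            r.participant_id, Timepoint(r.timepoint), Gene(r.gene), r.residues
        )
        for r in dataset.sequences.itertuples()
        if r.timepoint == timepoint.value
    }
    for (pid, gene_s), group in calls_df.groupby(["participant_id", "gene"], sort=True):
        gene = Gene(gene_s)
        calls = [parse_mutation(c, gene, lists.ias_drm_list) for c in group["call"]]
        seq = seq_index.get((pid, gene_s))
        res = filter_drms(calls, seq, lists)
        for call, status in [(c, "retained") for c in res.retained] + [
            (c, "disregarded") for c in res.disregarded
        ]:
            rows.append({
                "participant_id": pid,
                "gene": gene_s,
                "call": f"{call.reference_aa or ''}{call.position}"
                        f"{'/'.join(sorted(call.observed_aas))}",
                "drugs": ";".join(sorted(call.drug_classes)),
                "status": status,
                "apobec_evidence": res.apobec_evidence,
                "evidence_kind": res.evidence_kind,
            })
    return pd.DataFrame(
        rows, columns=["participant_id", "gene", "call", "drugs", "status",
                       "apobec_evidence", "evidence_kind"]
    )


def resistance_prevalence(
    dataset: TrialDataset,
    lists: MutationLists,
    drug: str,
    apply_filter: bool = True,
    gene: Optional[Gene] = None,
    arm: Optional[str] = None,
    timepoint: Timepoint = Timepoint.BASELINE,
) -> tuple[int, int]:
    """(numerator, denominator) for baseline resistance prevalence.

    Denominator: participants with a sequence for the drug's gene at the
    timepoint; numerator: those carrying at least one retained DRM for the
    drug (or at least one DRM at all when ``apply_filter`` is off).
    """
    if gene is None:
        genes = {g for (g, p, a) in lists.ias_drm_list.mutants(drug)}
        if len(genes) != 1:
            raise ValueError(f"ambiguous gene for drug {drug!r}; pass gene=")
        gene = Gene(genes.pop())
    seqs = dataset.sequences
    seqs = seqs[(seqs["timepoint"] == timepoint.value) & (seqs["gene"] == gene.value)]
    pids = set(seqs["participant_id"])
    if arm is not None:
        arm_pids = set(
            dataset.participants[dataset.participants["arm"] == arm]["participant_id"]
        )
        pids &= arm_pids
    denominator = len(pids)

    table = participant_filter_results(dataset, lists, timepoint)
    table = table[table["gene"] == gene.value]
    if apply_filter:
        table = table[table["status"] == "retained"]
    has_drm = {
        r.participant_id
        for r in table.itertuples()
        if drug in r.drugs.split(";") and r.participant_id in pids
    }
    return len(has_drm), denominator
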