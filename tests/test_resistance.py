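"""Mutation parsing and APOBEC-context DRM filtering."""

import numpy as np
import pytest

from virosnap.resistance import (
    APOBEC_CONTEXT_DRMS,
    FilterResult,
    MutationCall,
    MutationLists,
    MutationParseError,
    filter_drms,
    has_apobec_evidence,
    parse_mutation,
    resistance_prevalence,
)
from virosnap.types import Gene, SequenceRecord, Timepoint


def _seq(residues, gene=Gene.RT, pid="X1"):
    return SequenceRecord(pid, Timepoint.BASELINE, gene, residues)


def _lists(rt_sigs=(), in_sigs=()):
    from virosnap.resistance import DrmList
    return MutationLists(
        ias_drm_list=DrmList(frozenset()),
        apobec_signatures_rt=frozenset(rt_sigs),
        apobec_signatures_in=frozenset(in_sigs),
    )


class TestParseMutation:
    def test_mixture_keeps_both_mutants(self):
        call = parse_mutation("K103N/S", Gene.RT)
        assert call.position == 103
        assert call.observed_aas == frozenset("NS")
        assert call.reference_aa == "K"

    def test_reference_repeated_in_mixture_is_dropped(self):
        call = parse_mutation("M230M/L", Gene.RT)
        assert call.observed_aas == frozenset("L")

    def test_simple_call(self):
        call = parse_mutation("Q148R", Gene.IN)
        assert (call.gene, call.position, call.observed_aas) == (Gene.IN, 148, frozenset("R"))

    def test_call_without_reference(self):
        assert parse_mutation("118R", Gene.IN).reference_aa is None

    @pytest.mark.parametrize("bad", ["K103", "103", "K-103N", "KN", ""])
    def test_malformed_call_raises_with_offset(self, bad):
        with pytest.raises(MutationParseError):
            parse_mutation(bad, Gene.RT)

    def test_reference_only_mixture_rejected(self):
        with pytest.raises(MutationParseError):
            parse_mutation("M230M", Gene.RT)


class TestApobecEvidence:
    def test_stop_codon_is_evidence(self):
        seq = _seq("ACDEF*HIK")
        assert has_apobec_evidence(seq, _lists()) == (True, "stop_codon")

    def test_signature_mutation_is_evidence(self):
        seq = _seq("ACDEFKHIK")
        assert has_apobec_evidence(seq, _lists(rt_sigs=[(6, "K")])) == (True, "signature_mutation")

    def test_signature_matches_inside_mixture(self):
        seq = _seq("ACDEF[GK]HIK")
        assert has_apobec_evidence(seq, _lists(rt_sigs=[(6, "K")]))[0]

    def test_wild_type_has_no_evidence(self):
        seq = _seq("ACDEFGHIK")
        assert has_apobec_evidence(seq, _lists(rt_sigs=[(6, "K")])) == (False, "none")


class TestFilterDrms:
    def test_context_drm_on_evidence_sequence_disregarded(self):
        call = parse_mutation("E138K", Gene.RT)
        seq = _seq("A" * 137 + "K" + "A" * 50 + "*")
        res = filter_drms([call], seq, _lists())
        assert res.disregarded == (call,)
        assert res.apobec_evidence

    def test_integrase_context_drm_disregarded(self):
        call = parse_mutation("G118R", Gene.IN)
        seq = _seq("A" * 117 + "R" + "A" * 50, gene=Gene.IN)
        res = filter_drms([call], seq, _lists(in_sigs=[(30, "N")]))
        assert res.disregarded == ()  # no evidence on this sequence
        seq2 = _seq("A" * 29 + "N" + "A" * 87 + "R", gene=Gene.IN)
        res2 = filter_drms([call], seq2, _lists(in_sigs=[(30, "N")]))
        assert res2.disregarded == (call,)

    def test_non_context_drm_retained_despite_evidence(self):
        call = parse_mutation("K103N", Gene.RT)
        seq = _seq("A" * 102 + "N" + "*" * 1)
        res = filter_drms([call], seq, _lists())
        assert res.retained == (call,)
        assert res.apobec_evidence

    def test_context_drm_without_evidence_retained(self):
        call = parse_mutation("E138K", Gene.RT)
        seq = _seq("A" * 137 + "K")
        res = filter_drms([call], seq, _lists())
        assert res.retained == (call,)
        assert not res.apobec_evidence

    def test_partition_and_idempotence(self):
        calls = [parse_mutation(c, Gene.RT) for c in ("E138K", "K103N", "M184M/I")]
        seq = _seq("A" * 200 + "*")
        res = filter_drms(calls, seq, _lists())
        assert set(res.retained) | set(res.disregarded) == set(calls)
        assert not set(res.retained) & set(res.disregarded)
        again = filter_drms(list(res.retained), seq, _lists())
        assert set(again.retained) == set(res.retained)

    def test_matches_brute_force_oracle(self):
        """Randomized cross-check against a direct set-comprehension oracle."""
        rng = np.random.default_rng(3)
        n_mismatch = 0
        for _ in range(300):
            calls, seq, lists = random_filter_instance(rng)
            res = filter_drms(calls, seq, lists)
            retained, disregarded, evidence = brute_force_filter(calls, seq, lists)
            n_mismatch += (set(res.retained) != retained
                           or set(res.disregarded) != disregarded
                           or res.apobec_evidence != evidence)
        assert n_mismatch == 0


def random_filter_instance(rng):
    """A small random (calls, sequence, lists) triple for oracle checks."""
    length = 30
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    residues = [letters[i] for i in rng.integers(0, 20, size=length)]
    if rng.random() < 0.3:
        residues[int(rng.integers(0, length))] = "*"
    sigs = {(int(rng.integers(1, length + 1)), letters[int(rng.integers(0, 20))])
            for _ in range(3)}
    if rng.random() < 0.5:  # sometimes plant a signature match
        pos, aa = next(iter(sigs))
        residues[pos - 1] = aa
    seq = SequenceRecord("R1", Timepoint.BASELINE, Gene.RT, "".join(residues))
    context = {("RT", int(rng.integers(1, length + 1)), letters[int(rng.integers(0, 20))])
               for _ in range(4)}
    calls = []
    for _ in range(int(rng.integers(0, 5))):
        if rng.random() < 0.5 and context:
            g, p, a = next(iter(context))
            calls.append(MutationCall(Gene.RT, p, None, frozenset(a)))
        else:
            calls.append(MutationCall(
                Gene.RT, int(rng.integers(1, length + 1)), None,
                frozenset(letters[int(rng.integers(0, 20))])))
    from virosnap.resistance import DrmList
    lists = MutationLists(ias_drm_list=DrmList(frozenset()),
                          apobec_context_drms=frozenset(context),
                          apobec_signatures_rt=frozenset(sigs))
    return calls, seq, lists


def brute_force_filter(calls, seq, lists):
    """Independent re-statement of the filtering rule as set comprehensions."""
    pos_sets = seq.positions()
    evidence = any(
        p <= len(pos_sets) and aa in pos_sets[p - 1]
        for p, aa in lists.apobec_signatures_rt
    ) or any("*" in s for s in pos_sets)
    disregarded = {
        c for c in calls
        if evidence and any((c.gene.value, c.position, aa) in lists.apobec_context_drms
                            for aa in c.observed_aas)
    }
    return set(calls) - disregarded, disregarded, evidence


class TestPrevalence:
    def test_reference_fixture_rilpivirine_prevalence(self, reference_dataset, mutation_lists):
        num, den = resistance_prevalence(reference_dataset, mutation_lists,
                                         "rilpivirine", True, arm="long_acting")
        assert (num, den) == (14, 208)

    def test_filter_only_reduces_prevalence(self, reference_dataset, mutation_lists):
        for arm in ("long_acting", "oral"):
            for drug in ("rilpivirine", "cabotegravir"):
                filt, den = resistance_prevalence(reference_dataset, mutation_lists,
                                                  drug, True, arm=arm)
                raw, den2 = resistance_prevalence(reference_dataset, mutation_lists,
                                                  drug, False, arm=arm)
                assert den == den2 and filt <= raw

    def test_unfiltered_rilpivirine_doubles_filtered(self, reference_dataset, mutation_lists):
        # 25/208 (12%) unfiltered vs 14/208 (7%) after APOBEC exclusion
        raw, den = resistance_prevalence(reference_dataset, mutation_lists,
                                         "rilpivirine", False, arm="long_acting")
        assert (raw, den) == (25, 208)

    def test_no_calls_means_zero_prevalence(self, mutation_lists):
        from virosnap.io import dataset_from_records
        from virosnap.types import Arm, ParticipantRecord, Stratum
        ds = dataset_from_records(
            [ParticipantRecord("Z1", Arm.ORAL, Stratum.INSTI)],
            sequences=[SequenceRecord("Z1", Timepoint.BASELINE, Gene.RT, "ACDE")],
        )
        assert resistance_prevalence(ds, mutation_lists, "rilpivirine") == (0, 1)
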