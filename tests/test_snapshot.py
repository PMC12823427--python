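"""Modified FDA snapshot classification."""

import pytest

from virosnap.io import dataset_from_records
from virosnap.simulate import make_fixture, threshold200_fixture_spec
from virosnap.snapshot import (
    SnapshotCategory,
    SnapshotConfig,
    SnapshotReason,
    classify_snapshot,
    is_disqualifying_switch,
    snapshot_table,
)
from virosnap.types import (
    Arm,
    ChangeReason,
    ParticipantRecord,
    RegimenChange,
    Stratum,
    VLMeasurement,
    week_to_day,
)


def _p(arm=Arm.LONG_ACTING, **kw):
    return ParticipantRecord("X1", arm, Stratum.INSTI, **kw)


def _vl(day, value=0, lloq=True):
    return VLMeasurement("X1", day, round(day / 7), value, lloq)


class TestDisqualifyingSwitch:
    def test_within_class_change_in_oral_arm_is_not_a_switch(self):
        changes = [RegimenChange("X1", 200, None, within_class=True,
                                 reason=ChangeReason.ADVERSE_EVENT)]
        assert is_disqualifying_switch(changes, Arm.ORAL) == (False, None)

    def test_within_class_change_in_long_acting_arm_is_a_switch(self):
        changes = [RegimenChange("X1", 200, None, within_class=True,
                                 reason=ChangeReason.ADVERSE_EVENT)]
        ok, first = is_disqualifying_switch(changes, Arm.LONG_ACTING)
        assert ok and first is changes[0]

    def test_oral_bridging_with_return_is_not_a_switch(self):
        changes = [RegimenChange("X1", 400, 456, within_class=False,
                                 reason=ChangeReason.OTHER,
                                 to_long_acting_oral_forms=True)]
        assert is_disqualifying_switch(changes, Arm.LONG_ACTING) == (False, None)

    def test_temporary_change_up_to_31_days_is_not_a_switch(self):
        changes = [RegimenChange("X1", 100, 131, reason=ChangeReason.OTHER)]
        assert is_disqualifying_switch(changes, Arm.LONG_ACTING) == (False, None)
        changes = [RegimenChange("X1", 100, 132, reason=ChangeReason.OTHER)]
        assert is_disqualifying_switch(changes, Arm.LONG_ACTING)[0]

    def test_permanent_switch_for_adverse_event_is_a_switch(self):
        changes = [RegimenChange("X1", 350, None,
                                 reason=ChangeReason.ADVERSE_EVENT)]
        assert is_disqualifying_switch(changes, Arm.LONG_ACTING)[0]

    def test_overlapping_open_ended_changes_rejected(self):
        changes = [RegimenChange("X1", 100, None), RegimenChange("X1", 200, None)]
        with pytest.raises(ValueError, match="open-ended"):
            is_disqualifying_switch(changes, Arm.LONG_ACTING)


class TestClassify:
    def test_failure_switch_overrides_suppressed_vl(self):
        changes = [RegimenChange("X1", week_to_day(60), None,
                                 reason=ChangeReason.VIROLOGICAL_FAILURE)]
        res = classify_snapshot(_p(), [_vl(672, 30, False)], changes)
        assert res.category is SnapshotCategory.NONSUPPRESSED
        assert res.reason is SnapshotReason.ASSIGNED_FAILURE_SWITCH

    def test_withdrawal_without_window_vl_is_no_data(self):
        res = classify_snapshot(_p(withdrawal_day=540), [_vl(504)], [])
        assert res.category is SnapshotCategory.NO_DATA
        assert res.reason is SnapshotReason.WITHDRAWAL
        assert res.vl_used is None

    def test_death_takes_precedence_over_withdrawal(self):
        res = classify_snapshot(_p(withdrawal_day=540, death_day=545), [], [])
        assert res.reason is SnapshotReason.DEATH

    def test_single_censored_vl_at_nominal_day_is_suppressed(self):
        res = classify_snapshot(_p(), [_vl(672)], [])
        assert res.category is SnapshotCategory.SUPPRESSED
        assert res.reason is SnapshotReason.OBSERVED_VL

    def test_window_extension_admits_late_measurement(self):
        cfg = SnapshotConfig(window_extensions={"X1": 109})
        late = _vl(week_to_day(105))
        assert classify_snapshot(_p(), [late], [], cfg).category is SnapshotCategory.SUPPRESSED
        # without the extension the same measurement is outside the window
        res = classify_snapshot(_p(), [late], [])
        assert res.category is SnapshotCategory.NO_DATA
        assert res.reason is SnapshotReason.MISSING_IN_WINDOW

    def test_vl_selection_prefers_closest_then_later(self):
        vls = [_vl(660, 500, False), _vl(684, 30, False)]  # both 12 days away
        res = classify_snapshot(_p(), vls, [])
        assert res.vl_used.study_day == 684
        vls = [_vl(671, 500, False), _vl(700, 30, False)]
        assert classify_snapshot(_p(), vls, []).vl_used.study_day == 671

    def test_non_failure_switch_classified_from_window_vl(self):
        changes = [RegimenChange("X1", 350, None,
                                 reason=ChangeReason.ADVERSE_EVENT)]
        res = classify_snapshot(_p(), [_vl(672)], changes)
        assert res.category is SnapshotCategory.SUPPRESSED


class TestSnapshotTable:
    def test_reference_fixture_counts(self, reference_dataset):
        table = snapshot_table(reference_dataset).set_index("arm")
        assert tuple(table.loc["long_acting"][["suppressed", "nonsuppressed", "no_data"]]) == (247, 4, 4)
        assert tuple(table.loc["oral"][["suppressed", "nonsuppressed", "no_data"]]) == (250, 2, 5)

    def test_threshold_200_variant_counts(self):
        ds = make_fixture(threshold200_fixture_spec())
        table = snapshot_table(ds, SnapshotConfig(threshold=200)).set_index("arm")
        assert table.loc["long_acting", "suppressed"] == 249
        assert table.loc["oral", "suppressed"] == 251
        # the <50 marginals of the variant are unchanged
        t50 = snapshot_table(ds).set_index("arm")
        assert t50.loc["long_acting", "suppressed"] == 247

    def test_empty_dataset(self):
        ds = dataset_from_records([])
        table = snapshot_table(ds)
        assert table[["suppressed", "nonsuppressed", "no_data"]].to_numpy().sum() == 0

    @pytest.mark.parametrize("threshold", [50, 200])
    def test_partition_sums_to_n(self, reference_dataset, small_simulated_dataset, threshold):
        for ds in (reference_dataset, small_simulated_dataset):
            table = snapshot_table(ds, SnapshotConfig(threshold=threshold))
            assert (table["suppressed"] + table["nonsuppressed"] + table["no_data"]).equals(table["n"])

    def test_threshold_monotonicity(self, reference_dataset, small_simulated_dataset):
        for ds in (reference_dataset, small_simulated_dataset):
            s50 = snapshot_table(ds, SnapshotConfig(threshold=50))["suppressed"]
            s200 = snapshot_table(ds, SnapshotConfig(threshold=200))["suppressed"]
            assert (s200 >= s50).all()

    def test_idempotent(self, reference_dataset):
        a = snapshot_table(reference_dataset)
        b = snapshot_table(reference_dataset)
        assert a.equals(b)
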