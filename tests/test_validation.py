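"""Event-sourced correction workflow: flags, cascades, merges, replay,
correction accounting, and manual entry."""

from __future__ import annotations

import random
from datetime import datetime

import pytest

from sedaudit._util import ContractViolation, IntegrityError, LogError
from sedaudit.classify import BENZODIAZEPINE, PENDING
from sedaudit.ingest import ResidentProfile
from sedaudit.validation import (
    TransactionLogEntry,
    apply_correction,
    correction_stats,
    flag_suspects,
    log_from_jsonl,
    log_to_jsonl,
    manual_entry_session,
    mark_checked,
    merge_residents,
    propose_duplicates,
    record_correction,
    replay,
    verify_home,
)
from tests.conftest import make_record, make_state

TS = datetime(2016, 3, 2, 9, 0)


def _states_equal(a, b) -> bool:
    """Data equality (residents, medications, checks) ignoring the log."""
    return (
        dict(a.residents) == dict(b.residents)
        and dict(a.medications) == dict(b.medications)
        and a.checked == b.checked
    )


class TestFlagSuspects:
    def test_missing_quantity_and_unparseable_both_flagged(
        self, tiny_bundle, ddd_table
    ):
        rec = make_record(instructions="take as directed", quantity=None)
        state = make_state(tiny_bundle, ddd_table, [rec])
        reasons = {f.reason for f in flag_suspects(state)}
        assert "missing_dose_quantity" in reasons
        assert "unparseable_instructions" in reasons

    def test_dose_exactly_at_threshold_not_flagged(self, tiny_bundle, ddd_table):
        # diazepam 5 mg units, DDD 10 mg: "eight daily" = 40 mg = 4.0 x DDD
        rec = make_record(instructions="eight daily")
        state = make_state(tiny_bundle, ddd_table, [rec])
        assert not any(
            f.reason == "dose_out_of_range" for f in flag_suspects(state)
        )

    def test_dose_above_threshold_flagged(self, tiny_bundle, ddd_table):
        rec = make_record(instructions="nine daily")  # 45 mg = 4.5 x DDD
        state = make_state(tiny_bundle, ddd_table, [rec])
        assert any(f.reason == "dose_out_of_range" for f in flag_suspects(state))

    def test_threshold_configurable(self, tiny_bundle, ddd_table):
        rec = make_record(instructions="three daily")  # 15 mg = 1.5 x DDD
        state = make_state(tiny_bundle, ddd_table, [rec])
        assert any(
            f.reason == "dose_out_of_range"
            for f in flag_suspects(state, r_multiplier=1.0)
        )

    def test_unmapped_record_flagged(self, tiny_bundle, ddd_table):
        rec = make_record(vendor_code="ZZ9")
        state = make_state(tiny_bundle, ddd_table, [rec])
        assert any(
            f.reason == "unmapped_medication" for f in flag_suspects(state)
        )

    def test_valid_record_unflagged(self, tiny_bundle, ddd_table):
        state = make_state(tiny_bundle, ddd_table, [make_record()])
        assert flag_suspects(state) == []

    def test_non_sedative_not_dose_flagged(self, tiny_bundle, ddd_table):
        rec = make_record(
            vendor_code="P1", med_name="Paratab",
            instructions="take as directed", quantity=None,
        )
        state = make_state(tiny_bundle, ddd_table, [rec])
        assert flag_suspects(state) == []


class TestApplyCorrection:
    def test_modify_records_old_and_new(self, tiny_bundle, ddd_table):
        state = make_state(tiny_bundle, ddd_table, [make_record()])
        new = record_correction(
            state,
            phase="P2_offsite", actor_role="project_staff",
            action="modify", entity_kind="medication", entity_id="m1",
            changes=(("instructions", "one nocte", "two nocte"),),
            timestamp=TS,
        )
        assert new.medications["m1"].instructions == "two nocte"
        assert new.medications["m1"].daily_dose_mg == 10.0  # re-enriched
        assert new.log[-1].field_changes == (
            ("instructions", "one nocte", "two nocte"),
        )
        # original state untouched
        assert state.medications["m1"].instructions == "one nocte"

    def test_delete_resident_cascades_to_medications(self, tiny_bundle, ddd_table):
        recs = [make_record(f"m{i}", resident_id="res-a") for i in range(3)]
        state = make_state(tiny_bundle, ddd_table, recs)
        new = record_correction(
            state,
            phase="P3_inhome", actor_role="champion_nurse",
            action="delete", entity_kind="resident", entity_id="res-a",
            timestamp=TS,
        )
        assert "res-a" not in new.residents
        assert new.medications == {}
        cascade = [e for e in new.log if e.derived]
        assert len(cascade) == 3
        assert all(
            e.action == "delete" and e.actor_role == "system" for e in cascade
        )

    def test_add_medication_to_missing_resident_fails(self, tiny_bundle, ddd_table):
        state = make_state(tiny_bundle, ddd_table)
        with pytest.raises(IntegrityError):
            record_correction(
                state,
                phase="P3_inhome", actor_role="champion_nurse",
                action="add", entity_kind="medication", entity_id="new1",
                changes=(
                    ("resident_id", None, "ghost"),
                    ("vendor", None, "medipack"),
                    ("vendor_code", None, "D1"),
                    ("med_name", None, "Calmex"),
                    ("instructions", None, "one nocte"),
                ),
                timestamp=TS,
            )

    def test_added_medication_is_enriched_like_uploads(self, tiny_bundle, ddd_table):
        state = make_state(tiny_bundle, ddd_table)
        new = record_correction(
            state,
            phase="P3_inhome", actor_role="champion_nurse",
            action="add", entity_kind="medication", entity_id="new1",
            changes=(
                ("resident_id", None, "res-a"),
                ("vendor", None, "medipack"),
                ("vendor_code", None, "D1"),
                ("med_name", None, "Calmex 5mg"),
                ("instructions", None, "one nocte"),
                ("quantity_supplied", None, 28),
            ),
            timestamp=TS,
        )
        rec = new.medications["new1"]
        assert rec.class_label == BENZODIAZEPINE
        assert rec.daily_dose_mg == 5.0
        assert rec.source == "manual"

    def test_out_of_order_seq_rejected(self, tiny_bundle, ddd_table):
        state = make_state(tiny_bundle, ddd_table, [make_record()])
        entry = TransactionLogEntry(
            seq=5, phase="P2_offsite", actor_role="project_staff",
            action="delete", entity_kind="medication", entity_id="m1",
            field_changes=(), timestamp=TS,
        )
        with pytest.raises(LogError):
            apply_correction(state, entry)

    def test_mapping_add_re_resolves_pending_records(self, tiny_bundle, ddd_table):
        from tests.conftest import DIAZ_TPUU

        rec = make_record(vendor_code="ZZ9", med_name="Novovalium")
        state = make_state(tiny_bundle, ddd_table, [rec])
        assert state.medications["m1"].class_label == PENDING
        new = record_correction(
            state,
            phase="P1_mapping", actor_role="research_pharmacist",
            action="add", entity_kind="mapping", entity_id="medipack|ZZ9",
            changes=(
                ("vendor", None, "medipack"),
                ("vendor_code", None, "ZZ9"),
                ("target_concept_id", None, DIAZ_TPUU),
            ),
            timestamp=TS,
        )
        assert new.medications["m1"].class_label == BENZODIAZEPINE
        assert new.medications["m1"].display_name == "Novovalium"


class TestMergeResidents:
    def test_disjoint_medications_union(self, tiny_bundle, ddd_table):
        recs = [
            make_record("m1", resident_id="res-a"),
            make_record("m2", resident_id="res-b", vendor_code="T1",
                        med_name="Normitab"),
        ]
        state = make_state(tiny_bundle, ddd_table, recs)
        new = merge_residents(state, "res-b", "res-a", timestamp=TS)
        owners = {m.resident_id for m in new.medications.values()}
        assert owners == {"res-a"}
        assert len(new.medications) == 2
        assert new.residents["res-b"].merged_into == "res-a"

    def test_identical_row_collapsed(self, tiny_bundle, ddd_table):
        recs = [
            make_record("m1", resident_id="res-a"),
            make_record("m2", resident_id="res-b"),  # same drug/schedule/dates
            make_record("m3", resident_id="res-b", vendor_code="T1",
                        med_name="Normitab"),
        ]
        state = make_state(tiny_bundle, ddd_table, recs)
        new = merge_residents(state, "res-b", "res-a", timestamp=TS)
        # union minus the one exact duplicate
        assert len(new.medications) == 2
        assert {m.vendor_code for m in new.medications.values()} == {"D1", "T1"}

    def test_merge_into_self_violates_contract(self, tiny_bundle, ddd_table):
        state = make_state(tiny_bundle, ddd_table)
        with pytest.raises(ContractViolation):
            merge_residents(state, "res-a", "res-a", timestamp=TS)

    def test_cross_home_merge_refused_without_override(self, tiny_bundle, ddd_table):
        residents = [
            ResidentProfile("res-a", "A.AAA.1930", "H01", "North"),
            ResidentProfile("res-c", "C.CCC.1932", "H02", "South"),
        ]
        state = make_state(tiny_bundle, ddd_table, residents=residents)
        with pytest.raises(IntegrityError):
            merge_residents(state, "res-c", "res-a", timestamp=TS)
        merged = merge_residents(
            state, "res-c", "res-a", timestamp=TS, allow_cross_home=True
        )
        assert merged.residents["res-c"].merged_into == "res-a"


class TestProposeDuplicates:
    def test_key_collision_proposed_with_top_score(self, tiny_bundle, ddd_table):
        residents = [
            ResidentProfile("res-a", "J.SMI.1934", "H01", "N", match_key="k1"),
            ResidentProfile("res-a2", "J.SMI.1934", "H01", "N", match_key="k1"),
            ResidentProfile("res-b", "M.JON.1940", "H01", "N", match_key="k2"),
        ]
        recs = [make_record("m1", resident_id="res-a")]
        state = make_state(tiny_bundle, ddd_table, recs, residents=residents)
        proposals = propose_duplicates(state)
        assert proposals == [("res-a2", "res-a", 1.0)]

    def test_unrelated_not_proposed(self, tiny_bundle, ddd_table):
        state = make_state(tiny_bundle, ddd_table)
        assert propose_duplicates(state) == []

    def test_three_way_collision_two_proposals_single_target(
        self, tiny_bundle, ddd_table
    ):
        residents = [
            ResidentProfile(f"res-{i}", "J.SMI.1934", "H01", "N", match_key="k1")
            for i in range(3)
        ]
        recs = [make_record("m1", resident_id="res-2")]
        state = make_state(tiny_bundle, ddd_table, recs, residents=residents)
        proposals = propose_duplicates(state)
        assert len(proposals) == 2
        assert {p[1] for p in proposals} == {"res-2"}  # one chosen target
        assert {p[0] for p in proposals} == {"res-0", "res-1"}

    def test_fuzzy_is_opt_in(self, tiny_bundle, ddd_table):
        residents = [
            ResidentProfile("res-a", "J.SMI.1934", "H01", "N", match_key="k1"),
            ResidentProfile("res-b", "J.SMI.1934", "H01", "N", match_key="k2"),
        ]
        state = make_state(tiny_bundle, ddd_table, residents=residents)
        assert propose_duplicates(state) == []
        fuzzy = propose_duplicates(state, fuzzy=True)
        assert len(fuzzy) == 1


class TestVerifyHome:
    def test_all_checked_no_flags_verified(self, tiny_bundle, ddd_table):
        state = make_state(
            tiny_bundle, ddd_table, [make_record()], checked=("res-a", "res-b")
        )
        assert verify_home(state, "H01").verified is True

    def test_one_unchecked_blocks(self, tiny_bundle, ddd_table):
        state = make_state(
            tiny_bundle, ddd_table, [make_record()], checked=("res-a",)
        )
        status = verify_home(state, "H01")
        assert status.verified is False
        assert status.unchecked_residents == ("res-b",)

    def test_unmapped_sedative_blocks_even_when_checked(
        self, tiny_bundle, ddd_table
    ):
        rec = make_record(vendor_code="ZZ9")
        state = make_state(
            tiny_bundle, ddd_table, [rec], checked=("res-a", "res-b")
        )
        status = verify_home(state, "H01")
        assert status.verified is False
        assert status.blocking_flags[0].reason == "unmapped_medication"

    def test_dose_range_flag_does_not_block(self, tiny_bundle, ddd_table):
        rec = make_record(instructions="nine daily")
        state = make_state(
            tiny_bundle, ddd_table, [rec], checked=("res-a", "res-b")
        )
        assert verify_home(state, "H01").verified is True


class TestReplay:
    def test_empty_log_is_identity(self, tiny_bundle, ddd_table):
        state = make_state(tiny_bundle, ddd_table, [make_record()])
        assert replay(state, []) is state

    def test_add_then_delete_restores_data(self, tiny_bundle, ddd_table):
        state = make_state(tiny_bundle, ddd_table)
        mid = record_correction(
            state,
            phase="P3_inhome", actor_role="champion_nurse",
            action="add", entity_kind="medication", entity_id="n1",
            changes=(
                ("resident_id", None, "res-a"),
                ("vendor", None, "medipack"),
                ("vendor_code", None, "D1"),
                ("med_name", None, "Calmex"),
                ("instructions", None, "one nocte"),
            ),
            timestamp=TS,
        )
        back = record_correction(
            mid,
            phase="P3_inhome", actor_role="champion_nurse",
            action="delete", entity_kind="medication", entity_id="n1",
            timestamp=TS,
        )
        assert _states_equal(back, state)

    def test_gap_in_seq_is_log_error(self, tiny_bundle, ddd_table):
        state = make_state(tiny_bundle, ddd_table, [make_record()])
        entry = TransactionLogEntry(
            seq=3, phase="P2_offsite", actor_role="project_staff",
            action="delete", entity_kind="medication", entity_id="m1",
            field_changes=(), timestamp=TS,
        )
        with pytest.raises(LogError):
            replay(state, [entry])

    @pytest.mark.parametrize("seed", range(25))
    def test_replay_equals_incremental_application(
        self, tiny_bundle, ddd_table, seed
    ):
        """Event-sourcing soundness on randomized correction sequences,
        including cascading deletes and merges."""
        rng = random.Random(seed)
        residents = [
            ResidentProfile(f"res-{i}", f"R.{i}.1930", "H01", "N",
                            match_key=f"mk{i % 3}")
            for i in range(4)
        ]
        recs = [
            make_record(
                f"m{i}",
                resident_id=f"res-{rng.randrange(4)}",
                vendor_code=rng.choice(["D1", "T1", "P1", "Q1"]),
                instructions=rng.choice(["one nocte", "two bd", "half mane"]),
            )
            for i in range(8)
        ]
        initial = make_state(tiny_bundle, ddd_table, recs, residents=residents)
        state = initial
        for _ in range(12):
            op = rng.random()
            live = [r.resident_id for r in state.current_residents()]
            mids = sorted(state.medications)
            try:
                if op < 0.3 and mids:
                    state = record_correction(
                        state,
                        phase="P2_offsite", actor_role="project_staff",
                        action="modify", entity_kind="medication",
                        entity_id=rng.choice(mids),
                        changes=(("instructions", None,
                                  rng.choice(["one bd", "two nocte"])),),
                        timestamp=TS,
                    )
                elif op < 0.45 and mids:
                    state = record_correction(
                        state,
                        phase="P3_inhome", actor_role="champion_nurse",
                        action="delete", entity_kind="medication",
                        entity_id=rng.choice(mids), timestamp=TS,
                    )
                elif op < 0.6 and live:
                    state = record_correction(
                        state,
                        phase="P3_inhome", actor_role="champion_nurse",
                        action="delete", entity_kind="resident",
                        entity_id=rng.choice(live), timestamp=TS,
                    )
                elif op < 0.8 and len(live) >= 2:
                    src, tgt = rng.sample(live, 2)
                    state = merge_residents(state, src, tgt, timestamp=TS)
                elif live:
                    state = mark_checked(state, rng.choice(live), timestamp=TS)
            except (IntegrityError, ContractViolation):
                continue
        replayed = replay(initial, state.log)
        assert _states_equal(replayed, state)
        assert replayed.log == state.log


class TestCorrectionStats:
    def _entry(self, seq, phase, note=""):
        return TransactionLogEntry(
            seq=seq, phase=phase, actor_role="project_staff",
            action="modify", entity_kind="medication", entity_id=f"m{seq}",
            field_changes=(("instructions", "a", "b"),),
            timestamp=TS, note=note,
        )

    def test_single_phase_is_all_of_total(self):
        log = [self._entry(i + 1, "P3_inhome") for i in range(5)]
        df = correction_stats(log)
        assert df.set_index("phase").loc["P3_inhome", "pct"] == 100.0
        assert df.set_index("phase").loc["P1_mapping", "corrections"] == 0

    def test_empty_log_all_zero(self):
        df = correction_stats([])
        assert (df["corrections"] == 0).all()
        assert df.attrs["total"] == 0

    def test_checked_marks_and_cascades_not_counted(self, tiny_bundle, ddd_table):
        state = make_state(tiny_bundle, ddd_table, [make_record()])
        state = mark_checked(state, "res-a", timestamp=TS)
        state = record_correction(
            state,
            phase="P3_inhome", actor_role="champion_nurse",
            action="delete", entity_kind="resident", entity_id="res-a",
            timestamp=TS,
        )  # also cascades one medication delete
        df = correction_stats(state.log)
        assert df.attrs["total"] == 1  # only the resident delete itself

    def test_known_error_partition_sums_exactly(self):
        log = [self._entry(i + 1, "P2_offsite") for i in range(10)]
        log += [self._entry(11 + i, "P3_inhome", note="known") for i in range(6)]
        df = correction_stats(log, known_error_filter=lambda e: e.note == "known")
        assert df["corrections"].sum() == df.attrs["total"] == 16
        assert df["corrections_excl_known"].sum() == df.attrs["total_excl_known"] == 10


class TestManualEntry:
    def _add(self, seq, entity_id, resident_id="res-a", code="D1", name="Calmex"):
        return TransactionLogEntry(
            seq=seq, phase="manual_entry", actor_role="project_staff",
            action="add", entity_kind="medication", entity_id=entity_id,
            field_changes=(
                ("resident_id", None, resident_id),
                ("vendor", None, "medipack"),
                ("vendor_code", None, code),
                ("med_name", None, name),
                ("instructions", None, "one nocte"),
            ),
            timestamp=TS,
        )

    def test_first_snapshot_logs_manual_adds(self, tiny_bundle, ddd_table):
        state = make_state(tiny_bundle, ddd_table)
        new, warnings = manual_entry_session(state, [self._add(1, "n1")])
        assert new.medications["n1"].source == "manual"
        assert new.log[-1].phase == "manual_entry"
        assert warnings == []

    def test_prepopulated_second_snapshot_with_no_deltas(
        self, tiny_bundle, ddd_table
    ):
        prior = make_state(tiny_bundle, ddd_table, [make_record()])
        empty = make_state(tiny_bundle, ddd_table, residents=[])
        new, _ = manual_entry_session(empty, [], prepopulate_from=prior)
        assert _states_equal(new, prior)

    def test_delta_removes_one_medication(self, tiny_bundle, ddd_table):
        prior = make_state(
            tiny_bundle, ddd_table,
            [make_record("m1"), make_record("m2", vendor_code="T1",
                                            med_name="Normitab")],
        )
        delete = TransactionLogEntry(
            seq=1, phase="manual_entry", actor_role="project_staff",
            action="delete", entity_kind="medication", entity_id="m2",
            field_changes=(), timestamp=TS,
        )
        new, _ = manual_entry_session(prior, [delete], prepopulate_from=prior)
        assert set(new.medications) == {"m1"}

    def test_non_sedative_entry_warned_but_accepted(self, tiny_bundle, ddd_table):
        state = make_state(tiny_bundle, ddd_table)
        new, warnings = manual_entry_session(
            state, [self._add(1, "n1", code="P1", name="Paratab")]
        )
        assert "n1" in new.medications
        assert len(warnings) == 1


def test_log_jsonl_round_trip(tmp_path, tiny_bundle, ddd_table):
    state = make_state(tiny_bundle, ddd_table, [make_record()])
    state = mark_checked(state, "res-a", timestamp=TS)
    state = record_correction(
        state,
        phase="P2_offsite", actor_role="project_staff",
        action="modify", entity_kind="medication", entity_id="m1",
        changes=(("date_started", None, TS.date()),),
        timestamp=TS,
    )
    path = tmp_path / "log.jsonl"
    log_to_jsonl(state.log, path)
    assert log_from_jsonl(path) == list(state.log)
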