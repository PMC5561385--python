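"""Generator determinism, terminology coverage, injection bookkeeping,
and session-log closure."""

from __future__ import annotations

import pytest

from sedaudit.classify import ANTIPSYCHOTIC, BENZODIAZEPINE, DEFAULT_RULES
from sedaudit.pipeline import build_state, ingest_export
from sedaudit.ingest import ExportData
from sedaudit.synthdata import (
    GeneratorConfig,
    generate_dataset,
    generate_pharmacy_data,
    generate_session_log,
    generate_terminology,
    write_dataset,
)
from sedaudit.validation import flag_suspects, replay


def _ingest(ds, cfg):
    snaps = []
    for ph in ds.pharmacies:
        export = ExportData(
            dialect=ph.dialect, pharmacy_id=ph.pharmacy_id, vendor=ph.vendor,
            rows=ph.rows, residents=ph.residents, rejects=(),
        )
        snaps.append(ingest_export(export, ds.home_registry, ds.key, cfg.snapshot_time))
    return build_state(
        snaps, ds.terminology.bundle, DEFAULT_RULES, ds.terminology.ddd_table
    )


SMALL = dict(n_homes=2, residents_per_home_mean=12, residents_per_home_sd=3)


class TestTerminologyGeneration:
    def test_bundle_passes_all_invariants(self):
        terms = generate_terminology(GeneratorConfig())
        terms.bundle.validate()  # raises on violation

    def test_rule_table_coverage(self):
        """At least one concept per inclusion class and per excluded drug,
        plus reference DDD rows and non-sedative distractors."""
        terms = generate_terminology(GeneratorConfig())
        atcs = {d.atc for d in terms.drugs}
        # every include prefix of the study rule set is represented
        for prefix, _label in DEFAULT_RULES.include_prefixes:
            assert any(a.startswith(prefix) for a in atcs), prefix
        # both exclusions are present as concepts (classified NONE)
        excluded = {d.atc for d in terms.drugs if d.class_label == "NONE"}
        assert any(a.startswith("N05AN") for a in excluded)
        assert "N05AB04" in excluded
        assert len(terms.distractors) > 10
        # reference drugs for equivalents are in the DDD table
        assert "N05BA01" in terms.ddd_table
        assert "N05AA01" in terms.ddd_table

    def test_both_resolution_paths_exist(self):
        terms = generate_terminology(GeneratorConfig())
        assert any(d.ctpp_id is not None for d in terms.drugs)
        assert any(d.ctpp_id is None for d in terms.drugs)


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = GeneratorConfig(seed=42, **SMALL)
        for sub in ("a", "b"):
            ds = generate_dataset(cfg)
            write_dataset(ds, tmp_path / sub)
        files_a = sorted((tmp_path / "a").rglob("*"))
        files_b = sorted((tmp_path / "b").rglob("*"))
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            if fa.is_file():
                assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_different_seeds_differ(self):
        a = generate_dataset(GeneratorConfig(seed=1, **SMALL))
        b = generate_dataset(GeneratorConfig(seed=2, **SMALL))
        assert a.ledger.records != b.ledger.records


class TestInjection:
    def test_all_rates_zero_is_perfect_data(self):
        cfg = GeneratorConfig(
            seed=5, duplicate_resident_rate=0, unmapped_medication_rate=0,
            missing_dose_rate=0, prn_omission_rate=0, regular_omission_rate=0,
            transposed_field_rate=0, ceased_rate=0, **SMALL,
        )
        ds = generate_dataset(cfg)
        assert all(t.injected is None for t in ds.ledger.records)
        state = _ingest(ds, cfg)
        # pipeline output matches ledger truth with no corrections at all
        by_key = {
            (m.resident_id, m.vendor, m.vendor_code): m
            for m in state.medications.values()
        }
        for t in ds.ledger.records:
            m = by_key[(t.owner_resident_id, t.vendor, t.vendor_code)]
            assert m.class_label == t.class_label
            assert m.prn == t.prn
            assert m.daily_dose_mg == pytest.approx(t.daily_dose_mg)
        assert flag_suspects(state) == []

    def test_missing_dose_saturation_flags_every_sedative(self):
        cfg = GeneratorConfig(
            seed=6, missing_dose_rate=1.0, prn_omission_rate=0,
            regular_omission_rate=0, unmapped_medication_rate=0,
            transposed_field_rate=0, ceased_rate=0,
            duplicate_resident_rate=0, **SMALL,
        )
        ds = generate_dataset(cfg)
        state = _ingest(ds, cfg)
        flagged = {
            f.entity_id for f in flag_suspects(state)
            if f.reason == "missing_dose_quantity"
        }
        sedative_ids = {
            m.record_id for m in state.medications.values()
            if m.class_label in (ANTIPSYCHOTIC, BENZODIAZEPINE)
        }
        n_sed_true = sum(1 for t in ds.ledger.records if t.class_label != "NONE")
        assert n_sed_true > 0
        assert sedative_ids == flagged
        assert len(flagged) == n_sed_true

    def test_duplicate_rate_reproducible_from_seed(self):
        cfg = GeneratorConfig(seed=7, duplicate_resident_rate=0.5, **SMALL)
        first = generate_dataset(cfg).ledger.counts["duplicate_profiles"]
        second = generate_dataset(cfg).ledger.counts["duplicate_profiles"]
        assert first == second > 0

    def test_injected_labels_disjoint_and_ledger_total(self):
        cfg = GeneratorConfig(seed=8, missing_dose_rate=0.3,
                              unmapped_medication_rate=0.2, **SMALL)
        ds = generate_dataset(cfg)
        c = ds.ledger.counts
        assert c["records"] == len(ds.ledger.records)
        # every record carries at most one injected error label, and the
        # export holds exactly the non-omitted records (ceased rows stay in
        # the file; the snapshot excludes them later)
        exported = sum(len(ph.rows) for ph in ds.pharmacies)
        assert exported == c["records"] - c["omitted"]
        assert (
            c["omitted"] + c["missing_dose"] + c["unmapped"] + c["transposed"]
            == sum(1 for t in ds.ledger.records if t.injected is not None)
        )


class TestSessionLog:
    def test_zero_errors_empty_correction_stream(self):
        cfg = GeneratorConfig(
            seed=9, duplicate_resident_rate=0, unmapped_medication_rate=0,
            missing_dose_rate=0, prn_omission_rate=0, regular_omission_rate=0,
            transposed_field_rate=0, ceased_rate=0, **SMALL,
        )
        ds = generate_dataset(cfg)
        state = _ingest(ds, cfg)
        session = generate_session_log(cfg, ds.ledger, state)
        assert session.corrections == ()
        # sign-offs still happen so homes can verify
        assert len(session.entries) == len(state.residents)

    def test_replay_of_generated_log_reaches_final_state(self, small_dataset):
        state = small_dataset["state"]
        session = small_dataset["session"]
        replayed = replay(state, session.entries)
        assert dict(replayed.medications) == dict(session.final_state.medications)
        assert dict(replayed.residents) == dict(session.final_state.residents)
        assert replayed.log == session.final_state.log

    def test_phase_histogram_matches_injection_categories(self, small_dataset):
        ds = small_dataset["dataset"]
        session = small_dataset["session"]
        by_phase: dict[str, list] = {}
        for e in session.corrections:
            by_phase.setdefault(e.phase, []).append(e)
        current = [t for t in ds.ledger.records if t.current]
        n_unmapped_codes = len(
            {(t.vendor, t.vendor_code) for t in current if t.injected == "unmapped"}
        )
        n_transposed = sum(1 for t in current if t.injected == "transposed")
        n_missing = sum(1 for t in current if t.injected == "missing_dose")
        n_omitted = sum(1 for t in current if t.injected == "omitted")
        n_dups = ds.ledger.counts["duplicate_profiles"]
        assert len(by_phase.get("P1_mapping", [])) == n_unmapped_codes
        assert len(by_phase.get("P2_offsite", [])) == n_transposed
        p3 = by_phase.get("P3_inhome", [])
        assert sum(1 for e in p3 if e.action == "modify") == n_missing
        assert sum(1 for e in p3 if e.action == "add") == n_omitted
        assert len(by_phase.get("P4_retrospective", [])) == n_dups

    def test_all_homes_verified_after_session(self, small_dataset):
        from sedaudit.validation import verify_home

        final = small_dataset["session"].final_state
        for hid in small_dataset["dataset"].home_registry:
            assert verify_home(final, hid).verified, hid

    def test_interaction_events_usable_for_timing(self, small_dataset):
        from datetime import timedelta
        from sedaudit.reporting import session_time_estimate

        events = small_dataset["session"].events
        assert events
        times = session_time_estimate(events, timedelta(minutes=10))
        assert all(v >= 0 for v in times.minutes_per_actor_home.values())


class TestEndToEndRecovery:
    def test_ledger_truth_recovered_after_corrections(self, small_dataset):
        ds = small_dataset["dataset"]
        final = small_dataset["session"].final_state
        by_key = {
            (m.resident_id, m.vendor, m.vendor_code): m
            for m in final.medications.values()
        }
        n = mismatches = 0
        for t in ds.ledger.records:
            if not t.current:
                continue
            n += 1
            m = by_key.get((t.owner_resident_id, t.vendor, t.vendor_code))
            if (
                m is None
                or m.class_label != t.class_label
                or m.prn != t.prn
                or m.daily_dose_mg is None
                or abs(m.daily_dose_mg - t.daily_dose_mg) > 1e-9
            ):
                mismatches += 1
        assert n > 100
        assert mismatches == 0
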