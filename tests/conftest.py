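"""Shared fixtures: a tiny hand-built terminology bundle and a small
synthetic dataset, plus helpers for constructing audit states."""

from __future__ import annotations

from datetime import date, datetime

import pytest

from sedaudit.classify import DEFAULT_RULES
from sedaudit.doseload import DddReference
from sedaudit.enrich import enrich_record
from sedaudit.ingest import MedicationRecord, ResidentProfile
from sedaudit.terminology import (
    AtcAssignment,
    Concept,
    ConceptEdge,
    TerminologyBundle,
    VendorMapping,
)
from sedaudit.validation import PipelineState

# Concept ids for the tiny fixture hierarchy (diazepam with a full
# CTPP->TPP->TPUU->MPUU chain, temazepam TPUU-only, paracetamol distractor).
DIAZ_MPUU, DIAZ_TPUU, DIAZ_TPP, DIAZ_CTPP = 101, 102, 103, 104
TEMAZ_MPUU, TEMAZ_TPUU = 111, 112
PARA_MPUU, PARA_TPUU = 121, 122
QUET_MPUU, QUET_TPUU = 131, 132


@pytest.fixture(scope="session")
def tiny_bundle() -> TerminologyBundle:
    concepts = [
        Concept(DIAZ_MPUU, "MPUU", "diazepam 5 mg tablet", 5.0, "mg", "tablet"),
        Concept(DIAZ_TPUU, "TPUU", "Calmex 5 mg tablet", 5.0, "mg", "tablet"),
        Concept(DIAZ_TPP, "TPP", "Calmex 5 mg tablet, 50 pack"),
        Concept(DIAZ_CTPP, "CTPP", "Calmex 5 mg tablet, 50 pack, bottle"),
        Concept(TEMAZ_MPUU, "MPUU", "temazepam 10 mg tablet", 10.0, "mg", "tablet"),
        Concept(TEMAZ_TPUU, "TPUU", "Normitab 10 mg tablet", 10.0, "mg", "tablet"),
        Concept(PARA_MPUU, "MPUU", "paracetamol 500 mg tablet", 500.0, "mg", "tablet"),
        Concept(PARA_TPUU, "TPUU", "Paratab 500 mg tablet", 500.0, "mg", "tablet"),
        Concept(QUET_MPUU, "MPUU", "quetiapine 100 mg tablet", 100.0, "mg", "tablet"),
        Concept(QUET_TPUU, "TPUU", "Quetex 100 mg tablet", 100.0, "mg", "tablet"),
    ]
    edges = [
        ConceptEdge(DIAZ_CTPP, DIAZ_TPP, "contains"),
        ConceptEdge(DIAZ_TPP, DIAZ_TPUU, "contains"),
        ConceptEdge(DIAZ_TPUU, DIAZ_MPUU, "is_generic_of"),
        ConceptEdge(TEMAZ_TPUU, TEMAZ_MPUU, "is_generic_of"),
        ConceptEdge(PARA_TPUU, PARA_MPUU, "is_generic_of"),
        ConceptEdge(QUET_TPUU, QUET_MPUU, "is_generic_of"),
    ]
    mappings = [
        VendorMapping("medipack", "D1", DIAZ_TPUU),
        VendorMapping("blisterpro", "D2", DIAZ_CTPP),
        VendorMapping("medipack", "T1", TEMAZ_TPUU),
        VendorMapping("medipack", "P1", PARA_TPUU),
        VendorMapping("medipack", "Q1", QUET_TPUU),
    ]
    assignments = [
        AtcAssignment(DIAZ_MPUU, "N05BA01", primary=True),
        AtcAssignment(TEMAZ_MPUU, "N05CD07", primary=True),
        AtcAssignment(PARA_MPUU, "N02BE01", primary=True),
        AtcAssignment(QUET_MPUU, "N05AH04", primary=True),
    ]
    return TerminologyBundle.build(concepts, edges, mappings, assignments)


@pytest.fixture(scope="session")
def ddd_table() -> dict[str, DddReference]:
    return {
        "N05BA01": DddReference("N05BA01", 10.0),   # diazepam (reference)
        "N05CD07": DddReference("N05CD07", 20.0),   # temazepam
        "N05AA01": DddReference("N05AA01", 300.0),  # chlorpromazine (reference)
        "N05AH04": DddReference("N05AH04", 400.0),  # quetiapine
        "N02BE01": DddReference("N02BE01", 3000.0),
    }


def make_record(
    record_id: str = "m1",
    resident_id: str = "res-a",
    vendor: str = "medipack",
    vendor_code: str = "D1",
    med_name: str = "Calmex 5mg",
    instructions: str = "one nocte",
    quantity: int | None = 28,
    date_started: date | None = date(2015, 6, 1),
) -> MedicationRecord:
    return MedicationRecord(
        record_id=record_id,
        resident_id=resident_id,
        vendor=vendor,
        vendor_code=vendor_code,
        med_name=med_name,
        display_name=med_name,
        instructions=instructions,
        quantity_supplied=quantity,
        date_started=date_started,
    )


def make_state(tiny_bundle, ddd_table, records=(), residents=None, checked=()):
    """Build an enriched PipelineState around the tiny fixture bundle."""
    if residents is None:
        residents = [
            ResidentProfile("res-a", "A.AAA.1930", "H01", "North", match_key="mk-a"),
            ResidentProfile("res-b", "B.BBB.1931", "H01", "North", match_key="mk-b"),
        ]
    return PipelineState(
        residents={r.resident_id: r for r in residents},
        medications={
            m.record_id: enrich_record(m, tiny_bundle, DEFAULT_RULES)
            for m in records
        },
        checked=frozenset(checked),
        log=(),
        bundle=tiny_bundle,
        rules=DEFAULT_RULES,
        ddd_table=ddd_table,
    )


@pytest.fixture()
def base_state(tiny_bundle, ddd_table):
    return make_state(tiny_bundle, ddd_table)


@pytest.fixture(scope="session")
def small_dataset():
    """Small but complete synthetic world with elevated error rates, plus
    its ingested state and the generated correction session."""
    from sedaudit.pipeline import build_state, ingest_export
    from sedaudit.synthdata import (
        GeneratorConfig,
        generate_dataset,
        generate_session_log,
    )
    from sedaudit.ingest import ExportData

    cfg = GeneratorConfig(
        seed=11,
        n_homes=2,
        residents_per_home_mean=18,
        residents_per_home_sd=4,
        missing_dose_rate=0.2,
        unmapped_medication_rate=0.1,
    )
    ds = generate_dataset(cfg)
    snaps = []
    for ph in ds.pharmacies:
        export = ExportData(
            dialect=ph.dialect,
            pharmacy_id=ph.pharmacy_id,
            vendor=ph.vendor,
            rows=ph.rows,
            residents=ph.residents,
            rejects=(),
        )
        snaps.append(
            ingest_export(export, ds.home_registry, ds.key, cfg.snapshot_time)
        )
    state = build_state(
        snaps, ds.terminology.bundle, DEFAULT_RULES, ds.terminology.ddd_table
    )
    session = generate_session_log(cfg, ds.ledger, state)
    return {"config": cfg, "dataset": ds, "state": state, "session": session}
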