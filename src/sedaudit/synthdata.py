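"""Synthetic fixture generator: terminology, homes, exports, error injection.

Generates a complete offline world for the pipeline: an AMT-style
terminology bundle with full resolution chains, nursing homes with
residents and packed medications rendered in both export dialects, and a
ground-truth ledger recording every record's true class, PRN status and
daily dose together with every injected error. A session-log generator then
emits phase-labelled corrections that exactly repair the injections, so
end-to-end recovery is testable by construction.

Default rates mirror the magnitudes observed in a national sedative audit
of Australian nursing homes (90 residents per home, SD 37.5; ~11.8
medications per resident; 5.13% sedatives; 45% of sedatives PRN; 3.62% of
regular and 6.12% of PRN sedatives absent from packing; 11.07% duplicate
resident profiles). All are configurable; no claim is made that a synthetic
run reproduces any study's exact counts. Names are drawn from a fixed
synthetic list; no real-person data is ever used.

Error injection samples at most one mode per record from a categorical
distribution whose component probabilities are the configured rates, so
each mode's marginal frequency is exactly Bernoulli(rate) while labels stay
disjoint per record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np

from .classify import DEFAULT_RULES, classify_atc
from .doseload import DddReference, save_ddd_table
from .ingest import (
    RawMedicationRow,
    RawResident,
    pseudonymize,
    write_export,
)
from .terminology import (
    AtcAssignment,
    Concept,
    ConceptEdge,
    TerminologyBundle,
    VendorMapping,
    save_bundle,
)
from .validation import (
    PipelineState,
    TransactionLogEntry,
    apply_correction,
    mark_checked,
    merge_residents,
)

VENDORS = ("medipack", "sachetrx", "blisterpro", "packmaster")
#: medipack/sachetrx expose their database (table_export, codes -> TPUU);
#: blisterpro/packmaster produce flat reports (report, codes -> CTPP).
VENDOR_DIALECT = {
    "medipack": "table_export",
    "sachetrx": "table_export",
    "blisterpro": "report",
    "packmaster": "report",
}
VENDOR_TARGET_KIND = {
    "medipack": "TPUU",
    "sachetrx": "TPUU",
    "blisterpro": "CTPP",
    "packmaster": "CTPP",
}

# (generic name, ATC, unit strength mg, DDD mg). DDD values are synthetic
# but plausible; real WHO values drop in via ddd.tsv unchanged.
_SEDATIVE_DRUGS = [
    ("chlorpromazine", "N05AA01", 100.0, 300.0),
    ("haloperidol", "N05AD01", 5.0, 8.0),
    ("quetiapine", "N05AH04", 100.0, 400.0),
    ("olanzapine", "N05AH03", 10.0, 10.0),
    ("risperidone", "N05AX08", 2.0, 5.0),
    ("diazepam", "N05BA01", 5.0, 10.0),
    ("oxazepam", "N05BA04", 30.0, 50.0),
    ("lorazepam", "N05BA06", 1.0, 2.5),
    ("temazepam", "N05CD07", 10.0, 20.0),
    ("nitrazepam", "N05CD02", 5.0, 5.0),
    ("clonazepam", "N03AE01", 0.5, 8.0),
    ("zopiclone", "N05CF01", 7.5, 7.5),
    ("zolpidem", "N05CF02", 10.0, 10.0),
]
# Includes the two explicitly excluded psycholeptics (lithium N05AN01,
# prochlorperazine N05AB04) so the exclusion rules are exercised.
_DISTRACTOR_DRUGS = [
    ("lithium carbonate", "N05AN01", 250.0, 24.0),
    ("prochlorperazine", "N05AB04", 5.0, 100.0),
    ("paracetamol", "N02BE01", 500.0, 3000.0),
    ("ibuprofen", "M01AE01", 200.0, 1200.0),
    ("aspirin", "B01AC06", 100.0, 1.0),
    ("atorvastatin", "C10AA05", 20.0, 20.0),
    ("simvastatin", "C10AA01", 20.0, 30.0),
    ("metformin", "A10BA02", 500.0, 2000.0),
    ("gliclazide", "A10BB09", 30.0, 60.0),
    ("furosemide", "C03CA01", 40.0, 40.0),
    ("perindopril", "C09AA04", 5.0, 4.0),
    ("ramipril", "C09AA05", 5.0, 2.5),
    ("amlodipine", "C08CA01", 5.0, 5.0),
    ("metoprolol", "C07AB02", 50.0, 150.0),
    ("digoxin", "C01AA05", 0.25, 0.25),
    ("warfarin", "B01AA03", 5.0, 7.5),
    ("omeprazole", "A02BC01", 20.0, 20.0),
    ("pantoprazole", "A02BC02", 40.0, 40.0),
    ("sertraline", "N06AB06", 50.0, 50.0),
    ("citalopram", "N06AB04", 20.0, 20.0),
    ("mirtazapine", "N06AX11", 30.0, 30.0),
    ("donepezil", "N06DA02", 10.0, 7.5),
    ("memantine", "N06DX01", 10.0, 20.0),
    ("levothyroxine", "H03AA01", 0.1, 0.15),
    ("allopurinol", "M04AA01", 100.0, 400.0),
    ("prednisolone", "H02AB06", 5.0, 10.0),
    ("salbutamol inhaler", "R03AC02", 0.1, 0.8),
    ("tiotropium", "R03BB04", 0.018, 0.005),
    ("docusate", "A06AA02", 100.0, 200.0),
    ("vitamin d3", "A11CC05", 0.025, 0.02),
]

_FIRST_NAMES = [
    "alma", "arthur", "beryl", "bruce", "clara", "colin", "daphne", "dennis",
    "edith", "ernest", "florence", "frank", "gladys", "gordon", "hazel",
    "harold", "irene", "ivan", "joyce", "john", "kathleen", "keith", "lorna",
    "leonard", "mavis", "maxwell", "nancy", "norman", "olive", "oswald",
    "peggy", "percy", "ruth", "ronald", "sylvia", "stanley", "thelma",
    "trevor", "vera", "wallace",
]
_LAST_NAMES = [
    "anderson", "bailey", "barnes", "bennett", "brown", "carter", "clarke",
    "collins", "cooper", "davies", "dawson", "edwards", "evans", "fisher",
    "foster", "gibson", "graham", "green", "harris", "hughes", "jackson",
    "james", "johnson", "kelly", "king", "lewis", "martin", "mason",
    "mitchell", "morgan", "murphy", "murray", "nelson", "owen", "palmer",
    "parker", "pearson", "reid", "roberts", "robinson", "rogers", "russell",
    "scott", "shaw", "simpson", "smith", "stewart", "taylor", "thompson",
    "turner", "walker", "ward", "watson", "webb", "white", "wilson", "wood",
    "wright", "young", "yates",
]
_HOME_NAMES = [
    "Acacia Lodge", "Banksia House", "Correa Gardens", "Dryandra Court",
    "Eucalypt Manor", "Grevillea Park", "Hakea Village", "Melaleuca Home",
    "Waratah Lodge", "Boronia House", "Callistemon Court", "Kurrajong Manor",
]

_COUNT_WORDS = {0.5: "half", 1.0: "one", 2.0: "two"}
_FREQS = ["mane", "nocte", "midday", "daily", "bd", "tds"]
_FREQ_PER_DAY = {"mane": 1, "nocte": 1, "midday": 1, "daily": 1, "bd": 2, "tds": 3}


@dataclass(frozen=True)
class GeneratorConfig:
    """Stated world for the generator; identical seed => identical output."""

    seed: int = 0
    n_homes: int = 4
    residents_per_home_mean: float = 90.0
    residents_per_home_sd: float = 37.5
    meds_per_resident_mean: float = 11.84
    sedative_fraction: float = 0.0513
    prn_fraction: float = 0.4506          # among sedatives
    distractor_prn_fraction: float = 0.15
    duplicate_resident_rate: float = 0.1107
    unmapped_medication_rate: float = 0.0078
    missing_dose_rate: float = 0.05
    prn_omission_rate: float = 0.0612
    regular_omission_rate: float = 0.0362
    transposed_field_rate: float = 0.02
    ceased_rate: float = 0.03
    dialect_mix: float = 0.5              # P(pharmacy uses a table_export vendor)
    snapshot_time: datetime = datetime(2016, 3, 1, 12, 0)

    def __post_init__(self):
        for name in (
            "sedative_fraction", "prn_fraction", "distractor_prn_fraction",
            "duplicate_resident_rate", "unmapped_medication_rate",
            "missing_dose_rate", "prn_omission_rate", "regular_omission_rate",
            "transposed_field_rate", "ceased_rate", "dialect_mix",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass(frozen=True)
class DrugEntry:
    name: str
    atc: str
    strength_mg: float
    ddd_mg: float
    class_label: str
    mpuu_id: int
    tpuu_id: int
    ctpp_id: int | None
    vendor_codes: Mapping[str, str]  # vendor -> code


@dataclass(frozen=True)
class SynthTerminology:
    bundle: TerminologyBundle
    ddd_table: Mapping[str, DddReference]
    drugs: tuple[DrugEntry, ...]

    @property
    def sedatives(self) -> tuple[DrugEntry, ...]:
        return tuple(d for d in self.drugs if d.class_label != "NONE")

    @property
    def distractors(self) -> tuple[DrugEntry, ...]:
        return tuple(d for d in self.drugs if d.class_label == "NONE")


@dataclass(frozen=True)
class TrueRecord:
    uid: str
    home_id: str
    pharmacy_id: str
    owner_resident_id: str      # primary profile after any merge
    profile_resident_id: str    # profile the record appears under pre-merge
    resident_key: str
    vendor: str
    vendor_code: str            # code as (would be) exported
    true_target_concept: int    # TPUU/CTPP id, for repairing unmapped codes
    med_name: str
    true_instructions: str
    export_instructions: str
    quantity_supplied: int | None
    export_quantity: int | None
    prescriber: str
    export_prescriber: str
    date_started: date
    date_ceased: date | None
    current: bool               # False iff ceased before the snapshot
    atc: str
    mpuu_id: int
    class_label: str
    prn: bool
    daily_dose_mg: float
    injected: str | None        # omitted | missing_dose | unmapped | transposed


@dataclass(frozen=True)
class TrueResident:
    resident_key: str
    name: str
    birth_date: date
    home_id: str
    wing: str
    resident_id: str
    primary_resident_id: str
    is_duplicate: bool


@dataclass(frozen=True)
class GroundTruthLedger:
    records: tuple[TrueRecord, ...]
    residents: tuple[TrueResident, ...]
    counts: Mapping[str, int]


@dataclass(frozen=True)
class PharmacyExport:
    pharmacy_id: str
    vendor: str
    dialect: str
    home_ids: tuple[str, ...]
    residents: tuple[RawResident, ...]
    rows: tuple[RawMedicationRow, ...]


@dataclass(frozen=True)
class SynthDataset:
    config: GeneratorConfig
    key: str
    terminology: SynthTerminology
    home_registry: Mapping[str, tuple[str, ...]]
    pharmacies: tuple[PharmacyExport, ...]
    ledger: GroundTruthLedger


# -- terminology ----------------------------------------------------------

def generate_terminology(config: GeneratorConfig) -> SynthTerminology:
    """Build the synthetic terminology bundle and DDD table.

    Every sedative class of the default rule set gets at least one MPUU, the
    excluded drugs (a lithium and a prochlorperazine entry) and non-sedative
    distractors are present, and roughly half the drugs carry a full
    CTPP -> TPP -> TPUU -> MPUU chain so both resolution paths are
    exercised. Deterministic in the config (ids are sequential).
    """
    concepts: list[Concept] = []
    edges: list[ConceptEdge] = []
    mappings: list[VendorMapping] = []
    assignments: list[AtcAssignment] = []
    drugs: list[DrugEntry] = []
    ddd_table: dict[str, DddReference] = {}
    next_id = 100001
    code_counter = {v: 1000 for v in VENDORS}

    def new_id() -> int:
        nonlocal next_id
        next_id += 1
        return next_id - 1

    catalogue = _SEDATIVE_DRUGS + _DISTRACTOR_DRUGS
    for idx, (name, atc, strength, ddd_mg) in enumerate(catalogue):
        mp_id = new_id()
        concepts.append(Concept(mp_id, "MP", name))
        mpuu_id = new_id()
        form = "tablet" if "inhaler" not in name else "inhalation"
        concepts.append(
            Concept(mpuu_id, "MPUU", f"{name} {strength:g} mg {form}",
                    strength_value=strength, strength_unit="mg", dose_form=form)
        )
        brand = f"{name.split()[0].capitalize()}ex"
        tp_id = new_id()
        concepts.append(Concept(tp_id, "TP", brand))
        tpuu_id = new_id()
        concepts.append(
            Concept(tpuu_id, "TPUU", f"{brand} {strength:g} mg {form}",
                    strength_value=strength, strength_unit="mg", dose_form=form)
        )
        edges.append(ConceptEdge(tpuu_id, mpuu_id, "is_generic_of"))
        ctpp_id = None
        if idx % 2 == 0:  # half the drugs get the full pack chain
            tpp_id = new_id()
            concepts.append(
                Concept(tpp_id, "TPP", f"{brand} {strength:g} mg {form}, 28 pack")
            )
            edges.append(ConceptEdge(tpp_id, tpuu_id, "contains"))
            ctpp_id = new_id()
            concepts.append(
                Concept(
                    ctpp_id, "CTPP",
                    f"{brand} {strength:g} mg {form}, 28 pack, blister",
                )
            )
            edges.append(ConceptEdge(ctpp_id, tpp_id, "contains"))
        assignments.append(AtcAssignment(mpuu_id, atc, primary=True))
        ddd_table[atc] = DddReference(atc, ddd_mg, "mg")
        vendor_codes: dict[str, str] = {}
        for vendor in VENDORS:
            code = f"{vendor[:2].upper()}{code_counter[vendor]}"
            code_counter[vendor] += 1
            target = ctpp_id if (
                VENDOR_TARGET_KIND[vendor] == "CTPP" and ctpp_id is not None
            ) else tpuu_id
            mappings.append(VendorMapping(vendor, code, target))
            vendor_codes[vendor] = code
        drugs.append(
            DrugEntry(
                name=name, atc=atc, strength_mg=strength, ddd_mg=ddd_mg,
                class_label=classify_atc(atc, DEFAULT_RULES),
                mpuu_id=mpuu_id, tpuu_id=tpuu_id, ctpp_id=ctpp_id,
                vendor_codes=vendor_codes,
            )
        )
    bundle = TerminologyBundle.build(concepts, edges, mappings, assignments)
    return SynthTerminology(bundle=bundle, ddd_table=ddd_table, drugs=tuple(drugs))


# -- pharmacy data --------------------------------------------------------

def _instruction(rng, prn: bool) -> tuple[str, float]:
    """A parseable instruction string and its true units/day."""
    if rng.random() < 0.15:  # additive two-part instruction
        c1 = [0.5, 1.0, 2.0][rng.integers(0, 3)]
        c2 = [0.5, 1.0, 2.0][rng.integers(0, 3)]
        text = f"{_COUNT_WORDS[c1]} mane and {_COUNT_WORDS[c2]} nocte"
        units = c1 + c2
    else:
        c = [0.5, 1.0, 1.0, 2.0][rng.integers(0, 4)]
        f = _FREQS[rng.integers(0, len(_FREQS))]
        noise = " tablet" if rng.random() < 0.4 else ""
        text = f"{_COUNT_WORDS[c]}{noise} {f}"
        units = c * _FREQ_PER_DAY[f]
    if prn:
        text += " PRN"
    return text, units


def generate_pharmacy_data(
    config: GeneratorConfig, terms: SynthTerminology
) -> SynthDataset:
    """Generate homes, residents, medications and exports with injected
    errors; every generated record and injection lands in the ledger."""
    rng = np.random.default_rng(config.seed)
    key = f"synthetic-key-{config.seed}"
    sedatives = terms.sedatives
    distractors = terms.distractors

    home_ids = [f"H{i+1:02d}" for i in range(config.n_homes)]
    registry: dict[str, tuple[str, ...]] = {}
    wings_of: dict[str, list[str]] = {}
    for i, hid in enumerate(home_ids):
        hname = _HOME_NAMES[i % len(_HOME_NAMES)]
        if i >= len(_HOME_NAMES):  # keep wing names unique across many homes
            hname = f"{hname} {i // len(_HOME_NAMES) + 1}"
        wings = [f"{hname} North", f"{hname} South"]
        wings_of[hid] = wings
        registry[hid] = tuple(wings)

    # pharmacies: ~22% supply two homes, vendor style set by dialect_mix
    pharmacies: list[tuple[str, str, list[str]]] = []  # (id, vendor, homes)
    i = 0
    p = 0
    while i < len(home_ids):
        p += 1
        take = 2 if (i + 1 < len(home_ids) and rng.random() < 0.22) else 1
        if rng.random() < config.dialect_mix:
            vendor = VENDORS[int(rng.integers(0, 2))]
        else:
            vendor = VENDORS[2 + int(rng.integers(0, 2))]
        pharmacies.append((f"PH{p:02d}", vendor, home_ids[i:i + take]))
        i += take

    used_identities: set[tuple[str, str]] = set()
    true_residents: list[TrueResident] = []
    true_records: list[TrueRecord] = []
    exports: list[PharmacyExport] = []
    unmapped_counter = 1
    uid_counter = 1
    snapshot_date = config.snapshot_time.date()

    for pharmacy_id, vendor, homes in pharmacies:
        raw_residents: list[RawResident] = []
        raw_rows: list[RawMedicationRow] = []
        for hid in homes:
            n_res = max(5, int(round(rng.normal(
                config.residents_per_home_mean, config.residents_per_home_sd
            ))))
            for r_i in range(n_res):
                while True:
                    name = (
                        f"{_FIRST_NAMES[rng.integers(0, len(_FIRST_NAMES))]} "
                        f"{_LAST_NAMES[rng.integers(0, len(_LAST_NAMES))]}"
                    ).title()
                    birth = date(1920, 1, 1) + timedelta(
                        days=int(rng.integers(0, 365 * 35))
                    )
                    if (name.casefold(), birth.isoformat()) not in used_identities:
                        used_identities.add((name.casefold(), birth.isoformat()))
                        break
                wing = wings_of[hid][int(rng.integers(0, len(wings_of[hid])))]
                res_key = f"{pharmacy_id}-{hid}-R{r_i:04d}"
                rid = pseudonymize(name, birth, key)
                primary = TrueResident(
                    resident_key=res_key, name=name, birth_date=birth,
                    home_id=hid, wing=wing, resident_id=rid,
                    primary_resident_id=rid, is_duplicate=False,
                )
                true_residents.append(primary)
                raw_residents.append(RawResident(res_key, name, birth, wing))

                n_meds = max(1, int(rng.poisson(config.meds_per_resident_mean)))
                sed_flags = rng.random(n_meds) < config.sedative_fraction
                n_sed = min(int(sed_flags.sum()), len(sedatives))
                n_dis = min(n_meds - n_sed, len(distractors))
                sed_pick = rng.choice(len(sedatives), size=n_sed, replace=False)
                dis_pick = rng.choice(len(distractors), size=n_dis, replace=False)
                meds = [sedatives[j] for j in sed_pick] + [
                    distractors[j] for j in dis_pick
                ]

                dup_profile: TrueResident | None = None
                if config.duplicate_resident_rate and len(meds) >= 2 and (
                    rng.random() < config.duplicate_resident_rate
                ):
                    dup_name = f"{name} (2)"
                    dup_key = f"{res_key}b"
                    dup_rid = pseudonymize(dup_name, birth, key)
                    dup_profile = TrueResident(
                        resident_key=dup_key, name=dup_name, birth_date=birth,
                        home_id=hid, wing=wing, resident_id=dup_rid,
                        primary_resident_id=rid, is_duplicate=True,
                    )
                    true_residents.append(dup_profile)
                    raw_residents.append(
                        RawResident(dup_key, dup_name, birth, wing)
                    )

                for m_i, drug in enumerate(meds):
                    is_sed = drug.class_label != "NONE"
                    prn_p = (
                        config.prn_fraction if is_sed
                        else config.distractor_prn_fraction
                    )
                    prn = bool(rng.random() < prn_p)
                    instructions, units_per_day = _instruction(rng, prn)
                    dose = units_per_day * drug.strength_mg
                    quantity = int(math.ceil(units_per_day * 28))
                    started = snapshot_date - timedelta(
                        days=int(rng.integers(10, 400))
                    )
                    ceased = None
                    current = True
                    if rng.random() < config.ceased_rate:
                        ceased = started + timedelta(days=int(rng.integers(1, 9)))
                        current = ceased >= snapshot_date
                    prescriber = (
                        f"Dr {_LAST_NAMES[rng.integers(0, len(_LAST_NAMES))].title()}"
                    )
                    # at most one injected error mode per record
                    injected = None
                    u = rng.random()
                    if is_sed and current:
                        omit_p = (
                            config.prn_omission_rate if prn
                            else config.regular_omission_rate
                        )
                        thresholds = [
                            ("omitted", omit_p),
                            ("missing_dose", config.missing_dose_rate),
                            ("unmapped", config.unmapped_medication_rate),
                            ("transposed", config.transposed_field_rate),
                        ]
                    else:
                        thresholds = [("transposed", config.transposed_field_rate)]
                    acc = 0.0
                    for label, prob in thresholds:
                        acc += prob
                        if u < acc:
                            injected = label
                            break

                    code = drug.vendor_codes[vendor]
                    export_code = code
                    export_instructions = instructions
                    export_quantity = quantity
                    export_prescriber = prescriber
                    if injected == "unmapped":
                        export_code = f"XU{unmapped_counter}"
                        unmapped_counter += 1
                    elif injected == "missing_dose":
                        export_quantity = None
                        export_instructions = "take as directed" + (
                            " PRN" if prn else ""
                        )
                    elif injected == "transposed":
                        export_instructions, export_prescriber = (
                            prescriber, instructions
                        )

                    profile = primary
                    if dup_profile is not None and m_i % 2 == 1:
                        profile = dup_profile  # split pack across profiles
                    target = drug.ctpp_id if (
                        VENDOR_TARGET_KIND[vendor] == "CTPP"
                        and drug.ctpp_id is not None
                    ) else drug.tpuu_id
                    true_records.append(
                        TrueRecord(
                            uid=f"T{uid_counter:07d}",
                            home_id=hid, pharmacy_id=pharmacy_id,
                            owner_resident_id=rid,
                            profile_resident_id=profile.resident_id,
                            resident_key=profile.resident_key,
                            vendor=vendor, vendor_code=export_code,
                            true_target_concept=target,
                            med_name=drug.name,
                            true_instructions=instructions,
                            export_instructions=export_instructions,
                            quantity_supplied=quantity,
                            export_quantity=export_quantity,
                            prescriber=prescriber,
                            export_prescriber=export_prescriber,
                            date_started=started, date_ceased=ceased,
                            current=current,
                            atc=drug.atc, mpuu_id=drug.mpuu_id,
                            class_label=drug.class_label, prn=prn,
                            daily_dose_mg=dose, injected=injected,
                        )
                    )
                    uid_counter += 1
                    if injected == "omitted":
                        continue  # present in the ledger, absent from the file
                    raw_rows.append(
                        RawMedicationRow(
                            vendor_med_id=export_code,
                            med_name=drug.name,
                            instructions=export_instructions,
                            quantity_supplied=export_quantity,
                            date_started=started,
                            date_ceased=ceased,
                            prescriber=export_prescriber,
                            resident_key=profile.resident_key,
                            wing_name=profile.wing,
                        )
                    )
        exports.append(
            PharmacyExport(
                pharmacy_id=pharmacy_id,
                vendor=vendor,
                dialect=VENDOR_DIALECT[vendor],
                home_ids=tuple(homes),
                residents=tuple(raw_residents),
                rows=tuple(raw_rows),
            )
        )

    counts = {
        "homes": len(home_ids),
        "pharmacies": len(pharmacies),
        "residents": sum(1 for r in true_residents if not r.is_duplicate),
        "duplicate_profiles": sum(1 for r in true_residents if r.is_duplicate),
        "records": len(true_records),
        "sedative_records": sum(
            1 for t in true_records if t.class_label != "NONE"
        ),
        "omitted": sum(1 for t in true_records if t.injected == "omitted"),
        "missing_dose": sum(
            1 for t in true_records if t.injected == "missing_dose"
        ),
        "unmapped": sum(1 for t in true_records if t.injected == "unmapped"),
        "transposed": sum(1 for t in true_records if t.injected == "transposed"),
    }
    return SynthDataset(
        config=config,
        key=key,
        terminology=terms,
        home_registry={h: tuple(w) for h, w in registry.items()},
        pharmacies=tuple(exports),
        ledger=GroundTruthLedger(
            records=tuple(true_records),
            residents=tuple(true_residents),
            counts=counts,
        ),
    )


def generate_dataset(config: GeneratorConfig) -> SynthDataset:
    """Terminology + pharmacy data in one call."""
    return generate_pharmacy_data(config, generate_terminology(config))


def write_dataset(dataset: SynthDataset, out_dir) -> dict[str, str]:
    """Write the whole fixture tree (terminology TSVs, ddd.tsv, registry,
    key, one export file per pharmacy in its dialect). Returns a manifest of
    written paths. Identical datasets write byte-identical files."""
    import json

    out = Path(out_dir)
    term_dir = out / "terminology"
    save_bundle(dataset.terminology.bundle, term_dir)
    save_ddd_table(dataset.terminology.ddd_table, term_dir / "ddd.tsv")
    (out / "home_registry.json").write_text(
        json.dumps({h: list(w) for h, w in dataset.home_registry.items()}, indent=1)
        + "\n",
        encoding="utf-8",
    )
    (out / "key.txt").write_text(dataset.key + "\n", encoding="utf-8")
    manifest = {"terminology": str(term_dir)}
    for ph in dataset.pharmacies:
        path = out / f"{ph.pharmacy_id}.{ph.dialect}.tsv"
        write_export(
            path, ph.dialect, ph.rows, ph.residents,
            pharmacy_id=ph.pharmacy_id, vendor=ph.vendor,
        )
        manifest[ph.pharmacy_id] = str(path)
    return manifest


# -- session log ----------------------------------------------------------

@dataclass(frozen=True)
class SessionLog:
    entries: tuple[TransactionLogEntry, ...]  # includes derived cascades
    events: tuple[tuple[str, str, datetime], ...]
    final_state: PipelineState

    @property
    def corrections(self) -> tuple[TransactionLogEntry, ...]:
        """Data-changing entries only (no sign-offs, no cascades)."""
        from .validation import is_correction

        return tuple(e for e in self.entries if is_correction(e))


def generate_session_log(
    config: GeneratorConfig,
    ledger: GroundTruthLedger,
    state: PipelineState,
) -> SessionLog:
    """Phase-labelled corrections that exactly repair the injected errors.

    P1 adds terminology mappings for unmapped codes, P2 untransposes
    swapped fields, P3 repairs missing dose data, adds omitted sedatives
    and marks every resident checked, P4 merges duplicate profiles.
    Corrections are applied while being generated so sequence numbers
    (including system cascades) are authoritative; the returned entry
    stream replays over the initial state to exactly the final state.
    Timestamped interaction events for the in-home phase are emitted for
    session-time estimation.
    """
    rng = np.random.default_rng(config.seed + 7)
    t0 = config.snapshot_time
    initial_len = len(state.log)
    by_key = {
        (m.resident_id, m.vendor, m.vendor_code): m.record_id
        for m in state.medications.values()
    }

    def rec_id(t: TrueRecord) -> str | None:
        return by_key.get((t.profile_resident_id, t.vendor, t.vendor_code))

    def apply(state, **kw):
        entry = TransactionLogEntry(seq=state.next_seq, **kw)
        return apply_correction(state, entry)

    ts = t0 + timedelta(days=1)
    # P1: one manual mapping per distinct unmapped vendor code
    seen_codes: set[tuple[str, str]] = set()
    for t in ledger.records:
        if t.injected != "unmapped" or not t.current:
            continue
        code_key = (t.vendor, t.vendor_code)
        if code_key in seen_codes:
            continue
        seen_codes.add(code_key)
        state = apply(
            state,
            phase="P1_mapping", actor_role="research_pharmacist",
            action="add", entity_kind="mapping",
            entity_id=f"{t.vendor}|{t.vendor_code}",
            field_changes=(
                ("vendor", None, t.vendor),
                ("vendor_code", None, t.vendor_code),
                ("target_concept_id", None, t.true_target_concept),
            ),
            timestamp=ts,
        )
    ts += timedelta(days=1)
    # P2: off-site validation untransposes swapped fields
    for t in ledger.records:
        if t.injected != "transposed" or not t.current:
            continue
        mid = rec_id(t)
        if mid is None:
            continue
        state = apply(
            state,
            phase="P2_offsite", actor_role="project_staff",
            action="modify", entity_kind="medication", entity_id=mid,
            field_changes=(
                ("instructions", t.export_instructions, t.true_instructions),
                ("prescriber", t.export_prescriber, t.prescriber),
            ),
            timestamp=ts,
        )
    ts += timedelta(days=1)
    # P3: in-home verification — repair doses, add omitted sedatives, check
    events: list[tuple[str, str, datetime]] = []
    add_counter = 1
    homes = sorted({r.home_id for r in state.current_residents()})
    for hid in homes:
        nurse = f"nurse-{hid}"
        ev_time = ts
        home_residents = {
            r.resident_id for r in state.current_residents(hid)
        }
        for t in ledger.records:
            if t.home_id != hid or not t.current:
                continue
            if t.injected == "missing_dose":
                mid = rec_id(t)
                if mid is None:
                    continue
                state = apply(
                    state,
                    phase="P3_inhome", actor_role="champion_nurse",
                    action="modify", entity_kind="medication", entity_id=mid,
                    field_changes=(
                        ("instructions", t.export_instructions, t.true_instructions),
                        ("quantity_supplied", None, t.quantity_supplied),
                    ),
                    timestamp=ev_time,
                )
                events.append((nurse, hid, ev_time))
                ev_time += timedelta(minutes=2)
            elif t.injected == "omitted":
                state = apply(
                    state,
                    phase="P3_inhome", actor_role="champion_nurse",
                    action="add", entity_kind="medication",
                    entity_id=f"add:{add_counter:06d}",
                    field_changes=(
                        ("resident_id", None, t.profile_resident_id),
                        ("vendor", None, t.vendor),
                        ("vendor_code", None, t.vendor_code),
                        ("med_name", None, t.med_name),
                        ("instructions", None, t.true_instructions),
                        ("quantity_supplied", None, t.quantity_supplied),
                        ("date_started", None, t.date_started),
                        ("prescriber", None, t.prescriber),
                        ("source", None, "manual"),
                    ),
                    timestamp=ev_time,
                )
                add_counter += 1
                events.append((nurse, hid, ev_time))
                ev_time += timedelta(minutes=2)
        for rid in sorted(home_residents):
            state = mark_checked(state, rid, timestamp=ev_time)
            events.append((nurse, hid, ev_time))
            ev_time += timedelta(seconds=30)
        ts += timedelta(hours=8)
    ts += timedelta(days=1)
    # P4: retrospective cleaning — merge duplicate profiles
    for r in ledger.residents:
        if not r.is_duplicate:
            continue
        if r.resident_id not in state.residents:
            continue
        state = merge_residents(
            state, r.resident_id, r.primary_resident_id,
            phase="P4_retrospective", timestamp=ts,
        )
    return SessionLog(
        entries=tuple(state.log[initial_len:]),
        events=tuple(events),
        final_state=state,
    )
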