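"""Reading packing-system exports, pseudonymization, and snapshot assembly.

Two text dialects stand in for the proprietary pharmacy packing systems:

``table_export``
    One tab-separated file containing three sections marked ``#[residents]``,
    ``#[wings]`` and ``#[medications]`` — the shape of a raw database export.
``report``
    One flat tab-separated file with repeated resident blocks, one row per
    medication — the shape of a generated medication report.

Both start with a header line ``#sedaudit-export<TAB>dialect=...`` declaring
the dialect, the pharmacy and the packing-software vendor. Malformed rows
are never dropped silently: every input row ends up parsed or in the reject
list, with its line number.

Residents are pseudonymized with a keyed digest of the normalized name and
birth date — deterministic (stable identity across snapshots) and
non-reversible (the package exposes no inverse).
"""

from __future__ import annotations

import hashlib
import hmac
import json
import re
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping

from ._util import (
    AmbiguousWingError,
    IntegrityError,
    UnsupportedFormatError,
    ValidationError,
)

DIALECTS = ("table_export", "report")

_MED_COLUMNS = (
    "resident_key",
    "vendor_med_id",
    "med_name",
    "instructions",
    "quantity_supplied",
    "date_started",
    "date_ceased",
    "prescriber",
)
_RESIDENT_COLUMNS = ("resident_key", "name", "birth_date", "wing_name")
_REPORT_COLUMNS = _RESIDENT_COLUMNS + _MED_COLUMNS[1:]


@dataclass(frozen=True)
class RawMedicationRow:
    vendor_med_id: str
    med_name: str
    instructions: str
    quantity_supplied: int | None
    date_started: date | None
    date_ceased: date | None
    prescriber: str | None
    resident_key: str
    wing_name: str


@dataclass(frozen=True)
class RawResident:
    resident_key: str
    name: str
    birth_date: date | None
    wing_name: str


@dataclass(frozen=True)
class RejectedRow:
    line_no: int
    reason: str
    raw: str


@dataclass(frozen=True)
class ExportData:
    dialect: str
    pharmacy_id: str
    vendor: str
    rows: tuple[RawMedicationRow, ...]
    residents: tuple[RawResident, ...]
    rejects: tuple[RejectedRow, ...]


@dataclass(frozen=True)
class ResidentProfile:
    resident_id: str
    display_token: str
    home_id: str
    wing: str
    source: str = "uploaded"  # uploaded | manual
    merged_into: str | None = None
    match_key: str = ""  # annotation-stripped identity digest, for dedup


@dataclass(frozen=True)
class MedicationRecord:
    """One packed medication line plus enrichment fields.

    ``display_name`` stays the vendor-supplied name even when the record is
    mapped through a chemically equivalent fallback concept, so nursing
    staff always see the name on the prescription.
    """

    record_id: str
    resident_id: str
    vendor: str
    vendor_code: str
    med_name: str
    instructions: str
    quantity_supplied: int | None = None
    date_started: date | None = None
    date_ceased: date | None = None
    prescriber: str | None = None
    display_name: str = ""
    vendor_prn_flag: bool | None = None
    source: str = "uploaded"
    # enrichment (filled by the pipeline)
    mpuu_id: object = None  # int, or terminology.UNMAPPED
    atc_code: str | None = None
    atc_codes: tuple[str, ...] = ()
    class_label: str = "PENDING"
    prn: bool = False
    schedule: object = None  # doseload.DoseSchedule
    daily_dose_mg: float | None = None


@dataclass(frozen=True)
class UploadSnapshot:
    pharmacy_id: str
    snapshot_label: str
    timestamp: datetime
    vendor: str
    home_ids: tuple[str, ...]
    residents: tuple[ResidentProfile, ...]
    medications: tuple[MedicationRecord, ...]
    counts: Mapping[str, int] = field(default_factory=dict)
    schema_version: int = 1


# -- pseudonymization -----------------------------------------------------

_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)
_ANNOTATION = re.compile(r"\([^)]*\)")


def normalize_name(name: str) -> str:
    """Case-fold, resolve 'Surname, Given' ordering, strip punctuation,
    collapse whitespace."""
    text = name.strip()
    if "," in text:
        head, _, tail = text.partition(",")
        text = f"{tail.strip()} {head.strip()}"
    text = _PUNCT.sub(" ", text.casefold())
    return " ".join(text.split())


def strip_annotations(name: str) -> str:
    """Remove parenthetical pack annotations like '(pack 2)' before matching."""
    return _ANNOTATION.sub(" ", name)


def pseudonymize(name: str, birth_date: date | None, key: str) -> str:
    """Deterministic keyed digest of (normalized name, birth date).

    Identical inputs under the same key always give the same id; there is no
    inverse. When the source system supplies no birth date, identity falls
    back to the name alone.
    """
    if not name or not name.strip():
        raise ValidationError("resident name must be non-empty")
    normalized = normalize_name(name)
    bd = birth_date.isoformat() if birth_date is not None else ""
    digest = hmac.new(
        key.encode("utf-8"), f"{normalized}|{bd}".encode("utf-8"), hashlib.sha256
    )
    return digest.hexdigest()[:24]


def display_token(name: str, birth_date: date | None) -> str:
    """Short human-checkable token: initial + surname stem + birth year."""
    parts = normalize_name(strip_annotations(name)).split()
    initial = parts[0][0].upper() if parts else "?"
    surname = parts[-1][:3].upper() if len(parts) > 1 else (parts[0][:3].upper() if parts else "???")
    year = str(birth_date.year) if birth_date else "----"
    return f"{initial}.{surname}.{year}"


# -- export reading/writing ----------------------------------------------

def _parse_header(line: str) -> dict[str, str]:
    if not line.startswith("#sedaudit-export"):
        raise UnsupportedFormatError(
            "file does not declare a supported packing-export format"
        )
    meta = {}
    for chunk in line.rstrip("\n").split("\t")[1:]:
        if "=" in chunk:
            k, _, v = chunk.partition("=")
            meta[k] = v
    return meta


def _opt_date(text: str, errors: list[str]) -> date | None:
    if not text:
        return None
    try:
        return date.fromisoformat(text)
    except ValueError:
        errors.append(f"bad date {text!r}")
        return None


def _parse_med_fields(fields: dict[str, str], line_no: int, wing_lookup) -> tuple:
    """Returns (RawMedicationRow|None, RejectedRow|None)."""
    raw = "\t".join(fields.values())
    problems: list[str] = []
    if not fields.get("vendor_med_id"):
        problems.append("missing vendor_med_id")
    if not fields.get("med_name"):
        problems.append("missing med_name")
    qty_text = fields.get("quantity_supplied", "")
    quantity: int | None = None
    if qty_text:
        try:
            quantity = int(qty_text)
            if quantity < 0:
                problems.append("negative quantity_supplied")
        except ValueError:
            problems.append(f"bad quantity {qty_text!r}")
    started = _opt_date(fields.get("date_started", ""), problems)
    ceased = _opt_date(fields.get("date_ceased", ""), problems)
    if started and ceased and ceased < started:
        problems.append("date_ceased before date_started")
    if problems:
        return None, RejectedRow(line_no, "; ".join(problems), raw)
    row = RawMedicationRow(
        vendor_med_id=fields["vendor_med_id"],
        med_name=fields["med_name"],
        instructions=fields.get("instructions", ""),
        quantity_supplied=quantity,
        date_started=started,
        date_ceased=ceased,
        prescriber=fields.get("prescriber") or None,
        resident_key=fields["resident_key"],
        wing_name=wing_lookup(fields["resident_key"]),
    )
    return row, None


def read_export(path, dialect: str) -> ExportData:
    """Parse an export file; the declared dialect must match ``dialect``.

    Every body row is either parsed or recorded in the reject list with its
    line number (no silent loss: rows_in == rows_parsed + rows_rejected).
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise UnsupportedFormatError(f"{path} is empty")
    meta = _parse_header(lines[0])
    declared = meta.get("dialect")
    if declared not in DIALECTS:
        raise UnsupportedFormatError(f"unknown dialect {declared!r} in {path}")
    if declared != dialect:
        raise UnsupportedFormatError(
            f"{path} declares dialect {declared!r}, expected {dialect!r}"
        )
    pharmacy = meta.get("pharmacy", "")
    vendor = meta.get("vendor", "")
    if dialect == "table_export":
        rows, residents, rejects = _read_table_export(lines[1:])
    else:
        rows, residents, rejects = _read_report(lines[1:])
    return ExportData(
        dialect=dialect,
        pharmacy_id=pharmacy,
        vendor=vendor,
        rows=tuple(rows),
        residents=tuple(residents),
        rejects=tuple(rejects),
    )


def _read_table_export(lines):
    sections: dict[str, list[tuple[int, str]]] = {}
    current = None
    for i, line in enumerate(lines, start=2):
        if line.startswith("#["):
            current = line.strip("#[] \t")
            sections.setdefault(current, [])
        elif line.strip():
            if current is None:
                continue
            sections[current].append((i, line))
    residents: list[RawResident] = []
    rejects: list[RejectedRow] = []
    wing_of: dict[str, str] = {}
    res_rows = sections.get("residents", [])
    for line_no, line in res_rows[1:] if res_rows else []:
        parts = line.split("\t")
        if len(parts) != len(_RESIDENT_COLUMNS):
            rejects.append(RejectedRow(line_no, "wrong column count", line))
            continue
        fields = dict(zip(_RESIDENT_COLUMNS, parts))
        problems: list[str] = []
        if not fields["name"]:
            problems.append("missing name")
        bd = _opt_date(fields["birth_date"], problems)
        if problems:
            rejects.append(RejectedRow(line_no, "; ".join(problems), line))
            continue
        residents.append(
            RawResident(fields["resident_key"], fields["name"], bd, fields["wing_name"])
        )
        wing_of[fields["resident_key"]] = fields["wing_name"]
    rows: list[RawMedicationRow] = []
    med_rows = sections.get("medications", [])
    for line_no, line in med_rows[1:] if med_rows else []:
        parts = line.split("\t")
        if len(parts) != len(_MED_COLUMNS):
            rejects.append(RejectedRow(line_no, "wrong column count", line))
            continue
        fields = dict(zip(_MED_COLUMNS, parts))
        row, reject = _parse_med_fields(
            fields, line_no, lambda k: wing_of.get(k, "")
        )
        if reject:
            rejects.append(reject)
        else:
            rows.append(row)
    return rows, residents, rejects


def _read_report(lines):
    residents: list[RawResident] = []
    seen_keys: set[str] = set()
    rows: list[RawMedicationRow] = []
    rejects: list[RejectedRow] = []
    body = [l for l in lines if l.strip()]
    for line_no, line in enumerate(body[1:], start=3) if body else []:
        parts = line.split("\t")
        if len(parts) != len(_REPORT_COLUMNS):
            rejects.append(RejectedRow(line_no, "wrong column count", line))
            continue
        fields = dict(zip(_REPORT_COLUMNS, parts))
        problems: list[str] = []
        if not fields["name"]:
            problems.append("missing name")
        bd = _opt_date(fields["birth_date"], problems)
        if problems:
            rejects.append(RejectedRow(line_no, "; ".join(problems), line))
            continue
        key = fields["resident_key"]
        if key not in seen_keys:
            seen_keys.add(key)
            residents.append(RawResident(key, fields["name"], bd, fields["wing_name"]))
        if not fields["vendor_med_id"] and not fields["med_name"]:
            continue  # resident-only block row (resident with no packed meds)
        row, reject = _parse_med_fields(
            fields, line_no, lambda k, w=fields["wing_name"]: w
        )
        if reject:
            rejects.append(reject)
        else:
            rows.append(row)
    return rows, residents, rejects


def write_export(
    path,
    dialect: str,
    rows: Iterable[RawMedicationRow],
    residents: Iterable[RawResident],
    pharmacy_id: str,
    vendor: str,
) -> None:
    """Render rows/residents in one of the two dialects (round-trippable)."""
    if dialect not in DIALECTS:
        raise UnsupportedFormatError(f"unknown dialect {dialect!r}")
    residents = list(residents)
    rows = list(rows)
    header = (
        f"#sedaudit-export\tdialect={dialect}\tversion=1"
        f"\tpharmacy={pharmacy_id}\tvendor={vendor}"
    )
    lines = [header]

    def _d(v):
        return v.isoformat() if v else ""

    def _med_fields(r: RawMedicationRow) -> list[str]:
        return [
            r.vendor_med_id,
            r.med_name,
            r.instructions,
            "" if r.quantity_supplied is None else str(r.quantity_supplied),
            _d(r.date_started),
            _d(r.date_ceased),
            r.prescriber or "",
        ]

    if dialect == "table_export":
        lines.append("#[residents]")
        lines.append("\t".join(_RESIDENT_COLUMNS))
        for res in residents:
            lines.append(
                "\t".join([res.resident_key, res.name, _d(res.birth_date), res.wing_name])
            )
        lines.append("#[wings]")
        lines.append("wing_name")
        for wing in sorted({res.wing_name for res in residents}):
            lines.append(wing)
        lines.append("#[medications]")
        lines.append("\t".join(_MED_COLUMNS))
        for r in rows:
            lines.append("\t".join([r.resident_key] + _med_fields(r)))
    else:
        lines.append("\t".join(_REPORT_COLUMNS))
        res_by_key = {res.resident_key: res for res in residents}
        meds_by_key: dict[str, list[RawMedicationRow]] = {}
        for r in rows:
            meds_by_key.setdefault(r.resident_key, []).append(r)
        for key, res in res_by_key.items():
            res_fields = [res.resident_key, res.name, _d(res.birth_date), res.wing_name]
            meds = meds_by_key.get(key, [])
            if not meds:
                lines.append("\t".join(res_fields + [""] * 7))
            for r in meds:
                lines.append("\t".join(res_fields + _med_fields(r)))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# -- wing/home linkage ----------------------------------------------------

def load_home_registry(path) -> dict[str, list[str]]:
    """JSON mapping home_id -> accepted wing names/aliases."""
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def link_wings(
    wing_names: Iterable[str], home_registry: Mapping[str, Iterable[str]]
) -> tuple[dict[str, str], list[str]]:
    """Assign each pharmacy wing name to a participating home.

    Matching is case-insensitive on the registry's accepted aliases. Returns
    (assignment, unassigned). A wing matching two homes is an ambiguity the
    operator must resolve in the registry, not a guess.
    """
    alias_map: dict[str, set[str]] = {}
    for home_id, aliases in home_registry.items():
        for alias in aliases:
            alias_map.setdefault(alias.strip().casefold(), set()).add(home_id)
    assignment: dict[str, str] = {}
    unassigned: list[str] = []
    for wing in wing_names:
        homes = alias_map.get(wing.strip().casefold(), set())
        if len(homes) > 1:
            raise AmbiguousWingError(
                f"wing {wing!r} matches multiple homes: {sorted(homes)}"
            )
        if homes:
            assignment[wing] = next(iter(homes))
        else:
            unassigned.append(wing)
    return assignment, unassigned


# -- snapshot assembly ----------------------------------------------------

def assemble_upload(
    rows: Iterable[RawMedicationRow],
    residents: Iterable[RawResident],
    wing_assignment: Mapping[str, str],
    timestamp: datetime,
    *,
    pharmacy_id: str,
    vendor: str,
    key: str,
    snapshot_label: str = "baseline",
) -> UploadSnapshot:
    """Build a point-in-time snapshot from parsed export content.

    Excludes records ceased before the snapshot timestamp and residents in
    wings not linked to a participating home; both exclusions are counted,
    never silent. One upload may span several homes (a pharmacy commonly
    supplies more than one).
    """
    rows = list(rows)
    residents = list(residents)
    counts: dict[str, int] = {
        "rows_in": len(rows),
        "excluded_ceased": 0,
        "excluded_unassigned_residents": 0,
        "excluded_unassigned_medications": 0,
    }
    profiles: dict[str, ResidentProfile] = {}
    key_to_id: dict[str, str] = {}
    for res in residents:
        home = wing_assignment.get(res.wing_name)
        if home is None:
            counts["excluded_unassigned_residents"] += 1
            continue
        rid = pseudonymize(res.name, res.birth_date, key)
        key_to_id[res.resident_key] = rid
        if rid not in profiles:
            core = strip_annotations(res.name)
            profiles[rid] = ResidentProfile(
                resident_id=rid,
                display_token=display_token(res.name, res.birth_date),
                home_id=home,
                wing=res.wing_name,
                source="uploaded",
                match_key=pseudonymize(core, res.birth_date, key),
            )
    known_keys = {r.resident_key for r in residents}
    orphans = sorted({r.resident_key for r in rows if r.resident_key not in known_keys})
    if orphans:
        raise IntegrityError(
            f"medication rows reference unknown residents: {orphans}"
        )
    medications: list[MedicationRecord] = []
    snapshot_date = timestamp.date()
    for i, r in enumerate(rows):
        rid = key_to_id.get(r.resident_key)
        if rid is None:
            counts["excluded_unassigned_medications"] += 1
            continue
        if r.date_ceased is not None and r.date_ceased < snapshot_date:
            counts["excluded_ceased"] += 1
            continue
        medications.append(
            MedicationRecord(
                record_id=f"{pharmacy_id}:m{i:06d}",
                resident_id=rid,
                vendor=vendor,
                vendor_code=r.vendor_med_id,
                med_name=r.med_name,
                display_name=r.med_name,
                instructions=r.instructions,
                quantity_supplied=r.quantity_supplied,
                date_started=r.date_started,
                date_ceased=r.date_ceased,
                prescriber=r.prescriber,
            )
        )
    home_ids = tuple(sorted({p.home_id for p in profiles.values()}))
    for p in profiles.values():
        counts[f"residents:{p.home_id}"] = counts.get(f"residents:{p.home_id}", 0) + 1
    for m in medications:
        home = profiles[m.resident_id].home_id
        counts[f"medications:{home}"] = counts.get(f"medications:{home}", 0) + 1
    counts["residents_total"] = len(profiles)
    counts["medications_total"] = len(medications)
    return UploadSnapshot(
        pharmacy_id=pharmacy_id,
        snapshot_label=snapshot_label,
        timestamp=timestamp,
        vendor=vendor,
        home_ids=home_ids,
        residents=tuple(profiles.values()),
        medications=tuple(medications),
        counts=counts,
    )
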