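"""Four-phase validation/verification workflow over an immutable log.

The audit dataset is event-sourced: the live state is a pure function of
the ingested snapshot and an append-only transaction log. Corrections flow
through four phases —

P1_mapping        resolving medications the terminology could not link
P2_offsite        off-site validation by project staff
P3_inhome         in-home verification by the champion nurse
P4_retrospective  retrospective cleaning, chiefly duplicate-resident merges

— plus ``ingest`` and ``manual_entry`` for bookkeeping. Deleting a resident
cascades to their medications; the cascade is itself logged as
system-generated entries so replaying the full log reproduces the live
state exactly.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from typing import Callable, Iterable, Mapping

import pandas as pd

from ._util import ContractViolation, IntegrityError, LogError, pct
from .classify import PENDING, SEDATIVE_CLASSES, SedativeRuleSet
from .doseload import DddReference, ddd_ratio
from .enrich import enrich_record
from .ingest import MedicationRecord, ResidentProfile
from .terminology import TerminologyBundle, add_manual_mapping

PHASES = (
    "P1_mapping",
    "P2_offsite",
    "P3_inhome",
    "P4_retrospective",
    "ingest",
    "manual_entry",
)
CORRECTION_PHASES = PHASES[:4]
ACTOR_ROLES = ("system", "research_pharmacist", "project_staff", "champion_nurse")
ACTIONS = ("add", "modify", "delete", "merge")
ENTITY_KINDS = ("resident", "medication", "mapping")

#: Suspect-flag reasons that block home verification when on a sedative.
BLOCKING_REASONS = ("missing_dose_quantity", "unmapped_medication")


@dataclass(frozen=True)
class TransactionLogEntry:
    seq: int
    phase: str
    actor_role: str
    action: str
    entity_kind: str
    entity_id: str
    field_changes: tuple[tuple[str, object, object], ...]
    timestamp: datetime
    derived: bool = False  # system-generated cascade entry
    note: str = ""

    def __post_init__(self):
        if self.phase not in PHASES:
            raise LogError(f"unknown phase {self.phase!r}")
        if self.actor_role not in ACTOR_ROLES:
            raise LogError(f"unknown actor role {self.actor_role!r}")
        if self.action not in ACTIONS:
            raise LogError(f"unknown action {self.action!r}")
        if self.entity_kind not in ENTITY_KINDS:
            raise LogError(f"unknown entity kind {self.entity_kind!r}")
        if self.action == "modify" and not self.field_changes:
            raise LogError("modify entries must carry at least one field change")


@dataclass(frozen=True)
class SuspectFlag:
    entity_id: str
    reason: str
    detail: str = ""


@dataclass(frozen=True)
class VerificationStatus:
    home_id: str
    verified: bool
    unchecked_residents: tuple[str, ...] = ()
    blocking_flags: tuple[SuspectFlag, ...] = ()


@dataclass(frozen=True)
class PipelineState:
    """Immutable audit state; corrections return a new state."""

    residents: Mapping[str, ResidentProfile]
    medications: Mapping[str, MedicationRecord]
    checked: frozenset[str]
    log: tuple[TransactionLogEntry, ...]
    bundle: TerminologyBundle
    rules: SedativeRuleSet
    ddd_table: Mapping[str, DddReference]
    equivalents: Mapping[str, float] | None = None

    @property
    def next_seq(self) -> int:
        return len(self.log) + 1

    def current_residents(self, home_id: str | None = None) -> list[ResidentProfile]:
        out = [r for r in self.residents.values() if r.merged_into is None]
        if home_id is not None:
            out = [r for r in out if r.home_id == home_id]
        return out

    def medications_of(self, resident_id: str) -> list[MedicationRecord]:
        return [m for m in self.medications.values() if m.resident_id == resident_id]


_MED_FIELDS = {
    "resident_id", "vendor", "vendor_code", "med_name", "instructions",
    "quantity_supplied", "date_started", "date_ceased", "prescriber",
    "vendor_prn_flag", "source",
}
_REENRICH_TRIGGERS = {"vendor", "vendor_code", "instructions", "vendor_prn_flag"}
_RES_FIELDS = {"display_token", "home_id", "wing", "source", "match_key"}


def _dup_key(m: MedicationRecord):
    """Exact-duplicate key: same MPUU, same schedule text, same dates."""
    return (
        m.mpuu_id if isinstance(m.mpuu_id, int) else None,
        m.vendor_code,
        " ".join(m.instructions.lower().split()),
        m.date_started,
        m.date_ceased,
    )


def _apply_one(
    residents: dict,
    medications: dict,
    checked: set,
    bundle_box: list,
    rules,
    entry: TransactionLogEntry,
) -> list[TransactionLogEntry]:
    """Mutate the working copies for one entry; return cascade entries to
    materialize (without seq numbers — the caller assigns them)."""
    bundle = bundle_box[0]
    kind, action = entry.entity_kind, entry.action
    changes = {f: new for f, _old, new in entry.field_changes}
    cascades: list[TransactionLogEntry] = []

    if kind == "medication" and action == "add":
        if entry.entity_id in medications:
            raise IntegrityError(f"medication {entry.entity_id} already exists")
        rid = changes.get("resident_id")
        if rid not in residents or residents[rid].merged_into is not None:
            raise IntegrityError(
                f"medication {entry.entity_id} references unknown resident {rid}"
            )
        rec = MedicationRecord(
            record_id=entry.entity_id,
            resident_id=rid,
            vendor=changes.get("vendor", ""),
            vendor_code=changes.get("vendor_code", ""),
            med_name=changes.get("med_name", ""),
            display_name=changes.get("med_name", ""),
            instructions=changes.get("instructions", ""),
            quantity_supplied=changes.get("quantity_supplied"),
            date_started=changes.get("date_started"),
            date_ceased=changes.get("date_ceased"),
            prescriber=changes.get("prescriber"),
            vendor_prn_flag=changes.get("vendor_prn_flag"),
            source=changes.get("source", "manual"),
        )
        medications[entry.entity_id] = enrich_record(rec, bundle, rules)
    elif kind == "medication" and action == "modify":
        rec = medications.get(entry.entity_id)
        if rec is None:
            raise IntegrityError(f"unknown medication {entry.entity_id}")
        bad = set(changes) - _MED_FIELDS
        if bad:
            raise LogError(f"cannot modify medication fields {sorted(bad)}")
        if "resident_id" in changes:
            rid = changes["resident_id"]
            if rid not in residents:
                raise IntegrityError(f"target resident {rid} does not exist")
        rec = replace(rec, **changes)
        if _REENRICH_TRIGGERS & set(changes) or "quantity_supplied" in changes:
            rec = enrich_record(rec, bundle, rules)
        medications[entry.entity_id] = rec
    elif kind == "medication" and action == "delete":
        if entry.entity_id not in medications:
            raise IntegrityError(f"unknown medication {entry.entity_id}")
        del medications[entry.entity_id]

    elif kind == "resident" and action == "add":
        if entry.entity_id in residents:
            raise IntegrityError(f"resident {entry.entity_id} already exists")
        residents[entry.entity_id] = ResidentProfile(
            resident_id=entry.entity_id,
            display_token=changes.get("display_token", ""),
            home_id=changes.get("home_id", ""),
            wing=changes.get("wing", ""),
            source=changes.get("source", "manual"),
            match_key=changes.get("match_key", ""),
        )
    elif kind == "resident" and action == "modify":
        prof = residents.get(entry.entity_id)
        if prof is None:
            raise IntegrityError(f"unknown resident {entry.entity_id}")
        if "checked" in changes:
            if changes["checked"]:
                checked.add(entry.entity_id)
            else:
                checked.discard(entry.entity_id)
            changes = {k: v for k, v in changes.items() if k != "checked"}
        if changes:
            bad = set(changes) - _RES_FIELDS
            if bad:
                raise LogError(f"cannot modify resident fields {sorted(bad)}")
            residents[entry.entity_id] = replace(prof, **changes)
    elif kind == "resident" and action == "delete":
        prof = residents.get(entry.entity_id)
        if prof is None:
            raise IntegrityError(f"unknown resident {entry.entity_id}")
        del residents[entry.entity_id]
        checked.discard(entry.entity_id)
        # cascade: a departed resident's medications are excluded with them
        for mid in sorted(
            m.record_id
            for m in medications.values()
            if m.resident_id == entry.entity_id
        ):
            cascades.append(
                TransactionLogEntry(
                    seq=0,
                    phase=entry.phase,
                    actor_role="system",
                    action="delete",
                    entity_kind="medication",
                    entity_id=mid,
                    field_changes=(),
                    timestamp=entry.timestamp,
                    derived=True,
                    note=f"cascade of resident delete {entry.entity_id}",
                )
            )
    elif kind == "resident" and action == "merge":
        source = entry.entity_id
        target = changes.get("merged_into")
        if source == target:
            raise ContractViolation("cannot merge a resident into itself")
        src = residents.get(source)
        tgt = residents.get(target)
        if src is None or tgt is None:
            raise IntegrityError(f"merge references unknown resident(s) {source}, {target}")
        if src.merged_into is not None or tgt.merged_into is not None:
            raise IntegrityError("cannot merge an already-merged profile")
        if src.home_id != tgt.home_id and "cross_home_override" not in entry.note:
            raise IntegrityError(
                f"refusing cross-home merge {source} ({src.home_id}) -> "
                f"{target} ({tgt.home_id}); requires explicit override"
            )
        target_keys = {
            _dup_key(m) for m in medications.values() if m.resident_id == target
        }
        for mid in sorted(
            m.record_id for m in medications.values() if m.resident_id == source
        ):
            m = medications[mid]
            key = _dup_key(m)
            if key in target_keys:
                # exact duplicate row collapses rather than moving across
                cascades.append(
                    TransactionLogEntry(
                        seq=0, phase=entry.phase, actor_role="system",
                        action="delete", entity_kind="medication", entity_id=mid,
                        field_changes=(), timestamp=entry.timestamp, derived=True,
                        note=f"duplicate row collapsed in merge {source}->{target}",
                    )
                )
            else:
                target_keys.add(key)
                cascades.append(
                    TransactionLogEntry(
                        seq=0, phase=entry.phase, actor_role="system",
                        action="modify", entity_kind="medication", entity_id=mid,
                        field_changes=(("resident_id", source, target),),
                        timestamp=entry.timestamp, derived=True,
                        note=f"reassigned by merge {source}->{target}",
                    )
                )
        residents[source] = replace(src, merged_into=target)
        checked.discard(source)

    elif kind == "mapping" and action == "add":
        bundle_box[0] = add_manual_mapping(
            bundle,
            vendor=changes["vendor"],
            vendor_code=changes["vendor_code"],
            target_concept_id=changes["target_concept_id"],
            equivalent_of_name=changes.get("equivalent_of_name"),
        )
        # newly mapped: re-resolve any pending records with this code
        for mid, m in list(medications.items()):
            if (
                m.class_label == PENDING
                and m.vendor == changes["vendor"]
                and m.vendor_code == changes["vendor_code"]
            ):
                medications[mid] = enrich_record(m, bundle_box[0], rules)
    else:
        raise LogError(f"unsupported log action {action!r} on {kind!r}")
    return cascades


def apply_correction(state: PipelineState, entry: TransactionLogEntry) -> PipelineState:
    """Apply one correction, returning a new state (original untouched).

    The entry's seq must be exactly the state's next sequence number.
    Cascade effects (resident-delete exclusions, merge reassignments and
    duplicate collapses) are appended as derived system entries.
    """
    if entry.seq != state.next_seq:
        raise LogError(
            f"out-of-order log entry: got seq {entry.seq}, expected {state.next_seq}"
        )
    residents = dict(state.residents)
    medications = dict(state.medications)
    checked = set(state.checked)
    bundle_box = [state.bundle]
    cascades = _apply_one(residents, medications, checked, bundle_box, state.rules, entry)
    log = list(state.log) + [entry]
    pending = list(cascades)
    while pending:
        c = pending.pop(0)
        c = replace(c, seq=len(log) + 1)
        more = _apply_one(residents, medications, checked, bundle_box, state.rules, c)
        log.append(c)
        pending = more + pending
    return replace(
        state,
        residents=residents,
        medications=medications,
        checked=frozenset(checked),
        log=tuple(log),
        bundle=bundle_box[0],
    )


def record_correction(
    state: PipelineState,
    *,
    phase: str,
    actor_role: str,
    action: str,
    entity_kind: str,
    entity_id: str,
    changes: Iterable[tuple[str, object, object]] = (),
    timestamp: datetime | None = None,
    note: str = "",
) -> PipelineState:
    """Convenience wrapper: build an entry with the next seq and apply it."""
    entry = TransactionLogEntry(
        seq=state.next_seq,
        phase=phase,
        actor_role=actor_role,
        action=action,
        entity_kind=entity_kind,
        entity_id=entity_id,
        field_changes=tuple(changes),
        timestamp=timestamp or datetime(2000, 1, 1),
        note=note,
    )
    return apply_correction(state, entry)


def merge_residents(
    state: PipelineState,
    source_id: str,
    target_id: str,
    phase: str = "P4_retrospective",
    actor_role: str = "project_staff",
    timestamp: datetime | None = None,
    allow_cross_home: bool = False,
) -> PipelineState:
    """Merge a duplicate resident profile into its primary profile.

    Medications move to the target; exact-duplicate rows (same concept,
    schedule and dates — the split-pack signature) collapse to one; the
    source profile is retained, marked ``merged_into``.
    """
    if source_id == target_id:
        raise ContractViolation("cannot merge a resident into itself")
    return record_correction(
        state,
        phase=phase,
        actor_role=actor_role,
        action="merge",
        entity_kind="resident",
        entity_id=source_id,
        changes=(("merged_into", None, target_id),),
        timestamp=timestamp,
        note="cross_home_override" if allow_cross_home else "",
    )


def mark_checked(
    state: PipelineState,
    resident_id: str,
    actor_role: str = "champion_nurse",
    timestamp: datetime | None = None,
) -> PipelineState:
    """Record the in-home (P3) sign-off for one resident."""
    return record_correction(
        state,
        phase="P3_inhome",
        actor_role=actor_role,
        action="modify",
        entity_kind="resident",
        entity_id=resident_id,
        changes=(("checked", False, True),),
        timestamp=timestamp,
    )


def replay(initial_state: PipelineState, log: Iterable[TransactionLogEntry]) -> PipelineState:
    """Rebuild state deterministically from a log.

    Entries already present in the state (seq within its log) must match it
    exactly — this is how derived cascade entries in a full session log are
    consumed. A gap or reorder in seq is a log error.
    """
    state = initial_state
    last_seq = 0
    for entry in log:
        if entry.seq <= last_seq:
            raise LogError(f"log reorder: seq {entry.seq} after {last_seq}")
        last_seq = entry.seq
        if entry.seq < state.next_seq:
            if state.log[entry.seq - 1] != entry:
                raise LogError(
                    f"log mismatch at seq {entry.seq}: replayed entry differs"
                )
            continue
        if entry.seq > state.next_seq:
            raise LogError(
                f"log gap: got seq {entry.seq}, expected {state.next_seq}"
            )
        state = apply_correction(state, entry)
    return state


# -- suspect flagging -----------------------------------------------------

def flag_suspects(state: PipelineState, r_multiplier: float = 4.0) -> list[SuspectFlag]:
    """Recompute suspect flags from current state (derived, never stored).

    Sedative records are flagged for missing pack quantity, unparseable
    instructions, and daily doses outside the typical range (zero, or
    strictly above ``r_multiplier`` x DDD). Unmapped records are flagged
    pending a terminology mapping.
    """
    flags: list[SuspectFlag] = []
    live = {r.resident_id for r in state.current_residents()}
    for m in state.medications.values():
        if m.resident_id not in live:
            continue
        if m.class_label == PENDING:
            flags.append(
                SuspectFlag(m.record_id, "unmapped_medication", m.med_name)
            )
            continue
        if m.class_label not in SEDATIVE_CLASSES:
            continue
        if m.quantity_supplied is None:
            flags.append(
                SuspectFlag(m.record_id, "missing_dose_quantity", m.med_name)
            )
        if m.schedule is not None and m.schedule.parse_status != "parsed":
            flags.append(
                SuspectFlag(m.record_id, "unparseable_instructions", m.instructions)
            )
        if not m.med_name or m.date_started is None:
            flags.append(SuspectFlag(m.record_id, "missing_field", "date_started"))
        if m.daily_dose_mg is not None and m.atc_code in state.ddd_table:
            ratio = ddd_ratio(m.daily_dose_mg, m.atc_code, state.ddd_table)
            if m.daily_dose_mg == 0 or ratio > r_multiplier:
                flags.append(
                    SuspectFlag(
                        m.record_id,
                        "dose_out_of_range",
                        f"{m.daily_dose_mg} mg/day = {ratio:.2f} DDD",
                    )
                )
    return flags


def verify_home(
    state: PipelineState, home_id: str, r_multiplier: float = 4.0
) -> VerificationStatus:
    """A home is VERIFIED when every current resident has been explicitly
    checked in phase P3 and no blocking flags remain on its sedatives.
    Audit-report generation is gated on this status."""
    residents = state.current_residents(home_id)
    unchecked = tuple(
        sorted(r.resident_id for r in residents if r.resident_id not in state.checked)
    )
    home_residents = {r.resident_id for r in residents}
    blocking = tuple(
        f
        for f in flag_suspects(state, r_multiplier)
        if f.reason in BLOCKING_REASONS
        and state.medications.get(f.entity_id) is not None
        and state.medications[f.entity_id].resident_id in home_residents
    )
    return VerificationStatus(
        home_id=home_id,
        verified=not unchecked and not blocking,
        unchecked_residents=unchecked,
        blocking_flags=blocking,
    )


# -- duplicate-resident proposals ----------------------------------------

def propose_duplicates(
    state: PipelineState,
    fuzzy: bool = False,
    similarity_threshold: float = 0.88,
) -> list[tuple[str, str, float]]:
    """Candidate (source, target, score) duplicate-profile pairs.

    Default rule is conservative: profiles whose annotation-stripped
    identity keys collide (same person, split medication packs). Fuzzy
    display-token similarity is opt-in, because a false merge is worse than
    a miss in a medication audit. In an n-way collision the profile with
    the most medications becomes the single target. Proposals only —
    nothing is merged until applied.
    """
    residents = state.current_residents()
    by_key: dict[str, list[ResidentProfile]] = {}
    for r in residents:
        if r.match_key:
            by_key.setdefault(r.match_key, []).append(r)
    proposals: list[tuple[str, str, float]] = []
    proposed_pairs: set[tuple[str, str]] = set()

    def n_meds(rid: str) -> int:
        return sum(1 for m in state.medications.values() if m.resident_id == rid)

    for group in by_key.values():
        if len(group) < 2:
            continue
        target = max(group, key=lambda r: (n_meds(r.resident_id), r.resident_id))
        for r in group:
            if r.resident_id == target.resident_id:
                continue
            proposals.append((r.resident_id, target.resident_id, 1.0))
            proposed_pairs.add(
                tuple(sorted((r.resident_id, target.resident_id)))
            )
    if fuzzy:
        by_home: dict[str, list[ResidentProfile]] = {}
        for r in residents:
            by_home.setdefault(r.home_id, []).append(r)
        for group in by_home.values():
            group = sorted(group, key=lambda r: r.resident_id)
            for i, a in enumerate(group):
                for b in group[i + 1:]:
                    pair = tuple(sorted((a.resident_id, b.resident_id)))
                    if pair in proposed_pairs:
                        continue
                    score = difflib.SequenceMatcher(
                        None, a.display_token, b.display_token
                    ).ratio()
                    if score >= similarity_threshold:
                        src, tgt = (a, b) if n_meds(a.resident_id) <= n_meds(b.resident_id) else (b, a)
                        proposals.append((src.resident_id, tgt.resident_id, score))
                        proposed_pairs.add(pair)
    proposals.sort(key=lambda t: (-t[2], t[0]))
    return proposals


# -- correction accounting ------------------------------------------------

def is_correction(entry: TransactionLogEntry) -> bool:
    """A correction is a non-derived entry in a validation phase that
    changes data — per-resident 'checked' sign-offs are verification acts,
    not corrections, and system cascades are consequences, not decisions."""
    if entry.derived or entry.phase not in CORRECTION_PHASES:
        return False
    if (
        entry.entity_kind == "resident"
        and entry.action == "modify"
        and all(f == "checked" for f, _o, _n in entry.field_changes)
    ):
        return False
    return True


def correction_stats(
    log: Iterable[TransactionLogEntry],
    known_error_filter: Callable[[TransactionLogEntry], bool] | None = None,
) -> pd.DataFrame:
    """Per-phase correction counts and percentage shares.

    Counts every correction (see :func:`is_correction`) in the four
    validation phases. The optional predicate marks entries caused by known
    (since-fixed) extraction defects; the second column pair excludes them,
    mirroring the two-column accounting used when reporting correction
    burden with and without known error sources.
    """
    entries = [e for e in log if is_correction(e)]
    counts = {p: 0 for p in CORRECTION_PHASES}
    counts_excl = {p: 0 for p in CORRECTION_PHASES}
    for e in entries:
        counts[e.phase] += 1
        if known_error_filter is None or not known_error_filter(e):
            counts_excl[e.phase] += 1
    total = sum(counts.values())
    total_excl = sum(counts_excl.values())
    rows = []
    for p in CORRECTION_PHASES:
        rows.append(
            {
                "phase": p,
                "corrections": counts[p],
                "pct": pct(counts[p], total) if total else 0.0,
                "corrections_excl_known": counts_excl[p],
                "pct_excl_known": pct(counts_excl[p], total_excl) if total_excl else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["total"] = total
    df.attrs["total_excl_known"] = total_excl
    return df


# -- manual entry ---------------------------------------------------------

def manual_entry_session(
    state: PipelineState,
    entries: Iterable[TransactionLogEntry],
    prepopulate_from: PipelineState | None = None,
) -> tuple[PipelineState, list[str]]:
    """Apply a manual data-entry session (the no-upload fallback path).

    When a prior snapshot state is given, its residents and medications are
    copied forward first, so only the deltas need entering. Manually
    entered medications go through the same enrichment as uploads, so the
    downstream shape is identical. Manual mode expects sedatives only;
    non-sedative additions are accepted but reported as warnings.
    """
    if prepopulate_from is not None:
        state = replace(
            state,
            residents=dict(prepopulate_from.residents),
            medications=dict(prepopulate_from.medications),
            checked=prepopulate_from.checked,
        )
    warnings: list[str] = []
    for entry in entries:
        if entry.phase != "manual_entry":
            raise LogError("manual sessions must log entries in phase manual_entry")
        entry = replace(entry, seq=state.next_seq)
        state = apply_correction(state, entry)
        if entry.entity_kind == "medication" and entry.action == "add":
            rec = state.medications[entry.entity_id]
            if rec.class_label not in SEDATIVE_CLASSES and rec.class_label != PENDING:
                warnings.append(
                    f"non-sedative medication {rec.med_name!r} entered in manual mode"
                )
    return state, warnings


# -- log serialization (JSON lines, append-only) --------------------------

def _encode_value(v):
    if isinstance(v, date) and not isinstance(v, datetime):
        return {"$date": v.isoformat()}
    if isinstance(v, datetime):
        return {"$datetime": v.isoformat()}
    return v


def _decode_value(v):
    if isinstance(v, dict):
        if "$date" in v:
            return date.fromisoformat(v["$date"])
        if "$datetime" in v:
            return datetime.fromisoformat(v["$datetime"])
    return v


def log_to_jsonl(log: Iterable[TransactionLogEntry], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in log:
            fh.write(
                json.dumps(
                    {
                        "seq": e.seq,
                        "phase": e.phase,
                        "actor_role": e.actor_role,
                        "action": e.action,
                        "entity_kind": e.entity_kind,
                        "entity_id": e.entity_id,
                        "field_changes": [
                            [f, _encode_value(o), _encode_value(n)]
                            for f, o, n in e.field_changes
                        ],
                        "timestamp": e.timestamp.isoformat(),
                        "derived": e.derived,
                        "note": e.note,
                    }
                )
                + "\n"
            )


def log_from_jsonl(path) -> list[TransactionLogEntry]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(
                TransactionLogEntry(
                    seq=d["seq"],
                    phase=d["phase"],
                    actor_role=d["actor_role"],
                    action=d["action"],
                    entity_kind=d["entity_kind"],
                    entity_id=d["entity_id"],
                    field_changes=tuple(
                        (f, _decode_value(o), _decode_value(n))
                        for f, o, n in d["field_changes"]
                    ),
                    timestamp=datetime.fromisoformat(d["timestamp"]),
                    derived=d["derived"],
                    note=d["note"],
                )
            )
    return out
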