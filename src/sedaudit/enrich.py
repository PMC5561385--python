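"""Record enrichment: terminology resolution + classification + dosing.

One place computes every derived field of a MedicationRecord so uploaded
records, manually entered records, and records re-derived after a
correction all share exactly the same shape.
"""

from __future__ import annotations

from dataclasses import replace

from .classify import PENDING, SedativeRuleSet, classify_codes, detect_prn
from .doseload import daily_dose_mg, parse_schedule
from .ingest import MedicationRecord
from .terminology import (
    UNMAPPED,
    TerminologyBundle,
    all_atc_codes,
    resolve_to_mpuu,
)


def enrich_record(
    record: MedicationRecord,
    bundle: TerminologyBundle,
    rules: SedativeRuleSet,
) -> MedicationRecord:
    """Fill mpuu_id, ATC codes, class label, PRN flag, schedule and dose.

    The display name always stays the vendor-supplied medication name, even
    when resolution goes through a chemically-equivalent fallback mapping.
    """
    mpuu = resolve_to_mpuu(record.vendor, record.vendor_code, bundle)
    schedule = parse_schedule(record.instructions)
    prn = detect_prn(record.instructions, record.vendor_prn_flag) or schedule.prn
    if mpuu is UNMAPPED:
        return replace(
            record,
            mpuu_id=UNMAPPED,
            atc_code=None,
            atc_codes=(),
            class_label=PENDING,
            prn=prn,
            schedule=schedule,
            daily_dose_mg=None,
            display_name=record.med_name,
        )
    codes = all_atc_codes(mpuu, bundle)
    label = classify_codes(codes, rules) if codes else PENDING
    primary = None
    for a in bundle.atc_map.get(mpuu, ()):
        if a.primary:
            primary = a.atc_code
    strength = bundle.concepts[mpuu].strength_value
    dose = None
    if schedule.parse_status == "parsed" and strength:
        dose = daily_dose_mg(schedule, strength)
    return replace(
        record,
        mpuu_id=mpuu,
        atc_code=primary,
        atc_codes=codes,
        class_label=label,
        prn=prn,
        schedule=schedule,
        daily_dose_mg=dose,
        display_name=record.med_name,
    )
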