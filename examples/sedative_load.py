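"""Parse dosing instructions and compute a resident's sedative load.

Shows the instruction grammar, the DDD ratio, reference-drug equivalents
(diazepam for benzodiazepines, chlorpromazine for antipsychotics), and the
aggregation that excludes PRN sedatives.
"""

from sedaudit.classify import BENZODIAZEPINE, DEFAULT_RULES
from sedaudit.doseload import (
    daily_dose_mg,
    ddd_ratio,
    equivalent_dose,
    parse_schedule,
    resident_load,
)
from sedaudit.enrich import enrich_record
from sedaudit.ingest import MedicationRecord
from sedaudit.synthdata import GeneratorConfig, generate_terminology

terms = generate_terminology(GeneratorConfig(seed=0))
ddd = terms.ddd_table

for text in ("One tablet nocte", "one mane and two nocte", "half bd PRN",
             "Take as directed"):
    s = parse_schedule(text)
    print(f"{text!r:32} -> status={s.parse_status:11} "
          f"units/day={s.units_per_day} prn={s.prn}")

# temazepam 10 mg nocte: 10 mg/day against a 20 mg DDD is 0.5 DDD, which
# converts to 5 mg/day of diazepam (whose DDD is 10 mg).
schedule = parse_schedule("one nocte")
dose = daily_dose_mg(schedule, 10.0)
print(f"\ntemazepam one nocte: {dose} mg/day "
      f"= {ddd_ratio(dose, 'N05CD07', ddd)} DDD "
      f"= {equivalent_dose(dose, 'N05CD07', BENZODIAZEPINE, ddd)} mg diazepam")


def record(rid, vendor_code, name, instructions):
    rec = MedicationRecord(
        record_id=rid, resident_id="res-1", vendor="medipack",
        vendor_code=vendor_code, med_name=name, instructions=instructions,
        quantity_supplied=28,
    )
    return enrich_record(rec, terms.bundle, DEFAULT_RULES)


diazepam = next(d for d in terms.drugs if d.name == "diazepam")
temazepam = next(d for d in terms.drugs if d.name == "temazepam")
risperidone = next(d for d in terms.drugs if d.name == "risperidone")

meds = [
    record("m1", diazepam.vendor_codes["medipack"], "Diazepamex", "one nocte"),
    record("m2", temazepam.vendor_codes["medipack"], "Temazepamex",
           "one nocte PRN"),
    record("m3", risperidone.vendor_codes["medipack"], "Risperidonex",
           "half bd"),
]
load = resident_load(meds, ddd)
print(f"\nresident load: {load.benzodiazepine_diazepam_equiv_mg_per_day} mg "
      f"diazepam-equivalent/day, "
      f"{load.antipsychotic_chlorpromazine_equiv_mg_per_day} mg "
      f"chlorpromazine-equivalent/day, {load.ddd_sum} DDD total")
print(f"PRN sedatives excluded from the load: {load.excluded_prn_count}")
# Only the regular diazepam and risperidone count; the PRN temazepam is
# recorded but contributes nothing, as administered PRN doses are unknown.
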