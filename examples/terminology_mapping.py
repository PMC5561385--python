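"""Resolve packing-system medication codes to MPUU concepts and ATC codes.

Builds the synthetic terminology bundle, resolves one vendor code through
each path (TPUU-level and CTPP-level), shows the unmapped-code queue, and
adds a manual mapping the way a research pharmacist would.
"""

from sedaudit.classify import DEFAULT_RULES
from sedaudit.enrich import enrich_record
from sedaudit.ingest import MedicationRecord
from sedaudit.synthdata import GeneratorConfig, generate_terminology
from sedaudit.terminology import (
    UNMAPPED,
    add_manual_mapping,
    list_unmapped,
    mpuu_to_atc,
    resolve_to_mpuu,
)

terms = generate_terminology(GeneratorConfig(seed=0))
bundle = terms.bundle

diazepam = next(d for d in terms.drugs if d.name == "diazepam")
temazepam = next(d for d in terms.drugs if d.name == "temazepam")

# medipack maps codes at TPUU level; blisterpro at CTPP level. Both chains
# end at the same generic MPUU concept.
for vendor, drug in (("medipack", diazepam), ("blisterpro", temazepam)):
    code = drug.vendor_codes[vendor]
    mpuu = resolve_to_mpuu(vendor, code, bundle)
    atc = mpuu_to_atc(mpuu, bundle)
    print(f"{vendor} code {code} -> MPUU {mpuu} "
          f"({bundle.concepts[mpuu].preferred_name}) -> ATC {atc}")

# An unknown code returns the UNMAPPED marker and lands on the queue that
# is sent to the research pharmacist.
record = MedicationRecord(
    record_id="m1", resident_id="r1", vendor="medipack",
    vendor_code="XU999", med_name="Novocalm 5mg", instructions="one nocte",
)
record = enrich_record(record, bundle, DEFAULT_RULES)
print("unknown code resolves to:", record.mpuu_id)
print("unmapped queue:", list_unmapped([record]))

# The pharmacist maps it manually (here to the diazepam brand concept);
# re-resolution then succeeds while the prescription's own name is kept
# for display.
bundle = add_manual_mapping(
    bundle, "medipack", "XU999", diazepam.tpuu_id,
    equivalent_of_name="Novocalm 5mg",
)
record = enrich_record(record, bundle, DEFAULT_RULES)
print(f"after manual mapping: MPUU {record.mpuu_id}, class "
      f"{record.class_label}, displayed as {record.display_name!r}")
# The displayed name stays the vendor's name so nursing staff recognise it.
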