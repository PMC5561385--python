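# sedaudit

Auditing sedative medication use in nursing homes from community-pharmacy
packing-system data.

Most nursing homes receive their medications from community pharmacies that
pack each resident's drugs into blister packs or sachets using commercial
packing software. Those packing databases are the closest consistently
electronic record of what residents actually take — but every vendor stores
medicines under its own identifiers, and the raw data contains missing dose
quantities, duplicate resident profiles, and medications that were never
entered into packing at all. `sedaudit` is a library for turning such
exports into validated, per-home audit reports of antipsychotic and
benzodiazepine use. It is aimed at medication-outcomes researchers and
quality-improvement programs that need auditable drug-utilisation data at
the individual-home level, not just aggregate statistics.

## What it does

**Terminology mapping.** Vendor medication codes are resolved through an
AMT-style concept hierarchy (the Australian Medicines Terminology pattern:
branded pack concepts CTPP → TPP → TPUU down to the generic Medicinal
Product Unit of Use, MPUU) and then to WHO ATC codes. Codes the terminology
cannot resolve queue for manual mapping by a pharmacist, with a
chemically-equivalent fallback that preserves the prescription's own name
for display to nursing staff.

**Classification.** A medicine is a sedative under the audit definition iff
its ATC code falls in N05A (antipsychotics, excluding lithium N05AN and
prochlorperazine N05AB04) or in the benzodiazepine groups N05BA, N05CD,
N05CF, or N03AE01 (clonazepam). Matching is string-prefix matching on the
ATC code; the rule set is configuration, so other drug classes can be
audited with the same machinery. PRN ("as required") status is detected
from the dosing instructions or a vendor flag.

**Sedative load.** Dosing instructions are parsed by a small additive
grammar ("one mane and two nocte" = 3 units/day) into a daily dose in mg,
expressed in WHO Defined Daily Doses:

    dose_DDD = daily_dose_mg / DDD(drug)

and converted to reference-drug equivalents — diazepam for benzodiazepines,
chlorpromazine for antipsychotics:

    equiv_mg = dose_DDD × DDD(reference)

with an optional per-drug clinical equivalence table overriding the DDD
ratio. PRN sedatives are counted but never contribute to the load, because
administered PRN quantities cannot be known from packing data.

**Validation workflow.** The audit state is event-sourced: every add,
modify, delete, and merge is an entry in an append-only transaction log,
labelled with one of four phases (unmapped-medication resolution, off-site
validation, in-home verification by a "champion nurse", retrospective
cleaning). Deleting a departed resident cascades to their medications;
merging duplicate profiles reassigns medications and collapses exact
split-pack duplicates; suspect data (missing quantities, unparseable
instructions, doses above 4×DDD) is flagged; and a home's audit report is
gated on every resident being explicitly verified with no blocking flags.
Replaying the log deterministically reproduces the live state.

**Reporting.** Per-home prevalence of regular and PRN antipsychotic and
benzodiazepine use (a resident counts once per class), mean sedative loads,
coverage/accuracy statistics, a pooled two-proportion z-test, and
interaction-time estimates from website-style event streams.

**Synthetic data.** `sedaudit.synthdata` generates a complete offline
world — terminology bundle, homes, residents, exports in both supported
dialects — with configurable injected error modes (omitted records, missing
dose quantities, unmapped codes, transposed fields, duplicate profiles) and
a ground-truth ledger, plus a session-log generator whose corrections
exactly repair the injections. Defaults mirror the magnitudes reported for
a national Australian audit (90 residents per home SD 37.5, ~11.8
medications per resident, 5.13% sedatives, 3.62%/6.12% regular/PRN omission
rates, 11.07% duplicate profiles).

## Worked example

```python
from sedaudit.doseload import parse_schedule, daily_dose_mg, ddd_ratio, equivalent_dose
from sedaudit.classify import BENZODIAZEPINE
from sedaudit.synthdata import GeneratorConfig, generate_terminology

terms = generate_terminology(GeneratorConfig(seed=0))
s = parse_schedule("one nocte")            # 1 unit x 1/day, not PRN
dose = daily_dose_mg(s, 10.0)              # temazepam 10 mg tablets
print(dose,
      ddd_ratio(dose, "N05CD07", terms.ddd_table),
      equivalent_dose(dose, "N05CD07", BENZODIAZEPINE, terms.ddd_table))
```

prints `10.0 0.5 5.0`: one 10 mg temazepam at night is 10 mg/day, which is
half the temazepam DDD (20 mg), and therefore equivalent to 5 mg/day of
diazepam (half the diazepam DDD of 10 mg). Running
`python examples/sedative_load.py` continues this into a full resident
load; its final lines,

    resident load: 5.0 mg diazepam-equivalent/day, 120.0 mg chlorpromazine-equivalent/day, 0.9 DDD total
    PRN sedatives excluded from the load: 1

show a resident on regular diazepam 5 mg nocte and risperidone 1 mg bd
(0.9 DDD combined) whose PRN temazepam is recorded but excluded. The other
scripts in `examples/` walk through terminology mapping, the validation
workflow, and a complete audit run from generated exports to verified
per-home reports.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a synthetic pharmacy world from the seed, runs the full
pipeline (ingest both export dialects, terminology and ATC enrichment,
suspect flagging, the generated four-phase correction session, home
verification), prints the resulting per-home prevalence reports, correction
accounting, and the omission z-test, and writes the results file.
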