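"""Dose-instruction parsing, DDD ratios, and sedative-load aggregation.

Daily doses are computed from the packing instructions (the instruction
string is the ground truth the validation workflow repairs toward), compared
with WHO Defined Daily Dose (DDD) reference values, and expressed as
milligram equivalents of a reference drug: diazepam for benzodiazepines,
chlorpromazine for antipsychotics. PRN ("as required") sedatives are counted
but contribute nothing to the load, because administered PRN quantities are
unquantifiable from packing data.

Instruction grammar
-------------------
Additive sequence of (count, frequency) parts, e.g. ``one mane and two
nocte`` is 3 units/day. Counts are integers, decimals, simple fractions
("1/2") or the words one..twelve / "half" / "quarter". Frequencies:
mane, nocte, midday, daily (1/day), bd (2/day), tds (3/day), qid (4/day).
PRN vocabulary sets the PRN flag without touching the numeric fields.
Anything else that is not filler ("take", "tablet", ...) makes the
instruction unparseable — signalled in the status field, never an exception.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from ._util import ConfigurationError, ContractViolation, ValidationError
from .classify import ANTIPSYCHOTIC, BENZODIAZEPINE, SEDATIVE_CLASSES

#: ATC codes of the reference drugs for equivalent-dose conversion.
REFERENCE_ATC = {
    BENZODIAZEPINE: "N05BA01",  # diazepam
    ANTIPSYCHOTIC: "N05AA01",  # chlorpromazine
}

_FREQ = {
    "mane": 1.0,
    "nocte": 1.0,
    "midday": 1.0,
    "daily": 1.0,
    "bd": 2.0,
    "tds": 3.0,
    "qid": 4.0,
}

_COUNT_WORDS = {
    "half": 0.5,
    "quarter": 0.25,
    "one": 1.0,
    "two": 2.0,
    "three": 3.0,
    "four": 4.0,
    "five": 5.0,
    "six": 6.0,
    "seven": 7.0,
    "eight": 8.0,
    "nine": 9.0,
    "ten": 10.0,
    "eleven": 11.0,
    "twelve": 12.0,
}

#: Filler words carrying no dose information.
_NOISE = {
    "take", "tablet", "tablets", "capsule", "capsules", "tab", "tabs",
    "cap", "caps", "wafer", "wafers", "drop", "drops", "and", "plus",
    "at", "in", "the", "with", "of", "a", "an", "food", "meals", "orally",
    "po", "each", "every", "day", "night", "morning",
}

_PRN_PHRASES = ("as required", "when required", "as needed")
_NUMBER = re.compile(r"^\d+(\.\d+)?$")
_FRACTION = re.compile(r"^(\d+)/(\d+)$")


@dataclass(frozen=True)
class DoseSchedule:
    units_per_administration: float | None
    administrations_per_day: float | None
    prn: bool
    parse_status: str  # parsed | unparseable | missing

    @property
    def units_per_day(self) -> float | None:
        if self.parse_status != "parsed":
            return None
        return self.units_per_administration * self.administrations_per_day


UNPARSEABLE = DoseSchedule(None, None, False, "unparseable")
MISSING = DoseSchedule(None, None, False, "missing")


@dataclass(frozen=True)
class DddReference:
    atc_code: str
    ddd_value: float  # mg
    ddd_unit: str = "mg"

    def __post_init__(self):
        if self.ddd_value <= 0:
            raise ValidationError(f"DDD for {self.atc_code} must be positive")


def parse_schedule(instructions: str | None) -> DoseSchedule:
    """Parse a dosing instruction string into a DoseSchedule.

    Never raises: failure is reported in ``parse_status``.
    """
    if instructions is None or not instructions.strip():
        return MISSING
    text = instructions.lower()
    prn = False
    if re.search(r"\bprn\b", text):
        prn = True
        text = re.sub(r"\bprn\b", " ", text)
    for phrase in _PRN_PHRASES:
        if phrase in text:
            prn = True
            text = text.replace(phrase, " ")
    text = re.sub(r"[,;]+|\.(?!\d)", " ", text)  # keep decimal points
    tokens = text.split()

    parts: list[tuple[float, float]] = []  # (count, administrations/day)
    pending_count: float | None = None
    for tok in tokens:
        if tok in _FREQ:
            count = 1.0 if pending_count is None else pending_count
            parts.append((count, _FREQ[tok]))
            pending_count = None
        elif tok in _COUNT_WORDS:
            if pending_count is not None:
                return DoseSchedule(None, None, prn, "unparseable")
            pending_count = _COUNT_WORDS[tok]
        elif _NUMBER.match(tok):
            if pending_count is not None:
                return DoseSchedule(None, None, prn, "unparseable")
            pending_count = float(tok)
        elif _FRACTION.match(tok):
            if pending_count is not None:
                return DoseSchedule(None, None, prn, "unparseable")
            num, den = _FRACTION.match(tok).groups()
            pending_count = float(num) / float(den)
        elif tok in _NOISE:
            continue
        else:
            return DoseSchedule(None, None, prn, "unparseable")
    if pending_count is not None or not parts:
        # trailing count with no frequency, or nothing recognised
        return DoseSchedule(None, None, prn, "unparseable")
    administrations = sum(freq for _, freq in parts)
    total_units = sum(count * freq for count, freq in parts)
    return DoseSchedule(
        units_per_administration=total_units / administrations,
        administrations_per_day=administrations,
        prn=prn,
        parse_status="parsed",
    )


def daily_dose_mg(schedule: DoseSchedule, mpuu_strength_mg: float) -> float | None:
    """units/administration x administrations/day x unit strength (mg).

    Returns None for unparseable/missing schedules (the caller flags these).
    """
    if mpuu_strength_mg is None or mpuu_strength_mg <= 0:
        raise ValidationError("MPUU strength must be positive")
    if schedule.parse_status != "parsed":
        return None
    return schedule.units_per_day * mpuu_strength_mg


def ddd_ratio(
    daily_dose: float, atc_code: str, ddd_table: Mapping[str, DddReference]
) -> float:
    """Daily dose expressed in DDD units (doses/day)."""
    ref = ddd_table.get(atc_code)
    if ref is None:
        raise ConfigurationError(f"no DDD reference row for ATC code {atc_code}")
    return daily_dose / ref.ddd_value


def equivalent_dose(
    daily_dose: float,
    atc_code: str,
    class_label: str,
    ddd_table: Mapping[str, DddReference],
    equivalents: Mapping[str, float] | None = None,
) -> float:
    """Convert a daily dose to mg/day of the class reference drug.

    Default conversion is DDD-ratio based: dose in DDDs times the reference
    drug's DDD (so any drug taken at exactly 1 DDD maps to one reference
    DDD). A per-drug clinical equivalence table (mg reference per mg drug)
    overrides the default when supplied.
    """
    if class_label not in SEDATIVE_CLASSES:
        raise ContractViolation(
            f"equivalent_dose is defined for sedative classes only, got {class_label}"
        )
    if equivalents and atc_code in equivalents:
        return daily_dose * equivalents[atc_code]
    reference_atc = REFERENCE_ATC[class_label]
    ref = ddd_table.get(reference_atc)
    if ref is None:
        raise ConfigurationError(
            f"no DDD reference row for reference drug {reference_atc}"
        )
    return ddd_ratio(daily_dose, atc_code, ddd_table) * ref.ddd_value


@dataclass(frozen=True)
class SedativeLoadResult:
    resident_id: str
    benzodiazepine_diazepam_equiv_mg_per_day: float
    antipsychotic_chlorpromazine_equiv_mg_per_day: float
    ddd_sum: float
    excluded_prn_count: int
    unparseable_count: int = 0


def resident_load(
    records: Iterable,
    ddd_table: Mapping[str, DddReference],
    equivalents: Mapping[str, float] | None = None,
) -> SedativeLoadResult:
    """Aggregate one resident's regular sedative use into a load result.

    ``records`` are enriched medication records (class_label, prn,
    daily_dose_mg, atc_code) all belonging to the same resident. Regular
    (non-PRN) sedatives with a computable dose are summed; PRN sedatives are
    counted in ``excluded_prn_count``; sedatives whose dose could not be
    determined are counted in ``unparseable_count`` and excluded from sums.
    """
    records = list(records)
    resident_ids = {r.resident_id for r in records}
    if len(resident_ids) > 1:
        raise ContractViolation(f"records span residents: {sorted(resident_ids)}")
    resident_id = resident_ids.pop() if resident_ids else ""
    benzo = 0.0
    anti = 0.0
    ddd_sum = 0.0
    prn_excluded = 0
    unparseable = 0
    for r in records:
        if r.class_label not in SEDATIVE_CLASSES:
            continue
        if r.prn:
            prn_excluded += 1
            continue
        if r.daily_dose_mg is None:
            unparseable += 1
            continue
        atc = r.atc_code
        equiv = equivalent_dose(
            r.daily_dose_mg, atc, r.class_label, ddd_table, equivalents
        )
        ddd_sum += ddd_ratio(r.daily_dose_mg, atc, ddd_table)
        if r.class_label == BENZODIAZEPINE:
            benzo += equiv
        else:
            anti += equiv
    return SedativeLoadResult(
        resident_id=resident_id,
        benzodiazepine_diazepam_equiv_mg_per_day=benzo,
        antipsychotic_chlorpromazine_equiv_mg_per_day=anti,
        ddd_sum=ddd_sum,
        excluded_prn_count=prn_excluded,
        unparseable_count=unparseable,
    )


# -- reference-table I/O --------------------------------------------------

def load_ddd_table(path) -> dict[str, DddReference]:
    """Read ddd.tsv (atc_code, ddd_value, ddd_unit) into a lookup dict."""
    df = pd.read_csv(path, sep="\t")
    table = {}
    for r in df.itertuples():
        if r.atc_code in table:
            raise ConfigurationError(f"duplicate DDD row for {r.atc_code}")
        table[str(r.atc_code)] = DddReference(
            str(r.atc_code), float(r.ddd_value), str(r.ddd_unit)
        )
    return table


def save_ddd_table(table: Mapping[str, DddReference], path) -> None:
    pd.DataFrame(
        [
            {"atc_code": ref.atc_code, "ddd_value": ref.ddd_value, "ddd_unit": ref.ddd_unit}
            for ref in table.values()
        ]
    ).to_csv(path, sep="\t", index=False)


def load_equivalents(path) -> dict[str, float]:
    """Read equivalents.tsv (atc_code, reference_mg_per_drug_mg)."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.atc_code): float(r.reference_mg_per_drug_mg) for r in df.itertuples()
    }
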