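"""Sedative classification from ATC codes, and PRN detection.

The audit's working definition of "sedative" is psycholeptic medication:
antipsychotics (ATC N05A, excluding lithium N05AN and prochlorperazine
N05AB04) together with benzodiazepines and related drugs (N05BA anxiolytic
benzodiazepines, N05CD hypnotic benzodiazepines, N05CF benzodiazepine-related
z-drugs, and clonazepam N03AE01 which ATC files under antiepileptics).

ATC membership is prefix membership: a code belongs to a group iff the code
string starts with the group's code, so mixed-level rule sets (whole N05A
versus a single seventh-level exclusion) compose naturally. The longest
matching include prefix decides the class; an exclusion only fires when it
refines the winning include.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace as _dc_replace
from typing import Iterable

import yaml

from ._util import ValidationError
from .terminology import UNMAPPED, all_atc_codes, is_valid_atc

ANTIPSYCHOTIC = "ANTIPSYCHOTIC"
BENZODIAZEPINE = "BENZODIAZEPINE"
NONE = "NONE"
PENDING = "PENDING"  # unmapped medication awaiting a terminology mapping

SEDATIVE_CLASSES = (ANTIPSYCHOTIC, BENZODIAZEPINE)

_PRN_TOKENS = ("as required", "when required", "as needed")
_PRN_WORD = re.compile(r"\bprn\b", re.IGNORECASE)


@dataclass(frozen=True)
class SedativeRuleSet:
    """Include/exclude ATC prefixes with class labels.

    ``include_prefixes`` pairs an ATC prefix with a class label;
    ``exclude_codes`` are refinements (string-prefix extensions) of an
    include prefix that are carved back out of it.
    """

    include_prefixes: tuple[tuple[str, str], ...]
    exclude_codes: tuple[str, ...]

    def __post_init__(self):
        for prefix, _label in self.include_prefixes:
            if not is_valid_atc(prefix):
                raise ValidationError(f"include prefix {prefix!r} is not ATC-shaped")
        for code in self.exclude_codes:
            if not is_valid_atc(code):
                raise ValidationError(f"exclude code {code!r} is not ATC-shaped")
            if not any(
                code.startswith(prefix) for prefix, _ in self.include_prefixes
            ):
                raise ValidationError(
                    f"exclude code {code!r} refines no include prefix"
                )


#: The audit's default drug-of-interest definition (see module docstring).
DEFAULT_RULES = SedativeRuleSet(
    include_prefixes=(
        ("N05A", ANTIPSYCHOTIC),
        ("N05BA", BENZODIAZEPINE),
        ("N05CD", BENZODIAZEPINE),
        ("N05CF", BENZODIAZEPINE),
        ("N03AE01", BENZODIAZEPINE),
    ),
    exclude_codes=("N05AN", "N05AB04"),
)


def classify_atc(atc_code: str, rules: SedativeRuleSet = DEFAULT_RULES) -> str:
    """Class of a single ATC code under the rule set.

    Returns ANTIPSYCHOTIC, BENZODIAZEPINE or NONE. Raises ValidationError on
    a malformed code.
    """
    if not is_valid_atc(atc_code):
        raise ValidationError(f"malformed ATC code {atc_code!r}")
    best: tuple[str, str] | None = None
    for prefix, label in rules.include_prefixes:
        if atc_code.startswith(prefix):
            if best is None or len(prefix) > len(best[0]):
                best = (prefix, label)
    if best is None:
        return NONE
    prefix, label = best
    for excl in rules.exclude_codes:
        if excl.startswith(prefix) and atc_code.startswith(excl):
            return NONE
    return label


def classify_codes(atc_codes: Iterable[str], rules: SedativeRuleSet = DEFAULT_RULES) -> str:
    """Combine classes over ALL ATC assignments of one medicine.

    Any sedative assignment makes the medicine a sedative (conservative
    capture); when both classes occur, ANTIPSYCHOTIC wins deterministically.
    """
    labels = {classify_atc(code, rules) for code in atc_codes}
    for label in (ANTIPSYCHOTIC, BENZODIAZEPINE):
        if label in labels:
            return label
    return NONE


def detect_prn(instructions: str | None, vendor_prn_flag: bool | None = None) -> bool:
    """Is the medication taken pro re nata ("as required")?

    A vendor-supplied PRN flag, when present, dominates the instruction
    text; otherwise the text is scanned case-insensitively for the PRN
    vocabulary.
    """
    if vendor_prn_flag is not None:
        return vendor_prn_flag
    if not instructions:
        return False
    low = instructions.lower()
    if _PRN_WORD.search(low):
        return True
    return any(tok in low for tok in _PRN_TOKENS)


def classify_medication(record, bundle, rules: SedativeRuleSet = DEFAULT_RULES):
    """Attach class label and PRN flag to an enriched medication record.

    The record must already carry ``mpuu_id`` (an MPUU concept id or the
    UNMAPPED marker). Unmapped records get class PENDING and are picked up
    by the unmapped-code queue.
    """
    if record.mpuu_id is UNMAPPED or record.mpuu_id is None:
        label = PENDING
    else:
        codes = all_atc_codes(record.mpuu_id, bundle)
        label = classify_codes(codes, rules) if codes else PENDING
    prn = detect_prn(record.instructions, getattr(record, "vendor_prn_flag", None))
    return _dc_replace(record, class_label=label, prn=prn)


def load_rules(path) -> SedativeRuleSet:
    """Read a rule set from YAML: {include: [{prefix, label}], exclude: [code]}."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return SedativeRuleSet(
        include_prefixes=tuple(
            (item["prefix"], item["label"]) for item in raw.get("include", [])
        ),
        exclude_codes=tuple(raw.get("exclude", [])),
    )


def save_rules(rules: SedativeRuleSet, path) -> None:
    payload = {
        "include": [
            {"prefix": p, "label": l} for p, l in rules.include_prefixes
        ],
        "exclude": list(rules.exclude_codes),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
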