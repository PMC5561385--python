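"""Small shared helpers: rounding and error types."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (unlike Python's banker's rounding).

    Percentages in audit outputs are rounded this way so that recomputed
    shares match the convention used in published drug-utilisation tables.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 2) -> float | None:
    """100*numerator/denominator rounded half-away-from-zero; None if undefined."""
    if denominator == 0:
        return None
    return round_half_away(100.0 * numerator / denominator, ndigits)


class SedauditError(Exception):
    """Base class for all package errors."""


class TerminologyIntegrityError(SedauditError):
    """The concept graph violates a structural invariant (names the concept)."""


class KindError(SedauditError):
    """A concept id of the wrong kind was supplied to an operation."""


class MappingConflictError(SedauditError):
    """A vendor-code mapping already exists; overwriting must be explicit."""


class UnsupportedFormatError(SedauditError):
    """An export file does not declare a known dialect."""


class ValidationError(SedauditError):
    """Malformed input value (empty name, bad ATC code, ...)."""


class IntegrityError(SedauditError):
    """Referential integrity violated (medication without resident, ...)."""


class AmbiguousWingError(SedauditError):
    """A pharmacy wing name matches more than one participating home."""


class ConfigurationError(SedauditError):
    """A reference table is missing a required row (e.g. a DDD value)."""


class LogError(SedauditError):
    """Transaction log sequence gap, reorder, or malformed entry."""


class GatingError(SedauditError):
    """Report requested for a home that has not completed verification."""


class ContractViolation(SedauditError):
    """An operation was called outside its stated preconditions."""
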