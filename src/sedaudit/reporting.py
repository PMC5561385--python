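"""Audit outputs: prevalence, coverage/accuracy statistics, z-test, timing.

Percentages are rounded half-away-from-zero to 2 decimal places throughout,
so shares recomputed from stored counts never drift from the counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Mapping

from scipy import stats

from ._util import ContractViolation, GatingError, pct, round_half_away
from .classify import ANTIPSYCHOTIC, BENZODIAZEPINE
from .doseload import resident_load
from .validation import PipelineState, verify_home


@dataclass(frozen=True)
class PrevalenceReport:
    home_id: str
    snapshot_label: str
    n_residents: int
    pct_on_antipsychotic_regular: float
    pct_on_benzodiazepine_regular: float
    pct_on_antipsychotic_prn: float
    pct_on_benzodiazepine_prn: float
    mean_diazepam_equiv_mg: float
    mean_chlorpromazine_equiv_mg: float


@dataclass(frozen=True)
class CoverageStats:
    """Accuracy accounting for one audit: records extracted automatically,
    records added during validation, and extracted records modified."""

    extracted: int
    added: int
    modified: int
    identified_share: float | None  # % of true records captured by extraction
    modified_share: float | None    # % of extracted records needing modification
    added_share: float | None       # % of true records added manually
    correct_share: float | None     # % of extracted records correct as uploaded


@dataclass(frozen=True)
class ZTestResult:
    z: float | None
    p_two_tailed: float
    p1: float
    p2: float
    pooled_p: float


def prevalence_report(
    state: PipelineState,
    home_id: str,
    snapshot_label: str = "",
) -> PrevalenceReport:
    """Per-home prevalence of antipsychotic/benzodiazepine use plus mean
    sedative loads, over current (non-merged, non-deleted) residents.

    A resident counts once per class however many drugs of the class they
    take; regular and PRN use are reported separately. Generation is gated
    on the home's verification status.
    """
    status = verify_home(state, home_id)
    if not status.verified:
        raise GatingError(
            f"home {home_id} is not verified: "
            f"{len(status.unchecked_residents)} unchecked residents, "
            f"{len(status.blocking_flags)} blocking flags"
        )
    residents = state.current_residents(home_id)
    n = len(residents)
    ap_reg = ap_prn = bz_reg = bz_prn = 0
    dz_total = cp_total = 0.0
    for r in residents:
        meds = state.medications_of(r.resident_id)
        if any(m.class_label == ANTIPSYCHOTIC and not m.prn for m in meds):
            ap_reg += 1
        if any(m.class_label == ANTIPSYCHOTIC and m.prn for m in meds):
            ap_prn += 1
        if any(m.class_label == BENZODIAZEPINE and not m.prn for m in meds):
            bz_reg += 1
        if any(m.class_label == BENZODIAZEPINE and m.prn for m in meds):
            bz_prn += 1
        load = resident_load(meds, state.ddd_table, state.equivalents)
        dz_total += load.benzodiazepine_diazepam_equiv_mg_per_day
        cp_total += load.antipsychotic_chlorpromazine_equiv_mg_per_day
    return PrevalenceReport(
        home_id=home_id,
        snapshot_label=snapshot_label,
        n_residents=n,
        pct_on_antipsychotic_regular=pct(ap_reg, n) or 0.0,
        pct_on_benzodiazepine_regular=pct(bz_reg, n) or 0.0,
        pct_on_antipsychotic_prn=pct(ap_prn, n) or 0.0,
        pct_on_benzodiazepine_prn=pct(bz_prn, n) or 0.0,
        mean_diazepam_equiv_mg=round_half_away(dz_total / n, 2) if n else 0.0,
        mean_chlorpromazine_equiv_mg=round_half_away(cp_total / n, 2) if n else 0.0,
    )


def coverage_stats(extracted: int, added: int, modified: int) -> CoverageStats:
    """Shares at 2 dp, half-away-from-zero.

    identified = 100*extracted/(extracted+added) — the fraction of all
    records actually taken that the automatic extraction captured;
    modified share = 100*modified/extracted; added share =
    100*added/(extracted+added). Undefined shares (zero denominators) are
    reported as absent, never as zero.
    """
    if min(extracted, added, modified) < 0:
        raise ContractViolation("counts must be non-negative")
    total = extracted + added
    return CoverageStats(
        extracted=extracted,
        added=added,
        modified=modified,
        identified_share=pct(extracted, total),
        modified_share=pct(modified, extracted),
        added_share=pct(added, total),
        correct_share=pct(extracted - modified, extracted),
    )


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> ZTestResult:
    """Pooled two-proportion z-test (normal approximation, no continuity
    correction); two-tailed p from the standard normal distribution.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion.
    Degenerate pooled proportions (0 or 1) leave z undefined with p = 1.
    """
    if n1 <= 0 or n2 <= 0 or not (0 <= x1 <= n1) or not (0 <= x2 <= n2):
        raise ContractViolation("need 0 <= x <= n and n > 0 for both groups")
    p1 = x1 / n1
    p2 = x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ZTestResult(z=None, p_two_tailed=1.0, p1=p1, p2=p2, pooled_p=pooled)
    se = (pooled * (1 - pooled) * (1 / n1 + 1 / n2)) ** 0.5
    z = (p1 - p2) / se
    p = 2 * stats.norm.sf(abs(z))
    return ZTestResult(z=z, p_two_tailed=p, p1=p1, p2=p2, pooled_p=pooled)


@dataclass(frozen=True)
class SessionTimes:
    minutes_per_actor_home: Mapping[tuple[str, str], float]
    minutes_per_resident: Mapping[tuple[str, str], float]


def session_time_estimate(
    events: Iterable[tuple[str, str, datetime]],
    gap_threshold: timedelta = timedelta(minutes=10),
    resident_counts: Mapping[str, int] | None = None,
) -> SessionTimes:
    """Estimate interaction time by aggregating continuous activity blocks.

    Events (actor, home, timestamp) separated by at most ``gap_threshold``
    belong to one block; a block's duration is last minus first (a lone
    event contributes zero). Totals are summed per (actor, home); when home
    resident counts are supplied, per-resident minutes are derived.
    """
    by_pair: dict[tuple[str, str], list[datetime]] = {}
    for actor, home, ts in events:
        by_pair.setdefault((actor, home), []).append(ts)
    minutes: dict[tuple[str, str], float] = {}
    per_resident: dict[tuple[str, str], float] = {}
    for pair, stamps in by_pair.items():
        stamps.sort()
        total = timedelta(0)
        block_start = prev = stamps[0]
        for ts in stamps[1:]:
            if ts - prev > gap_threshold:
                total += prev - block_start
                block_start = ts
            prev = ts
        total += prev - block_start
        minutes[pair] = total.total_seconds() / 60.0
        if resident_counts and resident_counts.get(pair[1]):
            per_resident[pair] = minutes[pair] / resident_counts[pair[1]]
    return SessionTimes(minutes_per_actor_home=minutes, minutes_per_resident=per_resident)
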