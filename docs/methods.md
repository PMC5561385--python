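# Methods

This note documents the models, conventions and numerical choices behind
`sedaudit`, what the synthetic generator does and does not emulate, and the
design decisions taken where the problem left the design open.

## Terminology model

The medicines terminology is an AMT/SNOMED-CT-style concept graph with
seven kinds: MP, MPUU, MPP (generic) and TP, TPUU, TPP, CTPP (branded).
Only three edge triples are traversable for resolution — CTPP→TPP
(`contains`), TPP→TPUU (`contains`), TPUU→MPUU (`is_generic_of`) — and the
bundle validator enforces that this restricted edge set is acyclic
(networkx DAG check), that every TPUU has exactly one MPUU parent, and
consequently that every mapped vendor code reaches exactly one MPUU.
Concept ids are opaque positive integers in the SCTID style; no real
terminology release is parsed, and versioning/diffing is out of scope.
Packing vendors map their codes at either TPUU level (database-style
systems) or CTPP level (report-style systems); both paths are exercised by
the generator.

Manual mappings never overwrite silently (conflict error). A
chemically-equivalent fallback mapping carries the original vendor name,
and enrichment always displays the vendor-supplied medication name, so a
drug counted under an equivalent concept is still shown to nurses under
the name on the prescription.

An MPUU may carry several ATC assignments with exactly one primary.
Classification uses *all* assignments (any sedative assignment makes the
medicine a sedative) so conservative capture is preserved; when both
classes occur the label is ANTIPSYCHOTIC by fixed priority.

## Classification rules

ATC membership is prefix membership on the code string. The default rule
set is: include N05A as ANTIPSYCHOTIC; include N05BA, N05CD, N05CF,
N03AE01 as BENZODIAZEPINE; exclude N05AN (lithium) and N05AB04
(prochlorperazine). The longest matching include prefix wins, and an
exclusion only fires when it refines the winning include, so a sibling
such as N05AB03 remains included. The rule set is configuration
(`rules.yaml`), not code. PRN detection matches the tokens "prn" (whole
word), "as required", "when required", "as needed", case-insensitively; a
vendor-supplied PRN flag, when present, dominates the text.

## Dose model

Daily doses are computed from the instruction text, not from
quantity-supplied arithmetic: packing quantities describe what was packed,
not the daily regimen, and instruction text is what validation repairs
toward. The grammar is an additive sequence of (count, frequency) parts
with counts as integers, decimals, simple fractions, or number words
(including "half" and "quarter"), frequencies mane/nocte/midday/daily
(1/day), bd (2), tds (3), qid (4), and a small filler vocabulary. Any
non-filler token outside the grammar makes the instruction unparseable —
reported in a status field, never an exception, because unparseable
instructions are a first-class data-quality outcome that must surface as a
suspect flag, not crash ingestion.

DDD values are configuration (`ddd.tsv`, mg units); the shipped table is
synthetic-but-plausible and real WHO values drop in unchanged. The
equivalent-dose conversion defaults to the DDD ratio — dose in DDDs times
the reference drug's DDD (diazepam N05BA01 for benzodiazepines,
chlorpromazine N05AA01 for antipsychotics) — which guarantees the identity
`equivalent_dose(reference, d) = d` and linearity. Whether a published
clinical equivalence table is preferable is a clinical judgement the
package does not make: an optional per-drug override table
(`equivalents.tsv`, mg reference per mg drug) takes precedence when
supplied, so either convention is available and neither is asserted as
the original study's.

Resident load sums equivalents over regular sedatives only. PRN sedatives
increment an exclusion counter; sedatives with unparseable doses are
counted separately and excluded from sums. Loads are additive over record
lists and invariant to any number of PRN additions (both property-tested).

## Ingest and identity

Two text dialects stand in for four proprietary packing systems, because
the extraction styles reduce to two access patterns: a multi-table
database export (`table_export`: one tab-separated file with
residents/wings/medications sections) and a flat generated report
(`report`: one row per medication with repeated resident columns). Every
file declares its dialect in its header line; parsing never drops a row
silently (rows in = rows parsed + rows rejected, with line numbers).
Missing quantity values are legal at ingest and survive to flagging —
defaulting them would destroy the dominant real-world error signal.

Residents are pseudonymized with an HMAC-SHA256 keyed digest of the
normalized name (case-folded, "Surname, Given" comma order resolved,
punctuation stripped) plus birth date. A keyed digest rather than
reversible encryption: stable identity is the only property the pipeline
needs, and no decryption surface exists to protect. Birth date is assumed
available; when a source lacks it, identity degrades to name-only. The
snapshot timestamp is an explicit input (never wall clock); records ceased
strictly before it are excluded and counted, making snapshots
point-in-time and runs reproducible.

## Validation workflow

State is a pure function of (initial snapshot, transaction log). Entries
carry phase (P1 mapping, P2 off-site, P3 in-home, P4 retrospective, plus
ingest/manual_entry), actor role, action, and per-field old/new values;
sequence numbers are dense and strictly increasing, and replay verifies
in-stream cascade entries against the cascades it regenerates, so a full
session log replays to the live state exactly.

Concretizations of informally stated behaviour:

- "Typical range" for a sedative daily dose is (0, R×DDD] with R = 4 by
  default, configurable; the boundary is inclusive (strictly above R×DDD
  flags).
- A home is VERIFIED iff every current resident is explicitly marked
  checked in P3 and no blocking flags (missing dose quantity, unmapped
  sedative) remain; dose-range flags warn but do not block. Report
  generation is gated on VERIFIED.
- Resident "checked" marks and system-generated cascade entries are not
  corrections; correction accounting counts data-changing entries in the
  four validation phases, with an optional known-error predicate producing
  the with/without columns.
- Duplicate proposal is conservative: annotation-stripped identity-key
  collision (same person, split packs) proposes with score 1.0 and a single
  target (the profile with most medications). Fuzzy display-token
  similarity is opt-in with a threshold, because a false merge is worse
  than a missed one in a medication audit.
- Merges collapse exact-duplicate medication rows (same concept, same
  normalized instruction text, same dates) and refuse cross-home merges
  without an explicit override.

Manual entry reuses the same add/modify/delete machinery in a dedicated
phase, enriches entries identically to uploads, accepts non-sedative
entries with a warning (manual mode expects sedatives only), and can
prepopulate from a prior snapshot so later snapshots need only deltas.

## Statistics

Percentages are rounded half away from zero to 2 decimal places (1 dp
where a quantity is conventionally printed at 1 dp), so shares always
recompute exactly from their counts. The two-proportion z-test is the
pooled normal approximation without continuity correction, two-tailed p
from the standard normal; degenerate pooled proportions (0 or 1) yield an
absent z with p = 1. The test is cross-checked against statsmodels'
implementation and a label-permutation Monte-Carlo estimate in the suite.
Interaction time aggregates events into continuous blocks separated by
more than a gap threshold (default 10 min, chosen; only "continuous
blocks" was stated); a block's duration is last-minus-first, so a lone
event contributes zero.

## Synthetic generator

The generator's stated world: homes with Normal(90, 37.5) residents
(truncated at 5), Poisson(11.84) medications per resident, 5.13% sedatives,
45.06% of sedatives PRN, 11.07% of residents duplicated with split packs,
omission rates 3.62% (regular) / 6.12% (PRN) among sedatives, 0.78%
unmapped sedative codes, 2% transposed fields, and — where no magnitude was
stated — 5% missing dose data (observed per-software rates ranged roughly
1.4%–43%; a mid-low steady state was chosen once), 15% PRN among
non-sedatives, 3% ceased records. One pharmacy supplies two homes with
probability 0.22. Error modes are sampled at most one per record from a
categorical distribution whose component probabilities are the configured
rates, keeping marginal frequencies exactly Bernoulli(rate) while labels
stay disjoint. Identical seeds produce byte-identical files.

The session-log generator emits corrections that exactly repair the
injections (P1 mappings for unmapped codes, P2 untranspositions, P3 dose
repairs and additions of omitted records plus per-resident sign-offs, P4
duplicate merges), applying them as it goes so cascade sequence numbers
are authoritative.

What a green end-to-end test establishes: the pipeline loses nothing, the
enrichment chain is correct on parseable data, and the correction
machinery can restore a known truth through the same interfaces a human
would use. What it does not establish: robustness to real vendor formats,
realistic prescribing correlations (drugs are sampled independently),
free-text instruction idiosyncrasies beyond the grammar, or human
judgement quality during verification.

## Known limitations

- The instruction grammar covers the common Latin-abbreviation style only;
  weekly schedules, tapering regimens, and route qualifiers are
  unparseable by design and surface as flags.
- DDD values and equivalence factors shipped with the generator are
  illustrative, not clinical reference data.
- Quantified PRN consumption is out of scope (unknowable from packing
  data), as are non-oral bioequivalence adjustments.
- The event log records actor roles but does not enforce permissions; the
  original system's web UI, transport security and account management are
  deliberately absent.
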