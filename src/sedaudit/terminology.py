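"""Medicines-terminology concept hierarchy and vendor-code resolution.

Models an AMT-style (Australian Medicines Terminology / SNOMED CT flavoured)
concept hierarchy and performs the mapping chain from proprietary
packing-system medication codes through branded concepts down to the generic
Medicinal Product Unit of Use (MPUU) and on to WHO ATC codes.

Concept kinds
-------------
MP    medicinal product (ingredient)
MPUU  medicinal product unit of use: generic drug + strength + dose form
MPP   medicinal product pack
TP    trade product (brand)
TPUU  trade product unit of use: branded equivalent of an MPUU
TPP   trade product pack
CTPP  containered trade product pack (brand + container + pack size)

Resolution follows the canonical containment/genericisation order
CTPP -> TPP -> TPUU -> MPUU; packing systems map their codes to either a
TPUU or a CTPP depending on vendor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from ._util import (
    KindError,
    MappingConflictError,
    TerminologyIntegrityError,
    ValidationError,
)

CONCEPT_KINDS = frozenset({"MP", "MPUU", "MPP", "TP", "TPUU", "TPP", "CTPP"})

#: (child kind, parent kind, relation) triples the resolver may traverse.
TRAVERSAL_EDGES = (
    ("CTPP", "TPP", "contains"),
    ("TPP", "TPUU", "contains"),
    ("TPUU", "MPUU", "is_generic_of"),
)

#: ATC code: letter, 2 digits, letter, letter, 2 digits — truncatable at any level.
ATC_PATTERN = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")


class _Unmapped:
    """Singleton marker for a code/concept that has no mapping."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNMAPPED"

    def __bool__(self) -> bool:
        return False


UNMAPPED = _Unmapped()


def is_valid_atc(code: str) -> bool:
    return bool(ATC_PATTERN.match(code))


@dataclass(frozen=True)
class Concept:
    concept_id: int
    kind: str
    preferred_name: str
    strength_value: float | None = None
    strength_unit: str | None = None
    dose_form: str | None = None

    def __post_init__(self):
        if self.kind not in CONCEPT_KINDS:
            raise ValidationError(f"unknown concept kind {self.kind!r}")
        if self.concept_id <= 0:
            raise ValidationError("concept_id must be a positive integer")


@dataclass(frozen=True)
class ConceptEdge:
    child_id: int
    parent_id: int
    relation: str  # contains | is_generic_of


@dataclass(frozen=True)
class VendorMapping:
    vendor: str
    vendor_code: str
    target_concept_id: int
    origin: str = "automatic"  # automatic | manual | equivalent_fallback
    equivalent_of_name: str | None = None


@dataclass(frozen=True)
class AtcAssignment:
    mpuu_id: int
    atc_code: str
    primary: bool = True

    def __post_init__(self):
        if not is_valid_atc(self.atc_code):
            raise ValidationError(f"malformed ATC code {self.atc_code!r}")


@dataclass(frozen=True)
class TerminologyBundle:
    """Immutable terminology release: concepts, edges, vendor map, ATC map.

    ``vendor_map`` is keyed by (vendor, vendor_code); ``atc_map`` maps an
    MPUU id to its AtcAssignments (one or more; exactly one primary).
    """

    concepts: Mapping[int, Concept]
    edges: tuple[ConceptEdge, ...]
    vendor_map: Mapping[tuple[str, str], VendorMapping]
    atc_map: Mapping[int, tuple[AtcAssignment, ...]]
    _parent_of: Mapping[int, int] = field(default_factory=dict, repr=False)

    @staticmethod
    def build(
        concepts: Iterable[Concept],
        edges: Iterable[ConceptEdge],
        vendor_mappings: Iterable[VendorMapping],
        atc_assignments: Iterable[AtcAssignment],
    ) -> "TerminologyBundle":
        cmap: dict[int, Concept] = {}
        for c in concepts:
            if c.concept_id in cmap:
                raise TerminologyIntegrityError(
                    f"duplicate concept_id {c.concept_id}"
                )
            cmap[c.concept_id] = c
        edge_tuple = tuple(edges)
        vmap: dict[tuple[str, str], VendorMapping] = {}
        for m in vendor_mappings:
            key = (m.vendor, m.vendor_code)
            if key in vmap:
                raise MappingConflictError(f"duplicate vendor mapping {key}")
            vmap[key] = m
        amap: dict[int, list[AtcAssignment]] = {}
        for a in atc_assignments:
            amap.setdefault(a.mpuu_id, []).append(a)
        bundle = TerminologyBundle(
            concepts=cmap,
            edges=edge_tuple,
            vendor_map=vmap,
            atc_map={k: tuple(v) for k, v in amap.items()},
        )
        bundle.validate()
        # precompute the single-parent traversal map for fast resolution
        object.__setattr__(bundle, "_parent_of", bundle._traversal_parents())
        return bundle

    # -- structural validation -------------------------------------------

    def _traversal_edges(self) -> list[ConceptEdge]:
        legal = set(TRAVERSAL_EDGES)
        out = []
        for e in self.edges:
            child = self.concepts.get(e.child_id)
            parent = self.concepts.get(e.parent_id)
            if child is None or parent is None:
                raise TerminologyIntegrityError(
                    f"edge {e.child_id}->{e.parent_id} references unknown concept"
                )
            if (child.kind, parent.kind, e.relation) in legal:
                out.append(e)
        return out

    def _traversal_parents(self) -> dict[int, int]:
        parents: dict[int, list[int]] = {}
        for e in self._traversal_edges():
            parents.setdefault(e.child_id, []).append(e.parent_id)
        flat: dict[int, int] = {}
        for child, ps in parents.items():
            kind = self.concepts[child].kind
            if len(ps) != 1:
                raise TerminologyIntegrityError(
                    f"{kind} concept {child} has {len(ps)} traversal parents "
                    "(expected exactly 1)"
                )
            flat[child] = ps[0]
        return flat

    def validate(self) -> None:
        """Enforce graph invariants; raises naming the offending concept."""
        g = nx.DiGraph()
        for e in self._traversal_edges():
            g.add_edge(e.child_id, e.parent_id)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise TerminologyIntegrityError(f"concept graph has a cycle: {cycle}")
        parents = self._traversal_parents()
        for cid, concept in self.concepts.items():
            if concept.kind == "TPUU":
                parent = parents.get(cid)
                if parent is None or self.concepts[parent].kind != "MPUU":
                    raise TerminologyIntegrityError(
                        f"TPUU concept {cid} has no single MPUU parent"
                    )
            if concept.kind in ("MPUU", "TPUU"):
                if concept.strength_value is None or not concept.strength_unit:
                    raise TerminologyIntegrityError(
                        f"{concept.kind} concept {cid} lacks strength"
                    )
        for mpuu_id, assignments in self.atc_map.items():
            if sum(a.primary for a in assignments) != 1:
                raise TerminologyIntegrityError(
                    f"MPUU {mpuu_id} must have exactly one primary ATC assignment"
                )
        for key, m in self.vendor_map.items():
            target = self.concepts.get(m.target_concept_id)
            if target is None or target.kind not in ("TPUU", "CTPP"):
                raise TerminologyIntegrityError(
                    f"vendor mapping {key} targets non-TPUU/CTPP concept "
                    f"{m.target_concept_id}"
                )

    # -- resolution -------------------------------------------------------

    def ascend_to_mpuu(self, concept_id: int) -> int:
        """Walk CTPP->TPP->TPUU->MPUU (or any suffix) to the unique MPUU."""
        seen = set()
        current = concept_id
        while True:
            concept = self.concepts.get(current)
            if concept is None:
                raise TerminologyIntegrityError(f"unknown concept {current}")
            if concept.kind == "MPUU":
                return current
            if current in seen:  # defensive; validate() forbids cycles
                raise TerminologyIntegrityError(f"cycle at concept {current}")
            seen.add(current)
            nxt = self._parent_of.get(current)
            if nxt is None:
                raise TerminologyIntegrityError(
                    f"{concept.kind} concept {current} has no path to an MPUU"
                )
            current = nxt


def resolve_to_mpuu(vendor: str, vendor_code: str, bundle: TerminologyBundle):
    """Resolve a packing-system code to its MPUU concept id, or UNMAPPED.

    Unmapped (vendor, code) pairs are the raw material for the manual
    mapping workflow; callers collect them via :func:`list_unmapped`.
    """
    mapping = bundle.vendor_map.get((vendor, vendor_code))
    if mapping is None:
        return UNMAPPED
    return bundle.ascend_to_mpuu(mapping.target_concept_id)


def mpuu_to_atc(mpuu_id: int, bundle: TerminologyBundle):
    """Primary ATC code for an MPUU; UNMAPPED when no assignment exists."""
    concept = bundle.concepts.get(mpuu_id)
    if concept is None or concept.kind != "MPUU":
        raise KindError(f"concept {mpuu_id} is not an MPUU")
    assignments = bundle.atc_map.get(mpuu_id)
    if not assignments:
        return UNMAPPED
    return next(a.atc_code for a in assignments if a.primary)


def all_atc_codes(mpuu_id: int, bundle: TerminologyBundle) -> tuple[str, ...]:
    """Every ATC assignment of an MPUU (classification uses all of them)."""
    concept = bundle.concepts.get(mpuu_id)
    if concept is None or concept.kind != "MPUU":
        raise KindError(f"concept {mpuu_id} is not an MPUU")
    return tuple(a.atc_code for a in bundle.atc_map.get(mpuu_id, ()))


def add_manual_mapping(
    bundle: TerminologyBundle,
    vendor: str,
    vendor_code: str,
    target_concept_id: int,
    equivalent_of_name: str | None = None,
) -> TerminologyBundle:
    """Return a new bundle with a pharmacist-supplied mapping added.

    When ``equivalent_of_name`` is given the mapping is a chemically
    equivalent fallback: the drug is counted under the equivalent concept
    but downstream display keeps the original vendor-supplied name so
    nursing staff see the name they know.
    """
    key = (vendor, vendor_code)
    if key in bundle.vendor_map:
        raise MappingConflictError(f"mapping for {key} already exists")
    target = bundle.concepts.get(target_concept_id)
    if target is None or target.kind not in ("TPUU", "CTPP"):
        raise KindError(
            f"manual mapping target {target_concept_id} must be TPUU or CTPP"
        )
    origin = "equivalent_fallback" if equivalent_of_name else "manual"
    new_map = dict(bundle.vendor_map)
    new_map[key] = VendorMapping(
        vendor=vendor,
        vendor_code=vendor_code,
        target_concept_id=target_concept_id,
        origin=origin,
        equivalent_of_name=equivalent_of_name,
    )
    return replace(bundle, vendor_map=new_map)


def list_unmapped(records: Iterable) -> list[tuple[str, str, str, int]]:
    """Distinct unmapped codes in an upload, descending by occurrence count.

    ``records`` is any iterable of medication records carrying ``vendor``,
    ``vendor_code``, ``med_name`` and ``mpuu_id`` attributes; rows whose
    mpuu_id is UNMAPPED (or None) are aggregated. Returns
    (vendor, vendor_code, med_name, count) tuples.
    """
    counts: dict[tuple[str, str, str], int] = {}
    for r in records:
        if r.mpuu_id is UNMAPPED or r.mpuu_id is None:
            key = (r.vendor, r.vendor_code, r.med_name)
            counts[key] = counts.get(key, 0) + 1
    rows = [(v, c, n, k) for (v, c, n), k in counts.items()]
    rows.sort(key=lambda t: (-t[3], t[0], t[1]))
    return rows


# -- delimited-file interchange ------------------------------------------
# A terminology bundle travels as four UTF-8 tab-separated files with header
# rows: concepts.tsv, edges.tsv, vendor_map.tsv, atc_map.tsv. (ddd.tsv, the
# fifth file of the distribution, is consumed by the dose-load module.)

def _opt(value):
    return None if pd.isna(value) else value


def load_bundle(directory) -> TerminologyBundle:
    from pathlib import Path

    d = Path(directory)
    concepts_df = pd.read_csv(d / "concepts.tsv", sep="\t")
    edges_df = pd.read_csv(d / "edges.tsv", sep="\t")
    vendor_df = pd.read_csv(d / "vendor_map.tsv", sep="\t", dtype={"vendor_code": str})
    atc_df = pd.read_csv(d / "atc_map.tsv", sep="\t")
    concepts = [
        Concept(
            concept_id=int(r.concept_id),
            kind=str(r.kind),
            preferred_name=str(r.preferred_name),
            strength_value=_opt(r.strength_value),
            strength_unit=_opt(r.strength_unit),
            dose_form=_opt(r.dose_form),
        )
        for r in concepts_df.itertuples()
    ]
    edges = [
        ConceptEdge(int(r.child_id), int(r.parent_id), str(r.relation))
        for r in edges_df.itertuples()
    ]
    vendor_mappings = [
        VendorMapping(
            vendor=str(r.vendor),
            vendor_code=str(r.vendor_code),
            target_concept_id=int(r.target_concept_id),
            origin=str(r.origin),
            equivalent_of_name=_opt(r.equivalent_of_name),
        )
        for r in vendor_df.itertuples()
    ]
    assignments = [
        AtcAssignment(int(r.mpuu_id), str(r.atc_code), bool(r.primary))
        for r in atc_df.itertuples()
    ]
    return TerminologyBundle.build(concepts, edges, vendor_mappings, assignments)


def save_bundle(bundle: TerminologyBundle, directory) -> None:
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "concept_id": c.concept_id,
                "kind": c.kind,
                "preferred_name": c.preferred_name,
                "strength_value": c.strength_value,
                "strength_unit": c.strength_unit,
                "dose_form": c.dose_form,
            }
            for c in bundle.concepts.values()
        ]
    ).to_csv(d / "concepts.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"child_id": e.child_id, "parent_id": e.parent_id, "relation": e.relation}
            for e in bundle.edges
        ]
    ).to_csv(d / "edges.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "vendor": m.vendor,
                "vendor_code": m.vendor_code,
                "target_concept_id": m.target_concept_id,
                "origin": m.origin,
                "equivalent_of_name": m.equivalent_of_name,
            }
            for m in bundle.vendor_map.values()
        ]
    ).to_csv(d / "vendor_map.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"mpuu_id": a.mpuu_id, "atc_code": a.atc_code, "primary": a.primary}
            for assignments in bundle.atc_map.values()
            for a in assignments
        ]
    ).to_csv(d / "atc_map.tsv", sep="\t", index=False)
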