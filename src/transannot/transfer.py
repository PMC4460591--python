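"""Length-2 transitive annotation transfer with error-propagation controls.

The engine enumerates every admissible ``A - B - C`` path in the knowledge
base (admissibility decided by the ruleset), applies the quality filters
that keep known error sources out of automatic inference, and emits derived
``A -> C`` associations marked ``TRANSITIVE_RELATIONSHIP`` with the full
two-edge provenance retained.

Filters (each is a separate counter in :class:`TransferStats`):

* obsolete      — a support edge, one of its endpoints, or the target
                  ontology term is obsolete;
* recursive     — a support was itself produced by a previous transfer run
                  (never re-used, so no transitive closure can build up);
* computational — a support marked ``SOURCE_COMPUTATIONAL``;
* evidence      — an annotation support whose evidence codes fall entirely
                  inside an excluded profile (default: IEA-only);
* already_known — the derived triple already exists in the KB;
* pseudogene    — functional annotations are never transferred to genes
                  classified as pseudogenes;
* redundant     — the derived ontology term is the target term itself or an
                  ancestor of a term already annotated to the subject (the
                  true-path rule makes it implicit);
* within_run_redundant — the run would emit both a term and its strict
                  ancestor for the same subject; only the most specific is
                  kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import (
    Association,
    Category,
    ConfigurationError,
    FeatureItem,
    Inferred,
    KnowledgeBase,
    SemanticType,
)
from .ontology import OntologyDAG
from .rules import Direction, RuleSet, default_ruleset

_DEFAULT_PROFILES = frozenset({frozenset({"IEA"})})


@dataclass(frozen=True)
class FilterConfig:
    """Error-propagation controls.

    ``excluded_evidence_profiles``: a support annotation whose (non-empty)
    evidence set is a subset of any profile is disqualified; the default
    profile ``{IEA}`` drops IEA-only annotations while keeping mixed ones
    such as ``{IEA, NAS}``.  Edges without evidence information are never
    evidence-filtered.

    ``exclude_pseudogene_functional_targets``: feature-type names to which a
    pseudogene may not be annotated; ``None`` means every ontology-typed
    characteristic plus any type named ``enzyme``.

    Supports produced by a previous transfer run are always excluded; that
    control is structural and cannot be disabled.
    """

    excluded_evidence_profiles: frozenset[frozenset[str]] = _DEFAULT_PROFILES
    exclude_obsolete: bool = True
    exclude_pseudogene_functional_targets: Optional[frozenset[str]] = None
    exclude_source_computational: bool = True

    @property
    def exclude_transferred_support(self) -> bool:
        return True

    def pseudogene_targets(self, kb: KnowledgeBase) -> frozenset[str]:
        if self.exclude_pseudogene_functional_targets is not None:
            return self.exclude_pseudogene_functional_targets
        names = {t.name for t in kb.feature_types.values() if t.is_ontology}
        if "enzyme" in kb.feature_types:
            names.add("enzyme")
        return frozenset(names)


@dataclass(frozen=True)
class TransferredAnnotation:
    """A derived association plus the support-edge pairs that justify it.

    ``provenance`` holds one or more ordered (A-B edge, B-C edge) pairs; the
    two edges of each pair share the middle item and neither is itself a
    transferred annotation.
    """

    association: Association
    provenance: tuple[tuple[Association, Association], ...]
    candidate_only: bool
    middle_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.association.inferred is Inferred.TRANSITIVE_RELATIONSHIP
        assert self.provenance
        for ab, bc in self.provenance:
            assert ab.inferred is not Inferred.TRANSITIVE_RELATIONSHIP
            assert bc.inferred is not Inferred.TRANSITIVE_RELATIONSHIP


@dataclass
class TransferStats:
    matched_paths: int = 0
    rejected: dict[str, int] = field(default_factory=dict)
    emitted_paths: int = 0
    emitted_records: int = 0

    def reject(self, reason: str, n: int = 1) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + n

    @property
    def total_rejected(self) -> int:
        return sum(self.rejected.values())


_REASON_ORDER = ("obsolete", "recursive", "computational", "evidence")


def _support_rejection(assoc: Association, subject_item: FeatureItem,
                       object_item: FeatureItem,
                       cfg: FilterConfig) -> Optional[str]:
    if cfg.exclude_obsolete and (assoc.obsolete or subject_item.obsolete
                                 or object_item.obsolete):
        return "obsolete"
    if assoc.inferred is Inferred.TRANSITIVE_RELATIONSHIP:
        return "recursive"
    if cfg.exclude_source_computational and \
            assoc.inferred is Inferred.SOURCE_COMPUTATIONAL:
        return "computational"
    if assoc.semantic_type is SemanticType.ANNOTATED_TO and assoc.evidence_codes:
        for profile in cfg.excluded_evidence_profiles:
            if assoc.evidence_codes <= profile:
                return "evidence"
    return None


def eligible_support(assoc: Association, subject_item: FeatureItem,
                     object_item: FeatureItem, cfg: FilterConfig) -> bool:
    """May this stored edge support a transitive transfer?"""
    return _support_rejection(assoc, subject_item, object_item, cfg) is None


def is_redundant_ontology_target(kb: KnowledgeBase, entity_id: str, term: str,
                                 dag: OntologyDAG) -> bool:
    """True when ``term`` is already implied for ``entity_id`` by the
    true-path rule: it equals, or is an ancestor of, a term already
    annotated to the entity by a non-transferred, non-obsolete association
    in the same ontology."""
    if term not in dag:
        raise KeyError(f"unknown ontology term {term!r}")
    for a in kb.by_subject(entity_id):
        if a.semantic_type is not SemanticType.ANNOTATED_TO:
            continue
        if a.inferred is Inferred.TRANSITIVE_RELATIONSHIP or a.obsolete:
            continue
        if a.object_id in dag and term in dag.ancestors(a.object_id):
            return True
    return False


def _incident_ab(kb: KnowledgeBase, b: str):
    """Traversals arriving at middle item ``b`` as (edge, A id, direction)."""
    for e in kb.by_object(b):
        yield e, e.subject_id, Direction.FORWARD
    for e in kb.by_subject(b):
        yield e, e.object_id, Direction.REVERSE


def _incident_bc(kb: KnowledgeBase, b: str):
    """Traversals leaving middle item ``b`` as (edge, C id, direction)."""
    for e in kb.by_subject(b):
        yield e, e.object_id, Direction.FORWARD
    for e in kb.by_object(b):
        yield e, e.subject_id, Direction.REVERSE


def _provenance_sort_key(pair: tuple[Association, Association]) -> tuple:
    ab, bc = pair
    return (*ab.sort_key(), *bc.sort_key())


def transfer(kb: KnowledgeBase, ruleset: Optional[RuleSet] = None,
             cfg: Optional[FilterConfig] = None) -> list[TransferredAnnotation]:
    """Enumerate and filter all admissible length-2 transfers."""
    out, _ = transfer_with_stats(kb, ruleset, cfg)
    return out


def transfer_with_stats(
    kb: KnowledgeBase,
    ruleset: Optional[RuleSet] = None,
    cfg: Optional[FilterConfig] = None,
) -> tuple[list[TransferredAnnotation], TransferStats]:
    if ruleset is None:
        ruleset = default_ruleset()
    if cfg is None:
        cfg = FilterConfig()
    ruleset.validate_against(kb)
    stats = TransferStats()
    pseudo_targets = cfg.pseudogene_targets(kb)

    # (subject, object, derived sem) -> {"rule", "pairs": [(ab, bc, middle)]}
    found: dict[tuple, dict] = {}

    for b, b_item in kb.items.items():
        type_b = kb.feature_types[b_item.feature_type]
        ab_list = list(_incident_ab(kb, b))
        bc_list = list(_incident_bc(kb, b))
        if not ab_list or not bc_list:
            continue
        for e1, a, d1 in ab_list:
            type_a = kb.type_of(a)
            for e2, c, d2 in bc_list:
                if e1 is e2 or a == c:
                    continue
                rule = ruleset.match(type_a, e1.semantic_type, d1,
                                     type_b, e2.semantic_type, d2,
                                     kb.type_of(c))
                if rule is None:
                    continue
                stats.matched_paths += 1
                reason = _support_rejection(e1, kb.items[e1.subject_id],
                                            kb.items[e1.object_id], cfg)
                if reason is None:
                    reason = _support_rejection(e2, kb.items[e2.subject_id],
                                                kb.items[e2.object_id], cfg)
                if reason is not None:
                    stats.reject(reason)
                    continue
                derived = rule.derived_sem
                subj, obj = a, c
                if derived is SemanticType.INTERACT_WITH and obj < subj:
                    subj, obj = obj, subj
                if kb.has_association(subj, obj, derived):
                    stats.reject("already_known")
                    continue
                type_c = kb.type_of(c)
                a_item = kb.items[a]
                if a_item.item_class == "pseudogene" and \
                        type_c.name in pseudo_targets:
                    stats.reject("pseudogene")
                    continue
                if type_c.is_ontology:
                    dag = kb.ontologies.get(type_c.name)
                    if dag is not None and c in dag:
                        if cfg.exclude_obsolete and c in dag.obsolete:
                            stats.reject("obsolete")
                            continue
                        if is_redundant_ontology_target(kb, a, c, dag):
                            stats.reject("redundant")
                            continue
                key = (subj, obj, derived)
                rec = found.setdefault(key, {"rule": rule, "pairs": []})
                rec["pairs"].append((e1, e2, b))

    # within-run true-path redundancy: keep only the most specific ontology
    # terms per (subject, ontology).  Terms transferred by a previous run
    # (already stored, marked TRANSITIVE_RELATIONSHIP) dominate as well —
    # they are outputs of this same procedure — which makes repeated runs
    # idempotent.
    dropped_keys = set()
    by_subject_dag: dict[tuple, list] = {}
    for key in found:
        subj, obj, derived = key
        type_c = kb.type_of(obj)
        if derived is SemanticType.ANNOTATED_TO and type_c.is_ontology:
            dag = kb.ontologies.get(type_c.name)
            if dag is not None and obj in dag:
                by_subject_dag.setdefault((subj, type_c.name), []).append(obj)
    for (subj, tname), terms in by_subject_dag.items():
        dag = kb.ontologies[tname]
        dominators = set(terms)
        for a in kb.by_subject(subj):
            if (a.semantic_type is SemanticType.ANNOTATED_TO
                    and a.inferred is Inferred.TRANSITIVE_RELATIONSHIP
                    and not a.obsolete and a.object_id in dag):
                dominators.add(a.object_id)
        for t in dominators:
            strict_anc = dag.ancestors(t) - {t}
            for anc in strict_anc & set(terms):
                if anc != t:
                    dropped_keys.add((subj, anc, SemanticType.ANNOTATED_TO))
    for key in dropped_keys:
        stats.reject("within_run_redundant", n=len(found[key]["pairs"]))
        del found[key]

    results: list[TransferredAnnotation] = []
    for key in sorted(found, key=lambda k: (k[0], k[1], k[2].value)):
        subj, obj, derived = key
        rec = found[key]
        pairs = sorted(((ab, bc) for ab, bc, _ in rec["pairs"]),
                       key=_provenance_sort_key)
        middles = tuple(sorted({m for _, _, m in rec["pairs"]}))
        evidence = frozenset().union(*(ab.evidence_codes | bc.evidence_codes
                                       for ab, bc in pairs))
        first_ab, first_bc = pairs[0]
        assoc = Association(
            subject_id=subj, object_id=obj, semantic_type=derived,
            evidence_codes=evidence,
            source=f"transitive_relationship({first_ab.source},{first_bc.source})",
            inferred=Inferred.TRANSITIVE_RELATIONSHIP, obsolete=False)
        results.append(TransferredAnnotation(
            association=assoc, provenance=tuple(pairs),
            candidate_only=rec["rule"].candidate_only, middle_ids=middles))
        stats.emitted_paths += len(pairs)
        stats.emitted_records += 1
    return results, stats


def apply_transfers(kb: KnowledgeBase,
                    transfers: Iterable[TransferredAnnotation]) -> int:
    """Add derived associations to the KB (skipping exact duplicates);
    returns the number actually added."""
    added = 0
    for t in transfers:
        if t.association.key in kb._assoc_keys:
            continue
        kb.add_association(t.association)
        added += 1
    return added
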