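"""Typed data model for feature items, associations and knowledge bases.

A knowledge base relates *feature items* — instances of declared feature
types — through directed semantic associations.  Feature types fall into two
categories: biomolecular entities (DNA sequences, genes, transcripts,
proteins) and biomedical-molecular characteristics (biological functions,
pathways, enzymes, genetic disorders).  Characteristic types may carry an
ontology (a rooted is_a DAG over their items).

The semantic type of an association constrains which categories may stand on
each side: ``ENCODES`` links entities, ``ANNOTATED_TO`` links an entity to a
characteristic, ``ASSOCIATED_WITH`` links characteristics, and
``INTERACT_WITH`` is symmetric (stored once with canonically ordered
endpoints).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .ontology import OntologyDAG


class TransannotError(Exception):
    """Base class for all package errors."""


class KBValidationError(TransannotError):
    """A knowledge-base invariant is violated."""


class UnknownItemError(TransannotError, KeyError):
    """A referenced item, term or type does not exist."""


class ConfigurationError(TransannotError):
    """A ruleset or filter configuration is inconsistent with the KB."""


class Category(str, enum.Enum):
    BIOMOLECULAR_ENTITY = "BIOMOLECULAR_ENTITY"
    BIOMEDICAL_CHARACTERISTIC = "BIOMEDICAL_CHARACTERISTIC"


class SemanticType(str, enum.Enum):
    ENCODES = "ENCODES"
    RELATED_TO = "RELATED_TO"
    INTERACT_WITH = "INTERACT_WITH"
    ANNOTATED_TO = "ANNOTATED_TO"
    ASSOCIATED_WITH = "ASSOCIATED_WITH"


class Inferred(str, enum.Enum):
    SOURCE = "SOURCE"
    SOURCE_COMPUTATIONAL = "SOURCE_COMPUTATIONAL"
    TRANSITIVE_RELATIONSHIP = "TRANSITIVE_RELATIONSHIP"


#: symbolic marker written into the ``inferred`` attribute of every
#: transferred annotation, so derived edges are always distinguishable from
#: source data and are never re-used as supports.
TRANSITIVE_RELATIONSHIP = Inferred.TRANSITIVE_RELATIONSHIP


@dataclass(frozen=True)
class FeatureType:
    name: str
    category: Category
    is_ontology: bool = False

    def __post_init__(self) -> None:
        if self.is_ontology and self.category is not Category.BIOMEDICAL_CHARACTERISTIC:
            raise KBValidationError(
                f"feature type {self.name!r}: only biomedical characteristics "
                "may carry an ontology"
            )


@dataclass(frozen=True)
class FeatureItem:
    item_id: str
    feature_type: str
    obsolete: bool = False
    item_class: Optional[str] = None
    source: str = ""


@dataclass(frozen=True)
class Association:
    """One directed semantic edge between two feature items.

    ``evidence_codes`` uses GO/GOA-style codes (``IEA``, ``NAS``, ...); an
    empty set means the source provides no evidence information (e.g.
    OMIM-style gene-disorder rows).
    """

    subject_id: str
    object_id: str
    semantic_type: SemanticType
    evidence_codes: frozenset[str] = frozenset()
    source: str = ""
    inferred: Inferred = Inferred.SOURCE
    obsolete: bool = False

    @property
    def triple(self) -> tuple[str, str, SemanticType]:
        return (self.subject_id, self.object_id, self.semantic_type)

    @property
    def key(self) -> tuple[str, str, SemanticType, str]:
        return (self.subject_id, self.object_id, self.semantic_type, self.source)

    def sort_key(self) -> tuple:
        return (
            self.subject_id,
            self.object_id,
            self.semantic_type.value,
            self.source,
            sorted(self.evidence_codes),
        )


@dataclass(frozen=True)
class PPIRecord:
    """A protein-protein interaction, symmetric, endpoints canonically ordered."""

    ppi_id: str
    protein_1_id: str
    protein_2_id: str
    source: str = ""
    obsolete: bool = False

    @classmethod
    def make(cls, ppi_id: str, p1: str, p2: str, source: str = "",
             obsolete: bool = False) -> "PPIRecord":
        if p2 < p1:
            p1, p2 = p2, p1
        return cls(ppi_id, p1, p2, source, obsolete)


# (subject type, semantic type, object type) -> "1:1" | "1:n" | "n:n"
Cardinality = str
CARDINALITIES = ("1:1", "1:n", "n:n")


class KnowledgeBase:
    """Feature types, items, associations, PPIs and per-type ontologies.

    All mutation goes through ``add_*`` methods, which enforce the model
    invariants eagerly so downstream modules may assume a valid KB.
    """

    def __init__(self) -> None:
        self.feature_types: dict[str, FeatureType] = {}
        self.items: dict[str, FeatureItem] = {}
        self.associations: list[Association] = []
        self.ppis: dict[str, PPIRecord] = {}
        self.ontologies: dict[str, OntologyDAG] = {}
        self.cardinalities: dict[tuple[str, SemanticType, str], Cardinality] = {}
        self._by_subject: dict[str, list[Association]] = {}
        self._by_object: dict[str, list[Association]] = {}
        self._assoc_keys: set[tuple] = set()

    # ------------------------------------------------------------------ types

    def add_feature_type(self, ftype: FeatureType,
                         ontology: Optional[OntologyDAG] = None) -> None:
        if ftype.name in self.feature_types:
            raise KBValidationError(f"duplicate feature type {ftype.name!r}")
        if ftype.is_ontology and ontology is None:
            ontology = OntologyDAG()
        self.feature_types[ftype.name] = ftype
        if ontology is not None:
            if not ftype.is_ontology:
                raise KBValidationError(
                    f"feature type {ftype.name!r} is not ontology-typed")
            self.ontologies[ftype.name] = ontology

    def declare_cardinality(self, subject_type: str, semantic_type: SemanticType,
                            object_type: str, cardinality: Cardinality) -> None:
        if cardinality not in CARDINALITIES:
            raise KBValidationError(f"unknown cardinality {cardinality!r}")
        self.cardinalities[(subject_type, semantic_type, object_type)] = cardinality

    # ------------------------------------------------------------------ items

    def add_item(self, item: FeatureItem) -> None:
        ftype = self.feature_types.get(item.feature_type)
        if ftype is None:
            raise UnknownItemError(
                f"item {item.item_id!r}: unknown feature type {item.feature_type!r}")
        if item.item_id in self.items:
            raise KBValidationError(f"duplicate item id {item.item_id!r}")
        if item.item_class == "pseudogene" and ftype.name != "gene":
            raise KBValidationError(
                f"item {item.item_id!r}: item_class 'pseudogene' is only "
                "allowed on gene-typed items")
        self.items[item.item_id] = item

    def type_of(self, item_id: str) -> FeatureType:
        item = self.items.get(item_id)
        if item is None:
            raise UnknownItemError(f"unknown item {item_id!r}")
        return self.feature_types[item.feature_type]

    def category_of(self, item_id: str) -> Category:
        return self.type_of(item_id).category

    # ----------------------------------------------------------- associations

    def add_association(self, assoc: Association) -> Association:
        """Validate and store one association; returns the stored record
        (possibly endpoint-swapped for symmetric ``INTERACT_WITH``)."""
        if assoc.semantic_type is SemanticType.INTERACT_WITH and \
                assoc.object_id < assoc.subject_id:
            assoc = replace(assoc, subject_id=assoc.object_id,
                            object_id=assoc.subject_id)
        scat = self.category_of(assoc.subject_id)
        ocat = self.category_of(assoc.object_id)
        st = assoc.semantic_type
        if st is SemanticType.ENCODES:
            if scat is not Category.BIOMOLECULAR_ENTITY or \
                    ocat is not Category.BIOMOLECULAR_ENTITY:
                raise KBValidationError(
                    f"{assoc.triple}: ENCODES only links biomolecular entities")
        elif st is SemanticType.ANNOTATED_TO:
            if scat is not Category.BIOMOLECULAR_ENTITY or \
                    ocat is not Category.BIOMEDICAL_CHARACTERISTIC:
                raise KBValidationError(
                    f"{assoc.triple}: ANNOTATED_TO only links an entity to a "
                    "characteristic")
        elif st is SemanticType.ASSOCIATED_WITH:
            if scat is not Category.BIOMEDICAL_CHARACTERISTIC or \
                    ocat is not Category.BIOMEDICAL_CHARACTERISTIC:
                raise KBValidationError(
                    f"{assoc.triple}: ASSOCIATED_WITH only links characteristics")
        if assoc.key in self._assoc_keys:
            raise KBValidationError(f"duplicate association {assoc.key}")
        self._assoc_keys.add(assoc.key)
        self.associations.append(assoc)
        self._by_subject.setdefault(assoc.subject_id, []).append(assoc)
        self._by_object.setdefault(assoc.object_id, []).append(assoc)
        return assoc

    def by_subject(self, item_id: str) -> list[Association]:
        return self._by_subject.get(item_id, [])

    def by_object(self, item_id: str) -> list[Association]:
        return self._by_object.get(item_id, [])

    def has_association(self, subject_id: str, object_id: str,
                        semantic_type: SemanticType,
                        include_obsolete: bool = False) -> bool:
        """True if any stored association carries this triple (symmetric
        triples are checked in canonical order)."""
        if semantic_type is SemanticType.INTERACT_WITH and object_id < subject_id:
            subject_id, object_id = object_id, subject_id
        for a in self._by_subject.get(subject_id, []):
            if a.object_id == object_id and a.semantic_type is semantic_type:
                if include_obsolete or not a.obsolete:
                    return True
        return False

    # ------------------------------------------------------------------- PPIs

    def add_ppi(self, ppi: PPIRecord) -> None:
        ppi = PPIRecord.make(ppi.ppi_id, ppi.protein_1_id, ppi.protein_2_id,
                             ppi.source, ppi.obsolete)
        for pid in (ppi.protein_1_id, ppi.protein_2_id):
            if pid not in self.items:
                raise UnknownItemError(
                    f"PPI {ppi.ppi_id!r}: unknown protein {pid!r}")
        if ppi.ppi_id in self.ppis:
            raise KBValidationError(f"duplicate PPI id {ppi.ppi_id!r}")
        self.ppis[ppi.ppi_id] = ppi

    # ------------------------------------------------------------- validation

    def validate(self) -> None:
        """Re-check every invariant; raises ``KBValidationError`` on the
        first violation.  ``add_*`` already enforces these eagerly; this is
        the belt-and-braces check run after loading a bundle."""
        for assoc in self.associations:
            for endpoint in (assoc.subject_id, assoc.object_id):
                if endpoint not in self.items:
                    raise KBValidationError(
                        f"association {assoc.triple}: dangling endpoint "
                        f"{endpoint!r}")
        for name, dag in self.ontologies.items():
            dag.validate()

    # ------------------------------------------------------------------ misc

    def ontology_for_type(self, type_name: str) -> Optional[OntologyDAG]:
        return self.ontologies.get(type_name)

    def copy(self) -> "KnowledgeBase":
        """Shallow-structural copy: shares immutable records, owns containers."""
        kb = KnowledgeBase.__new__(KnowledgeBase)
        kb.feature_types = dict(self.feature_types)
        kb.items = dict(self.items)
        kb.associations = list(self.associations)
        kb.ppis = dict(self.ppis)
        kb.ontologies = dict(self.ontologies)
        kb.cardinalities = dict(self.cardinalities)
        kb._by_subject = {k: list(v) for k, v in self._by_subject.items()}
        kb._by_object = {k: list(v) for k, v in self._by_object.items()}
        kb._assoc_keys = set(self._assoc_keys)
        return kb

    def remove_associations(self, predicate) -> list[Association]:
        """Remove (and return) every association for which ``predicate`` is
        true; used by the leave-out evaluation to hide known annotations."""
        removed = [a for a in self.associations if predicate(a)]
        if not removed:
            return []
        kept = [a for a in self.associations if not predicate(a)]
        self.associations = kept
        self._assoc_keys = {a.key for a in kept}
        self._by_subject = {}
        self._by_object = {}
        for a in kept:
            self._by_subject.setdefault(a.subject_id, []).append(a)
            self._by_object.setdefault(a.object_id, []).append(a)
        return removed
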