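"""Admissibility rules for length-2 transitive annotation transfer.

A :class:`TransferRule` describes one admissible pattern
``A -[sem_ab]- B -[sem_bc]- C`` in terms of the categories (or concrete
feature-type names) of the three items, the semantic types of the two
support edges, and the direction in which each stored edge is traversed
(``REVERSE`` walks a stored edge against its direction; ``EITHER`` is meant
for the symmetric ``INTERACT_WITH``).  A matching pattern yields a derived
``A -[derived_sem]-> C`` edge.

The semantics follow the cardinality reasoning of the underlying biology:
a relationship may be walked transitively only when its cardinality toward
the walked direction is 1:1 or 1:n.  Walking gene->protein ``ENCODES`` in
reverse crosses a 1-to-n edge against the "1" side (a gene may encode many
proteins through alternative splicing), so any rule doing that can only
yield *candidate* annotations (``candidate_only=True``).

Rules are data, not code: a ruleset can be loaded from a YAML config, and
the shipped default reproduces the reference rule system exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import yaml

from .model import (
    Category,
    ConfigurationError,
    FeatureType,
    KBValidationError,
    KnowledgeBase,
    SemanticType,
)


class Direction(str, enum.Enum):
    FORWARD = "FORWARD"
    REVERSE = "REVERSE"
    EITHER = "EITHER"


_CATEGORY_NAMES = {c.value for c in Category}


@dataclass(frozen=True)
class TransferRule:
    """One admissible length-2 pattern.

    ``category_a``/``b``/``c`` are either a :class:`Category` value name
    (matching any feature type of that category) or a concrete feature-type
    name (matching only that type).
    """

    name: str
    category_a: str
    sem_ab: SemanticType
    dir_ab: Direction
    category_b: str
    sem_bc: SemanticType
    dir_bc: Direction
    category_c: str
    derived_sem: SemanticType
    candidate_only: bool = False

    def __post_init__(self) -> None:
        reverse_encodes = (
            (self.sem_ab is SemanticType.ENCODES and self.dir_ab is Direction.REVERSE)
            or (self.sem_bc is SemanticType.ENCODES and self.dir_bc is Direction.REVERSE)
        )
        if reverse_encodes != self.candidate_only:
            raise KBValidationError(
                f"rule {self.name!r}: candidate_only must be set exactly when "
                "the pattern traverses a 1-to-n ENCODES edge in reverse")
        for d, st in ((self.dir_ab, self.sem_ab), (self.dir_bc, self.sem_bc)):
            if d is Direction.EITHER and st is not SemanticType.INTERACT_WITH:
                raise KBValidationError(
                    f"rule {self.name!r}: EITHER direction is only meaningful "
                    "for the symmetric INTERACT_WITH")

    def pattern_key(self) -> tuple:
        return (self.category_a, self.sem_ab, self.dir_ab, self.category_b,
                self.sem_bc, self.dir_bc, self.category_c)


def _field_matches(pattern_field: str, ftype: FeatureType) -> bool:
    return pattern_field == ftype.name or pattern_field == ftype.category.value


def _dir_matches(rule_dir: Direction, traversal_dir: Direction) -> bool:
    return rule_dir is Direction.EITHER or rule_dir is traversal_dir


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[TransferRule, ...]

    def __post_init__(self) -> None:
        seen = set()
        for rule in self.rules:
            key = rule.pattern_key()
            if key in seen:
                raise KBValidationError(
                    f"ruleset: two rules match the identical pattern {key}")
            seen.add(key)

    def match(self, type_a: FeatureType, sem_ab: SemanticType, dir_ab: Direction,
              type_b: FeatureType, sem_bc: SemanticType, dir_bc: Direction,
              type_c: FeatureType) -> Optional[TransferRule]:
        hit: Optional[TransferRule] = None
        for rule in self.rules:
            if (rule.sem_ab is sem_ab and rule.sem_bc is sem_bc
                    and _dir_matches(rule.dir_ab, dir_ab)
                    and _dir_matches(rule.dir_bc, dir_bc)
                    and _field_matches(rule.category_a, type_a)
                    and _field_matches(rule.category_b, type_b)
                    and _field_matches(rule.category_c, type_c)):
                if hit is not None:
                    raise ConfigurationError(
                        f"rules {hit.name!r} and {rule.name!r} both match "
                        f"({type_a.name}, {sem_ab.value}, {type_b.name}, "
                        f"{sem_bc.value}, {type_c.name})")
                hit = rule
        return hit

    def validate_against(self, kb: KnowledgeBase) -> None:
        """Every concrete type name used by a rule must exist in the KB, and
        every derivable edge must be category-legal for the KB's types."""
        known = set(kb.feature_types) | _CATEGORY_NAMES
        for rule in self.rules:
            for f in (rule.category_a, rule.category_b, rule.category_c):
                if f not in known:
                    raise ConfigurationError(
                        f"rule {rule.name!r} references {f!r}, which is "
                        "neither a category nor a feature type of this KB")
            for ta in _concrete_types(kb, rule.category_a):
                for tc in _concrete_types(kb, rule.category_c):
                    _check_derived_legal(rule, ta, tc)


def _concrete_types(kb: KnowledgeBase, pattern_field: str) -> list[FeatureType]:
    if pattern_field in _CATEGORY_NAMES:
        cat = Category(pattern_field)
        return [t for t in kb.feature_types.values() if t.category is cat]
    return [kb.feature_types[pattern_field]]


def _check_derived_legal(rule: TransferRule, type_a: FeatureType,
                         type_c: FeatureType) -> None:
    st = rule.derived_sem
    ent = Category.BIOMOLECULAR_ENTITY
    char = Category.BIOMEDICAL_CHARACTERISTIC
    ok = True
    if st is SemanticType.ENCODES:
        ok = type_a.category is ent and type_c.category is ent
    elif st is SemanticType.ANNOTATED_TO:
        ok = type_a.category is ent and type_c.category is char
    elif st is SemanticType.ASSOCIATED_WITH:
        ok = type_a.category is char and type_c.category is char
    elif st is SemanticType.RELATED_TO:
        ok = type_a.category is ent and type_c.category is ent
    if not ok:
        raise ConfigurationError(
            f"rule {rule.name!r} would derive an illegal "
            f"{type_a.name} -{st.value}-> {type_c.name} edge")


def match_rule(ruleset: RuleSet, type_a: FeatureType, sem_ab: SemanticType,
               dir_ab: Direction, type_b: FeatureType, sem_bc: SemanticType,
               dir_bc: Direction, type_c: FeatureType) -> Optional[TransferRule]:
    """Deterministic lookup of the admissible rule for a concrete pattern;
    None when the pattern is outside the ruleset."""
    return ruleset.match(type_a, sem_ab, dir_ab, type_b, sem_bc, dir_bc, type_c)


def default_ruleset() -> RuleSet:
    """The reference rule system.

    * R1 — protein annotations propagate to the encoding gene: the
      gene->protein ``ENCODES`` edge is 1:1 (or 1:n under alternative
      splicing) from the protein side, so every characteristic annotated to
      an encoded protein belongs to the gene.
    * R2 — chained ``ENCODES`` stays ``ENCODES``.
    * R3 — other specific protein relationships to biomolecular entities
      (e.g. transcripts, DNA sequences) propagate to the gene as the generic
      ``RELATED_TO``.
    * R4 — genetic-disorder annotations of a gene flow to its encoded
      proteins only as *candidates*: the traversal walks ``ENCODES`` in
      reverse, and under alternative splicing a gene can encode multiple
      proteins with different characteristics.

    No rule has a characteristic as middle item, and no rule derives a
    characteristic-characteristic edge (those relationships are n:n and are
    not transferable).  PPI-disorder candidates are a three-support pattern
    handled by :mod:`transannot.candidates`, not by a plain length-2 rule.
    """
    return RuleSet(rules=(
        TransferRule(
            name="gene_from_protein_annotation",
            category_a="gene", sem_ab=SemanticType.ENCODES, dir_ab=Direction.FORWARD,
            category_b="protein", sem_bc=SemanticType.ANNOTATED_TO,
            dir_bc=Direction.FORWARD,
            category_c=Category.BIOMEDICAL_CHARACTERISTIC.value,
            derived_sem=SemanticType.ANNOTATED_TO, candidate_only=False),
        TransferRule(
            name="encodes_chain",
            category_a=Category.BIOMOLECULAR_ENTITY.value,
            sem_ab=SemanticType.ENCODES, dir_ab=Direction.FORWARD,
            category_b=Category.BIOMOLECULAR_ENTITY.value,
            sem_bc=SemanticType.ENCODES, dir_bc=Direction.FORWARD,
            category_c=Category.BIOMOLECULAR_ENTITY.value,
            derived_sem=SemanticType.ENCODES, candidate_only=False),
        TransferRule(
            name="gene_from_protein_related_entity",
            category_a="gene", sem_ab=SemanticType.ENCODES, dir_ab=Direction.FORWARD,
            category_b="protein", sem_bc=SemanticType.RELATED_TO,
            dir_bc=Direction.FORWARD,
            category_c=Category.BIOMOLECULAR_ENTITY.value,
            derived_sem=SemanticType.RELATED_TO, candidate_only=False),
        TransferRule(
            name="protein_disorder_candidate",
            category_a="protein", sem_ab=SemanticType.ENCODES,
            dir_ab=Direction.REVERSE,
            category_b="gene", sem_bc=SemanticType.ANNOTATED_TO,
            dir_bc=Direction.FORWARD,
            category_c="genetic_disorder",
            derived_sem=SemanticType.ANNOTATED_TO, candidate_only=True),
    ))


# ------------------------------------------------------------- serialization

def ruleset_to_dicts(ruleset: RuleSet) -> list[dict]:
    out = []
    for r in ruleset.rules:
        out.append({
            "name": r.name,
            "category_a": r.category_a, "sem_ab": r.sem_ab.value,
            "dir_ab": r.dir_ab.value,
            "category_b": r.category_b, "sem_bc": r.sem_bc.value,
            "dir_bc": r.dir_bc.value,
            "category_c": r.category_c, "derived_sem": r.derived_sem.value,
            "candidate_only": r.candidate_only,
        })
    return out


def ruleset_from_dicts(records: list[dict]) -> RuleSet:
    rules = []
    for rec in records:
        rules.append(TransferRule(
            name=rec["name"],
            category_a=rec["category_a"],
            sem_ab=SemanticType(rec["sem_ab"]),
            dir_ab=Direction(rec["dir_ab"]),
            category_b=rec["category_b"],
            sem_bc=SemanticType(rec["sem_bc"]),
            dir_bc=Direction(rec["dir_bc"]),
            category_c=rec["category_c"],
            derived_sem=SemanticType(rec["derived_sem"]),
            candidate_only=bool(rec["candidate_only"]),
        ))
    return RuleSet(rules=tuple(rules))


def save_ruleset(ruleset: RuleSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"rules": ruleset_to_dicts(ruleset)}, fh,
                       sort_keys=False)


def load_ruleset(path) -> RuleSet:
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "rules" not in payload:
        raise ConfigurationError(f"{path}: not a ruleset file (missing 'rules')")
    return ruleset_from_dicts(payload["rules"])


def packaged_default_ruleset() -> RuleSet:
    """The default ruleset as shipped in the package's config file."""
    text = resources.files("transannot").joinpath("data/default_rules.yaml") \
        .read_text(encoding="utf-8")
    return ruleset_from_dicts(yaml.safe_load(text)["rules"])
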