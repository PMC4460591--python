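"""Leave-out estimation of transfer recall and precision.

All known gene annotations of the requested target types are hidden from a
copy of the KB; the transfer engine then re-derives gene annotations from
the remaining protein annotations and ENCODES edges alone.  The hidden
annotations serve only as the comparison standard: recall is the fraction
of known annotations re-identified, precision the fraction of identified
annotations that were known.  Because available annotations are incomplete
by definition, the precision figure is an approximation (an "unknown"
identification may simply be missing from the sources rather than wrong).

Hiding the gene annotations also disables the ancestor-redundancy check
against them, so the identified set is a superset of what a production run
would emit for the same types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import Inferred, KnowledgeBase, SemanticType
from .rules import RuleSet
from .transfer import FilterConfig, transfer


@dataclass
class TypeCounts:
    n_known: int = 0
    n_identified: int = 0
    n_overlap: int = 0

    @property
    def recall(self) -> Optional[float]:
        """Undefined (None) when no known annotation exists for the type."""
        if self.n_known == 0:
            return None
        return self.n_overlap / self.n_known

    @property
    def precision(self) -> Optional[float]:
        if self.n_identified == 0:
            return None
        return self.n_overlap / self.n_identified


@dataclass
class EvalResult:
    per_type: dict[str, TypeCounts] = field(default_factory=dict)
    overall: TypeCounts = field(default_factory=TypeCounts)
    #: genes carrying hidden annotations but no usable ENCODES edge; their
    #: annotations are legitimate misses, reported for transparency.
    n_known_genes_without_encodes: int = 0


def leave_out_eval(
    kb: KnowledgeBase,
    ruleset: Optional[RuleSet] = None,
    cfg: Optional[FilterConfig] = None,
    target_types: Iterable[str] = (),
    subject_type: str = "gene",
) -> EvalResult:
    """Hide gene annotations of ``target_types``, re-derive, compare.

    Known = the hidden non-obsolete source annotations (computationally
    derived ones included: their misses count against recall).  Matching is
    exact on (gene, target) pairs; per-type counts are pooled
    (micro-averaged) into the overall figure.
    """
    target_types = list(target_types)
    unknown = [t for t in target_types if t not in kb.feature_types]
    if unknown:
        raise KeyError(f"unknown target feature types: {unknown}")
    ttypes = set(target_types)

    def _is_gene_target(a) -> bool:
        return (kb.items[a.subject_id].feature_type == subject_type
                and kb.items[a.object_id].feature_type in ttypes
                and a.semantic_type in (SemanticType.ANNOTATED_TO,
                                        SemanticType.RELATED_TO))

    masked = kb.copy()
    hidden = masked.remove_associations(_is_gene_target)

    known: dict[str, set[tuple[str, str]]] = {t: set() for t in target_types}
    known_genes: set[str] = set()
    for a in hidden:
        if a.inferred is Inferred.TRANSITIVE_RELATIONSHIP or a.obsolete:
            continue
        known[kb.items[a.object_id].feature_type].add((a.subject_id, a.object_id))
        known_genes.add(a.subject_id)

    identified: dict[str, set[tuple[str, str]]] = {t: set() for t in target_types}
    for t in transfer(masked, ruleset, cfg):
        if t.candidate_only:
            continue
        a = t.association
        if kb.items[a.subject_id].feature_type != subject_type:
            continue
        obj_type = kb.items[a.object_id].feature_type
        if obj_type in ttypes:
            identified[obj_type].add((a.subject_id, a.object_id))

    result = EvalResult()
    for t in target_types:
        counts = TypeCounts(
            n_known=len(known[t]),
            n_identified=len(identified[t]),
            n_overlap=len(known[t] & identified[t]))
        result.per_type[t] = counts
        result.overall.n_known += counts.n_known
        result.overall.n_identified += counts.n_identified
        result.overall.n_overlap += counts.n_overlap

    genes_with_encodes = {
        a.subject_id for a in kb.associations
        if a.semantic_type is SemanticType.ENCODES and not a.obsolete
        and kb.items[a.subject_id].feature_type == subject_type}
    result.n_known_genes_without_encodes = len(known_genes - genes_with_encodes)
    return result
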