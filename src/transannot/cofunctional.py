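"""LCA-level co-functional assessment of genes sharing a pathway.

A transferred gene-pathway annotation is plausible when the gene's known
functional (ontology) annotations resemble those of the genes already known
in that pathway.  For a gene g and each known partner gene G of pathway P,
the pairwise statistic is the maximum level of the lowest common ancestors
over all pairs of their ontology annotations (MaxL(g-G)); per gene, MaxL is
the maximum and AvgL the arithmetic mean of these pairwise maxima over
partners that have ontology annotations.  High levels mean the most
specific shared function is deep in the hierarchy.  Genes without any
usable ontology annotation (or with no annotated partner) fall into the
separate category N.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import Inferred, KnowledgeBase, SemanticType
from .ontology import OntologyDAG, pair_max_lca_level
from .transfer import FilterConfig


class Scope(str, enum.Enum):
    KNOWN_ONLY = "KNOWN_ONLY"
    KNOWN_PLUS_TRANSFERRED = "KNOWN_PLUS_TRANSFERRED"


class Role(str, enum.Enum):
    TRANSFERRED = "TRANSFERRED"
    KNOWN = "KNOWN"


@dataclass(frozen=True)
class CoFuncScore:
    """Per (gene, pathway) MaxL/AvgL record; ``None`` levels mean category N
    (no usable ontology annotation for the gene, or no annotated partner)."""

    gene_id: str
    pathway_id: str
    role: Role
    max_level: Optional[int]
    avg_level: Optional[float]

    def __post_init__(self) -> None:
        if self.max_level is not None and self.avg_level is not None:
            assert self.avg_level <= self.max_level + 1e-9

    @property
    def is_n(self) -> bool:
        return self.max_level is None


def _gene_terms(kb: KnowledgeBase, dag: OntologyDAG, function_type: str,
                scope: Scope, cfg: FilterConfig) -> dict[str, set[str]]:
    """Usable ontology annotations per gene.

    Known annotations follow the global evidence policy (IEA-only excluded
    by default); transferred ones are included under
    ``KNOWN_PLUS_TRANSFERRED`` (their supports already passed the filters).
    """
    terms: dict[str, set[str]] = {}
    for a in kb.associations:
        if a.semantic_type is not SemanticType.ANNOTATED_TO or a.obsolete:
            continue
        if kb.items[a.object_id].feature_type != function_type:
            continue
        if a.object_id not in dag or a.object_id in dag.obsolete:
            continue
        if a.inferred is Inferred.TRANSITIVE_RELATIONSHIP:
            if scope is not Scope.KNOWN_PLUS_TRANSFERRED:
                continue
        elif a.evidence_codes and any(
                a.evidence_codes <= profile
                for profile in cfg.excluded_evidence_profiles):
            continue
        terms.setdefault(a.subject_id, set()).add(a.object_id)
    return terms


def cofunc_scores(
    kb: KnowledgeBase,
    dag: Optional[OntologyDAG] = None,
    scope: Scope = Scope.KNOWN_ONLY,
    role: Role = Role.TRANSFERRED,
    pathway_type: str = "pathway",
    function_type: str = "biological_function",
    gene_type: str = "gene",
    cfg: Optional[FilterConfig] = None,
) -> list[CoFuncScore]:
    """MaxL/AvgL for every (gene, pathway) annotation of the requested role.

    Partner genes are always those *known* (non-transferred, non-obsolete)
    to be annotated to the pathway; for ``role=KNOWN`` the scored gene is
    excluded from its own partner set.  Partners without ontology
    annotations are skipped from the average (the pairwise statistic is
    undefined for them), not counted as level 0.
    """
    if cfg is None:
        cfg = FilterConfig()
    if dag is None:
        dag = kb.ontologies.get(function_type)
        if dag is None:
            raise KeyError(f"no ontology for feature type {function_type!r}")
    gene_terms = _gene_terms(kb, dag, function_type, scope, cfg)

    known_by_pathway: dict[str, set[str]] = {}
    records: list[tuple[str, str]] = []
    for a in kb.associations:
        if a.semantic_type is not SemanticType.ANNOTATED_TO or a.obsolete:
            continue
        if kb.items[a.subject_id].feature_type != gene_type:
            continue
        if kb.items[a.object_id].feature_type != pathway_type:
            continue
        transferred = a.inferred is Inferred.TRANSITIVE_RELATIONSHIP
        if not transferred:
            known_by_pathway.setdefault(a.object_id, set()).add(a.subject_id)
        if (role is Role.TRANSFERRED) == transferred:
            records.append((a.subject_id, a.object_id))

    out: list[CoFuncScore] = []
    for gene, pathway in sorted(set(records)):
        partners = known_by_pathway.get(pathway, set()) - {gene}
        g_terms = gene_terms.get(gene, set())
        pair_levels: list[int] = []
        if g_terms:
            for partner in partners:
                p_terms = gene_terms.get(partner, set())
                lv = pair_max_lca_level(dag, g_terms, p_terms)
                if lv is not None:
                    pair_levels.append(lv)
        if pair_levels:
            out.append(CoFuncScore(gene, pathway, role,
                                   max_level=max(pair_levels),
                                   avg_level=sum(pair_levels) / len(pair_levels)))
        else:
            out.append(CoFuncScore(gene, pathway, role, None, None))
    return out


@dataclass
class LevelDistribution:
    """Histogram of CoFuncScore records over integer levels plus category N."""

    stat: str  # "max" | "avg"
    counts: dict[int, int] = field(default_factory=dict)
    n_count: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.n_count

    def percentages(self) -> dict:
        total = self.total
        if total == 0:
            return {**{k: 0.0 for k in self.counts}, "N": 0.0}
        pct = {k: 100.0 * v / total for k, v in self.counts.items()}
        pct["N"] = 100.0 * self.n_count / total
        return pct


def level_distribution(scores: Iterable[CoFuncScore], max_level_cap: int,
                       stat: str = "max") -> LevelDistribution:
    """Tally scores into level bins 0..cap (avg binned by floor, values
    beyond the cap clipped into the top bin) plus category N."""
    if stat not in ("max", "avg"):
        raise ValueError(f"stat must be 'max' or 'avg', got {stat!r}")
    dist = LevelDistribution(stat=stat,
                             counts={lv: 0 for lv in range(max_level_cap + 1)})
    for s in scores:
        value = s.max_level if stat == "max" else s.avg_level
        if value is None:
            dist.n_count += 1
        else:
            dist.counts[min(int(math.floor(value)), max_level_cap)] += 1
    return dist
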