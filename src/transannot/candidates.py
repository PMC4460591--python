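"""Candidate protein- and PPI-genetic-disorder association detection.

Gene-disorder annotations flow to encoded proteins only as *candidates*
(the gene->protein ``ENCODES`` edge is walked against its 1-to-n direction;
under alternative splicing a gene can encode multiple proteins with
different characteristics).  A protein-protein interaction becomes a
candidate for a disorder when the encoding genes of *both* interacting
proteins are annotated to that same disorder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import (
    Association,
    Inferred,
    KnowledgeBase,
    SemanticType,
)
from .transfer import FilterConfig, eligible_support


@dataclass(frozen=True)
class DisorderCandidate:
    """A suggested (protein or PPI, disorder) association.

    ``provenance`` holds (ENCODES edge, gene-disorder edge) pairs for every
    supporting gene; always ``candidate_only`` — candidates are suggestions
    for further association studies and are never fed back as supports.
    """

    target_kind: str  # "PROTEIN" | "PPI"
    target_id: str
    disorder_id: str
    provenance: tuple[tuple[Association, Association], ...]

    def __post_init__(self) -> None:
        assert self.target_kind in ("PROTEIN", "PPI")
        assert self.provenance

    @property
    def candidate_only(self) -> bool:
        return True


def _support_map(kb: KnowledgeBase, cfg: FilterConfig,
                 gene_type: str, protein_type: str, disorder_type: str
                 ) -> dict[tuple[str, str], list[tuple[Association, Association]]]:
    """(protein, disorder) -> supporting (ENCODES, gene-disorder) edge pairs."""
    gene_disorders: dict[str, list[Association]] = {}
    for a in kb.associations:
        if a.semantic_type is not SemanticType.ANNOTATED_TO:
            continue
        if kb.items[a.subject_id].feature_type != gene_type:
            continue
        if kb.items[a.object_id].feature_type != disorder_type:
            continue
        if not eligible_support(a, kb.items[a.subject_id],
                                kb.items[a.object_id], cfg):
            continue
        gene_disorders.setdefault(a.subject_id, []).append(a)
    support: dict[tuple[str, str], list] = {}
    for enc in kb.associations:
        if enc.semantic_type is not SemanticType.ENCODES:
            continue
        if kb.items[enc.subject_id].feature_type != gene_type:
            continue
        if kb.items[enc.object_id].feature_type != protein_type:
            continue
        if not eligible_support(enc, kb.items[enc.subject_id],
                                kb.items[enc.object_id], cfg):
            continue
        for gd in gene_disorders.get(enc.subject_id, []):
            support.setdefault((enc.object_id, gd.object_id), []).append((enc, gd))
    return support


def protein_disorder_candidates(
    kb: KnowledgeBase,
    cfg: Optional[FilterConfig] = None,
    gene_type: str = "gene",
    protein_type: str = "protein",
    disorder_type: str = "genetic_disorder",
) -> list[DisorderCandidate]:
    """One candidate per (protein, disorder) where some eligible gene both
    encodes the protein and is annotated to the disorder."""
    if cfg is None:
        cfg = FilterConfig()
    support = _support_map(kb, cfg, gene_type, protein_type, disorder_type)
    out = []
    for (protein, disorder) in sorted(support):
        pairs = sorted(support[(protein, disorder)],
                       key=lambda p: (p[0].sort_key(), p[1].sort_key()))
        out.append(DisorderCandidate("PROTEIN", protein, disorder, tuple(pairs)))
    return out


def ppi_disorder_candidates(
    kb: KnowledgeBase,
    cfg: Optional[FilterConfig] = None,
    gene_type: str = "gene",
    protein_type: str = "protein",
    disorder_type: str = "genetic_disorder",
    require_both_endpoints: bool = True,
) -> list[DisorderCandidate]:
    """One candidate per (PPI, disorder) where the interacting proteins are
    encoded by genes annotated to that same disorder.

    With ``require_both_endpoints`` (the default reading of "genes annotated
    to the same genetic disorder") both interacting proteins need an
    eligible encoding gene annotated to the disorder; a self-interaction
    needs only its single protein supported.  The laxer variant accepts a
    single supported endpoint.
    """
    if cfg is None:
        cfg = FilterConfig()
    support = _support_map(kb, cfg, gene_type, protein_type, disorder_type)
    disorders_of: dict[str, set[str]] = {}
    for (protein, disorder) in support:
        disorders_of.setdefault(protein, set()).add(disorder)
    out = []
    for ppi_id in sorted(kb.ppis):
        ppi = kb.ppis[ppi_id]
        if cfg.exclude_obsolete and (
                ppi.obsolete or kb.items[ppi.protein_1_id].obsolete
                or kb.items[ppi.protein_2_id].obsolete):
            continue
        d1 = disorders_of.get(ppi.protein_1_id, set())
        d2 = disorders_of.get(ppi.protein_2_id, set())
        if ppi.protein_1_id == ppi.protein_2_id:
            shared = d1
        elif require_both_endpoints:
            shared = d1 & d2
        else:
            shared = d1 | d2
        for disorder in sorted(shared):
            pairs = []
            for pid in {ppi.protein_1_id, ppi.protein_2_id}:
                pairs.extend(support.get((pid, disorder), []))
            pairs = sorted(set(pairs),
                           key=lambda p: (p[0].sort_key(), p[1].sort_key()))
            out.append(DisorderCandidate("PPI", ppi_id, disorder, tuple(pairs)))
    return out
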