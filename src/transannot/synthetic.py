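"""Seeded synthetic knowledge-base generator with ground-truth ledgers.

The generator emulates the structure the transfer method assumes: genes
encoding proteins (1-to-n through alternative splicing), protein
annotations to ontology terms, pathways and enzymes with mixed evidence
codes, protein-transcript relationships, gene-disorder annotations without
evidence codes, and protein-protein interactions.  Decoy data — obsolete
items and edges, IEA-only evidence, pseudogenes, pre-existing inferred
annotations — are injected with configurable probabilities and recorded in
a :class:`TruthLedger` so the filters can be audited.

Gene annotations derivable from the eligible protein supports are first
computed by construction (keeping only the most specific ontology terms per
gene), then a ``holdout_fraction`` of them is withheld from the KB into
``planted_holdout``; on decoy-free configurations the transfer engine must
recover the planted set exactly.  All construction-derivable
protein-disorder associations are materialised as known data so that a
zero-holdout KB yields an empty transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .model import (
    Association,
    Category,
    ConfigurationError,
    FeatureItem,
    FeatureType,
    Inferred,
    KnowledgeBase,
    PPIRecord,
    SemanticType,
)
from .ontology import OntologyDAG

_EVIDENCE_CHOICES = (("IDA",), ("NAS",), ("EXP", "IDA"), ("IEA", "NAS"))
_TARGET_TYPES = ("biological_function", "pathway", "enzyme")
_TARGET_WEIGHTS = (0.6, 0.25, 0.15)


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters; identical (config, seed) gives byte-identical
    serialized knowledge bases."""

    seed: int = 0
    n_genes: int = 60
    n_proteins: int = 80
    n_terms: int = 60
    n_pathways: int = 12
    n_disorders: int = 8
    n_ppis: int = 40
    n_transcripts: int = 25
    n_enzymes: int = 10
    p_alt_splice: float = 0.3
    p_pseudogene: float = 0.05
    p_obsolete: float = 0.05
    p_iea_only: float = 0.15
    p_computational: float = 0.05
    p_prior_inferred: float = 0.03
    dag_branching: float = 3.0
    p_second_parent: float = 0.2
    #: fraction of PPIs drawn between proteins whose encoding genes share a
    #: disorder annotation; models the disease-module enrichment of real
    #: interaction data (uniform pairs almost never share a disorder)
    p_ppi_disease_module: float = 0.3
    mean_protein_annotations: float = 3.0
    p_gene_disorder: float = 0.25
    holdout_fraction: float = 0.5

    def validate(self) -> None:
        for name in ("p_alt_splice", "p_pseudogene", "p_obsolete",
                     "p_iea_only", "p_computational", "p_prior_inferred",
                     "p_second_parent", "p_gene_disorder", "holdout_fraction",
                     "p_ppi_disease_module"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for name in ("n_genes", "n_proteins", "n_terms", "n_pathways",
                     "n_disorders"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_ppis < 0 or self.n_transcripts < 0 or self.n_enzymes < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.n_ppis > self.n_proteins * (self.n_proteins - 1) // 2:
            raise ConfigurationError(
                f"n_ppis={self.n_ppis} exceeds the number of distinct "
                f"protein pairs for n_proteins={self.n_proteins}")
        if self.p_iea_only + 2 * self.p_obsolete + self.p_computational \
                + self.p_prior_inferred > 1.0:
            raise ConfigurationError("decoy probabilities sum beyond 1")
        if self.dag_branching <= 0:
            raise ConfigurationError("dag_branching must be positive")


@dataclass(frozen=True)
class TruthLedger:
    """What the generator planted, for recovery and filter audits.

    ``planted_holdout``: (subject, object, semantic type) triples of the
    withheld derivable gene annotations; disjoint from the KB's
    associations by construction.  ``decoy_supports``: edges that the
    transfer filters must never use, tagged by decoy class.
    """

    planted_holdout: frozenset[tuple[str, str, SemanticType]]
    decoy_supports: tuple[tuple[str, Association], ...]
    expected_protein_candidates: frozenset[tuple[str, str]]
    expected_ppi_candidates: frozenset[tuple[str, str]]


def generate_ontology(cfg: SynthConfig,
                      rng: Optional[np.random.Generator] = None,
                      prefix: str = "BF") -> OntologyDAG:
    """Rooted DAG grown by preferential attachment with occasional second
    parents, so multi-level terms and diamond LCAs occur; ``dag_branching``
    is the attachment offset (larger values flatten the hub preference and
    deepen the tree)."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    dag = OntologyDAG(name=prefix)
    terms = [f"{prefix}:{i:05d}" for i in range(cfg.n_terms)]
    dag.add_term(terms[0])
    n_children = {terms[0]: 0}
    for i in range(1, cfg.n_terms):
        existing = terms[:i]
        weights = np.array([n_children[t] + cfg.dag_branching for t in existing])
        parent = existing[int(rng.choice(i, p=weights / weights.sum()))]
        dag.add_is_a(terms[i], parent)
        n_children[parent] += 1
        n_children[terms[i]] = 0
        if i >= 2 and rng.random() < cfg.p_second_parent:
            others = [t for t in existing if t != parent]
            second = others[int(rng.integers(len(others)))]
            dag.add_is_a(terms[i], second)
            n_children[second] += 1
        if i > 0 and rng.random() < cfg.p_obsolete:
            dag.obsolete.add(terms[i])
    dag.validate()
    return dag


def _schema(kb: KnowledgeBase, dag: OntologyDAG) -> None:
    ent, char = Category.BIOMOLECULAR_ENTITY, Category.BIOMEDICAL_CHARACTERISTIC
    kb.add_feature_type(FeatureType("gene", ent))
    kb.add_feature_type(FeatureType("protein", ent))
    kb.add_feature_type(FeatureType("transcript", ent))
    kb.add_feature_type(FeatureType("biological_function", char,
                                    is_ontology=True), ontology=dag)
    kb.add_feature_type(FeatureType("pathway", char))
    kb.add_feature_type(FeatureType("enzyme", char))
    kb.add_feature_type(FeatureType("genetic_disorder", char))
    kb.declare_cardinality("gene", SemanticType.ENCODES, "protein", "1:n")
    kb.declare_cardinality("protein", SemanticType.RELATED_TO, "transcript", "1:n")
    kb.declare_cardinality("gene", SemanticType.ANNOTATED_TO,
                           "genetic_disorder", "1:n")


def _is_eligible_annotation(a: Association, kb: KnowledgeBase) -> bool:
    # generator-side restatement of the default support filters
    if a.obsolete or kb.items[a.subject_id].obsolete \
            or kb.items[a.object_id].obsolete:
        return False
    if a.inferred is not Inferred.SOURCE:
        return False
    if a.semantic_type is SemanticType.ANNOTATED_TO and a.evidence_codes \
            and a.evidence_codes <= {"IEA"}:
        return False
    return True


def generate_kb(cfg: SynthConfig) -> tuple[KnowledgeBase, TruthLedger]:
    """Build one synthetic KB plus its ground-truth ledger."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    kb = KnowledgeBase()
    dag = generate_ontology(cfg, rng)
    _schema(kb, dag)

    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    proteins = [f"P{i:05d}" for i in range(cfg.n_proteins)]
    transcripts = [f"TR{i:05d}" for i in range(cfg.n_transcripts)]
    pathways = [f"PW{i:03d}" for i in range(cfg.n_pathways)]
    enzymes = [f"EC{i:03d}" for i in range(cfg.n_enzymes)]
    disorders = [f"DIS{i:03d}" for i in range(cfg.n_disorders)]

    decoys: list[tuple[str, Association]] = []

    # genes: a pseudogene fraction, but never all of them
    pseudo_flags = rng.random(cfg.n_genes) < cfg.p_pseudogene
    if pseudo_flags.all():
        pseudo_flags[0] = False
    pseudogenes = [g for g, f in zip(genes, pseudo_flags) if f]
    coding_genes = [g for g, f in zip(genes, pseudo_flags) if not f]
    for g, f in zip(genes, pseudo_flags):
        kb.add_item(FeatureItem(g, "gene", item_class="pseudogene" if f
                                else "protein_coding", source="syn"))

    # proteins; a small fraction are obsolete items (decoy class: obsolete)
    protein_obsolete = rng.random(cfg.n_proteins) < cfg.p_obsolete / 2
    for p, obs in zip(proteins, protein_obsolete):
        kb.add_item(FeatureItem(p, "protein", obsolete=bool(obs), source="syn"))
    for t in transcripts:
        kb.add_item(FeatureItem(t, "transcript", source="syn"))
    for term in sorted(dag.terms):
        kb.add_item(FeatureItem(term, "biological_function",
                                obsolete=term in dag.obsolete, source="syn"))
    for pw in pathways:
        kb.add_item(FeatureItem(pw, "pathway", source="syn"))
    for ec in enzymes:
        kb.add_item(FeatureItem(ec, "enzyme", source="syn"))
    for d in disorders:
        kb.add_item(FeatureItem(d, "genetic_disorder", source="syn"))

    # ENCODES map: pseudogenes get a dedicated protein each (their
    # annotations must only be reachable through the pseudogene); remaining
    # proteins cover the coding genes, extras model alternative splicing
    protein_gene: dict[str, str] = {}
    pool = list(proteins)
    for g in pseudogenes:
        if len(pool) <= len(coding_genes):
            break
        protein_gene[pool.pop()] = g
    for i, p in enumerate(pool):
        if i < len(coding_genes):
            protein_gene[p] = coding_genes[i]
    extras = pool[len(coding_genes):]
    if extras:
        n_multi = max(1, round(cfg.p_alt_splice * len(coding_genes)))
        multi = [coding_genes[int(j)]
                 for j in rng.choice(len(coding_genes),
                                     size=min(n_multi, len(coding_genes)),
                                     replace=False)]
        for p in extras:
            protein_gene[p] = multi[int(rng.integers(len(multi)))]
    pseudo_proteins = {p for p, g in protein_gene.items() if g in set(pseudogenes)}

    for p in proteins:
        g = protein_gene.get(p)
        if g is None:
            continue
        kb.add_association(Association(g, p, SemanticType.ENCODES,
                                       source="syn_encodes"))

    # protein -> transcript relationships (RELATED_TO, no evidence concept)
    usable_proteins = [p for p in proteins
                       if p in protein_gene and p not in pseudo_proteins]
    for t in transcripts:
        if not usable_proteins:
            break
        p = usable_proteins[int(rng.integers(len(usable_proteins)))]
        kb.add_association(Association(p, t, SemanticType.RELATED_TO,
                                       source="syn_tr"))

    # protein annotations with decoy injection
    clean_terms = sorted(dag.terms - dag.obsolete)
    obsolete_terms = sorted(dag.obsolete)
    used_pairs: set[tuple[str, str]] = set()
    p_iea = cfg.p_iea_only
    p_obs_edge = p_iea + cfg.p_obsolete
    p_comp = p_obs_edge + cfg.p_computational
    p_prior = p_comp + cfg.p_prior_inferred
    p_obs_term = p_prior + cfg.p_obsolete

    def _pick_target(kind: str) -> Optional[str]:
        options = {"biological_function": clean_terms, "pathway": pathways,
                   "enzyme": enzymes}[kind]
        if not options:
            return None
        return options[int(rng.integers(len(options)))]

    for p in proteins:
        if p not in protein_gene:
            continue
        k = 1 + int(rng.poisson(max(cfg.mean_protein_annotations - 1.0, 0.0)))
        for _ in range(k):
            if p in pseudo_proteins:
                # pseudogene decoys target only the excluded functional types
                kind = ("biological_function", "enzyme")[int(rng.integers(2))]
            else:
                kind = _TARGET_TYPES[int(rng.choice(3, p=_TARGET_WEIGHTS))]
            target = _pick_target(kind)
            if target is None or (p, target) in used_pairs:
                continue
            evidence = frozenset(
                _EVIDENCE_CHOICES[int(rng.integers(len(_EVIDENCE_CHOICES)))])
            assoc = Association(p, target, SemanticType.ANNOTATED_TO,
                                evidence_codes=evidence, source="syn_ann")
            decoy_class: Optional[str] = None
            if p in pseudo_proteins:
                decoy_class = "pseudogene"
            else:
                u = rng.random()
                if u < p_iea:
                    assoc = replace(assoc, evidence_codes=frozenset({"IEA"}))
                    decoy_class = "iea_only"
                elif u < p_obs_edge:
                    assoc = replace(assoc, obsolete=True)
                    decoy_class = "obsolete"
                elif u < p_comp:
                    assoc = replace(assoc,
                                    inferred=Inferred.SOURCE_COMPUTATIONAL)
                    decoy_class = "computational"
                elif u < p_prior:
                    assoc = replace(
                        assoc, inferred=Inferred.TRANSITIVE_RELATIONSHIP,
                        source="syn_prior_transfer")
                    decoy_class = "prior_transferred"
                elif u < p_obs_term and obsolete_terms:
                    target = obsolete_terms[int(rng.integers(len(obsolete_terms)))]
                    if (p, target) in used_pairs:
                        continue
                    assoc = replace(assoc, object_id=target)
                    decoy_class = "obsolete_target"
            used_pairs.add((assoc.subject_id, assoc.object_id))
            kb.add_association(assoc)
            if decoy_class is not None:
                decoys.append((decoy_class, assoc))
            if kb.items[p].obsolete:
                decoys.append(("obsolete_item", assoc))

    # gene-disorder annotations (OMIM-style: no evidence codes)
    for g in genes:
        if rng.random() < cfg.p_gene_disorder:
            n = 1 + int(rng.random() < 0.3)
            for j in rng.choice(cfg.n_disorders,
                                size=min(n, cfg.n_disorders), replace=False):
                kb.add_association(Association(
                    g, disorders[int(j)], SemanticType.ANNOTATED_TO,
                    source="syn_omim"))

    # sources sometimes carry a gene annotation whose only protein support
    # is computational/IEA-only: known but not re-derivable (recall decoys)
    pseudo_set = set(pseudogenes)
    for decoy_class, a in list(decoys):
        if decoy_class not in ("iea_only", "computational"):
            continue
        g = protein_gene.get(a.subject_id)
        if g is None or g in pseudo_set or kb.items[g].obsolete:
            continue
        if not kb.has_association(g, a.object_id, SemanticType.ANNOTATED_TO,
                                  include_obsolete=True):
            kb.add_association(Association(
                g, a.object_id, SemanticType.ANNOTATED_TO,
                evidence_codes=frozenset({"IEA"}), source="syn_gene_comp",
                inferred=Inferred.SOURCE_COMPUTATIONAL))

    # --------------------------------------------------- derivable closure
    eligible_encodes = [
        a for a in kb.associations
        if a.semantic_type is SemanticType.ENCODES
        and _is_eligible_annotation(a, kb)]
    derivable: set[tuple[str, str, SemanticType]] = set()
    pseudo_excluded = {"biological_function", "enzyme"}
    for enc in eligible_encodes:
        g, p = enc.subject_id, enc.object_id
        for a in kb.by_subject(p):
            if not _is_eligible_annotation(a, kb):
                continue
            if a.semantic_type is SemanticType.ANNOTATED_TO:
                ttype = kb.items[a.object_id].feature_type
                if g in pseudo_set and ttype in pseudo_excluded:
                    continue
                derivable.add((g, a.object_id, SemanticType.ANNOTATED_TO))
            elif a.semantic_type is SemanticType.RELATED_TO:
                derivable.add((g, a.object_id, SemanticType.RELATED_TO))

    # keep only the most specific ontology terms per gene (true-path rule)
    by_gene_terms: dict[str, set[str]] = {}
    for (g, obj, st) in derivable:
        if st is SemanticType.ANNOTATED_TO and obj in dag:
            by_gene_terms.setdefault(g, set()).add(obj)
    dominated: set[tuple[str, str, SemanticType]] = set()
    for g, terms in by_gene_terms.items():
        for t in terms:
            for anc in (dag.ancestors(t) - {t}) & terms:
                dominated.add((g, anc, SemanticType.ANNOTATED_TO))
    derivable -= dominated
    # triples already present as known annotations cannot be planted
    derivable = {t for t in derivable
                 if not kb.has_association(*t, include_obsolete=True)}

    # protein-disorder closure, materialised as known data
    expected_pd: set[tuple[str, str]] = set()
    for enc in eligible_encodes:
        g, p = enc.subject_id, enc.object_id
        for a in kb.by_subject(g):
            if a.semantic_type is SemanticType.ANNOTATED_TO \
                    and kb.items[a.object_id].feature_type == "genetic_disorder" \
                    and _is_eligible_annotation(a, kb):
                expected_pd.add((p, a.object_id))
    for p, d in sorted(expected_pd):
        if not kb.has_association(p, d, SemanticType.ANNOTATED_TO,
                                  include_obsolete=True):
            kb.add_association(Association(p, d, SemanticType.ANNOTATED_TO,
                                           source="syn_pd"))

    # holdout split of the derivable gene annotations
    planted: set[tuple[str, str, SemanticType]] = set()
    for triple in sorted(derivable, key=lambda t: (t[0], t[1], t[2].value)):
        if rng.random() < cfg.holdout_fraction:
            planted.add(triple)
        else:
            g, obj, st = triple
            evidence = frozenset({"TAS"}) if st is SemanticType.ANNOTATED_TO \
                else frozenset()
            kb.add_association(Association(g, obj, st, evidence_codes=evidence,
                                           source="syn_gene_ann"))

    # PPIs (canonical endpoint order, a few obsolete decoy records); a
    # fraction is drawn inside disease modules — between proteins whose
    # genes share a disorder — since uniform pairs rarely do
    ppi_pairs: set[tuple[str, str]] = set()
    module_proteins: dict[str, list[str]] = {}
    for p, d in sorted(expected_pd):
        module_proteins.setdefault(d, []).append(p)
    modules = [ps for _, ps in sorted(module_proteins.items()) if len(ps) >= 2]
    n_module_ppis = round(cfg.p_ppi_disease_module * cfg.n_ppis) \
        if modules else 0
    attempts = 0
    while len(ppi_pairs) < n_module_ppis and attempts < 50 * cfg.n_ppis + 100:
        attempts += 1
        ps = modules[int(rng.integers(len(modules)))]
        i, j = rng.choice(len(ps), size=2, replace=False)
        ppi_pairs.add(tuple(sorted((ps[int(i)], ps[int(j)]))))
    attempts = 0
    while len(ppi_pairs) < cfg.n_ppis and attempts < 50 * cfg.n_ppis + 100:
        attempts += 1
        i, j = rng.choice(cfg.n_proteins, size=2, replace=False)
        pair = tuple(sorted((proteins[int(i)], proteins[int(j)])))
        ppi_pairs.add(pair)
    ppi_obsolete = rng.random(len(ppi_pairs)) < cfg.p_obsolete
    for idx, (p1, p2) in enumerate(sorted(ppi_pairs)):
        kb.add_ppi(PPIRecord.make(f"PPI{idx:05d}", p1, p2, source="syn_ppi",
                                  obsolete=bool(ppi_obsolete[idx])))

    # expected PPI-disorder candidates by construction
    pd_by_protein: dict[str, set[str]] = {}
    for p, d in expected_pd:
        pd_by_protein.setdefault(p, set()).add(d)
    expected_ppi: set[tuple[str, str]] = set()
    for ppi_id in sorted(kb.ppis):
        ppi = kb.ppis[ppi_id]
        if ppi.obsolete or kb.items[ppi.protein_1_id].obsolete \
                or kb.items[ppi.protein_2_id].obsolete:
            continue
        d1 = pd_by_protein.get(ppi.protein_1_id, set())
        d2 = pd_by_protein.get(ppi.protein_2_id, set())
        shared = d1 if ppi.protein_1_id == ppi.protein_2_id else d1 & d2
        for d in shared:
            expected_ppi.add((ppi_id, d))

    kb.validate()
    ledger = TruthLedger(
        planted_holdout=frozenset(planted),
        decoy_supports=tuple(sorted(decoys,
                                    key=lambda x: (x[0], x[1].sort_key()))),
        expected_protein_candidates=frozenset(expected_pd),
        expected_ppi_candidates=frozenset(expected_ppi))
    return kb, ledger
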