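"""Shared fixtures: hand-built knowledge bases and random KB construction."""

from __future__ import annotations

import numpy as np
import pytest

from transannot.model import (
    Association,
    Category,
    FeatureItem,
    FeatureType,
    Inferred,
    KnowledgeBase,
    PPIRecord,
    SemanticType,
)
from transannot.ontology import OntologyDAG

ENT = Category.BIOMOLECULAR_ENTITY
CHAR = Category.BIOMEDICAL_CHARACTERISTIC


def standard_schema(dag: OntologyDAG | None = None) -> KnowledgeBase:
    """The canonical gene/protein/characteristic schema used across tests."""
    kb = KnowledgeBase()
    kb.add_feature_type(FeatureType("gene", ENT))
    kb.add_feature_type(FeatureType("protein", ENT))
    kb.add_feature_type(FeatureType("transcript", ENT))
    kb.add_feature_type(FeatureType("biological_function", CHAR,
                                    is_ontology=True),
                        ontology=dag or OntologyDAG("biological_function"))
    kb.add_feature_type(FeatureType("pathway", CHAR))
    kb.add_feature_type(FeatureType("enzyme", CHAR))
    kb.add_feature_type(FeatureType("genetic_disorder", CHAR))
    return kb


def add_items(kb: KnowledgeBase, ftype: str, *ids, **kwargs) -> None:
    for item_id in ids:
        kb.add_item(FeatureItem(item_id, ftype, **kwargs))


def chain_dag() -> OntologyDAG:
    """R <- X <- Y is_a chain (levels 0, 1, 2)."""
    dag = OntologyDAG("biological_function")
    dag.add_is_a("X", "R")
    dag.add_is_a("Y", "X")
    return dag


@pytest.fixture
def igf2_like_kb() -> KnowledgeBase:
    """One gene encoding one annotated protein, GO chain R <- GO:0002 <- GO:0005;
    the gene's own functional annotation is missing and should be transferred."""
    dag = OntologyDAG("biological_function")
    dag.add_is_a("GO:0002", "GO:0001")
    dag.add_is_a("GO:0005", "GO:0002")
    dag.add_is_a("GO:0008", "GO:0005")
    kb = standard_schema(dag)
    add_items(kb, "gene", "G1")
    add_items(kb, "protein", "P1")
    add_items(kb, "biological_function", "GO:0001", "GO:0002", "GO:0005", "GO:0008")
    kb.add_association(Association("G1", "P1", SemanticType.ENCODES,
                                   source="entrez"))
    kb.add_association(Association("P1", "GO:0005", SemanticType.ANNOTATED_TO,
                                   evidence_codes=frozenset({"NAS"}),
                                   source="goa"))
    return kb


def random_messy_kb(seed: int, n_items: int = 40, n_edges: int = 120
                    ) -> KnowledgeBase:
    """A random KB with decoy flags, odd patterns and symmetric edges; edges
    violating category legality are simply skipped."""
    rng = np.random.default_rng(seed)
    dag = OntologyDAG("biological_function")
    n_terms = max(3, n_items // 4)
    terms = [f"T{i}" for i in range(n_terms)]
    dag.add_term(terms[0])
    for i in range(1, n_terms):
        dag.add_is_a(terms[i], terms[int(rng.integers(i))])
        if i > 1 and rng.random() < 0.3:
            dag.add_is_a(terms[i], terms[int(rng.integers(i - 1))])
        if rng.random() < 0.1:
            dag.obsolete.add(terms[i])
    kb = standard_schema(dag)
    type_pool = ["gene", "protein", "transcript", "pathway", "enzyme",
                 "genetic_disorder"]
    ids = []
    for i in range(n_items):
        t = type_pool[int(rng.integers(len(type_pool)))]
        item_class = None
        if t == "gene" and rng.random() < 0.2:
            item_class = "pseudogene"
        item_id = f"{t[:2].upper()}{i}"
        kb.add_item(FeatureItem(item_id, t, obsolete=bool(rng.random() < 0.08),
                                item_class=item_class))
        ids.append(item_id)
    for term in terms:
        kb.add_item(FeatureItem(term, "biological_function",
                                obsolete=term in dag.obsolete))
        ids.append(term)
    sems = list(SemanticType)
    evidences = [frozenset(), frozenset({"IEA"}), frozenset({"NAS"}),
                 frozenset({"IEA", "NAS"}), frozenset({"IDA"})]
    inferreds = [Inferred.SOURCE] * 6 + [Inferred.SOURCE_COMPUTATIONAL,
                                         Inferred.TRANSITIVE_RELATIONSHIP]
    for j in range(n_edges):
        s = ids[int(rng.integers(len(ids)))]
        o = ids[int(rng.integers(len(ids)))]
        if s == o:
            continue
        assoc = Association(
            s, o, sems[int(rng.integers(len(sems)))],
            evidence_codes=evidences[int(rng.integers(len(evidences)))],
            source=f"src{j}",
            inferred=inferreds[int(rng.integers(len(inferreds)))],
            obsolete=bool(rng.random() < 0.08))
        try:
            kb.add_association(assoc)
        except Exception:
            continue
    proteins = [i for i in ids if kb.items[i].feature_type == "protein"]
    for j in range(min(10, len(proteins) // 2)):
        p1 = proteins[int(rng.integers(len(proteins)))]
        p2 = proteins[int(rng.integers(len(proteins)))]
        try:
            kb.add_ppi(PPIRecord.make(f"PPI{j}", p1, p2,
                                      obsolete=bool(rng.random() < 0.1)))
        except Exception:
            continue
    return kb


@pytest.fixture
def cystic_fibrosis_kb() -> KnowledgeBase:
    """Eight disorder-annotated genes/proteins and the six named PPIs."""
    kb = standard_schema()
    proteins = ["CFTR_HUMAN", "DERL1_HUMAN", "RNF5_HUMAN", "AHSA1_HUMAN",
                "GOPC_HUMAN", "CHIP_HUMAN", "HSP7C_HUMAN", "CLCN2_HUMAN"]
    add_items(kb, "genetic_disorder", "Cystic fibrosis")
    for p in proteins:
        gene = p.replace("_HUMAN", "")
        add_items(kb, "gene", gene)
        add_items(kb, "protein", p)
        kb.add_association(Association(gene, p, SemanticType.ENCODES,
                                       source="entrez"))
        kb.add_association(Association(gene, "Cystic fibrosis",
                                       SemanticType.ANNOTATED_TO,
                                       source="omim"))
    pairs = [("CFTR_HUMAN", "DERL1_HUMAN"), ("CFTR_HUMAN", "RNF5_HUMAN"),
             ("CFTR_HUMAN", "AHSA1_HUMAN"), ("CFTR_HUMAN", "GOPC_HUMAN"),
             ("CHIP_HUMAN", "HSP7C_HUMAN"), ("CHIP_HUMAN", "CLCN2_HUMAN")]
    for i, (p1, p2) in enumerate(pairs):
        kb.add_ppi(PPIRecord.make(f"PPI{i}", p1, p2, source="intact"))
    return kb
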