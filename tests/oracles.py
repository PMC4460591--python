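"""Independent brute-force oracles used to cross-check the engines.

Everything here is written as plainly as possible — nested loops over the
raw association list and networkx reachability — and never calls into the
package's transfer, candidate or LCA code paths.
"""

from __future__ import annotations

import itertools

import networkx as nx

from transannot.model import Inferred, KnowledgeBase, SemanticType


# --------------------------------------------------------------- DAG oracles

def oracle_ancestors(dag, term):
    g = dag.to_networkx()  # edges child -> parent
    return set(nx.descendants(g, term)) | {term}


def oracle_levels(dag):
    """Longest root-to-term path by exhaustive path enumeration."""
    g = dag.to_networkx().reverse()  # parent -> child
    roots = [t for t in dag.terms if not dag.parents(t)]
    levels = {}
    for t in dag.terms:
        best = 0
        for r in roots:
            if r == t:
                best = max(best, 0)
                continue
            for path in nx.all_simple_paths(g, r, t):
                best = max(best, len(path) - 1)
        levels[t] = best
    return levels


def oracle_lca_set(dag, t1, t2):
    common = oracle_ancestors(dag, t1) & oracle_ancestors(dag, t2)
    lowest = set()
    for c in common:
        if not any(d != c and c in oracle_ancestors(dag, d) for d in common):
            lowest.add(c)
    return lowest


def oracle_pair_max_lca_level(dag, terms_a, terms_b):
    if not terms_a or not terms_b:
        return None
    levels = oracle_levels(dag)
    found = [levels[l]
             for ta in terms_a for tb in terms_b
             for l in oracle_lca_set(dag, ta, tb)]
    return max(found) if found else None


# ---------------------------------------------------------- transfer oracle

def _edge_ok(kb: KnowledgeBase, a, check_evidence=True) -> bool:
    if a.obsolete:
        return False
    if kb.items[a.subject_id].obsolete or kb.items[a.object_id].obsolete:
        return False
    if a.inferred is Inferred.TRANSITIVE_RELATIONSHIP:
        return False
    if a.inferred is Inferred.SOURCE_COMPUTATIONAL:
        return False
    if check_evidence and a.semantic_type is SemanticType.ANNOTATED_TO \
            and a.evidence_codes and a.evidence_codes <= {"IEA"}:
        return False
    return True


def _tname(kb, item_id):
    return kb.items[item_id].feature_type


def _is_entity(kb, item_id):
    return kb.feature_types[_tname(kb, item_id)].category.value \
        == "BIOMOLECULAR_ENTITY"


def _is_char(kb, item_id):
    return not _is_entity(kb, item_id)


def _term_ancestors(kb, tname, term):
    dag = kb.ontologies.get(tname)
    if dag is None or term not in dag:
        return {term}
    return oracle_ancestors(dag, term)


def _redundant(kb, entity_id, term, tname):
    anc_of_known = set()
    for a in kb.associations:
        if (a.subject_id == entity_id
                and a.semantic_type is SemanticType.ANNOTATED_TO
                and a.inferred is not Inferred.TRANSITIVE_RELATIONSHIP
                and not a.obsolete
                and a.object_id in kb.ontologies.get(tname, ())):
            anc_of_known |= _term_ancestors(kb, tname, a.object_id)
    return term in anc_of_known


def brute_force_transfer(kb: KnowledgeBase):
    """Triple-loop re-derivation of the default-rule transfer output.

    Returns {(subject, object, sem, candidate): frozenset of (ab.key, bc.key)}.
    """
    found: dict[tuple, set] = {}

    def emit(subj, obj, sem, candidate, ab, bc):
        if subj == obj:
            return
        # existing non-obsolete association with the same triple blocks
        for x in kb.associations:
            if (x.subject_id, x.object_id, x.semantic_type) == (subj, obj, sem) \
                    and not x.obsolete:
                return
        tname_c = _tname(kb, obj)
        ftype_c = kb.feature_types[tname_c]
        pseudo_targets = {t.name for t in kb.feature_types.values()
                          if t.is_ontology}
        if "enzyme" in kb.feature_types:
            pseudo_targets.add("enzyme")
        if kb.items[subj].item_class == "pseudogene" and tname_c in pseudo_targets:
            return
        if ftype_c.is_ontology:
            dag = kb.ontologies.get(tname_c)
            if dag is not None and obj in dag:
                if obj in dag.obsolete:
                    return
                if _redundant(kb, subj, obj, tname_c):
                    return
        found.setdefault((subj, obj, sem, candidate), set()).add((ab.key, bc.key))

    for e1, e2 in itertools.permutations(kb.associations, 2):
        if not (_edge_ok(kb, e1) and _edge_ok(kb, e2)):
            continue
        # R1: gene -ENCODES-> protein -ANNOTATED_TO-> characteristic
        if (e1.semantic_type is SemanticType.ENCODES
                and _tname(kb, e1.subject_id) == "gene"
                and _tname(kb, e1.object_id) == "protein"
                and e2.semantic_type is SemanticType.ANNOTATED_TO
                and e1.object_id == e2.subject_id
                and _is_char(kb, e2.object_id)):
            emit(e1.subject_id, e2.object_id, SemanticType.ANNOTATED_TO,
                 False, e1, e2)
        # R2: entity -ENCODES-> entity -ENCODES-> entity
        if (e1.semantic_type is SemanticType.ENCODES
                and e2.semantic_type is SemanticType.ENCODES
                and e1.object_id == e2.subject_id):
            emit(e1.subject_id, e2.object_id, SemanticType.ENCODES,
                 False, e1, e2)
        # R3: gene -ENCODES-> protein -RELATED_TO-> entity
        if (e1.semantic_type is SemanticType.ENCODES
                and _tname(kb, e1.subject_id) == "gene"
                and _tname(kb, e1.object_id) == "protein"
                and e2.semantic_type is SemanticType.RELATED_TO
                and e1.object_id == e2.subject_id
                and _is_entity(kb, e2.object_id)):
            emit(e1.subject_id, e2.object_id, SemanticType.RELATED_TO,
                 False, e1, e2)
        # R4: protein <-ENCODES- gene -ANNOTATED_TO-> genetic disorder
        if (e1.semantic_type is SemanticType.ENCODES
                and _tname(kb, e1.subject_id) == "gene"
                and _tname(kb, e1.object_id) == "protein"
                and e2.semantic_type is SemanticType.ANNOTATED_TO
                and e1.subject_id == e2.subject_id
                and _tname(kb, e2.object_id) == "genetic_disorder"):
            emit(e1.object_id, e2.object_id, SemanticType.ANNOTATED_TO,
                 True, e1, e2)

    # within-run true-path redundancy: drop emitted strict ancestors of other
    # emitted terms, or of terms transferred by a previous run, for the same
    # subject
    drop = set()
    for (subj, obj, sem, cand) in found:
        tname = _tname(kb, obj)
        if sem is not SemanticType.ANNOTATED_TO or tname not in kb.ontologies:
            continue
        if obj not in kb.ontologies[tname]:
            continue
        dominators = set()
        for (s2, o2, sem2, c2) in found:
            if s2 == subj and sem2 is SemanticType.ANNOTATED_TO \
                    and _tname(kb, o2) == tname \
                    and o2 in kb.ontologies[tname]:
                dominators.add(o2)
        for a in kb.associations:
            if (a.subject_id == subj
                    and a.semantic_type is SemanticType.ANNOTATED_TO
                    and a.inferred is Inferred.TRANSITIVE_RELATIONSHIP
                    and not a.obsolete
                    and _tname(kb, a.object_id) == tname
                    and a.object_id in kb.ontologies[tname]):
                dominators.add(a.object_id)
        if any(o2 != obj and obj in _term_ancestors(kb, tname, o2)
               for o2 in dominators):
            drop.add((subj, obj, sem, cand))
    for key in drop:
        del found[key]
    return {k: frozenset(v) for k, v in found.items()}


def transfer_as_comparable(transfers):
    return {
        (t.association.subject_id, t.association.object_id,
         t.association.semantic_type, t.candidate_only):
        frozenset((ab.key, bc.key) for ab, bc in t.provenance)
        for t in transfers
    }


# --------------------------------------------------------- candidate oracle

def brute_force_protein_candidates(kb: KnowledgeBase):
    out = set()
    for enc in kb.associations:
        if enc.semantic_type is not SemanticType.ENCODES:
            continue
        if _tname(kb, enc.subject_id) != "gene" or \
                _tname(kb, enc.object_id) != "protein":
            continue
        if not _edge_ok(kb, enc):
            continue
        for gd in kb.associations:
            if gd.semantic_type is not SemanticType.ANNOTATED_TO:
                continue
            if gd.subject_id != enc.subject_id:
                continue
            if _tname(kb, gd.object_id) != "genetic_disorder":
                continue
            if not _edge_ok(kb, gd):
                continue
            out.add((enc.object_id, gd.object_id))
    return out


def brute_force_ppi_candidates(kb: KnowledgeBase):
    protein_support = brute_force_protein_candidates(kb)
    out = set()
    for ppi in kb.ppis.values():
        if ppi.obsolete or kb.items[ppi.protein_1_id].obsolete \
                or kb.items[ppi.protein_2_id].obsolete:
            continue
        for d in {x for _, x in protein_support}:
            ok1 = (ppi.protein_1_id, d) in protein_support
            ok2 = (ppi.protein_2_id, d) in protein_support
            if ppi.protein_1_id == ppi.protein_2_id:
                if ok1:
                    out.add((ppi.ppi_id, d))
            elif ok1 and ok2:
                out.add((ppi.ppi_id, d))
    return out
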