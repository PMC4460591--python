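"""Co-functional MaxL/AvgL scoring and level distributions."""

import pytest

from transannot.cofunctional import (
    Role,
    Scope,
    cofunc_scores,
    level_distribution,
)
from transannot.model import Association, Inferred, SemanticType
from transannot.ontology import OntologyDAG
from transannot.synthetic import SynthConfig, generate_kb
from transannot.transfer import apply_transfers, transfer

from conftest import add_items, standard_schema

ANN = SemanticType.ANNOTATED_TO


def _hand_kb():
    """Three genes, five terms.

    DAG: R <- A; A <- B, A <- C; B <- D  (levels R0 A1 B2 C2 D3).
    Pathway PW1: g1 has a TRANSFERRED annotation; g2, g3 are KNOWN.
    GO: g1={D}, g2={B}, g3={C}.

    Hand computation: lca(D,B)={B} level 2; lca(D,C)={A} level 1;
    lca(B,C)={A} level 1.  So g1: max=2, avg=1.5; g2: max=1, avg=1.0;
    g3: max=1, avg=1.0.
    """
    dag = OntologyDAG("biological_function")
    dag.add_is_a("A", "R")
    dag.add_is_a("B", "A")
    dag.add_is_a("C", "A")
    dag.add_is_a("D", "B")
    kb = standard_schema(dag)
    add_items(kb, "gene", "g1", "g2", "g3")
    add_items(kb, "biological_function", "R", "A", "B", "C", "D")
    add_items(kb, "pathway", "PW1")
    kb.add_association(Association("g1", "PW1", ANN,
                                   inferred=Inferred.TRANSITIVE_RELATIONSHIP,
                                   source="tr"))
    kb.add_association(Association("g2", "PW1", ANN, source="kegg"))
    kb.add_association(Association("g3", "PW1", ANN, source="kegg"))
    for g, term in (("g1", "D"), ("g2", "B"), ("g3", "C")):
        kb.add_association(Association(g, term, ANN,
                                       evidence_codes=frozenset({"IDA"}),
                                       source="goa"))
    return kb


class TestHandExample:
    def test_transferred_gene_scores(self):
        (s,) = cofunc_scores(_hand_kb(), role=Role.TRANSFERRED)
        assert (s.gene_id, s.pathway_id) == ("g1", "PW1")
        assert s.max_level == 2
        assert s.avg_level == pytest.approx(1.5)

    def test_known_genes_score_against_other_known_only(self):
        scores = {s.gene_id: s for s in cofunc_scores(_hand_kb(), role=Role.KNOWN)}
        assert set(scores) == {"g2", "g3"}
        for g in ("g2", "g3"):
            assert scores[g].max_level == 1
            assert scores[g].avg_level == pytest.approx(1.0)

    def test_gene_without_go_annotation_is_category_n(self):
        kb = _hand_kb()
        kb.remove_associations(
            lambda a: a.subject_id == "g1" and a.object_id == "D")
        (s,) = cofunc_scores(kb, role=Role.TRANSFERRED)
        assert s.is_n and s.max_level is None and s.avg_level is None

    def test_root_only_overlap_scores_zero(self):
        kb = _hand_kb()
        # move g1's annotation to a fresh branch sharing only the root
        dag = kb.ontologies["biological_function"]
        dag.add_is_a("Z", "R")
        add_items(kb, "biological_function", "Z")
        kb.remove_associations(
            lambda a: a.subject_id == "g1" and a.object_id == "D")
        kb.add_association(Association("g1", "Z", ANN,
                                       evidence_codes=frozenset({"IDA"})))
        (s,) = cofunc_scores(kb, role=Role.TRANSFERRED)
        assert s.max_level == 0 and s.avg_level == 0.0

    def test_iea_only_go_annotations_not_usable(self):
        kb = _hand_kb()
        kb.remove_associations(
            lambda a: a.subject_id == "g1" and a.object_id == "D")
        kb.add_association(Association("g1", "D", ANN,
                                       evidence_codes=frozenset({"IEA"})))
        (s,) = cofunc_scores(kb, role=Role.TRANSFERRED)
        assert s.is_n

    def test_transferred_go_counts_only_with_widened_scope(self):
        kb = _hand_kb()
        kb.remove_associations(
            lambda a: a.subject_id == "g1" and a.object_id == "D")
        kb.add_association(Association("g1", "D", ANN,
                                       inferred=Inferred.TRANSITIVE_RELATIONSHIP,
                                       source="tr"))
        (s_known,) = cofunc_scores(kb, scope=Scope.KNOWN_ONLY,
                                   role=Role.TRANSFERRED)
        (s_plus,) = cofunc_scores(kb, scope=Scope.KNOWN_PLUS_TRANSFERRED,
                                  role=Role.TRANSFERRED)
        assert s_known.is_n
        assert s_plus.max_level == 2


class TestLevelDistribution:
    def test_counts_and_percentages(self):
        scores = cofunc_scores(_hand_kb(), role=Role.TRANSFERRED) + \
            cofunc_scores(_hand_kb(), role=Role.KNOWN)
        dist = level_distribution(scores, max_level_cap=3, stat="max")
        assert dist.counts == {0: 0, 1: 2, 2: 1, 3: 0}
        assert dist.n_count == 0
        assert dist.total == 3
        pct = dist.percentages()
        assert pct[1] == pytest.approx(200 / 3)
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_avg_binned_by_floor(self):
        scores = cofunc_scores(_hand_kb(), role=Role.TRANSFERRED)
        dist = level_distribution(scores, max_level_cap=3, stat="avg")
        assert dist.counts[1] == 1  # avg 1.5 floors to 1

    def test_empty_input_all_zero(self):
        dist = level_distribution([], max_level_cap=2)
        assert dist.total == 0 and dist.n_count == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_distribution_matches_direct_tally(self, seed):
        kb, _ = generate_kb(SynthConfig(seed=seed))
        apply_transfers(kb, transfer(kb))
        scores = cofunc_scores(kb, role=Role.TRANSFERRED)
        cap = max(kb.ontologies["biological_function"].levels().values())
        dist = level_distribution(scores, cap, stat="max")
        assert dist.total == len(scores)
        tally = {}
        n = 0
        for s in scores:
            if s.max_level is None:
                n += 1
            else:
                tally[min(s.max_level, cap)] = tally.get(min(s.max_level, cap), 0) + 1
        assert dist.n_count == n
        assert {k: v for k, v in dist.counts.items() if v} == tally


class TestScopeMonotonicity:
    @pytest.mark.parametrize("seed", range(20))
    def test_widening_scope_never_hurts(self, seed):
        """Adding transferred GO annotations can only raise max levels and
        can never push a record into category N."""
        kb, _ = generate_kb(SynthConfig(seed=seed, holdout_fraction=0.7))
        apply_transfers(kb, transfer(kb))
        for role in (Role.TRANSFERRED, Role.KNOWN):
            base = cofunc_scores(kb, scope=Scope.KNOWN_ONLY, role=role)
            wide = cofunc_scores(kb, scope=Scope.KNOWN_PLUS_TRANSFERRED,
                                 role=role)
            by_key = {(s.gene_id, s.pathway_id): s for s in wide}
            assert set(by_key) == {(s.gene_id, s.pathway_id) for s in base}
            for s in base:
                w = by_key[(s.gene_id, s.pathway_id)]
                if s.max_level is not None:
                    assert w.max_level is not None
                    assert w.max_level >= s.max_level

    def test_avg_never_exceeds_max(self):
        kb, _ = generate_kb(SynthConfig(seed=31))
        apply_transfers(kb, transfer(kb))
        for role in (Role.TRANSFERRED, Role.KNOWN):
            for s in cofunc_scores(kb, role=role):
                if s.max_level is not None:
                    assert s.avg_level <= s.max_level
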