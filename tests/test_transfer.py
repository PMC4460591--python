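"""Transfer engine: filters, redundancy, provenance, oracle equivalence."""

import pytest

from transannot.model import (
    Association,
    FeatureItem,
    Inferred,
    SemanticType,
)
from transannot.synthetic import SynthConfig, generate_kb
from transannot.transfer import (
    FilterConfig,
    apply_transfers,
    eligible_support,
    is_redundant_ontology_target,
    transfer,
    transfer_with_stats,
)

from conftest import add_items, chain_dag, standard_schema
from oracles import brute_force_transfer, transfer_as_comparable

ANN, ENC = SemanticType.ANNOTATED_TO, SemanticType.ENCODES


def _ann(s, o, evidence=("NAS",), **kwargs):
    return Association(s, o, ANN, evidence_codes=frozenset(evidence), **kwargs)


class TestEligibleSupport:
    cfg = FilterConfig()

    def _items(self, obsolete_subject=False, obsolete_object=False):
        return (FeatureItem("p", "protein", obsolete=obsolete_subject),
                FeatureItem("t", "biological_function", obsolete=obsolete_object))

    def test_iea_only_excluded(self):
        assert not eligible_support(_ann("p", "t", ("IEA",)), *self._items(),
                                    cfg=self.cfg)

    def test_curated_evidence_kept(self):
        assert eligible_support(_ann("p", "t", ("NAS",)), *self._items(),
                                cfg=self.cfg)

    def test_mixed_iea_evidence_kept(self):
        assert eligible_support(_ann("p", "t", ("IEA", "NAS")), *self._items(),
                                cfg=self.cfg)

    def test_no_evidence_information_kept(self):
        assert eligible_support(_ann("p", "t", ()), *self._items(), cfg=self.cfg)

    def test_previously_transferred_always_excluded(self):
        a = _ann("p", "t", ("NAS",), inferred=Inferred.TRANSITIVE_RELATIONSHIP)
        assert not eligible_support(a, *self._items(), cfg=self.cfg)
        assert self.cfg.exclude_transferred_support is True

    def test_computational_source_excluded_by_default(self):
        a = _ann("p", "t", ("NAS",), inferred=Inferred.SOURCE_COMPUTATIONAL)
        assert not eligible_support(a, *self._items(), cfg=self.cfg)
        lax = FilterConfig(exclude_source_computational=False)
        assert eligible_support(a, *self._items(), cfg=lax)

    def test_obsolete_edge_or_endpoint_excluded(self):
        assert not eligible_support(_ann("p", "t", obsolete=True),
                                    *self._items(), cfg=self.cfg)
        assert not eligible_support(_ann("p", "t"),
                                    *self._items(obsolete_object=True),
                                    cfg=self.cfg)


class TestRedundancy:
    def _kb(self):
        kb = standard_schema(chain_dag())
        add_items(kb, "gene", "G1")
        add_items(kb, "biological_function", "R", "X", "Y")
        return kb

    def test_ancestor_of_known_is_redundant(self):
        kb = self._kb()
        kb.add_association(_ann("G1", "Y"))
        dag = kb.ontologies["biological_function"]
        assert is_redundant_ontology_target(kb, "G1", "X", dag)
        assert is_redundant_ontology_target(kb, "G1", "Y", dag)  # duplicate

    def test_unannotated_entity_never_redundant(self):
        kb = self._kb()
        dag = kb.ontologies["biological_function"]
        assert not is_redundant_ontology_target(kb, "G1", "X", dag)

    def test_transferred_annotations_do_not_count_as_known(self):
        kb = self._kb()
        kb.add_association(_ann("G1", "Y",
                                inferred=Inferred.TRANSITIVE_RELATIONSHIP))
        dag = kb.ontologies["biological_function"]
        assert not is_redundant_ontology_target(kb, "G1", "X", dag)


class TestTransferBasics:
    def test_missing_gene_annotation_is_transferred(self, igf2_like_kb):
        out = transfer(igf2_like_kb)
        assert len(out) == 1
        t = out[0]
        assert t.association.triple == ("G1", "GO:0005", ANN)
        assert t.association.inferred is Inferred.TRANSITIVE_RELATIONSHIP
        assert t.candidate_only is False
        assert len(t.provenance) == 1
        ab, bc = t.provenance[0]
        assert ab.triple == ("G1", "P1", ENC)
        assert bc.triple == ("P1", "GO:0005", ANN)
        assert t.association.evidence_codes == {"NAS"}

    def test_known_descendant_suppresses_ancestor_transfer(self, igf2_like_kb):
        # GO:0005 is an ancestor of the already-annotated GO:0008
        igf2_like_kb.add_association(_ann("G1", "GO:0008", source="goa"))
        assert transfer(igf2_like_kb) == []

    def test_pseudogene_gets_no_functional_annotation(self):
        kb = standard_schema(chain_dag())
        kb.add_item(FeatureItem("G2", "gene", item_class="pseudogene"))
        add_items(kb, "protein", "P2")
        add_items(kb, "biological_function", "R", "X", "Y")
        kb.add_association(Association("G2", "P2", ENC))
        kb.add_association(_ann("P2", "Y"))
        assert transfer(kb) == []
        # but the same chain from a protein-coding twin gene is emitted
        kb.add_item(FeatureItem("G3", "gene", item_class="protein_coding"))
        add_items(kb, "protein", "P3")
        kb.add_association(Association("G3", "P3", ENC))
        kb.add_association(_ann("P3", "Y"))
        out = transfer(kb)
        assert [t.association.triple for t in out] == [("G3", "Y", ANN)]

    def test_existing_annotation_not_rederived(self, igf2_like_kb):
        igf2_like_kb.add_association(_ann("G1", "GO:0005", source="goa"))
        assert transfer(igf2_like_kb) == []

    def test_two_provenance_paths_merge_into_one_record(self):
        kb = standard_schema(chain_dag())
        add_items(kb, "gene", "G1")
        add_items(kb, "protein", "P1", "P2")
        add_items(kb, "biological_function", "R", "X", "Y")
        for p in ("P1", "P2"):
            kb.add_association(Association("G1", p, ENC))
            kb.add_association(_ann(p, "Y"))
        out = transfer(kb)
        assert len(out) == 1
        assert len(out[0].provenance) == 2

    def test_within_run_ancestor_dropped(self):
        """When both a term and its strict ancestor become derivable in one
        run, only the most specific survives."""
        kb = standard_schema(chain_dag())
        add_items(kb, "gene", "G1")
        add_items(kb, "protein", "P1", "P2")
        add_items(kb, "biological_function", "R", "X", "Y")
        kb.add_association(Association("G1", "P1", ENC))
        kb.add_association(Association("G1", "P2", ENC))
        kb.add_association(_ann("P1", "Y"))
        kb.add_association(_ann("P2", "X"))
        out = transfer(kb)
        assert [t.association.triple for t in out] == [("G1", "Y", ANN)]


class TestTransferProperties:
    @pytest.mark.parametrize("seed", range(12))
    def test_idempotence_on_synthetic_kbs(self, seed):
        kb, _ = generate_kb(SynthConfig(seed=seed))
        out = transfer(kb)
        assert apply_transfers(kb, out) == len(out)
        assert transfer(kb) == []

    def test_provenance_edges_exist_and_share_middle(self):
        kb, _ = generate_kb(SynthConfig(seed=99))
        stored = set(a.key for a in kb.associations)
        for t in transfer(kb):
            for ab, bc in t.provenance:
                assert ab.key in stored and bc.key in stored
                shared = {ab.subject_id, ab.object_id} & \
                    {bc.subject_id, bc.object_id}
                assert shared, "support edges must share the middle item"

    def test_removing_a_support_removes_the_output(self, igf2_like_kb):
        (t,) = transfer(igf2_like_kb)
        ab, bc = t.provenance[0]
        for removed in (ab, bc):
            kb2 = igf2_like_kb.copy()
            kb2.remove_associations(lambda a: a.key == removed.key)
            assert transfer(kb2) == []

    def test_adding_encodes_edge_never_removes_outputs(self, igf2_like_kb):
        before = {t.association.triple for t in transfer(igf2_like_kb)}
        add_items(igf2_like_kb, "protein", "P9")
        igf2_like_kb.add_association(Association("G1", "P9", ENC))
        after = {t.association.triple for t in transfer(igf2_like_kb)}
        assert before <= after

    def test_stats_reconcile_with_matched_paths(self):
        kb, _ = generate_kb(SynthConfig(seed=4, p_obsolete=0.2, p_iea_only=0.3))
        _, stats = transfer_with_stats(kb)
        assert stats.matched_paths == stats.total_rejected + stats.emitted_paths


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_synthetic_kbs_match_brute_force(self, seed):
        kb, _ = generate_kb(SynthConfig(
            seed=seed, n_genes=20, n_proteins=28, n_terms=25, n_pathways=6,
            n_disorders=4, n_ppis=10, n_transcripts=8,
            p_obsolete=0.1, p_iea_only=0.2, p_pseudogene=0.1))
        assert transfer_as_comparable(transfer(kb)) == brute_force_transfer(kb)

    @pytest.mark.parametrize("seed", range(25))
    def test_messy_random_kbs_match_brute_force(self, seed):
        from conftest import random_messy_kb
        kb = random_messy_kb(seed)
        assert transfer_as_comparable(transfer(kb)) == brute_force_transfer(kb)
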