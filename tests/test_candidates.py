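"""Protein- and PPI-disorder candidate detection."""

import pytest

from transannot.candidates import (
    ppi_disorder_candidates,
    protein_disorder_candidates,
)
from transannot.model import Association, PPIRecord, SemanticType
from transannot.synthetic import SynthConfig, generate_kb

from conftest import add_items, random_messy_kb, standard_schema
from oracles import brute_force_ppi_candidates, brute_force_protein_candidates

ANN, ENC = SemanticType.ANNOTATED_TO, SemanticType.ENCODES


def _basic_kb():
    kb = standard_schema()
    add_items(kb, "gene", "gA", "gB")
    add_items(kb, "protein", "pA", "pB")
    add_items(kb, "genetic_disorder", "D", "D2")
    return kb


class TestProteinCandidates:
    def test_encoding_gene_with_disorder_yields_candidate(self):
        kb = _basic_kb()
        kb.add_association(Association("gA", "pA", ENC))
        kb.add_association(Association("gA", "D", ANN, source="omim"))
        out = protein_disorder_candidates(kb)
        assert [(c.target_id, c.disorder_id) for c in out] == [("pA", "D")]
        assert out[0].candidate_only is True
        assert out[0].target_kind == "PROTEIN"

    def test_disorder_without_encodes_yields_nothing(self):
        kb = _basic_kb()
        kb.add_association(Association("gA", "D", ANN, source="omim"))
        assert protein_disorder_candidates(kb) == []

    def test_two_encoding_genes_merge_into_one_candidate(self):
        kb = _basic_kb()
        for g in ("gA", "gB"):
            kb.add_association(Association(g, "pA", ENC))
            kb.add_association(Association(g, "D", ANN, source="omim"))
        out = protein_disorder_candidates(kb)
        assert len(out) == 1
        assert len(out[0].provenance) == 2


class TestPPICandidates:
    def _ppi_kb(self):
        kb = _basic_kb()
        kb.add_association(Association("gA", "pA", ENC))
        kb.add_association(Association("gB", "pB", ENC))
        kb.add_ppi(PPIRecord.make("ppi1", "pA", "pB"))
        return kb

    def test_shared_disorder_yields_candidate(self):
        kb = self._ppi_kb()
        kb.add_association(Association("gA", "D", ANN))
        kb.add_association(Association("gB", "D", ANN))
        out = ppi_disorder_candidates(kb)
        assert [(c.target_id, c.disorder_id) for c in out] == [("ppi1", "D")]

    def test_different_disorders_yield_nothing(self):
        kb = self._ppi_kb()
        kb.add_association(Association("gA", "D", ANN))
        kb.add_association(Association("gB", "D2", ANN))
        assert ppi_disorder_candidates(kb) == []
        # the laxer one-endpoint variant accepts both
        lax = ppi_disorder_candidates(kb, require_both_endpoints=False)
        assert {(c.target_id, c.disorder_id) for c in lax} == \
            {("ppi1", "D"), ("ppi1", "D2")}

    def test_self_interaction_needs_single_support(self):
        kb = _basic_kb()
        kb.add_association(Association("gA", "pA", ENC))
        kb.add_association(Association("gA", "D", ANN))
        kb.add_ppi(PPIRecord.make("self", "pA", "pA"))
        out = ppi_disorder_candidates(kb)
        assert [(c.target_id, c.disorder_id) for c in out] == [("self", "D")]

    def test_endpoint_order_does_not_matter(self):
        kb1 = self._ppi_kb()
        kb2 = _basic_kb()
        kb2.add_association(Association("gA", "pA", ENC))
        kb2.add_association(Association("gB", "pB", ENC))
        kb2.add_ppi(PPIRecord.make("ppi1", "pB", "pA"))  # swapped
        for kb in (kb1, kb2):
            kb.add_association(Association("gA", "D", ANN))
            kb.add_association(Association("gB", "D", ANN))
        as_set = lambda out: {(c.target_id, c.disorder_id) for c in out}
        assert as_set(ppi_disorder_candidates(kb1)) == \
            as_set(ppi_disorder_candidates(kb2))


class TestCysticFibrosisExample:
    def test_six_ppi_and_eight_protein_candidates(self, cystic_fibrosis_kb):
        prot = protein_disorder_candidates(cystic_fibrosis_kb)
        assert {(c.target_id, c.disorder_id) for c in prot} == {
            (p, "Cystic fibrosis")
            for p in ("CFTR_HUMAN", "DERL1_HUMAN", "RNF5_HUMAN", "AHSA1_HUMAN",
                      "GOPC_HUMAN", "CHIP_HUMAN", "HSP7C_HUMAN", "CLCN2_HUMAN")}
        ppi = ppi_disorder_candidates(cystic_fibrosis_kb)
        assert len(ppi) == 6
        assert all(c.disorder_id == "Cystic fibrosis" for c in ppi)
        named = {frozenset((cystic_fibrosis_kb.ppis[c.target_id].protein_1_id,
                            cystic_fibrosis_kb.ppis[c.target_id].protein_2_id))
                 for c in ppi}
        assert named == {
            frozenset(p) for p in [
                ("CFTR_HUMAN", "DERL1_HUMAN"), ("CFTR_HUMAN", "RNF5_HUMAN"),
                ("CFTR_HUMAN", "AHSA1_HUMAN"), ("CFTR_HUMAN", "GOPC_HUMAN"),
                ("CHIP_HUMAN", "HSP7C_HUMAN"), ("CHIP_HUMAN", "CLCN2_HUMAN")]}


class TestCandidateProperties:
    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_on_random_kbs(self, seed):
        kb = random_messy_kb(seed)
        got_p = {(c.target_id, c.disorder_id)
                 for c in protein_disorder_candidates(kb)}
        got_x = {(c.target_id, c.disorder_id)
                 for c in ppi_disorder_candidates(kb)}
        assert got_p == brute_force_protein_candidates(kb)
        assert got_x == brute_force_ppi_candidates(kb)

    @pytest.mark.parametrize("seed", range(10))
    def test_ppi_candidate_implies_both_protein_candidates(self, seed):
        kb, _ = generate_kb(SynthConfig(seed=seed))
        prot = {(c.target_id, c.disorder_id)
                for c in protein_disorder_candidates(kb)}
        for c in ppi_disorder_candidates(kb):
            ppi = kb.ppis[c.target_id]
            assert (ppi.protein_1_id, c.disorder_id) in prot
            assert (ppi.protein_2_id, c.disorder_id) in prot

    def test_provenance_never_empty(self):
        kb, _ = generate_kb(SynthConfig(seed=17))
        for c in protein_disorder_candidates(kb) + ppi_disorder_candidates(kb):
            assert c.provenance
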