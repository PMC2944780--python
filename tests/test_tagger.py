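"""Pattern matching contract, symbol disambiguation, concordance building."""

import numpy as np
import pytest

from conftest import naive_keyword_match

from litdisc.corpus_io import Concept, ConfigError, Corpus, DocumentRecord, PubDate
from litdisc.synthetic_data import ambiguity_fixture
from litdisc.tagger import (
    build_concordance,
    compile_pattern,
    compile_thesaurus,
    disambiguate_symbol_hits,
    tag_document,
)
from litdisc.thesaurus_prep import CleanedKeyword


def _kw(text, ktype="full_name"):
    return CleanedKeyword(text, text, ktype)


def _doc(body, doc_id="d1", title="", substances=()):
    return DocumentRecord(doc_id, title, body, tuple(substances), PubDate(1999))


class TestCompilePattern:
    @pytest.mark.parametrize(
        "keyword, text, hit",
        [
            ("cell death 1", "study of cell-death 1 in mice", True),
            ("cell death", "observed (cell deaths) were counted", True),
            ("cell death", "mycell death happened", False),
            ("cell death", "celldeath", False),
            ("cell death", "Cell Death:", True),  # case-insensitive full name
            ("cell death", "a cell death; b", True),
            ("cell death", "cell deathly", False),
        ],
    )
    def test_full_name_boundary_contract(self, keyword, text, hit):
        pat = compile_pattern(_kw(keyword), "g1", "gene")
        assert pat.search(text) is hit

    def test_symbols_match_case_sensitively(self):
        pat = compile_pattern(_kw("PDCD1", "symbol"), "g1", "gene")
        assert pat.search("role of PDCD1 in disease")
        assert not pat.search("role of pdcd1 in disease")

    def test_symbols_have_no_plural_by_default(self):
        pat = compile_pattern(_kw("PDCD1", "symbol"), "g1", "gene")
        assert not pat.search("the PDCD1s are")
        pat_s = compile_pattern(
            _kw("PDCD1", "symbol"), "g1", "gene", allow_plural_symbols=True
        )
        assert pat_s.search("the PDCD1s are")

    def test_agrees_with_naive_character_matcher(self, rng):
        """Regex contract equals a literal character-scanning oracle."""
        keywords = ["cell death", "insulin receptor 2", "ACTB", "tumor necrosis factor"]
        vocab = ["cell", "death", "cell-death", "insulin", "receptor", "2",
                 "ACTB", "actb", "tumor", "necrosis", "factor", "deaths",
                 "mycell", "(cell", "death)", "factor,", "of", "the"]
        for _ in range(300):
            text = " ".join(rng.choice(vocab, size=rng.integers(1, 12)))
            for kw_text in keywords:
                is_symbol = kw_text.isupper()
                ktype = "symbol" if is_symbol else "full_name"
                pat = compile_pattern(_kw(kw_text, ktype), "x", "gene")
                expected = naive_keyword_match(
                    text,
                    kw_text,
                    case_sensitive=is_symbol,
                    allow_plural=not is_symbol,
                    dash_for_space=not is_symbol,
                )
                assert pat.search(text) is expected, (text, kw_text)


class TestTagDocument:
    def _compiled(self):
        return compile_thesaurus(
            [
                Concept("g1", "gene",
                        (("programmed cell death 1", "full_name"), ("PDCD1", "symbol"))),
                Concept("d1", "disease", (("graves disease", "full_name"),)),
                Concept("p1", "pathway", (("insulin signaling", "full_name"),)),
            ]
        )

    def test_symbol_and_full_name_collapse_to_one_concept(self):
        thes = self._compiled()
        doc = _doc("PDCD1 is the programmed cell death 1 receptor")
        hits = tag_document(doc, thes.patterns)
        assert {cid for cid, _ in hits} == {"g1"}
        assert ("g1", "symbol") in hits and ("g1", "full_name") in hits

    def test_no_keywords_empty_set(self):
        thes = self._compiled()
        assert tag_document(_doc("nothing relevant here"), thes.patterns) == set()

    def test_three_concepts_three_hits(self):
        thes = self._compiled()
        doc = _doc(
            "graves disease links PDCD1 and programmed cell death 1 to insulin signaling"
        )
        hits = tag_document(doc, thes.patterns)
        assert {cid for cid, _ in hits} == {"g1", "d1", "p1"}

    def test_substances_field_is_searched(self):
        thes = self._compiled()
        doc = _doc("body text only", substances=["PDCD1 death"])
        hits = tag_document(doc, thes.patterns)
        assert ("g1", "symbol") in hits


class TestDisambiguation:
    def _thes(self):
        return compile_thesaurus(
            [
                Concept("g1", "gene",
                        (("programmed cell death 1", "full_name"), ("PDCD1", "symbol"))),
            ]
        )

    def test_symbol_only_without_full_name_word_discarded(self):
        thes = self._thes()
        doc = _doc("PDCD1 was observed in samples")
        hits = tag_document(doc, thes.patterns)
        assert hits == {("g1", "symbol")}
        assert disambiguate_symbol_hits(doc, hits, thes) == set()

    def test_symbol_with_full_name_word_retained(self):
        thes = self._thes()
        doc = _doc("PDCD1 mediates death of T cells")
        hits = tag_document(doc, thes.patterns)
        assert disambiguate_symbol_hits(doc, hits, thes) == hits

    def test_full_name_hit_bypasses_check(self):
        thes = self._thes()
        doc = _doc("programmed cell death 1 expression rose")
        hits = tag_document(doc, thes.patterns)
        assert disambiguate_symbol_hits(doc, hits, thes) == hits

    def test_fixture_corpus_end_to_end(self):
        corpus, thesaurus, expected = ambiguity_fixture()
        index = build_concordance(corpus, thesaurus)
        assert index.doc_to_concepts == expected.doc_to_concepts
        assert index.concept_to_docs == expected.concept_to_docs


class TestBuildConcordance:
    def _inputs(self):
        thesaurus = [
            Concept("g1", "gene", (("alpha regulator", "full_name"),)),
            Concept("d1", "disease", (("gravex syndrome", "full_name"),)),
        ]
        docs = [
            _doc("alpha regulator and gravex syndrome", doc_id="d1"),
            _doc("only alpha regulator here", doc_id="d2"),
            _doc("nothing at all", doc_id="d3"),
        ]
        return Corpus(tuple(docs)), thesaurus

    def test_inverse_map_property(self):
        corpus, thesaurus = self._inputs()
        index = build_concordance(corpus, thesaurus)
        for d, cs in index.doc_to_concepts.items():
            for c in cs:
                assert d in index.concept_to_docs[c]
        for c, ds in index.concept_to_docs.items():
            for d in ds:
                assert c in index.doc_to_concepts[d]

    def test_empty_docs_kept_in_denominator(self):
        corpus, thesaurus = self._inputs()
        index = build_concordance(corpus, thesaurus)
        assert index.n_docs == 3
        assert index.doc_to_concepts["d3"] == frozenset()

    def test_document_order_does_not_matter(self):
        corpus, thesaurus = self._inputs()
        shuffled = Corpus(tuple(reversed(corpus.documents)))
        i1 = build_concordance(corpus, thesaurus)
        i2 = build_concordance(shuffled, thesaurus)
        assert i1.doc_to_concepts == i2.doc_to_concepts
        assert i1.concept_to_docs == i2.concept_to_docs

    def test_removed_document_absent_from_both_maps(self):
        corpus, thesaurus = self._inputs()
        reduced = Corpus(tuple(d for d in corpus if d.doc_id != "d1"))
        index = build_concordance(reduced, thesaurus)
        assert "d1" not in index.doc_to_concepts
        assert all("d1" not in ds for ds in index.concept_to_docs.values())

    def test_empty_thesaurus_is_config_error(self):
        corpus, _ = self._inputs()
        with pytest.raises(ConfigError):
            build_concordance(corpus, [])

    def test_empty_corpus_gives_empty_index(self):
        _, thesaurus = self._inputs()
        index = build_concordance(Corpus(()), thesaurus)
        assert index.n_docs == 0
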