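"""Query-set construction, scoring, and report rendering."""

import io

import pytest

from phenonorm import generate_fixture
from phenonorm.bm25 import BM25Normalizer, RetrievalMode, build_index
from phenonorm.corpus import Origin, build_name_syn_corpus
from phenonorm.evaluation import (
    build_query_sets,
    constant_none,
    digit_suffix_mismatch,
    evaluate,
    gold_oracle,
    prompt_robustness,
    read_report_tsv,
    write_report,
)
from phenonorm.llm import ALTERNATE_PROMPT_TEMPLATE, DEFAULT_PROMPT_TEMPLATE, make_records
from phenonorm.ontology import extract_xref_terms
from phenonorm.perturb import hamming
from phenonorm.queries import Category, QueryItem


@pytest.fixture(scope="module")
def query_setup():
    vocab = generate_fixture(20, (3, 3), xref_rate=0.5, seed=7)
    corp = build_name_syn_corpus(vocab, seed=1)
    xrefs = extract_xref_terms(vocab, "SNOMEDCT_US")
    queries = build_query_sets(vocab, corp.held_out, xrefs, seed=2)
    return vocab, corp, queries


class TestBuildQuerySets:
    def test_category_counts(self, query_setup):
        vocab, corp, queries = query_setup
        by_cat = {cat: [q for q in queries if q.category == cat] for cat in Category}
        assert len(by_cat[Category.TRAIN_NAME]) == 20
        # 3 synonyms each, floor split -> 1 trained, 2 held out
        assert len(by_cat[Category.HELD_OUT_SYNONYM]) == 40
        assert len(by_cat[Category.SIMPLE_TYPO]) == 20
        assert len(by_cat[Category.COMPLEX_TYPO]) == 20
        assert len(by_cat[Category.LAYMEN]) == 0

    def test_simple_typos_at_distance_one_from_source(self, query_setup):
        _, _, queries = query_setup
        for q in queries:
            if q.category == Category.SIMPLE_TYPO:
                assert hamming(q.source_term, q.term) == 1

    def test_typos_derived_from_preferred_names_only(self, query_setup):
        vocab, _, queries = query_setup
        names = {c.name for c in vocab}
        for q in queries:
            if q.category in (Category.SIMPLE_TYPO, Category.COMPLEX_TYPO):
                assert q.source_term in names

    def test_laymen_rows_with_unknown_gold_dropped(self, query_setup):
        vocab, corp, _ = query_setup
        laymen = [
            QueryItem("passing out", vocab.concepts[0].id, Category.LAYMEN),
            QueryItem("ghost term", "HP:9999999", Category.LAYMEN),
        ]
        queries = build_query_sets(vocab, [], [], laymen, seed=0)
        kept = [q for q in queries if q.category == Category.LAYMEN]
        assert len(kept) == 1 and kept[0].term == "passing out"

    def test_deterministic_per_seed(self, query_setup):
        vocab, corp, _ = query_setup
        a = build_query_sets(vocab, corp.held_out, seed=5)
        b = build_query_sets(vocab, corp.held_out, seed=5)
        assert a == b

    def test_held_out_hygiene(self, query_setup):
        """No held-out synonym appears in the training corpus sentences."""
        _, corp, queries = query_setup
        training_terms = {s.term for s in corp.sentences}
        for q in queries:
            if q.category == Category.HELD_OUT_SYNONYM:
                assert q.term not in training_terms


class TestEvaluate:
    def test_oracle_sandwich(self, query_setup):
        vocab, _, queries = query_setup
        oracle_rep = evaluate(gold_oracle(queries), queries)
        none_rep = evaluate(constant_none, queries)
        index = build_index(vocab)
        bm25_rep = evaluate(BM25Normalizer(index, RetrievalMode.OR), queries)
        for row in oracle_rep.rows:
            assert row.accuracy == 1.0
        for row in none_rep.rows:
            assert row.accuracy == 0.0
            assert row.n_no_prediction == row.n_total
        for row in bm25_rep.rows:
            assert 0.0 <= row.accuracy <= 1.0

    def test_count_conservation(self, query_setup):
        vocab, _, queries = query_setup
        rep = evaluate(BM25Normalizer(build_index(vocab), RetrievalMode.AND), queries)
        assert sum(r.n_total for r in rep.rows) == len(queries)
        for r in rep.rows:
            assert 0 <= r.n_no_prediction <= r.n_total
            assert r.n_correct + r.n_no_prediction <= r.n_total

    def test_normalizer_exception_counts_as_no_prediction(self, query_setup):
        _, _, queries = query_setup

        def broken(term):
            raise RuntimeError("boom")

        rep = evaluate(broken, queries, name="broken")
        assert all(r.n_no_prediction == r.n_total for r in rep.rows)

    def test_digit_suffix_mismatch_diagnostic(self):
        assert digit_suffix_mismatch("HP:0000366", "HP:0000365") == 1
        assert digit_suffix_mismatch("HP:0000399", "HP:0000365") == 2
        assert digit_suffix_mismatch("HP:1000365", "HP:0000365") == 7
        assert digit_suffix_mismatch("XP:0000365", "HP:0000365") is None

    def test_near_miss_recorded_in_outcomes(self):
        queries = [QueryItem("t", "HP:0000365", Category.TRAIN_NAME)]

        def off_by_one(term):
            return "HP:0000366"

        rep = evaluate(off_by_one, queries, name="near")
        assert rep.outcomes[0].digit_suffix_mismatch == 1

    def test_hyphen_stripping_preprocessor_applied(self, query_setup):
        vocab, _, _ = query_setup
        seen = []

        def spy(term):
            seen.append(term)
            return None

        from phenonorm.perturb import strip_hyphens

        queries = [QueryItem("Kidney - Abnormal", vocab.concepts[0].id, Category.XREF)]
        evaluate(spy, queries, name="spy", term_preprocessor=strip_hyphens)
        assert seen == ["Kidney Abnormal"]


class TestPromptRobustness:
    def test_memorizing_stub_brittle_to_alternate_template(self, query_setup):
        vocab, corp, _ = query_setup
        records = make_records(corp)

        class Stub:
            table = {r.prompt: r.completion for r in records}

            def complete(self, prompt, max_new_chars=16):
                return self.table.get(prompt, "no idea")

        queries = [QueryItem(c.name, c.id, Category.TRAIN_NAME) for c in vocab]
        rep = prompt_robustness(Stub(), [DEFAULT_PROMPT_TEMPLATE, ALTERNATE_PROMPT_TEMPLATE], queries)
        accs = {r.metadata["template"]: r.accuracy for r in rep.rows}
        assert accs[DEFAULT_PROMPT_TEMPLATE] == 1.0
        assert accs[ALTERNATE_PROMPT_TEMPLATE] == 0.0

    def test_empty_template_list(self, query_setup):
        vocab, _, _ = query_setup
        rep = prompt_robustness(None, [], [])
        assert rep.rows == []


class TestWriteReport:
    def test_tsv_round_trip(self, query_setup):
        vocab, _, queries = query_setup
        rep = evaluate(BM25Normalizer(build_index(vocab), RetrievalMode.OR), queries)
        text = write_report(rep, "tsv")
        back = read_report_tsv(io.StringIO(text))
        assert [(r.category, r.n_total, r.n_correct) for r in back] == [
            (r.category, r.n_total, r.n_correct) for r in rep.rows
        ]

    def test_percentage_formatting(self, query_setup):
        vocab, _, queries = query_setup
        rep = evaluate(gold_oracle(queries), queries)
        text = write_report(rep, "tsv")
        assert "100.0%" in text
        aligned = write_report(rep, "text")
        assert "gold-oracle" in aligned

    def test_single_row_report(self):
        queries = [QueryItem("a", "HP:0000001", Category.TRAIN_NAME)]
        rep = evaluate(constant_none, queries)
        lines = write_report(rep, "tsv").strip().splitlines()
        assert len(lines) == 2

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError):
            write_report(evaluate(constant_none, []), "xlsx")
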