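"""BM25 indexing baseline: tokenization, scoring, AND/OR retrieval."""

import math

import numpy as np
import pytest

from phenonorm import generate_fixture
from phenonorm.bm25 import (
    BM25Normalizer,
    Entry,
    RetrievalMode,
    TermIndex,
    bm25_score,
    build_index,
    candidates,
    normalize,
    tokenize,
)
from phenonorm.ontology import Concept, Vocabulary
from phenonorm.perturb import simple_typo, strip_hyphens


def brute_force_normalize(index: TermIndex, query: str, mode: RetrievalMode) -> str | None:
    """Independent oracle: enumerate every entry, no postings lists."""
    tokens = tokenize(query)
    if not tokens:
        return None
    best = None
    for i, entry in enumerate(index.entries):
        present = [t in entry.tokens for t in tokens]
        if mode is RetrievalMode.AND and not all(present):
            continue
        if mode is RetrievalMode.OR and not any(present):
            continue
        score = bm25_score(index, tokens, i)
        key = (-score, entry.concept_id)
        if best is None or key < best[0]:
            best = (key, entry.concept_id)
    return best[1] if best else None


class TestTokenize:
    @pytest.mark.parametrize(
        "term,expected",
        [
            ("Kidney - Abnormal", ["kidney", "abnormal"]),
            ("Low-set, posteriorly rotated ears", ["low", "set", "posteriorly", "rotated", "ears"]),
            ("", []),
            ("   --- ", []),
            ("2-3 toe syndactyly", ["2", "3", "toe", "syndactyly"]),
        ],
    )
    def test_examples(self, term, expected):
        assert tokenize(term) == expected

    def test_hyphen_stripping_is_token_invariant(self, medium_vocab):
        for c in medium_vocab:
            for term in c.surface_terms:
                assert tokenize(strip_hyphens(term)) == tokenize(term)
        assert tokenize(strip_hyphens("Kidney - Abnormal")) == tokenize("Kidney - Abnormal")


class TestBuildIndex:
    def test_one_entry_per_surface_term(self):
        vocab = generate_fixture(50, (3, 3), 0.0, seed=2)
        index = build_index(vocab)
        assert index.n_entries == 200

    def test_single_concept_identity_retrieval(self):
        vocab = Vocabulary([Concept(id="HP:0000001", name="Hearing impairment")])
        index = build_index(vocab)
        assert index.n_entries == 1
        for mode in RetrievalMode:
            assert normalize(index, "Hearing impairment", mode) == "HP:0000001"

    def test_document_frequencies_match_brute_force(self, medium_vocab):
        index = build_index(medium_vocab)
        for token in list(index.postings)[:50]:
            expected = sum(token in e.tokens for e in index.entries)
            assert index.document_frequency(token) == expected

    def test_empty_vocabulary_fatal(self):
        with pytest.raises(ValueError):
            build_index(Vocabulary(concepts=[]))

    def test_json_round_trip(self, small_vocab, tmp_path):
        index = build_index(small_vocab)
        path = tmp_path / "index.json"
        with open(path, "w") as fh:
            index.to_json(fh)
        with open(path) as fh:
            back = TermIndex.from_json(fh)
        assert back.n_entries == index.n_entries
        for c in small_vocab:
            assert normalize(back, c.name, RetrievalMode.AND) == c.id


class TestBM25Score:
    def _single_entry_index(self):
        return TermIndex([Entry("hearing loss", "HP:0000365", ("hearing", "loss"))])

    def test_no_overlap_scores_zero(self):
        index = self._single_entry_index()
        assert bm25_score(index, ["kidney"], 0) == 0.0

    def test_closed_form_single_entry(self):
        """With N=1, df=1, tf=1, len=avglen: idf=ln(1+0.5/1.5), weight=1."""
        index = self._single_entry_index()
        idf = math.log(1 + 0.5 / 1.5)
        k1 = 1.2
        expected = 2 * idf * (k1 + 1) / (1 + k1)  # two query tokens, tf=1, norm=k1
        assert bm25_score(index, ["hearing", "loss"], 0) == pytest.approx(expected)

    def test_term_frequency_saturation(self):
        """Repeating a token raises the score sublinearly."""
        entries = [
            Entry("pain", "HP:0000001", ("pain",)),
            Entry("pain pain", "HP:0000002", ("pain", "pain")),
            Entry("pain pain pain pain", "HP:0000003", ("pain",) * 4),
        ]
        index = TermIndex(entries)
        s1 = bm25_score(index, ["pain"], 0)
        s2 = bm25_score(index, ["pain"], 1)
        s4 = bm25_score(index, ["pain"], 2)
        # tf gain shrinks: (s2-s1) > (s4-s2)/2, and scores stay ordered
        assert s1 < s2 < s4
        assert (s2 - s1) > (s4 - s2) / 2

    def test_scores_nonnegative(self, medium_vocab):
        index = build_index(medium_vocab)
        tokens = tokenize(medium_vocab.concepts[0].name)
        assert all(bm25_score(index, tokens, i) >= 0 for i in range(0, index.n_entries, 7))


class TestNormalize:
    def test_self_retrieval_all_names(self, medium_vocab):
        index = build_index(medium_vocab)
        for c in medium_vocab:
            assert normalize(index, c.name, RetrievalMode.AND) == c.id
            assert normalize(index, c.name, RetrievalMode.OR) == c.id

    def test_empty_query_returns_none(self, small_vocab):
        index = build_index(small_vocab)
        assert normalize(index, "  - ", RetrievalMode.OR) is None

    def test_and_candidates_subset_of_or(self, medium_vocab):
        index = build_index(medium_vocab)
        rng = np.random.default_rng(0)
        vocab_tokens = sorted(index.postings)
        for _ in range(500):
            k = int(rng.integers(1, 4))
            toks = [vocab_tokens[int(i)] for i in rng.integers(0, len(vocab_tokens), k)]
            c_and = candidates(index, toks, RetrievalMode.AND)
            c_or = candidates(index, toks, RetrievalMode.OR)
            assert c_and <= c_or

    def test_typo_asymmetry_between_modes(self, medium_vocab):
        """A typo'd token kills AND retrieval but OR can recover via the rest."""
        index = build_index(medium_vocab)
        rng = np.random.default_rng(1)
        and_hits = or_hits = n = 0
        for c in medium_vocab.concepts[:100]:
            if len(tokenize(c.name)) < 2:
                continue
            typo = simple_typo(c.name, seed=rng)
            n += 1
            and_hits += normalize(index, typo, RetrievalMode.AND) == c.id
            or_hits += normalize(index, typo, RetrievalMode.OR) == c.id
        assert n > 50
        assert or_hits > and_hits

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            vocab = generate_fixture(8, (0, 2), 0.0, seed=100 + trial)
            index = build_index(vocab)
            assert index.n_entries <= 30
            queries = [c.name for c in vocab]
            queries += [simple_typo(c.name, seed=rng) for c in vocab.concepts[:4]]
            for q in queries:
                for mode in RetrievalMode:
                    assert normalize(index, q, mode) == brute_force_normalize(index, q, mode)

    def test_tie_break_smallest_concept_id(self):
        entries = [
            Entry("zeta pain", "HP:0000009", ("zeta", "pain")),
            Entry("zeta pain", "HP:0000002", ("zeta", "pain")),
        ]
        index = TermIndex(entries)
        assert normalize(index, "zeta pain", RetrievalMode.AND) == "HP:0000002"

    def test_normalizer_wrapper_callable(self, small_vocab):
        index = build_index(small_vocab)
        norm = BM25Normalizer(index, RetrievalMode.OR)
        assert norm.name == "bm25-or"
        c = small_vocab.concepts[0]
        assert norm(c.name) == c.id
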