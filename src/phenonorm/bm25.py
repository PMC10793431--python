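"""Dictionary-lookup concept normalization with Okapi BM25.

Every preferred name and every synonym in the vocabulary is indexed as its
own entry (surface term, concept id), so synonyms compete as separate
retrieval candidates.  A query is tokenized, candidate entries are filtered
under one of two token semantics — ``AND`` requires every query token to
occur in the entry, ``OR`` requires at least one — and candidates are
ranked by Okapi BM25:

    score(q, e) = Σ_t IDF(t) · tf(t,e)·(k1+1) / (tf(t,e) + k1·(1−b+b·|e|/avglen))

with the non-negative IDF variant ``ln(1 + (N − df + 0.5)/(df + 0.5))``.
The top-1 concept id is the normalization result; ties break by higher
score then lexicographically smallest concept id, so retrieval is fully
deterministic.

The asymmetry between the two modes is the baseline's defining behavior: a
single mistyped token empties the AND candidate set outright, while OR can
still rank the entry via its unaltered tokens.
"""

from __future__ import annotations

import enum
import json
import math
import re
from collections import Counter
from dataclasses import dataclass
from typing import IO, Sequence

from .ontology import Vocabulary, iter_surface_terms

_TOKEN_RE = re.compile(r"[0-9a-z]+")

INDEX_FORMAT_VERSION = 1


class RetrievalMode(str, enum.Enum):
    AND = "AND"
    OR = "OR"


def tokenize(term: str) -> list[str]:
    """Lowercase and split on runs of non-alphanumerics; no stemming."""
    return _TOKEN_RE.findall(term.lower())


@dataclass(frozen=True)
class Entry:
    term: str
    concept_id: str
    tokens: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.tokens)


class TermIndex:
    """Inverted index over vocabulary surface terms with BM25 statistics."""

    def __init__(self, entries: Sequence[Entry], k1: float = 1.2, b: float = 0.75):
        if not entries:
            raise ValueError("cannot build an index with no entries")
        self.entries: list[Entry] = list(entries)
        self.k1 = float(k1)
        self.b = float(b)
        self.postings: dict[str, set[int]] = {}
        self._tf: list[Counter[str]] = []
        for i, e in enumerate(self.entries):
            tf = Counter(e.tokens)
            self._tf.append(tf)
            for tok in tf:
                self.postings.setdefault(tok, set()).add(i)
        self.n_entries = len(self.entries)
        self.avg_length = sum(e.length for e in self.entries) / self.n_entries

    def document_frequency(self, token: str) -> int:
        return len(self.postings.get(token, ()))

    def idf(self, token: str) -> float:
        df = self.document_frequency(token)
        n = self.n_entries
        return math.log(1.0 + (n - df + 0.5) / (df + 0.5))

    def term_frequency(self, entry_index: int, token: str) -> int:
        return self._tf[entry_index].get(token, 0)

    # -- persistence (versioned JSON) ------------------------------------
    def to_json(self, stream: IO[str]) -> None:
        json.dump(
            {
                "format_version": INDEX_FORMAT_VERSION,
                "k1": self.k1,
                "b": self.b,
                "entries": [[e.term, e.concept_id] for e in self.entries],
            },
            stream,
        )

    @classmethod
    def from_json(cls, stream: IO[str]) -> "TermIndex":
        d = json.load(stream)
        if d.get("format_version") != INDEX_FORMAT_VERSION:
            raise ValueError(f"unsupported index format version: {d.get('format_version')}")
        entries = [Entry(term=t, concept_id=c, tokens=tuple(tokenize(t))) for t, c in d["entries"]]
        return cls(entries, k1=d["k1"], b=d["b"])


def build_index(vocab: Vocabulary, k1: float = 1.2, b: float = 0.75) -> TermIndex:
    """Index every (name, id) and (synonym, id) pair in the vocabulary."""
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty")
    entries = [
        Entry(term=term, concept_id=cid, tokens=tuple(tokenize(term)))
        for term, cid in iter_surface_terms(vocab)
    ]
    return TermIndex(entries, k1=k1, b=b)


def bm25_score(index: TermIndex, query_tokens: Sequence[str], entry_index: int) -> float:
    """Okapi BM25 score of one indexed entry against the query tokens."""
    entry = index.entries[entry_index]
    norm = index.k1 * (1.0 - index.b + index.b * entry.length / index.avg_length)
    score = 0.0
    for tok in query_tokens:
        tf = index.term_frequency(entry_index, tok)
        if tf == 0:
            continue
        score += index.idf(tok) * tf * (index.k1 + 1.0) / (tf + norm)
    return score


def candidates(index: TermIndex, query_tokens: Sequence[str], mode: RetrievalMode) -> set[int]:
    """Entry indices passing the AND / OR token filter."""
    postings = [index.postings.get(tok, set()) for tok in query_tokens]
    if not postings:
        return set()
    if mode is RetrievalMode.AND:
        result = set(postings[0])
        for p in postings[1:]:
            result &= p
        return result
    return set().union(*postings)


def normalize(index: TermIndex, query: str, mode: RetrievalMode = RetrievalMode.OR) -> str | None:
    """Return the top-1 concept id for a query term, or None if no candidate.

    Ties break by (higher score, lexicographically smallest concept id).
    """
    tokens = tokenize(query)
    if not tokens:
        return None
    cand = candidates(index, tokens, mode)
    if not cand:
        return None
    best = min(cand, key=lambda i: (-bm25_score(index, tokens, i), index.entries[i].concept_id))
    return index.entries[best].concept_id


class BM25Normalizer:
    """Callable term → concept-id wrapper around an index and a mode."""

    def __init__(self, index: TermIndex, mode: RetrievalMode):
        self.index = index
        self.mode = mode
        self.name = f"bm25-{mode.value.lower()}"

    def __call__(self, term: str) -> str | None:
        return normalize(self.index, term, self.mode)
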