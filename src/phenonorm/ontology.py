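"""Reading, writing and synthesizing HPO-style vocabularies.

The Human Phenotype Ontology (HPO) assigns each phenotypic abnormality an
identifier of the form ``HP:`` followed by seven digits, one preferred name,
zero or more synonyms, and optional cross-references (xrefs) into other
vocabularies such as SNOMED-CT.  This module loads OBO flat files into a
light in-memory model, extracts xref surface terms as evaluation queries,
and generates deterministic synthetic vocabularies so the whole pipeline can
be built and tested without downloading an ontology release.

OBO stanza parsing is delegated to :mod:`obonet`; this module unwraps the
raw ``synonym:`` / ``xref:`` values (quoted surface strings, scope tags) and
applies the ingestion rules: obsolete stanzas and non-HP identifiers are
skipped, synonyms are deduplicated case-sensitively, and a synonym equal to
the preferred name is dropped.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np
import obonet

from .queries import Category, QueryItem

logger = logging.getLogger(__name__)

HP_ID_PATTERN = re.compile(r"^HP:[0-9]{7}$")

#: Raw OBO synonym value, e.g. ``"Deafness" EXACT []`` — the quoted portion
#: is the surface string; the scope tag is ignored (all scopes ingested).
_SYNONYM_RE = re.compile(r'^\s*"(?P<term>.*)"')

#: Raw OBO xref value, e.g. ``SNOMEDCT_US:15188001 "Hearing loss"``.
_XREF_RE = re.compile(r'^\s*(?P<source>[^:\s]+):(?P<fid>\S+)(?:\s+"(?P<term>.*)")?')


@dataclass(frozen=True)
class Xref:
    """A cross-reference to a concept in another vocabulary."""

    source: str
    foreign_id: str
    term: str | None = None


@dataclass
class Concept:
    """One ontology concept: identifier, preferred name, synonyms, xrefs."""

    id: str
    name: str
    synonyms: list[str] = field(default_factory=list)
    xrefs: list[Xref] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not HP_ID_PATTERN.match(self.id):
            raise ValueError(f"concept id {self.id!r} does not match HP:NNNNNNN")
        self.name = self.name.strip()
        if not self.name:
            raise ValueError(f"concept {self.id} has an empty name")
        # Deduplicate synonyms (case-sensitive, order-preserving) and drop
        # any synonym identical to the preferred name.
        seen: set[str] = set()
        deduped: list[str] = []
        for syn in self.synonyms:
            syn = syn.strip()
            if not syn or syn == self.name or syn in seen:
                continue
            seen.add(syn)
            deduped.append(syn)
        self.synonyms = deduped

    @property
    def surface_terms(self) -> list[str]:
        """Preferred name followed by all synonyms."""
        return [self.name, *self.synonyms]


@dataclass
class Vocabulary:
    """An ordered collection of concepts with unique identifiers."""

    concepts: list[Concept]
    source: str = "unknown"

    def __post_init__(self) -> None:
        ids = [c.id for c in self.concepts]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate concept ids: {dupes[:5]}")
        self._by_id = {c.id: c for c in self.concepts}

    def __iter__(self) -> Iterator[Concept]:
        return iter(self.concepts)

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._by_id

    def __getitem__(self, concept_id: str) -> Concept:
        return self._by_id[concept_id]

    @property
    def n_synonyms(self) -> int:
        return sum(len(c.synonyms) for c in self.concepts)


def _parse_synonym(raw: str) -> str | None:
    m = _SYNONYM_RE.match(raw)
    return m.group("term") if m else None


def _parse_xref(raw: str) -> Xref | None:
    m = _XREF_RE.match(raw)
    if not m:
        return None
    return Xref(source=m.group("source"), foreign_id=m.group("fid"), term=m.group("term"))


def parse_obo(stream: IO[str] | str) -> Vocabulary:
    """Parse OBO-format text into a :class:`Vocabulary`.

    Accepts a text stream, a path to an OBO file, or a literal OBO string
    (anything containing a ``[Term]`` stanza is treated as literal text).
    Obsolete stanzas and stanzas whose id lacks the ``HP:`` prefix are
    skipped; skip counts are logged.  Synonym surface strings are taken from
    the quoted portion of each ``synonym:`` line regardless of scope tag.
    """
    source = "stream"
    if isinstance(stream, str):
        if "[Term]" in stream or "\n" in stream:
            stream = io.StringIO(stream)
        else:
            source = stream
            stream = open(stream, encoding="utf-8")
    try:
        graph = obonet.read_obo(stream, ignore_obsolete=True)
    except Exception as exc:  # unreadable / structurally broken input
        raise ValueError(f"cannot parse OBO input: {exc}") from exc

    concepts: list[Concept] = []
    n_non_hp = n_malformed = 0
    for node_id, data in graph.nodes(data=True):
        if not isinstance(node_id, str) or not node_id.startswith("HP:"):
            n_non_hp += 1
            continue
        name = data.get("name")
        if not HP_ID_PATTERN.match(node_id) or not name or not name.strip():
            n_malformed += 1
            logger.warning("skipping malformed stanza %r (missing/invalid id or name)", node_id)
            continue
        synonyms = [s for s in (map(_parse_synonym, data.get("synonym", []))) if s is not None]
        xrefs = [x for x in (map(_parse_xref, data.get("xref", []))) if x is not None]
        concepts.append(Concept(id=node_id, name=name, synonyms=synonyms, xrefs=xrefs))
    if n_non_hp:
        logger.info("skipped %d non-HP stanzas", n_non_hp)
    if n_malformed:
        logger.warning("skipped %d malformed stanzas", n_malformed)
    return Vocabulary(concepts=concepts, source=source)


def write_obo(vocab: Vocabulary, stream: IO[str] | None = None) -> str:
    """Serialize a vocabulary to OBO text (round-trips through parse_obo)."""
    out = io.StringIO()
    out.write("format-version: 1.2\nontology: hp\n")
    for c in vocab:
        out.write("\n[Term]\n")
        out.write(f"id: {c.id}\n")
        out.write(f"name: {c.name}\n")
        for syn in c.synonyms:
            out.write(f'synonym: "{syn}" EXACT []\n')
        for x in c.xrefs:
            if x.term is not None:
                out.write(f'xref: {x.source}:{x.foreign_id} "{x.term}"\n')
            else:
                out.write(f"xref: {x.source}:{x.foreign_id}\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def write_vocab_tsv(vocab: Vocabulary, stream: IO[str]) -> None:
    """Write the vocabulary as TSV: id, name, synonyms (pipe-joined), xrefs."""
    stream.write("id\tname\tsynonyms\txrefs\n")
    for c in vocab:
        xr = "|".join(
            f"{x.source}:{x.foreign_id}" + (f" {x.term}" if x.term else "") for x in c.xrefs
        )
        stream.write(f"{c.id}\t{c.name}\t{'|'.join(c.synonyms)}\t{xr}\n")


def extract_xref_terms(vocab: Vocabulary, prefix: str) -> list[QueryItem]:
    """Collect xref surface terms matching a source prefix as XREF queries.

    Each xref whose source equals ``prefix`` *and* carries a quoted surface
    term yields one query with the owning concept's id as gold label; xrefs
    that carry only a foreign identifier are skipped.
    """
    if not prefix:
        raise ValueError("prefix must be non-empty")
    items: list[QueryItem] = []
    for c in vocab:
        for x in c.xrefs:
            if x.source == prefix and x.term:
                items.append(QueryItem(term=x.term, gold_id=c.id, category=Category.XREF))
    return items


# ---------------------------------------------------------------------------
# Synthetic fixture vocabularies

#: Building blocks for pseudo-phenotype phrases.  Multi-word names make
#: token-based retrieval non-trivial: terms share tokens without being equal.
_FIXTURE_WORDS = (
    "abnormal aplasia atrophy bilateral broad cardiac cortical cystic "
    "decreased delayed dilated distal dysplasia elevated enlarged femoral "
    "fibrosis focal frontal fusion gait generalized hepatic hyperplasia "
    "hypoplasia impaired increased infantile joint lesion limb lobe "
    "malformation metacarpal muscular nasal neural nodular ocular optic "
    "osseous palmar partial pigmentation progressive proximal pulmonary "
    "recurrent reduced renal retinal rigidity sclerosis segmental severe "
    "skeletal spinal stenosis thickened tubular unilateral valve ventricular "
    "vertebral webbed"
).split()


def generate_fixture(
    n_concepts: int,
    synonyms_per_concept: tuple[int, int] = (0, 4),
    xref_rate: float = 0.0,
    seed: int = 0,
) -> Vocabulary:
    """Generate a deterministic synthetic HPO-style vocabulary.

    Concept ids are sequential (``HP:0000001`` …).  Names and synonyms are
    2–5-token pseudo-phenotype phrases, globally unique across the whole
    fixture so exact lookup is unambiguous.  A fraction ``xref_rate`` of
    concepts carry one synthetic SNOMED-style xref whose surface term is
    hyphenated (to exercise hyphen normalization).

    Deterministic: identical arguments give byte-identical vocabularies.
    """
    lo, hi = synonyms_per_concept
    if n_concepts < 1:
        raise ValueError("n_concepts must be >= 1")
    if not (0 <= lo <= hi <= 8):
        raise ValueError("synonym range must satisfy 0 <= lo <= hi <= 8")
    if not (0.0 <= xref_rate <= 1.0):
        raise ValueError("xref_rate must be a probability")

    rng = np.random.default_rng(seed)
    used: set[str] = set()

    def phrase() -> str:
        # Uniqueness is enforced on the sorted token multiset (not just the
        # string), so no two surface terms are permutations of each other
        # and exact-name lookup stays unambiguous under token retrieval.
        while True:
            k = int(rng.integers(2, 6))
            idx = rng.choice(len(_FIXTURE_WORDS), size=k, replace=False)
            words = [_FIXTURE_WORDS[int(i)] for i in idx]
            key = " ".join(sorted(words))
            if key not in used:
                used.add(key)
                p = " ".join(words)
                return p[0].upper() + p[1:]

    concepts: list[Concept] = []
    for i in range(1, n_concepts + 1):
        name = phrase()
        n_syn = int(rng.integers(lo, hi + 1))
        synonyms = [phrase() for _ in range(n_syn)]
        xrefs: list[Xref] = []
        if rng.random() < xref_rate:
            words = name.split()
            head, tail = words[0], " ".join(words[1:]) or "Structure"
            term = f"{head} - {tail[0].upper()}{tail[1:]}"
            xrefs.append(
                Xref(source="SNOMEDCT_US", foreign_id=str(int(rng.integers(10**6, 10**9))), term=term)
            )
        concepts.append(Concept(id=f"HP:{i:07d}", name=name, synonyms=synonyms, xrefs=xrefs))
    return Vocabulary(concepts=concepts, source=f"fixture:seed={seed}")


def load_term_tsv(stream: IO[str] | str, category: Category = Category.LAYMEN) -> list[QueryItem]:
    """Load a two-column TSV of (term, gold HP id) as query items.

    Used both for sideloaded SNOMED-CT synonym lists and for laymen's-term
    files.  A header line ``term\\tgold_id`` is permitted and skipped.
    """
    if isinstance(stream, str):
        stream = open(stream, encoding="utf-8")
    items: list[QueryItem] = []
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.lower().startswith("term\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            logger.warning("skipping malformed term line: %r", line)
            continue
        term, gold = parts[0].strip(), parts[1].strip()
        if not HP_ID_PATTERN.match(gold):
            logger.warning("skipping term with invalid gold id: %r", line)
            continue
        items.append(QueryItem(term=term, gold_id=gold, category=category))
    return items


def iter_surface_terms(vocab: Vocabulary) -> Iterable[tuple[str, str]]:
    """Yield every (surface term, concept id) pair: names then synonyms."""
    for c in vocab:
        for term in c.surface_terms:
            yield term, c.id
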