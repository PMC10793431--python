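"""Fine-tuning corpus generation from a vocabulary.

Every training sentence instantiates one fixed template pairing a surface
term with its concept identifier::

    The Human Phenotype Ontology term {term} is identified by the HPO ID {id}

Three corpus variants exist:

* ``NAME`` — one sentence per concept using the preferred name only; all
  synonyms are held out.
* ``NAME_SYN`` — the NAME sentences plus, per concept, a seeded uniform
  sample of ⌊n_syn/2⌋ synonyms; the remaining ⌈n_syn/2⌉ synonyms are held
  out for generalization testing.
* ``NAME_SYN_TYPO`` — a typo-augmented copy of an existing corpus, with each
  term replaced by a single-character keyboard-proximity typo.

Sentences are rendered without a trailing period so the identifier is the
final token span of each sentence — the completion target during
autoregressive fine-tuning.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from typing import IO

import numpy as np

from . import perturb
from .ontology import HP_ID_PATTERN, Vocabulary

TEMPLATE_PREFIX = "The Human Phenotype Ontology term "
TEMPLATE_INFIX = " is identified by the HPO ID "

_SENTENCE_RE = re.compile(
    re.escape(TEMPLATE_PREFIX) + r"(?P<term>.+)" + re.escape(TEMPLATE_INFIX) + r"(?P<id>HP:[0-9]{7})$"
)


class Origin(str, enum.Enum):
    NAME = "NAME"
    SYNONYM = "SYNONYM"
    TYPO = "TYPO"


class Variant(str, enum.Enum):
    NAME = "NAME"
    NAME_SYN = "NAME_SYN"
    NAME_SYN_TYPO = "NAME_SYN_TYPO"


@dataclass(frozen=True)
class TrainingSentence:
    text: str
    term: str
    concept_id: str
    origin: Origin


@dataclass
class Corpus:
    sentences: list[TrainingSentence]
    variant: Variant
    held_out: list[tuple[str, str]] = field(default_factory=list)  # (synonym, concept_id)
    seed: int | None = None


def render_sentence(term: str, concept_id: str, origin: Origin = Origin.NAME) -> TrainingSentence:
    """Render the training template for one (term, id) pair."""
    if not term or not term.strip():
        raise ValueError("term must be non-empty")
    if not HP_ID_PATTERN.match(concept_id):
        raise ValueError(f"concept id {concept_id!r} does not match HP:NNNNNNN")
    text = f"{TEMPLATE_PREFIX}{term}{TEMPLATE_INFIX}{concept_id}"
    return TrainingSentence(text=text, term=term, concept_id=concept_id, origin=origin)


def parse_sentence(text: str) -> tuple[str, str]:
    """Invert :func:`render_sentence`: recover (term, concept_id) exactly."""
    m = _SENTENCE_RE.match(text)
    if not m:
        raise ValueError(f"not a template sentence: {text!r}")
    return m.group("term"), m.group("id")


def build_name_corpus(vocab: Vocabulary) -> Corpus:
    """One sentence per concept from its preferred name; synonyms held out."""
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty")
    sentences = [render_sentence(c.name, c.id, Origin.NAME) for c in vocab]
    held_out = [(syn, c.id) for c in vocab for syn in c.synonyms]
    return Corpus(sentences=sentences, variant=Variant.NAME, held_out=held_out)


def build_name_syn_corpus(vocab: Vocabulary, seed: int = 0) -> Corpus:
    """Names plus a seeded random half of each concept's synonyms.

    Per concept with n synonyms, ⌊n/2⌋ are sampled uniformly (without
    replacement) into the training corpus and the other ⌈n/2⌉ are recorded
    in ``held_out``.  Selection is seeded rather than positional to avoid
    ordering bias from the source file.
    """
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty")
    rng = np.random.default_rng(seed)
    sentences: list[TrainingSentence] = []
    held_out: list[tuple[str, str]] = []
    for c in vocab:
        sentences.append(render_sentence(c.name, c.id, Origin.NAME))
        n = len(c.synonyms)
        n_train = n // 2
        train_idx = set(int(i) for i in rng.choice(n, size=n_train, replace=False)) if n_train else set()
        for i, syn in enumerate(c.synonyms):
            if i in train_idx:
                sentences.append(render_sentence(syn, c.id, Origin.SYNONYM))
            else:
                held_out.append((syn, c.id))
    return Corpus(sentences=sentences, variant=Variant.NAME_SYN, held_out=held_out, seed=seed)


def build_typo_corpus(corpus: Corpus, seed: int = 0) -> Corpus:
    """Replace each sentence's term with a single-character keyboard typo.

    Emits one TYPO sentence per input sentence (same concept id).  The typo
    corpus is produced separately from the clean corpus so a training
    schedule can concatenate or substitute it for the extra typo-training
    epochs.
    """
    if corpus.variant not in (Variant.NAME, Variant.NAME_SYN):
        raise ValueError("typo augmentation applies to NAME or NAME_SYN corpora")
    rng = np.random.default_rng(seed)
    sentences = [
        render_sentence(perturb.simple_typo(s.term, seed=rng), s.concept_id, Origin.TYPO)
        for s in corpus.sentences
    ]
    return Corpus(sentences=sentences, variant=Variant.NAME_SYN_TYPO, held_out=list(corpus.held_out), seed=seed)


# ---------------------------------------------------------------------------
# Serialization

def write_jsonl(corpus: Corpus, stream: IO[str]) -> None:
    for s in corpus.sentences:
        stream.write(
            json.dumps(
                {"text": s.text, "term": s.term, "concept_id": s.concept_id, "origin": s.origin.value}
            )
            + "\n"
        )


def read_jsonl(stream: IO[str], variant: Variant = Variant.NAME_SYN) -> Corpus:
    sentences = []
    for line in stream:
        if not line.strip():
            continue
        d = json.loads(line)
        sentences.append(
            TrainingSentence(
                text=d["text"], term=d["term"], concept_id=d["concept_id"], origin=Origin(d["origin"])
            )
        )
    return Corpus(sentences=sentences, variant=variant)


def write_text(corpus: Corpus, stream: IO[str]) -> None:
    """Plain-text rendering: one sentence per line."""
    for s in corpus.sentences:
        stream.write(s.text + "\n")


def write_held_out_tsv(corpus: Corpus, stream: IO[str]) -> None:
    stream.write("term\tgold_id\n")
    for term, cid in corpus.held_out:
        stream.write(f"{term}\t{cid}\n")


def read_held_out_tsv(stream: IO[str]) -> list[tuple[str, str]]:
    pairs = []
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.lower().startswith("term\t"):
            continue
        term, cid = line.split("\t")[:2]
        pairs.append((term, cid))
    return pairs
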