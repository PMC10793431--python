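"""Adapter between corpora and autoregressive completion models.

A completion model is anything that continues a text prompt; normalization
works by prompting with the training template truncated right after
``"HPO ID "`` and parsing the first HPO identifier out of the greedy
continuation.  The adapter is model-agnostic: the same machinery wraps the
in-repo character-level model, a memorizing stub in tests, or an external
fine-tuned LLM behind the :class:`CompletionModel` contract.

The fine-tuning configuration mirrors the full-scale recipe — LoRA rank 32,
batch size 128, 100 epochs, plus 30 extra epochs for typo-augmented
training — as declarative configuration.  Desk-scale models consume the
epoch/batch/seed fields and ignore the LoRA fields, which only apply to
transformer fine-tuning.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import IO, Protocol, Sequence, runtime_checkable

from .corpus import TEMPLATE_INFIX, TEMPLATE_PREFIX, Corpus

_HP_ID_SEARCH = re.compile(r"[Hh][Pp]:([0-9]{7})")

#: Evaluation prompt: the training sentence truncated after "HPO ID ".
DEFAULT_PROMPT_TEMPLATE = TEMPLATE_PREFIX + "{term}" + TEMPLATE_INFIX
#: A structurally different prompt used to probe prompt brittleness.
ALTERNATE_PROMPT_TEMPLATE = "HPO ID of {term} is "


@dataclass(frozen=True)
class TrainingRecord:
    """A prompt/completion pair; prompt + completion reconstructs the text."""

    prompt: str
    completion: str

    @property
    def text(self) -> str:
        return self.prompt + self.completion


@dataclass
class FinetuneConfig:
    """Hyperparameters of the fine-tuning recipe.

    ``lora_rank`` and ``base_model`` describe the full-scale transformer
    path and are inert for desk-scale models; ``epochs``, ``batch_size``
    and ``seed`` drive any trainable model.
    """

    epochs: int = 100
    typo_extra_epochs: int = 30
    lora_rank: int = 32
    batch_size: int = 128
    seed: int = 0
    base_model: str = "llama2-7b"

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.lora_rank < 1 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0; lora_rank and batch_size >= 1")


@runtime_checkable
class CompletionModel(Protocol):
    def complete(self, prompt: str, max_new_chars: int = 16) -> str: ...


@runtime_checkable
class TrainableCompletionModel(CompletionModel, Protocol):
    def fit(self, records: Sequence[TrainingRecord], config: FinetuneConfig) -> list[float]: ...


def make_records(corpus: Corpus) -> list[TrainingRecord]:
    """Split each sentence into (prompt, completion) right after "HPO ID ".

    Lossless: re-joining every record reproduces the corpus sentences
    byte-for-byte.  A sentence that does not follow the template is a fatal
    error, reported with the offending line.
    """
    records: list[TrainingRecord] = []
    for s in corpus.sentences:
        head, sep, completion = s.text.rpartition(TEMPLATE_INFIX)
        if not sep or not re.fullmatch(r"HP:[0-9]{7}", completion):
            raise ValueError(f"sentence does not follow the template: {s.text!r}")
        records.append(TrainingRecord(prompt=head + sep, completion=completion))
    return records


def extract_hpo_id(completion: str) -> str | None:
    """First HP:NNNNNNN substring of a generated continuation, or None.

    Case-insensitive on the ``HP`` prefix and normalized to upper case, so
    hallucinated but well-formed identifiers are still extracted (and then
    scored as incorrect), while free text with no identifier yields None.
    """
    m = _HP_ID_SEARCH.search(completion)
    return f"HP:{m.group(1)}" if m else None


def completion_normalizer(
    model: CompletionModel,
    prompt_template: str = DEFAULT_PROMPT_TEMPLATE,
    max_new_chars: int = 16,
):
    """Wrap a completion model as a term → concept-id normalizer.

    The template must contain exactly one ``{term}`` placeholder.  The
    continuation is capped at ``max_new_chars`` characters — an HPO
    identifier plus slack — and parsed with :func:`extract_hpo_id`.
    """
    if prompt_template.count("{term}") != 1:
        raise ValueError("prompt_template must contain exactly one {term} placeholder")

    def normalizer(term: str) -> str | None:
        prompt = prompt_template.format(term=term)
        return extract_hpo_id(model.complete(prompt, max_new_chars=max_new_chars))

    normalizer.name = f"completion[{prompt_template!r}]"  # type: ignore[attr-defined]
    normalizer.prompt_template = prompt_template  # type: ignore[attr-defined]
    return normalizer


def finetune(
    model: CompletionModel,
    records: Sequence[TrainingRecord],
    config: FinetuneConfig,
) -> tuple[CompletionModel, list[float]]:
    """Train a trainable completion model; returns (model, per-epoch loss).

    The loss trace is the per-epoch mean negative log-likelihood of the next
    character/token.  With ``epochs=0`` the model is returned unchanged with
    an empty trace.  Models without a ``fit`` method are rejected.
    """
    if not isinstance(model, TrainableCompletionModel):
        raise TypeError(f"{type(model).__name__} does not implement the trainable contract")
    if config.epochs == 0:
        return model, []
    trace = model.fit(records, config)
    return model, trace


# ---------------------------------------------------------------------------
# Record serialization

def write_records_jsonl(records: Sequence[TrainingRecord], stream: IO[str]) -> None:
    for r in records:
        stream.write(json.dumps({"prompt": r.prompt, "completion": r.completion}) + "\n")


def read_records_jsonl(stream: IO[str]) -> list[TrainingRecord]:
    out = []
    for line in stream:
        if line.strip():
            d = json.loads(line)
            out.append(TrainingRecord(prompt=d["prompt"], completion=d["completion"]))
    return out
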