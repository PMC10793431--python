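"""Evaluation query items and their categories.

A :class:`QueryItem` is one term to normalize together with its gold HPO
identifier and the category it belongs to in the six-way evaluation design
(training names, held-out synonyms, simple/complex typos, cross-referenced
SNOMED-CT terms, laymen's terms).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class Category(str, enum.Enum):
    """The six evaluation query categories."""

    TRAIN_NAME = "TRAIN_NAME"
    HELD_OUT_SYNONYM = "HELD_OUT_SYNONYM"
    SIMPLE_TYPO = "SIMPLE_TYPO"
    COMPLEX_TYPO = "COMPLEX_TYPO"
    XREF = "XREF"
    LAYMEN = "LAYMEN"


@dataclass(frozen=True)
class QueryItem:
    """One evaluation query.

    Parameters
    ----------
    term:
        The query string presented to a normalizer.
    gold_id:
        The HPO identifier the normalizer should return.
    category:
        Which evaluation category the query belongs to.
    source_term:
        For typo categories, the unperturbed name the typo was derived
        from; ``None`` otherwise.
    """

    term: str
    gold_id: str
    category: Category
    source_term: str | None = None

    def __post_init__(self) -> None:
        if not self.term:
            raise ValueError("query term must be non-empty")
        if self.category in (Category.SIMPLE_TYPO, Category.COMPLEX_TYPO):
            if self.source_term is None:
                raise ValueError("typo queries require a source_term")
            if self.term == self.source_term:
                raise ValueError("typo query term must differ from its source")
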