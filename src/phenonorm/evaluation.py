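"""Build evaluation query sets, score normalizers, and render reports.

The evaluation design probes a normalizer with six query categories of
increasing difficulty: the exact training names, synonyms deliberately held
out of the fine-tuning corpus, single-character keyboard typos, multi-
character complex typos, terms cross-referenced from SNOMED-CT, and
colloquial laymen's terms.  Accuracy in a category is the fraction of
queries whose predicted identifier equals the gold identifier exactly; a
missing prediction counts as incorrect.

Any callable ``term -> concept_id-or-None`` is a normalizer, so the BM25
baseline and completion-model adapters are scored through identical code
paths.  Per-query outcomes are retained for error analysis, including the
digit-suffix near-miss diagnostic: wrong but well-formed predictions are
annotated with how many trailing digits differ from the gold identifier
(fine-tuned models' errors cluster at 1–2 trailing digits because
hierarchically close concepts share identifier prefixes).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Callable, Sequence

import numpy as np

from . import perturb
from .ontology import Vocabulary
from .queries import Category, QueryItem

Normalizer = Callable[[str], "str | None"]


@dataclass(frozen=True)
class QueryOutcome:
    query: QueryItem
    predicted: str | None
    correct: bool
    #: For wrong well-formed predictions: number of trailing digits of the
    #: 7-digit identifier that differ from gold (1 = off by last digit);
    #: None when prediction is missing, correct, or not comparable.
    digit_suffix_mismatch: int | None


@dataclass(frozen=True)
class ReportRow:
    normalizer: str
    category: Category
    n_total: int
    n_correct: int
    n_no_prediction: int
    metadata: dict = field(default_factory=dict, hash=False, compare=False)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total if self.n_total else 0.0


@dataclass
class EvaluationReport:
    rows: list[ReportRow]
    outcomes: list[QueryOutcome] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def row(self, normalizer: str, category: Category) -> ReportRow:
        for r in self.rows:
            if r.normalizer == normalizer and r.category == category:
                return r
        raise KeyError((normalizer, category))

    def accuracy(self, normalizer: str, category: Category) -> float:
        return self.row(normalizer, category).accuracy


def digit_suffix_mismatch(predicted: str, gold: str) -> int | None:
    """Length of the differing digit suffix between two HP identifiers.

    Returns the smallest k such that the first 7−k digits agree (so an
    error confined to the final digit gives 1); None if either identifier
    is not of the HP:NNNNNNN form.
    """
    if len(predicted) != 10 or len(gold) != 10 or predicted[:3] != "HP:" or gold[:3] != "HP:":
        return None
    pd, gd = predicted[3:], gold[3:]
    if not (pd.isdigit() and gd.isdigit()):
        return None
    prefix = 0
    while prefix < 7 and pd[prefix] == gd[prefix]:
        prefix += 1
    return 7 - prefix


def build_query_sets(
    vocab: Vocabulary,
    held_out: Sequence[tuple[str, str]] = (),
    xrefs: Sequence[QueryItem] = (),
    laymen: Sequence[QueryItem] = (),
    layout: perturb.KeyboardLayout = perturb.QWERTY,
    seed: int = 0,
) -> list[QueryItem]:
    """Assemble the six evaluation categories for a vocabulary.

    TRAIN_NAME uses every preferred name; SIMPLE_TYPO and COMPLEX_TYPO are
    seeded perturbations of the preferred names (typos are generated from
    standard names, not synonyms); HELD_OUT_SYNONYM comes from the corpus
    builder's hold-out; XREF and LAYMEN are passed in pre-built.  Laymen
    rows whose gold id is not in the vocabulary are dropped with a count in
    the report metadata consumer's log.
    """
    rng = np.random.default_rng(seed)
    queries: list[QueryItem] = []
    for c in vocab:
        queries.append(QueryItem(term=c.name, gold_id=c.id, category=Category.TRAIN_NAME))
    for term, cid in held_out:
        queries.append(QueryItem(term=term, gold_id=cid, category=Category.HELD_OUT_SYNONYM))
    for c in vocab:
        typo = perturb.simple_typo(c.name, layout, seed=rng)
        queries.append(
            QueryItem(term=typo, gold_id=c.id, category=Category.SIMPLE_TYPO, source_term=c.name)
        )
    for c in vocab:
        typo = perturb.complex_typo(c.name, layout, seed=rng)
        queries.append(
            QueryItem(term=typo, gold_id=c.id, category=Category.COMPLEX_TYPO, source_term=c.name)
        )
    queries.extend(xrefs)
    for q in laymen:
        if q.gold_id in vocab:
            queries.append(q)
    return queries


def evaluate(
    normalizer: Normalizer,
    queries: Sequence[QueryItem],
    name: str | None = None,
    term_preprocessor: Callable[[str], str] | None = None,
) -> EvaluationReport:
    """Score one normalizer on a query set, per category.

    A normalizer exception on a query is recorded as a missing prediction
    and the run continues.  ``term_preprocessor`` optionally transforms each
    query term before normalization (e.g. :func:`phenonorm.perturb.strip_hyphens`).
    """
    norm_name = name or getattr(normalizer, "name", type(normalizer).__name__)
    outcomes: list[QueryOutcome] = []
    for q in queries:
        term = term_preprocessor(q.term) if term_preprocessor else q.term
        try:
            predicted = normalizer(term)
        except Exception:
            predicted = None
        correct = predicted == q.gold_id
        mismatch = None
        if predicted is not None and not correct:
            mismatch = digit_suffix_mismatch(predicted, q.gold_id)
        outcomes.append(QueryOutcome(query=q, predicted=predicted, correct=correct, digit_suffix_mismatch=mismatch))

    rows: list[ReportRow] = []
    for cat in Category:
        cat_outcomes = [o for o in outcomes if o.query.category == cat]
        if not cat_outcomes:
            continue
        rows.append(
            ReportRow(
                normalizer=norm_name,
                category=cat,
                n_total=len(cat_outcomes),
                n_correct=sum(o.correct for o in cat_outcomes),
                n_no_prediction=sum(o.predicted is None for o in cat_outcomes),
            )
        )
    return EvaluationReport(rows=rows, outcomes=outcomes, metadata={"normalizer": norm_name})


def merge_reports(reports: Sequence[EvaluationReport]) -> EvaluationReport:
    """Concatenate rows/outcomes of several per-normalizer reports."""
    merged = EvaluationReport(rows=[], outcomes=[], metadata={})
    for r in reports:
        merged.rows.extend(r.rows)
        merged.outcomes.extend(r.outcomes)
    return merged


def prompt_robustness(
    model,
    templates: Sequence[str],
    queries: Sequence[QueryItem],
) -> EvaluationReport:
    """Evaluate a completion model under several prompt templates.

    One set of report rows per template; each row carries its template
    verbatim in metadata.  Templates are meaningless for index-based
    normalizers, so this takes a completion model, not a generic normalizer.
    """
    from .llm import completion_normalizer

    reports = []
    for tpl in templates:
        norm = completion_normalizer(model, prompt_template=tpl)
        rep = evaluate(norm, queries, name=f"completion[{tpl}]")
        rep.rows = [
            ReportRow(
                normalizer=r.normalizer,
                category=r.category,
                n_total=r.n_total,
                n_correct=r.n_correct,
                n_no_prediction=r.n_no_prediction,
                metadata={"template": tpl},
            )
            for r in rep.rows
        ]
        reports.append(rep)
    return merge_reports(reports)


def write_report(report: EvaluationReport, fmt: str = "tsv", stream: IO[str] | None = None) -> str:
    """Render the per-category accuracy table as TSV or aligned text.

    Percentages are printed to one decimal place ("45.0%").
    """
    out = io.StringIO()
    if fmt == "tsv":
        out.write("normalizer\tcategory\tn_total\tn_correct\tn_no_prediction\taccuracy\n")
        for r in report.rows:
            out.write(
                f"{r.normalizer}\t{r.category.value}\t{r.n_total}\t{r.n_correct}\t"
                f"{r.n_no_prediction}\t{100.0 * r.accuracy:.1f}%\n"
            )
    elif fmt == "text":
        header = f"{'normalizer':<28} {'category':<18} {'n':>6} {'accuracy':>9}"
        out.write(header + "\n" + "-" * len(header) + "\n")
        for r in report.rows:
            out.write(
                f"{r.normalizer:<28} {r.category.value:<18} {r.n_total:>6} {100.0 * r.accuracy:>8.1f}%\n"
            )
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def read_report_tsv(stream: IO[str]) -> list[ReportRow]:
    """Parse a TSV report back into rows (accuracy recomputed from counts)."""
    rows = []
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("normalizer\t"):
            continue
        norm, cat, n_total, n_correct, n_nopred, _acc = line.split("\t")
        rows.append(
            ReportRow(
                normalizer=norm,
                category=Category(cat),
                n_total=int(n_total),
                n_correct=int(n_correct),
                n_no_prediction=int(n_nopred),
            )
        )
    return rows


def gold_oracle(queries: Sequence[QueryItem]) -> Normalizer:
    """Upper-bound normalizer: returns the gold id for every known term."""
    table = {q.term: q.gold_id for q in queries}

    def oracle(term: str) -> str | None:
        return table.get(term)

    oracle.name = "gold-oracle"  # type: ignore[attr-defined]
    return oracle


def constant_none(term: str) -> None:
    """Lower-bound normalizer: never predicts."""
    return None


constant_none.name = "constant-none"  # type: ignore[attr-defined]
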