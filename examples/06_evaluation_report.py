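"""Score normalizers over the six query categories and print the report.

Categories: exact training names, held-out synonyms, simple typos, complex
typos, SNOMED-CT cross-referenced terms, laymen's terms (from a sideloaded
TSV when available).  Any callable term -> id-or-None is scored through the
same harness, so BM25 modes and completion models are directly comparable.
"""

from phenonorm import RetrievalMode, build_index, build_query_sets, evaluate, generate_fixture, write_report
from phenonorm.bm25 import BM25Normalizer
from phenonorm.corpus import build_name_syn_corpus
from phenonorm.evaluation import merge_reports
from phenonorm.ontology import extract_xref_terms

vocab = generate_fixture(200, (0, 4), xref_rate=0.3, seed=5)
corpus = build_name_syn_corpus(vocab, seed=6)
xrefs = extract_xref_terms(vocab, "SNOMEDCT_US")
queries = build_query_sets(vocab, corpus.held_out, xrefs, seed=7)
print(f"{len(queries)} queries across categories")

index = build_index(vocab)
reports = [
    evaluate(BM25Normalizer(index, mode), queries) for mode in RetrievalMode
]
print(write_report(merge_reports(reports), "text"))
# The OR >> AND gap on the typo categories is the baseline's signature:
# conjunctive retrieval fails as soon as any single token is mistyped.
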