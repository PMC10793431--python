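"""Fine-tune the desk-scale character model and probe prompt brittleness.

A ~0.3M-parameter character-level MLP memorizes a 20-concept NAME corpus in
100 epochs (seconds on one CPU), then normalizes the training names under
greedy decoding.  Swapping in a prompt template the model never saw makes
accuracy collapse — the same brittleness a fine-tuned LLM shows when the
evaluation sentence structure departs from the training template.

Takes ~20 s.
"""

from phenonorm import (
    ALTERNATE_PROMPT_TEMPLATE,
    FinetuneConfig,
    TinyCharLM,
    completion_normalizer,
    evaluate,
    finetune,
    generate_fixture,
    make_records,
)
from phenonorm.corpus import build_name_corpus
from phenonorm.queries import Category, QueryItem

vocab = generate_fixture(20, (0, 0), 0.0, seed=7)
records = make_records(build_name_corpus(vocab))
print("training record example:")
print("  prompt:    ", records[0].prompt)
print("  completion:", records[0].completion)

model = TinyCharLM(seed=0)
print(f"model parameters: {model.n_params:,}")
model, trace = finetune(model, records, FinetuneConfig(epochs=100, batch_size=128, seed=0))
print(f"mean NLL/char: epoch 1 = {trace[0]:.3f}, epoch 100 = {trace[-1]:.4f}")

queries = [QueryItem(c.name, c.id, Category.TRAIN_NAME) for c in vocab]
rep = evaluate(completion_normalizer(model), queries, name="tiny-default-prompt")
rep_alt = evaluate(completion_normalizer(model, ALTERNATE_PROMPT_TEMPLATE), queries, name="tiny-alt-prompt")
print(f"training-template accuracy: {100 * rep.rows[0].accuracy:.1f}%")
print(f"alternate-prompt accuracy:  {100 * rep_alt.rows[0].accuracy:.1f}%")
# Near-perfect recall on the memorized template vs collapse on the unseen
# prompt structure: the model learned the sentence, not the mapping.
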