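"""A minimal character-level autoregressive model for desk-scale training.

``TinyCharLM`` is a one-hidden-layer MLP over a fixed-width character
context window: embed the last ``context`` characters, flatten, tanh hidden
layer, softmax over the character set.  Trained with Adam on next-character
prediction, it can memorize a small template corpus (tens of sentences) in
a few hundred optimizer steps and then reproduce the concept identifiers
under greedy decoding.

It exists to exercise the full train → memorize → evaluate loop of the
normalization pipeline on one CPU in seconds.  It makes no claim of
generalizing to unseen synonyms the way a fine-tuned billion-parameter
transformer does; its scientific role is the loop, including the
prompt-brittleness effect (near-perfect recall on the training template,
degradation on a structurally different prompt).
"""

from __future__ import annotations

import json
from typing import IO, Sequence

import numpy as np

from .llm import FinetuneConfig, TrainingRecord

#: Characters the model can represent; anything else maps to the last slot.
DEFAULT_CHARSET = (
    " abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789:.,-'()/?"
)
_PAD = 0  # index of the padding character (space doubles as pad)


class TinyCharLM:
    """Character-level MLP language model with a fixed context window.

    Parameters
    ----------
    context:
        Width of the character window conditioning each prediction.  Must be
        large enough that the distinguishing part of the term is still in
        view while the identifier digits are generated (the template suffix
        plus identifier spans ~40 characters).
    embed_dim, hidden_dim:
        Embedding and hidden sizes; defaults give ~0.3M parameters.
    seed:
        Initialization seed (training order is seeded separately through
        the fine-tuning configuration).
    """

    def __init__(
        self,
        context: int = 80,
        embed_dim: int = 16,
        hidden_dim: int = 192,
        seed: int = 0,
        charset: str = DEFAULT_CHARSET,
    ):
        self.context = context
        self.charset = charset
        self.vocab_size = len(charset) + 1  # + unknown slot
        self._unk = self.vocab_size - 1
        self._char_to_idx = {c: i for i, c in enumerate(charset)}
        rng = np.random.default_rng(seed)
        v, e, h = self.vocab_size, embed_dim, hidden_dim
        self.emb = rng.normal(0, 0.1, (v, e))
        self.w1 = rng.normal(0, np.sqrt(1.0 / (context * e)), (context * e, h))
        self.b1 = np.zeros(h)
        self.w2 = rng.normal(0, np.sqrt(1.0 / h), (h, v))
        self.b2 = np.zeros(v)

    # -- encoding ---------------------------------------------------------
    def encode(self, text: str) -> np.ndarray:
        return np.array([self._char_to_idx.get(c, self._unk) for c in text], dtype=np.int64)

    @property
    def n_params(self) -> int:
        return sum(a.size for a in (self.emb, self.w1, self.b1, self.w2, self.b2))

    # -- forward ----------------------------------------------------------
    def _forward(self, ctx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x = self.emb[ctx].reshape(ctx.shape[0], -1)
        h = np.tanh(x @ self.w1 + self.b1)
        logits = h @ self.w2 + self.b2
        return x, h, logits

    @staticmethod
    def _log_softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        return z - np.log(np.exp(z).sum(axis=1, keepdims=True))

    # -- training ---------------------------------------------------------
    def _dataset(self, records: Sequence[TrainingRecord]) -> tuple[np.ndarray, np.ndarray]:
        ctxs, targets = [], []
        for r in records:
            ids = self.encode(r.text)
            padded = np.concatenate([np.full(self.context, _PAD, dtype=np.int64), ids])
            for t in range(len(ids)):
                ctxs.append(padded[t : t + self.context])
                targets.append(ids[t])
        return np.stack(ctxs), np.array(targets, dtype=np.int64)

    def fit(self, records: Sequence[TrainingRecord], config: FinetuneConfig) -> list[float]:
        """Adam training on next-character prediction; per-epoch mean NLL."""
        if not records:
            return []
        ctxs, targets = self._dataset(records)
        n = len(targets)
        rng = np.random.default_rng(config.seed)
        lr, beta1, beta2, eps = 3e-3, 0.9, 0.999, 1e-8
        params = [self.emb, self.w1, self.b1, self.w2, self.b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        step = 0
        trace: list[float] = []
        batch = min(config.batch_size, n)
        for _epoch in range(config.epochs):
            order = rng.permutation(n)
            epoch_nll = 0.0
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                ctx_b, tgt_b = ctxs[idx], targets[idx]
                x, h, logits = self._forward(ctx_b)
                logp = self._log_softmax(logits)
                epoch_nll += -logp[np.arange(len(idx)), tgt_b].sum()
                # backward
                probs = np.exp(logp)
                dlogits = probs
                dlogits[np.arange(len(idx)), tgt_b] -= 1.0
                dlogits /= len(idx)
                dw2 = h.T @ dlogits
                db2 = dlogits.sum(axis=0)
                dh = dlogits @ self.w2.T
                dpre = dh * (1.0 - h * h)
                dw1 = x.T @ dpre
                db1 = dpre.sum(axis=0)
                dx = (dpre @ self.w1.T).reshape(len(idx), self.context, -1)
                demb = np.zeros_like(self.emb)
                np.add.at(demb, ctx_b, dx)
                grads = [demb, dw1, db1, dw2, db2]
                step += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    mhat = mi / (1 - beta1**step)
                    vhat = vi / (1 - beta2**step)
                    p -= lr * mhat / (np.sqrt(vhat) + eps)
            trace.append(epoch_nll / n)
        return trace

    # -- generation -------------------------------------------------------
    def complete(self, prompt: str, max_new_chars: int = 16) -> str:
        """Greedy continuation of a prompt (deterministic)."""
        ids = self.encode(prompt)
        window = np.full(self.context, _PAD, dtype=np.int64)
        k = min(len(ids), self.context)
        if k:
            window[-k:] = ids[-k:]
        out: list[str] = []
        for _ in range(max_new_chars):
            _, _, logits = self._forward(window[None, :])
            nxt = int(np.argmax(logits[0]))
            out.append(self.charset[nxt] if nxt < len(self.charset) else "?")
            window = np.roll(window, -1)
            window[-1] = nxt
        return "".join(out)

    # -- persistence ------------------------------------------------------
    def save(self, stream: IO[str]) -> None:
        json.dump(
            {
                "context": self.context,
                "charset": self.charset,
                "weights": {
                    k: getattr(self, k).tolist() for k in ("emb", "w1", "b1", "w2", "b2")
                },
            },
            stream,
        )

    @classmethod
    def load(cls, stream: IO[str]) -> "TinyCharLM":
        d = json.load(stream)
        emb = np.array(d["weights"]["emb"])
        w1 = np.array(d["weights"]["w1"])
        model = cls(
            context=d["context"],
            embed_dim=emb.shape[1],
            hidden_dim=w1.shape[1],
            charset=d["charset"],
        )
        for k in ("emb", "w1", "b1", "w2", "b2"):
            setattr(model, k, np.array(d["weights"][k]))
        return model
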