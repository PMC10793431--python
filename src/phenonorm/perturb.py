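"""Term perturbations: keyboard-proximity typos and hyphen stripping.

Typos emulate realistic misspellings by substituting letters with physically
neighboring keys on a QWERTY keyboard.  A *simple* typo alters exactly one
letter; a *complex* typo alters 20% of the letters, at least one and at most
three.  Only letters are perturbed — spaces, digits and punctuation are left
untouched — and the replacement preserves the case of the original letter.

The adjacency table includes diagonal neighbors induced by the physical
half-key row stagger of a QWERTY keyboard, so e.g. 'i' neighbors
{'u','o','j','k'} and 'm' neighbors {'n','j','k'}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_ROWS = ("qwertyuiop", "asdfghjkl", "zxcvbnm")


def _build_qwerty_adjacency() -> dict[str, frozenset[str]]:
    adj: dict[str, set[str]] = {c: set() for row in _ROWS for c in row}

    def link(a: str, b: str) -> None:
        adj[a].add(b)
        adj[b].add(a)

    for row in _ROWS:
        for i in range(len(row) - 1):
            link(row[i], row[i + 1])
    # Row stagger: top-row key i sits between home-row keys i-1 and i;
    # bottom-row key i sits between home-row keys i and i+1.
    top, home, bottom = _ROWS
    for i, c in enumerate(top):
        for j in (i - 1, i):
            if 0 <= j < len(home):
                link(c, home[j])
    for i, c in enumerate(bottom):
        for j in (i, i + 1):
            if 0 <= j < len(home):
                link(c, home[j])
    return {c: frozenset(n) for c, n in adj.items()}


@dataclass(frozen=True)
class KeyboardLayout:
    """Letter adjacency on a physical keyboard (lowercase only)."""

    adjacency: dict[str, frozenset[str]] = field(default_factory=_build_qwerty_adjacency)

    def neighbors(self, char: str) -> frozenset[str]:
        return self.adjacency.get(char.lower(), frozenset())


#: The shipped QWERTY layout with diagonal neighbors.
QWERTY = KeyboardLayout()


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _letter_positions(term: str, layout: KeyboardLayout) -> list[int]:
    return [i for i, ch in enumerate(term) if ch.isalpha() and layout.neighbors(ch)]


def _substitute(term: str, pos: int, layout: KeyboardLayout, rng: np.random.Generator) -> str:
    original = term[pos]
    candidates = sorted(layout.neighbors(original))
    replacement = candidates[int(rng.integers(len(candidates)))]
    if original.isupper():
        replacement = replacement.upper()
    return term[:pos] + replacement + term[pos + 1 :]


def simple_typo(
    term: str,
    layout: KeyboardLayout = QWERTY,
    seed: int | np.random.Generator | None = None,
) -> str:
    """Alter exactly one letter of ``term`` to a keyboard-adjacent letter.

    The output has the same length as the input and character-level Hamming
    distance exactly 1; the altered position is chosen uniformly among the
    letter positions and the replacement uniformly among the original
    letter's neighbors.  Deterministic for a fixed integer seed.
    """
    rng = _as_rng(seed)
    positions = _letter_positions(term, layout)
    if not positions:
        raise ValueError(f"term {term!r} contains no perturbable letters")
    pos = positions[int(rng.integers(len(positions)))]
    return _substitute(term, pos, layout, rng)


def complex_typo(
    term: str,
    layout: KeyboardLayout = QWERTY,
    seed: int | np.random.Generator | None = None,
) -> str:
    """Alter 20% of the letters of ``term`` (at least 1, at most 3).

    The number of altered positions is ``k = min(3, max(1, round(0.2 * L)))``
    where ``L`` counts letter characters and ``round`` is half-up.  Positions
    are sampled without replacement, so the Hamming distance from the source
    equals ``k`` exactly.
    """
    rng = _as_rng(seed)
    positions = _letter_positions(term, layout)
    if not positions:
        raise ValueError(f"term {term!r} contains no perturbable letters")
    k = n_complex_alterations(len(positions))
    chosen = rng.choice(len(positions), size=min(k, len(positions)), replace=False)
    out = term
    for idx in sorted(int(i) for i in chosen):
        out = _substitute(out, positions[idx], layout, rng)
    return out


def n_complex_alterations(n_letters: int) -> int:
    """The complex-typo alteration count: min(3, max(1, round-half-up(0.2·L)))."""
    rounded = int(np.floor(0.2 * n_letters + 0.5))
    return min(3, max(1, rounded))


def strip_hyphens(term: str) -> str:
    """Replace hyphens with spaces and collapse whitespace; idempotent.

    ``"Kidney - Abnormal"`` becomes ``"Kidney Abnormal"``.  Stripping hyphens
    from query terms measurably helps normalizers trained or indexed on
    largely hyphen-free vocabulary entries.
    """
    return " ".join(term.replace("-", " ").split())


def hamming(a: str, b: str) -> int:
    """Character-level Hamming distance (strings must have equal length)."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))
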