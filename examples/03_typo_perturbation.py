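"""Simulate realistic misspellings with keyboard-proximity typos.

A simple typo substitutes exactly one letter with a physically adjacent
QWERTY key; a complex typo alters 20% of the letters (at least 1, at most
3).  Non-letters are never touched and case is preserved.
"""

from phenonorm.perturb import QWERTY, complex_typo, hamming, simple_typo, strip_hyphens

print("neighbors of 'i':", sorted(QWERTY.neighbors("i")))
print("neighbors of 'm':", sorted(QWERTY.neighbors("m")))

term = "Vascular dilatation"
for seed in range(3):
    out = simple_typo(term, seed=seed)
    print(f"simple typo (seed={seed}): {out!r}  hamming={hamming(term, out)}")

long_term = "Abnormality of the cardiovascular system"
out = complex_typo(long_term, seed=0)
print(f"complex typo: {out!r}  hamming={hamming(long_term, out)} (capped at 3)")

print("hyphen stripping:", repr(strip_hyphens("Kidney - Abnormal")))
# Stripping hyphens from hyphen-heavy SNOMED-CT terms before normalization
# helps models indexed/trained on largely hyphen-free vocabulary entries.
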