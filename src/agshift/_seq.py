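"""Small DNA-string helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: the three standard stop codons; selenocysteine readthrough is ignored
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: sense codons (everything except a stop)
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT",
               probs=None) -> str:
    if length <= 0:
        return ""
    if probs is None:
        idx = rng.integers(0, len(alphabet), size=length)
    else:
        idx = rng.choice(len(alphabet), size=length, p=probs)
    table = np.frombuffer(alphabet.encode("ascii"), dtype=np.uint8)
    return table[idx].tobytes().decode("ascii")


def random_codons(rng: np.random.Generator, n: int) -> str:
    """``n`` random sense codons (no in-frame stop)."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n)
    return "".join(SENSE_CODONS[i] for i in idx)
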