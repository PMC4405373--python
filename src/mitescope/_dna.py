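"""Low-level DNA helpers: integer encoding, complements, composition."""

from __future__ import annotations

import numpy as np

# A=0 C=1 G=2 T=3 N=4; complement(N) is encoded as 5 so that N never matches
# anything (including another N) under either direct or complement comparison.
_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGTN"):
    _CODE[ord(b)] = i
_N = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode an uppercase DNA string as int8 codes (A0 C1 G2 T3 N4)."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError("sequence contains characters outside A/C/G/T/N")
    return arr


def decode(arr: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in arr)


def complement_codes(arr: np.ndarray) -> np.ndarray:
    """Complement of encoded DNA; N maps to 5, which equals no code."""
    comp = 3 - arr
    comp[arr == _N] = 5
    return comp.astype(np.int8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def at_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    at = seq.count("A") + seq.count("T")
    return at / len(seq)


def gc_at_probs(at_content: float) -> np.ndarray:
    """Per-base sampling probabilities (A, C, G, T) for a target AT fraction."""
    at = at_content / 2.0
    gc = (1.0 - at_content) / 2.0
    return np.array([at, gc, gc, at])


TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"),
    "C": ("A", "G"), "T": ("A", "G"),
}
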