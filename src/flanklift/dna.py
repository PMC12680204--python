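"""Small DNA helpers shared across the package.

All sequences handled here are plain upper-case Python strings over the
alphabet {A, C, G, T, N}.  ``N`` is treated as an ambiguity code that never
matches any base, including another ``N``.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: numeric encoding used by the k-mer index and the aligner:
#: A=0, C=1, G=2, T=3, anything else (N) = -1.
_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

VALID_BASES = frozenset("ACGT")
VALID_ALPHABET = frozenset("ACGTN")


def complement(base: str) -> str:
    """Complement of a single base (or short string), case preserving."""
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as an int8 array (A=0 C=1 G=2 T=3, other=-1)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def sanitize(seq: str) -> str:
    """Upper-case ``seq`` and collapse any non-ACGT letter to ``N``."""
    up = seq.upper()
    if set(up) <= VALID_ALPHABET:
        return up
    return "".join(c if c in VALID_ALPHABET else "N" for c in up)
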