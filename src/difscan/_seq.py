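"""Nucleotide encoding helpers shared by the scanning modules.

Sequences are held as uppercase strings externally and as uint8 code
arrays (A=0, C=1, G=2, T=3, N=4) for vectorized window scoring.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
# complement in code space: A<->T (0<->3), C<->G (1<->2), N stays 4
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string to uint8 codes; raises on other letters."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted({seq[i] for i in np.nonzero(arr == 255)[0][:5]})
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    return arr


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_CODE[codes[::-1]]


def base_frequencies(codes: np.ndarray) -> np.ndarray:
    """Mononucleotide frequencies over A,C,G,T ignoring N; double-strand
    symmetrized so that scanning either strand sees the same background."""
    counts = np.bincount(codes[codes < 4], minlength=4).astype(float)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    # pool with the complementary strand: A+T and C+G symmetric
    counts = counts + counts[::-1]
    return counts / counts.sum()
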