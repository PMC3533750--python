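"""Nucleotide alphabet helpers shared across the package.

Sequences are plain uppercase strings over {A, C, G, T, N} at module
boundaries; hot loops work on uint8 code arrays (A=0, C=1, G=2, T=3, N=4).
N never matches anything, including another N.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
N_CODE = 4

_COMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte -> code lookup; anything unexpected maps to N
_ENCODE_LUT = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

_DECODE_LUT = np.frombuffer(BASES.encode(), dtype=np.uint8)
_COMP_CODE = np.array([3, 2, 1, 0, N_CODE], dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complements)."""
    return seq.translate(_COMP_TABLE)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a string into a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE_LUT[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_CODE[np.asarray(codes, dtype=np.uint8)][::-1]


def mismatches(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance under the N-is-always-a-mismatch rule."""
    a = np.asarray(a)
    b = np.asarray(b)
    return int(np.count_nonzero((a != b) | (a == N_CODE) | (b == N_CODE)))
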