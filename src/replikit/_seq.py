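"""Byte-level sequence encoding shared across the package.

Bases are stored as uint8 codes: A=0, C=1, G=2, T=3, anything else 4 ("N").
Code 4 never matches anything during alignment, so it doubles as a spacer
symbol between concatenated replicons.
"""

from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

PHRED_OFFSET = 33


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back into an upper-case string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes][::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def quals_to_string(quals: np.ndarray) -> str:
    return (quals + PHRED_OFFSET).astype(np.uint8).tobytes().decode("ascii")


def string_to_quals(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8) - PHRED_OFFSET
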