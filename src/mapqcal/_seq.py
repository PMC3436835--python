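"""Nucleotide encoding helpers shared across modules.

Bases are encoded as uint8 codes: A=0, C=1, G=2, T=3, N=4. Code 4 never
matches a reference code, so Hamming comparisons on code arrays treat N as
a mismatch automatically.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
N_CODE = 4

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("N")] = N_CODE
_ENCODE[ord("n")] = N_CODE

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement of codes 0..4 (N complements to N)
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_COMPLEMENT_STR = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code array."""
    codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size and codes.max() == 255:
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"invalid nucleotide character {bad!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an A/C/G/T/N string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes][::-1]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT_STR)[::-1]
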