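"""Nucleotide encoding helpers.

Sequences are held internally as numpy uint8 arrays with the 2-bit code
A=0, C=1, G=2, T=3. Conversion to/from ASCII happens only at I/O
boundaries (FASTA/FASTQ/SAM writing, VCF alleles).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE_TO_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)

# ASCII -> code lookup; non-ACGT maps to 255 (treated as "no call")
_ASCII_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ASCII_TO_CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ASCII_TO_CODE[_b] = _i

_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """ASCII nucleotides -> uint8 codes."""
    if isinstance(seq, str):
        seq = seq.encode()
    return _ASCII_TO_CODE[np.frombuffer(seq, dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    """uint8 codes -> ASCII string."""
    return _CODE_TO_ASCII[codes].tobytes().decode()


def decode_bytes(codes: np.ndarray) -> bytes:
    return _CODE_TO_ASCII[codes].tobytes()


def complement(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes]


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def complement_base(base: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}[base]


def ascii_to_codes(arr: np.ndarray) -> np.ndarray:
    """Vectorised ASCII uint8 array -> codes."""
    return _ASCII_TO_CODE[arr]
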