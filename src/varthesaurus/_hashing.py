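"""Vectorised sequence hashing utilities.

Two flavours are used in the package:

* exact 2-bit k-mer packing (k <= 32) for the homology-search seed index —
  collision free by construction;
* a 64-bit polynomial rolling hash over the ring Z/2^64 for long windows
  (e.g. read-length duplicate detection), whose candidate groups are always
  verified against the actual sequence before use.
"""

from __future__ import annotations

import numpy as np


def pack_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Exact 2-bit packing of every k-mer (k <= 32) into uint64."""
    if not 1 <= k <= 32:
        raise ValueError("pack_kmers requires 1 <= k <= 32")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    four = np.uint64(4)
    for i in range(k):
        out = out * four + codes[i:i + n].astype(np.uint64)
    return out


def rolling_hash(codes: np.ndarray, k: int, base: int = 1099511628211) -> np.ndarray:
    """Polynomial hash of every length-k window, computed in O(L).

    Works in the ring of uint64 with wraparound; ``base`` must be odd so it
    is invertible mod 2^64. Equal windows always hash equally; unequal
    windows collide with probability ~2^-64 (callers verify groups).
    """
    length = codes.size
    n = length - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    b = np.uint64(base)
    # q[t] = base^t (mod 2^64)
    q = np.empty(length, dtype=np.uint64)
    q[0] = 1
    if length > 1:
        np.multiply.accumulate(np.full(length - 1, b, dtype=np.uint64), out=q[1:])
    weights = q[::-1]  # base^(L-1-t)
    prefix = np.zeros(length + 1, dtype=np.uint64)
    np.cumsum(codes.astype(np.uint64) * weights, out=prefix[1:])
    raw = prefix[k:] - prefix[:n]  # = base^(L-k-p) * hash_p
    inv_b = pow(base, -1, 1 << 64)
    inv0 = np.uint64(pow(inv_b, length - k, 1 << 64))
    return raw * (inv0 * q[:n])
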