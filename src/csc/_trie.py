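"""Bounded-mismatch search kernels over sorted 2-bit-encoded protospacer keys.

The target index stores every protospacer as a ``uint64`` packing two bits per
base, most-significant bits first, and keeps the unique keys sorted.  Sorted
keys are equivalent to a prefix tree: all keys sharing a prefix occupy a
contiguous slice, and the four single-base extensions of a prefix partition
that slice.  ``query_sorted_keys`` walks this implicit trie depth-first,
spending the mismatch budget as it descends; once the budget is exhausted the
remaining suffix must match exactly, which collapses to a single binary
search.  The kernels are JIT-compiled with numba.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["encode_kmers", "query_sorted_keys", "decode_key"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@njit(cache=True)
def _query_kernel(keys, k, guide, max_d, out_idx, out_dist):
    """DFS over the implicit sorted-key trie.

    keys : sorted unique uint64 protospacer codes
    guide : (k,) uint8 base codes of the query
    Returns the number of hits written into out_idx / out_dist.
    """
    n = keys.shape[0]
    if n == 0:
        return 0
    # suffix_bits[d] = guide bases d..k-1 packed into the low 2*(k-d) bits
    suffix_bits = np.zeros(k + 1, dtype=np.uint64)
    for d in range(k - 1, -1, -1):
        shift = np.uint64(2 * (k - 1 - d))
        suffix_bits[d] = suffix_bits[d + 1] | (np.uint64(guide[d]) << shift)

    # explicit DFS stack: lo, hi, depth, used, prefix
    cap = 4 * k + 8
    st_lo = np.empty(cap, dtype=np.int64)
    st_hi = np.empty(cap, dtype=np.int64)
    st_depth = np.empty(cap, dtype=np.int64)
    st_used = np.empty(cap, dtype=np.int64)
    st_prefix = np.empty(cap, dtype=np.uint64)

    # stack entries are pushed in reverse base order so traversal is in
    # ascending key order, giving deterministic (sorted) output
    top = 0
    st_lo[0] = 0
    st_hi[0] = n
    st_depth[0] = 0
    st_used[0] = 0
    st_prefix[0] = np.uint64(0)
    top = 1
    n_out = 0

    while top > 0:
        top -= 1
        lo = st_lo[top]
        hi = st_hi[top]
        depth = st_depth[top]
        used = st_used[top]
        prefix = st_prefix[top]

        if depth == k:
            # keys are unique -> single key in range
            if n_out >= out_idx.shape[0]:
                return -1
            out_idx[n_out] = lo
            out_dist[n_out] = used
            n_out += 1
            continue

        if used == max_d:
            # budget exhausted: suffix must match exactly
            target = prefix | suffix_bits[depth]
            i = np.searchsorted(keys[lo:hi], target) + lo
            if i < hi and keys[i] == target:
                if n_out >= out_idx.shape[0]:
                    return -1
                out_idx[n_out] = i
                out_dist[n_out] = used
                n_out += 1
            continue

        shift = np.uint64(2 * (k - 1 - depth))
        # range boundaries of the four child prefixes
        b0 = lo
        b1 = np.searchsorted(keys[lo:hi], prefix | (np.uint64(1) << shift)) + lo
        b2 = np.searchsorted(keys[b1:hi], prefix | (np.uint64(2) << shift)) + b1
        b3 = np.searchsorted(keys[b2:hi], prefix | (np.uint64(3) << shift)) + b2
        b4 = hi
        g = guide[depth]
        for base in range(3, -1, -1):
            if base == 0:
                clo, chi = b0, b1
            elif base == 1:
                clo, chi = b1, b2
            elif base == 2:
                clo, chi = b2, b3
            else:
                clo, chi = b3, b4
            if clo == chi:
                continue
            nused = used + (1 if base != g else 0)
            if nused > max_d:
                continue
            if top >= cap:
                # cannot happen with cap = 4k+8, but guard anyway
                continue
            st_lo[top] = clo
            st_hi[top] = chi
            st_depth[top] = depth + 1
            st_used[top] = nused
            st_prefix[top] = prefix | (np.uint64(base) << shift)
            top += 1
    return n_out


def query_sorted_keys(keys: np.ndarray, k: int, guide_codes: np.ndarray, max_distance: int):
    """Return (indices into ``keys``, Hamming distances) for all keys within
    ``max_distance`` substitutions of the query, in ascending key order."""
    # worst case every key matches (repeat-heavy indexes); grow on overflow
    cap = 1024
    while True:
        out_idx = np.empty(cap, dtype=np.int64)
        out_dist = np.empty(cap, dtype=np.int64)
        n = _query_kernel(keys, k, guide_codes, max_distance, out_idx, out_dist)
        if n >= 0:
            return out_idx[:n], out_dist[:n]
        cap = min(cap * 8, keys.shape[0] + 1)


def encode_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack base codes (len L, values 0..3) into uint64 keys for every
    length-k window, via Horner's scheme.  Windows containing invalid codes
    (>3) must be masked out by the caller."""
    L = codes.shape[0]
    if L < k:
        return np.empty(0, dtype=np.uint64)
    n = L - k + 1
    keys = np.zeros(n, dtype=np.uint64)
    safe = np.where(codes > 3, 0, codes).astype(np.uint64)
    for j in range(k):
        keys = (keys << np.uint64(2)) | safe[j : j + n]
    return keys


def decode_key(key: int, k: int) -> str:
    out = bytearray(k)
    for i in range(k - 1, -1, -1):
        out[i] = _BASES[key & 3]
        key >>= 2
    return out.decode()
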