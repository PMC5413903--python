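"""Bit-parallel Levenshtein distance kernels (Myers 1999, Hyyrö variant).

Barcodes are at most 34 bases after the length filter, so a pattern always
fits in one 64-bit machine word and a pairwise distance costs O(|b|) word
operations.  These kernels back the greedy centroid clusterer and the
identity-threshold sweep, where up to ~8x10^8 pairwise distances are needed.
"""
from __future__ import annotations

import numpy as np
from numba import njit, uint64

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

MAX_PATTERN_LEN = 64


def encode_sequences(sequences):
    """Encode DNA strings into (codes, lengths, peq) arrays for the kernels.

    ``codes`` is an (n, Lmax) uint8 matrix of 2-bit base codes, ``lengths``
    the per-sequence lengths and ``peq`` the (n, 4) uint64 match-mask table
    used when the sequence plays the pattern role.
    """
    n = len(sequences)
    if n == 0:
        return (
            np.zeros((0, 1), dtype=np.uint8),
            np.zeros(0, dtype=np.int64),
            np.zeros((0, 4), dtype=np.uint64),
        )
    lmax = max(len(s) for s in sequences)
    if lmax > MAX_PATTERN_LEN:
        raise ValueError(f"sequences longer than {MAX_PATTERN_LEN} bases are not supported")
    codes = np.zeros((n, max(lmax, 1)), dtype=np.uint8)
    lengths = np.zeros(n, dtype=np.int64)
    peq = np.zeros((n, 4), dtype=np.uint64)
    one = np.uint64(1)
    for i, seq in enumerate(sequences):
        if not seq:
            raise ValueError("empty sequence")
        lengths[i] = len(seq)
        for p, ch in enumerate(seq):
            try:
                c = _BASE_CODE[ch]
            except KeyError:
                raise ValueError(f"non-ACGT base {ch!r} in sequence {seq!r}") from None
            codes[i, p] = c
            peq[i, c] |= one << np.uint64(p)
    return codes, lengths, peq


@njit(cache=True)
def _myers_ed(peq_a, len_a, codes_b, len_b):
    """Levenshtein distance between pattern a (as peq masks) and text b."""
    Pv = uint64(0xFFFFFFFFFFFFFFFF)
    Mv = uint64(0)
    score = len_a
    last = uint64(1) << uint64(len_a - 1)
    for j in range(len_b):
        Eq = peq_a[codes_b[j]]
        Xv = Eq | Mv
        Xh = (((Eq & Pv) + Pv) ^ Pv) | Eq
        Ph = Mv | ~(Xh | Pv)
        Mh = Pv & Xh
        if Ph & last:
            score += 1
        elif Mh & last:
            score -= 1
        Ph = (Ph << uint64(1)) | uint64(1)
        Mh = Mh << uint64(1)
        Pv = Mh | ~(Xv | Ph)
        Mv = Ph & Xv
    return score


@njit(cache=True)
def _max_edits(len_a, len_b, threshold):
    lmax = len_a if len_a >= len_b else len_b
    return np.int64(np.floor((1.0 - threshold) * lmax + 1e-9))


@njit(cache=True)
def greedy_assign(codes, lengths, peq, threshold):
    """Greedy centroid assignment over candidates given in processing order.

    Candidate i joins the earliest-founded centroid j with normalized
    identity 1 - d/max(len) >= threshold, else founds a new centroid.
    Returns ``assign`` where assign[i] is the processing-order index of the
    centroid that candidate i belongs to (assign[i] == i for centroids).
    """
    n = lengths.shape[0]
    centroid_idx = np.empty(n, dtype=np.int64)
    n_cent = 0
    assign = np.empty(n, dtype=np.int64)
    for i in range(n):
        chosen = -1
        for c in range(n_cent):
            j = centroid_idx[c]
            kmax = _max_edits(lengths[j], lengths[i], threshold)
            diff = lengths[j] - lengths[i]
            if diff < 0:
                diff = -diff
            if diff > kmax:
                continue
            d = _myers_ed(peq[j], lengths[j], codes[i], lengths[i])
            if d <= kmax:
                chosen = j
                break
        if chosen < 0:
            centroid_idx[n_cent] = i
            n_cent += 1
            assign[i] = i
        else:
            assign[i] = chosen
    return assign


@njit(cache=True)
def _all_pairs_within(codes, lengths, peq, k_max, out_i, out_j, out_d):
    n = lengths.shape[0]
    cap = out_i.shape[0]
    cnt = 0
    for i in range(n):
        for j in range(i + 1, n):
            diff = lengths[i] - lengths[j]
            if diff < 0:
                diff = -diff
            if diff > k_max:
                continue
            d = _myers_ed(peq[i], lengths[i], codes[j], lengths[j])
            if d <= k_max:
                if cnt < cap:
                    out_i[cnt] = i
                    out_j[cnt] = j
                    out_d[cnt] = d
                cnt += 1
    return cnt


def all_pairs_within(codes, lengths, peq, k_max, initial_capacity=1 << 20):
    """All (i<j) pairs with Levenshtein distance <= k_max, as three arrays."""
    cap = int(initial_capacity)
    while True:
        out_i = np.empty(cap, dtype=np.int32)
        out_j = np.empty(cap, dtype=np.int32)
        out_d = np.empty(cap, dtype=np.int16)
        cnt = _all_pairs_within(codes, lengths, peq, np.int64(k_max), out_i, out_j, out_d)
        if cnt <= cap:
            return out_i[:cnt].copy(), out_j[:cnt].copy(), out_d[:cnt].copy()
        cap = int(cnt * 1.2) + 1024


@njit(cache=True)
def greedy_assign_from_edges(n, edge_src, edge_dst, edge_d, lengths, threshold):
    """Replay greedy assignment using a precomputed bounded-distance edge list.

    ``edge_src < edge_dst`` are processing-order indices; the list must
    contain every pair within the loosest distance bound ever queried, so the
    replay is exactly equivalent to :func:`greedy_assign` at any tighter
    threshold.
    """
    m = edge_src.shape[0]
    # CSR of incoming (earlier-index) neighbours per vertex, sources ascending
    counts = np.zeros(n + 1, dtype=np.int64)
    for e in range(m):
        counts[edge_dst[e] + 1] += 1
    offsets = np.cumsum(counts)
    nbr_src = np.empty(m, dtype=np.int64)
    nbr_d = np.empty(m, dtype=np.int64)
    fill = offsets[:-1].copy()
    for e in range(m):  # edge list is produced in ascending (i, j) order
        v = edge_dst[e]
        nbr_src[fill[v]] = edge_src[e]
        nbr_d[fill[v]] = edge_d[e]
        fill[v] += 1
    assign = np.empty(n, dtype=np.int64)
    is_centroid = np.zeros(n, dtype=np.uint8)
    for v in range(n):
        chosen = -1
        for p in range(offsets[v], offsets[v + 1]):
            u = nbr_src[p]
            if not is_centroid[u]:
                continue
            if nbr_d[p] <= _max_edits(lengths[u], lengths[v], threshold):
                chosen = u
                break
        if chosen < 0:
            is_centroid[v] = 1
            assign[v] = v
        else:
            assign[v] = chosen
    return assign
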