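"""Error-tolerant barcode clustering.

PCR and sequencing introduce mutations into recovered barcode reads, so
near-identical sequences must be collapsed onto the true barcode while
genuinely independent barcodes stay apart.  The balance is controlled by an
identity threshold: two sequences belong together when their normalized
identity, ``1 - levenshtein(a, b) / max(len(a), len(b))``, reaches the
threshold (0.8 by default, the plateau of the threshold sweep on random
30-mers).

The clusterer is greedy and abundance-ordered: candidates are processed by
decreasing read count (ties broken lexicographically), each joining the
earliest-founded centroid it is similar enough to, otherwise founding a new
cluster.  This is the standard centroid scheme for barcode collapsing and is
fully deterministic.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from . import _myers


def sequence_identity(a: str, b: str) -> float:
    """Normalized identity ``1 - levenshtein / max(len)`` between two sequences."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    codes, lengths, peq = _myers.encode_sequences([a, b])
    d = _myers._myers_ed(peq[0], lengths[0], codes[1], lengths[1])
    return 1.0 - d / max(lengths[0], lengths[1])


def _processing_order(sequences, weights):
    order = sorted(range(len(sequences)), key=lambda i: (-weights[i], sequences[i]))
    return np.asarray(order, dtype=np.int64)


class BarcodeClusterer(ClusterMixin, BaseEstimator):
    """Greedy abundance-ordered centroid clustering of barcode sequences.

    Parameters
    ----------
    identity_threshold : float in (0, 1], default 0.8
        Minimum normalized identity for a candidate to join a centroid.

    Attributes
    ----------
    labels_ : ndarray of shape (n_sequences,)
        Cluster index per input sequence, numbered by cluster foundation
        order (0 = most abundant centroid).
    centroids_ : list of str
        Centroid sequence per cluster.
    cluster_read_counts_ : ndarray
        Summed sample weights (read counts) per cluster.
    cluster_sizes_ : ndarray
        Number of member sequence variants per cluster.
    n_clusters_ : int
    """

    def __init__(self, identity_threshold: float = 0.8):
        self.identity_threshold = identity_threshold

    def fit(self, X: Sequence[str], y=None, sample_weight=None):
        t = self.identity_threshold
        if not (0.0 < t <= 1.0):
            raise ValueError(f"identity_threshold must be in (0, 1], got {t}")
        X = list(X)
        if sample_weight is None:
            weights = np.ones(len(X), dtype=np.int64)
        else:
            weights = np.asarray(sample_weight)
            if weights.shape != (len(X),):
                raise ValueError("sample_weight must match the number of sequences")
            if np.any(weights < 0):
                raise ValueError("sample_weight must be non-negative")
        if len(X) == 0:
            self.labels_ = np.zeros(0, dtype=np.int64)
            self.centroids_ = []
            self.cluster_read_counts_ = np.zeros(0)
            self.cluster_sizes_ = np.zeros(0, dtype=np.int64)
            self.n_clusters_ = 0
            return self

        order = _processing_order(X, weights)
        codes, lengths, peq = _myers.encode_sequences([X[i] for i in order])
        assign = _myers.greedy_assign(codes, lengths, peq, float(t))
        self._finalize(X, weights, order, assign)
        return self

    def _finalize(self, X, weights, order, assign):
        """Convert processing-order assignment into user-facing attributes."""
        n = len(X)
        # cluster ids by foundation order
        cluster_of_pos = np.empty(n, dtype=np.int64)
        centroids = []
        cid_of_centroid_pos = {}
        for pos in range(n):
            c = assign[pos]
            if c == pos:
                cid_of_centroid_pos[pos] = len(centroids)
                centroids.append(X[order[pos]])
            cluster_of_pos[pos] = cid_of_centroid_pos[assign[pos]]
        labels = np.empty(n, dtype=np.int64)
        labels[order] = cluster_of_pos
        k = len(centroids)
        read_counts = np.zeros(k, dtype=np.asarray(weights).dtype)
        np.add.at(read_counts, labels, weights)
        sizes = np.bincount(labels, minlength=k).astype(np.int64)
        self.labels_ = labels
        self.centroids_ = centroids
        self.cluster_read_counts_ = read_counts
        self.cluster_sizes_ = sizes
        self.n_clusters_ = k


def threshold_sweep(
    sequences: Sequence[str],
    thresholds: Sequence[float],
    sample_weight=None,
):
    """Cluster counts across an ascending list of identity thresholds.

    Exactly equivalent to fitting :class:`BarcodeClusterer` at each
    threshold, but the pairwise distances within the loosest bound are
    computed once and the greedy assignment is replayed per threshold, which
    makes sweeps over tens of thousands of sequences tractable.

    Returns a list of ``(threshold, n_clusters)`` pairs.
    """
    thresholds = [float(t) for t in thresholds]
    if any(not (0.0 < t <= 1.0) for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    sequences = list(sequences)
    if not sequences:
        return [(t, 0) for t in thresholds]
    if sample_weight is None:
        weights = np.ones(len(sequences), dtype=np.int64)
    else:
        weights = np.asarray(sample_weight)
    order = _processing_order(sequences, weights)
    codes, lengths, peq = _myers.encode_sequences([sequences[i] for i in order])
    lmax = int(lengths.max())
    k_max = int(np.floor((1.0 - thresholds[0]) * lmax + 1e-9))
    src, dst, dist = _myers.all_pairs_within(codes, lengths, peq, k_max)
    out = []
    for t in thresholds:
        assign = _myers.greedy_assign_from_edges(
            len(sequences), src, dst, dist, lengths, float(t)
        )
        n_clusters = int(np.sum(assign == np.arange(len(sequences))))
        out.append((t, n_clusters))
    return out
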