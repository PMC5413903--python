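"""Barcode recovery from amplicon reads.

The pipeline mirrors the sequencing-analysis steps of a split-dish
barcoding experiment: reads are demultiplexed by their 10-bp dish
signature, the known flanks around the barcode are trimmed, low-quality and
off-length candidates are discarded, sequencing variants are collapsed by
greedy identity clustering, noise clusters are filtered, and finally each
barcode's per-dish presence pattern is tabulated into an overlap table.

Filters applied (in order):

* quality — a candidate is discarded when more than 20% of its bases have
  Phred quality below 20;
* length — trimmed barcodes shorter than 26 or longer than 34 bases are
  discarded;
* singleton — clusters supported by a single read overall are removed as
  noise;
* cross-dish — a dish counts as containing a barcode only when it holds at
  least 0.1% of the barcode's expected per-dish share (total reads / 4).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .cluster import BarcodeClusterer, sequence_identity, threshold_sweep  # noqa: F401

DEFAULT_MIN_LEN = 26
DEFAULT_MAX_LEN = 34
DEFAULT_MIN_QUALITY = 20
DEFAULT_MAX_LOWQ_FRACTION = 0.2
CROSS_DISH_FRACTION = 0.001


@dataclass
class Read:
    """One sequencing read."""

    id: str
    bases: str
    qualities: np.ndarray

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.bases) != self.qualities.size:
            raise ValueError("bases and qualities must have equal length")


def read_fastq(path) -> list[Read]:
    """Load a Sanger/Phred+33 FASTQ file."""
    reads = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            reads.append(
                Read(
                    id=title.split()[0],
                    bases=seq,
                    qualities=np.frombuffer(qual.encode("ascii"), dtype=np.uint8) - 33,
                )
            )
    return reads


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def validate_signatures(signatures: Sequence[str], max_mismatches: int = 1):
    signatures = tuple(signatures)
    lengths = {len(s) for s in signatures}
    if len(lengths) != 1:
        raise ValueError("signatures must share one length")
    for i in range(len(signatures)):
        for j in range(i + 1, len(signatures)):
            if _hamming(signatures[i], signatures[j]) <= max_mismatches:
                raise ValueError(
                    f"signatures {signatures[i]} and {signatures[j]} are ambiguous "
                    f"at max_mismatches={max_mismatches}"
                )
    return signatures


def demultiplex(
    reads: Iterable[Read],
    signatures: Sequence[str],
    max_mismatches: int = 1,
) -> tuple[dict[int, list[Read]], list[Read]]:
    """Sort reads into dishes by their signature prefix.

    A read goes to the dish whose signature is the unique nearest one within
    ``max_mismatches`` of the read prefix (the signature is stripped);
    anything ambiguous or too distant is returned unassigned.
    """
    signatures = validate_signatures(signatures, max_mismatches)
    sig_len = len(signatures[0])
    by_dish: dict[int, list[Read]] = {d: [] for d in range(1, len(signatures) + 1)}
    unassigned: list[Read] = []
    for read in reads:
        prefix = read.bases[:sig_len]
        dists = [_hamming(prefix, s) for s in signatures]
        best = min(dists)
        if best > max_mismatches or dists.count(best) > 1:
            unassigned.append(read)
            continue
        dish = dists.index(best) + 1
        by_dish[dish].append(
            Read(read.id, read.bases[sig_len:], read.qualities[sig_len:])
        )
    return by_dish, unassigned


def _find_approx(haystack: str, needle: str, max_mm: int = 1) -> int:
    """Leftmost position of ``needle`` in ``haystack`` allowing substitutions."""
    pos = haystack.find(needle)
    if pos >= 0 or max_mm == 0:
        return pos
    n = len(needle)
    for p in range(len(haystack) - n + 1):
        mm = 0
        window = haystack[p : p + n]
        for x, y in zip(window, needle):
            if x != y:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            return p
    return -1


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _locate_barcode(bases: str, left_flank: str, right_flank: str):
    lpos = _find_approx(bases, left_flank)
    if lpos < 0:
        return None
    start = lpos + len(left_flank)
    rrel = _find_approx(bases[start:], right_flank)
    if rrel < 0:
        return None
    return start, start + rrel


def trim_and_filter(
    reads: Iterable[Read],
    left_flank: str,
    right_flank: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_quality: int = DEFAULT_MIN_QUALITY,
    max_lowq_fraction: float = DEFAULT_MAX_LOWQ_FRACTION,
    search_reverse_complement: bool = False,
) -> tuple[dict[str, int], dict[str, int]]:
    """Extract barcode candidates between the flanks and apply read filters.

    Returns ``(candidates, discards)`` where ``candidates`` maps barcode
    strings to read counts and ``discards`` counts reads per discard reason
    (``no_flank``, ``low_quality``, ``too_short``, ``too_long``).  The
    amplicon design fixes the read orientation, so the reverse strand is
    only searched when ``search_reverse_complement`` is set.
    """
    if not left_flank or not right_flank:
        raise ValueError("flanks must be non-empty")
    candidates: dict[str, int] = {}
    discards = {"no_flank": 0, "low_quality": 0, "too_short": 0, "too_long": 0}
    for read in reads:
        bases, quals_full = read.bases, read.qualities
        span = _locate_barcode(bases, left_flank, right_flank)
        if span is None and search_reverse_complement:
            bases = reverse_complement(bases)
            quals_full = quals_full[::-1]
            span = _locate_barcode(bases, left_flank, right_flank)
        if span is None:
            discards["no_flank"] += 1
            continue
        start, end = span
        barcode = bases[start:end]
        quals = quals_full[start:end]
        if barcode and np.mean(quals < min_quality) > max_lowq_fraction:
            discards["low_quality"] += 1
            continue
        if len(barcode) < min_len:
            discards["too_short"] += 1
            continue
        if len(barcode) > max_len:
            discards["too_long"] += 1
            continue
        candidates[barcode] = candidates.get(barcode, 0) + 1
    return candidates, discards


@dataclass
class BarcodeCluster:
    """A recovered barcode: centroid sequence plus per-dish read support."""

    centroid: str
    dish_counts: np.ndarray
    n_variants: int

    def __post_init__(self):
        self.dish_counts = np.asarray(self.dish_counts, dtype=np.int64)

    @property
    def total_reads(self) -> int:
        return int(self.dish_counts.sum())


def cluster_barcodes(
    counts_by_dish: Mapping[int, Mapping[str, int]],
    identity_threshold: float = 0.8,
    n_dishes: int = 4,
) -> list[BarcodeCluster]:
    """Collapse sequencing variants pooled across dishes into barcode clusters.

    Candidates are pooled over dishes (clustering on total abundance), then
    per-dish read counts are summed per cluster.  Thin wrapper over
    :class:`clonetrace.cluster.BarcodeClusterer`.
    """
    pooled: dict[str, int] = {}
    for dish_counts in counts_by_dish.values():
        for seq, n in dish_counts.items():
            pooled[seq] = pooled.get(seq, 0) + n
    if not pooled:
        return []
    seqs = list(pooled)
    weights = np.asarray([pooled[s] for s in seqs], dtype=np.int64)
    est = BarcodeClusterer(identity_threshold=identity_threshold).fit(
        seqs, sample_weight=weights
    )
    label_of = dict(zip(seqs, est.labels_))
    dish_counts = np.zeros((est.n_clusters_, n_dishes), dtype=np.int64)
    for dish, counts in counts_by_dish.items():
        for seq, n in counts.items():
            dish_counts[label_of[seq], dish - 1] += n
    return [
        BarcodeCluster(
            centroid=est.centroids_[c],
            dish_counts=dish_counts[c],
            n_variants=int(est.cluster_sizes_[c]),
        )
        for c in range(est.n_clusters_)
    ]


def filter_clusters(clusters: Iterable[BarcodeCluster]) -> list[BarcodeCluster]:
    """Remove single-read clusters (sequencing noise)."""
    return [c for c in clusters if c.total_reads > 1]


def cross_dish_filter(cluster: BarcodeCluster, n_dishes: int = 4) -> np.ndarray:
    """Per-dish presence flags for a barcode.

    A dish counts as containing the barcode only when its read count reaches
    0.1% of the expected per-dish share (a quarter of the barcode's total
    reads), which suppresses cross-dish read bleed-through.
    """
    expected = cluster.total_reads / n_dishes
    threshold = CROSS_DISH_FRACTION * expected
    return (cluster.dish_counts > 0) & (cluster.dish_counts >= threshold)


@dataclass
class OverlapTable:
    """Counts of distinct barcodes by dish-membership pattern."""

    exactly: dict[int, int]
    per_dish_distinct: np.ndarray
    shared_patterns: list[tuple[str, tuple[int, ...]]]
    spike_in_report: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.exactly.values())

    @property
    def shared(self) -> int:
        return sum(v for k, v in self.exactly.items() if k >= 2)


def build_overlap_table(
    clusters: Iterable[BarcodeCluster],
    spike_in_sequences: Sequence[str] = (),
    identity_threshold: float = 0.8,
    n_dishes: int = 4,
) -> OverlapTable:
    """Tabulate barcodes by the number of dishes they appear in.

    Clusters whose centroid matches a spike-in control sequence (at the
    clustering identity threshold) are excluded from overlap counting and
    reported separately with their per-dish read counts.
    """
    exactly = {k: 0 for k in range(1, n_dishes + 1)}
    per_dish = np.zeros(n_dishes, dtype=np.int64)
    patterns: list[tuple[str, tuple[int, ...]]] = []
    spike_report = {s: np.zeros(n_dishes, dtype=np.int64) for s in spike_in_sequences}
    for cluster in clusters:
        spike_hit = None
        for s in spike_in_sequences:
            if sequence_identity(cluster.centroid, s) >= identity_threshold:
                spike_hit = s
                break
        if spike_hit is not None:
            spike_report[spike_hit] += cluster.dish_counts
            continue
        present = cross_dish_filter(cluster, n_dishes)
        k = int(present.sum())
        if k == 0:
            continue
        exactly[k] += 1
        per_dish += present.astype(np.int64)
        if k >= 2:
            patterns.append(
                (cluster.centroid, tuple(int(d) + 1 for d in np.flatnonzero(present)))
            )
    return OverlapTable(
        exactly=exactly,
        per_dish_distinct=per_dish,
        shared_patterns=patterns,
        spike_in_report=spike_report,
    )


@dataclass
class ExtractionResult:
    """End-to-end output of the read-processing pipeline."""

    clusters: list[BarcodeCluster]
    overlap: OverlapTable
    discards: dict[str, int]
    n_unassigned: int
    counts_by_dish: dict[int, dict[str, int]]


def run_extraction(
    fastq_paths,
    signatures: Sequence[str],
    left_flank: str,
    right_flank: str,
    identity_threshold: float = 0.8,
    max_mismatches: int = 1,
    spike_in_sequences: Sequence[str] = (),
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> ExtractionResult:
    """Run the full pipeline on one or more FASTQ files.

    Files may be per-dish or multiplexed; assignment always goes by the
    signature prefix, so both layouts are handled identically.
    """
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    reads: list[Read] = []
    for path in fastq_paths:
        reads.extend(read_fastq(path))
    by_dish, unassigned = demultiplex(reads, signatures, max_mismatches)
    counts_by_dish: dict[int, dict[str, int]] = {}
    discards = {"no_flank": 0, "low_quality": 0, "too_short": 0, "too_long": 0}
    for dish, dish_reads in by_dish.items():
        candidates, d = trim_and_filter(dish_reads, left_flank, right_flank,
                                        min_len=min_len, max_len=max_len)
        counts_by_dish[dish] = candidates
        for reason, n in d.items():
            discards[reason] += n
    clusters = cluster_barcodes(
        counts_by_dish, identity_threshold, n_dishes=len(signatures)
    )
    kept = filter_clusters(clusters)
    overlap = build_overlap_table(
        kept, spike_in_sequences, identity_threshold, n_dishes=len(signatures)
    )
    return ExtractionResult(
        clusters=kept,
        overlap=overlap,
        discards=discards,
        n_unassigned=len(unassigned),
        counts_by_dish=counts_by_dish,
    )


def overlap_table_to_frame(table: OverlapTable) -> pd.DataFrame:
    rows = [{"n_dishes": k, "n_barcodes": v} for k, v in sorted(table.exactly.items())]
    return pd.DataFrame(rows)


def clusters_to_frame(clusters: Iterable[BarcodeCluster],
                      spike_in_sequences: Sequence[str] = (),
                      identity_threshold: float = 0.8) -> pd.DataFrame:
    rows = []
    spikes = tuple(spike_in_sequences)
    for c in clusters:
        is_spike = any(
            sequence_identity(c.centroid, s) >= identity_threshold for s in spikes
        )
        row = {"barcode": c.centroid, "n_variants": c.n_variants, "spikein_flag": is_spike}
        for d, n in enumerate(c.dish_counts, start=1):
            row[f"dish{d}_reads"] = int(n)
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(result: ExtractionResult, out_dir,
                  spike_in_sequences: Sequence[str] = ()) -> dict[str, Path]:
    """Write the per-dish barcode count TSV, overlap TSV and discard JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "clusters": out_dir / "barcodes.tsv",
        "overlap": out_dir / "overlap.tsv",
        "discards": out_dir / "discards.json",
    }
    clusters_to_frame(result.clusters, spike_in_sequences).to_csv(
        paths["clusters"], sep="\t", index=False
    )
    overlap_table_to_frame(result.overlap).to_csv(paths["overlap"], sep="\t", index=False)
    summary = dict(result.discards)
    summary["unassigned"] = result.n_unassigned
    paths["discards"].write_text(json.dumps(summary, indent=2))
    return paths
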