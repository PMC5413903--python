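"""Synthetic barcoding experiments with known ground truth.

Generates random barcode libraries, full clonal experiments (via the same
generative steps as the stochastic model in :mod:`clonetrace.sim`) and
FASTQ reads mimicking the amplicon design: a 10-bp dish signature, a known
left flank, the 30-bp barcode with optional substitution/indel noise, and a
known right flank.  Spike-in control cells with the two fixed control
barcodes can be added in configurable per-dish cell numbers.

Every stage is seeded and deterministic, so the extraction pipeline can be
tested against exact ground truth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import sim
from .sim import SimParams

#: Control barcodes from clonal cell lines carrying a single verified
#: integration; added to each dish in known cell numbers to monitor PCR and
#: sequencing fidelity.
SPIKE_IN_BARCODES = (
    "TGCTGACCGCAGGTACGACGCCGAAGGATG",
    "GGACGCGCCTACTACTTCGCGAGCATCCTG",
)

#: Spike-in cell numbers per dish used in the three barcoded experiments:
#: (first barcode, second barcode) cells added to every dish.
SPIKE_IN_CELLS = ({SPIKE_IN_BARCODES[0]: 100, SPIKE_IN_BARCODES[1]: 400},
                  {SPIKE_IN_BARCODES[0]: 20, SPIKE_IN_BARCODES[1]: 80},
                  {SPIKE_IN_BARCODES[0]: 10, SPIKE_IN_BARCODES[1]: 50})

#: Default 10-bp dish signatures (pairwise Hamming distance >= 9).
DEFAULT_SIGNATURES = ("ACGTACCAGT", "CATGGTTCAA", "GTACCAGTCG", "TGCATGACTC")

#: Flanks bordering the random barcode in the linker oligo.
DEFAULT_LEFT_FLANK = "GTTGTAAAACGACGGCCAGT"
DEFAULT_RIGHT_FLANK = "GGTCATAGCTGTTTCCTGAC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class BarcodeLibrary:
    """A pool of unique random barcode sequences."""

    sequences: tuple[str, ...]
    barcode_length: int

    @property
    def diversity(self) -> int:
        return len(self.sequences)

    def __post_init__(self):
        if any(len(s) != self.barcode_length for s in self.sequences):
            raise ValueError("all barcodes must have the configured length")


def generate_library(diversity: int, barcode_length: int = 30, seed=None) -> BarcodeLibrary:
    """Draw ``diversity`` unique uniform-random barcodes of the given length."""
    if diversity < 1:
        raise ValueError("diversity must be positive")
    if barcode_length < 1:
        raise ValueError("barcode_length must be positive")
    if math.log(diversity) > barcode_length * math.log(4):
        raise ValueError(
            f"requested diversity {diversity} exceeds the 4^{barcode_length} "
            "possible sequences of this length"
        )
    rng = np.random.default_rng(seed)
    seqs: dict[str, None] = {}
    while len(seqs) < diversity:
        need = diversity - len(seqs)
        block = _BASES[rng.integers(0, 4, size=(need, barcode_length))]
        for row in block:
            seqs.setdefault(row.tobytes().decode("ascii"), None)
    return BarcodeLibrary(tuple(seqs), barcode_length)


@dataclass
class ReadModel:
    """Noise model for PCR amplification and sequencing of barcodes.

    ``pcr_sigma`` is the log-normal dispersion of the per-(barcode, dish)
    amplification factor; 0 means every cell yields exactly ``mean_reads``
    reads.  ``error_rate`` is the per-base substitution probability;
    ``indel_rate`` optionally adds per-base insertion/deletion noise
    (default 0, since the pipeline's 26-34 bp length filter is exercised
    separately).  ``low_quality_read_fraction`` injects reads whose bases are
    assigned ``low_quality_value`` to exercise the quality filter.
    """

    error_rate: float = 0.0
    indel_rate: float = 0.0
    pcr_sigma: float = 0.0
    mean_reads: float = 50.0
    quality: int = 30
    low_quality_read_fraction: float = 0.0
    low_quality_value: int = 10

    def validate(self):
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if not (0.0 <= self.indel_rate < 1.0):
            raise ValueError("indel_rate must be in [0, 1)")
        if self.pcr_sigma < 0:
            raise ValueError("pcr_sigma must be >= 0")
        if self.mean_reads < 1:
            raise ValueError("mean_reads must be >= 1")
        return self


@dataclass
class GroundTruth:
    """Complete record of a simulated experiment.

    ``cells`` holds one row per surviving cell (clone_id, dish 1..4,
    progeny_class, reprogrammed flag); ``clone_barcodes`` maps clone ids to
    the barcode sequences all its cells carry; ``spike_ins`` lists
    (sequence, dish, n_cells) control additions.
    """

    cells: pd.DataFrame
    clone_barcodes: dict[int, tuple[str, ...]]
    spike_ins: list[tuple[str, int, int]] = field(default_factory=list)
    overlap: sim.OverlapCounts | None = None

    def reprogrammed_barcodes_by_dish(self) -> dict[int, set[str]]:
        """Barcode sequences expected from each dish's sorted (GFP+) cells."""
        out: dict[int, set[str]] = {d: set() for d in sorted(self.cells["dish"].unique())}
        repro = self.cells[self.cells["reprogrammed"]]
        for clone_id, dish in zip(repro["clone_id"], repro["dish"]):
            out[int(dish)].update(self.clone_barcodes[int(clone_id)])
        return out

    def sequenced_cell_counts(self) -> dict[tuple[str, int], int]:
        """(barcode sequence, dish) -> number of reprogrammed cells carrying it."""
        counts: dict[tuple[str, int], int] = {}
        repro = self.cells[self.cells["reprogrammed"]]
        for clone_id, dish in zip(repro["clone_id"], repro["dish"]):
            for seq in self.clone_barcodes[int(clone_id)]:
                key = (seq, int(dish))
                counts[key] = counts.get(key, 0) + 1
        return counts


def generate_ground_truth(
    params: SimParams,
    library: BarcodeLibrary,
    seed,
    spike_in_cells: Mapping[str, int] | None = None,
) -> GroundTruth:
    """Run the generative model and record per-cell ground truth.

    The clone table is produced by the same seeding/division/plating/loss/
    reprogramming steps as :func:`clonetrace.sim.simulate_once`; barcode ids
    index into ``library`` so reads can later be synthesised.  Spike-in
    cells (default: the two control barcodes at 100 and 400 cells per dish)
    are recorded per dish.
    """
    params = replace(params, diversity=library.diversity)
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pop = sim.init_population(
        params.n_seeded, params.moi, params.diversity, rng, params.single_integration
    )
    pop = sim.divide(pop, params.progeny_dist, rng)
    pop = sim.plate(pop, rng, params.n_dishes)
    pop = sim.cull(pop, params.loss, rng)
    overlap = sim.reprogram(pop, params, rng)

    cells = pd.DataFrame(
        {
            "clone_id": pop.cell_clone,
            "dish": pop.cell_dish + 1,
            "progeny_class": pop.cell_class,
            "reprogrammed": pop.cell_repro,
        }
    )
    clone_barcodes = {}
    for c in np.unique(pop.cell_clone):
        ids = pop.clone_barcodes[pop.clone_offsets[c]: pop.clone_offsets[c + 1]]
        clone_barcodes[int(c)] = tuple(library.sequences[i] for i in ids)

    if spike_in_cells is None:
        spike_in_cells = SPIKE_IN_CELLS[0]
    spikes = [
        (seq, dish, int(n))
        for seq, n in spike_in_cells.items()
        for dish in range(1, params.n_dishes + 1)
    ]
    return GroundTruth(cells=cells, clone_barcodes=clone_barcodes,
                       spike_ins=spikes, overlap=overlap)


def _mutate_reads(barcode: str, n_reads: int, model: ReadModel, rng) -> list[str]:
    """Synthesise ``n_reads`` copies of ``barcode`` with per-base noise."""
    codes = np.frombuffer(barcode.encode("ascii"), dtype=np.uint8)
    mat = np.tile(codes, (n_reads, 1))
    if model.error_rate > 0:
        mask = rng.random(mat.shape) < model.error_rate
        if mask.any():
            # substitute with a uniformly chosen different base
            base_idx = np.searchsorted(_BASES, mat[mask])
            shift = rng.integers(1, 4, size=int(mask.sum()))
            mat[mask] = _BASES[(base_idx + shift) % 4]
    reads = [row.tobytes().decode("ascii") for row in mat]
    if model.indel_rate > 0:
        out = []
        for r in reads:
            chars = list(r)
            pos = 0
            while pos < len(chars):
                u = rng.random()
                if u < model.indel_rate / 2:
                    del chars[pos]
                    continue
                if u < model.indel_rate:
                    chars.insert(pos, "ACGT"[rng.integers(0, 4)])
                    pos += 1
                pos += 1
            out.append("".join(chars))
        reads = out
    return reads


def generate_fastq(
    truth: GroundTruth,
    model: ReadModel,
    out_dir,
    signatures: Sequence[str] = DEFAULT_SIGNATURES,
    left_flank: str = DEFAULT_LEFT_FLANK,
    right_flank: str = DEFAULT_RIGHT_FLANK,
    seed=None,
    multiplexed: bool = False,
) -> dict:
    """Write FASTQ reads (one file per dish, or one multiplexed file).

    Each read is ``signature + left_flank + noisy(barcode) + right_flank``
    with Sanger/Phred+33 qualities.  Read multiplicity per (barcode, dish)
    is ``round(n_cells * mean_reads * lognormal(0, pcr_sigma))`` with one
    amplification factor per barcode-dish pair.  A ground-truth manifest TSV
    is written alongside; its ``n_reads`` column sums to the reads emitted.
    """
    model.validate()
    signatures = tuple(signatures)
    if len(set(signatures)) != len(signatures):
        raise ValueError("signatures must be pairwise distinct")
    if not left_flank or not right_flank:
        raise ValueError("flanks must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # (barcode, dish) -> (n_cells, clone_id or spike marker, progeny_class)
    cell_counts = truth.sequenced_cell_counts()
    clone_of: dict[tuple[str, int], list] = {}
    repro = truth.cells[truth.cells["reprogrammed"]]
    for clone_id, dish, cls in zip(repro["clone_id"], repro["dish"], repro["progeny_class"]):
        for seq in truth.clone_barcodes[int(clone_id)]:
            clone_of.setdefault((seq, int(dish)), [int(clone_id), int(cls)])
    entries = []
    for (seq, dish), n_cells in sorted(cell_counts.items()):
        clone_id, cls = clone_of[(seq, dish)]
        entries.append((dish, seq, n_cells, str(clone_id), cls, False))
    for seq, dish, n_cells in sorted(truth.spike_ins):
        entries.append((dish, seq, n_cells, f"spike:{seq[:6]}", -1, True))
    entries.sort()

    manifest_rows = []
    reads_by_dish: dict[int, list[tuple[str, str, str]]] = {}
    for dish, seq, n_cells, clone_label, cls, is_spike in entries:
        factor = float(np.exp(rng.normal(0.0, model.pcr_sigma))) if model.pcr_sigma > 0 else 1.0
        n_reads = max(1, int(round(n_cells * model.mean_reads * factor)))
        barcodes = _mutate_reads(seq, n_reads, model, rng)
        sig = signatures[dish - 1]
        lowq = (
            rng.random(n_reads) < model.low_quality_read_fraction
            if model.low_quality_read_fraction > 0
            else np.zeros(n_reads, dtype=bool)
        )
        recs = reads_by_dish.setdefault(dish, [])
        for i, bc in enumerate(barcodes):
            bases = sig + left_flank + bc + right_flank
            q = model.low_quality_value if lowq[i] else model.quality
            qual = chr(33 + q) * len(bases)
            recs.append((f"d{dish}_{clone_label}_{len(recs)}", bases, qual))
        manifest_rows.append(
            {
                "clone_id": clone_label,
                "barcode_seq": seq,
                "dish": dish,
                "n_reads": n_reads,
                "reprogrammed": not is_spike,
                "progeny_class": cls,
                "spikein_flag": is_spike,
            }
        )

    manifest = pd.DataFrame(manifest_rows)
    manifest_path = out_dir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)

    paths = {"manifest": manifest_path}
    if multiplexed:
        path = out_dir / "reads.fastq"
        with open(path, "w") as fh:
            for dish in sorted(reads_by_dish):
                _write_fastq(fh, reads_by_dish[dish])
        paths["fastq"] = [path]
    else:
        paths["fastq"] = []
        for dish in sorted(reads_by_dish):
            path = out_dir / f"dish{dish}.fastq"
            with open(path, "w") as fh:
                _write_fastq(fh, reads_by_dish[dish])
            paths["fastq"].append(path)
    paths["manifest_frame"] = manifest
    return paths


def _write_fastq(fh, records):
    for rid, bases, qual in records:
        fh.write(f"@{rid}\n{bases}\n+\n{qual}\n")
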