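"""Stochastic model of the split-dish barcoding experiment.

The model follows the experiment step by step: seeding and infection of
fibroblasts (only cells that received at least one barcoded virus are
tracked), clonal expansion before factor induction, random splitting into
four dishes, loss of material, quota-driven reprogramming per dish, and
heritable reprogramming of sister cells.  Its output is the number of
barcodes shared between dishes — the signal that discriminates heritable
("deterministic") from stochastic reprogramming.

Cells are represented columnwise in numpy arrays; a clone is a founder cell
together with all of its progeny, which inherit every barcode integration of
the founder.  Barcodes are integer ids drawn uniformly from the viral
library, so barcode collisions between unrelated clones (a finite-diversity
artefact) arise naturally at small library sizes.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

#: Stand-in progeny-count distribution P(k), k = 0..8, for the pre-split
#: expansion window: most cells divide once or twice, a 15% minority
#: produces more than four progenies (fast-cycling cells).
DEFAULT_PROGENY_DIST = (0.05, 0.10, 0.35, 0.20, 0.15, 0.06, 0.05, 0.02, 0.02)

MAX_PROGENY = 8


def validate_progeny_dist(progeny_dist) -> np.ndarray:
    p = np.asarray(progeny_dist, dtype=float)
    if p.ndim != 1 or p.size < 1 or p.size > MAX_PROGENY + 1:
        raise ValueError(f"progeny distribution must cover k = 0..{MAX_PROGENY}")
    if np.any(p < 0):
        raise ValueError("progeny probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"progeny probabilities must sum to 1, got {p.sum()!r}")
    return p


@dataclass
class SimParams:
    """Parameters of one split-dish simulation.

    ``heritability`` is either a single probability applied to every sister
    of a reprogrammed cell, or a mapping from progeny class (number of
    progenies the founder produced) to a class-specific probability
    (proliferation-dependent heritability); classes absent from the mapping
    default to 0.

    ``dish_targets`` fixes the per-dish barcode quotas BA_1..BA_4 explicitly;
    otherwise the quotas are drawn from a Gaussian with mean ``mu`` and
    standard deviation ``si``, mirroring the dish-to-dish variation of
    observed barcode counts.
    """

    n_seeded: int
    moi: float
    diversity: int = 8_000_000
    progeny_dist: Sequence[float] = DEFAULT_PROGENY_DIST
    loss: float = 0.0
    heritability: float | Mapping[int, float] = 0.0
    mu: float | None = None
    si: float | None = None
    dish_targets: Sequence[int] | None = None
    n_dishes: int = 4
    n_replicates: int = 1
    single_integration: bool = False
    multi_integration_correction: bool = False

    def validate(self):
        if self.n_seeded < 1:
            raise ValueError("n_seeded must be positive")
        if self.moi <= 0:
            raise ValueError("MOI must be positive")
        if self.diversity < 1:
            raise ValueError("library diversity must be positive")
        validate_progeny_dist(self.progeny_dist)
        if not (0.0 <= self.loss < 1.0):
            raise ValueError("loss must be in [0, 1)")
        for h in self._heritability_values():
            if not (0.0 <= h <= 1.0):
                raise ValueError("heritability must be in [0, 1]")
        if self.dish_targets is not None:
            if len(self.dish_targets) != self.n_dishes:
                raise ValueError("dish_targets must give one quota per dish")
            if any(t < 0 for t in self.dish_targets):
                raise ValueError("dish_targets must be non-negative")
        elif self.mu is None or self.si is None:
            raise ValueError("either dish_targets or (mu, si) must be given")
        elif self.si < 0:
            raise ValueError("si must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        return self

    def _heritability_values(self):
        if isinstance(self.heritability, Mapping):
            return list(self.heritability.values())
        return [self.heritability]

    def heritability_for_class(self) -> np.ndarray:
        """Per-progeny-class heritability as an array indexed by class."""
        h = np.zeros(MAX_PROGENY + 1)
        if isinstance(self.heritability, Mapping):
            for k, v in self.heritability.items():
                h[int(k)] = v
        else:
            h[:] = self.heritability
        return h


@dataclass
class Population:
    """Columnwise cell table plus per-clone barcode storage.

    ``clone_barcodes``/``clone_offsets`` form a CSR layout: clone c carries
    barcode ids ``clone_barcodes[clone_offsets[c]:clone_offsets[c + 1]]``.
    All progeny of a clone share those ids.  ``dish`` is -1 before plating.
    """

    clone_barcodes: np.ndarray
    clone_offsets: np.ndarray
    cell_clone: np.ndarray
    cell_class: np.ndarray
    cell_dish: np.ndarray
    cell_repro: np.ndarray

    @property
    def n_clones(self) -> int:
        return self.clone_offsets.size - 1

    @property
    def n_cells(self) -> int:
        return self.cell_clone.size

    def cell_barcode_arrays(self, cell_index: np.ndarray):
        """Flattened barcode ids for the given cells, with the owning cell row.

        Returns ``(flat_barcodes, flat_cell_row)`` where ``flat_cell_row[t]``
        indexes into ``cell_index`` for flattened entry t; entries appear in
        cell order.
        """
        clones = self.cell_clone[cell_index]
        starts = self.clone_offsets[clones]
        counts = self.clone_offsets[clones + 1] - starts
        total = int(counts.sum())
        flat_rows = np.repeat(np.arange(cell_index.size), counts)
        # positions: starts repeated, plus within-cell offsets 0..k-1
        within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        flat_pos = np.repeat(starts, counts) + within
        return self.clone_barcodes[flat_pos], flat_rows


@dataclass
class OverlapCounts:
    """Barcode-sharing summary of one simulated experiment."""

    exactly: dict[int, int]  # k -> barcodes present in exactly k dishes
    per_dish_distinct: np.ndarray  # distinct barcodes among reprogrammed cells per dish
    contribution_exactly2: dict[int, int]  # progeny class -> exactly-2 barcodes
    dish_targets: np.ndarray  # the BA_i quotas used
    clamped: bool  # True if any quota was truncated by availability
    n_cells: int
    n_reprogrammed: int
    correction_factor: float = 1.0  # divide counts by this in corrected mode

    @property
    def shared(self) -> int:
        return sum(v for k, v in self.exactly.items() if k >= 2)

    @property
    def corrected_shared(self) -> float:
        return self.shared / self.correction_factor


def _zero_truncated_poisson(m: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Integration counts per infected cell: Poisson(m) conditioned on >= 1."""
    k = rng.poisson(m, size)
    zeros = np.flatnonzero(k == 0)
    while zeros.size:
        k[zeros] = rng.poisson(m, zeros.size)
        zeros = zeros[k[zeros] == 0]
    return k


def init_population(
    n_seeded: int,
    moi: float,
    diversity: int,
    rng: np.random.Generator,
    single_integration: bool = False,
) -> Population:
    """Seed, infect and barcode the starting cells.

    The number of tracked (barcode-carrying) cells is
    ``N0 = round(n_seeded * (1 - exp(-moi)))``; each carries a
    zero-truncated-Poisson(moi) number of integrations (or exactly one when
    ``single_integration``), each integration a uniform draw from the
    library.
    """
    if moi <= 0:
        raise ValueError("MOI must be positive")
    n0 = int(round(n_seeded * -np.expm1(-moi)))
    if n0 < 1:
        raise ValueError("no infected cells at these parameters (N0 = 0)")
    if single_integration:
        k_int = np.ones(n0, dtype=np.int64)
    else:
        k_int = _zero_truncated_poisson(moi, n0, rng)
    offsets = np.zeros(n0 + 1, dtype=np.int64)
    np.cumsum(k_int, out=offsets[1:])
    barcodes = rng.integers(0, diversity, size=offsets[-1], dtype=np.int64)
    return Population(
        clone_barcodes=barcodes,
        clone_offsets=offsets,
        cell_clone=np.arange(n0, dtype=np.int64),
        cell_class=np.full(n0, -1, dtype=np.int64),
        cell_dish=np.full(n0, -1, dtype=np.int64),
        cell_repro=np.zeros(n0, dtype=bool),
    )


def divide(pop: Population, progeny_dist, rng: np.random.Generator) -> Population:
    """Replace each founder by k progeny, k drawn from the progeny distribution.

    Progeny inherit every barcode of the founder; the drawn k is recorded as
    the progeny class of each of those cells.
    """
    p = validate_progeny_dist(progeny_dist)
    k = rng.choice(p.size, size=pop.n_clones, p=p)
    per_founder_k = k[pop.cell_clone]
    return replace(
        pop,
        cell_clone=np.repeat(pop.cell_clone, per_founder_k),
        cell_class=np.repeat(per_founder_k, per_founder_k).astype(np.int64),
        cell_dish=np.full(int(per_founder_k.sum()), -1, dtype=np.int64),
        cell_repro=np.zeros(int(per_founder_k.sum()), dtype=bool),
    )


def plate(pop: Population, rng: np.random.Generator, n_dishes: int = 4) -> Population:
    """Assign each cell an i.i.d. uniform dish label 1..n_dishes (stored 0-based)."""
    return replace(pop, cell_dish=rng.integers(0, n_dishes, size=pop.n_cells))


def cull(pop: Population, loss: float, rng: np.random.Generator) -> Population:
    """Loss of material: remove round(loss * size) uniformly chosen cells per dish."""
    if not (0.0 <= loss < 1.0):
        raise ValueError("loss must be in [0, 1)")
    if loss == 0.0:
        return pop
    keep = np.ones(pop.n_cells, dtype=bool)
    for d in np.unique(pop.cell_dish):
        members = np.flatnonzero(pop.cell_dish == d)
        n_drop = int(round(loss * members.size))
        if n_drop:
            keep[rng.choice(members, size=n_drop, replace=False)] = False
    return replace(
        pop,
        cell_clone=pop.cell_clone[keep],
        cell_class=pop.cell_class[keep],
        cell_dish=pop.cell_dish[keep],
        cell_repro=pop.cell_repro[keep],
    )


def _draw_dish_targets(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    if params.dish_targets is not None:
        return np.asarray(params.dish_targets, dtype=np.int64)
    ba = np.rint(rng.normal(params.mu, params.si, size=params.n_dishes)).astype(np.int64)
    return np.maximum(ba, 0)


def reprogram(
    pop: Population, params: SimParams, rng: np.random.Generator
) -> OverlapCounts:
    """Quota-driven reprogramming plus heritable sister reprogramming.

    Stage 1: in each dish, cells are drawn uniformly without replacement
    until at least BA_i distinct barcodes are represented among the dish's
    reprogrammed cells (quotas beyond the dish's available distinct barcodes
    are clamped and flagged).  Stage 2: every not-yet-reprogrammed sibling of
    a stage-1 cell, in any dish, is reprogrammed with the heritability
    probability of its progeny class.  Overlaps are then counted on the
    union of flags at the barcode level.
    """
    targets = _draw_dish_targets(params, rng)
    flags = pop.cell_repro.copy()
    clamped = False
    for d in range(params.n_dishes):
        members = np.flatnonzero(pop.cell_dish == d)
        ba = int(targets[d])
        if ba == 0:
            continue
        if members.size == 0:
            clamped = True
            continue
        perm = members[rng.permutation(members.size)]
        flat_bc, flat_row = pop.cell_barcode_arrays(perm)
        # distinct-barcode count after each draw, in draw order
        _, first_pos = np.unique(flat_bc, return_index=True)
        new_bc = np.zeros(flat_bc.size, dtype=np.int64)
        new_bc[first_pos] = 1
        cum_distinct = np.cumsum(new_bc)
        if cum_distinct[-1] < ba:
            clamped = True
            n_take = perm.size
        else:
            # last flattened entry per cell gives distinct count incl. that cell
            last_of_cell = np.flatnonzero(np.diff(np.append(flat_row, perm.size)))
            per_cell_distinct = cum_distinct[last_of_cell]
            n_take = int(np.searchsorted(per_cell_distinct, ba)) + 1
        flags[perm[:n_take]] = True

    # stage 2: heritable reprogramming of siblings
    h_by_class = params.heritability_for_class()
    stage1_clones = np.zeros(pop.n_clones, dtype=bool)
    stage1_clones[pop.cell_clone[flags]] = True
    siblings = np.flatnonzero(stage1_clones[pop.cell_clone] & ~flags)
    if siblings.size:
        h = h_by_class[pop.cell_class[siblings]]
        flags[siblings[rng.random(siblings.size) < h]] = True

    pop.cell_repro = flags
    return count_overlaps(pop, params, targets, clamped)


def count_overlaps(
    pop: Population, params: SimParams, targets: np.ndarray, clamped: bool
) -> OverlapCounts:
    """Count barcodes by the number of dishes they were recovered from."""
    repro = np.flatnonzero(pop.cell_repro)
    n_dishes = params.n_dishes
    exactly = {k: 0 for k in range(1, n_dishes + 1)}
    per_dish = np.zeros(n_dishes, dtype=np.int64)
    contribution2: dict[int, int] = {}
    if repro.size:
        flat_bc, flat_row = pop.cell_barcode_arrays(repro)
        dish = pop.cell_dish[repro][flat_row]
        cls = pop.cell_class[repro][flat_row]
        # unique (barcode, dish) pairs; keep a representative progeny class
        key = flat_bc * n_dishes + dish
        uniq_key, first = np.unique(key, return_index=True)
        u_bc = uniq_key // n_dishes
        u_dish = uniq_key % n_dishes
        u_cls = cls[first]
        per_dish = np.bincount(u_dish, minlength=n_dishes).astype(np.int64)
        bc_vals, bc_start, bc_ndish = np.unique(
            u_bc, return_index=True, return_counts=True
        )
        for k in range(1, n_dishes + 1):
            exactly[k] = int(np.sum(bc_ndish == k))
        two = np.flatnonzero(bc_ndish == 2)
        if two.size:
            classes = u_cls[bc_start[two]]
            vals, cnts = np.unique(classes, return_counts=True)
            contribution2 = {int(v): int(c) for v, c in zip(vals, cnts)}
    correction = 1.0
    if params.multi_integration_correction and not params.single_integration:
        correction = params.moi / -np.expm1(-params.moi)  # mean integrations per cell
    return OverlapCounts(
        exactly=exactly,
        per_dish_distinct=per_dish,
        contribution_exactly2=contribution2,
        dish_targets=targets,
        clamped=clamped,
        n_cells=pop.n_cells,
        n_reprogrammed=int(pop.cell_repro.sum()),
        correction_factor=correction,
    )


def simulate_once(params: SimParams, rng: np.random.Generator) -> OverlapCounts:
    """One full pass of the model: seed, divide, plate, cull, reprogram."""
    pop = init_population(
        params.n_seeded, params.moi, params.diversity, rng, params.single_integration
    )
    pop = divide(pop, params.progeny_dist, rng)
    pop = plate(pop, rng, params.n_dishes)
    pop = cull(pop, params.loss, rng)
    return reprogram(pop, params, rng)


@dataclass
class SimResult:
    params: SimParams
    replicates: list[OverlapCounts] = field(default_factory=list)

    @property
    def shared_counts(self) -> np.ndarray:
        return np.asarray([r.corrected_shared for r in self.replicates])

    def summary(self) -> dict:
        shared = self.shared_counts
        exactly = {
            k: float(np.mean([r.exactly.get(k, 0) for r in self.replicates]))
            for k in range(1, self.params.n_dishes + 1)
        }
        return {
            "n_replicates": len(self.replicates),
            "shared_median": float(np.median(shared)),
            "shared_mean": float(np.mean(shared)),
            "shared_std": float(np.std(shared, ddof=1)) if len(shared) > 1 else 0.0,
            "mean_exactly": exactly,
            "clamped_fraction": float(np.mean([r.clamped for r in self.replicates])),
        }


def run(params: SimParams, seed) -> SimResult:
    """Run ``params.n_replicates`` independent seeded replicates of the model."""
    params.validate()
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    result = SimResult(params=params)
    for child in ss.spawn(params.n_replicates):
        result.replicates.append(simulate_once(params, np.random.default_rng(child)))
    return result
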