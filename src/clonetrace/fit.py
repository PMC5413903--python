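"""Heritability estimation by grid search against the stochastic model.

For each loss-of-material value d and heritability level h on a grid, the
split-dish model is run repeatedly and the simulated numbers of shared
barcodes are compared with the observed number using a Kruskal-Wallis
rank test.  Heritability levels whose simulations are statistically
compatible with the observation (p >= alpha, i.e. the test fails to reject)
form the accepted set; the best-fit level is the accepted level whose
median simulated shared count lies closest to the observed value.

Because the observed shared count is a single number, the default
comparison uses an exact permutation p-value for the two-group
Kruskal-Wallis statistic with a singleton group (the chi-square
approximation is unreliable at n = 1); a joint mode comparing the
double/triple/quadruple overlap classes is available as well.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from . import sim
from .sim import OverlapCounts, SimParams

DEFAULT_D_GRID = tuple(np.round(np.arange(0.1, 0.91, 0.1), 10))
DEFAULT_H_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))


@dataclass(frozen=True)
class ObservedOverlaps:
    """Observed overlap counts and per-dish distinct-barcode counts."""

    exactly2: int
    exactly3: int
    exactly4: int
    per_dish_distinct: tuple[int, ...]

    def __post_init__(self):
        if min(self.exactly2, self.exactly3, self.exactly4) < 0:
            raise ValueError("overlap counts must be non-negative")
        if any(n < 0 for n in self.per_dish_distinct):
            raise ValueError("per-dish barcode counts must be non-negative")

    @property
    def shared(self) -> int:
        return self.exactly2 + self.exactly3 + self.exactly4

    @property
    def mu(self) -> float:
        return float(np.mean(self.per_dish_distinct))

    @property
    def si(self) -> float:
        return float(np.std(self.per_dish_distinct, ddof=1))

    @classmethod
    def from_overlap_counts(cls, counts: OverlapCounts) -> "ObservedOverlaps":
        return cls(
            exactly2=counts.exactly.get(2, 0),
            exactly3=counts.exactly.get(3, 0),
            exactly4=counts.exactly.get(4, 0),
            per_dish_distinct=tuple(int(n) for n in counts.per_dish_distinct),
        )

    @classmethod
    def from_overlap_table(cls, table) -> "ObservedOverlaps":
        return cls(
            exactly2=table.exactly.get(2, 0),
            exactly3=table.exactly.get(3, 0),
            exactly4=table.exactly.get(4, 0),
            per_dish_distinct=tuple(int(n) for n in table.per_dish_distinct),
        )


def _tie_correction(ranks: np.ndarray) -> float:
    n = ranks.size
    _, counts = np.unique(ranks, return_counts=True)
    return 1.0 - np.sum(counts**3 - counts) / (n**3 - n)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H and its chi-square p-value, with tie correction."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    n = pooled.size
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + a.size]
        h += r.sum() ** 2 / a.size
        start += a.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    h /= _tie_correction(ranks)
    p = float(sps.chi2.sf(h, len(arrays) - 1))
    return float(h), p


def kruskal_wallis_singleton_pvalue(values: Sequence[float], observed: float) -> float:
    """Exact permutation p for KW with one group of size 1.

    Pools the simulated ``values`` with the single ``observed`` value and
    computes, over all N+1 equally likely placements of the singleton label,
    the fraction with an H statistic at least as large as the realised one.
    """
    vals = np.append(np.asarray(values, dtype=float), float(observed))
    n = vals.size
    if n < 3:
        raise ValueError("need at least 2 simulated values")
    if np.all(vals == vals[0]):
        return 1.0
    ranks = sps.rankdata(vals)
    total = ranks.sum()
    # H as a function of the singleton's rank r (tie correction cancels in
    # the >= comparison but is kept for transparency)
    corr = _tie_correction(ranks)

    def h_of(r):
        h = 12.0 / (n * (n + 1)) * (r**2 + (total - r) ** 2 / (n - 1)) - 3.0 * (n + 1)
        return h / corr

    h_obs = h_of(ranks[-1])
    h_all = h_of(ranks)
    return float(np.mean(h_all >= h_obs - 1e-12))


def _classes_pvalue(replicates: list[OverlapCounts], observed: ObservedOverlaps) -> float:
    """Joint compatibility of the 2/3/4-dish overlap classes (Bonferroni min-p)."""
    ps = []
    for k, obs in ((2, observed.exactly2), (3, observed.exactly3), (4, observed.exactly4)):
        sim_vals = [r.exactly.get(k, 0) / r.correction_factor for r in replicates]
        ps.append(kruskal_wallis_singleton_pvalue(sim_vals, obs))
    return min(1.0, 3.0 * min(ps))


@dataclass
class DFit:
    """Fit summary at one loss-of-material value."""

    d: float
    accepted_h: list[float]
    best_h: float | None
    closest_h: float
    no_fit: bool

    @property
    def best_or_closest(self) -> float:
        """Best-fit level, falling back to the closest-median level at no-fit."""
        return self.best_h if self.best_h is not None else self.closest_h


@dataclass
class FitResult:
    """Grid-fit output across loss-of-material values."""

    table: pd.DataFrame
    per_d: dict[float, DFit]
    min_accepted_h: float | None
    observed: ObservedOverlaps | None = None

    @property
    def no_fit(self) -> bool:
        return all(f.no_fit for f in self.per_d.values())


class HeritabilityGridSearch(BaseEstimator):
    """Grid search for the sister-cell reprogramming heritability level.

    Parameters
    ----------
    base_params : SimParams
        Model parameters shared across the grid (seeding, MOI, diversity,
        progeny distribution).  ``loss``, ``heritability`` and the dish
        quotas are overridden per grid point; quotas are drawn from a
        Gaussian whose mu/si come from the observed per-dish barcode counts
        unless the base params fix ``dish_targets`` explicitly.
    d_grid, h_grid : sequences of floats
        Loss-of-material and heritability grids (defaults 0.1..0.9 and
        0..1, step 0.1).
    n_replicates : int, default 100
        Model executions per (d, h) grid point.
    alpha : float, default 0.05
        Significance level; compatibility means p >= alpha under the default
        fail-to-reject direction.
    compare : {"shared", "classes"}
        Compare simulated shared counts against the observed shared count,
        or the three overlap classes jointly.
    acceptance : {"fail_to_reject", "reject"}
        Direction of the acceptance rule (the alternative reading accepts
        p < alpha).
    random_state : int or None
        Seed for all simulations.

    Attributes
    ----------
    result_ : FitResult
    results_ : pandas.DataFrame
        One row per (d, h): median/mean simulated shared count, p-value,
        acceptance, clamped-quota fraction.
    best_h_by_d_ : dict
    min_accepted_h_ : float or None
    best_h_ : float or None
        Best-fit heritability of the grid cell with the overall smallest
        |median simulated - observed| among accepted cells.
    """

    def __init__(
        self,
        base_params: SimParams = None,
        d_grid: Sequence[float] = DEFAULT_D_GRID,
        h_grid: Sequence[float] = DEFAULT_H_GRID,
        n_replicates: int = 100,
        alpha: float = 0.05,
        compare: str = "shared",
        acceptance: str = "fail_to_reject",
        random_state=None,
    ):
        self.base_params = base_params
        self.d_grid = d_grid
        self.h_grid = h_grid
        self.n_replicates = n_replicates
        self.alpha = alpha
        self.compare = compare
        self.acceptance = acceptance
        self.random_state = random_state

    def fit(self, X: ObservedOverlaps, y=None):
        observed = X
        if self.base_params is None:
            raise ValueError("base_params is required")
        if self.compare not in ("shared", "classes"):
            raise ValueError("compare must be 'shared' or 'classes'")
        if self.acceptance not in ("fail_to_reject", "reject"):
            raise ValueError("acceptance must be 'fail_to_reject' or 'reject'")
        if not isinstance(observed, ObservedOverlaps):
            raise TypeError("fit expects an ObservedOverlaps instance")

        base = self.base_params
        if base.dish_targets is None:
            base = replace(base, mu=observed.mu, si=observed.si)
        ss = np.random.SeedSequence(self.random_state)
        rows = []
        per_d: dict[float, DFit] = {}
        d_grid = [float(d) for d in self.d_grid]
        h_grid = [float(h) for h in self.h_grid]
        children = iter(ss.spawn(len(d_grid) * len(h_grid)))
        for d in d_grid:
            d_rows = []
            for h in h_grid:
                params = replace(
                    base, loss=d, heritability=h, n_replicates=self.n_replicates
                )
                res = sim.run(params, next(children))
                shared = res.shared_counts
                if self.compare == "shared":
                    p = kruskal_wallis_singleton_pvalue(shared, observed.shared)
                else:
                    p = _classes_pvalue(res.replicates, observed)
                accepted = (p >= self.alpha) == (self.acceptance == "fail_to_reject")
                clamped = float(np.mean([r.clamped for r in res.replicates]))
                row = {
                    "d": d,
                    "h": h,
                    "median_shared": float(np.median(shared)),
                    "mean_shared": float(np.mean(shared)),
                    "p_value": p,
                    "accepted": bool(accepted),
                    "clamped_fraction": clamped,
                    "infeasible": clamped > 0.5,
                }
                rows.append(row)
                d_rows.append(row)
            dev = [abs(r["median_shared"] - observed.shared) for r in d_rows]
            closest_h = h_grid[int(np.argmin(dev))]
            acc = [r["h"] for r in d_rows if r["accepted"]]
            if acc:
                acc_dev = [(abs(r["median_shared"] - observed.shared), r["h"])
                           for r in d_rows if r["accepted"]]
                best_h = min(acc_dev)[1]
            else:
                best_h = None
            per_d[d] = DFit(
                d=d, accepted_h=acc, best_h=best_h, closest_h=closest_h,
                no_fit=not acc,
            )
        table = pd.DataFrame(rows)
        accepted_rows = table[table["accepted"]]
        min_accepted = float(accepted_rows["h"].min()) if len(accepted_rows) else None
        self.result_ = FitResult(
            table=table, per_d=per_d, min_accepted_h=min_accepted, observed=observed
        )
        self.results_ = table
        self.best_h_by_d_ = {d: f.best_h for d, f in per_d.items()}
        self.min_accepted_h_ = min_accepted
        if len(accepted_rows):
            dev = (accepted_rows["median_shared"] - observed.shared).abs()
            order = accepted_rows.assign(dev=dev).sort_values(["dev", "h"])
            self.best_h_ = float(order.iloc[0]["h"])
        else:
            self.best_h_ = None
        return self


def grid_fit(
    observed: ObservedOverlaps,
    base_params: SimParams,
    d_grid: Sequence[float] = DEFAULT_D_GRID,
    h_grid: Sequence[float] = DEFAULT_H_GRID,
    n_replicates: int = 100,
    alpha: float = 0.05,
    seed=None,
    compare: str = "shared",
    acceptance: str = "fail_to_reject",
) -> FitResult:
    """Functional wrapper over :class:`HeritabilityGridSearch`."""
    est = HeritabilityGridSearch(
        base_params=base_params,
        d_grid=d_grid,
        h_grid=h_grid,
        n_replicates=n_replicates,
        alpha=alpha,
        compare=compare,
        acceptance=acceptance,
        random_state=seed,
    )
    est.fit(observed)
    return est.result_


def contribution_report(replicates: Sequence[OverlapCounts]) -> pd.Series:
    """Mean share of double overlaps contributed by each progeny class.

    Per replicate, the exactly-2 overlap counts attributed to each progeny
    class are normalized to shares summing to 1 (replicates with no double
    overlap are skipped); the mean share per class is returned.
    """
    shares: dict[int, list[float]] = {}
    n_used = 0
    for rep in replicates:
        total = sum(rep.contribution_exactly2.values())
        if total == 0:
            continue
        n_used += 1
        for k, v in rep.contribution_exactly2.items():
            shares.setdefault(k, []).append(v / total)
    if n_used == 0:
        return pd.Series(dtype=float, name="mean_share")
    out = {
        k: float(np.sum(v) / n_used) for k, v in sorted(shares.items())
    }
    return pd.Series(out, name="mean_share")
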