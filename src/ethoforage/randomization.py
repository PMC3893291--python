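"""Duration-resampling randomization test for diel dependence of time budgets.

The null hypothesis is that individuals allocate time to each activity
identically across diel bins.  Holding the observed number of bouts of each
activity in each bin fixed, every replicate redraws those bout durations with
replacement from the activity's population-level duration pool (all observed
durations of that activity, pooled across bins and individuals) and
recomputes, within each bin, the proportion of resampled time spent on each
activity.  R replicates (default 10,000) form the null distribution per cell.

Two-sided p-values count replicates at least as far from the null median as
the observed proportion, divided by R — an inclusive comparison with no +1
correction, so p = 0 is representable.

Each bout is assigned, whole, to the diel bin containing its start time, so
the observed statistic is computed from the same kind of whole-duration sums
as the null replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

from ethoforage._seeds import substream
from ethoforage.ethogram import BehaviorBout, BehaviorCategory, DielBin, assign_diel_bin

_BINS = tuple(DielBin)
_CATEGORIES = tuple(BehaviorCategory)


class EmptyPoolError(ValueError):
    """A cell has observed bouts but its activity's duration pool is empty."""


@dataclass(frozen=True)
class DurationPool:
    """All observed bout durations (seconds) of one activity, pooled."""

    activity: BehaviorCategory
    durations: np.ndarray

    def __len__(self) -> int:
        return len(self.durations)


@dataclass(frozen=True)
class RandTestResult:
    """One activity-by-bin cell of the randomization test."""

    diel_bin: DielBin
    activity: BehaviorCategory
    n_bouts: int
    observed_proportion: float
    null_median: float
    p_value: float
    n_replicates: int
    rng_seed: int


def build_duration_pools(
    bouts: Iterable[BehaviorBout],
) -> dict[BehaviorCategory, DurationPool]:
    """Partition observed bout durations into per-activity pools.

    Every bout's duration lands in exactly one pool (its activity's), so pool
    sizes sum to the number of bouts.  Activities with no observed bouts get
    an empty pool.
    """
    raw: dict[BehaviorCategory, list[int]] = {cat: [] for cat in _CATEGORIES}
    for b in bouts:
        raw[b.activity].append(b.duration_s)
    return {
        cat: DurationPool(activity=cat, durations=np.asarray(durs, dtype=float))
        for cat, durs in raw.items()
    }


def observed_cells(bouts: Iterable[BehaviorBout]) -> pd.DataFrame:
    """Observed per-cell bout counts, total seconds and within-bin proportions.

    Bouts are assigned whole to the bin of their start time.  Bins with no
    recorded time have NaN proportions.
    """
    counts = {(b_, c): 0 for b_ in _BINS for c in _CATEGORIES}
    seconds = {(b_, c): 0.0 for b_ in _BINS for c in _CATEGORIES}
    for bout in bouts:
        cell = (assign_diel_bin(bout.start), bout.activity)
        counts[cell] += 1
        seconds[cell] += bout.duration_s
    rows = []
    for bin_ in _BINS:
        total = sum(seconds[(bin_, c)] for c in _CATEGORIES)
        for cat in _CATEGORIES:
            rows.append(
                {
                    "diel_bin": bin_,
                    "activity": cat,
                    "n_bouts": counts[(bin_, cat)],
                    "seconds": seconds[(bin_, cat)],
                    "observed": seconds[(bin_, cat)] / total if total > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def simulate_null(
    counts: Mapping[tuple[DielBin, BehaviorCategory], int],
    pools: Mapping[BehaviorCategory, DurationPool],
    R: int,
    seed: Union[int, np.random.Generator],
) -> dict[tuple[DielBin, BehaviorCategory], np.ndarray]:
    """Build per-cell null distributions of within-bin time proportions.

    One shared replicate stream is used: in each replicate every cell with
    ``n > 0`` draws ``n`` durations with replacement from its activity's
    pool, and proportions are renormalized by the replicate's own total bin
    time, so cells of one bin are compositionally consistent (they sum to one
    replicate-wise).
    """
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    out: dict[tuple[DielBin, BehaviorCategory], np.ndarray] = {}
    for bin_ in _BINS:
        sums = np.zeros((R, len(_CATEGORIES)))
        for j, cat in enumerate(_CATEGORIES):
            n = int(counts.get((bin_, cat), 0))
            if n == 0:
                continue
            pool = pools.get(cat)
            if pool is None or len(pool) == 0:
                raise EmptyPoolError(
                    f"cell ({bin_.value}, {cat.value}) has {n} bouts but the "
                    f"{cat.value} duration pool is empty"
                )
            draws = rng.choice(pool.durations, size=(R, n), replace=True)
            sums[:, j] = draws.sum(axis=1)
        totals = sums.sum(axis=1)
        with np.errstate(invalid="ignore"):
            props = np.where(totals[:, None] > 0, sums / np.where(totals == 0, 1.0, totals)[:, None], 0.0)
        for j, cat in enumerate(_CATEGORIES):
            out[(bin_, cat)] = props[:, j]
    return out


def permutation_pvalue(observed: float, null: np.ndarray) -> float:
    """Two-sided p-value against the null distribution's median.

    ``p = #{i : |null_i - m| >= |observed - m|} / R`` with ``m`` the null
    median; the comparison is inclusive and there is no +1 correction, so an
    observation farther from the median than every replicate yields p = 0 and
    an observation at the median yields p = 1.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    m = float(np.median(null))
    d_obs = abs(observed - m)
    # tolerance keeps the comparison inclusive for mathematically tied
    # deviations computed along different floating-point paths
    tie_tol = 1e-12 * (1.0 + d_obs)
    return float(np.count_nonzero(np.abs(null - m) >= d_obs - tie_tol) / null.size)


def run_activity_randtest(
    bouts: Iterable[BehaviorBout],
    R: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    pool_scope: str = "activity",
) -> pd.DataFrame:
    """Run the full 6-activity x 4-bin randomization test.

    Returns a long-format table with one row per cell: observed proportion,
    null median, two-sided p-value, replicate count, seed and a significance
    flag at ``alpha``.  ``pool_scope="global"`` resamples every cell from one
    pool of all durations regardless of activity (a sensitivity variant);
    the default resamples each activity from its own pool.

    Cells in bins with no recorded time have NaN observed proportions and
    p-values.  Identical ``(bouts, R, seed)`` give identical results.
    """
    bouts = list(bouts)
    if not bouts:
        raise ValueError("no bouts supplied")
    if pool_scope not in ("activity", "global"):
        raise ValueError(f"pool_scope must be 'activity' or 'global', got {pool_scope!r}")

    obs = observed_cells(bouts)
    pools = build_duration_pools(bouts)
    if pool_scope == "global":
        everything = np.concatenate([p.durations for p in pools.values() if len(p)])
        pools = {cat: DurationPool(cat, everything) for cat in _CATEGORIES}

    counts = {
        (row.diel_bin, row.activity): int(row.n_bouts) for row in obs.itertuples(index=False)
    }
    rng = substream(seed, "randtest")
    null = simulate_null(counts, pools, R, rng)

    rows = []
    for row in obs.itertuples(index=False):
        cell = (row.diel_bin, row.activity)
        dist = null[cell]
        if np.isnan(row.observed):
            median, p = np.nan, np.nan
        else:
            median = float(np.median(dist))
            p = permutation_pvalue(row.observed, dist)
        rows.append(
            {
                "diel_bin": row.diel_bin.value,
                "activity": row.activity.value,
                "n_bouts": row.n_bouts,
                "observed": row.observed,
                "null_median": median,
                "p_value": p,
                "R": R,
                "seed": seed,
                "significant": bool(p < alpha) if not np.isnan(p) else False,
            }
        )
    return pd.DataFrame(rows)


def pvalue_grid(results: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-format results into the bins-by-activities p-value grid."""
    grid = results.pivot(index="diel_bin", columns="activity", values="p_value")
    grid = grid.reindex(index=[b.value for b in _BINS], columns=[c.value for c in _CATEGORIES])
    grid.index.name = "diel_bin"
    return grid
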