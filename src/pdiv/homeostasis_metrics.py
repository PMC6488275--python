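"""Quantifying cell-size homeostasis from completed division cycles.

The Fantes plot regresses length extension (division size minus birth size)
on birth size; its slope separates the classical control modes: a perfect
sizer gives -1, an adder 0, and a timer the positive value e**(g*T) - 1.
The coefficient of variation of division size measures size fidelity, and
:func:`sweep_grid` maps both metrics (plus mean division size) over a grid of
Hill-curve EC50 and coefficient values for the probabilistic rule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .simulator import (DivisionRecord, HillCurve, SimulationConfig,
                        default_config, run_simulation_arrays)

__all__ = [
    "FantesFit",
    "SweepResult",
    "DistributionSummary",
    "fantes_fit",
    "division_cov",
    "sweep_grid",
    "distribution_summary",
]

RecordsLike = Union[Sequence[DivisionRecord], pd.DataFrame, dict]


def _records_arrays(records: RecordsLike):
    """Birth-size / division-size columns from any record container."""
    if isinstance(records, pd.DataFrame):
        return (np.asarray(records["birth_size"], dtype=float),
                np.asarray(records["division_size"], dtype=float))
    if isinstance(records, dict):
        return (np.asarray(records["birth_size"], dtype=float),
                np.asarray(records["division_size"], dtype=float))
    return (np.asarray([r.birth_size for r in records], dtype=float),
            np.asarray([r.division_size for r in records], dtype=float))


@dataclass(frozen=True)
class FantesFit:
    """OLS regression of extension on birth size over completed cycles."""

    slope: float
    intercept: float
    r: float
    n_records: int


def fantes_fit(records: RecordsLike) -> FantesFit:
    """Fantes-plot regression: extension = slope * birth_size + intercept."""
    birth, division = _records_arrays(records)
    if birth.size < 3:
        raise ValueError("need at least 3 completed cycles")
    if np.ptp(birth) == 0.0:
        raise ValueError("birth sizes have zero variance")
    res = stats.linregress(birth, division - birth)
    return FantesFit(slope=float(res.slope), intercept=float(res.intercept),
                     r=float(res.rvalue), n_records=int(birth.size))


def division_cov(records: RecordsLike) -> float:
    """Sample CoV (SD/mean, ddof=1) of size at division."""
    _, division = _records_arrays(records)
    if division.size < 2:
        raise ValueError("need at least 2 completed cycles")
    mean = division.mean()
    if mean <= 0.0:
        raise ValueError("mean division size must be > 0")
    return float(division.std(ddof=1) / mean)


@dataclass
class DistributionSummary:
    """Box-and-whisker summary: quartiles, whiskers, outliers.

    Quartiles use linear interpolation.  Each whisker extends from its box
    edge by the distance to the furthest point on that side or by 1.5x the
    interquartile range, whichever is smaller; points beyond the whiskers are
    listed as outliers.
    """

    q25: float
    median: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def distribution_summary(values) -> DistributionSummary:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    iqr = q75 - q25
    lo = q25 - min(q25 - v.min(), 1.5 * iqr)
    hi = q75 + min(v.max() - q75, 1.5 * iqr)
    out = v[(v < lo) | (v > hi)]
    return DistributionSummary(q25=float(q25), median=float(med),
                               q75=float(q75), whisker_low=float(lo),
                               whisker_high=float(hi), outliers=out)


@dataclass
class SweepResult:
    """Replicate-averaged homeostasis metrics over an (EC50, n) grid.

    Matrices are indexed ``[i_ec50, j_n]``; entries are NaN where every
    replicate of that grid cell failed.
    """

    ec50_grid: np.ndarray
    n_grid: np.ndarray
    mean_size: np.ndarray
    cov: np.ndarray
    fantes_slope: np.ndarray
    reps: int
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, ec50 in enumerate(self.ec50_grid):
            for j, n in enumerate(self.n_grid):
                rows.append({"ec50": ec50, "n": n,
                             "mean_size": self.mean_size[i, j],
                             "cov": self.cov[i, j],
                             "fantes_slope": self.fantes_slope[i, j],
                             "reps": self.reps})
        return pd.DataFrame(rows)


def _cell_seed(seed: int, i: int, j: int, r: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(i), int(j), int(r)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] >> 1)


def sweep_grid(base_config: Optional[SimulationConfig] = None,
               ec50_values: Optional[Sequence[float]] = None,
               n_values: Optional[Sequence[float]] = None,
               reps: int = 3,
               seed: Optional[int] = None) -> SweepResult:
    """Run the probabilistic-rule simulation over an EC50 x Hill-coefficient
    grid and collect replicate-mean division-size mean, CoV and Fantes slope.

    Every grid cell / replicate gets its own reproducibly derived seed.
    Failures inside a single cell are recorded as NaN without aborting the
    sweep.  Defaults: EC50 8..20 step 1, n 2..30 step 2, 3 replicates.
    """
    if base_config is None:
        base_config = default_config("pdiv")
    if base_config.rule != "pdiv":
        raise ValueError("sweep_grid sweeps the pdiv rule; got "
                         f"{base_config.rule!r}")
    ec50_grid = np.asarray(
        ec50_values if ec50_values is not None else np.arange(8.0, 21.0, 1.0),
        dtype=float)
    n_grid = np.asarray(
        n_values if n_values is not None else np.arange(2.0, 31.0, 2.0),
        dtype=float)
    if ec50_grid.size == 0 or n_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if seed is None:
        seed = base_config.seed
    pmax = base_config.rule_params.pmax
    shape = (ec50_grid.size, n_grid.size)
    mean_size = np.full(shape, np.nan)
    cov = np.full(shape, np.nan)
    slope = np.full(shape, np.nan)
    for i, ec50 in enumerate(ec50_grid):
        for j, n in enumerate(n_grid):
            means, covs, slopes = [], [], []
            for r in range(reps):
                try:
                    cfg = replace(base_config,
                                  rule_params=HillCurve(pmax, float(ec50),
                                                        float(n)),
                                  seed=_cell_seed(seed, i, j, r))
                    rec = run_simulation_arrays(cfg)
                    means.append(rec["division_size"].mean())
                    covs.append(division_cov(rec))
                    slopes.append(fantes_fit(rec).slope)
                except ValueError:
                    continue
            if means:
                mean_size[i, j] = np.mean(means)
                cov[i, j] = np.mean(covs)
                slope[i, j] = np.mean(slopes)
    return SweepResult(ec50_grid=ec50_grid, n_grid=n_grid,
                       mean_size=mean_size, cov=cov, fantes_slope=slope,
                       reps=int(reps), seed=int(seed))
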