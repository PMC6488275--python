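"""Synthetic per-cell cytometry tables with the structure the analyses assume.

Two generators, both driven by the population simulator so that the
statistical structure (steady-state size distribution, size-dependent
septation occupancy, size-correlated noisy cyclin expression) is emergent
rather than prescribed:

* :func:`synth_snapshot` -- a dividing steady-state population under the
  probabilistic size rule with a finite septation period, yielding
  (size, septated) rows whose binned septated fraction follows the renewal
  occupancy of the underlying Hill hazard.
* :func:`synth_cyclin_table` / :func:`synth_cyclin_pair` -- the shift-up
  design: a cyclin-threshold population sampled while dividing (permissive)
  and again after division has been blocked for a while so cyclin keeps
  accumulating (restrictive).  Measured fluorescence is the cyclin statistic
  under multiplicative lognormal measurement noise.

Tables use the cytometry schema: cell_id, size, septated, fluor, condition.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .simulator import (Cdc13Params, HillCurve, SimulationConfig,
                        SimulationEngine, PopulationSnapshot, snapshot_series)

__all__ = [
    "SynthConfig",
    "synth_snapshot",
    "synth_cyclin_table",
    "synth_cyclin_pair",
    "add_measurement_noise",
]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generators.

    ``expression_noise_cv`` is the lognormal coefficient of variation of the
    measured fluorescence around the true cyclin statistic (unit-mean noise);
    ``restrictive_extra_minutes`` is how long division stays blocked before
    the restrictive-condition sample is taken.  ``burn_in_cycles`` mean cycle
    times elapse before any sampling so the population is at steady state.

    The default cyclin rule is size-proportional synthesis with an *amount*
    threshold of 79 AU (sd 4, i.e. the same 5% relative noise as the
    published 6 +/- 0.3 constants): with synthesis 0.07*size/min the
    accumulated amount reads out current size, division triggers when that
    size readout crosses the threshold, and the steady-state birth size is
    ~7 length units.  This is the only reading of the accumulation model
    with a size-homeostatic steady state to sample from -- under a
    concentration threshold the dynamics dC/dt = 0.07 - g*C are
    size-independent, making the rule a timer whose sizes random-walk.
    """

    n_cells: int = 5000
    hill: HillCurve = field(default_factory=HillCurve)
    septation_duration: float = 30.0
    growth_rate: float = 0.006
    cyclin: Cdc13Params = field(default_factory=lambda: Cdc13Params(
        threshold_mean=79.0, threshold_sd=4.0, threshold_mode="amount"))
    expression_noise_cv: float = 0.05
    condition: str = "permissive"
    restrictive_extra_minutes: float = 35.0
    seed: int = 0
    n_init: int = 200
    burn_in_cycles: float = 5.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.expression_noise_cv < 0.0:
            raise ValueError("expression_noise_cv must be >= 0")
        if self.condition not in ("permissive", "restrictive"):
            raise ValueError(f"unknown condition {self.condition!r}")


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1, dtype=np.uint32)[0] >> 1)


def _mean_cycle_minutes(growth_rate: float, daughter_factor: float = 1.05) -> float:
    # time for a daughter (daughter_factor/2 of the division size) to regrow
    return math.log(2.0 / daughter_factor) / math.log(1.0 + growth_rate)


def _lognormal_noise(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0.0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=math.sqrt(sigma2), size=n)


def _sample_rows(rng: np.random.Generator, pool_size: np.ndarray,
                 pool_sept: np.ndarray, pool_cyclin: np.ndarray,
                 n_cells: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    total = pool_size.size
    replace = total < n_cells
    idx = rng.choice(total, size=n_cells, replace=replace)
    return pool_size[idx], pool_sept[idx], pool_cyclin[idx]


def synth_snapshot(config: SynthConfig) -> pd.DataFrame:
    """Steady-state (size, septated) snapshot table under the Hill hazard.

    The simulator runs with the configured septation duration for
    ``burn_in_cycles`` mean cycle times plus a 100-minute sampling window;
    rows are drawn from the pooled late snapshots (without replacement when
    the pool allows).  Fluorescence is not modelled here and is written as 0.
    """
    if config.hill.pmax <= 0.0:
        raise ValueError("hill.pmax must be > 0 for a dividing population")
    cycle = _mean_cycle_minutes(config.growth_rate)
    burn_in = math.ceil(config.burn_in_cycles * cycle)
    window = 100.0
    sim = SimulationConfig(
        rule="pdiv", rule_params=config.hill, growth_rate=config.growth_rate,
        septation_duration=config.septation_duration, n_init=config.n_init,
        init_mean=config.hill.ec50, init_sd=0.1 * config.hill.ec50,
        t_max=burn_in + window, seed=_stage_seed(config.seed, "synth_snapshot"))
    snaps = snapshot_series(sim, sample_interval=10.0)
    late = [s for s in snaps if s.time >= burn_in]
    size = np.concatenate([s.sizes for s in late])
    sept = np.concatenate([s.septated for s in late])
    cyc = np.concatenate([s.cyclin_amounts for s in late])
    rng = np.random.default_rng(_stage_seed(config.seed, "synth_snapshot/sample"))
    size, sept, cyc = _sample_rows(rng, size, sept, cyc, config.n_cells)
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(config.n_cells)],
        "size": size,
        "septated": sept.astype(bool),
        "fluor": np.zeros(config.n_cells),
        "condition": config.condition,
    })


def _cyclin_fluor(params: Cdc13Params, size: np.ndarray,
                  cyclin: np.ndarray) -> np.ndarray:
    if params.threshold_mode == "concentration":
        return cyclin / size
    return cyclin.copy()


def _run_cyclin(config: SynthConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """One shift-up experiment: permissive pool, then blocked continuation."""
    cycle = _mean_cycle_minutes(config.growth_rate)
    burn_in = math.ceil(config.burn_in_cycles * cycle)
    sim = SimulationConfig(
        rule="cdc13", rule_params=config.cyclin,
        growth_rate=config.growth_rate,
        septation_duration=config.septation_duration,
        n_init=config.n_init, init_mean=7.0, init_sd=0.7,
        t_max=burn_in + config.restrictive_extra_minutes,
        seed=_stage_seed(config.seed, "synth_cyclin"))
    engine = SimulationEngine(sim)
    engine.run(burn_in)
    # one imaging time point for the dividing culture
    perm_snap = engine.snapshot()
    # shift-up: no new division triggers; septated cells complete their split
    engine.division_enabled = False
    engine.run(config.restrictive_extra_minutes)
    rest_snap = engine.snapshot()

    rng = np.random.default_rng(_stage_seed(config.seed, "synth_cyclin/sample"))
    p_size, p_sept, p_cyc = _sample_rows(rng, perm_snap.sizes,
                                         perm_snap.septated,
                                         perm_snap.cyclin_amounts,
                                         config.n_cells)
    r_size, r_sept, r_cyc = _sample_rows(rng, rest_snap.sizes,
                                         rest_snap.septated,
                                         rest_snap.cyclin_amounts,
                                         config.n_cells)

    def table(size, sept, cyc, condition, tag):
        fluor = _cyclin_fluor(config.cyclin, size, cyc)
        fluor = fluor * _lognormal_noise(rng, config.expression_noise_cv,
                                         fluor.size)
        return pd.DataFrame({
            "cell_id": [f"{tag}{i}" for i in range(size.size)],
            "size": size,
            "septated": sept.astype(bool),
            "fluor": fluor,
            "condition": condition,
        })

    return (table(p_size, p_sept, p_cyc, "permissive", "p"),
            table(r_size, r_sept, r_cyc, "restrictive", "r"))


def synth_cyclin_pair(config: SynthConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Matched (permissive, restrictive) tables from one simulated shift-up."""
    return _run_cyclin(config)


def synth_cyclin_table(config: SynthConfig) -> pd.DataFrame:
    """The table for ``config.condition`` from the simulated shift-up.

    Deterministic per seed: requesting the two conditions separately with the
    same seed yields the same matched pair as :func:`synth_cyclin_pair`.
    """
    perm, rest = _run_cyclin(config)
    return perm if config.condition == "permissive" else rest


def add_measurement_noise(table: pd.DataFrame, cv: float,
                          seed: Optional[int] = None,
                          rng: Optional[np.random.Generator] = None
                          ) -> pd.DataFrame:
    """Multiply fluorescence by i.i.d. unit-mean lognormal noise of the given
    CV; sizes and flags are untouched."""
    if cv < 0.0:
        raise ValueError("cv must be >= 0")
    out = table.copy()
    if cv == 0.0:
        return out
    if rng is None:
        rng = np.random.default_rng(seed)
    out["fluor"] = np.asarray(out["fluor"], dtype=float) * _lognormal_noise(
        rng, cv, len(out))
    return out
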