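"""Agent-based simulation of cell growth and division in fission yeast.

Discrete-time (1-minute step) population model in which every cell elongates
exponentially and divides according to one of five pluggable control rules:

``sizer``
    divide once current size reaches a per-cell threshold drawn at birth.
``adder``
    divide once the size added since birth reaches a per-cell threshold.
``timer``
    divide once the age reaches a per-cell threshold.
``pdiv``
    each minute, divide with a probability read off a Hill dose-response of
    current size (the probabilistic size-control model).
``cdc13``
    accumulate a noisy cyclin (Cdc13) amount each minute and divide once the
    cyclin statistic (amount or concentration) reaches a per-cell threshold.

Division may optionally pass through a non-elongating septated phase of fixed
duration before the cell splits into two daughters sized
``daughter_factor * division_size / 2 ± N(0, asymmetry_sd)``.

The module exposes both single-cell operations (:func:`grow_step`,
:func:`division_decision`, :func:`cdc13_update`, :func:`divide`) operating on
:class:`CellState`, and a vectorised population engine used by
:func:`run_simulation` and :func:`snapshot_series`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "RULES",
    "HillCurve",
    "AdderParams",
    "SizerParams",
    "TimerParams",
    "Cdc13Params",
    "CellState",
    "DivisionRecord",
    "PopulationSnapshot",
    "SimulationConfig",
    "SimulationEngine",
    "default_config",
    "hill_eval",
    "grow_step",
    "division_decision",
    "cdc13_update",
    "divide",
    "init_population",
    "run_simulation",
    "run_simulation_arrays",
    "snapshot_series",
    "records_to_dataframe",
]

RULES = ("adder", "sizer", "timer", "pdiv", "cdc13")

GROWING = "growing"
SEPTATED = "septated"


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HillCurve:
    """Hill dose-response from cell size to a per-step division probability.

    ``eval(size) = pmax * size**n / (ec50**n + size**n)``; half-maximal at
    ``ec50``, saturating at ``pmax`` (a probability per time step, so bounded
    by 1), with ultrasensitivity exponent ``n``.  ``pmax = 0`` is admitted as
    the degenerate never-dividing limit.
    """

    pmax: float = 0.1
    ec50: float = 14.0
    n: float = 14.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pmax <= 1.0):
            raise ValueError(f"pmax must be in [0, 1], got {self.pmax}")
        if self.ec50 <= 0.0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if self.n <= 0.0:
            raise ValueError(f"n must be > 0, got {self.n}")

    def __call__(self, size):
        return hill_eval(self, size)


def hill_eval(curve: HillCurve, size):
    """Evaluate a :class:`HillCurve` at one or many sizes.

    Uses the overflow-safe form ``pmax / (1 + (ec50/size)**n)``; ``size == 0``
    maps to 0 and negative sizes are rejected.
    """
    arr = np.asarray(size, dtype=float)
    if np.any(arr < 0.0):
        raise ValueError("size must be non-negative")
    out = np.zeros_like(arr)
    pos = arr > 0.0
    with np.errstate(over="ignore"):
        ratio = np.power(curve.ec50 / arr[pos], curve.n)
    out[pos] = curve.pmax / (1.0 + ratio)
    if np.isscalar(size) or arr.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class AdderParams:
    """Gaussian per-cell added-size threshold (length units)."""

    mean: float = 6.75
    sd: float = 1.0


@dataclass(frozen=True)
class SizerParams:
    """Gaussian per-cell target division size (length units)."""

    mean: float = 14.5
    sd: float = 1.2


@dataclass(frozen=True)
class TimerParams:
    """Gaussian per-cell target cycle duration (minutes)."""

    mean: float = 100.0
    sd: float = 5.0


@dataclass(frozen=True)
class Cdc13Params:
    """Cyclin (Cdc13) accumulation-to-threshold rule parameters.

    Per minute a growing cell gains ``synthesis_rate`` cyclin units plus
    Gaussian synthesis noise of sd ``synthesis_noise_sd``, and loses
    ``degradation_rate``; in ``size_proportional`` mode both the rate and the
    noise sd scale with current size (the synthesis machinery, noise
    included, scales with cell mass).  ``basal_synthesis_rate`` is an
    optional size-independent synthesis component added in either mode
    (a purely time-dependent accumulation term).  Division triggers when the
    cyclin statistic -- the raw amount, or the concentration amount/size --
    reaches a per-cell Gaussian threshold drawn at birth.  Daughters start
    with ``birth_level_factor * birth_size`` cyclin units.
    """

    synthesis_rate: float = 0.07
    synthesis_noise_sd: float = 0.05
    degradation_rate: float = 0.0001
    threshold_mean: float = 6.0
    threshold_sd: float = 0.3
    birth_level_factor: float = 0.7
    synthesis_mode: str = "size_proportional"
    threshold_mode: str = "concentration"
    basal_synthesis_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("synthesis_rate", "synthesis_noise_sd", "degradation_rate",
                     "threshold_sd", "birth_level_factor",
                     "basal_synthesis_rate"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")
        if self.threshold_mean <= 0.0:
            raise ValueError("threshold_mean must be > 0")
        if self.synthesis_mode not in ("absolute", "size_proportional"):
            raise ValueError(f"unknown synthesis_mode {self.synthesis_mode!r}")
        if self.threshold_mode not in ("amount", "concentration"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")


_DEFAULT_PARAMS = {
    "adder": AdderParams,
    "sizer": SizerParams,
    "timer": TimerParams,
    "pdiv": HillCurve,
    "cdc13": Cdc13Params,
}


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------


@dataclass
class CellState:
    """One live cell.

    ``rule_threshold`` is the rule-specific private threshold drawn at birth
    (size to add, target size, target duration, or cyclin threshold; unused by
    the ``pdiv`` rule).  ``tracked`` is False for cells created at t=0, whose
    first (birth-less) division must not emit a :class:`DivisionRecord`.
    """

    size: float
    birth_size: float
    birth_time: float = 0.0
    age: float = 0.0
    cyclin_amount: float = 0.0
    phase: str = GROWING
    septation_entry_time: Optional[float] = None
    rule_threshold: float = math.nan
    tracked: bool = True

    def __post_init__(self) -> None:
        if self.size <= 0.0 or self.birth_size <= 0.0:
            raise ValueError("cell sizes must be > 0")
        if self.age < 0.0:
            raise ValueError("age must be >= 0")
        if self.phase not in (GROWING, SEPTATED):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.phase == SEPTATED and self.septation_entry_time is None:
            raise ValueError("septated cell must record septation_entry_time")


@dataclass(frozen=True)
class DivisionRecord:
    """One completed cell cycle: birth and division-trigger size and time."""

    birth_time: float
    division_time: float
    birth_size: float
    division_size: float

    def __post_init__(self) -> None:
        if self.division_time <= self.birth_time:
            raise ValueError("division_time must exceed birth_time")

    @property
    def extension(self) -> float:
        return self.division_size - self.birth_size

    @property
    def duration(self) -> float:
        return self.division_time - self.birth_time


@dataclass
class PopulationSnapshot:
    """Per-cell (size, phase, cyclin) state of the population at one time."""

    time: float
    sizes: np.ndarray
    septated: np.ndarray
    cyclin_amounts: np.ndarray

    @property
    def phases(self) -> np.ndarray:
        return np.where(self.septated, SEPTATED, GROWING)

    @property
    def rows(self) -> List[Tuple[float, str, float]]:
        return list(zip(self.sizes.tolist(), self.phases.tolist(),
                        self.cyclin_amounts.tolist()))

    def __len__(self) -> int:
        return int(self.sizes.size)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": np.full(self.sizes.size, self.time),
            "size": self.sizes,
            "phase": self.phases,
            "cyclin_amount": self.cyclin_amounts,
        })


RuleParams = Union[AdderParams, SizerParams, TimerParams, HillCurve, Cdc13Params]


@dataclass
class SimulationConfig:
    """Full specification of one simulation run.

    ``growth_rate`` is the fractional size increase per minute (per-step
    multiplicative growth ``size *= (1 + growth_rate)**dt``);
    ``min_cycle_duration`` is an optional minimal-timer element below which no
    rule may fire; ``septation_duration`` > 0 inserts a non-elongating
    septated phase between division trigger and daughter split;
    ``record_initial`` additionally emits records for the first divisions of
    the founder cells (off by default -- founders have no observed birth).
    """

    rule: str = "pdiv"
    growth_rate: float = 0.006
    dt: float = 1.0
    n_init: int = 20
    t_max: float = 1000.0
    init_mean: float = 14.0
    init_sd: float = 1.4
    daughter_factor: float = 1.05
    asymmetry_sd: float = 1.0
    septation_duration: float = 0.0
    min_cycle_duration: float = 0.0
    rule_params: Optional[RuleParams] = None
    seed: int = 0
    record_initial: bool = False

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; expected one of {RULES}")
        if self.rule_params is None:
            self.rule_params = _DEFAULT_PARAMS[self.rule]()
        self.validate()

    def validate(self) -> None:
        if self.growth_rate < 0.0:
            raise ValueError("growth_rate must be >= 0")
        if self.dt <= 0.0:
            raise ValueError("dt must be > 0")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if self.t_max <= 0.0:
            raise ValueError("t_max must be > 0")
        if self.init_mean <= 0.0:
            raise ValueError("init_mean must be > 0")
        if self.init_sd < 0.0:
            raise ValueError("init_sd must be >= 0")
        if self.daughter_factor <= 0.0:
            raise ValueError("daughter_factor must be > 0")
        if self.asymmetry_sd < 0.0:
            raise ValueError("asymmetry_sd must be >= 0")
        if self.septation_duration < 0.0:
            raise ValueError("septation_duration must be >= 0")
        if self.min_cycle_duration < 0.0:
            raise ValueError("min_cycle_duration must be >= 0")
        expected = _DEFAULT_PARAMS[self.rule]
        if not isinstance(self.rule_params, expected):
            raise ValueError(
                f"rule {self.rule!r} requires {expected.__name__} parameters, "
                f"got {type(self.rule_params).__name__}")


def default_config(rule: str = "pdiv", **overrides) -> SimulationConfig:
    """Per-rule default configuration (initial-population and rule parameters
    of the published simulation blocks; 1000 one-minute steps, growth
    0.006/min)."""
    presets = {
        "adder": dict(init_mean=6.75, init_sd=0.675, n_init=20,
                      rule_params=AdderParams()),
        "sizer": dict(init_mean=7.25, init_sd=0.725, n_init=20,
                      rule_params=SizerParams()),
        "timer": dict(init_mean=7.0, init_sd=0.7, n_init=20,
                      rule_params=TimerParams()),
        "pdiv": dict(init_mean=14.0, init_sd=1.4, n_init=20,
                     rule_params=HillCurve()),
        "cdc13": dict(init_mean=7.0, init_sd=0.7, n_init=10,
                      rule_params=Cdc13Params()),
    }
    if rule not in presets:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    kwargs = dict(rule=rule, growth_rate=0.006, t_max=1000.0, **presets[rule])
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


# ---------------------------------------------------------------------------
# single-cell operations
# ---------------------------------------------------------------------------


def grow_step(cell: CellState, growth_rate: float, dt: float = 1.0) -> CellState:
    """Advance one cell by ``dt`` minutes of exponential elongation.

    Septated cells do not elongate; only their age advances.
    """
    if growth_rate < 0.0:
        raise ValueError("growth_rate must be >= 0")
    if cell.phase == SEPTATED:
        return replace(cell, age=cell.age + dt)
    return replace(cell, size=cell.size * (1.0 + growth_rate) ** dt,
                   age=cell.age + dt)


def division_decision(cell: CellState, rule: str, rule_params: RuleParams,
                      rng: Optional[np.random.Generator] = None,
                      min_cycle_duration: float = 0.0) -> bool:
    """Decide whether a growing cell triggers division this step."""
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    if cell.phase != GROWING:
        return False
    if cell.age < min_cycle_duration:
        return False
    if rule == "adder":
        return cell.size - cell.birth_size >= cell.rule_threshold
    if rule == "sizer":
        return cell.size >= cell.rule_threshold
    if rule == "timer":
        return cell.age >= cell.rule_threshold
    if rule == "pdiv":
        if rng is None:
            raise ValueError("pdiv rule requires a random generator")
        return bool(rng.random() < hill_eval(rule_params, cell.size))
    # cdc13
    stat = cell.cyclin_amount
    if rule_params.threshold_mode == "concentration":
        stat = stat / cell.size
    return stat >= cell.rule_threshold


def cdc13_update(cell: CellState, params: Cdc13Params, dt: float = 1.0,
                 rng: Optional[np.random.Generator] = None) -> CellState:
    """One minute of cyclin synthesis, noise, and degradation (floored at 0)."""
    rate = params.synthesis_rate
    noise_sd = params.synthesis_noise_sd
    if params.synthesis_mode == "size_proportional":
        rate = rate * cell.size
        noise_sd = noise_sd * cell.size
    rate = rate + params.basal_synthesis_rate
    noise = 0.0
    if params.synthesis_noise_sd > 0.0:
        if rng is None:
            raise ValueError("synthesis noise requires a random generator")
        noise = rng.normal(0.0, noise_sd)
    amount = cell.cyclin_amount + (rate + noise - params.degradation_rate) * dt
    return replace(cell, cyclin_amount=max(amount, 0.0))


def divide(cell: CellState, config: SimulationConfig,
           rng: np.random.Generator) -> Tuple[CellState, CellState, DivisionRecord]:
    """Split one triggered cell into two daughters plus its cycle record.

    Daughters are sized ``daughter_factor*division_size/2 ± eps`` with eps
    Gaussian; eps is redrawn if either daughter would be non-positive, which
    keeps the split unbiased because eps is symmetric.  The caller is
    responsible for discarding the record of untracked (founder) cells.
    """
    division_size = cell.size
    division_time = (cell.septation_entry_time if cell.phase == SEPTATED
                     else cell.birth_time + cell.age)
    base = 0.5 * config.daughter_factor * division_size
    eps = 0.0
    if config.asymmetry_sd > 0.0:
        eps = rng.normal(0.0, config.asymmetry_sd)
        tries = 0
        while base - abs(eps) <= 0.0:
            eps = rng.normal(0.0, config.asymmetry_sd)
            tries += 1
            if tries >= 100:  # degenerate mother far below the noise scale
                eps = 0.0
                break
    split_time = cell.birth_time + cell.age
    d1, d2 = base + eps, base - eps
    kids = []
    for s in (d1, d2):
        kids.append(CellState(size=s, birth_size=s, birth_time=split_time,
                              age=0.0, cyclin_amount=_birth_cyclin(config, s),
                              rule_threshold=_draw_threshold_scalar(config, rng)))
    record = DivisionRecord(birth_time=cell.birth_time,
                            division_time=division_time,
                            birth_size=cell.birth_size,
                            division_size=division_size)
    return kids[0], kids[1], record


def _birth_cyclin(config: SimulationConfig, birth_size: float) -> float:
    if config.rule == "cdc13":
        return config.rule_params.birth_level_factor * birth_size
    return 0.0


def _draw_threshold_scalar(config: SimulationConfig,
                           rng: np.random.Generator) -> float:
    arr = _draw_thresholds(config, rng, 1)
    return float(arr[0])


def _draw_thresholds(config: SimulationConfig, rng: np.random.Generator,
                     n: int) -> np.ndarray:
    rule = config.rule
    if rule == "pdiv":
        return np.full(n, np.nan)
    p = config.rule_params
    if rule == "cdc13":
        mean, sd = p.threshold_mean, p.threshold_sd
    else:
        mean, sd = p.mean, p.sd
    if sd == 0.0:
        return np.full(n, float(mean))
    out = rng.normal(mean, sd, n)
    bad = out <= 0.0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0.0
    return out


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      n: int) -> np.ndarray:
    if sd == 0.0:
        return np.full(n, float(mean))
    out = rng.normal(mean, sd, n)
    bad = out <= 0.0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0.0
    return out


def init_population(config: SimulationConfig,
                    rng: Optional[np.random.Generator] = None) -> List[CellState]:
    """Founder cells: sizes from a truncated Gaussian, age 0, untracked unless
    ``config.record_initial`` is set."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sizes = _truncated_normal(rng, config.init_mean, config.init_sd, config.n_init)
    thresholds = _draw_thresholds(config, rng, config.n_init)
    return [
        CellState(size=float(s), birth_size=float(s), birth_time=0.0, age=0.0,
                  cyclin_amount=_birth_cyclin(config, float(s)),
                  rule_threshold=float(th), tracked=bool(config.record_initial))
        for s, th in zip(sizes, thresholds)
    ]


# ---------------------------------------------------------------------------
# vectorised population engine
# ---------------------------------------------------------------------------


class SimulationEngine:
    """Struct-of-arrays population simulator advanced one step at a time.

    Holds one numpy array per cell attribute; divisions remove the mother row
    and append two daughter rows.  ``division_enabled`` can be switched off to
    emulate a division-blocked (shift-up) condition while growth and cyclin
    accumulation continue; cells already septated still complete their split.
    """

    def __init__(self, config: SimulationConfig,
                 rng: Optional[np.random.Generator] = None) -> None:
        config.validate()
        self.config = config
        self.rng = np.random.default_rng(config.seed) if rng is None else rng
        self.t = 0.0
        self.division_enabled = True
        n = config.n_init
        sizes = _truncated_normal(self.rng, config.init_mean, config.init_sd, n)
        self.size = sizes
        self.birth_size = sizes.copy()
        self.birth_time = np.zeros(n)
        self.age = np.zeros(n)
        if config.rule == "cdc13":
            self.cyclin = config.rule_params.birth_level_factor * sizes
        else:
            self.cyclin = np.zeros(n)
        self.threshold = _draw_thresholds(config, self.rng, n)
        self.tracked = np.full(n, bool(config.record_initial))
        self.septated = np.zeros(n, dtype=bool)
        self.trigger_time = np.full(n, np.nan)
        self._rec_birth_time: List[float] = []
        self._rec_division_time: List[float] = []
        self._rec_birth_size: List[float] = []
        self._rec_division_size: List[float] = []

    @property
    def n_cells(self) -> int:
        return int(self.size.size)

    def step(self) -> None:
        c = self.config
        rng = self.rng
        t_next = self.t + c.dt
        growing = ~self.septated
        self.size[growing] *= (1.0 + c.growth_rate) ** c.dt
        self.age += c.dt
        if c.rule == "cdc13":
            self._cyclin_step(growing)
        trig = np.zeros(self.n_cells, dtype=bool)
        if self.division_enabled:
            cand = growing
            if c.min_cycle_duration > 0.0:
                cand = cand & (self.age >= c.min_cycle_duration)
            idx = np.flatnonzero(cand)
            if idx.size:
                trig[idx] = self._rule_triggers(idx)
        if c.septation_duration > 0.0:
            self.septated |= trig
            self.trigger_time[trig] = t_next
            due = self.septated & (
                t_next - self.trigger_time >= c.septation_duration - 1e-9)
        else:
            self.trigger_time[trig] = t_next
            due = trig
        if np.any(due):
            self._split(np.flatnonzero(due), t_next)
        self.t = t_next

    def run(self, minutes: float) -> None:
        for _ in range(int(round(minutes / self.config.dt))):
            self.step()

    # -- internals ---------------------------------------------------------

    def _cyclin_step(self, growing: np.ndarray) -> None:
        p = self.config.rule_params
        idx = np.flatnonzero(growing)
        if not idx.size:
            return
        rate = p.synthesis_rate
        noise_sd = p.synthesis_noise_sd
        if p.synthesis_mode == "size_proportional":
            rate = rate * self.size[idx]
            noise_sd = noise_sd * self.size[idx]
        rate = rate + p.basal_synthesis_rate
        noise = 0.0
        if p.synthesis_noise_sd > 0.0:
            noise = self.rng.normal(0.0, 1.0, idx.size) * noise_sd
        delta = (rate + noise - p.degradation_rate) * self.config.dt
        self.cyclin[idx] = np.maximum(self.cyclin[idx] + delta, 0.0)

    def _rule_triggers(self, idx: np.ndarray) -> np.ndarray:
        c = self.config
        if c.rule == "adder":
            return self.size[idx] - self.birth_size[idx] >= self.threshold[idx]
        if c.rule == "sizer":
            return self.size[idx] >= self.threshold[idx]
        if c.rule == "timer":
            return self.age[idx] >= self.threshold[idx]
        if c.rule == "pdiv":
            u = self.rng.random(idx.size)
            return u < hill_eval(c.rule_params, self.size[idx])
        stat = self.cyclin[idx]
        if c.rule_params.threshold_mode == "concentration":
            stat = stat / self.size[idx]
        return stat >= self.threshold[idx]

    def _split(self, idx: np.ndarray, now: float) -> None:
        c = self.config
        division_size = self.size[idx]
        rec = self.tracked[idx]
        if np.any(rec):
            self._rec_birth_time.extend(self.birth_time[idx][rec].tolist())
            self._rec_division_time.extend(self.trigger_time[idx][rec].tolist())
            self._rec_birth_size.extend(self.birth_size[idx][rec].tolist())
            self._rec_division_size.extend(division_size[rec].tolist())
        m = idx.size
        base = 0.5 * c.daughter_factor * division_size
        if c.asymmetry_sd > 0.0:
            eps = self.rng.normal(0.0, c.asymmetry_sd, m)
            bad = base - np.abs(eps) <= 0.0
            tries = 0
            while np.any(bad):
                eps[bad] = self.rng.normal(0.0, c.asymmetry_sd, int(bad.sum()))
                bad = base - np.abs(eps) <= 0.0
                tries += 1
                if tries >= 100:  # degenerate mother far below the noise scale
                    eps[bad] = 0.0
                    break
        else:
            eps = np.zeros(m)
        new_size = np.concatenate([base + eps, base - eps])
        if c.rule == "cdc13":
            new_cyclin = c.rule_params.birth_level_factor * new_size
        else:
            new_cyclin = np.zeros(2 * m)
        new_threshold = _draw_thresholds(c, self.rng, 2 * m)
        keep = np.ones(self.n_cells, dtype=bool)
        keep[idx] = False
        self.size = np.concatenate([self.size[keep], new_size])
        self.birth_size = np.concatenate([self.birth_size[keep], new_size.copy()])
        self.birth_time = np.concatenate([self.birth_time[keep],
                                          np.full(2 * m, now)])
        self.age = np.concatenate([self.age[keep], np.zeros(2 * m)])
        self.cyclin = np.concatenate([self.cyclin[keep], new_cyclin])
        self.threshold = np.concatenate([self.threshold[keep], new_threshold])
        self.tracked = np.concatenate([self.tracked[keep],
                                       np.ones(2 * m, dtype=bool)])
        self.septated = np.concatenate([self.septated[keep],
                                        np.zeros(2 * m, dtype=bool)])
        self.trigger_time = np.concatenate([self.trigger_time[keep],
                                            np.full(2 * m, np.nan)])

    # -- outputs -----------------------------------------------------------

    def record_arrays(self) -> dict:
        birth_time = np.asarray(self._rec_birth_time)
        division_time = np.asarray(self._rec_division_time)
        birth_size = np.asarray(self._rec_birth_size)
        division_size = np.asarray(self._rec_division_size)
        return {
            "birth_time": birth_time,
            "division_time": division_time,
            "birth_size": birth_size,
            "division_size": division_size,
            "extension": division_size - birth_size,
            "duration": division_time - birth_time,
        }

    def records(self) -> List[DivisionRecord]:
        return [DivisionRecord(bt, dt_, bs, ds) for bt, dt_, bs, ds in zip(
            self._rec_birth_time, self._rec_division_time,
            self._rec_birth_size, self._rec_division_size)]

    def snapshot(self) -> PopulationSnapshot:
        return PopulationSnapshot(time=self.t, sizes=self.size.copy(),
                                  septated=self.septated.copy(),
                                  cyclin_amounts=self.cyclin.copy())


def run_simulation(config: SimulationConfig
                   ) -> Tuple[List[DivisionRecord], PopulationSnapshot]:
    """Run a configured simulation to ``t_max``; return all completed-cycle
    records and the final population snapshot.  Deterministic given
    ``config.seed``."""
    engine = SimulationEngine(config)
    engine.run(config.t_max)
    return engine.records(), engine.snapshot()


def run_simulation_arrays(config: SimulationConfig) -> dict:
    """Like :func:`run_simulation` but returning the record columns as numpy
    arrays (cheaper for sweeps)."""
    engine = SimulationEngine(config)
    engine.run(config.t_max)
    return engine.record_arrays()


def snapshot_series(config: SimulationConfig,
                    sample_interval: float) -> List[PopulationSnapshot]:
    """Population snapshots at t = 0, interval, 2*interval, ... up to t_max."""
    if sample_interval <= 0.0:
        raise ValueError("sample_interval must be > 0")
    engine = SimulationEngine(config)
    every = max(1, int(round(sample_interval / config.dt)))
    n_steps = int(round(config.t_max / config.dt))
    snaps = [engine.snapshot()]
    for k in range(1, n_steps + 1):
        engine.step()
        if k % every == 0:
            snaps.append(engine.snapshot())
    return snaps


def records_to_dataframe(records: Sequence[DivisionRecord]) -> pd.DataFrame:
    """Tidy table of completed cycles (one row per division)."""
    return pd.DataFrame({
        "birth_time": [r.birth_time for r in records],
        "division_time": [r.division_time for r in records],
        "birth_size": [r.birth_size for r in records],
        "division_size": [r.division_size for r in records],
        "extension": [r.extension for r in records],
        "duration": [r.duration for r in records],
    })
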