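"""Estimating the P(Div) dose-response from per-cell size/septation tables.

The septated fraction within uniform size bins is a snapshot surrogate for
the probability that a cell of that size is dividing; fitting a Hill curve to
the binned fractions recovers the dose-response (maximum, EC50, Hill
coefficient).  Dividing the septated fraction by the time cells spend
septated converts the occupancy curve into a per-minute division rate; the
steady-state inversion additionally accounts for septated cells re-entering
the growing pool (occupancy = h*tau / (1 + h*tau)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .simulator import HillCurve, hill_eval

__all__ = [
    "BinnedSeptation",
    "HillFit",
    "TimepointFit",
    "bin_fraction_septated",
    "fit_hill",
    "rate_from_fraction",
    "occupancy_from_rate",
    "pdiv_curve_timecourse",
]


@dataclass
class BinnedSeptation:
    """Septated fractions in uniform size bins (sparse bins already dropped).

    ``bin_lo``/``bin_hi`` delimit each retained bin ([lo, hi), last bin
    closed); ``fraction`` is ``n_septated / n_total`` per bin.
    """

    bin_lo: np.ndarray
    bin_hi: np.ndarray
    n_total: np.ndarray
    n_septated: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_lo + self.bin_hi)

    @property
    def fraction(self) -> np.ndarray:
        return self.n_septated / self.n_total

    @property
    def bin_edges(self) -> np.ndarray:
        return np.column_stack([self.bin_lo, self.bin_hi])

    def __len__(self) -> int:
        return int(self.bin_lo.size)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo": self.bin_lo, "bin_hi": self.bin_hi,
            "n_total": self.n_total, "n_septated": self.n_septated,
            "fraction": self.fraction,
        })


@dataclass
class HillFit:
    """Nonlinear least-squares Hill fit to binned septated fractions."""

    curve: HillCurve
    rss: float
    se_pmax: float
    se_ec50: float
    se_n: float
    converged: bool

    def to_dict(self) -> dict:
        return {
            "pmax": self.curve.pmax, "ec50": self.curve.ec50, "n": self.curve.n,
            "rss": self.rss, "se_pmax": self.se_pmax, "se_ec50": self.se_ec50,
            "se_n": self.se_n, "converged": self.converged,
        }


def bin_fraction_septated(table: pd.DataFrame, bin_width: float = 1.0,
                          min_count: int = 10) -> BinnedSeptation:
    """Septated fraction per uniform size bin.

    Bins span [floor(min size), ceil(max size)] with the stated width; bins
    holding fewer than ``min_count`` cells are dropped.
    """
    if bin_width <= 0.0:
        raise ValueError("bin_width must be > 0")
    if len(table) == 0:
        raise ValueError("empty table")
    size = np.asarray(table["size"], dtype=float)
    sept = np.asarray(table["septated"]).astype(bool)
    if np.any(size <= 0.0):
        raise ValueError("all sizes must be > 0")
    lo = np.floor(size.min())
    hi = np.ceil(size.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-12)))
    idx = np.floor((size - lo) / bin_width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # top edge joins the last bin
    n_total = np.bincount(idx, minlength=n_bins)
    n_sept = np.bincount(idx, weights=sept.astype(float), minlength=n_bins)
    keep = n_total >= max(min_count, 1)
    if not np.any(keep):
        raise ValueError("no bin reaches min_count cells")
    bins = np.flatnonzero(keep)
    return BinnedSeptation(
        bin_lo=lo + bins * bin_width,
        bin_hi=lo + (bins + 1) * bin_width,
        n_total=n_total[keep],
        n_septated=n_sept[keep],
    )


def _hill_model(s, pmax, ec50, n):
    with np.errstate(over="ignore"):
        return pmax / (1.0 + np.power(ec50 / s, n))


def fit_hill(binned: Union[BinnedSeptation, Tuple[np.ndarray, np.ndarray]],
             init: Optional[HillCurve] = None,
             weighted: bool = False) -> HillFit:
    """Nonlinear least squares of septated fraction against a Hill curve.

    The abscissa is the bin center.  The fit is unweighted by default;
    ``weighted=True`` weights bins by sqrt(count) (only available when fitting
    a :class:`BinnedSeptation`).  Default initialisation: pmax0 = max
    fraction, ec50_0 = center nearest half-max, n0 = 4; bounds pmax in (0,1],
    ec50 in (0, max size], n in (0, 100].  Non-convergence (or a fit pinned at
    a bound) is reported via ``converged=False``, never silently.
    """
    if isinstance(binned, BinnedSeptation):
        x = binned.centers
        y = binned.fraction
        max_size = float(binned.bin_hi.max())
        counts = binned.n_total
    else:
        x, y = (np.asarray(v, dtype=float) for v in binned)
        max_size = float(x.max())
        counts = None
        if weighted:
            raise ValueError("weighted fit requires a BinnedSeptation input")
    if x.size < 4:
        raise ValueError("need at least 4 bins to fit a 3-parameter Hill curve")
    if np.all(y == y[0]):
        raise ValueError("fractions are all equal; Hill fit is undetermined")
    if np.all(y == 0.0):
        raise ValueError("all fractions are zero")
    if init is not None:
        p0 = [init.pmax, init.ec50, init.n]
    else:
        pmax0 = float(np.clip(y.max(), 1e-6, 1.0))
        ec500 = float(x[np.argmin(np.abs(y - 0.5 * pmax0))])
        p0 = [pmax0, max(ec500, 1e-6), 4.0]
    lower = [1e-12, 1e-12, 1e-12]
    upper = [1.0, max_size, 100.0]
    p0 = [float(np.clip(v, lo, up)) for v, lo, up in zip(p0, lower, upper)]
    sigma = None
    if weighted and counts is not None:
        sigma = 1.0 / np.sqrt(np.maximum(counts, 1))
    try:
        popt, pcov = curve_fit(_hill_model, x, y, p0=p0, sigma=sigma,
                               bounds=(lower, upper), maxfev=20000)
        converged = True
    except RuntimeError:
        popt, pcov = np.asarray(p0), np.full((3, 3), np.nan)
        converged = False
    # a parameter pinned at a bound is a degenerate fit, flag it
    at_bound = (np.any(np.isclose(popt, lower, rtol=0.0, atol=1e-9))
                or np.isclose(popt[1], upper[1], rtol=1e-9)
                or np.isclose(popt[2], upper[2], rtol=1e-9))
    if at_bound:
        converged = False
    resid = y - _hill_model(x, *popt)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    return HillFit(
        curve=HillCurve(float(np.clip(popt[0], 1e-12, 1.0)),
                        float(max(popt[1], 1e-12)), float(max(popt[2], 1e-12))),
        rss=float(np.sum(resid ** 2)),
        se_pmax=float(se[0]), se_ec50=float(se[1]), se_n=float(se[2]),
        converged=bool(converged),
    )


def rate_from_fraction(fraction, septation_time: float, mode: str = "literal"):
    """Convert a septated fraction into a per-minute division rate.

    ``literal`` divides the fraction by the septation time (the published
    normalisation).  ``steady_state`` inverts the renewal occupancy relation
    occupancy = h*tau/(1 + h*tau), i.e. h = f / (tau * (1 - f)), which is the
    exact inverse of :func:`occupancy_from_rate`.
    """
    if septation_time <= 0.0:
        raise ValueError("septation_time must be > 0")
    if mode not in ("literal", "steady_state"):
        raise ValueError(f"unknown mode {mode!r}")
    f = np.asarray(fraction, dtype=float)
    if np.any((f < 0.0) | (f > 1.0)):
        raise ValueError("fraction must lie in [0, 1]")
    if mode == "literal":
        out = f / septation_time
    else:
        if np.any(f >= 1.0):
            raise ValueError("steady_state mode requires fraction < 1 "
                             "(occupancy 1 implies an infinite rate)")
        out = f / (septation_time * (1.0 - f))
    return float(out) if np.isscalar(fraction) else out


def occupancy_from_rate(rate, septation_time: float):
    """Steady-state septated occupancy h*tau/(1 + h*tau) for entry hazard h."""
    if septation_time <= 0.0:
        raise ValueError("septation_time must be > 0")
    h = np.asarray(rate, dtype=float)
    if np.any(h < 0.0):
        raise ValueError("rate must be >= 0")
    out = h * septation_time / (1.0 + h * septation_time)
    return float(out) if np.isscalar(rate) else out


@dataclass
class TimepointFit:
    """One entry of a P(Div) time course: a fit, or the reason it failed."""

    label: object
    fit: Optional[HillFit]
    error: Optional[str] = None


def pdiv_curve_timecourse(tables: Sequence[pd.DataFrame],
                          labels: Optional[Sequence] = None,
                          bin_width: float = 1.0, min_count: int = 10,
                          weighted: bool = False) -> List[TimepointFit]:
    """Independent bin-and-fit per table, order preserved.

    Per-table failures (too few bins, degenerate fractions, ...) are captured
    in the returned entry instead of aborting the series, so EC50 shifts over
    a perturbation time course can be read off the successful fits.
    """
    if labels is None:
        labels = list(range(len(tables)))
    if len(labels) != len(tables):
        raise ValueError("labels and tables must have equal length")
    out: List[TimepointFit] = []
    for label, table in zip(labels, tables):
        try:
            binned = bin_fraction_septated(table, bin_width=bin_width,
                                           min_count=min_count)
            fit = fit_hill(binned, weighted=weighted)
            out.append(TimepointFit(label=label, fit=fit))
        except (ValueError, KeyError) as exc:
            out.append(TimepointFit(label=label, fit=None, error=str(exc)))
    return out
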