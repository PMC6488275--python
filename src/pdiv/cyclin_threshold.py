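"""Cyclin-threshold analysis of paired dividing / division-blocked tables.

Given per-cell (size, septation, fluorescence) snapshots from a dividing
("permissive") culture and a matched division-blocked ("restrictive")
culture, this module bins cells over the dividing-size range and asks
whether a cyclin threshold explains the size-dependent division probability:

* a within-bin cyclin threshold (mean of the brightest k cells in the
  dividing population, where suprathreshold cells have been removed by
  division) and their across-bin mean, the global threshold;
* P(septation): septated fraction per bin in the dividing culture;
* P(suprathreshold): fraction of blocked-culture cells above the threshold;
* P(overlap): fraction of dividing-culture cells whose fluorescence falls in
  the interval where the two conditions overlap;
* Pearson correlations of those per-bin probabilities, and the CoV of
  fluorescence inside a window at a low decile of the division-size
  distribution versus the CoV of division size itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ThresholdResult",
    "DecileWindowResult",
    "assign_bins",
    "bin_threshold",
    "global_threshold",
    "p_septation_per_bin",
    "p_suprathreshold_per_bin",
    "p_overlap_per_bin",
    "threshold_correlation",
    "compute_threshold_result",
    "decile_window_cov",
]

PERMISSIVE = "permissive"
RESTRICTIVE = "restrictive"


def _required(table: pd.DataFrame, columns: Sequence[str]) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks required column(s): {missing}")


def assign_bins(table: pd.DataFrame, n_bins: int = 8,
                size_range: Optional[Tuple[float, float]] = None
                ) -> Tuple[pd.DataFrame, np.ndarray]:
    """Tag rows with equal-width size-bin indices over ``size_range``.

    Rows outside the range are dropped.  Bins are half-open [lo, hi) with the
    last bin closed.  When ``size_range`` is omitted it spans the observed
    division sizes, i.e. the sizes of septated permissive-condition rows (or
    of all septated rows if no condition column is present).

    Returns the tagged copy (new ``size_bin`` column) and the bin edges.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    _required(table, ["size"])
    if size_range is None:
        sub = table
        if "condition" in table.columns:
            sub = table[table["condition"] == PERMISSIVE]
        sept = sub[np.asarray(sub["septated"]).astype(bool)]
        if len(sept) == 0:
            raise ValueError("cannot derive size_range: no septated "
                             "permissive cells")
        size_range = (float(sept["size"].min()), float(sept["size"].max()))
    lo, hi = map(float, size_range)
    if not hi > lo:
        raise ValueError(f"empty size range [{lo}, {hi}]")
    edges = np.linspace(lo, hi, n_bins + 1)
    size = np.asarray(table["size"], dtype=float)
    inside = (size >= lo) & (size <= hi)
    out = table.loc[inside].copy()
    idx = np.floor((size[inside] - lo) / (hi - lo) * n_bins).astype(int)
    out["size_bin"] = np.clip(idx, 0, n_bins - 1)
    return out, edges


def bin_threshold(fluor_values, k: int = 10) -> float:
    """Within-bin cyclin threshold: mean of the k brightest cells."""
    v = np.sort(np.asarray(fluor_values, dtype=float))
    if v.size < k:
        raise ValueError(f"bin holds {v.size} cells, fewer than k={k}")
    return float(v[-k:].mean())


def global_threshold(per_bin_thresholds) -> float:
    """Unweighted mean of the valid (non-NaN) per-bin thresholds."""
    t = np.asarray(per_bin_thresholds, dtype=float)
    valid = t[~np.isnan(t)]
    if valid.size == 0:
        raise ValueError("no valid per-bin thresholds")
    return float(valid.mean())


def _per_bin(table: pd.DataFrame, n_bins: int, fn) -> np.ndarray:
    """Apply ``fn`` to each bin's sub-table; empty bins give NaN (missing)."""
    out = np.full(n_bins, np.nan)
    groups = table.groupby("size_bin")
    for b, sub in groups:
        out[int(b)] = fn(sub)
    return out


def p_septation_per_bin(permissive_binned: pd.DataFrame,
                        n_bins: int = 8) -> np.ndarray:
    """Septated fraction per size bin in the dividing condition; empty bins
    are NaN (missing), never 0."""
    _required(permissive_binned, ["size_bin", "septated"])
    return _per_bin(permissive_binned, n_bins,
                    lambda sub: np.asarray(sub["septated"]).astype(bool).mean())


def p_suprathreshold_per_bin(restrictive_binned: pd.DataFrame,
                             threshold: float, n_bins: int = 8) -> np.ndarray:
    """Fraction of blocked-condition cells strictly above the threshold."""
    if threshold <= 0.0:
        raise ValueError("threshold must be > 0")
    _required(restrictive_binned, ["size_bin", "fluor"])
    return _per_bin(restrictive_binned, n_bins,
                    lambda sub: float(np.mean(
                        np.asarray(sub["fluor"], dtype=float) > threshold)))


def p_overlap_per_bin(permissive_binned: pd.DataFrame,
                      overlap_interval: Tuple[float, float],
                      n_bins: int = 8) -> np.ndarray:
    """Fraction of dividing-condition cells with fluorescence inside
    [lo, hi] (closed interval)."""
    lo, hi = map(float, overlap_interval)
    if lo > hi:
        raise ValueError("overlap interval must satisfy lo <= hi")
    _required(permissive_binned, ["size_bin", "fluor"])

    def frac(sub):
        f = np.asarray(sub["fluor"], dtype=float)
        return float(np.mean((f >= lo) & (f <= hi)))

    return _per_bin(permissive_binned, n_bins, frac)


def threshold_correlation(x, y) -> float:
    """Pearson correlation over paired per-bin values, NaN pairs dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired non-missing bins")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero variance in a series")
    return float(stats.pearsonr(x, y)[0])


@dataclass
class ThresholdResult:
    """Full per-bin threshold analysis of a permissive/restrictive pair."""

    bin_edges: np.ndarray
    thresholds: np.ndarray
    global_threshold: float
    p_septation: np.ndarray
    p_suprathreshold: np.ndarray
    p_overlap: np.ndarray
    overlap_intervals: np.ndarray  # (n_bins, 2); the interval actually used
    correlation_sept_vs_supra: float
    correlation_overlap_vs_supra: float
    n_permissive: np.ndarray
    n_restrictive: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo": self.bin_edges[:-1], "bin_hi": self.bin_edges[1:],
            "threshold": self.thresholds,
            "p_septation": self.p_septation,
            "p_suprathreshold": self.p_suprathreshold,
            "p_overlap": self.p_overlap,
            "overlap_lo": self.overlap_intervals[:, 0],
            "overlap_hi": self.overlap_intervals[:, 1],
            "n_permissive": self.n_permissive,
            "n_restrictive": self.n_restrictive,
        })

    def to_dict(self) -> dict:
        def lst(a):
            return [None if np.isnan(v) else float(v) for v in a]
        return {
            "bin_edges": [float(v) for v in self.bin_edges],
            "thresholds": lst(self.thresholds),
            "global_threshold": float(self.global_threshold),
            "p_septation": lst(self.p_septation),
            "p_suprathreshold": lst(self.p_suprathreshold),
            "p_overlap": lst(self.p_overlap),
            "correlation_sept_vs_supra": float(self.correlation_sept_vs_supra),
            "correlation_overlap_vs_supra":
                float(self.correlation_overlap_vs_supra),
        }


def compute_threshold_result(permissive: pd.DataFrame,
                             restrictive: pd.DataFrame,
                             n_bins: int = 8, k: int = 10,
                             threshold: Optional[float] = None,
                             overlap_interval: Optional[Tuple[float, float]] = None,
                             size_range: Optional[Tuple[float, float]] = None
                             ) -> ThresholdResult:
    """Run the whole per-bin threshold pipeline on a condition pair.

    Per-bin thresholds come from the permissive (dividing) condition; bins
    with fewer than ``k`` cells are excluded from the global mean.  When no
    ``overlap_interval`` is supplied it is derived per bin as [lower
    quartile of restrictive fluorescence, 95th percentile of permissive
    fluorescence] -- the region where the dividing population still looks
    like the bulk of the non-dividing one -- clipped to lo <= hi; the
    interval used is always reported.
    """
    _required(permissive, ["size", "septated", "fluor"])
    _required(restrictive, ["size", "fluor"])
    if size_range is None:
        sept = permissive[np.asarray(permissive["septated"]).astype(bool)]
        if len(sept) == 0:
            raise ValueError("no septated permissive cells to set the "
                             "division-size range")
        size_range = (float(sept["size"].min()), float(sept["size"].max()))
    perm, edges = assign_bins(permissive, n_bins, size_range)
    rest, _ = assign_bins(restrictive, n_bins, size_range)

    def thr(sub):
        try:
            return bin_threshold(sub["fluor"], k=k)
        except ValueError:
            return np.nan

    thresholds = _per_bin(perm, n_bins, thr)
    gthr = global_threshold(thresholds)
    supra_thr = float(threshold) if threshold is not None else gthr

    p_sept = p_septation_per_bin(perm, n_bins)
    p_supra = p_suprathreshold_per_bin(rest, supra_thr, n_bins)

    intervals = np.full((n_bins, 2), np.nan)
    p_over = np.full(n_bins, np.nan)
    for b in range(n_bins):
        psub = perm[perm["size_bin"] == b]
        rsub = rest[rest["size_bin"] == b]
        if overlap_interval is not None:
            lo, hi = map(float, overlap_interval)
        elif len(psub) and len(rsub):
            # where the dividing population still looks like the
            # non-dividing one: from the floor of the restrictive
            # distribution's bulk (lower quartile, robust to its long
            # lower tail) up to the dividing distribution's ceiling
            lo = float(np.percentile(rsub["fluor"], 25))
            hi = float(np.percentile(psub["fluor"], 95))
            if lo > hi:
                lo = hi
        else:
            continue
        intervals[b] = (lo, hi)
        if len(psub):
            f = np.asarray(psub["fluor"], dtype=float)
            p_over[b] = float(np.mean((f >= lo) & (f <= hi)))

    def corr(x, y):
        try:
            return threshold_correlation(x, y)
        except ValueError:
            return float("nan")  # degenerate series: correlation undefined

    r_ss = corr(p_sept, p_supra)
    r_os = corr(p_over, p_supra)
    counts_p = _per_bin(perm, n_bins, len)
    counts_r = _per_bin(rest, n_bins, len)
    return ThresholdResult(
        bin_edges=edges, thresholds=thresholds, global_threshold=gthr,
        p_septation=p_sept, p_suprathreshold=p_supra, p_overlap=p_over,
        overlap_intervals=intervals,
        correlation_sept_vs_supra=r_ss, correlation_overlap_vs_supra=r_os,
        n_permissive=np.nan_to_num(counts_p).astype(int),
        n_restrictive=np.nan_to_num(counts_r).astype(int),
    )


@dataclass
class DecileWindowResult:
    """CoV comparison in a narrow window at a low division-size decile."""

    window_center: float
    half_window: float
    cov_division_size: float
    cov_fluor: float
    n_window: int
    low_confidence: bool


def decile_window_cov(table: pd.DataFrame, decile: float = 0.1,
                      half_window: float = 1.0) -> DecileWindowResult:
    """CoV of division size versus CoV of blocked-condition fluorescence in a
    window centred on the stated decile of the division-size distribution.

    Division sizes are the septated permissive-condition cells; fluorescence
    comes from restrictive-condition cells with |size - center| <=
    half_window (an infinite half-window reduces to the plain CoV of all
    restrictive fluorescence).  Quantiles use linear interpolation.  Windows
    holding fewer than 10 cells are flagged low-confidence.
    """
    _required(table, ["size", "septated", "fluor", "condition"])
    if not 0.0 < decile < 1.0:
        raise ValueError("decile must lie strictly inside (0, 1)")
    if half_window <= 0.0:
        raise ValueError("half_window must be > 0")
    perm = table[table["condition"] == PERMISSIVE]
    rest = table[table["condition"] == RESTRICTIVE]
    div_sizes = np.asarray(
        perm.loc[np.asarray(perm["septated"]).astype(bool), "size"],
        dtype=float)
    if div_sizes.size < 2:
        raise ValueError("need at least 2 division (septated permissive) sizes")
    center = float(np.quantile(div_sizes, decile))
    cov_div = float(div_sizes.std(ddof=1) / div_sizes.mean())
    rsize = np.asarray(rest["size"], dtype=float)
    rfluor = np.asarray(rest["fluor"], dtype=float)
    in_win = np.abs(rsize - center) <= half_window
    f = rfluor[in_win]
    if f.size < 2:
        raise ValueError("fewer than 2 restrictive cells in the window")
    cov_fluor = float(f.std(ddof=1) / f.mean())
    return DecileWindowResult(window_center=center, half_window=float(half_window),
                              cov_division_size=cov_div, cov_fluor=cov_fluor,
                              n_window=int(f.size),
                              low_confidence=bool(f.size < 10))
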