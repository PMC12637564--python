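"""Growth-rate extraction from plate-reader OD600 time courses.

The procedure mirrors quantitative growth-based kinase-substrate interaction
assays: curves sampled every 15 minutes for 60 hours are smoothed with a
centered 25-point moving average, an initial burn-in of 100 smoothed points is
excluded, exponential-phase points are selected where the numerical derivative
of smoothed OD exceeds a dynamic threshold (tau, starting at 5e-3 per hour and
shrunk by a factor 1.25 until at least 25 points qualify), and the growth rate
is the least-squares slope across the selected window. When too few points
qualify or the final OD is below 0.05, the whole post-burn-in trace is used.
Rates are z-scored within each kinase and rescaled to [0, 2] for cross-kinase
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import GrowthCurve


@dataclass
class WindowSelection:
    indices: np.ndarray
    final_tau: float
    fallback_used: bool

    def __len__(self) -> int:
        return len(self.indices)


def smooth_od(curve: GrowthCurve, window: int = 25) -> GrowthCurve:
    """Centered moving average; the window truncates symmetrically at the edges."""
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    n = len(curve.od)
    if n < window:
        raise ValueError(f"curve has {n} points, shorter than window {window}")
    half = window // 2
    od = np.asarray(curve.od, dtype=float)
    out = np.empty(n)
    for i in range(n):
        h = min(i, n - 1 - i, half)
        out[i] = od[i - h : i + h + 1].mean()
    return GrowthCurve(
        time_min=np.asarray(curve.time_min, dtype=float).copy(),
        od=out,
        kinase=curve.kinase,
        substrate=curve.substrate,
        replicate=curve.replicate,
    )


def select_window(
    curve: GrowthCurve,
    tau0: float = 5e-3,
    shrink: float = 1.25,
    min_points: int = 25,
    burn_in: int = 100,
    od_floor: float = 0.05,
    max_iter: int = 200,
) -> WindowSelection:
    """Select exponential-phase indices of a smoothed curve by dynamic threshold.

    The derivative is a first-order forward difference of smoothed OD per hour.
    tau starts at ``tau0`` and shrinks by ``shrink`` until ``min_points`` points
    exceed it; if that never happens (or the curve ends below ``od_floor``) the
    entire post-burn-in trace is selected (``fallback_used``).
    """
    od = np.asarray(curve.od, dtype=float)
    t_h = np.asarray(curve.time_min, dtype=float) / 60.0
    n = len(od)
    if n <= burn_in:
        raise ValueError(f"curve has {n} points; burn-in of {burn_in} not removable")
    post = np.arange(burn_in, n)
    if od[-1] < od_floor:
        return WindowSelection(indices=post, final_tau=tau0, fallback_used=True)
    deriv = np.diff(od) / np.diff(t_h)  # deriv[i] ~ slope on [i, i+1]
    candidates = post[post < n - 1]
    tau = tau0
    for _ in range(max_iter):
        sel = candidates[deriv[candidates] > tau]
        if len(sel) >= min_points:
            return WindowSelection(indices=sel, final_tau=tau, fallback_used=False)
        tau /= shrink
    return WindowSelection(indices=post, final_tau=tau, fallback_used=True)


def estimate_rate(curve: GrowthCurve, window: WindowSelection, log_mode: bool = False) -> float:
    """Least-squares slope of (smoothed) OD -- or ln OD in log mode -- vs time (h)."""
    idx = np.asarray(window.indices)
    if len(idx) < 2:
        raise ValueError("window must contain at least 2 points")
    t = np.asarray(curve.time_min, dtype=float)[idx] / 60.0
    y = np.asarray(curve.od, dtype=float)[idx]
    if log_mode:
        if (y <= 0).any():
            raise ValueError("log mode requires positive OD values")
        y = np.log(y)
    slope, _ = np.polyfit(t, y, 1)
    return float(slope)


def extract_rate(
    curve: GrowthCurve, window: int = 25, log_mode: bool = False, **window_kwargs
) -> tuple[float, WindowSelection]:
    """Smooth, select the exponential window, and estimate the raw rate."""
    sm = smooth_od(curve, window)
    sel = select_window(sm, **window_kwargs)
    return estimate_rate(sm, sel, log_mode=log_mode), sel


def normalize_rates(rates: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-kinase z-score then min-max rescale of raw rates onto [0, 2].

    ``rates`` needs columns kinase, substrate, replicate, rate. Returns the
    per-curve table with a ``normalized`` column and a per-condition summary
    (median and s.d. of normalized replicate values). Kinases with zero
    within-kinase variance map to 1.0 with a warning.
    """
    out = rates.copy()
    out["normalized"] = np.nan
    for kinase, sub in out.groupby("kinase"):
        vals = sub["rate"].to_numpy(dtype=float)
        sd = vals.std(ddof=0)
        if sd == 0 or len(vals) < 2:
            warnings.warn(f"kinase {kinase}: zero within-kinase variance; normalized rates set to 1.0")
            out.loc[sub.index, "normalized"] = 1.0
            continue
        z = (vals - vals.mean()) / sd
        span = z.max() - z.min()
        out.loc[sub.index, "normalized"] = 2.0 * (z - z.min()) / span
    summary = (
        out.groupby(["kinase", "substrate"])["normalized"]
        .agg(median="median", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
        .reset_index()
    )
    return out, summary
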