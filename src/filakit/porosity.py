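"""Porosity-based polymerization kinetics with photobleaching correction.

Porosity is the fraction of ROI pixels BELOW an Otsu threshold of the
filament-fluorescence channel.  When tiles condense into filaments the
signal concentrates into thin bright structures and most of the lumen
becomes dark pore space (high porosity); after disassembly the
fluorescence spreads homogeneously and few pixels fall below the
threshold (low porosity).  Porosity is therefore a proxy for the degree
of polymerization.

Acquisition photobleaching inflates the measured pore fraction over
time; the correction multiplies the raw trace by (1 - x_slope*t), with
x_slope estimated from the disassembled (homogeneous) states where the
drift-free porosity is constant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "PorosityTrace",
    "otsu_threshold_index",
    "frame_porosity",
    "trace_from_stack",
    "bleach_correct",
    "cycle_summary",
]


@dataclass(frozen=True)
class PorosityTrace:
    """Time series of raw / bleach-corrected / normalized porosity."""

    t_min: np.ndarray
    p_raw: np.ndarray
    p_corr: np.ndarray
    p_norm: np.ndarray
    uv_events_min: list[float]
    x_slope_per_min: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.t_min)
        if not (len(self.p_raw) == len(self.p_corr) == len(self.p_norm) == n):
            raise ValueError("all trace arrays must have equal length")


def otsu_threshold_index(values: np.ndarray, nbins: int = 256) -> tuple[int, np.ndarray]:
    """Otsu's threshold on a min-max-scaled histogram.

    Scales the values to [0, 1], bins them into ``nbins`` equal bins and
    returns the bin index k maximizing the inter-class variance for the
    split {bins 0..k} vs {bins k+1..}, together with the per-value bin
    assignment.  Ties are broken toward the lower threshold.  The exact
    binning and tie-break are part of the contract so that porosity is
    invariant under monotone affine intensity rescaling.
    """
    v = np.asarray(values, dtype=float).ravel()
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("constant image: threshold undefined")
    scaled = (v - lo) / (hi - lo)
    bin_idx = np.minimum((scaled * nbins).astype(int), nbins - 1)
    hist = np.bincount(bin_idx, minlength=nbins).astype(float)
    p = hist / hist.sum()
    centers = (np.arange(nbins) + 0.5) / nbins
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    mu0 = np.cumsum(p * centers)[:-1]
    mu_t = float(np.sum(p * centers))
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * w0 - mu0) ** 2 / (w0 * w1)
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    k = int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximizer
    return k, bin_idx


def frame_porosity(image: np.ndarray, roi_mask: np.ndarray | None = None) -> float:
    """Below-Otsu-threshold pixel fraction of one frame (within an ROI).

    Returns 1.0 with a warning-free sentinel for a constant image,
    whose single-class histogram leaves the threshold undefined.
    """
    img = np.asarray(image, dtype=float)
    if roi_mask is not None:
        vals = img[np.asarray(roi_mask, dtype=bool)]
        if vals.size == 0:
            raise ValueError("empty ROI")
    else:
        vals = img.ravel()
    try:
        k, bin_idx = otsu_threshold_index(vals)
    except ValueError:
        return 1.0
    return float(np.mean(bin_idx <= k))


def trace_from_stack(
    stack: np.ndarray,
    dt_min: float,
    uv_events_min: list[float] | None = None,
    roi_mask: np.ndarray | None = None,
) -> PorosityTrace:
    """Per-frame porosity of a time-lapse stack, uncorrected."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a (frames, rows, cols) stack")
    p = np.array([frame_porosity(frame, roi_mask) for frame in stack])
    t = np.arange(stack.shape[0]) * dt_min
    norm = 100.0 * p / p[0] if p[0] > 0 else np.full_like(p, np.nan)
    return PorosityTrace(
        t_min=t, p_raw=p, p_corr=p.copy(), p_norm=norm,
        uv_events_min=list(uv_events_min or []),
    )


def fit_bleach_slope(
    t_min: np.ndarray, p_raw: np.ndarray, windows: list[tuple[float, float]]
) -> float:
    """Estimate the bleach slope x_slope from disassembled-state windows.

    Under the multiplicative drift model p_raw = p0 / (1 - x_slope*t)
    within a window of constant true porosity p0, the reciprocal
    1/p_raw = (1 - x_slope*t)/p0 is exactly linear in t; a straight-line
    fit of 1/p over the concatenated windows therefore yields x_slope =
    -slope/intercept exactly in the noise-free case.
    """
    t = np.asarray(t_min, dtype=float)
    p = np.asarray(p_raw, dtype=float)
    sel = np.zeros_like(t, dtype=bool)
    for a, b in windows:
        if b < t[0] or a > t[-1]:
            raise ValueError(f"window ({a}, {b}) lies outside the trace")
        sel |= (t >= a) & (t <= b)
    if sel.sum() < 2:
        raise ValueError("need at least 2 points inside the disassembled windows")
    if np.any(p[sel] <= 0):
        raise ValueError("nonpositive porosity inside fit window")
    coef = np.polyfit(t[sel], 1.0 / p[sel], 1)
    slope, intercept = coef
    if intercept == 0:
        raise ValueError("degenerate reciprocal fit")
    return float(-slope / intercept)


def bleach_correct(
    trace: PorosityTrace,
    disassembled_windows: list[tuple[float, float]] | None = None,
    window_after_event_min: float = 2.0,
) -> PorosityTrace:
    """Apply the linear bleach correction p_corr = p_raw * (1 - x_slope*t).

    x_slope is fitted on the disassembled-state windows (defaulting to
    the ``window_after_event_min`` minutes following each UV event,
    where the true porosity sits at its constant disassembled level),
    and the corrected disassembled baseline is stationary by
    construction.  Normalized porosity is re-referenced to the first
    frame.
    """
    if disassembled_windows is None:
        if not trace.uv_events_min:
            raise ValueError("no disassembled windows and no UV events to derive them from")
        disassembled_windows = [
            (ev, ev + window_after_event_min) for ev in trace.uv_events_min
        ]
    x_slope = fit_bleach_slope(trace.t_min, trace.p_raw, disassembled_windows)
    p_corr = trace.p_raw * (1.0 - x_slope * trace.t_min)
    p_norm = 100.0 * p_corr / p_corr[0]
    return replace(trace, p_corr=p_corr, p_norm=p_norm, x_slope_per_min=x_slope)


def cycle_summary(trace: PorosityTrace) -> pd.DataFrame:
    """Per-UV-event drop/recovery summary on the normalized trace.

    For each event: the normalized porosity just before (pre_percent)
    and just after (post_percent) the event, the drop magnitude in
    percentage points, the recovery plateau (mean of the last 10% of
    the inter-event window) and the half-time -- the first time after
    the event at which the trace crosses the midpoint between the
    post-event level and the pre-event level.  Events with fewer than
    3 samples before the trace end are flagged incomplete.
    """
    if not trace.uv_events_min:
        raise ValueError("trace carries no UV events")
    t = trace.t_min
    p = trace.p_norm
    events = list(trace.uv_events_min)
    bounds = events[1:] + [t[-1] + (t[1] - t[0] if len(t) > 1 else 0.0)]
    rows = []
    for ev, end in zip(events, bounds):
        pre_idx = np.nonzero(t < ev)[0]
        pre = float(p[pre_idx[-1]]) if pre_idx.size else 100.0
        win = np.nonzero((t >= ev) & (t < end))[0]
        if win.size < 3:
            rows.append({"event_min": ev, "pre_percent": pre, "post_percent": np.nan,
                         "drop_percent": np.nan, "recovery_percent": np.nan,
                         "halftime_min": np.nan, "flag": "incomplete"})
            continue
        post = float(p[win[0]])
        tail = win[-max(1, int(np.ceil(0.1 * win.size))):]
        plateau = float(np.mean(p[tail]))
        midpoint = 0.5 * (post + pre)
        crossed = win[p[win] >= midpoint]
        if crossed.size == 0:
            halftime = np.nan
        else:
            j = crossed[0]
            if j > win[0] and p[j] != p[j - 1]:
                # linear interpolation between the bracketing samples
                frac = (midpoint - p[j - 1]) / (p[j] - p[j - 1])
                halftime = float(t[j - 1] + frac * (t[j] - t[j - 1]) - ev)
            else:
                halftime = float(t[j] - ev)
        rows.append({"event_min": ev, "pre_percent": pre, "post_percent": post,
                     "drop_percent": pre - post, "recovery_percent": plateau,
                     "halftime_min": halftime, "flag": ""})
    return pd.DataFrame(rows)
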