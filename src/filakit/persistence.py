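"""Persistence-length estimation from tangent correlations.

For filaments adsorbed to a surface (or projected to the focal plane)
the tangent autocorrelation of a worm-like chain decays as
``<t(x) . t(x + dx)> = exp(-dx / (2 P))`` with ``P`` the persistence
length -- the factor 2 (rather than the 3D curve's 1) reflecting the
single bending mode available in the plane.  The estimator resamples
each traced path to uniform arc-length spacing, pools the tangent dot
products at each lag over all filaments, and fits the exponential over
a configurable lag window (default lags 2..8, i.e. 1.24-4.96 um at the
default 0.62 um spacing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .tracing import FilamentPath, resample_path

__all__ = [
    "CorrelationProfile",
    "PersistenceFit",
    "tangent_correlation",
    "fit_persistence",
    "persistence_by_condition",
    "select_near_mean_length",
]

#: above this mean correlation, the log-linear fit is used; below, nonlinear
LOGLIN_MIN_CORR = 0.2


@dataclass(frozen=True)
class CorrelationProfile:
    """Pooled tangent-correlation profile.

    lags are in index units of the resampling step; ``lags_um`` gives
    the arc-length separations.  ``n_pairs[k]`` counts the tangent
    pairs contributing at lag k, pooled over all filaments.
    """

    lags: np.ndarray
    mean_corr: np.ndarray
    n_pairs: np.ndarray
    step_um: float

    def __post_init__(self) -> None:
        if not np.isclose(self.mean_corr[0], 1.0):
            raise ValueError("zero-lag correlation must be 1")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(np.diff(self.n_pairs) > 0):
            raise ValueError("n_pairs must be nonincreasing in lag")

    @property
    def lags_um(self) -> np.ndarray:
        return self.lags * self.step_um


@dataclass(frozen=True)
class PersistenceFit:
    """Result of the exponential tangent-correlation fit."""

    P_um: float
    fit_lag_min: int
    fit_lag_max: int
    residual_rms: float
    n_filaments: int
    fit_se_um: float = float("nan")
    bootstrap_sd_um: float = float("nan")


def _tangents(path: FilamentPath) -> np.ndarray:
    seg = np.diff(path.points, axis=0)
    return seg / np.linalg.norm(seg, axis=1, keepdims=True)


def tangent_correlation(
    paths: list[FilamentPath],
    step_um: float = 0.62,
    max_lag: int = 8,
    resample: bool = True,
    per_filament_mean: bool = False,
) -> CorrelationProfile:
    """Average tangent correlation versus arc-length separation.

    Each path is resampled to uniform spacing ``step_um`` (skip with
    ``resample=False`` if already uniform); tangents are the unit
    vectors of consecutive segments, and lag k collects the dot
    products of all tangent pairs (i, i+k) within each path.  By
    default pairs are pooled with equal weight across filaments; set
    ``per_filament_mean`` to average per filament first and then across
    filaments.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=int)
    fil_means: list[np.ndarray] = []
    usable = 0
    for path in paths:
        try:
            rp = resample_path(path, step_um) if resample else path
        except ValueError:
            continue
        t = _tangents(rp)
        n = t.shape[0]
        if n < 2:
            continue
        usable += 1
        this_sum = np.zeros(max_lag + 1)
        this_cnt = np.zeros(max_lag + 1, dtype=int)
        this_sum[0] = n
        this_cnt[0] = n
        for k in range(1, min(max_lag, n - 1) + 1):
            d = np.einsum("ij,ij->i", t[:-k], t[k:])
            this_sum[k] = d.sum()
            this_cnt[k] = d.size
        sums += this_sum
        counts += this_cnt
        with np.errstate(invalid="ignore"):
            fil_means.append(np.where(this_cnt > 0, this_sum / np.maximum(this_cnt, 1), np.nan))
    if usable == 0 or counts[1] == 0:
        raise ValueError("no path long enough for lag 1 at this step")
    if per_filament_mean:
        stack = np.vstack(fil_means)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(stack, axis=0)
        n_pairs = np.sum(~np.isnan(stack), axis=0).astype(int)
        mean = np.where(n_pairs > 0, mean, np.nan)
    else:
        with np.errstate(invalid="ignore"):
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        n_pairs = counts
    # drop trailing lags with no pairs
    last = int(np.max(np.nonzero(n_pairs > 0)[0]))
    return CorrelationProfile(
        lags=np.arange(last + 1),
        mean_corr=mean[: last + 1],
        n_pairs=n_pairs[: last + 1],
        step_um=step_um,
    )


def fit_persistence(
    profile: CorrelationProfile,
    lag_min: int = 2,
    lag_max: int = 8,
    n_filaments: int = 0,
) -> PersistenceFit:
    """Fit ``exp(-dx / 2P)`` to a correlation profile over a lag window.

    The model has no intercept (pinned to 1 at dx=0).  When every mean
    correlation in the window exceeds LOGLIN_MIN_CORR the fit is least
    squares on the log-linear form ``ln c = -dx/(2P)``; otherwise a
    nonlinear fit is used, and values <= 0 are excluded from a
    log-linear path entirely.  A profile indistinguishable from 1
    returns ``P_um = inf`` with a warning (rigid-rod limit).
    """
    if lag_min >= lag_max:
        raise ValueError("lag_min must be below lag_max")
    if profile.lags[-1] < lag_max:
        raise ValueError("profile does not cover the fit window")
    sel = (profile.lags >= lag_min) & (profile.lags <= lag_max)
    x = profile.lags_um[sel]
    c = profile.mean_corr[sel]
    if np.any(~np.isfinite(c)):
        raise ValueError("fit window contains undefined correlations")

    if np.all(c >= 1.0 - 1e-9):
        warnings.warn("correlation indistinguishable from 1; rigid-rod limit", stacklevel=2)
        return PersistenceFit(
            P_um=float("inf"),
            fit_lag_min=lag_min,
            fit_lag_max=lag_max,
            residual_rms=0.0,
            n_filaments=n_filaments,
        )

    if np.all(c > LOGLIN_MIN_CORR):
        y = np.log(c)
        # least squares through the origin: slope = sum(xy)/sum(x^2)
        slope = float(np.dot(x, y) / np.dot(x, x))
        if slope >= 0:
            warnings.warn("non-decaying correlation; rigid-rod limit", stacklevel=2)
            return PersistenceFit(
                P_um=float("inf"),
                fit_lag_min=lag_min,
                fit_lag_max=lag_max,
                residual_rms=float(np.sqrt(np.mean((c - 1.0) ** 2))),
                n_filaments=n_filaments,
            )
        P = -1.0 / (2.0 * slope)
        resid = c - np.exp(slope * x)
        dof = max(x.size - 1, 1)
        slope_se = np.sqrt(np.sum((y - slope * x) ** 2) / dof / np.dot(x, x))
        P_se = slope_se / (2.0 * slope**2)
    else:
        def model(xx, P):
            return np.exp(-xx / (2.0 * P))

        try:
            popt, pcov = curve_fit(model, x, c, p0=[max(x.mean(), 1e-3)], maxfev=10000)
        except RuntimeError as exc:  # pragma: no cover - pathological profiles
            raise ValueError("insufficient correlation signal") from exc
        P = float(popt[0])
        if P <= 0 or not np.isfinite(P):
            raise ValueError("insufficient correlation signal")
        resid = c - model(x, P)
        P_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    return PersistenceFit(
        P_um=float(P),
        fit_lag_min=lag_min,
        fit_lag_max=lag_max,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_filaments=n_filaments,
        fit_se_um=float(P_se),
    )


def select_near_mean_length(
    paths: list[FilamentPath], n_sd: float = 1.0
) -> list[FilamentPath]:
    """Keep filaments whose length lies within ``n_sd`` SD of the group mean.

    Persistence fits are most reliable for filaments near the typical
    length: very short paths carry few lags and very long ones dominate
    the pooled average.
    """
    L = np.array([p.length_um for p in paths])
    if L.size < 3:
        return list(paths)
    mean, sd = L.mean(), L.std(ddof=1)
    keep = np.abs(L - mean) <= n_sd * sd + 1e-12
    return [p for p, k in zip(paths, keep) if k]


def persistence_by_condition(
    groups: dict[str, list[FilamentPath]],
    step_um: float = 0.62,
    lag_min: int = 2,
    lag_max: int = 8,
    bootstrap_reps: int = 200,
    seed: int = 0,
    length_filter_sd: float | None = 1.0,
) -> pd.DataFrame:
    """Fit one persistence length per condition with a bootstrap SD.

    Filaments are optionally pre-filtered to lengths within
    ``length_filter_sd`` SD of the group mean.  The bootstrap resamples
    filaments with replacement (``bootstrap_reps`` replicates, seeded);
    groups with fewer than 3 usable filaments are flagged instead of
    fitted.
    """
    if not groups:
        raise ValueError("at least one condition group required")
    rng = np.random.default_rng(seed)
    rows = []
    for name, paths in groups.items():
        used = select_near_mean_length(paths, length_filter_sd) if length_filter_sd else list(paths)
        if len(used) < 3:
            rows.append(
                {"condition": name, "P_um": np.nan, "bootstrap_sd_um": np.nan,
                 "fit_se_um": np.nan, "n_filaments": len(used), "flag": "too_few_filaments"}
            )
            continue
        prof = tangent_correlation(used, step_um=step_um, max_lag=lag_max)
        fit = fit_persistence(prof, lag_min, lag_max, n_filaments=len(used))
        boots = []
        for _ in range(bootstrap_reps):
            idx = rng.integers(0, len(used), size=len(used))
            try:
                bp = tangent_correlation([used[i] for i in idx], step_um=step_um, max_lag=lag_max)
                bf = fit_persistence(bp, lag_min, lag_max)
                if np.isfinite(bf.P_um):
                    boots.append(bf.P_um)
            except ValueError:
                continue
        bsd = float(np.std(boots, ddof=1)) if len(boots) > 1 else float("nan")
        rows.append(
            {"condition": name, "P_um": fit.P_um, "bootstrap_sd_um": bsd,
             "fit_se_um": fit.fit_se_um, "n_filaments": len(used), "flag": ""}
        )
    return pd.DataFrame(rows)
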