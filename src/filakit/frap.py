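"""FRAP: diffusion coefficients from circular-spot recovery curves.

The model is the uniform-disk 2D-diffusion closed form (Soumpasis):
f(t) = exp(-2 tau_D / t) [I0(2 tau_D / t) + I1(2 tau_D / t)],
tau_D = r^2 / (4 D), where r is the bleach-spot radius.  The fitted
curve is I(t) = f0 + (f_inf - f0) * f(t), from which the diffusion
coefficient D, the mobile fraction (f_inf - f0)/(1 - f0), and the
recovery half-time follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit
from scipy.special import ive

__all__ = ["RecoveryCurve", "FrapFit", "normalize_curve", "fit_frap", "half_recovery_time"]


@dataclass(frozen=True)
class RecoveryCurve:
    """Normalized FRAP recovery: intensity vs time since first postbleach frame."""

    t_s: np.ndarray
    intensity_norm: np.ndarray
    bleach_radius_um: float
    prebleach_frames: int = 3

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_s must be strictly increasing")
        if len(t) != len(self.intensity_norm):
            raise ValueError("time and intensity arrays must match")
        if self.bleach_radius_um <= 0:
            raise ValueError("bleach_radius_um must be positive")


@dataclass(frozen=True)
class FrapFit:
    """Fitted diffusion parameters of one recovery curve."""

    D_um2_per_s: float
    mobile_fraction: float
    tau_half_s: float
    residual_rms: float
    tau_d_s: float
    f0: float
    f_inf: float
    approximate: bool = False  # True when the exponential fallback was used


def _soumpasis(t: np.ndarray, tau_d: float) -> np.ndarray:
    from .synthdata import soumpasis_recovery

    return soumpasis_recovery(t, tau_d)


# x solving ive(0,x) + ive(1,x) = 1/2: the half-recovery point of the model
_X_HALF = brentq(lambda x: ive(0, x) + ive(1, x) - 0.5, 1e-6, 1e3)


def half_recovery_time(tau_d_s: float) -> float:
    """Time at which the uniform-disk model reaches half of its recovery."""
    return 2.0 * tau_d_s / _X_HALF


def normalize_curve(
    t_s: np.ndarray,
    i_roi: np.ndarray,
    i_ref: np.ndarray | None = None,
    prebleach_frames: int = 3,
    bleach_radius_um: float = 5.0,
) -> RecoveryCurve:
    """Double-normalize a raw FRAP measurement.

    Divides the ROI intensity by a reference-region intensity to cancel
    acquisition bleaching (skipped with a warning-free fallback when no
    reference is given), scales so the prebleach mean is 1, and rebases
    time so t = 0 at the first postbleach frame (which is excluded from
    the curve's time axis origin but kept as the first sample).
    """
    t = np.asarray(t_s, dtype=float)
    roi = np.asarray(i_roi, dtype=float)
    if prebleach_frames < 2:
        raise ValueError("need at least 2 prebleach frames")
    if len(t) <= prebleach_frames:
        raise ValueError("no postbleach frames")
    if i_ref is not None:
        ref = np.asarray(i_ref, dtype=float)
        if np.any(ref <= 0):
            raise ValueError("reference intensities must be positive")
        roi = roi / ref
    pre = roi[:prebleach_frames].mean()
    if pre <= 0:
        raise ValueError("nonpositive prebleach intensity")
    norm = roi / pre
    post_t = t[prebleach_frames:] - t[prebleach_frames]
    post_i = norm[prebleach_frames:]
    # shift so the first postbleach sample sits at one frame interval,
    # not exactly 0 (the model diverges at t=0)
    if len(post_t) > 1:
        dt = post_t[1] - post_t[0]
    else:
        dt = t[prebleach_frames] - t[prebleach_frames - 1]
    return RecoveryCurve(
        t_s=post_t + dt,
        intensity_norm=post_i,
        bleach_radius_um=bleach_radius_um,
        prebleach_frames=prebleach_frames,
    )


def fit_frap(curve: RecoveryCurve) -> FrapFit:
    """Fit the uniform-disk diffusion model to a normalized recovery curve.

    Nonlinear least squares over (tau_D, f0, f_inf) with deterministic
    multi-start initialization of tau_D on a log grid spanning 0.1-100 s;
    the best-SSE start wins.  If no start converges, a single-exponential
    fallback is fitted and flagged ``approximate``.
    """
    t = np.asarray(curve.t_s, dtype=float)
    y = np.asarray(curve.intensity_norm, dtype=float)
    if t.size < 10:
        raise ValueError("need at least 10 postbleach points")

    def model(tt, tau_d, f0, f_inf):
        return f0 + (f_inf - f0) * _soumpasis(tt, tau_d)

    f0_guess = float(np.clip(y[0], 0.0, 0.99))
    finf_guess = float(np.clip(np.mean(y[-max(3, t.size // 10):]), f0_guess + 1e-3, 1.5))
    best = None
    for tau0 in np.geomspace(0.1, 100.0, 13):
        try:
            popt, _ = curve_fit(
                model, t, y, p0=[tau0, f0_guess, finf_guess],
                bounds=([1e-6, -0.5, -0.5], [1e5, 1.5, 2.0]), maxfev=5000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        # exponential fallback: f0 + (f_inf - f0) (1 - exp(-t/tau))
        def expmodel(tt, tau, f0, f_inf):
            return f0 + (f_inf - f0) * (1.0 - np.exp(-tt / tau))

        popt, _ = curve_fit(expmodel, t, y, p0=[t[t.size // 2], f0_guess, finf_guess],
                            maxfev=10000)
        tau, f0, f_inf = popt
        # exponential half-time tau*ln2 mapped back through the disk model
        tau_d = _X_HALF * tau * np.log(2.0) / 2.0
        resid = expmodel(t, *popt) - y
        approx = True
    else:
        tau_d, f0, f_inf = best[1]
        resid = model(t, *best[1]) - y
        approx = False
    D = curve.bleach_radius_um**2 / (4.0 * tau_d)
    mobile = float(np.clip((f_inf - f0) / (1.0 - f0), 0.0, 1.0)) if f0 < 1 else float("nan")
    return FrapFit(
        D_um2_per_s=float(D),
        mobile_fraction=mobile,
        tau_half_s=float(half_recovery_time(tau_d)),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        tau_d_s=float(tau_d),
        f0=float(f0),
        f_inf=float(f_inf),
        approximate=approx,
    )
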