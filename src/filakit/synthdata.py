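"""Synthetic inputs with known ground truth for every pipeline stage.

Generates planar worm-like chains, renders them into noisy fluorescence
images, simulates assembly/disassembly porosity time series with a
photobleaching drift, builds two-channel GUV cross-section scenes, and
produces FRAP recovery curves from the uniform-disk 2D-diffusion closed
form.  Every generator takes an explicit seed; randomness never flows
through global state.

Conventions
-----------
Chains are 2D because the analysis targets surface-adsorbed/projected
filaments; successive tangent angles differ by independent Gaussian
increments of variance step/P, so the lag-k tangent correlation is
exactly exp(-k*step/(2P)) -- the same 2D convention the persistence
estimator fits.  Image noise is Poisson shot noise followed by additive
Gaussian read noise; both can be switched off.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage, special

from .tracing import FilamentPath

__all__ = [
    "WLCParams",
    "RenderParams",
    "KineticsParams",
    "GUVSceneParams",
    "FRAPParams",
    "PorosityGroundTruth",
    "sample_wlc",
    "render_filaments",
    "simulate_porosity_series",
    "render_guv_scene",
    "simulate_frap",
    "soumpasis_recovery",
]


# --------------------------------------------------------------------------
# parameter models


class WLCParams(BaseModel):
    """Worm-like chain sampling parameters (2D)."""

    persistence_length_um: float = Field(gt=0)
    contour_length_um: float = Field(gt=0)
    step_um: float = Field(default=0.62, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "WLCParams":
        if self.contour_length_um < 2 * self.step_um:
            raise ValueError("contour length must be at least two steps")
        if self.persistence_length_um < self.step_um / 2:
            raise ValueError(
                "persistence length below step/2 is outside the Gaussian-increment model"
            )
        return self


class RenderParams(BaseModel):
    """Image rendering parameters (pixel grid, PSF, noise)."""

    pixel_um: float = Field(default=0.155, gt=0)
    psf_sigma_um: float = Field(default=0.15, gt=0)  # confocal lateral resolution, FWHM ~0.35 um
    amplitude: float = Field(default=1000.0, gt=0)  # photons per filament pixel
    background: float = Field(default=10.0, ge=0)
    read_noise_sd: float = Field(default=2.0, ge=0)
    image_shape: tuple[int, int] = (256, 256)
    shot_noise: bool = True
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "RenderParams":
        if self.psf_sigma_um < self.pixel_um / 2:
            raise ValueError("psf_sigma_um must be at least half a pixel to be renderable")
        if min(self.image_shape) < 16:
            raise ValueError("image_shape must be at least 16x16")
        return self


class KineticsParams(BaseModel):
    """Assembly/disassembly porosity kinetics with bleach drift.

    Porosity relaxes first-order toward ``porosity_assembled`` with time
    constant ``tau_assembly_min``; each UV event instantaneously resets
    it to ``porosity_disassembled``.  Photobleaching inflates the raw
    pore fraction multiplicatively: raw = truth / (1 - bleach_slope*t),
    the drift that the standard correction p_corr = p*(1 - x_slope*t)
    inverts exactly.
    """

    tau_assembly_min: float = Field(gt=0)
    bleach_slope_per_min: float = Field(default=0.0, ge=0)
    porosity_assembled: float = Field(default=1.0, gt=0, le=1)
    porosity_disassembled: float = Field(default=0.18, ge=0, lt=1)
    uv_events_min: list[float] = Field(default_factory=list)
    duration_min: float = Field(gt=0)
    dt_min: float = Field(default=0.1, gt=0)
    noise_sd: float = Field(default=0.0, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "KineticsParams":
        if self.porosity_assembled <= self.porosity_disassembled:
            raise ValueError("assembled state must have higher porosity than disassembled")
        ev = self.uv_events_min
        if any(e < 0 for e in ev) or any(b <= a for a, b in zip(ev, ev[1:])):
            raise ValueError("uv_events_min must be nonnegative and strictly increasing")
        if ev and ev[-1] >= self.duration_min:
            raise ValueError("uv events must fall inside the duration")
        if self.bleach_slope_per_min * self.duration_min >= 1:
            raise ValueError("bleach_slope*duration >= 1 is nonphysical")
        return self


class GUVSceneParams(BaseModel):
    """Two-channel GUV equatorial cross-section scene."""

    radius_um: float = Field(gt=0)
    peripheral_fraction: float = Field(ge=0, le=1)
    membrane_intensity: float = Field(default=300.0, gt=0)
    filament_total: float = Field(default=1.0e6, gt=0)  # summed signal, channel 2
    shape: str = "circle"  # circle | ellipse | polygonal-deflated
    axis_ratio: float = Field(default=1.0, ge=1)
    n_vertices: int = Field(default=7, ge=3)  # polygonal-deflated only
    deflation: float = Field(default=0.12, ge=0, lt=0.5)
    shell_width_um: float = Field(default=0.8, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GUVSceneParams":
        if self.shape not in {"circle", "ellipse", "polygonal-deflated"}:
            raise ValueError("shape must be circle, ellipse or polygonal-deflated")
        return self


class FRAPParams(BaseModel):
    """Circular-spot FRAP recovery curve parameters."""

    D_um2_per_s: float = Field(gt=0)
    bleach_radius_um: float = Field(default=5.0, gt=0)
    bleach_depth: float = Field(default=0.8, gt=0, le=1)
    immobile_fraction: float = Field(default=0.0, ge=0, lt=1)
    t_max_s: float = Field(default=60.0, gt=0)
    dt_s: float = Field(default=0.5, gt=0)
    noise_sd: float = Field(default=0.0, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "FRAPParams":
        if self.dt_s >= self.t_max_s:
            raise ValueError("dt_s must be smaller than t_max_s")
        return self


# --------------------------------------------------------------------------
# worm-like chains


def sample_wlc(params: WLCParams) -> FilamentPath:
    """Sample one 2D worm-like chain with uniform spacing.

    Tangent angles follow a Gaussian random walk with per-step variance
    step/P, giving E[t(x) . t(x+ds)] = exp(-ds/(2P)) -- the planar
    convention.  The chain starts at the origin with a uniformly random
    initial direction and has floor(L/step)+1 points.
    """
    rng = np.random.default_rng(params.seed)
    step = params.step_um
    n_seg = int(np.floor(params.contour_length_um / step + 1e-9))
    sigma = np.sqrt(step / params.persistence_length_um)
    theta0 = rng.uniform(0, 2 * np.pi)
    dtheta = rng.normal(0.0, sigma, size=n_seg - 1) if n_seg > 1 else np.empty(0)
    theta = theta0 + np.concatenate([[0.0], np.cumsum(dtheta)])
    steps = step * np.stack([np.cos(theta), np.sin(theta)], axis=1)
    pts = np.concatenate([[[0.0, 0.0]], np.cumsum(steps, axis=0)])
    return FilamentPath(points=pts, pixel_um=np.nan, source_id=f"wlc-seed{params.seed}")


# --------------------------------------------------------------------------
# image rendering


def _deposit_psf(
    canvas: np.ndarray, pts_px: np.ndarray, mass_per_sample: float, sigma_px: float
) -> None:
    """Add a Gaussian PSF of total mass ``mass_per_sample`` at each point.

    Evaluated analytically on the pixel grid so the rendered
    cross-section of a line carries exactly the requested PSF sigma at
    any sub-pixel position.
    """
    H, W = canvas.shape
    r = int(np.ceil(4 * sigma_px))
    off = np.arange(-r, r + 1)
    x = pts_px[:, 0]
    y = pts_px[:, 1]
    cx = np.round(x).astype(int)
    cy = np.round(y).astype(int)
    gx = cx[:, None] + off[None, :]  # (n, w)
    gy = cy[:, None] + off[None, :]
    wx = np.exp(-((gx - x[:, None]) ** 2) / (2 * sigma_px**2))
    wy = np.exp(-((gy - y[:, None]) ** 2) / (2 * sigma_px**2))
    norm = mass_per_sample / (2 * np.pi * sigma_px**2)
    weights = norm * wy[:, :, None] * wx[:, None, :]  # (n, w, w)
    rows = np.broadcast_to(gy[:, :, None], weights.shape)
    cols = np.broadcast_to(gx[:, None, :], weights.shape)
    ok = (rows >= 0) & (rows < H) & (cols >= 0) & (cols < W)
    np.add.at(canvas, (rows[ok], cols[ok]), weights[ok])


def render_filaments(
    paths: list[FilamentPath], rp: RenderParams, offsets_um: list[tuple[float, float]] | None = None
) -> np.ndarray:
    """Render filaments into a noisy fluorescence image.

    Each path contributes a line-integrated Gaussian PSF profile whose
    integral is ``amplitude`` photons per pixel of backbone length, on a
    uniform ``background``; Poisson shot noise is applied first, then
    Gaussian read noise.  Paths must fit inside the field of view after
    the optional per-path offset (um) is applied.
    """
    H, W = rp.image_shape
    canvas = np.zeros((H, W), dtype=float)
    if offsets_um is None:
        offsets_um = [(0.0, 0.0)] * len(paths)
    sub = rp.pixel_um / 4.0  # dense sampling along the backbone
    for i, (path, off) in enumerate(zip(paths, offsets_um)):
        pts = path.points + np.asarray(off)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        targets = np.arange(0.0, s[-1] + sub / 2, sub)
        x = np.interp(targets, s, pts[:, 0]) / rp.pixel_um
        y = np.interp(targets, s, pts[:, 1]) / rp.pixel_um
        if x.min() < 0 or y.min() < 0 or x.max() > W - 1 or y.max() > H - 1:
            raise ValueError(f"path {i} falls outside the field of view")
        mass = rp.amplitude * (sub / rp.pixel_um)  # photons per backbone sample
        _deposit_psf(
            canvas, np.stack([x, y], axis=1), mass, rp.psf_sigma_um / rp.pixel_um
        )
    expected = canvas + rp.background
    rng = np.random.default_rng(rp.seed)
    img = rng.poisson(expected).astype(float) if rp.shot_noise else expected.copy()
    if rp.read_noise_sd > 0:
        img += rng.normal(0.0, rp.read_noise_sd, size=img.shape)
    return img


# --------------------------------------------------------------------------
# porosity kinetics


class PorosityGroundTruth(BaseModel, arbitrary_types_allowed=True):
    """Raw trace plus the drift-free ground truth, for validation."""

    t_min: np.ndarray
    p_raw: np.ndarray
    p_true: np.ndarray
    uv_events_min: list[float]
    bleach_slope_per_min: float


def simulate_porosity_series(kp: KineticsParams) -> PorosityGroundTruth:
    """Simulate a porosity time series over assembly/disassembly cycles.

    The drift-free porosity starts assembled, drops instantaneously to
    the disassembled level at each UV event and relaxes back first-order
    with ``tau_assembly_min``.  The raw (observed) trace divides the
    truth by (1 - bleach_slope*t), the multiplicative inflation that the
    linear bleach-correction formula removes exactly, then adds Gaussian
    noise.
    """
    t = np.arange(0.0, kp.duration_min + kp.dt_min / 2, kp.dt_min)
    p = np.full_like(t, kp.porosity_assembled)
    for ev in kp.uv_events_min:
        after = t >= ev
        dt = t[after] - ev
        p[after] = kp.porosity_disassembled + (
            kp.porosity_assembled - kp.porosity_disassembled
        ) * (1.0 - np.exp(-dt / kp.tau_assembly_min))
    raw = p / (1.0 - kp.bleach_slope_per_min * t)
    if kp.noise_sd > 0:
        rng = np.random.default_rng(kp.seed)
        raw = raw + rng.normal(0.0, kp.noise_sd, size=raw.shape)
    return PorosityGroundTruth(
        t_min=t,
        p_raw=raw,
        p_true=p,
        uv_events_min=list(kp.uv_events_min),
        bleach_slope_per_min=kp.bleach_slope_per_min,
    )


# --------------------------------------------------------------------------
# GUV scenes


def _scene_contour(gp: GUVSceneParams, n: int = 720) -> np.ndarray:
    """Closed contour (x_um, y_um) of the requested vesicle shape, centered at 0."""
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    if gp.shape == "circle":
        r = np.full_like(phi, gp.radius_um)
    elif gp.shape == "ellipse":
        a = gp.radius_um * gp.axis_ratio
        b = gp.radius_um
        r = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    else:  # polygonal-deflated: convex polygon inscribed in the circle
        rng = np.random.default_rng(gp.seed)
        verts_phi = np.sort(rng.uniform(0, 2 * np.pi, gp.n_vertices))
        verts_r = gp.radius_um * (1.0 - gp.deflation * rng.uniform(0.3, 1.0, gp.n_vertices))
        vx = verts_r * np.cos(verts_phi)
        vy = verts_r * np.sin(verts_phi)
        # straight segments between consecutive vertices, resampled by angle
        pts = []
        for k in range(gp.n_vertices):
            p0 = np.array([vx[k], vy[k]])
            p1 = np.array([vx[(k + 1) % gp.n_vertices], vy[(k + 1) % gp.n_vertices]])
            tt = np.linspace(0, 1, max(2, n // gp.n_vertices), endpoint=False)
            pts.append(p0[None, :] + tt[:, None] * (p1 - p0)[None, :])
        return np.concatenate(pts, axis=0)
    return np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)


def render_guv_scene(
    gp: GUVSceneParams, rp: RenderParams
) -> tuple[np.ndarray, np.ndarray]:
    """Render a (membrane, filament) channel pair of one GUV cross-section.

    The membrane channel is a thin bright contour of the requested
    shape.  The filament channel distributes ``filament_total`` signal
    as peripheral_fraction in a shell of width ``shell_width_um`` just
    inside the contour and the remainder uniformly over the lumen, so
    total above-background signal is conserved across
    peripheral_fraction.  Both channels get the RenderParams noise
    model.
    """
    H, W = rp.image_shape
    cx = (W - 1) / 2.0 * rp.pixel_um
    cy = (H - 1) / 2.0 * rp.pixel_um
    contour = _scene_contour(gp) + np.array([cx, cy])
    max_r = gp.radius_um * gp.axis_ratio
    if max_r + 2 * rp.psf_sigma_um > min(cx, cy):
        raise ValueError("vesicle does not fit inside the field of view")

    from skimage.draw import polygon as _rasterize_polygon

    rr, cc = _rasterize_polygon(
        contour[:, 1] / rp.pixel_um, contour[:, 0] / rp.pixel_um, shape=(H, W)
    )
    inside = np.zeros((H, W), dtype=bool)
    inside[rr, cc] = True

    # distance (um) from each inside pixel to the contour
    dist_px = ndimage.distance_transform_edt(inside)
    dist_um = dist_px * rp.pixel_um

    membrane = np.zeros((H, W))
    band = inside & (dist_um <= 2 * rp.pixel_um)
    membrane[band] = gp.membrane_intensity

    shell = inside & (dist_um <= gp.shell_width_um)
    lumen = inside
    filament = np.zeros((H, W))
    n_shell = int(shell.sum())
    n_lumen = int(lumen.sum())
    if n_shell == 0 or n_lumen == 0:
        raise ValueError("degenerate scene geometry")
    filament[shell] += gp.peripheral_fraction * gp.filament_total / n_shell
    filament[lumen] += (1.0 - gp.peripheral_fraction) * gp.filament_total / n_lumen

    def _noisy(expected: np.ndarray, seed: int) -> np.ndarray:
        blurred = ndimage.gaussian_filter(expected, rp.psf_sigma_um / rp.pixel_um)
        blurred = blurred + rp.background
        rng = np.random.default_rng(seed)
        img = rng.poisson(blurred).astype(float) if rp.shot_noise else blurred
        if rp.read_noise_sd > 0:
            img = img + rng.normal(0.0, rp.read_noise_sd, size=img.shape)
        return img

    return _noisy(membrane, rp.seed), _noisy(filament, rp.seed + 1)


# --------------------------------------------------------------------------
# FRAP


def soumpasis_recovery(t_s: np.ndarray, tau_d_s: float) -> np.ndarray:
    """Fractional recovery of a uniformly bleached disk under 2D diffusion.

    f(t) = exp(-2*tau_D/t) * [I0(2*tau_D/t) + I1(2*tau_D/t)], with
    tau_D = r^2/(4D); rises from 0 at t=0+ to 1 as t -> inf.  Uses
    exponentially scaled Bessel functions for numerical stability.
    """
    t = np.asarray(t_s, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = 2.0 * tau_d_s / t[pos]
    out[pos] = special.ive(0, x) + special.ive(1, x)
    return out


def simulate_frap(fp: FRAPParams) -> "RecoveryCurve":
    """Simulate a normalized FRAP recovery curve.

    intensity(t) = (1 - depth) + depth * (1 - immobile) * f(t), where f
    is the uniform-disk diffusion recovery with tau_D = r^2/(4D); the
    curve starts at 1 - depth and plateaus at 1 - immobile*depth.
    Gaussian noise of SD ``noise_sd`` is added when requested.
    """
    from .frap import RecoveryCurve

    t = np.arange(fp.dt_s, fp.t_max_s + fp.dt_s / 2, fp.dt_s)
    tau_d = fp.bleach_radius_um**2 / (4.0 * fp.D_um2_per_s)
    f = soumpasis_recovery(t, tau_d)
    intensity = (1.0 - fp.bleach_depth) + fp.bleach_depth * (1.0 - fp.immobile_fraction) * f
    if fp.noise_sd > 0:
        rng = np.random.default_rng(fp.seed)
        intensity = intensity + rng.normal(0.0, fp.noise_sd, size=intensity.shape)
    return RecoveryCurve(
        t_s=t,
        intensity_norm=intensity,
        bleach_radius_um=fp.bleach_radius_um,
        prebleach_frames=3,
    )
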