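"""GUV cross-section morphology: segmentation, cortex ratio, circularity.

Segments the vesicle from the membrane channel, extracts a subpixel
contour, and quantifies (a) cortex-like filament recruitment as the
ratio of membrane-proximal to luminal filament intensity,
I_peri / I_in, and (b) shape as the isoperimetric circularity
4*pi*A / Per^2 (1 for a circle, below 1 for deflated vesicles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .porosity import otsu_threshold_index

__all__ = [
    "GUVProfile",
    "segment_guv",
    "cortex_ratio",
    "circularity",
    "polygon_area",
    "polygon_perimeter",
    "profile_from_contour",
]


def polygon_area(contour: np.ndarray) -> float:
    """Shoelace area of a closed polygon (last-first edge implied)."""
    x, y = contour[:, 0], contour[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def polygon_perimeter(contour: np.ndarray) -> float:
    seg = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    return float(np.linalg.norm(seg, axis=1).sum())


@dataclass(frozen=True)
class GUVProfile:
    """Segmented vesicle: contour geometry plus an optional radial profile."""

    contour_um: np.ndarray  # closed ordered (x_um, y_um), last point != first
    center_um: tuple[float, float]
    area_um2: float
    perimeter_um: float
    pixel_um: float
    radial_profile: np.ndarray | None = None  # (r_norm, mean_intensity) rows

    def __post_init__(self) -> None:
        if self.contour_um.shape[0] < 10:
            raise ValueError("degenerate contour (fewer than 10 points)")
        if self.area_um2 <= 0 or self.perimeter_um <= 0:
            raise ValueError("area and perimeter must be positive")

    @property
    def equivalent_radius_um(self) -> float:
        return float(np.sqrt(self.area_um2 / np.pi))

    @property
    def circularity(self) -> float:
        return 4.0 * np.pi * self.area_um2 / self.perimeter_um**2


def profile_from_contour(contour_um: np.ndarray, pixel_um: float = 1.0) -> GUVProfile:
    """Build a GUVProfile directly from an analytic closed contour."""
    c = np.asarray(contour_um, dtype=float)
    return GUVProfile(
        contour_um=c,
        center_um=(float(c[:, 0].mean()), float(c[:, 1].mean())),
        area_um2=polygon_area(c),
        perimeter_um=polygon_perimeter(c),
        pixel_um=pixel_um,
    )


def _smooth_closed(contour: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Gaussian smoothing along a closed contour (wrap-around).

    Removes the pixel-level staircase of marching-squares contours,
    which would otherwise overestimate the perimeter and bias
    circularity low.
    """
    out = np.empty_like(contour)
    for j in (0, 1):
        out[:, j] = ndimage.gaussian_filter1d(contour[:, j], sigma, mode="wrap")
    return out


def segment_guv(
    membrane_image: np.ndarray, pixel_um: float, smooth_sigma_px: float = 3.0
) -> GUVProfile:
    """Segment one vesicle from its membrane channel.

    Otsu-thresholds the membrane signal, closes and fills the ring into
    a disk, keeps the largest connected component, and extracts a
    subpixel marching-squares contour smoothed with a Gaussian along
    the contour.  Raises if no vesicle is found; warns and takes the
    largest when several candidates exist.
    """
    img = np.asarray(membrane_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D membrane image")
    if img.max() == img.min():
        raise ValueError("no vesicle found")
    k, bin_idx = otsu_threshold_index(img.ravel())
    mask = (bin_idx > k).reshape(img.shape)
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3)), iterations=2)
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("no vesicle found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    if n > 1 and sizes[order[1]] > 0.5 * sizes[order[0]]:
        warnings.warn("multiple similar-size vesicles; taking the largest", stacklevel=2)
    mask = labels == (order[0] + 1)
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("no vesicle found")
    contour_rc = max(contours, key=len)
    if len(contour_rc) < 10:
        raise ValueError("degenerate contour (fewer than 10 points)")
    if np.allclose(contour_rc[0], contour_rc[-1]):
        contour_rc = contour_rc[:-1]
    contour_rc = _smooth_closed(contour_rc, smooth_sigma_px)
    contour_um = np.stack([contour_rc[:, 1], contour_rc[:, 0]], axis=1) * pixel_um
    return profile_from_contour(contour_um, pixel_um)


def _normalized_radius_map(
    profile: GUVProfile, shape: tuple[int, int]
) -> np.ndarray:
    """Per-pixel r/R(theta): radius normalized by the contour radius in
    that pixel's direction from the centroid (valid for star-shaped
    contours, which covers circles, ellipses and mildly deflated
    vesicles)."""
    cx, cy = profile.center_um
    c = profile.contour_um
    ang = np.arctan2(c[:, 1] - cy, c[:, 0] - cx)
    rad = np.hypot(c[:, 0] - cx, c[:, 1] - cy)
    order = np.argsort(ang)
    ang_s = ang[order]
    rad_s = rad[order]
    # pad for periodic interpolation
    ang_p = np.concatenate([ang_s - 2 * np.pi, ang_s, ang_s + 2 * np.pi])
    rad_p = np.tile(rad_s, 3)
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    px = xx * profile.pixel_um - cx
    py = yy * profile.pixel_um - cy
    theta = np.arctan2(py, px)
    r_contour = np.interp(theta.ravel(), ang_p, rad_p).reshape(H, W)
    return np.hypot(px, py) / r_contour


def radial_profile(
    intensity_image: np.ndarray, profile: GUVProfile, n_bins: int = 24, r_max: float = 1.2
) -> np.ndarray:
    """Mean intensity vs normalized radius r/R in equal bins up to r_max."""
    rn = _normalized_radius_map(profile, intensity_image.shape)
    img = np.asarray(intensity_image, dtype=float)
    edges = np.linspace(0.0, r_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    means = np.full(n_bins, np.nan)
    idx = np.digitize(rn.ravel(), edges) - 1
    flat = img.ravel()
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            means[b] = flat[sel].mean()
    return np.stack([centers, means], axis=1)


def estimate_background(
    intensity_image: np.ndarray, profile: GUVProfile, margin_um: float = 1.0
) -> float:
    """Background level: mode (histogram peak) of intensities outside the
    contour dilated by ``margin_um``."""
    rn = _normalized_radius_map(profile, intensity_image.shape)
    R = profile.equivalent_radius_um
    outside = rn > 1.0 + margin_um / R
    vals = np.asarray(intensity_image, dtype=float)[outside]
    if vals.size == 0:
        return 0.0
    hist, edges = np.histogram(vals, bins=64)
    j = int(np.argmax(hist))
    return float(0.5 * (edges[j] + edges[j + 1]))


def cortex_ratio(
    filament_image: np.ndarray,
    profile: GUVProfile,
    shell_frac: float = 0.15,
    lumen_frac: float = 0.7,
    background: float | None = None,
) -> float:
    """Peripheral-to-luminal filament intensity ratio I_peri / I_in.

    I_peri is the mean background-subtracted filament intensity in the
    shell r/R in [1 - shell_frac, 1]; I_in the mean in the central disk
    r/R in [0, lumen_frac].  A guard gap between lumen_frac and
    1 - shell_frac keeps membrane-adjacent signal out of the lumen
    estimate.  Returns 1 for a uniformly filled vesicle.
    """
    if not 0 < shell_frac < 1 or not 0 < lumen_frac < 1:
        raise ValueError("shell_frac and lumen_frac must lie in (0, 1)")
    if lumen_frac > 1 - shell_frac:
        raise ValueError("lumen and shell regions overlap; leave a guard gap")
    img = np.asarray(filament_image, dtype=float)
    rn = _normalized_radius_map(profile, img.shape)
    if background is None:
        background = estimate_background(img, profile)
    shell = (rn >= 1.0 - shell_frac) & (rn <= 1.0)
    lumen = rn <= lumen_frac
    if not shell.any() or not lumen.any():
        raise ValueError("degenerate shell/lumen geometry")
    i_peri = img[shell].mean() - background
    i_in = img[lumen].mean() - background
    if i_in <= 0:
        raise ValueError("empty lumen: luminal intensity at or below background")
    return float(i_peri / i_in)


def circularity(profile: GUVProfile) -> float:
    """Isoperimetric circularity 4*pi*A / Per^2 of the vesicle contour."""
    return profile.circularity
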