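"""Shared fixtures and helpers for the filakit test-suite.

All image fixtures are generated at test time from the synthetic-data
module; nothing is loaded from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

import filakit as fk


@pytest.fixture
def noise_free_render() -> fk.RenderParams:
    """Default rendering geometry with every noise source disabled."""
    return fk.RenderParams(shot_noise=False, read_noise_sd=0.0, seed=0)


@pytest.fixture
def noisy_render() -> fk.RenderParams:
    """Default rendering geometry with the full Poisson+Gaussian noise model."""
    return fk.RenderParams(seed=0)


def field_center_um(rp: fk.RenderParams) -> np.ndarray:
    H, W = rp.image_shape
    return np.array([(W - 1) / 2.0, (H - 1) / 2.0]) * rp.pixel_um


def center_chain(chain: fk.FilamentPath, rp: fk.RenderParams) -> fk.FilamentPath | None:
    """Recenter a chain in the field of view; None if it does not fit."""
    c = field_center_um(rp)
    pts = chain.points - chain.points.mean(axis=0) + c
    H, W = rp.image_shape
    margin = 3 * rp.psf_sigma_um
    if (
        pts[:, 0].min() < margin
        or pts[:, 1].min() < margin
        or pts[:, 0].max() > (W - 1) * rp.pixel_um - margin
        or pts[:, 1].max() > (H - 1) * rp.pixel_um - margin
    ):
        return None
    return fk.FilamentPath(points=pts, pixel_um=rp.pixel_um, source_id=chain.source_id)


def render_chains_and_trace(
    P_um: float,
    length_um: float,
    n_images: int,
    rp: fk.RenderParams,
    cfg: fk.TraceConfig | None = None,
    seed0: int = 0,
    min_keep_um: float = 0.0,
) -> list[fk.FilamentPath]:
    """Render one worm-like chain per image and trace it back.

    Skips chains that do not fit the field; keeps going until n_images
    renders were made or the candidate budget is exhausted.
    """
    cfg = cfg or fk.TraceConfig()
    paths: list[fk.FilamentPath] = []
    made = 0
    s = 0
    while made < n_images and s < 8 * n_images:
        chain = fk.sample_wlc(
            fk.WLCParams(
                persistence_length_um=P_um, contour_length_um=length_um, seed=seed0 + s
            )
        )
        s += 1
        placed = center_chain(chain, rp)
        if placed is None:
            continue
        img = fk.render_filaments([placed], rp.model_copy(update={"seed": seed0 + s}))
        made += 1
        traced = fk.trace_filaments(img, cfg, rp.pixel_um, source_id=f"sim{s}")
        paths.extend(t for t in traced if t.length_um >= min_keep_um)
    return paths
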