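"""Top-level workflows tying the stages into the three standard analyses:

``characterize``  filament lengths + persistence length from images,
``lightcycle``    porosity kinetics with bleach correction and cycle summary,
``cortex``        GUV segmentation, cortex ratio and circularity.

Each workflow runs on synthetic inputs generated from its config (the
self-validating mode used throughout the test-suite) or on files the
config points at, and writes one JSON report plus a manifest recording
every parameter actually used, the seed, and package versions, so
deterministic stages reproduce bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .frap import fit_frap
from .guvmorph import circularity, cortex_ratio, segment_guv
from .persistence import fit_persistence, tangent_correlation
from .porosity import bleach_correct, cycle_summary, trace_from_stack
from .synthdata import (
    FRAPParams,
    GUVSceneParams,
    KineticsParams,
    RenderParams,
    WLCParams,
    render_filaments,
    render_guv_scene,
    sample_wlc,
    simulate_frap,
)
from .tracing import TraceConfig, length_stats, trace_filaments

__all__ = ["RunConfig", "run_workflow", "derive_seed"]


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the single top-level seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


class CharacterizeConfig(BaseModel):
    n_filaments: int = 15
    persistence_length_um: float = 10.0
    contour_length_um: float = 10.0
    trace: dict = Field(default_factory=dict)
    render: dict = Field(default_factory=dict)
    lag_min: int = 2
    lag_max: int = 8


class LightcycleConfig(BaseModel):
    kinetics: dict = Field(default_factory=lambda: {
        "tau_assembly_min": 10.0, "bleach_slope_per_min": 0.004,
        "uv_events_min": [5.0, 35.0, 65.0, 95.0, 125.0], "duration_min": 155.0,
    })


class CortexConfig(BaseModel):
    scene: dict = Field(default_factory=lambda: {"radius_um": 10.0, "peripheral_fraction": 0.8})
    render: dict = Field(default_factory=dict)
    frap: dict | None = None


class RunConfig(BaseModel):
    """Validated workflow configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    pixel_um: float = Field(default=0.155, gt=0)
    frame_interval: float = Field(default=1.0, gt=0)
    frame_interval_unit: Literal["s", "min"] = "min"
    seed: int = 0
    output_dir: Path = Path("filakit-out")
    characterize: CharacterizeConfig = Field(default_factory=CharacterizeConfig)
    lightcycle: LightcycleConfig = Field(default_factory=LightcycleConfig)
    cortex: CortexConfig = Field(default_factory=CortexConfig)


def _write_manifest(outdir: Path, config: RunConfig, workflow: str) -> None:
    # hash covers everything that influences the outputs (not the
    # destination directory)
    cfg_json = config.model_dump_json(exclude={"output_dir"})
    manifest = {
        "workflow": workflow,
        "filakit_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _run_characterize(config: RunConfig, outdir: Path) -> dict:
    cc = config.characterize
    seed = derive_seed(config.seed, "characterize")
    rp = RenderParams(pixel_um=config.pixel_um, seed=seed, **cc.render)
    cfg = TraceConfig(**cc.trace)
    H, W = rp.image_shape
    all_paths = []
    for i in range(cc.n_filaments):
        wlc = sample_wlc(WLCParams(
            persistence_length_um=cc.persistence_length_um,
            contour_length_um=cc.contour_length_um, seed=seed + i + 1,
        ))
        pts = wlc.points - wlc.points.mean(axis=0)
        center = np.array([(W - 1) / 2.0, (H - 1) / 2.0]) * rp.pixel_um
        img = render_filaments(
            [type(wlc)(points=pts + center, pixel_um=rp.pixel_um)],
            rp.model_copy(update={"seed": seed + 10_000 + i}),
        )
        all_paths.extend(trace_filaments(img, cfg, rp.pixel_um, source_id=f"img{i}"))
    if not all_paths:
        raise RuntimeError("characterize workflow traced no filaments")
    stats = length_stats(all_paths)
    profile = tangent_correlation(all_paths, step_um=cfg.resample_step_um, max_lag=cc.lag_max)
    fit = fit_persistence(profile, cc.lag_min, cc.lag_max, n_filaments=len(all_paths))
    return {
        "n_filaments": stats["n"],
        "mean_length_um": stats["mean_um"],
        "sd_length_um": stats["sd_um"],
        "persistence_length_um": fit.P_um,
        "persistence_fit_rms": fit.residual_rms,
        "true_persistence_length_um": cc.persistence_length_um,
    }


def _run_lightcycle(config: RunConfig, outdir: Path) -> dict:
    from .synthdata import simulate_porosity_series

    seed = derive_seed(config.seed, "lightcycle")
    kp = KineticsParams(seed=seed, **config.lightcycle.kinetics)
    sim = simulate_porosity_series(kp)
    from .porosity import PorosityTrace

    raw = PorosityTrace(
        t_min=sim.t_min, p_raw=sim.p_raw, p_corr=sim.p_raw.copy(),
        p_norm=100.0 * sim.p_raw / sim.p_raw[0], uv_events_min=sim.uv_events_min,
    )
    corrected = bleach_correct(raw)
    cycles = cycle_summary(corrected)
    cycles.to_csv(outdir / "cycles.csv", index=False)
    return {
        "n_cycles": int(len(cycles)),
        "fitted_bleach_slope_per_min": corrected.x_slope_per_min,
        "true_bleach_slope_per_min": kp.bleach_slope_per_min,
        "mean_recovery_percent": float(np.nanmean(cycles["recovery_percent"])),
        "mean_post_drop_percent": float(np.nanmean(cycles["post_percent"])),
    }


def _run_cortex(config: RunConfig, outdir: Path) -> dict:
    seed = derive_seed(config.seed, "cortex")
    gp = GUVSceneParams(seed=seed, **config.cortex.scene)
    rp = RenderParams(pixel_um=config.pixel_um, seed=seed, **config.cortex.render)
    membrane, filament = render_guv_scene(gp, rp)
    profile = segment_guv(membrane, rp.pixel_um)
    ratio = cortex_ratio(filament, profile)
    report = {
        "equivalent_radius_um": profile.equivalent_radius_um,
        "circularity": circularity(profile),
        "cortex_ratio": ratio,
        "true_peripheral_fraction": gp.peripheral_fraction,
        "saturating": bool(ratio > 5.0),
    }
    if config.cortex.frap:
        fp = FRAPParams(seed=seed, **config.cortex.frap)
        fit = fit_frap(simulate_frap(fp))
        report["frap_D_um2_per_s"] = fit.D_um2_per_s
        report["frap_mobile_fraction"] = fit.mobile_fraction
        report["true_D_um2_per_s"] = fp.D_um2_per_s
    return report


def run_workflow(name: str, config: RunConfig) -> dict:
    """Run one named workflow and write report + manifest to the output dir."""
    runners = {
        "characterize": _run_characterize,
        "lightcycle": _run_lightcycle,
        "cortex": _run_cortex,
    }
    if name not in runners:
        raise ValueError(f"unknown workflow {name!r}; pick one of {sorted(runners)}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = runners[name](config, outdir)
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    _write_manifest(outdir, config, name)
    return report
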