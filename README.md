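# filakit

Quantitative image analysis for DNA-filament cytoskeletons inside giant
unilamellar vesicles (GUVs), aimed at synthetic-cell experiments in
which DNA-tile nanotubes polymerize into micrometer-long filaments,
bundle under macromolecular crowding, disassemble on UV illumination
via azobenzene photoswitches, and attach to the membrane to form a
cortex-like network.

The package implements the five measurements such experiments rely on,
together with a synthetic-data generator that produces every input with
known ground truth, so that each stage is validated by parameter
recovery:

- **Filament tracing** (`filakit.tracing`) — Steger-style ridge
  detection (Hessian eigenvalue response, non-maximum suppression,
  hysteresis linking, sub-pixel centerline refinement) extracts ordered
  filament coordinates and length statistics from fluorescence images.
- **Persistence length** (`filakit.persistence`) — for surface-adsorbed
  (planar) filaments the tangent autocorrelation decays as
  ⟨t̂(x)·t̂(x+Δx)⟩ = e^(−Δx/2P); the estimator resamples traced paths to
  Δs = 0.62 µm spacing, pools tangent pairs at each lag, and fits the
  exponential over lags 2–8.
- **Porosity kinetics** (`filakit.porosity`) — the below-Otsu-threshold
  pixel fraction measures the degree of polymerization (condensed
  filaments → large dark pores → high porosity); photobleaching drift
  is removed with the linear correction p_corr = p·(1 − x_slope·t)
  fitted on disassembled-state baselines, and assembly/disassembly
  cycles are summarized per UV event.
- **GUV morphology** (`filakit.guvmorph`) — membrane-channel
  segmentation to a sub-pixel contour; cortex formation quantified as
  I_peri/I_in (membrane-proximal over luminal filament intensity);
  shape quantified as circularity 4πA/Per².
- **FRAP** (`filakit.frap`) — recovery of a uniformly bleached disk
  under 2D diffusion, f(t) = e^(−2τ_D/t)[I₀(2τ_D/t) + I₁(2τ_D/t)] with
  τ_D = r²/4D, fitted for the diffusion coefficient and mobile
  fraction.
- **Synthetic data** (`filakit.synthdata`) — seeded generators for 2D
  worm-like chains, rendered noisy images (Gaussian PSF, Poisson + read
  noise), porosity time series with bleach drift, two-channel GUV
  scenes, and FRAP curves.

## Worked example

```python
import filakit as fk

chains = [
    fk.sample_wlc(fk.WLCParams(
        persistence_length_um=21.7, contour_length_um=108.5, seed=s))
    for s in range(200)
]
profile = fk.tangent_correlation(chains, step_um=0.62, max_lag=8, resample=False)
fit = fk.fit_persistence(profile, lag_min=2, lag_max=8)
print(f"fitted persistence length: {fit.P_um:.2f} um")
```

prints

```
fitted persistence length: 21.99 um
```

— the tangent-correlation fit recovers the 21.7 µm ground-truth
stiffness of the simulated chains to within its Monte-Carlo spread.
The `examples/` directory holds one short script per capability
(tracing round trip, light-cycle porosity, GUV cortex/shape, FRAP),
each printing the recovered values next to the ground truth.

A thin command-line layer exposes the same stages
(`filakit simulate|trace|persistence|porosity|guv|frap|run`); TIFF in,
CSV/JSON out.

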