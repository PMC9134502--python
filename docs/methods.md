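# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Worm-like chains and the persistence-length estimator

Filaments adsorbed to a surface (or projected into the focal plane) are
modeled as planar worm-like chains: tangent angles perform a Gaussian
random walk with per-step variance Δs/P, so the tangent correlation at
arc separation Δx is exactly e^(−Δx/2P). The factor 2 in the exponent
is the two-dimensional convention (one bending mode); estimator and
generator share it, so recovery is self-consistent by construction.
The default step Δs = 0.62 µm (4 pixels at 0.155 µm/pixel) matches the
coordinate spacing of the tracing convention. Chains with P < Δs/2 are
rejected: there the unwrapped-Gaussian angle model stops being a
meaningful discretization of a continuous filament.

`tangent_correlation` pools all tangent pairs at a given lag over all
filaments with equal weight (a per-filament-first average is available
behind a flag). `fit_persistence` fits e^(−Δx/2P) with no amplitude
parameter, by least squares on ln c when every windowed value exceeds
0.2 and by direct nonlinear least squares otherwise; the default
window, lags 2–8 (1.24–4.96 µm), skips the lags most affected by
tracing noise and PSF smoothing. Δx enters the exponent in µm; since
the model is a pure exponential, an index-unit convention would only
rescale P by Δs and both are exposed through `step_um`. A profile
indistinguishable from 1 returns P = +inf with a warning rather than an
unstable large number. `persistence_by_condition` adds a
filaments-with-replacement bootstrap (default 200 replicates, seeded)
and, by default, pre-filters each group to filaments within 1 SD of the
group's mean length, where the pooled estimator is best conditioned.

Two systematic effects are worth knowing about. First, with few, short
filaments the estimator inherits the convexity of P = −1/(2·slope):
noisy slopes inflate the mean recovered P (about +10% at 12 chains of
10 µm, vanishing by ~50 chains). Second, tracing smooths the
centerline at the PSF/ridge-filter scale, which raises all tangent
correlations by a nearly constant factor; because the fit is pinned
through 1 at Δx = 0, this inflates P by a further ~10–15% at P = 10–20
µm under the default imaging conditions. The full-pipeline validation
(render → trace → resample → fit) therefore targets 25% accuracy,
while the tracing-free estimator is validated to 5%.

## Image rendering

Rendered filaments deposit an analytically evaluated Gaussian PSF at
densely spaced backbone samples (quarter-pixel spacing), so a line's
perpendicular cross-section carries exactly the requested PSF sigma at
any sub-pixel position. Defaults: 0.155 µm pixels, PSF σ = 0.15 µm
(FWHM ≈ 0.35 µm, a typical working confocal lateral resolution),
amplitude 1000 photons per pixel of backbone length over a 10-photon
background — dye-dense DNA nanotubes image brightly, and this puts the
peak signal-to-noise near 15. Noise is Poisson on the expected photon
count followed by additive Gaussian read noise (SD 2); both can be
switched off, and every generator takes an explicit seed (no global
random state).

## Filament tracing

The tracer follows the curvilinear-detector recipe: ridge response =
the negative of the most negative Hessian eigenvalue at scale
`ridge_sigma_px` (default 1.15, the low end of the standard 1.15–2
range, appropriate for thin lines), computed with Gaussian derivatives
and reflective boundaries; non-maximum suppression across the local
ridge normal (the Hessian eigenvector); hysteresis linking on the
response normalized to 0–255, keeping candidate chains that contain at
least one pixel above the upper threshold (defaults 2/27, inside the
conventional 0–5 and 26–28 ranges); skeletonization; and a graph walk
that splits the skeleton at junction pixels, so each crossing branch
becomes its own path (merging through crossings would inflate lengths);
branches are extended back to the junction pixel so no length is lost
at splits. Centerlines are refined to sub-pixel accuracy by a quadratic
peak fit across the ridge normal. Tips are localized by the
half-maximum rule: the ridge response of a terminating line falls to
half its mid-line value exactly at the endpoint, so each path is
trimmed (with sub-pixel interpolation) to the half-of-median crossing.
Paths shorter than 1 µm are discarded as noise. On noise-free rendered
chains with P ≥ 10 µm the traced length is within 3% of the true
contour length in over 95% of cases; noise adds ~1 µm of scatter and
occasional short spurious fragments, which the minimum-length filter
removes.

`resample_path` re-parameterizes a path to uniform **chord** spacing:
each point is placed where a circle of radius Δs around the previous
point first meets the remaining polyline. This matches the chain
generator's convention (segments are exact chords), makes consecutive
spacing exactly Δs, and is idempotent.

## Porosity and bleach correction

Porosity is the fraction of ROI pixels below an Otsu threshold. The
orientation matters: polymerization condenses fluorescence into thin
bright filaments and leaves large dark pores (high porosity), while
UV-disassembled homogeneous fluorescence puts most pixels above
threshold (low porosity). The threshold is computed on a 256-bin
histogram after per-ROI min–max scaling, maximizing inter-class
variance with ties broken toward the lower threshold; this exact
binning/tie-break contract is implemented directly (and cross-checked
against both an exhaustive search and `skimage.filters.threshold_otsu`
in the tests) so that porosity is invariant under monotone affine
intensity rescaling. A constant frame returns porosity 1.0 (single
class, threshold undefined).

Photobleaching dims the signal over an acquisition and thereby
inflates the below-threshold fraction; the generator models this as a
multiplicative drift p_raw = p_true/(1 − x_slope·t), the form that the
standard linear correction p_corr = p_raw·(1 − x_slope·t) inverts
exactly. x_slope is estimated from disassembled-state windows, where
the drift-free porosity is constant: there 1/p_raw is exactly linear in
t, so a straight-line fit of the reciprocal gives x_slope =
−slope/intercept with no linearization error (a direct linear fit of p
itself would carry an O((x_slope·t)²) bias and could not reach the
machine-precision inversion the tests require). Default windows are
the 2 minutes after each UV event; the validation uses the event
instants themselves, where the disassembled level holds exactly even
while reassembly is underway.

`cycle_summary` reports, per UV event on the first-frame-normalized
trace: the pre-event level, the post-event level (first sample after
the event), their difference as the drop, the recovery plateau (mean of
the last 10% of the inter-event window — for a first-order recovery
with τ = 10 min over 30 min this sits ~0.7 points below the endpoint
value), and the half-time, interpolated linearly at the crossing of the
midpoint between post-event and pre-event levels (τ·ln 2 for a clean
first-order recovery). Events with fewer than three remaining samples
are flagged incomplete rather than summarized.

## GUV morphology

Vesicles are segmented from the membrane channel: Otsu threshold →
morphological closing and hole filling → largest connected component →
marching-squares sub-pixel contour, smoothed along the contour with a
Gaussian of σ = 3 samples (≈3 px). The smoothing scale is chosen to
cancel the pixel-staircase perimeter overestimate of marching squares
(≈3% for a 50 px radius circle, which would bias circularity to ~0.97);
at σ = 3 a rendered circle measures circularity 0.998–0.999 while the
area changes by <0.2%, and shape differences at the vesicle scale
(many pixels) are preserved. Circularity is 4πA/Per² from the shoelace
area and polygon perimeter of that contour.

The cortex ratio divides the mean background-subtracted filament
intensity in the shell r/R ∈ [0.85, 1] by the mean in the central disk
r/R ∈ [0, 0.7]; the gap in between keeps membrane-adjacent signal out
of the luminal estimate. Radii are normalized direction-wise by the
contour radius at each pixel's bearing from the centroid (valid for
star-shaped contours, which covers circles, ellipses and mildly
deflated shapes). Background defaults to the histogram mode outside
the contour dilated by 1 µm. A lumen at or below background raises an
"empty lumen" error rather than returning an unstable ratio; fully
cortical scenes should be measured with explicit background handling.

The scene generator conserves total filament signal across
peripheral-fraction settings, placing the peripheral share in a
0.8-µm-wide shell inside the contour and the rest uniformly over the
whole interior. Deflated vesicles are modeled as convex polygons
inscribed in the nominal circle — a shape proxy that lowers circularity
the way osmotic deflation does, without any membrane mechanics.

## FRAP

Simulator and fitter share the uniform-disk 2D-diffusion closed form
f(t) = e^(−2τ_D/t)[I₀ + I₁](2τ_D/t), τ_D = r²/4D, evaluated with
exponentially scaled Bessel functions. The fitted curve is
I(t) = f0 + (f∞ − f0)·f(t) with parameters (τ_D, f0, f∞), giving
D = r²/4τ_D, mobile fraction (f∞ − f0)/(1 − f0), and the half-time
from the model's midpoint crossing (t_half = 2τ_D/x½ with
ive₀(x½)+ive₁(x½) = ½). Initialization is a deterministic multi-start
over τ_D ∈ [0.1, 100] s (13 log-spaced starts, best SSE wins); if no
start converges, a single-exponential fallback is fitted and flagged
approximate. Because one declared model serves both sides, round-trip
recovery alone would not catch a wrong model; the (D, r) → (4D, 2r)
scaling-law test provides a dimensional-analysis check that does not
share that blindness. Defaults follow the standard acquisition: 5 µm
bleach radius (10 µm ROI diameter), three prebleach frames, ≤60 s
recovery window. Double normalization (ROI over reference region, then
prebleach mean to 1) is the default; without a reference channel the
ROI-only normalization is used. Reaction-binding FRAP models and
membrane-curvature corrections are out of scope.

## Workflows, I/O and seeds

Three end-to-end workflows (`characterize`, `lightcycle`, `cortex`)
validate their configuration with pydantic (unknown keys rejected),
derive one sub-seed per stage from the single top-level seed via
SHA-256, and write a JSON report plus a manifest (config hash excluding
the output directory, seed, package versions) sufficient to reproduce
the outputs bit-for-bit. Images travel as TIFF with pixel size and
frame interval in a JSON ImageDescription tag; traces, curves and paths
as CSV. The command-line layer is a thin wrapper over these functions.

## Validation scale and limitations

The test-suite and the acceptance script size their simulations to run
on a single CPU in minutes: 200 chains per stiffness for the direct
estimator (validated to 5% bias / 10% spread over P = 2–30 µm), 20
seeds × 25 rendered images per stiffness for the full tracing pipeline
(validated to 25% at P = 10 and 20 µm), 100 images for the Otsu
cross-check, and 20 noisy curves for the slow-diffusion FRAP regime.

The generator emulates the geometry and noise of the real experiments
but not everything in them: filaments are rendered as uniform-intensity
planar curves (no 3D excursions, no intensity variation along bundles,
no depletion-force physics — bundling enters only as a larger
ground-truth P); porosity kinetics are a clean first-order relaxation
with instantaneous UV resets; GUV scenes are single vesicles with
azimuthally uniform cortex signal; FRAP ignores diffusion during the
bleach pulse. Passing recovery tests therefore demonstrates that the
estimators are unbiased and stable under the declared models and
realistic sampling noise, not that they are robust to every artifact of
real microscopy (uneven illumination, filament overlap density,
membrane fluctuations, z-drift). Very long, low-contrast filaments may
be fragmented by the tracer, as interactive re-tracing is not
implemented.
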