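# Methods

## Scope and model

`frapsr` quantifies fluorescence recovery after photobleaching (FRAP) of
nuclear condensates imaged in the super-resolution regime, where a single
focus can be resolved into subcompartments with distinct protein
mobilities. The package couples a forward simulator (so every analysis
step can be exercised against known ground truth) with the analysis
pipeline itself: segmentation and morphometrics, double-normalized FRAP
kinetics, spatially resolved subcompartment analysis, and a twin-bead
resolvability assay.

### Kinetic model

Exchange is modelled compartmentally, not as a spatial diffusion PDE:
each subcompartment has one exchange rate constant `k` (1/s) and one
mobile fraction `m ∈ [0, 1]`. After an instantaneous bleach of depth `d`
at `t = 0`, the fluorescent fraction inside the bleached region follows
the one-phase association

    f(t) = f_post + m (1 − f_post)(1 − e^(−k t)),    f_post = 1 − d.

This is deliberate: the downstream analysis fits one-phase association
curves, so the generator realizes exactly that model and calibration
round-trips are meaningful. A reaction–diffusion mode is out of scope.
The free nucleoplasmic pool recovers by the same law with its own rate
(default 0.3 1/s, fast relative to focus exchange) and mobile fraction 1.

The real experiment's 0.5-s bleach pulse is collapsed to an event at
`t = 0` with uniform depth inside a disk ROI; laser physics, blinking,
reversible photobleaching, and acquisition photobleaching are not
modelled (the double normalization divides acquisition bleaching out in
any case, and the simulator's control region is stationary).

### Image formation

Scene coordinates are nanometres, origin at the top-left pixel centre,
x along columns; times are seconds relative to bleach end. Rendering per
frame: rasterize emitter densities at pixel centres → convolve with an
isotropic Gaussian PSF of the stated FWHM → scale to expected photons →
Poisson shot noise → Gaussian read noise → camera offset. Wide-field,
SIM, and diSIM rendering are emulated purely as PSF widths of 250, 120,
and 60 nm FWHM; no structured-illumination forward model or
reconstruction artifacts are simulated. Pixel size defaults to FWHM/2.5
(Nyquist requires ≤ FWHM/2 and construction enforces it). The default
stack has 3 pre-bleach and 24 post-bleach frames at 5-s intervals and 3
z-planes; kinetics are applied before projection and z-planes are
replicate 2-D renders with independent noise, matching the convention
that the z-stack sum intensity is used for kinetic measurements.

Default photon scale (80 photons per unit density) puts the focus
interior (density 5) at ≈ 400 expected photons/pixel, i.e. a per-pixel
shot-noise SNR of 20; read noise is 2 photons rms and the camera offset
100 counts.

### Scene presets

Four presets encode the study conditions through their published mean
half-times, converted to rates by `k = ln 2 / t½`:

| preset | foci | t½ (s) | mobile fraction |
|---|---|---|---|
| `untreated_compact` | 1 compact | 19.67 | 0.85 |
| `untreated_amorphous` | 1 amorphous, 2 subcompartments | 15.58 (mean) | 0.9 |
| `aphidicolin_arrest` | 1 compact | 28.6 | 0.7 |
| `aphidicolin_release` | 1 compact + 1 amorphous | 28.6 / 10.25 | 0.7 / 0.9 |

Amorphous presets split their mean rate geometrically with a 4× contrast
(fast = 2k̄, slow = k̄/2), comfortably above the ≥ 3× contrast at which
the multi-compartment caller is validated. Mobile fractions are not
reported per condition in the source data; the values above encode the
qualitative ordering (arrested compact foci show the largest immobile
fraction) and are stated generator conventions, not measurements.

A compact focus is a disk (600 nm radius); an amorphous focus is a
chain of five overlapping lobes (radii 235–285 nm) forming a connected,
clearly non-convex blob. Shape dynamics are a stationary AR(1)
(mean-reverting) walk of the lobe centres with stationary sd 45 nm per
coordinate and lag-1 correlation 0.8. A plain cumulative random walk was
rejected because its unbounded drift tears the blob into disconnected
components within a ~27-frame movie; the AR(1) keeps the contour
"irregular and dynamically shape changing" while remaining a single
object, which is also what keeps the frame-to-frame IoU feature of the
contour classifier meaningful.

### Bead phantoms

Twin-emitter pairs (DNA-origami nanoruler analogues) are rendered as two
equal analytic Gaussians at the stated separation with random
orientation, midpoints at least 5 PSF FWHM apart (rejection sampling;
an impossible packing raises). Ground truth (midpoint, angle,
separation) is returned as a table.

## Analysis pipeline

### Segmentation and morphometrics

The nucleus is the largest connected component above a three-class
multi-Otsu threshold (lowest cut), holes filled. Plain two-class Otsu
fails here: with bright foci present it separates foci from everything
else and returns the focus as the "nucleus". Foci are connected
components above an intensity threshold (default: Otsu within the
nucleus; absolute override available) filtered by minimum area and mean
intensity; border-touching foci are kept but flagged.

The sphericity index is the convex-hull perimeter divided by the
boundary perimeter — 1 for convex shapes, toward 0 with increasing
spikiness. Both perimeters are measured on the *same* sub-pixel
marching-squares boundary polygon so the ratio is internally consistent
and bounded by 1. The mask is lightly smoothed (Gaussian, σ = 1 px)
before contouring: the 0.5-level contour of a raw binary image is a
staircase whose length overestimates a disk's perimeter by ~5%, which
would bias every sphericity downward. With smoothing a rasterized disk
scores 1.0 ± 0.02; exact polygon input (e.g. the plus-pentomino with
perimeter 12 and hull perimeter 4 + 4√2) is handled without
rasterization.

Tracking is greedy nearest-centroid linking with a max-jump gate
(default 1 µm/frame); unmatched foci start or end tracks, never swap.
Displacement is the Euclidean distance between centroids at the frames
nearest −5 s and +40 s.

### FRAP normalization and fitting

The double normalization is

    r = (Fc − Fb)/(Fc₀ − Fb),  R = (Fi − Fb)/(Fi₀ − Fb),  N = R/r,

with the background Fb applied per frame and the baselines Fi₀, Fc₀
means over all pre-bleach frames. Near-zero denominators raise an error
naming the offending frame. For synthetic data the control region
defaults to the nucleus minus the (dilated) bleach ROI.

The fitter minimizes least squares of
`y(t) = f_post + (plateau − f_post)(1 − e^(−kt))` with bounds
k ∈ (10⁻⁴, 10] 1/s and three deterministic k starts (0.01, 0.05,
0.2 1/s) to avoid local minima; `t_half = ln 2 / k` exactly. Flat series
return `converged=False` with parameters and a message rather than being
dropped. The immobile fraction is `1 − (plateau − f_post)/(1 − f_post)`
clipped to [0, 1] — one documented choice among several plausible
normalizations of an acknowledged ambiguity, isolated in one function.
The recovery/plateau period partition takes the first five post-bleach
frames (< 25 s at the 5-s cadence) as the recovery period and the rest
as plateau; irregular timing falls back to the 25-s boundary.

### Subcompartment analysis

The recovery map applies the same double normalization per pixel, using
each pixel's own pre-bleach mean as baseline and the shared control and
background series; pixels that leave a shape-changing mask are carried
as missing, and a focus lost from tracking truncates the map with a
flag.

`watershed_lag` decomposition works on the per-pixel
time-to-half-recovery (lag) map: each pixel's first crossing of half its
own plateau, after a σ = 2 px spatial smoothing. Regions are found by
h-extrema level detection: the lag values of the h-minima and h-maxima
(h = 5 s, one frame interval) define levels; levels closer than h are
merged; pixels are assigned to the nearest level and connected
components become regions, with fragments below 20 px absorbed into
their largest neighbour. A lag map flat to within h yields one region.
Classical marker-based watershed flooding was tried and rejected: on
segmented (rather than ground-truth) masks the earliest-recovering
marker floods nearly the entire mask through low-gradient leaks around
the ends of the inter-compartment ridge, returning a degenerate
partition. The level-quantization formulation keeps the same feature,
the same flat-map contract, and is deterministic. `halves_pca` (split
along the first principal axis) and `grid` (bounding-box tiling) are
provided as controls.

Per-region curves are region means of the map, fitted as above. The
heterogeneity index is the population CV of per-region half-times; a
focus is called `multi` iff it has ≥ 2 subregions *and* CV > 0.3. The
CV gate makes the caller robust to over-segmentation: spuriously split
uniform foci produce regions with near-identical half-times and stay
`single`. This quantitative criterion is this package's
operationalization of subcompartments that were identified visually in
the source experiments, and outputs label it as such.

The contour classifier calls a focus `amorphous` iff its mean pre-bleach
sphericity falls below `s_thr` or its mean frame-to-frame mask IoU falls
below `iou_thr`. Post-bleach masks are excluded when at least three
pre-bleach frames exist, because a deeply bleached focus segments as its
recovery front, not its contour. The defaults `s_thr = 0.97`,
`iou_thr = 0.96` are calibrated on the phantom presets by
`scripts/calibrate_thresholds.py` (midpoints between the class extremes;
compact sphericity ≥ 0.998 vs amorphous ≤ 0.943 over 12 seeds per
class). They are tied to this generator's geometry and the smoothed
perimeter estimator; real data may need recalibration through the
config.

### Resolvability assay

A pair is measured by sampling the intensity profile along its axis
through the midpoint at pixel/4 spacing with cubic-spline interpolation.
Maxima require a prominence of 5% of the profile range; exactly two
significant maxima give status `twin`, with the distance between
parabolic-refined peak positions. The 5% default sits deliberately below
the ~7.3% dip of a pair at the two-Gaussian resolution limit ratio
d/σ = 2.355 (a 60-nm pair under a 60-nm-FWHM PSF), so a just-resolvable
noiseless pair is counted as twin; noisy data may warrant a higher
threshold. Near that limit the measured peak distance is biased below
the true separation (peak pulling: the analytic maxima for d = 60 nm,
σ = 25.5 nm sit 48.4 nm apart); the assay reports what the image shows,
and tests validate it against the numeric two-Gaussian oracle rather
than the nominal separation. Bead images for this assay should be
rendered at ~FWHM/4 pixels; at Nyquist-scale pixels interpolation
flattens the shallow dip of just-resolved pairs.

## Numerical and validation choices

- All randomness flows from one integer seed per simulation; identical
  specs and seed give bit-identical movies.
- Noiseless compact scenes conserve total pre-bleach intensity to 1e-9
  relative (jittering amorphous shapes change pixel counts by design).
- On noiseless data the whole-focus normalized trace equals the
  intensity-weighted reassembly of the per-pixel recovery map (and of
  any subregion partition of it) to 1e-9 — the partition identity used
  as a conservation check.
- Validation studies run 50 seeds per condition at diSIM rendering
  (≈ 280 × 350 px frames, 3 + 24 frames, 1 z-plane, per-pixel SNR 20):
  median fitted k within 10% of truth (observed ≈ 1% bias for compact
  presets, ≈ 2–4% per subcompartment for amorphous), multi/single call
  and contour classification accuracies at 100% in these conditions.
  These sizes keep a full study under a few minutes on one core.

## What the phantoms do not show

The generator realizes the same kinetic family the fitter assumes, so
round-trip accuracy demonstrates correctness of the estimation chain,
not of the model itself against real condensates. Real data add
diffusion gradients within compartments, reconstruction artifacts,
acquisition photobleaching, z-drift, and segmentation ambiguity that the
phantoms deliberately omit; classifier thresholds in particular are
preset-calibrated and should be revisited on experimental images. Bleach
depth and within-acquisition photobleaching rates are free parameters,
as they are not reported for the source experiments.
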