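# Methods

This note documents the models, numerical choices and limitations of the
package, and what the synthetic-data generator does and does not emulate.

## Observable and calibration

The assay observes the integrated fluorescence of individual
surface-tethered 2620-bp DNA templates. An intercalating dye stains dsDNA
strongly and ssDNA weakly, so the per-molecule DNA-stain intensity is a
proxy for remaining dsDNA; an optional second channel of labelled RPA
(a ssDNA-binding protein) proxies exposed ssDNA. Because absolute
fluorescence depends on the instrument, every molecule is calibrated
internally: the piecewise-linear fit's pre- and post-reaction plateaus are
mapped to 1 and 0 (swapped for rising RPA signals), and the calibrated
value times the template length gives base pairs. On this scale the slope
magnitude |m| is a fraction of template per second and |m| × 2620 is the
enzymatic rate in nt/s.

## Piecewise-linear change-point fit

The three-segment model f(x) = m·clip(x, a, b) + t is linear in (m, t)
given (a, b). The fit proceeds in three stages:

1. **Grid:** all (a, b) pairs on frame boundaries (exhaustive when the
   trajectory has ≤ 120 frames, otherwise a ≤ 120-point subsampled grid)
   with the closed-form ordinary-least-squares (m, t) per cell, evaluated
   in O(1) per cell via prefix sums. Ties resolve toward smaller a, then
   smaller b.
2. **Local pass:** frame-resolution re-evaluation around each coarse
   change point when the first grid was subsampled.
3. **Refinement:** bounded nonlinear least squares over (m, t, a, d) with
   d = b − a ≥ 0 enforcing a ≤ b, analytic Jacobian, trust-region
   reflective method, tolerances 1e−14. The refined solution is accepted
   only if it does not increase the SSE.

The refined optimum is therefore never worse than the frame-grid optimum;
tests verify agreement with an independent exhaustive-grid OLS oracle to
0.1% in SSE and exact parameter recovery (≤ 1e−6 relative) on noiseless
input. Trajectories with zero variance, or with a fitted plateau
difference below 3× the robust noise scale (1.4826 × median absolute
first difference / √2), are flagged degenerate instead of calibrated.

Filtering mirrors the assay logic: reactions are discarded when a < 0,
b < 0, or either change point falls beyond the movie (incomplete
reactions), when R² ≤ 0.7 (default, configurable; R² is computed for the
piecewise fit), and — in strand-displacement mode — when no confirming
single-frame dissociation drop is found. The R² threshold is applied in
all enzyme modes and recorded in the run manifest.

## Sudden-drop detection

Dissociation events (strand-displacement completion, tether rupture) are
single-frame intensity drops. The detector is a depth-1 regression tree on
time: the exhaustive single split minimising the within-segment sum of
squares of a two-level model, computed exactly with prefix sums. A change
point is reported only when the late level is below the early level and
the step model explains at least `min_score` (default 0.5) of the
variance; a noiseless step scores exactly 1. The drop time is the first
frame of the lower segment.

## Synchronisation

Anchors (fitted b, or the detected drop time) are snapped to the nearest
frame — detection is frame-quantised, so sub-frame interpolation would
manufacture precision; interpolation is deliberately not attempted.
Means and SEMs (std/√n, 0 where n < 2) are accumulated per grid point;
points with fewer than 5 contributing molecules (configurable) can be
masked for downstream fits. With heterogeneous linear decays anchored at
their end, the ensemble mean is exactly linear wherever all contributing
molecules are inside their ramp — the linearity control used to validate
the synchronisation.

## Ensemble kinetics

* **Synthesis:** exp(k(x − x₀)) fitted to the synchronised, normalised RPA
  mean for rel_time < −10 s (the signal saturates near the anchor and is
  no longer single-exponential); rate in bp/s is k × 2620.
* **Michaelis–Menten:** weighted (1/sem²) nonlinear least squares of
  v = v_max[S]/(K_M + [S]); requires ≥ 3 distinct concentrations; exactly
  satisfies v(K_M) = v_max/2 and scale equivariance.
* **RPA binding:** 2620 − f₀·e^(−k(x−x₀)) fitted for rel_time ≥ −20 s on
  the nt-scaled signal. Only the product f₀·e^(k·x₀) is identifiable, so
  x₀ is a *fixed input*, never optimised. The reported bimolecular
  association constant uses the declared convention
  k_on = k_exp × 2620 nt / [RPA in nM] (default 20 nM); this convention is
  recorded in every output manifest because other unit conventions exist.

## First-passage-time analysis

The first-passage time (FPT) of a molecule is the time from reaction start
to its terminal event; molecules without a detected event are censored at
the movie end. The survival curve is defined as
(n_total − events ≤ t)/n_total with censored molecules never
decrementing — deliberately *not* Kaplan–Meier, matching how fractions of
still-bound substrates are reported in this assay.

The FPT density is the standard shifted gamma
k^n (x−x₀)^(n−1) e^(−k(x−x₀)) / Γ(n), x > x₀, with x₀ fixed at 20 s
(reagent arrival). The shape MLE solves log(n) − ψ(n) = log(ȳ) − mean(log y)
(Minka initialisation, bracketed Brent refinement to 1e−12); the rate is
n/ȳ. Events at or before x₀ are dropped with a logged count (the earliest
histogram bins are unreliable while the reagent concentration is still
rising); censored events are excluded from the likelihood — a
censoring-aware likelihood is out of scope. A method-of-moments estimate
(n = ȳ²/s², k = ȳ/s²) backs the MLE as a cross-check and as the fallback
reported on non-convergence. Tests verify agreement with an independent
SciPy fixed-location MLE to 0.1% and that exponential (n = 1) data do not
produce spurious intermediates under a likelihood-ratio test.

## Synthetic-data generator

The generator is the package's testbed and defines its operating
conditions:

* **Rates.** Digestion/unwinding rates are drawn from a normal truncated
  at 0. The parent's location is solved so the *truncated* mean equals the
  requested mean (σ kept as requested) — the sample mean then converges to
  the stated population value instead of drifting upward with truncation.
  For heavy-tailed helicase rate distributions reported as median ± STD, a
  lognormal parameterised by median and standard deviation is provided
  (σ_log solves (std/median)² = u(u−1), u = e^(σ²)).
* **Trajectories.** Calibrated-unit piecewise signals per kinetic program
  (plateau–ramp–plateau; constant-then-drop DNA with saturating
  first-order RPA; single-frame disappearance) plus additive Gaussian
  noise (default σ 0.05 of the full-template intensity, i.e. SNR 20 per
  frame at 5 fps). Each molecule's movie covers its full program with a
  60-s pre-activity baseline and a 60-s tail; a single global movie length
  would censor the slowest molecules and bias recovered means upward.
* **Movies.** Spots are isotropic 2-D Gaussians (σ default 1 px; the
  optics are diffraction-limited, and the exact PSF is not critical) with
  peak amplitude photon_scale × calibrated intensity, placed by random
  sequential adsorption with minimum separation max(6 px, 4σ_psf) — spots
  closer than a diffraction width merge under connected-component
  detection, so overlap has to be requested explicitly by lowering
  `min_separation`. Frames add a flat background, are translated by
  cumulative stage drift, modulated by a centred Gaussian beam profile,
  and receive Poisson shot noise plus Gaussian read noise (an EMCCD
  gain-register cascade is approximated by this Poisson + Gaussian model).
  Pixel size defaults to 0.16 µm/px and is configurable; dense-field
  scenes should be Nyquist-sampled (≈ 0.11 µm/px in the end-to-end tests)
  so that 0.5 molecules/µm² remain resolvable. Two-channel movies are
  perfectly registered.

Not emulated: flow-induced DNA stretching, dye photobleaching, RPA
exchange dynamics (the RPA channel is modelled only at the first-order
binding level), pausing and burst kinetics within single molecules, and
mobile (untethered) molecules. Passing tests therefore demonstrate
correctness of the estimators under these idealised conditions, not
robustness to every artefact of real movies.

## Image processing

Flat-fielding divides by a large-σ Gaussian blur (default 25 px) of the
temporal mean frame, normalised to unit mean; the smoothing scale must sit
between the spot radius and the beam-profile scale. Drift is estimated by
sub-pixel phase cross-correlation of each frame against the first frame
(default; chaining against the previous frame is available for large slow
drifts) and removed by linear interpolation. Drift estimation needs
persistent image structure: a field in which *every* molecule has reacted
to completion goes featureless and the late-frame estimates degrade —
harmless for trajectories that ended earlier, but worth checking in the
QC shift series. Spots are detected on the temporal mean of the first 10
frames (all molecules still present) with a median + k·MAD threshold
(k = 5) and 8-connected components gated by area; centroids are
intensity-weighted. Molecules are surface-tethered, so one spot set serves
the whole movie — there is no tracking. Intensities are integrated over a
disc (radius 4 px) minus the annulus (6–9 px) background median times the
disc area; edge spots whose annulus leaves the field are dropped with a
logged count, and overlapping ROIs are kept but flagged.

## Problem sizes and determinism

Recovery studies use 1000 molecules per digestion condition, 500 for
unwinding, 5000 first-passage times per gamma condition and 1000
Michaelis–Menten replicates — sizes at which the estimator spread is a few
percent, comfortably inside the 10–15% acceptance bands, while a full run
of suite plus acceptance script stays within a couple of minutes on one
CPU. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical seeds give bit-identical
trajectories, movies and result bundles.

## Known limitations

* Single change-point-pair model only: pausing molecules are fitted with
  one average slope; multi-pause segmentation is out of scope.
* The exact threshold and drift algorithms of the original assay software
  are not public; the implementations here are functionally equivalent on
  simulated ground truth but not claimed identical.
* The R² > 0.7 criterion is ambiguous in provenance (piecewise vs drop
  model); it is applied to the piecewise fit, and rate fitting is
  standardised on calibrated trajectories.
* Gamma fitting pools all events; per-experiment fitting (different
  reagent-arrival offsets) is available only by calling the fit per
  subset.
* The gamma likelihood ignores censoring; with heavy censoring the shape
  and rate are biased toward the fast sub-population.
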