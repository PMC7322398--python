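# Methods

## FRAP model and estimator

A uniform circular spot of radius *w* (default 2 µm, i.e. a Ø 4 µm spot) is
bleached instantaneously on a flat, laterally homogeneous membrane with
lateral diffusion coefficient *D*. For this geometry the spot-averaged
fractional recovery has the closed form

    f(t) = exp(−2τ/t) · [I₀(2τ/t) + I₁(2τ/t)],    τ = w² / (4D),

with I₀, I₁ modified Bessel functions (evaluated via exponentially scaled
Bessel functions, `scipy.special.ive`, so small *t* is stable). The
half-crossing f(t₁/₂) = 1/2 gives the dimensionless constant

    c = D · t₁/₂ / w² = 0.22365 (three decimals: 0.224),

obtained here by bracketed root solving (`brentq`, relative tolerance
≤ 1e-8) and verified against a dense-grid argmin in the tests. The
estimator, however, is not the closed form: following common practice, an
exponential y₀(1 − exp(−a·t)) is least-squares fitted to the measured
fractional recovery and D = 0.224 · w² / t₁/₂ with t₁/₂ = ln 2 / a. Because
the physical curve is not exponential, this estimator carries a
model-mismatch bias: on noise-free closed-form traces sampled at dt = 0.2 s
over 100 frames it returns D/D_true ≈ 0.8775 (−12%), which the test suite
pins as a regression value and bounds at 20%. On traces whose shape is
exponential (the model-matched generator) the estimator is unbiased.

Definitions pinned where conventions diverge:

* F(0) is the literal first post-bleach frame, not a back-extrapolated
  value; F(∞) is the mean of the last 8 recovery frames; F(pre) the mean of
  the 8 pre-bleach frames. Both the fractional trace and M follow from
  these, making the analysis invariant under affine detector rescaling.
* t₁/₂ = ln 2 / a, i.e. time to half the *fitted* asymptote y₀. When y₀ ≈ 1
  (good plateau normalization) this coincides with the time to f = 0.5.
* The fit includes the t = 0 point (f = 0 exactly), uses unweighted least
  squares with bounds y₀ ∈ (0, 1.5], a > 0, deterministic initialization
  (y₀ from the plateau, a from the first half-crossing) and up to three
  fixed rate perturbations (×0.3, ×3); non-convergence is reported as a
  flag, never an exception.

## Quality control

Four inclusive checks: effective-radius ratio √(A/π)/w ≥ 5 (the spot must be
small relative to the observed membrane disc of area A — the dimensionally
sensible reading of the "spot small vs. diffusion area" guideline);
t_B ≤ t₁/₂/10 for the 0.1 s bleach pulse; mobile fraction M ≥ 0.75 (a finite
lipid reservoir or immobile dye otherwise biases D down); and drift
≤ w/2 when movement information is available (skipped with a warning
otherwise — movers must be flagged upstream for trace-only input). Relaxing
any threshold can only turn failures into passes. Note a built-in tension:
at w = 2 µm the pulse rule requires t₁/₂ ≥ 1 s, i.e. D ≤ 0.9 µm²/s, so
fast-diffusing vesicles fail it by construction; results carry their
numbers together with the QC verdicts and downstream summaries decide what
to filter.

## Synthetic data

`generate_trace` builds ROI-mean traces directly: n_pre = 8 pre-bleach
frames at F_pre, an instantaneous bleach to F(0) = F_pre(1 − β) at t = 0
(the finite 0.1 s pulse enters only QC, justified exactly when the pulse
rule holds), then recovery toward F_plateau = F(0) + M_true(F_pre − F(0))
with shape g(t) either the closed form or the exponential family. Defaults:
w = 2 µm, dt = 0.2 s, 100 recovery frames, β = 0.8, M_true = 0.95,
F_pre = 100 a.u., additive Gaussian noise on ROI means (σ = 5, i.e. 5% of
F_pre, in the condition presets). Bleach depth, frame interval, pixel size
and noise level are not experimentally constrained; these defaults are
plausible confocal values chosen once, not inferred facts.

`simulate_lattice_frap` is the independent physics oracle: Brownian walkers
with per-axis step variance 2·D·dt and radial reflection at a finite
reservoir disc of radius R (default R/w = 10). Rather than counting bright
particles over the whole disc — which at R/w = 20 leaves only ~N/400
particles in the spot and ~6% shot noise — the simulator tracks the
bleach-origin walkers (initially uniform in the spot) at full resolution and
adds the unbleached field analytically: a uniform initial distribution stays
exactly uniform under reflecting boundaries, so the bright field's ROI mean
is constant and the bleach probability β enters the expectation exactly,
giving F(t) = F_pre(1 − β·u(t)) with u(t) the in-spot fraction of walkers.
This conditional Monte Carlo estimator has the same mean as the naive count
and variance ~1/N, which is what makes a 0.02 sup-norm comparison against
the closed form feasible at N = 1e5. Finite reservoirs reproduce the
apparent immobile fraction (plateau 1 − (w/R)²); frozen walkers implement
M_true < 1.

`render_frap_stack` draws the acquisition (bright membrane disc, evolving
dark spot) either from walker histograms or from the closed-form radial
bleach profile (heat-kernel convolution of the disc indicator, numerically
integrated); sharp edges (t = 0, immobile part) are evaluated per pixel
rather than interpolated so the ROI round-trip against `generate_trace` holds
to well under 2% per frame. Optional Gaussian PSF blur and Gaussian or
Poisson pixel noise.

Composition data: per-vesicle intensity I = b·x + ε, truncated at zero, with
x ∈ {1, 2, 3} the relative labelled-lipid concentration of the 3:1, 2:2 and
1:3 (unlabelled:labelled) mixtures, b = 10 a.u. per unit and σ = 1 a.u. by
default (n = 50 vesicles/group); optional rendered annulus images exercise
the image path end to end.

What the generators do **not** emulate: 3-D point-spread functions and the
spherical-cap projection of the vesicle bottom, photobleaching during
acquisition, vesicle drift/advection, octanol pockets, and detector
saturation. Passing tests therefore validate the estimator chain and its
stated conventions, not robustness to those real-data effects.

## Condition presets and statistics

The built-in cohort presets carry the reported per-condition lateral
diffusion means (and sd, N) for DOPC/POPC GUVs made by electroformation vs.
the microfluidic OLA method, with and without the poloxamer P-188, plus the
glycerol/temperature control series (1.0–2.2 µm²/s). They serve as generator
ground truths for parameter-recovery checks; the experimental values
themselves are not reproducible from raw data here.

Group summaries report mean, sample sd (n−1), SEM, median, linear-interpolated
quartiles and min/max whiskers; boxplot outliers beyond 1.5×IQR are flagged
but retained in every statistic. Two-group comparisons use Welch's
unequal-variance two-sided t-test (the least-assuming two-group default for
threshold-style reporting at 0.05/0.01/0.001), with the convention p = 1 for
two zero-variance groups with equal means. Calibration of the type-I error
at α = 0.05 is verified over 1000 simulated null cohort pairs (n = 17 per
group) against the binomial 99% interval.

## Ring extraction

The vesicle center is the background-subtracted intensity centroid (or a
supplied seed); the ring radius is the global argmax of the radial
mean-intensity profile (rounded-radius binning, refined by an
intensity-weighted mean over the half-max neighbourhood; multiple peaks
warn and take the brighter ring); the reported mean covers an annulus of
3 px band width with the median beyond 1.5× the radius subtracted as
background (a switch, on for images, off for tabulated intensities whose
background treatment happened upstream). A uniform image raises a detection
error. The zero-intercept slope is fitted per lipid system pooled over
individual vesicles (s = Σxᵢ·Iᵢ / Σxᵢ²), requiring only Σx² > 0 — a single
concentration level suffices to define a slope through the origin.

## Problem sizes and determinism

Defaults keep every check fast on one core: the lattice oracle uses 1e5
walkers × 100 steps (≈1 s), rendering uses 0.2 µm pixels over a 21 µm field,
recovery cohorts use the reported per-condition N (7–34), and the
calibration study 1000 replicate pairs. All randomness flows through
`numpy.random.default_rng` seeds carried in the configs; identical seed and
config give bit-identical output, and cohort seeds are spawned from a single
parent seed.
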