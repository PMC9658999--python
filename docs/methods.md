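# Methods

This note documents the models, numerical choices, and defaults behind each
module, what the synthetic fixtures do and do not emulate, and the known
limitations.

## N/C-ratio quantification (`imgquant`)

The readout for a frame is the mean GFP intensity inside a small disk of
radius 0.48 µm centered at the nucleus centroid, divided by the mean GFP
over the cell mask minus a large disk of radius 1.44 µm. The two radii
keep the numerator well inside the nucleus and keep perinuclear signal out
of the cytosolic reference. Design points:

* **Nucleus segmentation.** "A simple intensity threshold in the RFP
  channel" is made concrete as the between-class-variance (Otsu) criterion,
  computed by an exhaustive sweep over the unique in-mask intensities
  rather than a binned histogram: parameter-free, exact for the sample, and
  reproducible. The largest connected component above threshold is the
  nucleus; its centroid is the unweighted mean pixel coordinate
  (intensity weighting is a plausible alternative; unweighted is assumed).
  A contrast floor (in-mask max/median < 1.2) raises a "no nucleus
  detectable" error instead of thresholding noise.
* **Disk rasterization.** A pixel belongs to a disk when its center lies
  within the physical radius converted to pixels without rounding — a
  deterministic, resolution-independent rule.
* **Pixel size.** Default 0.16 µm/px (typical 100× objective + EMCCD),
  configurable; at this size the disks are 3 px and 9 px.
* **Background subtraction.** The rolling-ball correction is implemented as
  grayscale morphological opening with a disk structuring element, clipped
  at zero. Opening is the standard morphological analogue of the
  rolling-ball estimator; the two differ only in the ball's curvature along
  the intensity axis.
* Frames where the nucleus touches the cell boundary are flagged, not
  dropped — mitosis frames matter. A cytosolic region under 20 px yields a
  missing value for the frame, not an abort.

## Cycle alignment (`cyclealign`)

Cycles are anchored at karyokinesis (K), budding (B), and the next
karyokinesis. G1 = [K, B), S/G2/M = [B, K′]; both phases are linearly
resampled onto equidistant points, 80 per cycle by default (60 for
synthesis rates), with per-phase counts `round(n_total · mean_g1 /
(mean_g1 + mean_sg2m))` (ties up) and the complement — 40/60-min means give
32/48. The mean durations come from the analyzed cycle set itself. The G1
grid is half-open at budding so the boundary sample is not duplicated
across phases (duplication would bias the boundary). The averaged band is
1.96·sd/√n per grid point; with ≥ ~40 cycles per point the difference from
t-quantiles is negligible. Normalization modes (`minmax_sym`, `minmax01`,
`mean`, `none`) are applied per cycle *before* averaging, matching the
plotting conventions they implement.

Cross-correlation between two readouts is computed per cell at integer
frame lags on mean-subtracted overlapping windows (Pearson), then averaged
over cells; the sign convention is that a negative lag at the maximum means
the second readout's features precede the first's. Distribution
comparisons use the two-tailed Mann–Whitney test (exact when n₁·n₂ ≤ 400
and tie-free, otherwise the tie-corrected normal approximation, via scipy)
with the rank-biserial magnitude r = |1 − 2U/(n₁n₂)| as effect size; the
sign is dropped because only the magnitude is reported downstream.

## Synthesis-rate estimation (`riborate`)

Two-compartment maturation model: the protein is synthesized into an
immature pool at rate K_p(t) and matures at K_m = ln2/t_half
(t_half = 6 min for sfGFP ⇒ K_m = 0.116 min⁻¹), giving
K_p(t) = P_m″/K_m + P_m′. No degradation term is included. Abundance is
mean GFP × total (mother + bud) volume, assuming equal concentration in
mother and bud.

* **Window extension.** The fitting window is the cycle plus three frames
  (9 min at 3-min frames) on each side, so spline edge effects fall outside
  the reported window; extension frames never appear in outputs and
  truncation at trace ends is flagged.
* **Smoothing selection.** The abundance spline's penalty minimizes the
  generalized cross-validation score with the effective degrees of freedom
  capped at n/2 — an automatic, reproducible stand-in for an interactive
  choice. The smoother matrix needed for GCV/edf is obtained by probing the
  (linear) penalized solver with unit vectors.
* **"Closely fitting" second spline.** The first derivative on the frame
  grid is refit with the penalty chosen (by bisection) so the effective
  degrees of freedom are ≈ 0.8·n, a deterministic reading of "closely
  fitting".
* Negative recovered rates are reported as-is but flagged: they diagnose
  over-smoothing. Recovery tolerances are set by the synthetic round trip
  (see below), not by any real-data figure, because the smoothing used on
  real data is only qualitatively specified.

## GP group comparison (`gptools`)

Model: x_i(t) = B′(t)α + d(t) + noise. B(t) and C(t) are Gaussian-kernel
bases, k(t;c) = exp(−(t−c)²/2h²), with evenly spaced centers spanning
[t₁, t_T] and bandwidth h equal to the center spacing (J = 10 mean kernels,
L = 5 hyperparameter kernels; the kernel form is the most common
convention for "Gaussian kernels with common bandwidth"). σ(t) = exp(C′β)
and ℓ(t) = exp(C′γ) keep both positive. The GP covariance is the
Paciorek–Schervish non-stationary Matérn-5/2,

    K(s,t) = σ(s)σ(t)·√(2ℓ(s)ℓ(t)/(ℓ(s)²+ℓ(t)²)) · M₅/₂(Q),
    Q = √(2(s−t)²/(ℓ(s)²+ℓ(t)²)),   M₅/₂(Q) = (1+√5Q+5Q²/3)e^(−√5Q),

plus τ² on the diagonal for measurement noise; it reduces exactly to the
stationary Matérn-5/2 for constant σ, ℓ.

Priors: α ~ N(0, 10²) per component, β_l and τ ~ Γ(1,1), γ_l ~
Γ(0.2(t_T−t₁), 1), shape–rate (with rate 1 the shape–scale reading
coincides). Note the Γ(1,1) prior on β confines σ(t) to ≥ 1, which couples
the method to the data's scale; traces should live on a scale where unit
population sd is sensible.

* **MAP estimation.** The posterior is maximized jointly over
  (α, β, γ, τ). Because the posterior is a Gaussian quadratic in α, its
  conditional minimizer has a closed form and is profiled out exactly; the
  remaining 2L+1 parameters are optimized by L-BFGS-B in the original
  constrained parameterization (bounds ≥ 10⁻⁶; a log transform would move
  the MAP point). Multi-start with 5 seeded restarts by default: α from
  ridge regression of the pooled mean on B, β from the log pooled sd, γ
  from log of a quarter of the time range, τ from the high-frequency
  (first-difference) residual sd; restarts perturb multiplicatively. The
  optimized α is discarded — it is re-estimated with proper uncertainty in
  the next step.
* **Posterior of the mean.** With Σ fixed at its MAP value, the posterior
  of α is Gaussian with precision A = 10⁻²I + M·B′Σ⁻¹B; m(s) = B(s)α is
  evaluated on a sparse grid of J evenly spaced points (more points would
  make the covariance rank-deficient by construction).
* **Inference.** S = Σ_x + Σ_y is eigendecomposed; ν counts eigenvalues
  above eps·J·λ_max (the standard numerical-rank rule; configurable since ν
  depends on it), T is the squared whitened norm of the mean difference on
  the positive eigenspace, ε = P(χ²(ν) > T), and E = Λ^(−1/2)V′Δ is the
  per-grid-point effect profile. Jitter of 1e−9·max(diag), escalating, is
  added whenever a factorization fails — non-stationary covariances are
  near-singular for smooth ℓ(t).

Because hyperparameters are plugged in at their MAP values rather than
marginalized, the null distribution of T is only approximately χ²(ν); the
calibration benchmark below quantifies the effect (false-positive rate
≈ 0.05–0.07 rather than exactly 0.05).

## Synthetic data (`synthdata`)

* **Scenes** are piecewise-constant two-channel images (elliptical cell,
  disk nucleus) plus i.i.d. Gaussian noise. The default nucleus radius
  (8 px) sits between the small (3 px) and large (9 px) quantification
  disks so that noise-free recovery of the true N/C ratio is exact. Not
  emulated: shot-noise statistics, bleaching, cell-shape dynamics, so
  passing tests say nothing about segmentation robustness on real images.
* **GP populations** are exact generative twins of the fitted model
  (eigendecomposition sampling with negative eigenvalues clipped at zero).
  An explicit `sigma_scale` factor allows low-noise fixtures despite the
  σ ≥ 1 prior support. Benchmark conditions, chosen once as a realistic
  single-cell imaging setting: 40 time points over 117 min (3-min frames),
  M = N = 60 cells, an oscillatory mean of amplitude ≈ 2 around ≈ 10 a.u.,
  σ(t) ≈ 1.3–1.5, ℓ(t) ≈ 15–30 min, τ = 0.3.
* **Cycle traces** draw phase durations from a gamma distribution with the
  stated means (40/60 min) and CV, truncated at two frames (positive,
  right-skewed, simple); the readout is a prescribed waveform of the
  phase-proportional relative cycle position plus Gaussian noise. The
  default waveform (G1 peak, dips at budding and karyokinesis) is
  illustrative plumbing, not an estimate of any real localization profile.
* **Maturation trajectories** integrate the two-compartment ODE with
  fixed-step RK4 at 20 substeps per frame; the integration error
  (≪ 10⁻⁹ relative) is far below any measurement noise.

## Benchmarks computed by tests and `scripts/acceptance.py`

All figures below are recomputed at run time; none are constants.

* Synthesis-rate round trip: K_p(t) = 10 + 3·sin(2πt/100) a.u./min over a
  99-min cycle at 3-min frames, simulated forward and inverted. Interior
  80% relative RMS error: < 3% noise-free, < 15% at 2% multiplicative
  noise.
* GP calibration: 200 replicate pairs of identical populations under the
  benchmark conditions; the fraction with ε < 0.05 must lie in
  [0.01, 0.12] (plug-in caveat above). Power against a 2-pooled-sd mean
  shift on the last quarter of the grid: > 80% of 25 replicates. These
  replicate fits use 2 optimizer restarts (the full default is 5); spot
  checks show the extra restarts change ε negligibly on these problem
  sizes.
* Image quantification: noise-free scenes recover the true N/C ratio
  exactly; noisy scenes match independent per-pixel mask arithmetic to
  1e−12.
* Alignment: deterministic (phase-CV 0, noise-free) simulated cycles with
  frame-commensurate 39/60-min phases reproduce the generating waveform on
  the 80-point grid to linear-interpolation error (< 2e−3).

## Known limitations

* Hyperparameter uncertainty is not propagated (no MCMC); ε is mildly
  anticonservative.
* Cells must share one measurement grid (event-aligned traces satisfy
  this).
* The rolling-ball approximation (opening) slightly overestimates the
  background in concave intensity valleys relative to the true
  ball-rolling construction.
* Segmentation and tracking are consumed, not computed; bud volumes are an
  optional input, so `bud_volume_at_karyokinesis` is NaN unless a
  bud-volume series is supplied.
* The smoothing-spline edf targets (n/2 cap, 0.8·n for the derivative
  refit) are deterministic conventions; very short cycles (< 8 frames in
  the extended window) are rejected rather than fitted.
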