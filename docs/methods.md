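# Methods

## Recovery model and fitting

The recovery of a uniformly bleached disk of radius *w* (default 5 µm,
i.e. a 10 µm spot) refilled by free 2-D Brownian diffusion is the
Soumpasis closed form

    f(t) = exp(−2τD/t) · [I₀(2τD/t) + I₁(2τD/t)],   τD = w²/(4D),

wrapped affinely as F(t) = b + a·f(t): *b* is the fluorescence remaining
immediately after the bleach, *a* the recovery amplitude, and the plateau
a + b (relative to the pre-bleach level of 1) encodes the mobile fraction
a/(1 − b). The model assumes an ideal, instantaneous, sharp-edged disk
bleach, a single freely diffusing species, and no exchange with an
immobile pool during recovery. No Gaussian-beam (Axelrod) profile or
reaction–diffusion correction is applied.

Numerics. The combination e^(−x)(I₀(x)+I₁(x)) is evaluated with the
exponentially scaled Bessel routines `scipy.special.i0e/i1e`, which are
accurate for all x and cannot overflow — the argument x = 2τD/t is
enormous at early times for slow diffusion, so an unscaled evaluation
would fail. The half-recovery time obeys t½ = 0.8946·τD (a universal
constant of the curve, found once by bracketed root finding).

Fitting. Traces are fitted by bounded nonlinear least squares (lmfit with
the scipy trust-region-reflective solver). Free parameters are b ∈ [0, 1),
τD ∈ [10⁻³, 10⁴] s, and the plateau p = a + b ∈ (0, 1.05]; the amplitude
is the derived quantity a = p − b. Parameterizing through the plateau
enforces the physical constraint that a recovery cannot overshoot its
pre-bleach level beyond noise (the 0.05 headroom is ~5σ at the default 1%
noise), and this is what keeps the fit identifiable when only a fraction
of the recovery falls inside the 50 s acquisition window: for
D ≈ 0.04 µm²/s (τD ≈ 156 s, <35% recovery in-window) the likelihood
valley in (a, τD) is nearly flat along a·f(τD) ≈ const, and without the
plateau cap the optimizer drifts to nonphysical a with τD severalfold too
large. Initial guesses are derivative-free: b₀ = first post-bleach
intensity, a₀ = tail mean − b₀, τD₀ = empirical half-recovery time / 0.8946.
Fits terminating on a bound are flagged (`at_bounds`), non-convergence
raises with diagnostics, and a first post-bleach intensity ≥ 0.95 raises a
no-bleach error rather than fitting noise.

Uncertainty. 95% confidence bounds on D come from the linearized
covariance at the optimum: the τD standard error is propagated by the
delta method (σ_D = D·σ_τ/τD) and expanded with the normal 1.96 factor.
These are per-fit bounds; scatter across replicate spots is carried
separately as the calibration band (both are reported, since either can
dominate depending on sample heterogeneity).

Timing convention: the first fitted point sits at t = Δt/2 after the
bleach (mid-exposure of the first post-bleach frame); f(0) is never
evaluated.

## Trace extraction and normalization

The ROI is the bleached disk; membership is pixel-center-within-radius
(deterministic, adequate at the ≥64² grids used). The reference is the
entire imaged field minus the ROI disk, optionally minus a guard annulus
(default off). Double normalization divides the ROI trace frame-wise by
the reference (cancelling global acquisition photobleaching exactly, since
both regions fade by the same factor) and then by the mean pre-bleach
corrected value, pinning the pre-bleach level to 1.

Known limitation: immediately after the bleach the destroyed-fluorophore
deficit diffuses out of the spot *through the imaged field*, transiently
depressing the reference by up to ~2.5% of its level (the deficit is
~3.1% of the field's signal for a full-depth 10 µm bleach in a 50 µm
field). Dividing by this dipping reference inflates the normalized trace
mid-recovery, which biases fitted D by <1% at 5.35 µm²/s but up to ~5% at
1.66 µm²/s and ~8% at 0.25 µm²/s. The same artifact affects any real FRAP
analysis that uses the field-minus-spot reference; it is not a simulator
defect, and it is why simulator validation against the analytic solution
is done on the raw ROI recovery.

## Synthetic data generator

The generator emulates the standard acquisition: 50 µm × 50 µm imaged
field, 10 µm-diameter spot bleached instantaneously to a chosen depth
(default: full), 5 pre-bleach frames and 100 post-bleach frames at 0.5 s.

*Analytic traces* (`simulate_trace`) draw F(tᵢ) = b + a·f(tᵢ) directly
with b = 1 − bleach_depth and a = bleach_depth·(1 − immobile_fraction),
plus seeded Gaussian read noise (default study condition for validation:
1% relative).

*Image stacks* (`simulate_stack`) evolve the mobile concentration field
with the exact Gaussian heat propagator applied spectrally (FFT, periodic
boundaries); the immobile pool stays frozen. Mass is conserved to machine
precision by construction. The membrane is simulated on a computational
domain `pad_factor` (default 4) times wider than the imaged field, and
only the central field is recorded: a real SLB extends far beyond the
imaged area, whereas a closed periodic 50 µm field would lose 3.1% of its
fluorophore to the bleach and recover to a visibly depleted plateau.
With padding, the raw ROI recovery matches the analytic Soumpasis curve
to ≤0.6% absolute over D ∈ {0.05, 0.25, 1.66, 5.35} µm²/s on the default
128² field grid (the residual is disk-edge pixelation, which also leaves
a ~1.8% underestimate in D fitted from raw stack traces). Setting
`pad_factor=1` restores the closed field for mass-conservation checks.
Optional effects, applied in order: global exponential acquisition
bleaching (per-frame fraction), Poisson shot noise (at 1000 photons per
unit intensity), Gaussian read noise. One integer seed drives all draws.

*RH series* (`simulate_rh_series`) map a protocol of RH set-points through
monotone interpolation of a D(RH) table. A first-order equilibration lag
(time constant in units of protocol steps, default 0 = instantaneous)
emulates the finite hydration response of the bilayer — experimentally the
membrane needs ~10 min to equilibrate while set-points may dwell for less,
so the first measurement after a swing under- or overshoots its target.

What the simulator does not model: confocal PSF blurring, photophysics
(blinking, reversible bleaching), spatially heterogeneous (phase-separated)
diffusion maps, stage drift, camera offset. Passing tests therefore
validate the analysis chain under ideal disk-bleach physics with realistic
noise, not robustness to optical artifacts.

### Canonical D(RH) profiles

The built-in single-component profile pins the measured endpoints
(0% → 0.25, 85% → 4.75, 100% → 5.35 µm²/s) and fills the unmeasured
intermediate levels (30% → 0.35, 45% → 0.42, 65% → 1.8) to reproduce the
curve's characteristic shape: nearly flat below 50% RH, steep between 50%
and 100%, with the change point at ~50% RH where the clathrate cage
collapses. The phase-separated analogue scales the same shape to its
endpoints (0% → 0.04, 85% → 1.52, 100% → 1.66). "Fully hydrated" (bulk
buffer) is encoded as RH = 100 for calibration purposes.

## Calibration, inversion, breakpoint, hysteresis

Calibration curves interpolate (RH, mean D over replicates) knots with a
shape-preserving monotone piecewise cubic (PCHIP) — smoothing splines are
avoided because the sensing inversion requires monotonicity. Replicate SD
is carried per knot as an uncertainty band, linearly interpolated. Knot
means must be non-decreasing in RH: dips within one pooled replicate SD
are projected onto the nearest non-decreasing sequence
(pool-adjacent-violators, replicate-count weighted) and flagged; larger
dips are an error. Branches (dehydration / rehydration / bulk) are never
pooled. Outside the knot range the curve is clamped and queries flagged,
never extrapolated.

Sensing inverts the interpolant by bracketed root finding (ties on flat
segments resolve inside the bracket); the D confidence interval endpoints
are pushed through the same inverse to an RH interval, then through the
waters mapping. Waters per lipid interpolate the anchors
(25, 2.4), (50, 3.6), (75, 6.3), (95, 10.5) monotonically; below 25% RH
the mapping returns the residual floor — point value 4 ("not more than
four"), interval [3, 4] — with `floor_applied` set, and above 95% RH the
anchor 10.5 is a lower bound with `extrapolated` set.

The breaking point is located by continuous hinge regression: a two-
segment piecewise-linear model continuous at the candidate breakpoint,
scanned over a 1% RH grid, minimizing total SSE over the knot means
(unweighted by default; replicate counts are small). Ties break to the
lowest RH. If the best hinge improves SSE by less than 5% over a single
line, the curve is flagged as having no breakpoint.

Hysteresis between branches is summarized as ΔD(RH) = D_dehydration −
D_rehydration on the common RH domain (mean, max, fraction positive). The
reversibility verdict compares the top-of-range (bulk) D of the two
branches within their combined replicate SD: matching bulk D with
positive ΔD mid-range reads "reversible with hysteresis".

## Problem sizes used in validation

Parameter-recovery checks use 50 seeded replicates of 100-frame traces at
each of the four reference D values; simulator–theory equivalence uses one
noiseless 105-frame stack per D on the default 128² field grid (512²
computational domain); the end-to-end sensing check runs 50 replicates of
a full calibrate-and-sense cycle (6 levels × 5 replicate fits + 1 held-out
fit each). These sizes give stable medians and coverage estimates while
keeping the whole suite under a minute.
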