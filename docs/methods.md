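# Methods

## The measurement model

A cheliceral strike is a near-planar rotation of each chelicera (the basal
segment, the paturon, modelled as a rigid rod of length *L*) about a fixed
pivot. High-speed video filmed perpendicular to the plane of movement is
digitized by clicking the distal cheliceral edge in successive frames, which
yields, per chelicera, a series of pixel coordinates at times *k*/fps. Three
properties of this process shape everything downstream:

1. the click lands on the true point plus roughly isotropic error of a
   fraction of a pixel to a pixel;
2. at high frame rates the between-frame motion is smaller than that error,
   so digitizers mark only every *k*-th frame ("set intervals");
3. the whole animal may lunge during the strike, superimposing a
   translation on the rotation (removed in practice by image stabilization;
   here by subtracting a tracked body-reference point,
   `trapjaw.io.remove_drift`).

## Displacement, smoothing, derivatives

Cumulative displacement is the unsigned chord sum of the calibrated track,
and angular displacement is θ = *s*/*L*. Since *L* is constant, fitting θ or
*s* is the same up to a factor; the spline is fit to θ and linear kinematics
are derived as *v* = ω*L*, *a* = α*L* (identical peaks after unit
conversion).

The smoother is a P-spline: a degree-5 open-uniform B-spline basis on the
strike interval (time internally normalized to [0, 1]) with a 3rd-order
difference penalty on the coefficients, solved by ridge-type normal
equations. The penalty null space contains all quadratics, so
constant-acceleration motion is never shrunk; a quintic displacement lies in
the spline space and is reproduced to solver tolerance when the data are
noise-free (the selection then drives the penalty to the bottom of the
grid). The penalty weight λ is chosen by generalized cross-validation,
GCV(λ) = n·RSS/(n − tr H)², over a 61-point grid from 10⁻¹⁴ to 10⁶; a
caller can instead fix λ or request a target effective degrees of freedom
(tr H, solved by bisection — the reported results always carry the edf
used). The basis size is capped near half the sample count
(nseg = min(35, ⌈n/2⌉ − 5), K = nseg + 5): large enough for any plausible
closure profile, small enough that GCV cannot select interpolation of click
noise, whose derivative would be unbounded. Velocity and acceleration are
the analytic B-spline derivatives, evaluated on a dense grid of at least 10×
the input sampling; peaks are maxima over that grid (|α| for acceleration),
with ties resolved to the earliest time.

Strike duration is defined as first-to-last digitized frame (the digitizer
marks from open to closed position); a thresholded alternative
(ω ≥ f·peak ω) is available for sensitivity analysis. Non-monotone raw
displacement from noise back-steps is permitted — chord sums are unsigned by
construction.

## Two opposing biases of chord-summed digitization

Chord sums *under*-measure arc length at coarse sampling (per-step factor
sinc(Δθ/2), ≈ −0.9 % at 1 kHz for a 12 ms strike) and *over*-measure it at
fine sampling, because click noise inflates every unsigned step
(bias per step ≈ σ²/step, so total bias grows with frame rate). On synthetic
strikes at 0.5 px noise the recovered peak-ω error is therefore not monotone
in frame rate when every frame is digitized: ≈0.9 % at 1 kHz (discretization,
negative), ≈0.4 % at 2.5 kHz (the two biases nearly cancel), ≈2 % at 10 kHz
(noise accumulation, positive; the sweep inflates by ~10 %). This is exactly
why strided digitization is standard practice: the package models the
protocol as `digitization_stride(fps)` — every frame up to an effective rate
of 2.5 kHz, every 4th frame at 10 kHz — under which recovery error does not
increase with frame rate and sweep error stays near 1 %.

## The synthetic generator

The default closure profile is the quintic smoothstep
θ(t) = Θ(10τ³ − 15τ⁴ + 6τ⁵), τ = t/T: C² at both ends, monotone, with
closed-form extrema peak ω = 1.875 Θ/T (at τ = ½) and
peak α = (10/√3) Θ/T². It was chosen over a logistic because it has compact
support, exact extrema for oracle tests, and lies in the quintic spline
space. Tracks place the pivot at the origin, chelicerae opening
symmetrically about the midline to a half-gape each, the left a mirror image
of the right, both sharing timestamps (strikes are synchronous). Degradation
follows the measurement model: conversion to pixels, i.i.d. Gaussian click
noise (default 0.5 px per coordinate), optional constant-velocity lunge
applied to point and pivot alike, and frame-stride subsampling. One integer
seed drives all draws through numpy's PCG64 generator.

Campaign-level generation (`simulate_study`, 16 strikes from 10
individuals) draws gape from a truncated normal (172.4 ± 7.9°, clipped to
152.62–179.78°), closure duration from a lognormal matched to mean 12 ms and
SD 9 ms (clipped to 3.4–36.3 ms — strike durations are strongly
right-skewed), and cheliceral length per individual from a truncated normal
(0.46 ± 0.019 mm on 0.43–0.48 mm).

What the generator does **not** emulate: out-of-plane rotation and camera
obliquity (real left/right curves differ; synthetic ones are exact mirrors),
correlated or anisotropic digitization error, rolling-shutter or motion
blur, gape–duration correlation across strikes, and any opening-phase
motion. Passing recovery tests therefore demonstrate correctness of the
estimation chain under the stated noise model, not robustness to every
artefact of real footage. One visible consequence: with a fixed profile
family, peak ω per strike is exactly 1.875 Θ/T, so synthetic species means
(~500–700 rad s⁻¹, dominated by short-duration strikes through E[1/T]) sit
above what heterogeneous real profiles produce at the same gapes and
durations.

## Energetics

I = ⅓ML², E = ½Iω² on the smoothed ω series (never raw finite differences),
P = E_max/t_{E,max} with onset at the first digitized frame, O = P/m.
E peaks where ω peaks (E is monotone in |ω|), so E_max = ½I·(peak ω)²
exactly; a peak at onset is rejected as a degenerate 0/0. O is compared
against the conventional-muscle ceiling of 400 W kg⁻¹.

Masses of sub-milligram chelicerae cannot be weighed; they are estimated by
geometric similarity m = c·L³ (exponent overridable). The coefficients are
**required inputs** with recorded "allometric estimate" provenance — no
default is claimed, because any credible value must come from a regression
on related species measured directly. The analysis scripts document their
choice: treating the chelicera as a cuticle-density rod
(ρ ≈ 1100 kg m⁻³, radius ≈ L/9) gives ~4 μg at L = 0.46 mm
(c_chelicera = 4·10⁻⁸ kg mm⁻³), with an adductor muscle of ~1.5 μg
(c_muscle = 1.5·10⁻⁸ kg mm⁻³). The resulting O of a mean strike is a few
W kg⁻¹; the no-amplification verdict is insensitive to these choices over
two orders of magnitude in either coefficient (the margin to 400 W kg⁻¹ is
~10²).

## Aggregation and morphometrics conventions

Scalar results are averaged between the two chelicerae of a strike
(arithmetic means; a lone chelicera passes through flagged), then across
strikes with equal weight — individuals contribute unequal strike counts and
are deliberately not re-weighted. SD is the sample (n−1) estimator, noted in
the output; a single observation reports SD 0 with a flag.

Muscle measurements average left/right with extrapolation flags propagated
by OR. Size correction divides by the measuring specimen's carapace width
(closed 500.4 μm, open 495.5 μm); table rendering rounds ratios
half-to-even to 2 decimals and carries a documented ±0.01 tolerance against
published tables, whose own rounding is inconsistent in a few cells. The
clypeus trait is stored both as raw thickness and as the ratio to the
carapace thickness between the anterior median eyes. Endosternite muscles,
absent in this species, are represented as absent rows, never zeros.

## Problem sizes and numerical tolerances

The test suite and the acceptance script run the campaign at its natural
size (16 strikes, ~30 digitized frames each), 100-replicate noise
benchmarks, 40-replicate frame-rate comparisons, and a 10⁶-segment rod
oracle; everything completes in seconds. Key tolerances: noise-free peak-ω
recovery within 1 %, peak-α within 3 %, sweep within 0.5 %; noisy median
peak-ω error below 5 %; chord-summed quarter circle within 0.005 % of π/2;
inertia within 10⁻⁵ of the discretized rod.

## Known limitations

- The smoothing parameter matters: real analyses should report the edf used
  (the pipeline always emits it), and reproducing someone else's peaks to
  better than a few percent may require matching their smoothing.
- Chord-sum noise accumulation biases sweep upward when dense frames are
  digitized; use the stride protocol or a drift/threshold window.
- Planar analysis only; out-of-plane strike components are unobservable.
- The energetics inherits all uncertainty of the allometric mass
  coefficients linearly in 1/m; O values are order-of-magnitude statements,
  which is sufficient for the 400 W kg⁻¹ classification but not for
  comparative rankings.
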