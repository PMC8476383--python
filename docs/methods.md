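# Methods

## MP2RAGE signal model

The engine models the longitudinal magnetization m (normalized to its
equilibrium value) over one MP2RAGE cycle as a composition of affine maps
m → a·m + b:

* **Partial inversion** — m → (1 − 2·eff)·m, where `inv_efficiency` (eff)
  is the *fraction of magnetization inverted*: eff = 1 is a perfect
  inversion (m → −m), eff = 0 leaves the magnetization untouched, so a
  degenerate protocol with eff = 0 and vanishing flip angles has the
  thermal equilibrium m = 1 as its steady state. Default 0.96, typical of
  an adiabatic pulse at 3 T.
* **Free relaxation** over t — m → m·E + (1 − E), E = e^(−t/T1).
* **RAGE block** of k excitations at flip angle α spaced `tr_gre` apart —
  per excitation m → m·cos α·E1 + (1 − E1) with E1 = e^(−tr_gre/T1); the
  k-fold composition is a geometric sum evaluated in closed form (with the
  degenerate r → 1 limit handled explicitly as k·(1 − E1)).

Composing inversion → TA → block 1 → TB → block 2 → TC (the gaps derived
from TI₁, TI₂, the cycle TR and the block geometry, all validated
non-negative) gives the cycle map; its fixed point m\* = b/(1 − a) exists
because |a| < 1 for any physical input. The two image signals are
Sᵢ = m0·sin(b1·αᵢ)·m_z evaluated immediately before the k-space-center
excitation of each block. Signals are real and signed (S1 < 0 for long-T1
tissue not yet recovered through null at TI₁); complex phase bookkeeping
adds nothing for these computations. All signal functions broadcast over
numpy arrays, so a 64³ phantom evaluates in one vectorized pass.

Default protocol: TR_cycle 5.0 s, TI 700/2500 ms, flips 4°/5°, echo
spacing 7.1 ms, 59 excitations per block with the center at index 29. The
block length is the value a 176-partition acquisition with threefold
parallel acceleration implies; it, the center index (linear phase-encode
ordering) and the inversion efficiency are configurable because consoles
do not export them. Protocol files are flat YAML with times in
milliseconds (the scanner dialect) or seconds via a units flag; in memory
everything is seconds.

## T1 estimation

UNI = S1·S2/(S1² + S2²) is bounded in [−0.5, 0.5], invariant under joint
rescaling of the pair (hence insensitive to receive sensitivity and proton
density), and strictly monotone in T1 over the physiological range for
this protocol. Estimation tabulates UNI on a T1 grid (default
0.05–5.0 s, 1 ms step), extracts the largest strictly monotone contiguous
span containing T1 = 1 s, and linearly interpolates UNI → T1 on that
span. UNI values beyond the span clip to the nearest endpoint and are
flagged rather than raising: noisy voxels routinely exceed the physical
range, and downstream ROI statistics exclude (and count) flagged voxels.
The noise-free round trip T1 → UNI → T1 is exact to one grid step.

## Transmit-field bias

A B1+ deviation scales the excitation flip angles (the adiabatic inversion
is kept at nominal efficiency — its whole point is B1 insensitivity). The
bias analysis simulates signals at a given B1 scale, inverts them with the
*nominal* lookup, and reports the relative R1 error in percent. The error
is referenced to the nominal-B1 estimate through the same lookup rather
than to the analytic truth, which isolates the transmit effect from grid
discretization and makes the bias identically zero at nominal B1. For
this protocol a +10% flip-angle scaling biases grey/white-matter-like R1
by well under 5% (of order half a percent), consistent with the known
first-order B1 robustness of the uniform ratio; the exact magnitude
depends on the assumed tissue T1 and on whether inversion efficiency is
held fixed, so it is treated as a bound, not a point value.

## Growth model and fitting

R1(t) = R1∞ + A·e^(−t/τ), age t in months. The fit minimizes
Σ((r1ᵢ − model(tᵢ))/σᵢ)² with σᵢ the subject's ROI standard deviation —
the only per-observation uncertainty the pipeline produces. If any σᵢ is
non-positive the fit falls back to unweighted with a warning. The
optimizer is bounded trust-region least squares (scipy `curve_fit`) with
initialization R1∞⁰ = max(r1) + 0.05, A⁰ = min(r1) − R1∞⁰ and τ⁰ from a
log-linear regression of |r1 − R1∞⁰| on age; bounds τ ∈ [0.1, 1000]
months, with a τ landing at a bound reported as a fit failure rather than
a result. The parameter covariance is the inverse weighted
Jacobian-product at the optimum taken at face value (`absolute_sigma`
semantics, so doubling all σᵢ quadruples the covariance and leaves the
point estimates untouched), and the quoted τ uncertainty is the square
root of its diagonal entry — a linearization, adequate at the
signal-to-noise of these cohorts. Preconditions: at least 4 observations
spanning at least 12 months of age.

Fitting requires ≥ 4 points, but reconstructing a curve from published
values needs only its printed τ and two tabulated (age, R1) cells:
`params_from_anchors` solves A = (r1₂ − r1₁)/(e^(−t₂/τ) − e^(−t₁/τ)),
R1∞ = r1₁ − A·e^(−t₁/τ) in closed form. Reference tables round half away
from zero at the stated precision. Two published 24-month cells (right
posterior limb of the internal capsule, pons) differ by 0.01 from any
two-decimal reconstruction — their printed inputs were evidently rounded
from more precise fits — and are documented exclusions from the
reproduction checks.

Individual scoring: z = (r1 − prediction)/√(σ_obs² + σ_model²), with
σ_model the covariance-propagated prediction SD (0 when no covariance is
stored); |z| > 2.5 flags a deviation by default — a conventional
normative-modeling cutoff (≈ 99% two-sided coverage), configurable. A
zero-uncertainty observation against a covariance-free curve is an error,
not a zero division. The sex-stratified comparison fits each stratum
separately and reports whether the τ ± uncertainty intervals overlap per
region.

Ages are prematurity-corrected at ingest when a gestational-age column is
present: corrected = chronological − (40 − GA_weeks) weeks, clipped at 0.

## Synthetic data

The cohort generator draws subject ages uniformly over 3–72 months by
default (optional per-bin weights emulate non-uniform recruitment, e.g. a
mean near 34 months with SD near 21), assigns sex at a 60:34 ratio, and
sets each region's observation to curve(age) + N(0, σ) with σ = 0.03 1/s
— the middle of the 0.01–0.05 1/s range of real ROI standard deviations —
and records σ as the observation's r1_sd. Region truths default to
curves reconstructed from the published anchors (right side for bilateral
structures; the left-side published values differ by ≤ 0.01 1/s).

Phantoms place ellipsoidal stand-ins for the ten ROI structures inside a
brain ellipsoid (background T1 2.0 s, roughly unmyelinated parenchyma) on
a 64³ grid of 2 mm voxels, RAS+ affine. Region T1 is the growth curve
evaluated at the phantom age. Transmit and receive bias are smooth
multiplicative fields 1 + a·g with g a random-phase product of
half-period sinusoids in [−1, 1]; a defaults to 0.10 when enabled (±10%
is the variation expected in the brain at 3 T). Noise is additive
Gaussian on the two inversion-time images — Rician magnitude bias is
negligible at the simulated SNR and magnitude modeling is out of scope.
Overlapping structures resolve last-listed-wins with a warning; the
default layout is disjoint.

What the synthetic data does **not** emulate: real anatomy and partial
volume, motion, flow, B0 effects, T2\* decay across the echo train, slab
profiles, and k-space reconstruction (parallel imaging, partial Fourier).
Passing tests therefore demonstrate correctness of the estimation and
modeling chain under its own assumptions, not robustness to those
acquisition physics.

## ROI statistics and reliability

ROI summaries use the population SD (divide by n): the SD describes the
voxel population of that ROI. Inside the ICC's ANOVA, sample conventions
(n − 1) apply, as unbiased mean squares require. Flagged voxels are
excluded and counted per ROI; bilateral regions are separate left/right
records, and any "left only" reliability subset is a filter, not a merge.

The ICC is assembled from the two-way mean squares (subjects × raters);
the default variant is two-way random effects, absolute agreement, single
measure — ICC(2,1) = (MSB − MSE)/(MSB + (k−1)·MSE + k·(MSJ − MSE)/n) —
the standard choice for inter-rater agreement of continuous measurements;
consistency and average-measure variants are selectable since reliability
reports do not always state theirs. All-identical ratings are undefined
(0/0) and raise. Bland–Altman reports bias = mean(m1 − m2) and
bias ± 1.96·SD(d) with the sample SD.

## Problem sizes and numerical choices

The test suite and acceptance script run everything at the sizes the
analysis is designed for: 94-subject cohorts, 100 Monte-Carlo replicates
per region for τ recovery, 64³ phantoms, 5001-point lookup tables — a few
seconds each on one core. Deterministic seeds flow through
`numpy.random.default_rng` everywhere; CLI commands echo their full
configuration, seed and protocol fingerprint to a JSON run manifest so
any output can be regenerated.

Known limitations: the growth model is a single exponential (no logistic
or bi-exponential alternatives, no longitudinal repeated-measures
structure); τ is weakly identified in slow regions whose amplitude is
comparable to the noise (the caudate, amplitude ≈ 0.08 1/s against
σ = 0.03 1/s, carries a heavy-tailed τ estimate); and voxel-wise normative
maps are out of scope.
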