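# Methods

This note documents the models implemented in `svsdg`, the choices made where
the design was genuinely open, what the synthetic protocol generator does and
does not emulate, and the known limitations of the estimators. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Autonomic indices from RR intervals

The heartbeat observable is the RR-interval series RR(k) in seconds. Its
history is expanded on a discrete orthonormal Laguerre basis with discount
α and orders 0..8,

    L_j(k) = Σ_{n=0}^{k-1} φ_j(n) · RR(k−n−1),

a strictly causal convolution that compresses long heartbeat memory into nine
regressors. The interval model

    RR(k) = g0(k) + Σ_{j=0}^{8} g1,j(k) · L_j(k) + ε_RR(k)

carries time-varying coefficients that follow a random walk
g(k) = g(k−1) + ε_g and are tracked by a Kalman filter with the time-varying
observation vector [1, L_0(k), …, L_8(k)]. The sympathetic and
parasympathetic activity indices read the coefficients out through fixed
published kernels:

    SAI(k) = [Ψs0 + Ψs1·g1,0(k) + Ψs2·g1,1(k)] / RR(k)
    PAI(k) = [Ψp0 + Σ_{j=1..7} Ψpj·g1,j+1(k)] · 2·RR(k)

with Ψs = {39.2343, 10.1963, −5.9242} and Ψp = {28.4875, −17.3627, 5.8798,
12.0628, 5.6408, −7.0664, −5.6779, −3.9474}. RR is in seconds throughout;
index units are arbitrary. The first two Laguerre coefficients (slow memory)
carry the sympathetic branch; the remaining seven the parasympathetic one.

Defaults and why:

* α = 0.2 — standard in the point-process HRV estimation literature;
  exposed as a parameter.
* Kalman: g(0) from batch least squares over the first 50 beats
  (`warmup_beats`), state covariance 10·r·I, per-coefficient state-noise
  variance q = 1e-5, observation-noise variance re-estimated adaptively from
  a 30-beat innovation window. These give stable tracking on the synthetic
  benchmarks in the test suite; filtered (not smoothed) estimates are
  reported so downstream directional claims remain causal.
* State model: random walk with a very weak mean-reversion anchor
  (λ = 0.005 per beat toward the warm-up solution). A pure random walk
  drifts systematically along the unobservable (collinear) coefficient
  directions — in simulation the parasympathetic numerator slid ~12% over
  16 minutes in every run — which injects monotone time structure into every
  ratio built from the indices. The anchor suppresses this wander; it is
  ~200 beats weak, so tracked (observable) directions are unaffected, and
  the recovery benchmarks that probe the q = 0 least-squares limit disable
  it. The filter additionally needs ~300 beats past warm-up before its
  covariance and adaptive noise estimates equilibrate; analyses should
  discard (or precede the protocol with) that much recording.

**Identifiability.** The nine Laguerre regressors of a quasi-stationary RR
series are strongly collinear (each is a near-constant multiple of mean RR
plus a small fluctuation). Consequences, demonstrated in the test suite:

* Individual coefficients g1,j are *not* recoverable to within 10% at
  realistic series lengths (the per-coefficient error floor at 500 beats is
  roughly 0.04–0.1 in coefficient units regardless of the noise level). The
  kernel-projected functionals that SAI/PAI actually consume — the numerators
  Ψs·g and Ψp·g — are recovered to within a few percent, and are what the
  acceptance battery asserts (10% bound, plus a 20% bound on the whole
  coefficient vector in Euclidean norm).
* A slow oscillation planted on one coefficient is tracked in the model
  *output* g(k)·L(k) (correlation ≥ 0.99) but cannot be attributed to that
  coefficient.

## EEG band power

Raw EEG (default 256 Hz, 9 channels F3, Fz, F4, C3, Cz, C4, P3, POz, P4) is
band-pass filtered with a zero-phase Butterworth filter of order 4 between
0.5 and 45 Hz, transformed with a short-time Fourier transform using a 2-s
Hanning taper at 50% overlap (exactly 1-s time step and 0.5-Hz frequency
step), and integrated over δ 1–4, θ 4–8, α 8–12, β 12–30 and γ 30–45 Hz.
Band intervals are half-open [low, high) so each boundary bin belongs to
exactly one band; band power is integrated spectral density (µV²), and the
spectrogram normalisation satisfies a Parseval identity against the
windowed-signal variance to within 2%. Zero-phase filtering is chosen over
causal filtering so band power carries no filter lag that would bias the
directional coupling (a deliberate design choice; a causal filter would
delay band power by tens of milliseconds).

## Directional coupling (SV-SDG coefficients)

All grid-domain series live on a shared 1-s grid; "t−1" always means one
grid step.

*Descending (brain → heart).* The instantaneous rate 1/RR — stamped at the
interval midpoint to avoid a systematic half-beat lag — is interpolated to
the grid; the modulation m(t) is its fluctuation about a 15-s sliding-window
baseline. Per sliding window (step 1 s), m is regressed with no intercept on
SAI and PAI:

    m(t) = C_SAI(t)·SAI(t) + C_PAI(t)·PAI(t).

The solve uses the within-window *centred* series (fluctuation components):
m is a baseline-removed fluctuation by construction, so the autonomic
regressors enter through their within-window fluctuations as well. With raw
(large-mean) regressors and a zero-mean target, the no-intercept solution is
attenuated toward zero and the planted-coupling recovery benchmarks become
unidentifiable; centring preserves the noiseless identities exactly
(m = 2·SAI recovers C_SAI = 2, C_PAI = 0 to 1e-8). Windows whose design
matrix has condition number above 1e8 are masked invalid and logged. The
per-band coupling is the lagged ratio SDG_{EEG_F→X}(t) = C_X(t)/EEG_F(t−1).

*Ascending (heart → brain).* Band power follows the lag-1 adaptive Markov
model EEG_F(t) = κ_F·EEG_F(t−1) + Ψ_F(t−1) + ε_F. κ_F is fitted per sliding
window by no-intercept least squares of EEG_F(t) on EEG_F(t−1); the drive is
identified with the pointwise residual Ψ_F(t−1) = EEG_F(t) − κ̂·EEG_F(t−1)
(the adjusted error is absorbed into Ψ_F — the only identification
computable from the lag-1 model alone; a zero-drive surrogate test bounds
the resulting bias). The coupling is SDG_{X→EEG_F}(t) = Ψ_F(t)/X(t) — note
the denominator is unlagged in the ascending direction and lagged in the
descending one, exactly as the model defines them.

Denominator guard: points with |denominator| below 1e-6 times the series
median magnitude are masked, never clipped, and masked points are excluded
from every condensation.

**Property of the uncentred AR fit.** On positive, mean-dominated power the
no-intercept lag-1 slope is κ̂ ≈ (µ² + κσ²)/(µ² + σ²) ≈ 1 regardless of the
underlying κ, so Ψ̂ behaves like a first difference plus a leak term
(κ̂−κ)·EEG. κ is therefore only recoverable on (near) zero-mean fluctuation
series — the condition under which the AR benchmarks are run — and the
ascending SDG on real-scale power should be read as a normalised
power-innovation, not as drive-minus-noise.

## Condensation, statistics, multivariate models

Per condition the time-resolved markers are condensed into median and MAD
(median absolute deviation, no 1.4826 consistency constant — a descriptive
variability measure). Autonomic markers are z-scored over the whole protocol
first; coupling features enter the feature table as raw MADs (z-scoring is
affine and leaves rank statistics and MI rankings unchanged). A condition
with fewer than 10 valid points is marked missing with a warning.

Condition-wise tests: Friedman (rank-based, average-rank tie correction,
χ² reference; a fully tied matrix returns statistic 0, p = 1), Wilcoxon
signed-rank (zero differences dropped; exact enumeration of the signed
rank-sum null for n ≤ 25 via dynamic programming, normal approximation with
tie correction above), Bonferroni threshold α/9 ≈ 0.0056 across the nine
channels.

Feature ranking is the staged MRMR procedure on plug-in mutual information
(10 equal-width bins per continuous variable, bits; "zero" means < 1e-12
bits): seed with the most relevant feature; admit zero-redundancy,
nonzero-relevance features by relevance; then admit by the mutual information
quotient MIQ = I(x,y) / [(1/|S|)·Σ_{z∈S} I(x,z)]; append zero-relevance
leftovers in seeded-random order. Relevance is I(candidate, target); the
variant that substitutes the running mean relevance of the selected set is
available behind `literal_relevance=True` (that form makes relevance
independent of the candidate, which we read as a notational conflation).

Stress models, evaluated in subject-stratified five-fold cross-validation
(all four conditions of a subject share a fold, preventing identity
leakage): Gaussian-kernel ridge regression onto the stress level coded
0/1/4/5 (regularisation strength 0.027; bandwidth = median pairwise training
distance; features z-scored per training fold; RMSE on pooled held-out
predictions) and a kernel naive Bayes classifier for low (rest + stressor 1)
vs high (stressors 2 + 3) stress (per-feature Gaussian KDE per class,
Silverman bandwidth; accuracy, sensitivity for high-stress detection,
specificity). By default MRMR selection of the top five features is nested
inside each training fold; one-shot selection on the full table is available
behind a flag.

## Synthetic protocol generator

The generator emulates a graded mental-stress protocol — 60-s rest plus
three 300-s stressor blocks, preceded by a 360-s lead-in that represents the
pre-protocol recording and lets the Kalman filter pass both its warm-up and
its covariance-equilibration transient before the first condition starts —
for a default cohort of 37 subjects, 9 channels and 5 bands. Condition
effects are planted on coupling *variances*, not means: variability, not
central tendency, is what separates the conditions.

Generation chain per subject (one master seed spawns per-subject child
seeds, so enlarging the cohort leaves existing subjects untouched):

1. Two independent band-limited latent oscillations S*(t), P*(t)
   (~0.05–0.2 Hz, Mayer-wave scale) stand for sympathetic and
   parasympathetic outflow; their amplitude grows with the stress level
   (1.2 → 2.2 a.u.), alongside a smaller graded fast rate noise η.
2. The planted descending control m(t) = C_SAI(t)·S* + C_PAI(t)·P* + η
   (C means ±0.012 Hz/a.u., slow fluctuation sd 0.006, condition-invariant)
   drives an integrate-and-fire heartbeat generator with threshold 1 and
   rate µ + m (µ = 1.2 Hz), which makes RR = 1/(µ+m) exact for constant
   modulation. Resulting RR variability is ≈ 20–45 ms — physiological.
3. The SAI/PAI series used for the ascending drive are the package's own
   Laguerre/Kalman estimates of the generated RR series, so they equal what
   the analysis stage recomputes, bit for bit.
4. Band power per (channel, band) follows the lag-1 adaptive Markov model
   with κ = 0.7, heart drive gS(t)·SAI + gP(t)·PAI and innovation sd 5% of
   the band's mean-power target. For the planted bands (α, β, γ) the
   relative gain fluctuation grows with the stress level (0.30 → 0.80); the
   null bands (δ, θ) stay at the rest level throughout. Negative generated
   power is floored at 1e-6 µV² with a logged count.

Three design choices keep the null features clean, i.e. make the false-flag
criterion meaningful:

* planted bands are driven by both branches with gains inversely
  proportional to each index's mean, so the composite drive tracks relative
  autonomic state and the opposite-signed mechanical rate sensitivities of
  SAI (∝ 1/RR) and PAI (∝ RR) cancel to first order;
* the slow null bands carry a weak drive that fluctuates with its own gain
  process but not with beat-to-beat autonomic input (largely non-cardiac
  slow-band power), making them true nulls for the directional battery;
* Monte-Carlo replicate cohorts use equal-length condition blocks so the
  small-sample bias of the per-condition MAD estimate is uniform across
  conditions;
* the long lead-in (above) keeps estimator transients out of the
  time-ordered conditions, where they would masquerade as condition effects
  — verified by a stationary-cohort control in which no variability map is
  graded and the battery flags ≤ 10% of pairs.

Two distinct condition effects are planted. The ascending drive-gain grading
is *band-specific* (α, β, γ). The autonomic-amplitude grading is a
*pathway-level* brain-to-heart effect: because the descending control
coefficients are shared across bands (one C_SAI, C_PAI per window), every
descending feature inherits it — descending condition effects are planted,
but not band-resolved. Band-specific false-flag accounting is therefore only
meaningful on the ascending side (δ and θ are the true null bands).

**What the generator does not emulate**, hence what passing tests do not
show about real data: raw ECG/EEG waveforms and their artifacts; ectopic
beats; non-stationary baselines, movement, and electrode noise; genuine
closed-loop brain-heart feedback (the planted coupling is feed-forward from
latent autonomic oscillations); inter-channel correlation structure beyond a
per-channel gain factor; respiratory sinus arrhythmia as a distinct
oscillator.

**Identifiability of the planted couplings.** With the estimators as
defined, the descending control-coefficient *trajectories* C_X(t) are not
recoverable through the double-estimation chain: the estimated SAI/PAI
fluctuations of any such dataset are dominated by the mechanical 1/RR
response, which makes the two regressors near-collinear and the m ↔ SAI
relation independent of the planted C. (Closed-loop constructions that
define the truth on the estimated indices are either unstable or concentrate
all information in a single observable direction.) The recoverable planted
quantities are: the modulation m(t) (correlation ≥ 0.95), the
kernel-functional content of the autonomic dynamics, the ascending drive and
its gain on fluctuation-dominated series, and — the scientific target — the
condition-wise *variance structure*, which the Friedman battery detects with
measured sensitivity ≥ 0.8 and false-flag rate ≤ 0.1 over 100 replicate
cohorts.

## Problem sizes used by the test battery

The feature-space check runs 5 subjects over the full protocol plan. The
Monte-Carlo power experiment uses 100 replicate cohorts of 10 subjects with
equal 120-s condition blocks and a 3-channel montage (F3, Cz, P4) — a
deliberately compact replicate of the study design whose planted effect
sizes are stated above; the sensitivity/false-flag criteria are evaluated at
the Bonferroni-corrected threshold for the montage in use, pair-flagging a
(branch, band) if any channel is significant. A companion control runs 30
stationary cohorts (no planted grading) through the same battery and
requires ≤ 10% flags overall.

## Known limitations

* Filtered (not smoothed) Kalman estimates trade some accuracy for
  causality; innovations are white on well-specified data but the
  coefficient attribution is collinearity-limited (see above).
* The ascending κ̂ on mean-dominated power saturates near 1; SDG ratios are
  unaffected as ratios but κ itself is only meaningful for fluctuation
  series.
* An autocorrelated heart drive is partially absorbed into κ̂ by the lag-1
  fit; drive-gain benchmarks therefore use white fluctuation drives.
* The plug-in MI estimator with 10 equal-width bins is biased upward for
  small samples; MRMR rankings are compared against a literal brute-force
  oracle rather than against an unbiased MI.
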