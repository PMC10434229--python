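# Methods

This note documents the model, every default parameter, the numerical
choices, what the synthetic generator does and does not emulate, and the
known limitations. Units are seconds, Hz and microvolt unless stated.

## 1. Signal model and pipeline

The analysis chain estimates a time-varying directed network between a small
set of cortical regions from epoched, stimulus-locked multichannel EEG.

### 1.1 Conditioning (`adtfnet.preprocessing`)

Epochs span −200…1000 ms around stimulus onset, materialized as 300 samples
at 250 Hz on the half-open interval [−0.2, 1.0) (the nominal end time is not
itself sampled). Steps, in order:

1. **Baseline correction** — per channel and epoch, subtract the mean over
   the pre-stimulus window (default −0.2…0 s).
2. **Artifact rejection** — drop any epoch with a sample strictly exceeding
   ±75 µV on any channel. Samples exactly at the threshold are kept
   (strict-inequality convention); survivors are returned unmodified and in
   order.
3. **Band-pass 0.1–30 Hz** — zero-phase (forward–backward) 4th-order
   Butterworth. Each epoch is demeaned exactly first. When the epoch is
   shorter than two periods of the low cut-off (the 1.2 s default epoch vs.
   the 10 s period of 0.1 Hz), the IIR high-pass section is dropped: its
   impulse response outlasts the epoch, so it contributes only edge
   transients that distort in-band amplitudes by tens of percent, while the
   sub-cut-off content it would remove is precisely the per-epoch mean
   already subtracted. Long recordings get the true band-pass.
4. Optional common-average reference (off by default; it stands in for
   reference standardization schemes that require head-model information).

### 1.2 Minimum-norm inverse (`adtfnet.inverse`)

Scalp potentials `x(t)` map to source activity `φ(t) = W x(t)` with

    W = Cs Aᵀ (A Cs Aᵀ + µ² Cn)⁻¹,   µ² = tr(A Cs Aᵀ) / (tr(Cn) · snr²)

- `A` — lead field (channels × sources).
- `Cs` — source covariance prior; default identity (no prior).
- `Cn` — noise covariance, estimated from the pooled pre-stimulus baseline
  (demeaned, symmetrized, diagonal loading 1e−12·tr/n). `tr(Cn) = 0` is
  treated as the noiseless limit µ² = 0.
- `snr` — assumed amplitude signal-to-noise ratio; default 3, the standard
  choice for evoked responses. The µ² expression makes the regularization
  scale-invariant in both signal and noise units: µ is dimensionless
  relative to the mean eigenvalue ratio of signal to noise.

ROI time series are means over member sources, resolved from coordinates by
Euclidean distance (sources within the ROI radius; nearest source as a
logged fallback). A packaged four-ROI table (TPJ, STG, A1, V1 per visual
field) is included.

### 1.3 Time-varying MVAR by multi-trial Kalman filtering (`adtfnet.tvar`)

The source vector follows

    X(t) = Σⱼ₌₁..p Aⱼ(t) X(t−j) + η(t),   η white, covariance V(t).

The vectorized coefficients form the Kalman state, evolving as a random walk
with state-noise variance `uc` per step. At each time point the measurement
update uses the *whole epoch ensemble simultaneously* (epochs are independent
realizations of the same stimulus-locked process), so the coefficient
trajectory is time-locked and has ensemble-level statistical power. Update
written in information form: with `Z` the (epochs × np) lagged design and σ²
the tracked innovation scale, `P⁺ = (P⁻¹ + ZᵀZ/σ²)⁻¹` — identical to the
gain form but O((np)³) instead of O(epochs³) per step.

- `p` — model order, selected by the Schwarz Bayesian Criterion on a pooled
  stationary least-squares fit: `SBC(p) = N·log det(Σ_res) + p·n²·log N`,
  minimum wins, ties toward the smaller order. The scheduled generator is
  AR(2), and SBC recovers p = 2 reliably at the default data sizes.
- `uc` — default 1e−3. Governs the tracking/variance trade-off: the
  adaptation time constant is roughly `1/uc` samples of ensemble data, and
  the steady-state coefficient ripple grows as √uc. 1e−3 tracks the
  scheduled 100-ms-scale coupling switches with ≲0.1 s lag at 100 epochs; at
  1e−5 the estimate converges to the stationary least-squares fit (verified
  to 0.05 elementwise); 1e−2 is noticeably noisier but still directionally
  correct. The same constant is used as the exponential-smoothing rate of
  the innovation covariance estimate.
- State initialization: zero coefficients, identity state covariance,
  innovation covariance initialized at the empirical data covariance. The
  first `p` samples lack a full lag history and are flagged as burn-in.

### 1.4 Adaptive directed transfer function (`adtfnet.adtf`)

    Ā(f,t) = I − Σₖ₌₁..p Aₖ(t) e^(−i2πfk/fs),  H(f,t) = Ā(f,t)⁻¹,
    ι²ᵢⱼ(f,t) = |Hᵢⱼ(f,t)|² / Σₖ |Hᵢₖ(f,t)|²

Rows of ι² sum to 1 exactly (enforced to 1e−9 in tests). The integrated flow
υ²ᵢⱼ(t) is the **mean** of ι² over the grid frequencies inside the analysis
band — using the in-band grid count as denominator (not the band width in
Hz) keeps υ² in [0, 1] independent of grid resolution. Defaults: 1 Hz grid
over 1–30 Hz, band (1, 30). υ² is invariant to common rescaling of all node
series (to machine precision, after refitting).

**Mediated flow.** H contains all directed paths, not only direct links:
with V1→STG and STG→TPJ both active, υ²(V1→TPJ) is genuinely nonzero. This
is a property of the transfer-function family (DTF/ADTF), not leakage; such
path-connected detections are counted as true positives in the recovery
experiments, and only path-disconnected pairs can be false edges.

### 1.5 Surrogate statistics (`adtfnet.surrogates`)

Null model: every node series, in every epoch, is independently Fourier
phase-randomized (uniform phases on positive frequencies; DC and Nyquist
kept real), which preserves each amplitude spectrum to machine precision
while destroying all cross-node structure. For each of `n_surrogates`
(default 200; 50 in the replicate experiments) the full fit + ADTF is re-run
with identical parameters.

Two-stage edge significance at level α = 0.05 with Bonferroni family
m = n(n−1) directed edges:

1. **Per-subject quantile gate** — the group-median flow must exceed the
   group median of the per-subject null quantiles at level `1 − α/m`.
2. **Group signed-rank test** — one-sided exact Wilcoxon signed-rank of
   (observed − per-subject-median-null) across subjects, at `α/m`. The exact
   tail distribution is computed by dynamic programming and vectorized over
   all edge/time cells; cells with zero differences fall back to the
   reference implementation.

The quantile gate bounds the family-wise error over the (strongly
autocorrelated, uncorrected) time axis; the signed-rank stage enforces group
consistency. Below 5 subjects the signed-rank test has no attainable
rejection at α/m, so a quantile-only mode exists (`group_test="quantile"`)
and the pipeline selects it automatically with a logged notice.

Optional `time_correction=True` additionally divides the level by the number
of reported time points; off by default because the quantile gate already
controls the familywise rate empirically (see §3).

### 1.6 Network timeline and behaviour (`adtfnet.network`)

Significant edges are reduced to maximal runs of consecutive significant
time points; runs shorter than `min_duration` (default 0.02 s, one step of
the decimated network grid) are discarded. Events are ranked by onset;
onsets within `tie_tol` (default 0.04 s, two grid steps) merge into one
connection step, and reciprocal overlapping pairs render as `A<->B`.
Per-subject flow summaries (mean υ² over an edge's significant times;
`peak` optional) are correlated with mean reaction times by sample Pearson r
with the two-sided t-distribution p-value (n − 2 df).

The network time grid is the reporting window (default 0.2–0.9 s) decimated
by `network_decimate = 5`, i.e. 20 ms resolution. Justification: the Kalman
adaptation time constant at uc = 1e−3 and the 0.02 s `min_duration` both
exceed 20 ms, so the full 4 ms grid adds surrogate cost (×5) without
temporal information.

## 2. The synthetic generator (`adtfnet.synthetic`)

Purpose: a ground truth with *known* directed structure, onsets and
behavioural coupling, at realistic data sizes, so every pipeline claim is
checkable. Defaults emulate a 15-subject, 100-epoch, 32-channel, 250 Hz
cued-attention study.

- **Nodes** — four sources (V1, A1, STG, TPJ). Each has intrinsic stable
  AR(2) damped-oscillator dynamics with pole radius 0.5 and frequencies
  (10, 12, 7, 5) Hz, giving in-band spectral content.
- **Schedule** — piecewise-constant couplings at lag 1: V1↔STG of ±0.25 on
  [0.25, 0.9) s and STG↔TPJ of ±0.25 on [0.55, 0.9) s. The reciprocal
  coefficients have opposite signs: antisymmetric coupling perturbs the
  companion-matrix spectrum at second order, so the system stays stable
  (worst spectral radius 0.909), whereas symmetric ±0.25 coupling is
  unstable at this damping. Stability is asserted at every time point, not
  assumed.
- **Subjects** — a per-subject multiplicative coupling scale
  γ_s ~ N(1, 0.1), clipped to [0.7, 1.2], is the subject's true
  "information flow" level.
- **Epochs** — independent realizations driven by unit-variance Gaussian
  innovations, with a 0.4 s pre-epoch burn-in under the epoch-start
  coefficients so the process is stationary at the first sample.
- **Forward model** — a smooth synthetic lead field: channels on a regular
  1-D axis, each source a Gaussian topography (width 0.3× source spacing,
  jittered centers, 1% broadband perturbation, unit-norm columns, full
  column rank). Sensor noise is white Gaussian scaled so the realized
  signal-power/noise-power ratio equals `sensor_snr` (default 5).
- **Reaction times** — linear in γ_s plus Gaussian noise (sd 15 ms), slope
  calibrated so the population correlation equals `rt_target_r`
  (default −0.55), mean 280 ms. The noiseless case is an exact linear map.
- Everything is a pure function of (arguments, seed); one master seed drives
  the whole study via spawned independent streams.

**Not emulated:** realistic head geometry (no BEM/FEM, no dipole
orientations), fMRI/BOLD, ocular artifacts, bad channels, per-condition
designs beyond free-form labels, non-Gaussian innovations.

## 3. Operating characteristics (measured)

- **Ordering recovery** — with the default study settings and 50 surrogates,
  the two-step timeline (V1↔STG before STG↔TPJ) is recovered with correct
  onsets (±0.2 s) and rank order in ≥ 90% of 50 replicate studies
  (observed: 100% in development runs).
- **Family-wise type-I error** — on null studies (independent nodes,
  15 subjects), the probability that any edge/time point is flagged is
  ≤ 0.05 over ≥ 100 replicates (observed: 0 flags). Estimated at the node
  level by design: statistical independence must hold at the tested series
  for the claim to be about the statistics rather than source separation.
- **Why the quantile gate uses 1 − α/m** — band-limited sensor noise shared
  across estimated sources survives the inverse and is invisible to the
  per-node phase-randomized null (the classic false-connectivity problem).
  The Bonferroni-corrected per-subject quantile empirically suppresses these
  weak shared-noise edges while leaving true flows (an order of magnitude
  above the null) untouched.

## 4. Numerical choices

- Kalman hot loop and epoch simulation are numba-compiled (cached); a full
  4-node, 100-epoch fit takes ~4 ms, a 50-surrogate subject ~0.4 s.
- Spectral inversion uses batched LAPACK inverses on (F, T, n, n) stacks;
  singular matrices are reported with their (frequency, time) coordinates.
- The exact signed-rank tail is a convolution table (O(n·W) with
  W = n(n+1)/2), evaluated once and indexed vectorially; half-integer
  statistics from average ranks are ceiled conservatively.
- Seeds are spawned via `numpy.random.SeedSequence`; derived integer seeds
  are reduced modulo 2³¹ − 1.

## 5. Limitations

- The minimum-norm inverse with a generic identity source prior gives biased
  amplitude estimates; only correlation-level recovery (> 0.9 per node at
  sensor SNR ≥ 10) is claimed, not amplitude fidelity.
- ADTF directionality is within-model: it assumes the MVAR order captures
  the relevant dynamics; severe order misspecification degrades both power
  and calibration (the SBC stage mitigates this).
- Phase-randomization nulls preserve each node's spectrum but not shared
  noise structure; the Bonferroni quantile gate compensates empirically, but
  very high shared-noise regimes (sensor SNR ≪ 1) are untested.
- Mediated (indirect-path) flow is reported as flow; if direct-link topology
  is required, a partial-coherence-style factorization would be needed and
  is out of scope.
- The RT model is linear with Gaussian noise; real response-time
  distributions are skewed.
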