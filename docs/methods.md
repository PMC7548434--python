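# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the problem was genuinely open.

## Signal model of the synthetic flash task

Occipital channels share a single alpha source

    s(t) = A(t) · cos(φ(t) + ψ_h(t))

* **Envelope** `A(t)`: log-normal, obtained by exponentiating a
  low-pass-filtered (< 1 Hz, default cutoff 0.5 Hz) standard-normal process
  scaled to a target mean (default 10 µV) and SD (4 µV). A log-normal,
  slowly drifting envelope reproduces the unimodal, right-skewed amplitude
  distributions seen in posterior alpha and the non-stationarity that
  degrades prestimulus (−100 ms) phase measurements.
* **Phase** `φ(t)`: integral of an instantaneous frequency that wanders
  slowly around 10 Hz (low-pass-filtered Gaussian jitter, SD 0.4 Hz), so the
  rhythm is narrowband but not perfectly stationary.
* **Hemispheric wander** `ψ_h(t)`: each hemisphere adds an independent slow
  phase offset (SD 20° by default), so left/right occipital phases agree
  most of the time and the >90° asynchrony rejection fires only rarely. A
  larger SD emulates cohorts with more inter-hemispheric asynchrony.
* **Noise**: each channel adds independent 1/f noise (spectral shaping of
  white noise; default slope 1, scale 8 µV). Mastoids carry attenuated
  noise; Fp/infraorbital channels carry noise plus optional blink pulses
  that appear with opposite sign above and below the eye, so the bipolar
  vEOG derivation sees their full amplitude.

**Behavior.** Trial `i`'s flash is observed with probability

    p_i = clamp( base_rate + d_i · cos(θ_i − θ*) , 0, 1)

where `θ_i` is the *true* generator phase at `t0 + true_t2` (90° = peak
convention), `θ*` the true preferred phase (default 270°, the trough), and
`d_i = gating_depth · A_i / median(A)` when amplitude gating is on
(constant `gating_depth` otherwise). Outcomes are Bernoulli draws at `t0`;
this places the causal event at the conduction-delayed phase, which is
exactly what the analysis tries to recover. Configs that clamp more than
5% of trial probabilities are rejected as mis-specified.

Defaults mirror the study conditions: 160 trials per participant, 10–15 s
uniform inter-stimulus intervals, base observation rate 0.58, gating depth
0.15, 512 Hz sampling (the analysis rate, so the down-sampling step is an
identity on synthetic data; the VEP task is generated at 2048 Hz).

**What the generator does not emulate.** Stimuli are scheduled uniformly in
time rather than triggered on visible alpha as a human experimenter would;
consequently short synthetic recordings can contain long low-alpha
stretches in which phases are noise-dominated and many trials are rejected.
There is no eyelid-transmission optics, no evoked response to the flash
(deliberately — the induced-activity control tests rely on this), no alpha
blocking, and no inter-individual alpha-frequency differences. Passing
recovery tests therefore show that the *analysis* is correct and calibrated
under the assumed signal model, not that real EEG satisfies that model.

**Seeding.** Every generator expands one master seed into named sub-streams
(envelope, phase, noise, behavior, blinks, schedule) via `SeedSequence`
spawning, so outputs are bit-for-bit reproducible and individual components
can be varied independently.

## Preprocessing conventions

* The band-pass (0.01–50 Hz) is a second-order Butterworth applied
  forward–backward (`sosfiltfilt`): each pass is −3 dB at the edges, −6 dB
  combined, with exactly zero phase shift. It is applied to the continuous
  recording before epoching, keeping filter transients away from analysis
  windows. The 0.01 Hz pole has a time constant of tens of seconds; the
  resulting slow edge drift lies far below the alpha band and does not
  affect wavelet phase or amplitude.
* Epoch windows are half-open in samples, `[onset+lo, onset+hi)`; a
  (−50, 200) ms window at 2048 Hz is exactly 512 samples. Baselines use the
  same half-open rule.
* Blink windows start at the epoch's first sample and advance by the step;
  a final partial window is evaluated iff at least half the window length
  remains. Rejection threshold is peak-to-peak ≥ 100 µV (at exactly the
  threshold, the trial is rejected; at 90° asynchrony, the trial is kept —
  both follow the strict/non-strict wording of the respective rules).
* Down-sampling is polyphase (`resample_poly`), which anti-aliases even
  though the preceding band-pass has already removed most content above
  50 Hz. Event onsets are stored in seconds and survive rate changes.

## Morlet wavelet and FWHM conventions

The kernel is `exp(−t²/2σ_t²)·exp(2πi f₀ t)` with
`σ_t = n_c/(2π f₀)` (42.44 ms at f₀ = 10 Hz, n_c = 8/3), sampled on an odd,
centered grid truncated at ±3σ_t, and scaled so a unit-amplitude cosine at
f₀ yields output magnitude 1 (hence peak-to-peak amplitude exactly 2; the
residual ripple from truncation sidelobes is < 5·10⁻⁴). The ±3σ support is
deliberate: it is the truncation at which the measured spectral width of
the sampled kernel matches the width this pipeline is specified to have
(below); wider supports converge to the continuous limit instead.

Reported phase is `(raw angle + 90°) mod 360`, making 90° the oscillation
peak and 270° the trough — so phase-bin labels can be read directly
against the physiological hypothesis (trough = excitable).

Two discrete FWHM measurement conventions are used, both documented here
because the sampled, finite-support kernel differs slightly from the
continuous Gaussian:

* **Time domain**: the width between the first sample *below* half-maximum
  on each side of the envelope peak (outward-rounded crossings, i.e. the
  closed span of above-half sample bins). At 512 Hz this is 52 samples =
  101.56 ms; the continuous-limit value `2√(2 ln 2)·σ_t` is 99.94 ms.
* **Frequency domain**: linear-interpolated half-maximum crossings of the
  amplitude spectrum of the truncated kernel on a zero-padded grid
  (2¹⁸ points). This measures 8.87 Hz with half-power points at 5.57 and
  14.44 Hz; the continuous limit `2√(2 ln 2)·f₀/n_c` is 8.83 Hz.

Samples within half a kernel support of a series edge are flagged invalid
for phase read-out.

## ΔOR, profiles, preferred phase

* Phase-bin membership is circularly half-open `[c−45°, c+45°)`, so the four
  cardinal bins partition the circle and the 1°-step rotating bins agree
  with the 2×4 grid at 0/90/180/270.
* The overall OR subtracted from every bin is computed over *all* retained
  trials of the participant (both amplitude levels), for the grid and the
  rotating profiles alike. ΔOR is a difference of percentages, not a
  percent change.
* The amplitude median is computed per participant on retained trials only
  (rejection precedes binning); values strictly above the median are
  "high". If all amplitudes tie, everything is "low" and a warning is
  logged.
* Empty rotating bins are linearly interpolated across circular gaps of at
  most 5°; wider gaps flag the participant, who keeps their 2×4 grid but is
  excluded from profile-based aggregates. Participants with an empty 2×4
  cell are excluded from the ANOVA (exclusions are logged and reported).
* The preferred phase is the direction of
  `(1/360) Σ_c profile(c)·(cos c, sin c)`; its magnitude is the
  center-of-mass offset in ΔOR units. PPE is evaluated at the nearest
  integer degree of the preferred and pessimal angles. Individual vectors
  carry center-of-mass magnitudes (not PPEs); for cosine-like profiles the
  two are proportional (PPE = 4·magnitude).
* The group preferred phase is the vector mean of individual vectors, which
  by linearity equals the preferred phase of the across-participant mean
  profile to machine precision; the group PPE is read off the mean profile.
* The group CI converts individual vectors to cartesian components, takes
  t-based 95% CIs on x and y, and returns the arc of directions from the
  origin to the CI rectangle (corner bearings around the group angle; the
  full circle if the rectangle contains the origin).

## Statistical battery

* The 2×4 within-subjects ANOVA uses the standard balanced decomposition
  with each effect tested against its own effect-by-subject error term
  (df 1/19, 3/57, 3/57 at n = 20).
* Mauchly's W is computed from the covariance of orthonormal contrast
  scores (Helmert contrasts; W is rotation-invariant), with
  `χ² = −(n−1)·d·ln W`, `d = 1 − (2m²+m+2)/(6m(n−1))`,
  `df = m(m+1)/2 − 1`. The p-value is the **first-order** χ² tail
  probability. Some references (R's `mauchly.test`, pingouin) add a
  second-order Box term; W, χ² and df are identical under either
  convention, and the first-order tail is the one this pipeline's reported
  p-values follow.
* Partial η² is `F·df₁/(F·df₁+df₂)`; observed power uses a noncentral F
  with `λ = F·df₁` (the convention of mainstream statistics packages) —
  both are pure functions of the printed F and dfs.
* Tukey HSD within an amplitude level uses the per-level phase-by-subject
  error term (df = (n−1)(k−1) = 57 at n = 20) with studentized-range
  p-values; a pooled omnibus error term can be supplied instead (the right
  choice is genuinely ambiguous for within-subject designs, so both modes
  exist and the per-level refit is the default).
* Cell-vs-zero tests are one-sample t (df = n−1) with Bonferroni correction
  for the 8 cells. Reported p-values are rounded to 4 decimals and floored
  at 0.0001 (never printed as 0); exact values are kept alongside.

## Staircase calibration

The threshold procedure is a fixed-step 1-up/1-down rule on greyscale
intensity (clamped to 0–255, clamps logged); a reversal is a sign change in
the trial-to-trial intensity slope, and the threshold is the mean intensity
of all trials strictly after the third reversal. For a logistic observer
this converges to the 50%-observation intensity as the trial count grows
and the step shrinks (the 1-up/1-down equilibrium). No step-halving is
applied — the rule is deliberately the simple fixed-step variant.

## Problem sizes used by the validation suite

Chosen as the package's own desk-scale validation conditions: parameter
recovery runs 20 participants × 160 trials (full chain including
VEP-estimated t2, with each participant's embedded `true_t2` drawn from
63–89 ms); the type-I calibration uses 500 reduced cohorts of 8
participants × 64 trials at 1.2–1.8 s inter-stimulus intervals with gating
depth 0, asserting a phase-effect rejection rate of 0.05 within three
binomial standard errors. C1-latency recovery uses the full 600+600-trial
task per participant.

## Known limitations

* The generator's amplitude gating is linear in the normalized envelope;
  real amplitude–effect relations may be steeper, so low-amplitude PPEs in
  synthetic cohorts are larger (relative to high) than in real data.
* Phase measured through the wavelet is smoothed over ~100 ms; with
  frequency jitter this attenuates, but does not bias, the recovered
  gating. The measurement time is snapped to the nearest sample, which at
  512 Hz contributes up to ±1 ms (±3.6° at 10 Hz).
* Trials scheduled at short inter-stimulus intervals are serially
  correlated through the slow envelope and phase processes; the ANOVA's
  type-I rate remains nominal under the null (verified by simulation), but
  per-participant profiles can have empty bins at small trial counts.
* EDF/BDF files are read through MNE when it is installed; the package's
  native container is HDF5 and no EDF writer is provided.
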