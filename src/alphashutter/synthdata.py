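"""Synthetic recordings with a known, embedded phase-gating ("shutter") effect.

The generator emulates the two experimental tasks:

* Flash task: occipital channels carry a shared ~10 Hz alpha source with a
  slowly varying log-normal envelope on top of 1/f background noise.  Flash
  observation is a Bernoulli draw whose probability is gated by the *true*
  alpha phase at a known conduction delay (``true_t2``) after stimulus onset,
  with the gating depth optionally scaling with the instantaneous envelope.
* Checkerboard VEP task: POz carries opposite-polarity C1 deflections for
  upper- versus lower-field stimuli at a known peak latency; a configured
  fraction of epochs carry >100 uV blink artifacts on the vEOG derivation.

Phase convention everywhere: degrees in [0, 360) with 90 deg = alpha peak and
270 deg = trough (an ascending zero-crossing is 0 deg).

All generators are pure functions of (config, seed): one master seed expands
into named sub-streams (envelope, phase, noise, behavior, blinks), so the same
config reproduces outputs bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigError, ThresholdUndefinedError
from .preprocess import (
    FRONTAL,
    INFRAORBITAL,
    LEFT_OCCIPITAL,
    MASTOIDS,
    RIGHT_OCCIPITAL,
    Recording,
)

logger = logging.getLogger("alphashutter.synthdata")

_STREAMS = ("envelope", "phase", "noise", "behavior", "blinks", "schedule")


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_STREAMS, children)}


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, scale: float) -> np.ndarray:
    """1/f^exponent noise via spectral shaping, unit-std then scaled (uV)."""
    from scipy.fft import next_fast_len

    m = next_fast_len(n)
    white = rng.standard_normal(m)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(m)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, m)[:n]
    sd = x.std()
    return x / sd * scale if sd > 0 else x


def _slow_gaussian(rng: np.random.Generator, n: int, fs: float, cutoff_hz: float) -> np.ndarray:
    """Low-pass-filtered standard-normal process (zero mean, unit variance)."""
    sos = signal.butter(2, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    g = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return (g - g.mean()) / g.std()


# ---------------------------------------------------------------------------
# Flash task
# ---------------------------------------------------------------------------

@dataclass
class ShutterConfig:
    """Conditions of the flash-observation task.

    The defaults mirror the study: ~160 flashes per participant at long
    (10-15 s) inter-stimulus intervals, a 10 Hz occipital alpha rhythm with a
    slowly drifting envelope, a base observation rate near 58%, gating whose
    depth scales with the normalized envelope, and a true preferred phase at
    the alpha trough (270 deg).
    """

    sampling_rate: float = 512.0
    n_trials: int = 160
    alpha_freq: float = 10.0
    envelope_mean: float = 10.0          # uV, log-normal envelope mean
    envelope_sd: float = 4.0             # uV
    envelope_cutoff_hz: float = 0.5      # low-pass (<1 Hz) envelope drift
    freq_jitter_sd: float = 0.4          # Hz, sd of slow instantaneous-frequency drift
    hemi_phase_sd_deg: float = 20.0      # sd of slow per-hemisphere phase wander
    noise_exponent: float = 1.0          # 1/f slope of the background noise
    noise_scale: float = 8.0             # uV, per-channel independent noise
    true_t2: float = 75.0                # ms, embedded conduction delay
    true_preferred_phase: float = 270.0  # deg, phase of maximal observation
    base_rate: float = 0.58              # overall observation probability
    gating_depth: float = 0.15           # probability units of the cosine gate
    amplitude_gating: bool = True        # depth scales with envelope/median
    inter_stimulus_interval_range: tuple[float, float] = (10.0, 15.0)
    blink_rate: float = 0.05             # per-trial blink probability (vEOG)
    blink_amplitude: float = 150.0       # uV
    max_clip_fraction: float = 0.05      # tolerated fraction of clamped p
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 2 * self.alpha_freq:
            raise ConfigError("sampling_rate must exceed 2 * alpha_freq")
        if not (0.0 <= self.true_preferred_phase < 360.0):
            raise ConfigError("true_preferred_phase must lie in [0, 360)")
        if not (0.0 <= self.base_rate <= 1.0):
            raise ConfigError("base_rate must be a probability")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be positive")
        lo, hi = self.inter_stimulus_interval_range
        if not (0 < lo <= hi):
            raise ConfigError("invalid inter-stimulus interval range")
        if self.envelope_mean <= 0 or self.envelope_sd <= 0:
            raise ConfigError("envelope parameters must be positive")


@dataclass
class ShutterGroundTruth:
    """Embedded per-trial truth used by recovery tests."""

    onset_s: np.ndarray            # flash onsets (seconds)
    true_phase_deg: np.ndarray     # true phase at onset + true_t2 (90 deg = peak)
    envelope_uv: np.ndarray        # true envelope at onset + true_t2
    p_observe: np.ndarray          # gated Bernoulli probability
    observed: np.ndarray           # drawn outcome
    true_t2_ms: float
    true_preferred_phase_deg: float
    gating_depth: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.onset_s.size),
                "onset_s": self.onset_s,
                "type": "flash",
                "observed": self.observed,
                "true_phase_deg": self.true_phase_deg,
                "envelope_uv": self.envelope_uv,
                "p_observe": self.p_observe,
            }
        )


def gen_shutter_recording(
    config: ShutterConfig,
) -> tuple[Recording, pd.DataFrame, ShutterGroundTruth]:
    """Generate the flash-task recording, its event table, and ground truth.

    All occipital channels share one alpha source; each hemisphere adds a
    slow phase wander (``hemi_phase_sd_deg``) and each channel small
    independent 1/f noise, so with the defaults the hemispheric phases only
    rarely differ by more than 90 deg.  The observation probability of
    trial i is::

        clamp(base_rate + depth_i * cos(phase_i - true_preferred_phase))

    with ``depth_i = gating_depth * envelope_i / median(envelope)`` when
    ``amplitude_gating`` is on, else ``gating_depth``.  A config that clamps
    more than ``max_clip_fraction`` of trials raises ``ConfigError``.
    """
    config.validate()
    rngs = _substreams(config.seed)
    fs = config.sampling_rate

    isi = rngs["schedule"].uniform(*config.inter_stimulus_interval_range, size=config.n_trials)
    onsets = 2.0 + np.cumsum(isi) - isi[0]
    duration = onsets[-1] + 2.0
    n = int(round(duration * fs))

    # alpha source: log-normal envelope x drifting-frequency oscillator
    g = _slow_gaussian(rngs["envelope"], n, fs, config.envelope_cutoff_hz)
    sigma2 = np.log1p((config.envelope_sd / config.envelope_mean) ** 2)
    mu = np.log(config.envelope_mean) - sigma2 / 2.0
    envelope = np.exp(mu + np.sqrt(sigma2) * g)

    jitter = _slow_gaussian(rngs["phase"], n, fs, 1.0) * config.freq_jitter_sd
    inst_freq = config.alpha_freq + jitter
    phi = 2.0 * np.pi * np.cumsum(inst_freq) / fs  # raw phase: 0 = signal peak
    # slow, independent per-hemisphere phase wander around the shared source
    psi = {
        hemi: np.radians(
            _slow_gaussian(rngs["phase"], n, fs, 0.3) * config.hemi_phase_sd_deg
        )
        for hemi in ("left", "right")
    }
    alpha_h = {hemi: envelope * np.cos(phi + psi[hemi]) for hemi in psi}

    occipital = list(LEFT_OCCIPITAL + RIGHT_OCCIPITAL)
    labels = occipital + ["POz"] + list(FRONTAL) + list(INFRAORBITAL) + list(MASTOIDS)
    noise_rng = rngs["noise"]
    data = np.empty((len(labels), n))
    for i, ch in enumerate(labels):
        noise = _pink_noise(noise_rng, n, config.noise_exponent, config.noise_scale)
        if ch in occipital:
            hemi = "left" if ch in LEFT_OCCIPITAL else "right"
            data[i] = alpha_h[hemi] + noise
        elif ch == "POz":
            data[i] = 0.4 * (alpha_h["left"] + alpha_h["right"]) + noise
        elif ch in MASTOIDS:
            data[i] = 0.3 * noise
        else:
            data[i] = noise

    # blink artifacts on the vEOG derivation (frontal up, infraorbital down)
    blink_rng = rngs["blinks"]
    n_blinks = int(np.sum(blink_rng.random(config.n_trials) < config.blink_rate))
    if n_blinks:
        t_axis = np.arange(n) / fs
        centers = blink_rng.uniform(1.0, duration - 1.0, size=n_blinks)
        for c in centers:
            pulse = config.blink_amplitude * np.exp(-((t_axis - c) ** 2) / (2 * 0.08**2))
            for ch in FRONTAL:
                data[labels.index(ch)] += pulse / 2.0
            for ch in INFRAORBITAL:
                data[labels.index(ch)] -= pulse / 2.0

    # behavior: gate observation by the true phase at onset + true_t2
    meas_idx = np.round((onsets + config.true_t2 / 1e3) * fs).astype(int)
    true_phase = (np.degrees(phi[meas_idx]) + 90.0) % 360.0  # 90 deg = peak
    trial_env = envelope[meas_idx]
    if config.amplitude_gating:
        depth = config.gating_depth * trial_env / np.median(trial_env)
    else:
        depth = np.full(config.n_trials, config.gating_depth)
    p_raw = config.base_rate + depth * np.cos(np.radians(true_phase - config.true_preferred_phase))
    clipped = (p_raw < 0.0) | (p_raw > 1.0)
    if clipped.mean() > config.max_clip_fraction:
        raise ConfigError(
            f"{clipped.mean():.1%} of trial probabilities leave [0,1]; "
            "base_rate/gating_depth are mis-specified"
        )
    p = np.clip(p_raw, 0.0, 1.0)
    behavior = rngs["behavior"]
    observed = behavior.random(config.n_trials) < p
    rt = behavior.uniform(0.3, 1.2, size=config.n_trials)

    rows = [
        {"onset_s": float(t0), "type": "flash", "observed": bool(o)}
        for t0, o in zip(onsets, observed)
    ]
    for t0, o, r in zip(onsets, observed, rt):
        if o:
            rows.append({"onset_s": float(t0 + r), "type": "response", "observed": None})
    events = pd.DataFrame(rows).sort_values("onset_s", kind="stable").reset_index(drop=True)
    events["observed"] = events["observed"].astype("boolean")

    truth = ShutterGroundTruth(
        onset_s=onsets,
        true_phase_deg=true_phase,
        envelope_uv=trial_env,
        p_observe=p,
        observed=observed,
        true_t2_ms=config.true_t2,
        true_preferred_phase_deg=config.true_preferred_phase,
        gating_depth=config.gating_depth,
    )
    recording = Recording(data, labels, fs, events)
    return recording, events, truth


# ---------------------------------------------------------------------------
# Checkerboard VEP task
# ---------------------------------------------------------------------------

@dataclass
class VepConfig:
    """Conditions of the conduction-delay (C1 VEP) task.

    Defaults follow the study: 600 upper- plus 600 lower-field checkerboards
    at 250-450 ms inter-stimulus intervals, recorded at 2048 Hz.  The C1
    deflection is negative for upper-field and positive for lower-field
    stimuli (calcarine polarity inversion), peaking at ``c1_peak_latency``.
    """

    n_upper: int = 600
    n_lower: int = 600
    c1_peak_latency: float = 75.0   # ms
    c1_amplitude: float = 4.0       # uV (magnitude; sign set by field)
    c1_width: float = 40.0          # ms, FWHM of the Gaussian deflection
    blink_rate: float = 0.05        # per-epoch blink probability
    blink_amplitude: float = 150.0  # uV on the vEOG derivation
    noise_scale: float = 5.0        # uV
    sampling_rate: float = 2048.0
    isi_range: tuple[float, float] = (0.25, 0.45)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.c1_peak_latency < 110.0):
            raise ConfigError("c1_peak_latency must lie in (0, 110) ms")
        if self.n_upper < 1 or self.n_lower < 1:
            raise ConfigError("stimulus counts must be positive")
        if self.c1_width <= 0:
            raise ConfigError("c1_width must be positive")


def gen_vep_recording(config: VepConfig) -> tuple[Recording, pd.DataFrame]:
    """Generate the checkerboard VEP recording and its event table."""
    config.validate()
    rngs = _substreams(config.seed)
    fs = config.sampling_rate
    n_stim = config.n_upper + config.n_lower

    types = np.array(["upper"] * config.n_upper + ["lower"] * config.n_lower)
    rngs["schedule"].shuffle(types)
    isi = rngs["schedule"].uniform(*config.isi_range, size=n_stim)
    onsets = 1.0 + np.cumsum(isi) - isi[0]
    duration = onsets[-1] + 1.0
    n = int(round(duration * fs))
    t_axis = np.arange(n) / fs

    sigma_s = config.c1_width / 1e3 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    poz = np.zeros(n)
    half = int(round(4 * sigma_s * fs))
    kernel_t = np.arange(-half, half + 1) / fs
    kernel = np.exp(-(kernel_t**2) / (2 * sigma_s**2))
    for t0, typ in zip(onsets, types):
        c = int(round((t0 + config.c1_peak_latency / 1e3) * fs))
        amp = -config.c1_amplitude if typ == "upper" else config.c1_amplitude
        a, b = max(0, c - half), min(n, c + half + 1)
        poz[a:b] += amp * kernel[a - (c - half) : b - (c - half)]

    labels = ["POz"] + list(FRONTAL) + list(INFRAORBITAL) + list(MASTOIDS)
    noise_rng = rngs["noise"]
    data = np.empty((len(labels), n))
    for i, ch in enumerate(labels):
        noise = (
            _pink_noise(noise_rng, n, 1.0, config.noise_scale)
            if config.noise_scale > 0
            else np.zeros(n)
        )
        data[i] = (poz + noise) if ch == "POz" else (0.3 * noise if ch in MASTOIDS else noise)

    blink_rng = rngs["blinks"]
    blinks = blink_rng.random(n_stim) < config.blink_rate
    for t0 in onsets[blinks]:
        c = t0 + blink_rng.uniform(0.0, 0.15)
        pulse = config.blink_amplitude * np.exp(-((t_axis - c) ** 2) / (2 * 0.03**2))
        for ch in FRONTAL:
            data[labels.index(ch)] += pulse / 2.0
        for ch in INFRAORBITAL:
            data[labels.index(ch)] -= pulse / 2.0

    events = pd.DataFrame({"onset_s": onsets, "type": types})
    events["observed"] = pd.array([None] * n_stim, dtype="boolean")
    return Recording(data, labels, fs, events), events


# ---------------------------------------------------------------------------
# Psychometric observer and the 1-up/1-down staircase
# ---------------------------------------------------------------------------

@dataclass
class LogisticObserver:
    """Bernoulli observer: P(observed) = logistic(slope * (intensity - threshold)).

    At ``intensity == threshold`` the observation probability is exactly 0.5.
    ``slope`` is in 1/greyscale units; ``slope -> inf`` is a step function.
    """

    threshold: float
    slope: float
    rng: np.random.Generator

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ConfigError("observer slope must be positive")

    def prob(self, intensity: float) -> float:
        z = self.slope * (intensity - self.threshold)
        if np.isinf(z):
            return 0.5 if intensity == self.threshold else float(z > 0)
        return 1.0 / (1.0 + np.exp(-z))

    def __call__(self, intensity: float) -> bool:
        return bool(self.rng.random() < self.prob(intensity))


def simulated_observer(
    intensity: float, threshold: float, slope: float, rng: np.random.Generator
) -> bool:
    """Single Bernoulli draw from a logistic psychometric function."""
    return LogisticObserver(threshold, slope, rng)(intensity)


@dataclass
class StaircaseTrace:
    """Record of a 1-up/1-down run over greyscale intensities (0-255)."""

    intensity: np.ndarray
    response: np.ndarray
    reversal_indices: np.ndarray  # 0-based trial index of each slope reversal
    threshold: float | None = field(default=None)


def run_staircase(
    observer,
    start_intensity: float = 128.0,
    step: float = 5.0,
    n_trials: int = 40,
    intensity_range: tuple[float, float] = (0.0, 255.0),
) -> StaircaseTrace:
    """Fixed-step 1-up/1-down staircase.

    The intensity decreases by ``step`` after every observed trial and
    increases after every missed trial (clamped to the greyscale range, with
    clamping logged).  A reversal is a trial at which the direction of the
    intensity change flips; the trace's threshold is the mean intensity of
    all trials strictly after the third reversal (None if undefined).
    """
    if n_trials < 4:
        raise ConfigError("a staircase needs at least 4 trials")
    lo, hi = intensity_range
    intensities = np.empty(n_trials)
    responses = np.empty(n_trials, dtype=bool)
    x = float(np.clip(start_intensity, lo, hi))
    for k in range(n_trials):
        intensities[k] = x
        responses[k] = observer(x)
        nxt = x - step if responses[k] else x + step
        clamped = float(np.clip(nxt, lo, hi))
        if clamped != nxt:
            logger.info("staircase intensity clamped at trial %d (%.1f)", k, nxt)
        x = clamped

    directions = np.where(responses, -1, 1)
    reversals = np.nonzero(directions[1:] != directions[:-1])[0] + 1
    trace = StaircaseTrace(intensities, responses, reversals)
    if reversals.size >= 3 and reversals[2] + 1 < n_trials:
        trace.threshold = staircase_threshold(trace)
    return trace


def staircase_threshold(trace: StaircaseTrace) -> float:
    """Mean intensity of all trials strictly after the third reversal."""
    if trace.reversal_indices.size < 3:
        raise ThresholdUndefinedError(
            f"need >=3 reversals, got {trace.reversal_indices.size}"
        )
    start = int(trace.reversal_indices[2]) + 1
    tail = trace.intensity[start:]
    if tail.size == 0:
        raise ThresholdUndefinedError("no trials after the third reversal")
    return float(tail.mean())
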