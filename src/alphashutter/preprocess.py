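"""Continuous-EEG containers and the two preprocessing chains.

The analysis uses two chains built from the same primitives:

* VEP chain (conduction-delay task): keep the native sampling rate,
  re-reference to averaged mastoids, zero-phase band-pass, derive the bipolar
  vertical EOG, epoch around checkerboard onsets, and reject blink epochs with
  a sliding peak-to-peak criterion.
* Observation-rate chain (flash task): down-sample to 512 Hz, re-reference,
  band-pass identically, and pool the occipital channels into left (O1, PO3,
  PO7) and right (O2, PO4, PO8) hemisphere signals.

Epoch windows are half-open in samples, ``[onset + lo, onset + hi)``, so a
(-50, 200) ms window at 2048 Hz is exactly 512 samples long.

Amplitudes are microvolts throughout; event onsets are seconds from the start
of the recording, so they survive resampling unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigError, DataError

logger = logging.getLogger("alphashutter.preprocess")

#: Default channel roles used by the convenience wrappers.
MASTOIDS = ("M1", "M2")
FRONTAL = ("Fp1", "Fp2")
INFRAORBITAL = ("IO1", "IO2")
LEFT_OCCIPITAL = ("O1", "PO3", "PO7")
RIGHT_OCCIPITAL = ("O2", "PO4", "PO8")

EVENT_COLUMNS = ("onset_s", "type", "observed")


@dataclass
class Recording:
    """Continuous multichannel time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    channels : list of str
        Unique 10-10 channel labels, one per row of ``data``.
    sfreq : float
        Sampling rate in Hz.
    events : pandas.DataFrame, optional
        Event table with columns ``onset_s`` (seconds, non-decreasing),
        ``type`` ({'upper','lower','flash','response'}) and ``observed``
        (nullable bool, defined for flash events only).
    """

    data: np.ndarray
    channels: list[str]
    sfreq: float
    events: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise DataError("Recording data must be 2-D (channels x samples)")
        if len(self.channels) != self.data.shape[0]:
            raise DataError("channel label count does not match data rows")
        if len(set(self.channels)) != len(self.channels):
            raise DataError("channel labels must be unique")
        if not self.sfreq > 0:
            raise DataError("sampling rate must be positive")
        if self.events is not None:
            onsets = np.asarray(self.events["onset_s"], dtype=float)
            if np.any(np.diff(onsets) < 0):
                raise DataError("event onsets must be non-decreasing")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def get(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(label)]
        except ValueError:
            raise DataError(f"channel {label!r} not present") from None

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(),
            list(self.channels),
            self.sfreq,
            None if self.events is None else self.events.copy(),
        )


@dataclass
class Epochs:
    """Stimulus-locked trials: trial x channel x time, with a rejection mask.

    ``time_zero_index`` is the sample of stimulus onset within each epoch.
    Rejected trials carry a reason string and are excluded from every average.
    """

    data: np.ndarray
    channels: list[str]
    sfreq: float
    window_ms: tuple[float, float]
    time_zero_index: int
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]
    reject_reason: list[str | None] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        n = self.data.shape[0]
        if self.rejected is None:
            self.rejected = np.zeros(n, dtype=bool)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        if self.reject_reason is None:
            self.reject_reason = [None] * n
        if not (self.window_ms[0] <= 0.0 <= self.window_ms[1]):
            raise DataError("epoch window must contain time zero")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis in ms relative to stimulus onset."""
        return (np.arange(self.n_times) - self.time_zero_index) / self.sfreq * 1e3

    @property
    def accepted(self) -> np.ndarray:
        return ~self.rejected

    def pick(self, label: str) -> np.ndarray:
        """Trials x time array for one channel."""
        try:
            return self.data[:, self.channels.index(label), :]
        except ValueError:
            raise DataError(f"channel {label!r} not present") from None

    def reject(self, index: int, reason: str) -> None:
        if not self.rejected[index]:
            self.rejected[index] = True
            self.reject_reason[index] = reason


# ---------------------------------------------------------------------------
# Filtering, referencing, derived channels
# ---------------------------------------------------------------------------

def bandpass_zero_phase(
    recording: Recording,
    low: float = 0.01,
    high: float = 50.0,
    order: int = 2,
) -> Recording:
    """Zero-phase band-pass: forward-backward second-order Butterworth.

    Each pass is -3 dB at the band edges, so the combined response is -6 dB
    there; the forward-backward application cancels the phase response
    exactly.  Applied to the continuous recording (never to epochs) to keep
    edge transients away from the analysis windows.
    """
    nyq = recording.sfreq / 2.0
    if not (0.0 < low < high < nyq):
        raise ConfigError(
            f"band edges must satisfy 0 < {low} < {high} < Nyquist ({nyq})"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=recording.sfreq, output="sos")
    out = recording.copy()
    out.data = signal.sosfiltfilt(sos, out.data, axis=-1)
    return out


def rereference_mastoids(
    recording: Recording, mastoids: tuple[str, str] = MASTOIDS
) -> Recording:
    """Subtract the mean of the two mastoid channels from every channel."""
    ref = (recording.get(mastoids[0]) + recording.get(mastoids[1])) / 2.0
    out = recording.copy()
    out.data = out.data - ref[None, :]
    return out


def derive_veog(
    recording: Recording,
    frontal: tuple[str, str] = FRONTAL,
    infraorbital: tuple[str, str] = INFRAORBITAL,
) -> np.ndarray:
    """Bipolar vertical EOG: mean(Fp1, Fp2) - mean(left, right infraorbital)."""
    fp = (recording.get(frontal[0]) + recording.get(frontal[1])) / 2.0
    io = (recording.get(infraorbital[0]) + recording.get(infraorbital[1])) / 2.0
    return fp - io


def resample(recording: Recording, target_rate: float) -> Recording:
    """Polyphase resampling with built-in anti-aliasing.

    Event onsets are stored in seconds and therefore need no conversion; the
    sample grid they map to is recomputed on demand at the new rate.
    """
    if target_rate > recording.sfreq:
        raise ConfigError("target rate exceeds source rate")
    if target_rate == recording.sfreq:
        return recording.copy()
    frac = Fraction(target_rate / recording.sfreq).limit_denominator(1000)
    out = recording.copy()
    out.data = signal.resample_poly(out.data, frac.numerator, frac.denominator, axis=-1)
    out.sfreq = target_rate
    return out


# ---------------------------------------------------------------------------
# Epoching and artifact rejection
# ---------------------------------------------------------------------------

def epoch(
    recording: Recording,
    onsets_s: np.ndarray,
    window_ms: tuple[float, float] = (-50.0, 200.0),
    channels: list[str] | None = None,
) -> Epochs:
    """Cut fixed-length, half-open stimulus-locked windows.

    Trials whose window would fall outside the recording are kept in the
    array (zero-filled) but flagged rejected with reason ``"edge"``.
    """
    onsets_s = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    if onsets_s.size == 0:
        raise DataError("empty event selection")
    fs = recording.sfreq
    lo = int(round(window_ms[0] / 1e3 * fs))
    n_t = int(round((window_ms[1] - window_ms[0]) / 1e3 * fs))
    if channels is None:
        channels = list(recording.channels)
    rows = [recording.channels.index(c) for c in channels]

    data = np.zeros((onsets_s.size, len(rows), n_t))
    rejected = np.zeros(onsets_s.size, dtype=bool)
    reasons: list[str | None] = [None] * onsets_s.size
    for i, t0 in enumerate(onsets_s):
        start = int(round(t0 * fs)) + lo
        stop = start + n_t
        if start < 0 or stop > recording.n_samples:
            rejected[i] = True
            reasons[i] = "edge"
            continue
        data[i] = recording.data[rows, start:stop]
    return Epochs(
        data=data,
        channels=channels,
        sfreq=fs,
        window_ms=(float(window_ms[0]), float(window_ms[1])),
        time_zero_index=-lo,
        rejected=rejected,
        reject_reason=reasons,
    )


def _blink_windows(n_t: int, win: int, step: int) -> list[tuple[int, int]]:
    """Sliding-window start/stop pairs over an epoch of n_t samples.

    Full windows start at sample 0 and advance by ``step``; one final partial
    window is evaluated iff at least half the window length remains.
    """
    spans = []
    start = 0
    while start + win <= n_t:
        spans.append((start, start + win))
        start += step
    if start < n_t and (n_t - start) >= win / 2.0:
        spans.append((start, n_t))
    return spans


def reject_blinks(
    epochs: Epochs,
    veog_epochs: np.ndarray,
    win_ms: float = 150.0,
    step_ms: float = 75.0,
    threshold_uv: float = 100.0,
) -> Epochs:
    """Flag trials whose vEOG contains a window with peak-to-peak >= threshold.

    ``veog_epochs`` is a (trials x time) array aligned with ``epochs``.
    Rejections add to (never clear) any existing flags.
    """
    veog_epochs = np.asarray(veog_epochs, dtype=float)
    if veog_epochs.shape[0] != epochs.n_trials or veog_epochs.shape[1] != epochs.n_times:
        raise DataError("vEOG epochs are not aligned with the data epochs")
    win = int(round(win_ms / 1e3 * epochs.sfreq))
    step = int(round(step_ms / 1e3 * epochs.sfreq))
    if win > epochs.n_times:
        raise DataError("blink window longer than epoch")
    out = Epochs(
        data=epochs.data.copy(),
        channels=list(epochs.channels),
        sfreq=epochs.sfreq,
        window_ms=epochs.window_ms,
        time_zero_index=epochs.time_zero_index,
        rejected=epochs.rejected.copy(),
        reject_reason=list(epochs.reject_reason),
    )
    for i in range(out.n_trials):
        if out.rejected[i]:
            continue
        v = veog_epochs[i]
        for a, b in _blink_windows(out.n_times, win, step):
            seg = v[a:b]
            if seg.max() - seg.min() >= threshold_uv:
                out.reject(i, "blink")
                break
    n = int(out.rejected.sum())
    logger.info("blink rejection: %d/%d trials rejected", n, out.n_trials)
    return out


def pool_occipital(
    recording: Recording,
    left: tuple[str, ...] = LEFT_OCCIPITAL,
    right: tuple[str, ...] = RIGHT_OCCIPITAL,
) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic-mean left/right occipital pools (LO, RO)."""
    lo = np.mean([recording.get(c) for c in left], axis=0)
    ro = np.mean([recording.get(c) for c in right], axis=0)
    return lo, ro


# ---------------------------------------------------------------------------
# IO: HDF5 container, CSV events, EDF/BDF import
# ---------------------------------------------------------------------------

def save_recording(path: str | Path, recording: Recording) -> None:
    """Write a recording (and its event table, if any) to the HDF5 container."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=recording.data)
        d.attrs["sfreq"] = recording.sfreq
        d.attrs["channels"] = [c.encode() for c in recording.channels]
        if recording.events is not None:
            g = f.create_group("events")
            g.create_dataset("onset_s", data=np.asarray(recording.events["onset_s"], dtype=float))
            g.create_dataset(
                "type", data=[str(t).encode() for t in recording.events["type"]]
            )
            obs = recording.events.get("observed")
            if obs is not None:
                coded = np.array(
                    [-1 if pd.isna(v) else int(bool(v)) for v in obs], dtype=np.int8
                )
                g.create_dataset("observed", data=coded)


def _as_str(values) -> list[str]:
    return [v.decode() if isinstance(v, bytes) else str(v) for v in values]


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        d = f["data"]
        channels = _as_str(d.attrs["channels"])
        events = None
        if "events" in f:
            g = f["events"]
            events = pd.DataFrame(
                {
                    "onset_s": np.asarray(g["onset_s"]),
                    "type": _as_str(g["type"]),
                }
            )
            if "observed" in g:
                raw = np.asarray(g["observed"], dtype=np.int8)
                events["observed"] = pd.array(
                    [None if v < 0 else bool(v) for v in raw], dtype="boolean"
                )
        return Recording(np.asarray(d), channels, float(d.attrs["sfreq"]), events)


def save_events_csv(path: str | Path, events: pd.DataFrame) -> None:
    events.to_csv(path, index=False)


def load_events_csv(path: str | Path) -> pd.DataFrame:
    ev = pd.read_csv(path)
    if "observed" in ev.columns:
        ev["observed"] = ev["observed"].astype("boolean")
    return ev


def read_raw_edf(path: str | Path) -> Recording:
    """Import an EDF/BDF file (BioSemi family) through MNE into a Recording."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise DataError("reading EDF/BDF requires the 'mne' package") from exc
    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(data, list(raw.ch_names), float(raw.info["sfreq"]))
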