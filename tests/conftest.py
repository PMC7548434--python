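"""Shared fixtures: small synthetic recordings and trial tables."""

import numpy as np
import pandas as pd
import pytest

from alphashutter import AnalyticSeries, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """A 10 s, 512 Hz recording with every channel role the pipeline uses."""
    fs = 512.0
    n = int(10 * fs)
    t = np.arange(n) / fs
    alpha = 8.0 * np.cos(2 * np.pi * 10 * t)
    labels = ["O1", "PO3", "PO7", "O2", "PO4", "PO8", "POz",
              "Fp1", "Fp2", "IO1", "IO2", "M1", "M2"]
    data = np.vstack([alpha + rng.normal(0, 1.0, n) for _ in labels])
    return Recording(data, labels, fs)


def make_analytic(phases_deg, amps, fs=512.0):
    """AnalyticSeries whose phase/amplitude at sample i are given directly."""
    phases_deg = np.asarray(phases_deg, dtype=float)
    amps = np.asarray(amps, dtype=float)
    # invert the package conventions: angle = phase - 90, |z| = amp / 2
    z = (amps / 2.0) * np.exp(1j * np.radians(phases_deg - 90.0))
    return AnalyticSeries(values=z, sampling_rate=fs, edge_valid=np.ones(z.size, bool))


def make_trials(phases_deg, observed, amps=None, rejected=None):
    """Minimal trial table in the shape trial_measures produces."""
    phases_deg = np.asarray(phases_deg, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    n = phases_deg.size
    if amps is None:
        amps = np.ones(n)
    if rejected is None:
        rejected = np.zeros(n, dtype=bool)
    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "onset_s": np.arange(n, dtype=float),
            "lo_phase": phases_deg,
            "ro_phase": phases_deg,
            "lo_amp": amps,
            "ro_amp": amps,
            "combined_phase": np.where(rejected, np.nan, phases_deg),
            "combined_amp": np.where(rejected, np.nan, amps),
            "observed": observed,
            "rejected_asynchrony": rejected,
            "measurement_time_ms": 75.0,
        }
    )
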