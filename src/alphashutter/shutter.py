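"""Phase-binned observation rates: the delta-OR statistic and its geometry.

Per trial, alpha phase and peak-to-peak amplitude are read from the left
(LO) and right (RO) occipital pools at the individual's conduction delay
relative to flash onset.  Trials whose hemispheric phases differ by more
than 90 deg are rejected (alpha asynchrony); retained trials get a combined
phase (two-point circular mean) and amplitude (arithmetic mean).

Retained trials are median-split by amplitude and grouped into 90-deg phase
bins; each bin's observation rate (OR, percent observed) minus the overall
OR over all retained trials gives delta-OR.  Rotating the 90-deg bin in
1-deg steps yields a 360-point delta-OR profile per amplitude level whose
center-of-mass direction is the *preferred phase*; the delta-OR difference
between the preferred and opposite (pessimal) directions is the preferred
phase effect (PPE).  For a cosine-shaped profile, PPE = 4 x the
center-of-mass magnitude.

Phase-bin membership is circularly half-open, ``[center - 45, center + 45)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, NumericalError, ZeroResultantError
from .stats import circ_diff, circ_mean, wrap360
from .tfr import AnalyticSeries

logger = logging.getLogger("alphashutter.shutter")

DEFAULT_BIN_CENTERS = (0.0, 90.0, 180.0, 270.0)
AMPLITUDE_LEVELS = ("high", "low")


# ---------------------------------------------------------------------------
# Per-trial measures
# ---------------------------------------------------------------------------

def trial_measures(
    lo_series: AnalyticSeries,
    ro_series: AnalyticSeries,
    events: pd.DataFrame,
    t_measure_ms: float,
    asynchrony_threshold_deg: float = 90.0,
) -> pd.DataFrame:
    """Phase/amplitude of every flash trial at onset + t_measure.

    The measurement time is snapped to the nearest sample.  Returns one row
    per flash with LO/RO phase (deg) and peak-to-peak amplitude (uV), the
    asynchrony-rejection flag (strictly greater than the threshold rejects;
    exactly 90 deg is retained), and combined phase/amplitude for retained
    trials (NaN otherwise).
    """
    flashes = events[events["type"] == "flash"].reset_index(drop=True)
    if len(flashes) == 0:
        raise DataError("no flash events")
    fs = lo_series.sampling_rate
    t_samp = int(round(t_measure_ms / 1e3 * fs))
    idx = np.round(np.asarray(flashes["onset_s"], dtype=float) * fs).astype(int) + t_samp
    n = lo_series.values.size
    if idx.min() < 0 or idx.max() >= n:
        raise DataError("a measurement point falls outside the recorded series")

    lo_phase = lo_series.phase_deg[idx]
    ro_phase = ro_series.phase_deg[idx]
    lo_amp = lo_series.p2p_amplitude[idx]
    ro_amp = ro_series.p2p_amplitude[idx]
    asym = np.abs(circ_diff(lo_phase, ro_phase))
    rejected = asym > asynchrony_threshold_deg

    combined_phase = np.full(len(flashes), np.nan)
    for i in np.nonzero(~rejected)[0]:
        combined_phase[i], _ = circ_mean(np.array([lo_phase[i], ro_phase[i]]))
    combined_amp = np.where(rejected, np.nan, (lo_amp + ro_amp) / 2.0)

    return pd.DataFrame(
        {
            "trial": np.arange(len(flashes)),
            "onset_s": flashes["onset_s"].to_numpy(dtype=float),
            "lo_phase": lo_phase,
            "ro_phase": ro_phase,
            "lo_amp": lo_amp,
            "ro_amp": ro_amp,
            "combined_phase": combined_phase,
            "combined_amp": combined_amp,
            "observed": flashes["observed"].to_numpy(dtype=bool),
            "rejected_asynchrony": rejected,
            "measurement_time_ms": t_measure_ms,
        }
    )


def amplitude_split(trials: pd.DataFrame) -> pd.Series:
    """Median split of combined amplitude over retained trials.

    Amplitudes strictly above the per-participant median are "high", the
    rest "low" (equal sample sizes up to median ties).  Rejected trials get
    a null label.
    """
    retained = trials[~trials["rejected_asynchrony"]]
    if len(retained) < 2:
        raise DataError("need >= 2 retained trials for a median split")
    med = retained["combined_amp"].median()
    labels = pd.Series([None] * len(trials), index=trials.index, dtype=object)
    labels[retained.index] = np.where(retained["combined_amp"] > med, "high", "low")
    if (labels[retained.index] == "low").all():
        logger.warning("degenerate amplitude split: all amplitudes at/below median")
    return labels


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def _in_bin(phases: np.ndarray, center: float, width: float = 90.0) -> np.ndarray:
    """Circularly half-open membership: phase in [center - w/2, center + w/2)."""
    return (phases - center + width / 2.0) % 360.0 < width


@dataclass
class BinGrid:
    """2 (amplitude) x 4 (phase) delta-OR grid for one participant."""

    table: pd.DataFrame  # columns: amplitude_level, phase_center, n_trials, n_observed, or_pct, delta_or
    overall_or: float    # percent observed over all retained trials

    @property
    def complete(self) -> bool:
        return not self.table["or_pct"].isna().any()

    def cell(self, level: str, center: float) -> pd.Series:
        m = (self.table["amplitude_level"] == level) & (self.table["phase_center"] == center)
        return self.table[m].iloc[0]

    def delta_or_array(
        self,
        levels: tuple[str, ...] = AMPLITUDE_LEVELS,
        centers: tuple[float, ...] = DEFAULT_BIN_CENTERS,
    ) -> np.ndarray:
        """(len(levels) x len(centers)) delta-OR matrix (NaN for empty cells)."""
        out = np.full((len(levels), len(centers)), np.nan)
        for i, lev in enumerate(levels):
            for j, c in enumerate(centers):
                out[i, j] = self.cell(lev, c)["delta_or"]
        return out


def bin_grid(
    trials: pd.DataFrame,
    labels: pd.Series,
    centers: tuple[float, ...] = DEFAULT_BIN_CENTERS,
) -> BinGrid:
    """ORs and delta-ORs for the amplitude x phase grid.

    delta-OR is the cell OR minus the overall OR across all retained trials
    (a difference of percentages, not a percent change).  Empty cells carry
    NaN and flag the grid incomplete.
    """
    retained = trials[~trials["rejected_asynchrony"]]
    if len(retained) == 0:
        raise DataError("no retained trials")
    overall = 100.0 * retained["observed"].mean()
    phases = retained["combined_phase"].to_numpy(dtype=float)
    observed = retained["observed"].to_numpy(dtype=bool)
    lab = labels[retained.index].to_numpy()

    rows = []
    for level in AMPLITUDE_LEVELS:
        in_level = lab == level
        for c in centers:
            m = in_level & _in_bin(phases, c)
            n = int(m.sum())
            n_obs = int(observed[m].sum())
            or_pct = 100.0 * n_obs / n if n else np.nan
            if n == 0:
                logger.warning("empty bin: %s amplitude, %g deg", level, c)
            rows.append(
                {
                    "amplitude_level": level,
                    "phase_center": float(c),
                    "n_trials": n,
                    "n_observed": n_obs,
                    "or_pct": or_pct,
                    "delta_or": or_pct - overall if n else np.nan,
                }
            )
    return BinGrid(table=pd.DataFrame(rows), overall_or=float(overall))


@dataclass
class PhaseProfile:
    """360-point delta-OR curve (1-deg rotating 90-deg bins) for one level."""

    values: np.ndarray          # delta-OR at integer bin centers 0..359
    amplitude_level: str
    n_trials: int
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (360,):
            raise DataError("a phase profile has exactly 360 points")
        if self.interpolated is None:
            self.interpolated = np.zeros(360, dtype=bool)

    def at(self, angle_deg: float) -> float:
        """Profile value at the nearest integer bin center."""
        return float(self.values[int(round(angle_deg)) % 360])


def rotating_profile(
    trials: pd.DataFrame,
    labels: pd.Series,
    max_gap_deg: int = 5,
) -> dict[str, PhaseProfile]:
    """delta-OR profiles from 90-deg bins rotated in 1-deg steps, per level.

    The same overall OR (all retained trials) is subtracted as in the 2x4
    grid, so the profile agrees with the grid at 0/90/180/270.  Empty bins
    are linearly interpolated across circular gaps of at most ``max_gap_deg``
    degrees; wider gaps flag the participant (NumericalError).
    """
    retained = trials[~trials["rejected_asynchrony"]]
    if len(retained) == 0:
        raise DataError("no retained trials")
    overall = 100.0 * retained["observed"].mean()
    phases = retained["combined_phase"].to_numpy(dtype=float)
    observed = retained["observed"].to_numpy(dtype=float)
    lab = labels[retained.index].to_numpy()

    centers = np.arange(360.0)
    out: dict[str, PhaseProfile] = {}
    for level in AMPLITUDE_LEVELS:
        ph = phases[lab == level]
        ob = observed[lab == level]
        if ph.size == 0:
            logger.warning("no trials at %s amplitude: profile skipped", level)
            continue
        # membership matrix: trials x 360 bins
        member = (ph[:, None] - centers[None, :] + 45.0) % 360.0 < 90.0
        counts = member.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            or_pct = 100.0 * (ob @ member) / counts
        values = np.where(counts > 0, or_pct - overall, np.nan)
        interpolated = np.isnan(values)
        if interpolated.any():
            values = _fill_circular_gaps(values, max_gap_deg)
        out[level] = PhaseProfile(
            values=values,
            amplitude_level=level,
            n_trials=int((lab == level).sum()),
            interpolated=interpolated,
        )
    return out


def _fill_circular_gaps(values: np.ndarray, max_gap: int) -> np.ndarray:
    """Linear interpolation of NaN runs on the circle; long gaps are fatal."""
    n = values.size
    nan = np.isnan(values)
    if nan.all():
        raise NumericalError("profile undefined everywhere")
    out = values.copy()
    i = 0
    while i < n:
        if not nan[i]:
            i += 1
            continue
        j = i
        while nan[j % n] and j - i < n:
            j += 1
        # run [i, j) is NaN; may wrap (handled by starting at a non-NaN anchor)
        run = j - i
        if run > max_gap:
            raise NumericalError(
                f"empty rotating-bin gap of {run} deg exceeds {max_gap} deg; "
                "participant flagged"
            )
        left = (i - 1) % n
        right = j % n
        for k in range(run):
            w = (k + 1) / (run + 1)
            out[(i + k) % n] = (1 - w) * values[left] + w * values[right]
        i = j
    # handle leading NaNs that belong to a wrapped run
    if np.isnan(out).any():
        out = _fill_circular_gaps(np.roll(out, n // 2), max_gap)
        out = np.roll(out, -(n // 2))
    return out


# ---------------------------------------------------------------------------
# Preferred phase geometry
# ---------------------------------------------------------------------------

@dataclass
class PreferredPhase:
    """Center-of-mass direction of a delta-OR profile and derived quantities."""

    angle_deg: float
    magnitude: float              # |center-of-mass offset|, delta-OR units
    pessimal_deg: float           # angle - 180, wrapped
    ppe: float                    # profile(angle) - profile(pessimal), percent
    ci_deg: tuple[float, float] | None = None
    ci_full_circle: bool = False

    @property
    def vector(self) -> np.ndarray:
        return self.magnitude * np.array(
            [np.cos(np.radians(self.angle_deg)), np.sin(np.radians(self.angle_deg))]
        )

    def to_record(self, amplitude_level: str | None = None) -> dict:
        rec = {
            "angle_deg": self.angle_deg,
            "magnitude": self.magnitude,
            "pessimal_deg": self.pessimal_deg,
            "ppe_pct": self.ppe,
            "ci_deg": None if self.ci_deg is None else [self.ci_deg[0], self.ci_deg[1]],
            "ci_full_circle": self.ci_full_circle,
        }
        if amplitude_level is not None:
            rec = {"amplitude_level": amplitude_level, **rec}
        return rec


def _com_vector(values: np.ndarray) -> np.ndarray:
    c = np.radians(np.arange(360.0))
    return np.array([np.mean(values * np.cos(c)), np.mean(values * np.sin(c))])


def preferred_phase(profile: PhaseProfile) -> PreferredPhase:
    """Center-of-mass direction, magnitude, pessimal angle and PPE.

    The preferred angle is the direction of ``(1/360) * sum profile(c) *
    (cos c, sin c)``; PPE is evaluated at the nearest integer degrees.
    """
    if np.isnan(profile.values).any():
        raise DataError("profile has undefined points")
    v = _com_vector(profile.values)
    mag = float(np.hypot(*v))
    if mag < 1e-12:
        raise ZeroResultantError("preferred phase undefined: zero center-of-mass vector")
    angle = wrap360(np.degrees(np.arctan2(v[1], v[0])))
    pessimal = wrap360(angle - 180.0)
    ppe = profile.at(angle) - profile.at(pessimal)
    return PreferredPhase(angle_deg=angle, magnitude=mag, pessimal_deg=pessimal, ppe=float(ppe))


def group_preferred_phase(
    individuals: list[PreferredPhase],
    profiles: list[PhaseProfile] | None = None,
) -> PreferredPhase:
    """Vector mean of individual preferred-phase vectors.

    By linearity of the center-of-mass map this equals the preferred phase of
    the across-participant mean profile exactly.  The group PPE is evaluated
    on the group-mean profile when the profiles are supplied (NaN otherwise).
    """
    if len(individuals) < 2:
        raise DataError("need >= 2 individuals")
    v = np.mean([p.vector for p in individuals], axis=0)
    mag = float(np.hypot(*v))
    if mag < 1e-12:
        raise ZeroResultantError("group preferred phase undefined: zero resultant")
    angle = wrap360(np.degrees(np.arctan2(v[1], v[0])))
    pessimal = wrap360(angle - 180.0)
    if profiles is not None:
        mean_profile = PhaseProfile(
            values=np.mean([p.values for p in profiles], axis=0),
            amplitude_level=profiles[0].amplitude_level,
            n_trials=int(np.sum([p.n_trials for p in profiles])),
        )
        ppe = mean_profile.at(angle) - mean_profile.at(pessimal)
    else:
        ppe = np.nan
    return PreferredPhase(angle_deg=angle, magnitude=mag, pessimal_deg=pessimal, ppe=float(ppe))


def preferred_phase_ci(
    individuals: list[PreferredPhase],
    level: float = 0.95,
) -> tuple[tuple[float, float], bool]:
    """Angular interval spanned by t-based cartesian CIs on the mean vector.

    The individual vectors are converted to cartesian components; a t-based
    CI is computed separately on x and y; the returned interval is the set of
    directions from the origin to the CI rectangle (corner bearings on the
    arc containing the group angle).  Returns ``((lo_deg, hi_deg),
    full_circle)``; if the rectangle contains the origin, the interval is the
    full circle, with a logged warning.
    """
    if len(individuals) < 3:
        raise DataError("need >= 3 individuals for a CI")
    xy = np.array([p.vector for p in individuals])
    n = xy.shape[0]
    mean = xy.mean(axis=0)
    sem = xy.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = sps.t.ppf(0.5 + level / 2.0, n - 1)
    lo = mean - tcrit * sem
    hi = mean + tcrit * sem
    if lo[0] <= 0.0 <= hi[0] and lo[1] <= 0.0 <= hi[1]:
        logger.warning("CI rectangle contains the origin: full-circle interval")
        return (0.0, 360.0), True
    group_angle = np.degrees(np.arctan2(mean[1], mean[0])) % 360.0
    corners = [(lo[0], lo[1]), (lo[0], hi[1]), (hi[0], lo[1]), (hi[0], hi[1])]
    rel = [circ_diff(np.degrees(np.arctan2(y, x)), group_angle) for x, y in corners]
    return (
        (float((group_angle + min(rel)) % 360.0), float((group_angle + max(rel)) % 360.0)),
        False,
    )
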