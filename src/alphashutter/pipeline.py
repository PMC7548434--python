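"""End-to-end orchestration: simulate -> preprocess -> c1 -> analyze -> stats.

The in-memory functions (`compute_analytic`, `analyze_trials`,
`cohort_stats`) carry the science; the disk-facing stage functions wrap them
with the HDF5/CSV/JSON layout used by the CLI, cache the analytic series so
the measurement time can be changed without redoing the wavelet transform,
and echo every parameter with the results for provenance.

All user-facing angles are degrees in [0, 360) with 90 deg = alpha peak.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .c1vep import VepResult, estimate_t2
from .errors import ConfigError, DataError, NumericalError
from .preprocess import (
    Recording,
    bandpass_zero_phase,
    load_recording,
    pool_occipital,
    rereference_mastoids,
    resample,
    save_events_csv,
    save_recording,
)
from .shutter import (
    AMPLITUDE_LEVELS,
    BinGrid,
    DEFAULT_BIN_CENTERS,
    PhaseProfile,
    PreferredPhase,
    amplitude_split,
    bin_grid,
    group_preferred_phase,
    preferred_phase,
    preferred_phase_ci,
    rotating_profile,
    trial_measures,
)
from .stats import mauchly_test, one_sample_t_bonferroni, rm_anova_2x4, tukey_hsd
from .synthdata import ShutterConfig, VepConfig, gen_shutter_recording, gen_vep_recording
from .tfr import AnalyticSeries, morlet_wavelet, wavelet_transform

logger = logging.getLogger("alphashutter.pipeline")

STAGES = ("simulate", "c1", "analyze", "stats", "report")


@dataclass
class AnalysisParams:
    """Signal-analysis parameters of the observation-rate chain."""

    filter_low: float = 0.01        # Hz
    filter_high: float = 50.0       # Hz
    filter_order: int = 2
    analysis_rate: float = 512.0    # Hz
    wavelet_freq: float = 10.0      # Hz
    wavelet_cycles: float = 8.0 / 3.0
    wavelet_support_sigmas: float = 3.0
    asynchrony_threshold_deg: float = 90.0
    bin_centers: tuple[float, ...] = DEFAULT_BIN_CENTERS
    max_gap_deg: int = 5
    alpha: float = 0.05

    def cache_key(self) -> str:
        fields = (
            self.filter_low,
            self.filter_high,
            self.filter_order,
            self.analysis_rate,
            self.wavelet_freq,
            self.wavelet_cycles,
            self.wavelet_support_sigmas,
        )
        return "|".join(f"{v:.9g}" for v in fields)


@dataclass
class PipelineConfig:
    """Configuration of a full run; serialized with every result bundle."""

    seed: int = 0
    outdir: str = "alphashutter_out"
    n_participants: int = 20
    measure_time: str | float = "t2"  # "t2" or a fixed time in ms (e.g. -100)
    shutter: dict = field(default_factory=dict)  # ShutterConfig overrides
    vep: dict = field(default_factory=dict)      # VepConfig overrides
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    m_comparisons: int = 8

    def __post_init__(self) -> None:
        if isinstance(self.analysis, dict):
            self.analysis = AnalysisParams(**self.analysis)
        if self.n_participants < 1:
            raise ConfigError("n_participants must be positive")
        if isinstance(self.measure_time, str) and self.measure_time != "t2":
            try:
                self.measure_time = float(self.measure_time)
            except ValueError:
                raise ConfigError(
                    "measure_time must be 't2' or a time in ms"
                ) from None

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            return cls(**json.load(f))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2, sort_keys=True)
            f.write("\n")

    def participant_seeds(self) -> np.ndarray:
        """Deterministic per-participant (shutter, vep) seed pairs."""
        state = np.random.SeedSequence(self.seed).generate_state(2 * self.n_participants)
        return (state % (2**31)).reshape(self.n_participants, 2)


# ---------------------------------------------------------------------------
# In-memory analysis core
# ---------------------------------------------------------------------------

def compute_analytic(
    recording: Recording, params: AnalysisParams
) -> tuple[AnalyticSeries, AnalyticSeries]:
    """Observation-rate preprocessing chain up to the LO/RO analytic series.

    Down-sample to the analysis rate, re-reference to averaged mastoids,
    zero-phase band-pass, pool the occipital channels, and convolve both
    pools with the alpha Morlet kernel.  Only the channels this chain
    consumes (occipital six plus mastoids) are carried through.
    """
    from .preprocess import LEFT_OCCIPITAL, MASTOIDS, RIGHT_OCCIPITAL

    needed = [
        c
        for c in recording.channels
        if c in LEFT_OCCIPITAL + RIGHT_OCCIPITAL + MASTOIDS
    ]
    rows = [recording.channels.index(c) for c in needed]
    recording = Recording(recording.data[rows], needed, recording.sfreq, recording.events)
    rec = resample(recording, params.analysis_rate)
    rec = rereference_mastoids(rec)
    rec = bandpass_zero_phase(rec, params.filter_low, params.filter_high, params.filter_order)
    lo, ro = pool_occipital(rec)
    kernel = morlet_wavelet(
        params.wavelet_freq,
        params.wavelet_cycles,
        params.analysis_rate,
        params.wavelet_support_sigmas,
    )
    return wavelet_transform(lo, kernel), wavelet_transform(ro, kernel)


@dataclass
class ParticipantAnalysis:
    """One participant's trial table, bin grid, profiles and preferred phases.

    ``profile_flagged`` marks participants whose rotating profile had empty
    bins spanning more than the tolerated gap; they keep their 2x4 grid but
    are excluded from profile-based (preferred-phase) aggregates.
    """

    trials: pd.DataFrame
    labels: pd.Series
    grid: BinGrid
    profiles: dict[str, PhaseProfile]
    preferred: dict[str, PreferredPhase]
    t_measure_ms: float
    profile_flagged: bool = False


def analyze_trials(
    lo_series: AnalyticSeries,
    ro_series: AnalyticSeries,
    events: pd.DataFrame,
    t_measure_ms: float,
    params: AnalysisParams | None = None,
) -> ParticipantAnalysis:
    """Per-trial measures -> rejection -> median split -> bins and profiles."""
    params = params or AnalysisParams()
    trials = trial_measures(
        lo_series, ro_series, events, t_measure_ms, params.asynchrony_threshold_deg
    )
    labels = amplitude_split(trials)
    grid = bin_grid(trials, labels, params.bin_centers)
    flagged = False
    try:
        profiles = rotating_profile(trials, labels, params.max_gap_deg)
        preferred = {lev: preferred_phase(prof) for lev, prof in profiles.items()}
    except NumericalError as exc:
        logger.warning("participant flagged, excluded from profiles: %s", exc)
        profiles, preferred, flagged = {}, {}, True
    return ParticipantAnalysis(
        trials=trials,
        labels=labels,
        grid=grid,
        profiles=profiles,
        preferred=preferred,
        t_measure_ms=t_measure_ms,
        profile_flagged=flagged,
    )


@dataclass
class CohortStats:
    """Group-level battery over a cohort of participant analyses."""

    anova: pd.DataFrame
    mauchly: pd.DataFrame
    tukey: dict[str, pd.DataFrame]
    t_tests: pd.DataFrame
    group_preferred: dict[str, PreferredPhase]
    n_included: int
    excluded: list[int]


def cohort_stats(
    analyses: list[ParticipantAnalysis],
    params: AnalysisParams | None = None,
    m_comparisons: int = 8,
) -> CohortStats:
    """The repeated-measures battery plus group preferred-phase geometry.

    Participants with an empty 2x4 cell are excluded from the ANOVA and post
    hoc contrasts (logged); the group preferred phase uses every participant
    with defined profiles.
    """
    params = params or AnalysisParams()
    centers = params.bin_centers
    included, excluded = [], []
    for i, a in enumerate(analyses):
        if a.grid.complete:
            included.append(a)
        else:
            excluded.append(i)
            logger.warning("participant %d excluded from ANOVA (empty cell)", i)
    if len(included) < 2:
        raise DataError("fewer than 2 complete participants")

    arr = np.stack([a.grid.delta_or_array(AMPLITUDE_LEVELS, centers) for a in included])
    anova = rm_anova_2x4(arr, factor_names=("amplitude", "phase"), alpha=params.alpha)
    mau_rows = []
    for effect, label in (("B", "phase"), ("AB", "phase x amplitude")):
        try:
            W, chi2, df, p = mauchly_test(arr, effect)
        except DataError as exc:
            logger.warning("Mauchly test for %s skipped: %s", label, exc)
            W = chi2 = p = np.nan
            df = 0
        mau_rows.append({"effect": label, "W": W, "chi2": chi2, "df": df, "p": p})
    mauchly = pd.DataFrame(mau_rows)

    tukey = {}
    for k, lev in enumerate(AMPLITUDE_LEVELS):
        tukey[lev] = tukey_hsd(arr[:, k, :], level_names=list(centers))
    cells = arr.reshape(arr.shape[0], -1)
    t_tests = one_sample_t_bonferroni(cells, m_comparisons)
    t_tests["amplitude_level"] = [AMPLITUDE_LEVELS[j // len(centers)] for j in t_tests["cell"]]
    t_tests["phase_center"] = [centers[j % len(centers)] for j in t_tests["cell"]]

    group = {}
    for lev in AMPLITUDE_LEVELS:
        with_level = [a for a in analyses if lev in a.preferred]
        if len(with_level) < 2:
            logger.warning("too few unflagged participants for %s-amplitude group", lev)
            continue
        indiv = [a.preferred[lev] for a in with_level]
        profs = [a.profiles[lev] for a in with_level]
        g = group_preferred_phase(indiv, profs)
        if len(indiv) >= 3:
            g.ci_deg, g.ci_full_circle = preferred_phase_ci(indiv)
        group[lev] = g

    return CohortStats(
        anova=anova,
        mauchly=mauchly,
        tukey=tukey,
        t_tests=t_tests,
        group_preferred=group,
        n_included=len(included),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Disk-facing stages
# ---------------------------------------------------------------------------

def _pdir(config: PipelineConfig, i: int) -> Path:
    d = Path(config.outdir) / f"participant_{i:02d}"
    d.mkdir(parents=True, exist_ok=True)
    return d


def stage_simulate(config: PipelineConfig) -> None:
    """Generate per-participant flash-task and VEP-task recordings."""
    seeds = config.participant_seeds()
    for i in range(config.n_participants):
        d = _pdir(config, i)
        scfg = ShutterConfig(**{**config.shutter, "seed": int(seeds[i, 0])})
        rec, events, truth = gen_shutter_recording(scfg)
        save_recording(d / "shutter.h5", rec)
        save_events_csv(d / "shutter_events.csv", events)
        truth.to_frame().to_csv(d / "ground_truth.csv", index=False)
        vcfg = VepConfig(**{**config.vep, "seed": int(seeds[i, 1])})
        vrec, vevents = gen_vep_recording(vcfg)
        save_recording(d / "vep.h5", vrec)
        save_events_csv(d / "vep_events.csv", vevents)
    config.to_json(Path(config.outdir) / "config.json")
    logger.info("simulated %d participants", config.n_participants)


def stage_c1(config: PipelineConfig) -> list[VepResult]:
    """Estimate each participant's conduction delay from the VEP recording."""
    results = []
    for i in range(config.n_participants):
        d = _pdir(config, i)
        rec = load_recording(d / "vep.h5")
        res = estimate_t2(rec)
        results.append(res)
        with open(d / "t2.json", "w") as f:
            json.dump(res.to_record(participant=i), f, indent=2, sort_keys=True)
            f.write("\n")
        res.waveforms_frame().to_csv(d / "vep_waveforms.csv", index=False)
    return results


def _analytic_cache_path(d: Path) -> Path:
    return d / "analytic.h5"


def _load_or_compute_analytic(
    d: Path, rec: Recording, params: AnalysisParams
) -> tuple[AnalyticSeries, AnalyticSeries]:
    cache = _analytic_cache_path(d)
    key = params.cache_key()
    if cache.exists():
        with h5py.File(cache, "r") as f:
            if f.attrs.get("key") == key:
                return (
                    AnalyticSeries(np.asarray(f["lo"]), params.analysis_rate, np.asarray(f["valid"])),
                    AnalyticSeries(np.asarray(f["ro"]), params.analysis_rate, np.asarray(f["valid"])),
                )
    lo, ro = compute_analytic(rec, params)
    with h5py.File(cache, "w") as f:
        f.attrs["key"] = key
        f.create_dataset("lo", data=lo.values)
        f.create_dataset("ro", data=ro.values)
        f.create_dataset("valid", data=lo.edge_valid)
    return lo, ro


def stage_analyze(config: PipelineConfig) -> list[ParticipantAnalysis]:
    """Per-participant shutter analysis at t2 (or a fixed measurement time).

    The LO/RO analytic series are cached per participant, keyed by the filter
    and wavelet parameters, so re-running at a different measurement time
    (e.g. -100 ms) reuses the transform.
    """
    params = config.analysis
    analyses = []
    for i in range(config.n_participants):
        d = _pdir(config, i)
        rec = load_recording(d / "shutter.h5")
        lo, ro = _load_or_compute_analytic(d, rec, params)
        if config.measure_time == "t2":
            with open(d / "t2.json") as f:
                t_ms = float(json.load(f)["t2_ms"])
        else:
            t_ms = float(config.measure_time)
        analysis = analyze_trials(lo, ro, rec.events, t_ms, params)
        analyses.append(analysis)
        tag = "t2" if config.measure_time == "t2" else f"{t_ms:g}ms"
        analysis.trials.to_csv(d / f"trials_{tag}.csv", index=False)
        analysis.grid.table.to_csv(d / f"bingrid_{tag}.csv", index=False)
        prof = pd.DataFrame(
            {
                "bin_center_deg": np.arange(360),
                **{lev: p.values for lev, p in analysis.profiles.items()},
            }
        )
        prof.to_csv(d / f"profile_{tag}.csv", index=False)
        with open(d / f"preferred_phase_{tag}.json", "w") as f:
            json.dump(
                {lev: p.to_record(lev) for lev, p in analysis.preferred.items()},
                f,
                indent=2,
                sort_keys=True,
            )
            f.write("\n")
    return analyses


def stage_stats(config: PipelineConfig, analyses: list[ParticipantAnalysis]) -> CohortStats:
    """Group battery over the cohort; writes Table-style CSV/JSON outputs."""
    stats = cohort_stats(analyses, config.analysis, config.m_comparisons)
    out = Path(config.outdir)
    tag = "t2" if config.measure_time == "t2" else f"{float(config.measure_time):g}ms"
    stats.anova.to_csv(out / f"anova_{tag}.csv", index=False)
    stats.mauchly.to_csv(out / f"mauchly_{tag}.csv", index=False)
    for lev, tk in stats.tukey.items():
        tk.to_csv(out / f"tukey_{lev}_{tag}.csv", index=False)
    stats.t_tests.to_csv(out / f"ttests_{tag}.csv", index=False)
    with open(out / f"group_preferred_phase_{tag}.json", "w") as f:
        json.dump(
            {lev: g.to_record(lev) for lev, g in stats.group_preferred.items()},
            f,
            indent=2,
            sort_keys=True,
        )
        f.write("\n")
    return stats


def stage_report(config: PipelineConfig, stats: CohortStats | None = None) -> dict:
    """Summary JSON: parameter echo, versions, and headline quantities."""
    summary: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": dataclasses.asdict(config),
        "phase_convention": "degrees in [0,360), 90 deg = alpha peak",
    }
    if stats is not None:
        summary["anova"] = stats.anova.drop(columns=["ss_effect", "ms_error"]).to_dict("records")
        summary["group_preferred_phase"] = {
            lev: g.to_record(lev) for lev, g in stats.group_preferred.items()
        }
        summary["n_included"] = stats.n_included
    path = Path(config.outdir) / "summary.json"
    with open(path, "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)
        f.write("\n")
    return summary


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in order; returns the report summary.

    A stage failure raises with a stage-tagged message; outputs from earlier
    stages are preserved on disk.
    """
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    analyses: list[ParticipantAnalysis] | None = None
    stats: CohortStats | None = None
    for stage in stages:
        if stage not in STAGES:
            raise ConfigError(f"unknown stage {stage!r}")
        logger.info("stage: %s", stage)
        try:
            if stage == "simulate":
                stage_simulate(config)
            elif stage == "c1":
                stage_c1(config)
            elif stage == "analyze":
                analyses = stage_analyze(config)
            elif stage == "stats":
                if analyses is None:
                    analyses = stage_analyze(config)
                stats = stage_stats(config, analyses)
            elif stage == "report":
                return stage_report(config, stats)
        except Exception as exc:
            raise type(exc)(f"[stage {stage}] {exc}") from exc
    return stage_report(config, stats)
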