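"""Trial measures, binning, rotating profiles, and preferred-phase geometry."""

import numpy as np
import pandas as pd
import pytest

import alphashutter as ash
from alphashutter.shutter import PhaseProfile, _in_bin

from conftest import make_analytic, make_trials


def events_frame(n):
    return pd.DataFrame(
        {
            "onset_s": np.arange(n, dtype=float),
            "type": "flash",
            "observed": pd.array([True] * n, dtype="boolean"),
        }
    )


class TestTrialMeasures:
    def _series_pair(self, lo_phases, ro_phases, fs=1.0):
        n = len(lo_phases)
        lo = make_analytic(lo_phases, np.full(n, 2.0), fs)
        ro = make_analytic(ro_phases, np.full(n, 4.0), fs)
        return lo, ro

    def test_asynchrony_above_90_rejected(self):
        lo, ro = self._series_pair([0.0], [120.0])
        t = ash.trial_measures(lo, ro, events_frame(1), 0.0)
        assert bool(t.rejected_asynchrony[0])
        assert np.isnan(t.combined_phase[0])

    def test_boundary_90_retained(self):
        lo, ro = self._series_pair([0.0], [90.0])
        t = ash.trial_measures(lo, ro, events_frame(1), 0.0)
        assert not bool(t.rejected_asynchrony[0])
        assert t.combined_phase[0] == pytest.approx(45.0)

    def test_circular_mean_and_amplitude_average(self):
        lo, ro = self._series_pair([30.0, 350.0], [60.0, 10.0])
        t = ash.trial_measures(lo, ro, events_frame(2), 0.0)
        assert t.combined_phase[0] == pytest.approx(45.0)
        assert t.combined_phase[1] == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(t.combined_amp, 3.0)

    def test_measurement_time_snapped_to_sample(self):
        fs = 512.0
        phases = np.linspace(0, 359, 1024)
        lo = make_analytic(phases, np.ones(1024), fs)
        ev = pd.DataFrame({"onset_s": [1.0], "type": ["flash"],
                           "observed": pd.array([True], dtype="boolean")})
        t = ash.trial_measures(lo, lo, ev, 75.0)
        expect_idx = 512 + int(round(0.075 * fs))
        assert t.lo_phase[0] == phases[expect_idx]

    def test_event_beyond_series_raises(self):
        lo, ro = self._series_pair([0.0] * 3, [0.0] * 3)
        with pytest.raises(ash.DataError):
            ash.trial_measures(lo, ro, events_frame(10), 0.0)


class TestAmplitudeSplit:
    def test_simple_median_split(self):
        t = make_trials([0, 90, 180, 270], [1, 0, 1, 0], amps=[1.0, 2.0, 3.0, 4.0])
        labels = ash.amplitude_split(t)
        assert labels.tolist() == ["low", "low", "high", "high"]

    def test_all_equal_degenerates_to_low(self):
        t = make_trials([0, 90, 180, 270], [1, 0, 1, 0], amps=[2.0] * 4)
        labels = ash.amplitude_split(t)
        assert (labels == "low").all()

    def test_balanced_up_to_ties(self, rng):
        for _ in range(10):
            n = 2 * rng.integers(4, 30)
            amps = np.round(rng.uniform(0, 5, n), 1)
            t = make_trials(rng.uniform(0, 360, n), rng.random(n) < 0.5, amps=amps)
            labels = ash.amplitude_split(t)
            med = np.median(amps)
            ties = int((amps == med).sum())
            # every imbalance is caused by values equal to the median landing
            # on the "low" side; the worst case is 2x the tie count
            assert abs((labels == "high").sum() - (labels == "low").sum()) <= 2 * ties

    def test_rejected_trials_excluded_from_median(self):
        t = make_trials([0, 90, 180, 270], [1, 0, 1, 0],
                        amps=[1.0, 2.0, 3.0, 100.0],
                        rejected=[False, False, False, True])
        labels = ash.amplitude_split(t)
        assert labels[3] is None
        assert labels.tolist()[:3] == ["low", "low", "high"]


class TestBinGrid:
    def test_all_observed_gives_zero_delta(self, rng):
        n = 80
        t = make_trials(rng.uniform(0, 360, n), np.ones(n, bool))
        g = ash.bin_grid(t, ash.amplitude_split(t))
        defined = g.table.dropna(subset=["or_pct"])
        np.testing.assert_allclose(defined["delta_or"], 0.0, atol=1e-12)
        assert g.overall_or == 100.0

    def test_single_cell_arithmetic(self):
        # 4 trials in one phase bin (3 observed), 4 in the opposite (1 observed)
        phases = [0, 1, 359, 2, 180, 181, 179, 182]
        observed = [1, 1, 1, 0, 0, 0, 0, 1]
        amps = [1, 1, 1, 1, 1, 1, 1, 1]
        t = make_trials(phases, observed, amps=amps)
        g = ash.bin_grid(t, ash.amplitude_split(t))
        assert g.overall_or == pytest.approx(50.0)
        cell = g.cell("low", 0.0)
        assert cell["or_pct"] == pytest.approx(75.0)
        assert cell["delta_or"] == pytest.approx(25.0)

    def test_counts_match_exhaustive_recount_oracle(self, rng):
        n = 300
        phases = rng.uniform(0, 360, n)
        observed = rng.random(n) < 0.6
        amps = rng.lognormal(1.0, 0.4, n)
        rejected = rng.random(n) < 0.15
        t = make_trials(phases, observed, amps=amps, rejected=rejected)
        labels = ash.amplitude_split(t)
        g = ash.bin_grid(t, labels)
        total = 0
        for _, row in g.table.iterrows():
            lev, c = row["amplitude_level"], row["phase_center"]
            m = np.zeros(n, bool)
            for i in range(n):
                if rejected[i] or labels[i] != lev:
                    continue
                d = (phases[i] - c + 45.0) % 360.0
                m[i] = d < 90.0
            assert row["n_trials"] == m.sum()
            assert row["n_observed"] == observed[m].sum()
            total += int(m.sum())
        assert total == (~rejected).sum()  # cells partition retained trials

    def test_empty_cell_flagged(self):
        t = make_trials([0.0, 1.0, 2.0, 3.0], [1, 0, 1, 0])
        g = ash.bin_grid(t, ash.amplitude_split(t))
        assert not g.complete


class TestRotatingProfile:
    def test_cosine_gated_observations_peak_at_270(self, rng):
        n = 6000
        phases = rng.uniform(0, 360, n)
        p = 0.5 + 0.3 * np.cos(np.radians(phases - 270.0))
        observed = rng.random(n) < p
        t = make_trials(phases, observed, amps=rng.lognormal(1.0, 0.4, n))
        profs = ash.rotating_profile(t, ash.amplitude_split(t))
        for lev in ("high", "low"):
            pref = ash.preferred_phase(profs[lev])
            assert abs(ash.circ_diff(pref.angle_deg, 270.0)) < 10.0

    def test_profile_agrees_with_grid_at_cardinal_centers(self, rng):
        n = 400
        t = make_trials(rng.uniform(0, 360, n), rng.random(n) < 0.6,
                        amps=rng.lognormal(1, 0.4, n))
        labels = ash.amplitude_split(t)
        g = ash.bin_grid(t, labels)
        profs = ash.rotating_profile(t, labels)
        for lev in ("high", "low"):
            for c in (0.0, 90.0, 180.0, 270.0):
                cell = g.cell(lev, c)
                if cell["n_trials"]:
                    assert profs[lev].values[int(c)] == pytest.approx(cell["delta_or"])

    def test_every_point_matches_independent_recount(self, rng):
        n = 250
        phases = rng.uniform(0, 360, n)
        observed = rng.random(n) < 0.55
        t = make_trials(phases, observed, amps=rng.lognormal(1.0, 0.4, n))
        labels = ash.amplitude_split(t)
        profs = ash.rotating_profile(t, labels)
        overall = 100.0 * observed.mean()
        lab = labels.to_numpy()
        for lev in ("high", "low"):
            sel = lab == lev
            for c in range(0, 360, 7):  # spot-check every 7 degrees
                m = sel & _in_bin(phases, float(c))
                if m.sum() == 0:
                    continue
                expect = 100.0 * observed[m].mean() - overall
                assert profs[lev].values[c] == pytest.approx(expect)

    def test_small_gaps_interpolated_large_gaps_flagged(self):
        vals = np.sin(np.radians(np.arange(360.0)))
        vals_gap = vals.copy()
        vals_gap[10:13] = np.nan
        from alphashutter.shutter import _fill_circular_gaps

        filled = _fill_circular_gaps(vals_gap, 5)
        assert not np.isnan(filled).any()
        np.testing.assert_allclose(filled[10:13], vals[10:13], atol=0.01)
        vals_gap[100:140] = np.nan
        with pytest.raises(ash.NumericalError):
            _fill_circular_gaps(vals_gap, 5)


class TestPreferredPhase:
    def test_cosine_profile_closed_form(self):
        """profile = k cos(c - 270) -> angle 270, magnitude k/2, PPE 2k."""
        k = 6.0
        c = np.arange(360.0)
        prof = PhaseProfile(k * np.cos(np.radians(c - 270.0)), "high", 100)
        pref = ash.preferred_phase(prof)
        assert pref.angle_deg == pytest.approx(270.0, abs=1e-6)
        assert pref.magnitude == pytest.approx(k / 2.0, rel=1e-9)
        assert pref.ppe == pytest.approx(2 * k, rel=1e-6)
        assert pref.pessimal_deg == pytest.approx(90.0)
        assert pref.ppe == pytest.approx(4.0 * pref.magnitude, rel=1e-6)

    def test_constant_profile_undefined(self):
        prof = PhaseProfile(np.full(360, 2.0), "low", 50)
        with pytest.raises(ash.ZeroResultantError):
            ash.preferred_phase(prof)

    def test_matches_brute_force_vector_sum(self, rng):
        vals = rng.normal(0, 3, 360)
        prof = PhaseProfile(vals, "high", 10)
        pref = ash.preferred_phase(prof)
        vx = np.mean([v * np.cos(np.radians(c)) for c, v in enumerate(vals)])
        vy = np.mean([v * np.sin(np.radians(c)) for c, v in enumerate(vals)])
        assert pref.angle_deg == pytest.approx(np.degrees(np.arctan2(vy, vx)) % 360)
        assert pref.magnitude == pytest.approx(np.hypot(vx, vy))


class TestGroupPreferredPhase:
    def _random_profiles(self, rng, n):
        profs = [PhaseProfile(rng.normal(0, 2, 360) +
                              rng.uniform(1, 4) * np.cos(np.radians(np.arange(360.0) - rng.uniform(0, 360))),
                              "high", 100) for _ in range(n)]
        return profs, [ash.preferred_phase(p) for p in profs]

    def test_identical_individuals_preserved(self):
        prof = PhaseProfile(3 * np.cos(np.radians(np.arange(360.0) - 100)), "high", 10)
        pref = ash.preferred_phase(prof)
        g = ash.group_preferred_phase([pref, pref], [prof, prof])
        assert g.angle_deg == pytest.approx(pref.angle_deg)
        assert g.magnitude == pytest.approx(pref.magnitude)

    def test_opposite_vectors_zero_resultant(self):
        a = ash.PreferredPhase(0.0, 1.0, 180.0, 0.0)
        b = ash.PreferredPhase(180.0, 1.0, 0.0, 0.0)
        with pytest.raises(ash.ZeroResultantError):
            ash.group_preferred_phase([a, b])

    def test_linearity_identity_machine_precision(self, rng):
        """Mean-of-vectors equals preferred-phase of the mean profile."""
        profs, prefs = self._random_profiles(rng, 12)
        g = ash.group_preferred_phase(prefs, profs)
        mean_prof = PhaseProfile(np.mean([p.values for p in profs], axis=0), "high", 1)
        direct = ash.preferred_phase(mean_prof)
        assert g.angle_deg == pytest.approx(direct.angle_deg, abs=1e-9)
        assert g.magnitude == pytest.approx(direct.magnitude, rel=1e-12)


class TestPreferredPhaseCi:
    def _prefs(self, angles, mags):
        return [ash.PreferredPhase(a, m, (a - 180) % 360, 0.0)
                for a, m in zip(angles, mags)]

    def test_tight_cluster_gives_narrow_interval(self, rng):
        prefs = self._prefs(90 + rng.normal(0, 2, 30), 5 + rng.normal(0, 0.1, 30))
        (lo, hi), full = ash.preferred_phase_ci(prefs)
        assert not full
        width = (hi - lo) % 360
        assert width < 10.0
        assert lo < 90.0 < hi or (hi < lo)  # interval brackets 90 deg

    def test_rectangle_containing_origin_full_circle(self, rng):
        angles = rng.uniform(0, 360, 40)
        prefs = self._prefs(angles, np.ones(40))
        (lo, hi), full = ash.preferred_phase_ci(prefs)
        assert full and (lo, hi) == (0.0, 360.0)

    def test_matches_dense_rectangle_sampling_oracle(self, rng):
        from scipy import stats as sps

        for trial in range(5):
            prefs = self._prefs(200 + rng.normal(0, 25, 15),
                                4 + rng.normal(0, 1.0, 15))
            (lo, hi), full = ash.preferred_phase_ci(prefs)
            xy = np.array([p.vector for p in prefs])
            mean = xy.mean(axis=0)
            sem = xy.std(axis=0, ddof=1) / np.sqrt(len(prefs))
            tc = sps.t.ppf(0.975, len(prefs) - 1)
            xs = np.linspace(mean[0] - tc * sem[0], mean[0] + tc * sem[0], 100)
            ys = np.linspace(mean[1] - tc * sem[1], mean[1] + tc * sem[1], 100)
            X, Y = np.meshgrid(xs, ys)
            if full:
                continue
            ang = np.degrees(np.arctan2(Y, X)) % 360
            ga = np.degrees(np.arctan2(mean[1], mean[0])) % 360
            rel = (ang - ga + 180) % 360 - 180
            assert lo == pytest.approx((ga + rel.min()) % 360, abs=0.5)
            assert hi == pytest.approx((ga + rel.max()) % 360, abs=0.5)

    def test_needs_three_individuals(self):
        prefs = self._prefs([10, 20], [1, 1])
        with pytest.raises(ash.DataError):
            ash.preferred_phase_ci(prefs)
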