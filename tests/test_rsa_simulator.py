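import numpy as np
import pytest
from scipy import stats

import hrvgame as hg
from hrvgame.rsa_simulator import respiratory_waveform

from conftest import make_rsa_series


class TestGenerateRR:
    def test_degenerate_config_is_constant(self):
        rr = hg.generate_rr(
            hg.SimConfig(mean_rr=1000.0, noise_sd=0.0, duration=60.0, seed=0),
            hg.BreathingPattern(freq=0.25, amplitude=0.0),
        )
        np.testing.assert_allclose(rr.intervals, 1000.0)

    def test_deterministic_under_seed(self):
        cfg = hg.SimConfig(duration=120.0, seed=77)
        a = hg.generate_rr(cfg)
        b = hg.generate_rr(cfg)
        np.testing.assert_array_equal(a.intervals, b.intervals)

    def test_mean_rr_recovered_within_sampling_error(self):
        cfg = hg.SimConfig(mean_rr=900.0, noise_sd=30.0, duration=600.0, seed=5)
        rr = hg.generate_rr(cfg, hg.BreathingPattern(amplitude=0.0))
        n = len(rr)
        assert abs(rr.intervals.mean() - 900.0) <= 2 * 30.0 / np.sqrt(n)

    def test_lf_paced_breathing_is_lf_dominant(self):
        rr = make_rsa_series(freq=0.1, amplitude=50.0, duration=300.0)
        lf, hf = hg.frequency_domain_metrics(rr)
        assert lf > 5 * hf

    def test_pathological_parameters_rejected(self):
        with pytest.raises(hg.PathologicalParametersError):
            hg.generate_rr(
                hg.SimConfig(mean_rr=220.0, noise_sd=0.0, duration=30.0, seed=0),
                hg.BreathingPattern(freq=0.25, amplitude=100.0),
            )

    def test_event_beyond_recording_rejected(self):
        with pytest.raises(ValueError):
            hg.generate_rr(
                hg.SimConfig(duration=60.0, seed=0),
                events=[hg.TechniqueEvent("apnea", onset=90.0, duration=10.0, magnitude=100.0)],
            )

    def test_amplitude_strictly_increases_rmssd_and_band_power(self):
        amps = [20.0, 40.0, 80.0]
        rmssds, lfs = [], []
        for a in amps:
            rr = make_rsa_series(freq=0.1, amplitude=a, duration=300.0)
            rmssds.append(hg.time_domain_metrics(rr).rmssd)
            lfs.append(hg.frequency_domain_metrics(rr)[0])
        assert rmssds[0] < rmssds[1] < rmssds[2]
        assert lfs[0] < lfs[1] < lfs[2]


class TestWaveform:
    def test_unit_amplitude_and_continuity(self):
        phase = np.linspace(0, 1, 1001, endpoint=False)
        for ie in (0.5, 1.0, 2.0):
            w = respiratory_waveform(phase, ie)
            assert np.max(np.abs(w)) <= 1.0 + 1e-12
            assert np.max(np.abs(np.diff(w))) < 0.05  # no jumps
            assert w.min() == pytest.approx(-1.0, abs=1e-4)
            assert w.max() == pytest.approx(1.0, abs=1e-4)

    def test_ie_ratio_shapes_rise_fraction(self):
        phase = np.linspace(0, 1, 10_000, endpoint=False)
        w = respiratory_waveform(phase, 0.5)  # exhalation twice the inhalation
        rise = np.mean(np.diff(w) > 0)
        assert rise == pytest.approx(1.0 / 3.0, abs=0.01)


class TestTechniqueEvents:
    def make_pair(self, events):
        cfg = hg.SimConfig(mean_rr=850.0, noise_sd=10.0, duration=120.0, seed=21)
        breathing = hg.BreathingPattern(freq=0.25, amplitude=40.0)
        control = hg.generate_rr(cfg, breathing)
        treated = hg.generate_rr(cfg, breathing, events)
        return control, treated

    def test_apnea_raises_rmssd_and_rr_mean(self):
        control, treated = self.make_pair(
            [hg.TechniqueEvent("apnea", onset=20.0, duration=60.0, magnitude=150.0)]
        )
        assert hg.time_domain_metrics(treated).rmssd > hg.time_domain_metrics(control).rmssd
        assert treated.intervals.mean() > control.intervals.mean()

    def test_hyperventilation_lowers_rmssd_and_rr_mean(self):
        control, treated = self.make_pair(
            [hg.TechniqueEvent("hyperventilation", onset=10.0, duration=80.0, magnitude=100.0)]
        )
        assert hg.time_domain_metrics(treated).rmssd < hg.time_domain_metrics(control).rmssd
        assert treated.intervals.mean() < control.intervals.mean()

    @pytest.mark.parametrize("kind", ["muscle", "swallow"])
    def test_biphasic_transients_leave_mean_nearly_unchanged(self, kind):
        control, treated = self.make_pair(
            [hg.TechniqueEvent(kind, onset=40.0, duration=6.0, magnitude=120.0)]
        )
        # a biphasic swing perturbs variability but roughly cancels in the mean
        assert abs(treated.intervals.mean() - control.intervals.mean()) < 15.0
        assert hg.time_domain_metrics(treated).sdrr > hg.time_domain_metrics(control).sdrr

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            hg.TechniqueEvent("yawning", onset=0.0, duration=5.0, magnitude=10.0)


class TestPlayerStreams:
    @pytest.fixture
    def track_and_cal(self):
        rr = make_rsa_series(freq=0.08, amplitude=60.0, duration=90.0, seed=13)
        cal = hg.calibrate(rr)
        return hg.build_track(hg.build_reference_curve(rr), cal), cal

    def test_perfect_stream_inverts_mapping(self, track_and_cal):
        track, cal = track_and_cal
        stream = hg.perfect_player_stream(track, cal)
        for i in range(track.duration):
            y = hg.map_ihr_to_position(cal, stream.values[i], track.vertical_extent)
            assert y == pytest.approx(track.target_y[i], abs=1e-12)

    def test_perfect_stream_on_flat_track_is_baseline(self, flat_track, calibration):
        stream = hg.perfect_player_stream(flat_track, calibration)
        np.testing.assert_allclose(stream.values, calibration.baseline_ihr)

    def test_skill_one_equals_perfect(self, track_and_cal):
        track, cal = track_and_cal
        perfect = hg.perfect_player_stream(track, cal)
        noisy = hg.noisy_player_stream(track, cal, skill=1.0, seed=3)
        np.testing.assert_allclose(noisy.values, perfect.values)

    def test_noisy_stream_deterministic(self, track_and_cal):
        track, cal = track_and_cal
        a = hg.noisy_player_stream(track, cal, skill=0.4, seed=8)
        b = hg.noisy_player_stream(track, cal, skill=0.4, seed=8)
        np.testing.assert_array_equal(a.values, b.values)

    def test_low_skill_earns_fewer_bonuses(self, track_and_cal):
        track, cal = track_and_cal
        cfg = hg.GameConfig()
        means = {}
        for skill in (0.2, 0.9):
            means[skill] = np.mean(
                [
                    hg.run_game(
                        hg.noisy_player_stream(track, cal, skill, seed=s), track, cfg, cal
                    ).bonus
                    for s in range(50)
                ]
            )
        assert means[0.2] < means[0.9]


class TestSimulateCohort:
    def test_shape_and_grouping(self):
        games = hg.simulate_cohort(n_per_group=3, seed=1)
        assert len(games) == 3 * 2 * 2 * 2  # groups x participants x phases x games
        assert set(games["group"]) == {"control", "experimental"}
        assert set(games["phase"]) == {"baseline", "test"}
        assert games.groupby(["participant", "phase"]).size().eq(2).all()

    def test_deterministic_under_seed(self):
        a = hg.simulate_cohort(n_per_group=2, seed=9)
        b = hg.simulate_cohort(n_per_group=2, seed=9)
        assert a.equals(b)

    def test_planted_effect_direction(self):
        """Experimental RMSSD and RR mean fall baseline->test more than control
        (sign check over cohort seeds)."""
        hits_rmssd = hits_rr = 0
        n_seeds = 20
        for seed in range(n_seeds):
            games = hg.simulate_cohort(n_per_group=8, seed=seed)
            summary = hg.group_change_table(hg.phase_averages(games))
            hits_rmssd += summary.interaction["rmssd"] < 0
            hits_rr += summary.interaction["rr_mean"] < 0
        assert hits_rmssd >= 0.9 * n_seeds
        assert hits_rr >= 0.9 * n_seeds

    def test_null_cohort_shows_no_false_signal(self):
        """With zero group effect the interaction is only sampling noise:
        the two-sample test on change scores rejects at about its nominal
        5% rate (a-priori binomial bound: <= 9 of 60 cohorts)."""
        rejections = 0
        for seed in range(60):
            games = hg.simulate_cohort(n_per_group=8, effects=hg.null_effects(), seed=seed)
            phases = hg.phase_averages(games)
            wide = phases.pivot_table(
                index=["participant", "group"], columns="phase", values="rmssd"
            ).reset_index()
            delta = wide["test"] - wide["baseline"]
            exp = delta[wide["group"] == "experimental"]
            ctl = delta[wide["group"] == "control"]
            _, p = stats.ttest_ind(exp, ctl)
            rejections += p < 0.05
        assert rejections <= 9
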