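import numpy as np
import pandas as pd
import pytest

from sffc import metrics as km


def make_min_jerk_trial(T=1.0, dist=0.10, rate=125.0, pad=0.3,
                        direction=0.0):
    dt = 1.0 / rate
    n_pad = int(round(pad * rate))
    n_move = int(np.ceil(T * rate))
    t = np.arange(n_move + 2 * n_pad + 1) * dt
    ang = np.deg2rad(direction)
    p1 = dist * np.array([np.cos(ang), np.sin(ang)])
    pos = km.min_jerk_position(t - n_pad * dt, T, np.zeros(2), p1)
    return km.RawTrial(t=t, pos=pos, condition={"direction": direction,
                                                "distance": dist,
                                                "duration": T})


class TestSmooth:
    def test_constant_position_unchanged(self):
        tr = km.RawTrial(t=np.arange(100) / 125.0,
                         pos=np.tile([0.1, 0.2], (100, 1)))
        sm = km.smooth(tr)
        assert np.allclose(sm.pos, tr.pos, atol=1e-12)

    def test_high_frequency_attenuated_beyond_20db(self):
        t = np.arange(1000) / 125.0
        pos = np.stack([0.01 * np.sin(2 * np.pi * 30.0 * t),
                        np.zeros_like(t)], axis=-1)
        sm = km.smooth(km.RawTrial(t=t, pos=pos))
        mid = slice(200, 800)  # avoid filter edge effects
        gain = np.abs(sm.pos[mid, 0]).max() / 0.01
        assert gain < 0.1

    def test_zero_phase_peak_not_shifted(self):
        tr = make_min_jerk_trial(T=0.8)
        sm = km.smooth(tr)
        sp_raw = km.speed_profile(tr)
        sp_sm = km.speed_profile(sm)
        assert abs(int(np.argmax(sp_sm)) - int(np.argmax(sp_raw))) <= 1

    def test_short_trial_rejected(self):
        tr = km.RawTrial(t=np.arange(10) / 125.0, pos=np.zeros((10, 2)))
        with pytest.raises(ValueError, match="too short"):
            km.smooth(tr)

    def test_low_sample_rate_rejected(self):
        tr = km.RawTrial(t=np.arange(100) / 20.0, pos=np.zeros((100, 2)))
        with pytest.raises(ValueError, match="sample rate"):
            km.smooth(tr)


class TestSegment:
    def test_min_jerk_crossings_recovered(self):
        T, dist = 1.0, 0.10
        tr = make_min_jerk_trial(T=T, dist=dist)
        sp = km.speed_profile(tr)
        i0, i1, dur = km.segment(sp, tr.t, threshold=0.01)
        # analytic crossing times of the closed-form speed profile
        tq = np.linspace(0, T, 100_001)
        v = km.min_jerk_speed(tq, T, dist)
        above = v > 0.01
        t_start = tq[np.argmax(above)]
        t_end = tq[len(tq) - 1 - np.argmax(above[::-1])]
        dt = tr.t[1] - tr.t[0]
        assert dur == pytest.approx(t_end - t_start, abs=2 * dt)

    def test_threshold_above_peak_is_error(self):
        tr = make_min_jerk_trial(T=1.0, dist=0.10)
        sp = km.speed_profile(tr)
        with pytest.raises(ValueError, match="no movement"):
            km.segment(sp, tr.t, threshold=2 * sp.max())

    def test_speed_rescaling_covariance(self):
        tr = make_min_jerk_trial(T=1.0, dist=0.10)
        sp = km.speed_profile(tr)
        i0, i1, _ = km.segment(sp, tr.t, threshold=0.01)
        j0, j1, _ = km.segment(2 * sp, tr.t, threshold=0.02)
        assert (i0, i1) == (j0, j1)


class TestSummarize:
    def test_known_endpoint_spread(self):
        # plant explicit endpoint offsets so the sample covariance is known
        rng = np.random.default_rng(0)
        trials = [make_min_jerk_trial(T=0.8, dist=0.12) for _ in range(5)]
        offsets = rng.normal(scale=[3e-3, 4e-3], size=(5, 2))
        for tr, off in zip(trials, offsets):
            tr.pos[-30:] += off
        s = km.summarize(trials, threshold=0.01)
        endpoints = np.array([tr.pos[km.segment(km.speed_profile(tr), tr.t,
                                                0.01)[1]] for tr in trials])
        expected = np.log(np.trace(np.cov(endpoints.T)) * 1e6)
        assert s.log_endpoint_variance == pytest.approx(expected, abs=1e-9)

    def test_identical_durations_mean(self):
        trials = [make_min_jerk_trial(T=0.8) for _ in range(3)]
        s = km.summarize(trials)
        sp = km.speed_profile(trials[0])
        _, _, dur = km.segment(sp, trials[0].t)
        assert s.duration == pytest.approx(dur)
        assert s.n_trials == 3

    def test_normalized_profile_grid(self):
        trials = [make_min_jerk_trial(T=T) for T in (0.6, 0.9)]
        s = km.summarize(trials, n_norm=101)
        assert s.mean_speed_profile.shape == (101,)
        assert s.mean_speed_profile[50] > s.mean_speed_profile[5]

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            km.summarize([make_min_jerk_trial()])


class TestCompare:
    @staticmethod
    def frame(values):
        rows = []
        for i, v in enumerate(values):
            rows.append({"direction": "N-E", "distance": 0.06 * (i + 1),
                         "vision": "with", "duration": v,
                         "peak_velocity": 2 * v,
                         "log_endpoint_variance": v / 2})
        return pd.DataFrame(rows)

    def test_identical_frames(self):
        a = self.frame([0.5, 0.7, 0.9, 1.1])
        res = km.compare(a, a.copy())
        assert np.allclose(res["rmsd"], 0.0)
        assert np.allclose(res["r_squared"], 1.0)

    def test_constant_offset(self):
        a = self.frame([0.5, 0.7, 0.9, 1.1])
        b = a.copy()
        b["duration"] += 0.1
        res = km.compare(a, b, metrics=("duration",))
        assert res.loc[0, "rmsd"] == pytest.approx(0.1)
        assert res.loc[0, "r_squared"] == pytest.approx(1.0)

    def test_rmsd_matches_direct_formula(self, rng):
        a = self.frame(rng.uniform(0.4, 1.2, 6))
        b = self.frame(rng.uniform(0.4, 1.2, 6))
        res = km.compare(a, b, metrics=("duration",))
        direct = np.sqrt(np.mean((a["duration"] - b["duration"]) ** 2))
        assert res.loc[0, "rmsd"] == pytest.approx(direct)

    def test_mismatched_conditions_rejected(self):
        a = self.frame([0.5, 0.7])
        b = self.frame([0.5, 0.7, 0.9])
        with pytest.raises(ValueError):
            km.compare(a, b)


class TestSyntheticGenerator:
    def test_noise_free_ground_truth_recovery(self):
        conds = [{"direction": 45.0, "distance": 0.12, "duration": 0.8}]
        trials = km.generate_synthetic_trials(conds, n_trials=3,
                                              endpoint_sd=0.0, timing_sd=0.0,
                                              measurement_sd=0.0, seed=1)
        s = km.summarize(trials, threshold=0.01)
        tq = np.linspace(0, 0.8, 200_001)
        v = km.min_jerk_speed(tq, 0.8, 0.12)
        above = v > 0.01
        dur_true = tq[len(tq) - 1 - np.argmax(above[::-1])] - tq[np.argmax(above)]
        assert s.duration == pytest.approx(dur_true, abs=2 / 125.0)
        assert s.peak_velocity == pytest.approx(
            100 * 1.875 * 0.12 / 0.8, rel=0.01)

    def test_endpoint_variance_converges_to_ground_truth(self):
        s_true = 0.004
        conds = [{"direction": 0.0, "distance": 0.10, "duration": 0.7}]
        trials = km.generate_synthetic_trials(conds, n_trials=3000,
                                              endpoint_sd=s_true,
                                              timing_sd=0.0,
                                              measurement_sd=0.0, seed=2)
        s = km.summarize(trials, threshold=0.01)
        assert s.log_endpoint_variance == pytest.approx(
            np.log(2 * (s_true * 1000) ** 2), abs=0.1)

    def test_seed_reproducibility(self):
        conds = [{"direction": 90.0, "distance": 0.06, "duration": 0.6}]
        a = km.generate_synthetic_trials(conds, n_trials=4, seed=7)
        b = km.generate_synthetic_trials(conds, n_trials=4, seed=7)
        assert all(np.array_equal(x.pos, y.pos) for x, y in zip(a, b))


class TestRawTrialValidation:
    def test_nonuniform_times_rejected(self):
        t = np.array([0.0, 0.008, 0.02, 0.028])
        with pytest.raises(ValueError):
            km.RawTrial(t=t, pos=np.zeros((4, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            km.RawTrial(t=np.arange(5) / 125.0, pos=np.zeros((4, 2)))
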