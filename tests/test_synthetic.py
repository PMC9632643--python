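"""Simulator tests: schedule statistics, trace geometry, parameter recovery."""

import numpy as np
import pytest

import dysmetrix as dx
from dysmetrix.synthetic import DEG_TO_NIC


def noiseless_profile(**kw):
    base = dict(group_label="control", primary_gain_mean=0.95,
                primary_gain_sd=0.0, blink_rate=0.0, drift_amplitude=0.0,
                noise_sd=0.0, left_right_asymmetry=0.0)
    base.update(kw)
    return dx.SubjectProfile(**base)


class TestSchedule:
    def test_paper_task_counts(self):
        s = dx.generate_schedule(n_trials=20, amplitude_deg=16,
                                 dwell_bounds=(1.3, 2.0), seed=0)
        assert s.n_trials == 20
        assert s.n_jumps == 40
        assert len(s.dwell_durations) == 40

    def test_dwells_within_bounds_and_onsets_increasing(self):
        s = dx.generate_schedule(seed=3)
        assert np.all(s.dwell_durations >= 1.3)
        assert np.all(s.dwell_durations <= 2.0)
        assert np.all(np.diff(s.onset_times) > 0)

    def test_degenerate_dwell_bounds(self):
        s = dx.generate_schedule(n_trials=1, dwell_bounds=(1.5, 1.5), seed=0)
        assert s.n_trials == 1
        assert np.allclose(s.dwell_durations, 1.5)

    def test_balanced_directions(self):
        s = dx.generate_schedule(n_trials=21, seed=5)
        n_left = sum(d == "left" for d in s.trial_directions)
        assert abs(n_left - (21 - n_left)) <= 1

    def test_seed_determinism_and_variability(self):
        a = dx.generate_schedule(seed=42)
        b = dx.generate_schedule(seed=42)
        assert a.trial_directions == b.trial_directions
        assert np.array_equal(a.onset_times, b.onset_times)
        orders = {dx.generate_schedule(seed=s).trial_directions
                  for s in range(100)}
        assert len(orders) > 50  # different seeds give differing orders

    def test_schedule_exceeding_duration_errors(self):
        with pytest.raises(ValueError, match="duration"):
            dx.generate_schedule(n_trials=20, duration=42.0, seed=0)

    def test_target_positions_alternate_with_center(self):
        s = dx.generate_schedule(n_trials=4, seed=1)
        pos = s.target_positions()
        assert np.allclose(pos[1::2], 0.0)  # every trial returns to center
        assert np.all(np.abs(pos[::2]) == pytest.approx(16 * DEG_TO_NIC))


class TestSimulateRecording:
    def test_noiseless_unity_gain_is_target_staircase(self):
        """With gain 1 and no noise/blinks/drift the trace reproduces the
        target staircase exactly outside the saccade transitions."""
        sched = dx.generate_schedule(n_trials=6, seed=2)
        # exact-staircase check needs gain exactly 1: bypass the control
        # near-unity band via a dysmetria-free mixed profile
        prof = dx.SubjectProfile(group_label="dysmetric",
                                 dysmetria_mode="mixed",
                                 mixed_gain_means=(1.0, 1.0),
                                 primary_gain_mean=1.0, primary_gain_sd=0.0,
                                 blink_rate=0, drift_amplitude=0, noise_sd=0,
                                 left_right_asymmetry=0)
        rec = dx.simulate_recording(sched, prof, fs=240, duration=42, seed=0,
                                    reaction_latency=0.2)
        # build the expected staircase from the schedule (response latency
        # is jittered, so compare at dwell midpoints only)
        targets = sched.target_positions()
        step = 16 * DEG_TO_NIC
        for onset, dwell, target in zip(sched.onset_times,
                                        sched.dwell_durations, targets):
            t_probe = onset + 0.2 + 0.15 + 0.5 * dwell  # well after the move
            if t_probe > 42 - 0.1 or onset + 0.5 > 42:
                continue
            i = int(round(t_probe * 240))
            if i >= rec.n_samples:
                continue
            assert abs(rec.left_x[i] - target) < 1e-9 * step

    def test_gain_recovery_from_noiseless_trace(self):
        """Measured primary-saccade gain matches the profile within 1%."""
        sched = dx.generate_schedule(n_trials=10, seed=4)
        prof = noiseless_profile(primary_gain_mean=0.95, primary_gain_sd=0.0)
        rec = dx.simulate_recording(sched, prof, fs=240, duration=42, seed=1)
        x = rec.left_x
        fs = 240.0
        gains = []
        level_pre = 0.0
        for onset, target in zip(sched.onset_times, sched.target_positions()):
            i0 = int((onset + 0.05) * fs)  # before the response
            i1 = int((onset + 0.45) * fs)  # after primary, before next jump
            if i1 >= len(x):
                break
            pre = x[i0]
            post = x[i1]
            if abs(target - pre) > 1e-6:
                gains.append((post - pre) / (target - pre))
        assert len(gains) >= 8
        assert np.mean(gains) == pytest.approx(0.95, rel=0.01)

    def test_hypermetric_overshoot_measured(self):
        """A gain-1.25 profile overshoots each step by ~25% before the
        corrective saccade."""
        sched = dx.generate_schedule(n_trials=8, seed=6)
        prof = dx.SubjectProfile(group_label="dysmetric",
                                 dysmetria_mode="hypermetric",
                                 primary_gain_mean=1.25, primary_gain_sd=0.0,
                                 blink_rate=0, drift_amplitude=0, noise_sd=0,
                                 left_right_asymmetry=0,
                                 corrective_latency_mean=0.25)
        rec = dx.simulate_recording(sched, prof, fs=240, duration=42, seed=2)
        x = rec.left_x
        fs = 240.0
        overshoots = []
        for onset, target in zip(sched.onset_times, sched.target_positions()):
            i0 = int((onset + 0.05) * fs)
            i1 = int((onset + 0.32) * fs)  # after primary, before corrective
            if i1 >= len(x):
                break
            pre = x[i0]
            post = x[i1]
            step = target - pre
            if abs(step) > 1e-6:
                overshoots.append((post - pre) / step - 1.0)
        assert len(overshoots) >= 6
        assert np.mean(overshoots) == pytest.approx(0.25, abs=0.03)

    def test_blink_count_poisson(self):
        """Inserted blink counts agree with the Poisson event model."""
        sched = dx.generate_schedule(n_trials=5, seed=0)
        prof = noiseless_profile(blink_rate=12.0)
        counts = [len(dx.simulate_recording(sched, prof, fs=120, duration=20,
                                            seed=s).meta["blink_times"])
                  for s in range(200)]
        lam = 12.0 * 20 / 60.0  # expected events per recording
        mean = np.mean(counts)
        sd_of_mean = np.sqrt(lam / 200)
        assert abs(mean - lam) < 2 * sd_of_mean * 2  # 2 SD with slack

    def test_blinks_return_to_baseline(self):
        """Blink excursions come back to the pre-blink level."""
        sched = dx.generate_schedule(n_trials=3, seed=1)
        prof = noiseless_profile(blink_rate=20.0)
        rec = dx.simulate_recording(sched, prof, fs=240, duration=30, seed=9)
        twin = dx.simulate_recording(sched, noiseless_profile(), fs=240,
                                     duration=30, seed=9)
        times = sorted(rec.meta["blink_times"])
        checked = 0
        for k, tb in enumerate(times):
            # only blinks isolated from their neighbours have settled again
            # 0.3 s after onset
            gap_ok = ((k == 0 or tb - times[k - 1] > 0.6)
                      and (k == len(times) - 1 or times[k + 1] - tb > 0.6))
            if not gap_ok:
                continue
            i_post = int((tb + 0.30) * 240)
            assert abs(rec.left_x[i_post] - twin.left_x[i_post]) < 1e-9
            checked += 1
        assert checked >= 1

    def test_invalid_fs_duration(self):
        sched = dx.generate_schedule(seed=0)
        prof = noiseless_profile()
        with pytest.raises(ValueError):
            dx.simulate_recording(sched, prof, fs=0, duration=42, seed=0)
        with pytest.raises(ValueError):
            dx.simulate_recording(sched, prof, fs=240, duration=-1, seed=0)


class TestProfileValidation:
    def test_control_requires_near_unity_gain(self):
        with pytest.raises(ValueError):
            dx.SubjectProfile(group_label="control", primary_gain_mean=0.7)

    def test_hypometric_gain_bound(self):
        with pytest.raises(ValueError):
            dx.SubjectProfile(group_label="dysmetric",
                              dysmetria_mode="hypometric",
                              primary_gain_mean=0.9)

    def test_hypermetric_gain_bound(self):
        with pytest.raises(ValueError):
            dx.SubjectProfile(group_label="dysmetric",
                              dysmetria_mode="hypermetric",
                              primary_gain_mean=1.0)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            dx.SubjectProfile(blink_rate=-1)


class TestCohort:
    def test_cohort_sizes_and_labels(self):
        recs = dx.generate_cohort(3, 4, seed=0, duration=10, n_trials=2)
        labels = [r.label for r in recs]
        assert labels.count("dysmetric") == 3
        assert labels.count("control") == 4

    def test_single_control(self):
        recs = dx.generate_cohort(0, 1, seed=0, duration=10, n_trials=2)
        assert len(recs) == 1 and recs[0].label == "control"

    def test_cohort_seed_determinism(self):
        a = dx.generate_cohort(2, 2, seed=7, duration=10, n_trials=2)
        b = dx.generate_cohort(2, 2, seed=7, duration=10, n_trials=2)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.left_x, rb.left_x)
            assert np.array_equal(ra.right_x, rb.right_x)


class TestIO:
    def test_csv_roundtrip(self, tmp_path):
        recs = dx.generate_cohort(1, 0, seed=3, duration=10, n_trials=2)
        path = tmp_path / "subj.csv"
        dx.write_recording(recs[0], path)
        back = dx.read_recording(path)
        assert back.label == "dysmetric"
        assert back.fs == recs[0].fs
        assert np.allclose(back.left_x, recs[0].left_x, atol=1e-9)
        assert np.allclose(back.right_x, recs[0].right_x, atol=1e-9)
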