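"""Generator contracts: fixed target counts, determinism, noise-free limits,
Poisson blink counts, CoP stationary behaviour, ground-truth round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from apakit.core_model import Signal
from apakit.emg_onset import background_stats, detect_burst, refine_onset
from apakit.preprocessing import emg_envelope_chain, envelope, rectify
from apakit.simulate import (
    SimulationConfig,
    SubjectProfile,
    _rng,
    generate_blinks,
    generate_cohort_measures,
    generate_cop,
    generate_eeg,
    generate_emg,
    generate_session,
    generate_stimulus_sequence,
)


class TestStimulusSequence:
    @pytest.mark.parametrize("cond,expected_targets", [("p15", 11), ("p45", 32)])
    def test_fixed_target_counts(self, cond, expected_targets):
        events = generate_stimulus_sequence(SimulationConfig(condition=cond, seed=1))
        targets = [e for e in events if e.label == "target"]
        assert len(events) == 72
        assert len(targets) == expected_targets

    def test_fixed_isi(self):
        events = generate_stimulus_sequence(SimulationConfig(seed=3), start_ms=100.0)
        gaps = np.diff([e.time_ms for e in events])
        assert np.all(gaps == 2500.0)
        assert events[0].time_ms == 100.0

    def test_same_seed_same_sequence(self):
        a = generate_stimulus_sequence(SimulationConfig(seed=9))
        b = generate_stimulus_sequence(SimulationConfig(seed=9))
        assert a == b

    def test_zero_target_configuration_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(condition="p15", n_stimuli=2)


class TestGenerateEmg:
    def test_no_burst_rarely_triggers_detection(self):
        prof = SubjectProfile()
        fp = 0
        for seed in range(200):
            sig = generate_emg(None, prof, 4000.0, _rng(seed, "fp-test"))
            rect, env = emg_envelope_chain(sig)
            bg = background_stats(env, 1000.0, -150.0, 0.0)
            if detect_burst(env, bg, 1200.0, 1500.0).detected:
                fp += 1
        assert fp / 200 < 0.05

    def test_onset_recovered_within_10ms_at_high_amplitude(self):
        prof = SubjectProfile()
        errs = []
        for seed in range(100):
            sig = generate_emg(3000.0, prof, 6000.0, _rng(seed, "rec-test"),
                               amplitude_multiple=8.0)
            rect, env = emg_envelope_chain(sig)
            bg = background_stats(env, 2750.0, -150.0, 0.0)
            det = detect_burst(env, bg, 2950.0, 3250.0)
            assert det.detected
            errs.append(refine_onset(rect, env, det.onset_ms, bg) - 3000.0)
        assert np.mean(np.abs(errs)) <= 10.0

    def test_onset_outside_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_emg(7000.0, SubjectProfile(), 6000.0, _rng(0, "x"))


class TestGenerateEeg:
    def test_noise_free_single_trial_peak(self):
        prof = SubjectProfile(eeg_noise_sd_uv=0.0)
        sig = generate_eeg([2000.0], prof, 6000.0, _rng(0, "eeg"),
                           latency_ms=350.0, amplitude_uv=10.0)
        i = int(np.argmax(sig.values))
        assert i == 2350
        assert sig.values[i] == pytest.approx(10.0)

    def test_zero_amplitude_indistinguishable_from_noise(self):
        prof = SubjectProfile()
        with_erp = generate_eeg([2000.0], prof, 6000.0, _rng(4, "eeg"),
                                amplitude_uv=0.0)
        without = generate_eeg([], prof, 6000.0, _rng(4, "eeg"))
        np.testing.assert_array_equal(with_erp.values, without.values)

    def test_nontargets_get_no_deflection(self):
        prof = SubjectProfile(eeg_noise_sd_uv=0.0)
        sig = generate_eeg([], prof, 4000.0, _rng(1, "eeg"))
        np.testing.assert_allclose(sig.values, 0.0)


class TestGenerateBlinks:
    def test_zero_rate_stays_below_limit(self):
        sig = generate_blinks(0.0, 300.0, 60000.0, _rng(0, "b"))
        assert np.max(np.abs(sig.values)) < 100.0

    def test_forced_blink_exceeds_limit_inside_window(self):
        sig = generate_blinks(0.0, 300.0, 10000.0, _rng(1, "b"),
                              force_times_ms=[3300.0])
        window = sig.values[2800:3800]
        assert np.max(np.abs(window)) > 100.0

    def test_poisson_count_within_95_band(self):
        # rate 6/min over 3 min -> lambda = 18
        counts = []
        for seed in range(60):
            sig = generate_blinks(6.0, 300.0, 180000.0, _rng(seed, "b"))
            counts.append(int(np.sum(np.diff((sig.values > 150.0).astype(int)) == 1)))
        lam = 18.0
        assert sst.poisson.ppf(0.025, lam) <= np.mean(counts) <= sst.poisson.ppf(0.975, lam)


class TestGenerateCop:
    def test_zero_drift_is_constant(self):
        sig = generate_cop(5.0, 0.0, [], 5000.0, _rng(0, "c"))
        np.testing.assert_allclose(sig.values, 5.0)

    def test_scheduled_excursion_applied(self):
        sig = generate_cop(5.0, 0.0, [(1000.0, 1500.0, 2.0)], 5000.0, _rng(0, "c"))
        assert np.all(sig.values[1000:1500] == 7.0)
        assert np.all(sig.values[1500:] == 5.0)

    def test_out_of_range_fraction_matches_stationary_distribution(self):
        # stationary law is N(qsp, drift_sd^2): P(|x| > 1) = 2*Phi(-1/0.5)
        fracs = [
            np.mean(np.abs(generate_cop(0.0, 0.5, [], 120000.0, _rng(s, "c")).values) > 1.0)
            for s in range(20)
        ]
        expected = 2 * sst.norm.sf(1.0 / 0.5)
        assert np.mean(fracs) == pytest.approx(expected, abs=0.015)

    def test_clamp_windows_keep_drift_in_range(self):
        sig = generate_cop(5.0, 0.8, [], 20000.0, _rng(3, "c"),
                           clamp_windows=[(4000.0, 8000.0)])
        assert np.max(np.abs(sig.values[4000:8000] - 5.0)) <= 0.95 + 1e-12


class TestGenerateSession:
    def test_ground_truth_row_count(self):
        rec, truth = generate_session(
            SimulationConfig(condition="p15", seed=0), SubjectProfile()
        )
        assert len(truth) == 22  # two 11-target blocks cover 20 wanted trials
        assert (truth.condition == "p15").all()

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(condition="p45", seed=11)
        rec1, t1 = generate_session(cfg, SubjectProfile())
        rec2, t2 = generate_session(cfg, SubjectProfile())
        for name in rec1.channels:
            np.testing.assert_array_equal(rec1.channels[name].values,
                                          rec2.channels[name].values)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_different_noise(self):
        a, _ = generate_session(SimulationConfig(seed=1), SubjectProfile())
        b, _ = generate_session(SimulationConfig(seed=2), SubjectProfile())
        assert not np.array_equal(a.channels["Pz"].values, b.channels["Pz"].values)

    def test_self_condition_has_go_markers_and_response_window(self):
        cfg = SimulationConfig(condition="self", seed=5, n_target_trials=8)
        rec, truth = generate_session(cfg, SubjectProfile())
        labels = {e.label for e in rec.events}
        assert labels == {"go_window_start"}
        lat = truth.true_ad_onset_ms - truth.anchor_ms
        assert ((lat >= 500.0) & (lat <= 3000.0)).all()

    def test_true_offsets_distributed_around_profile(self):
        prof = SubjectProfile()
        _, truth = generate_session(SimulationConfig(condition="p45", seed=3), prof)
        mean_gcm = truth.true_GcM_offset_ms.mean()
        assert mean_gcm == pytest.approx(prof.offsets_ms["GcM"]["p45"], abs=8.0)


class TestCohortMeasures:
    def test_shapes_and_determinism(self):
        onsets, erp = generate_cohort_measures(n_per_group=4, seed=2)
        assert len(onsets) == 2 * 4 * 3 * 3  # groups x subjects x muscles x conditions
        assert len(erp) == 2 * 4 * 2
        onsets2, erp2 = generate_cohort_measures(n_per_group=4, seed=2)
        pd.testing.assert_frame_equal(onsets, onsets2)
        pd.testing.assert_frame_equal(erp, erp2)

    def test_group_effect_structure_present_at_large_n(self):
        onsets, erp = generate_cohort_measures(n_per_group=300, seed=0)
        gcm = onsets[(onsets.group == "young") & (onsets.muscle == "GcM")]
        means = gcm.groupby("condition").mean_relative_onset_ms.mean()
        assert means["self"] < means["p45"] < means["p15"] < 0
        older_gcm = onsets[(onsets.group == "older") & (onsets.muscle == "GcM")]
        m_old = older_gcm.groupby("condition").mean_relative_onset_ms.mean()
        assert abs(m_old["p15"]) < 3.0 and abs(m_old["p45"]) < 3.0
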