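"""Forward model and cohort simulation: recoverability and distributional truth."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import brainvitals as bv
from brainvitals.reliability import PairedMeasures, icc_two_way_absolute_single
from brainvitals.simulate import (
    CohortConfig,
    GroupSpec,
    MeasureSpec,
    group_a_spec,
    group_b_spec,
    reference_cohort_config,
    simulate_cohort,
)


class TestRecordingSynthesis:
    def test_noiseless_round_trip_latencies_exact(self, noiseless_measures, truth):
        for comp, (_, lat) in truth.items():
            assert noiseless_measures[f"{comp}_latency"] == lat

    def test_noiseless_round_trip_amplitudes_within_filter_tolerance(self, noiseless_measures, truth):
        for comp, (amp, _) in truth.items():
            assert noiseless_measures[f"{comp}_amplitude"] == pytest.approx(amp, rel=0.02)

    def test_deterministic_per_seed(self, default_profile, short_sequences):
        tones, words = short_sequences
        a = bv.synthesize_recording(default_profile, tones, words, bv.NoiseConfig(), seed=11)
        b = bv.synthesize_recording(default_profile, tones, words, bv.NoiseConfig(), seed=11)
        assert np.array_equal(a.data, b.data)

    def test_zero_blink_rate_leaves_eog_at_noise_floor(self, default_profile, short_sequences):
        tones, words = short_sequences
        cfg = bv.NoiseConfig(background_sd_uv=0.0, blink_rate_hz=0.0)
        rec = bv.synthesize_recording(default_profile, tones, words, cfg, seed=1)
        assert np.max(np.abs(rec.channel("EOG"))) < 1e-12

    def test_latency_outside_window_raises(self, short_sequences):
        tones, words = short_sequences
        prof = bv.ParticipantProfile(id="bad")
        prof.true_components["n100"].latency = 200.0  # outside [70, 150]
        with pytest.raises(ValueError):
            bv.synthesize_recording(prof, tones, words, bv.NoiseConfig(), seed=0)

    def test_p300_amplitude_recovered_within_one_microvolt(self):
        """Mean measured P300 over seeds stays within +/-1 uV of an 8 uV truth
        at 120 deviant tones and 10 uV background noise."""
        prof = bv.ParticipantProfile(id="p", session_effects={})
        prof.true_components["p300"] = replace(prof.true_components["p300"], amplitude=8.0,
                                               latency=300.0)
        tones = bv.generate_tone_sequence(600, 0.2, isi=0.6, seed=5)
        noise = bv.NoiseConfig(background_sd_uv=10.0)
        measured = []
        for seed in range(10):
            rec = bv.synthesize_recording(prof, tones, None, noise, seed=seed)
            measured.append(bv.process_recording(rec).as_dict()["p300_amplitude"])
        assert abs(np.mean(measured) - 8.0) < 1.0


class TestCohortTableMode:
    def test_group_b_mean_within_sampling_error(self):
        cfg = reference_cohort_config()
        meas, _ = simulate_cohort(cfg, seed=0)
        vals = meas[(meas.group == "B") & (meas.measure == "n400_amplitude")]["value"]
        spec = group_b_spec().measures["n400_amplitude"]
        assert abs(vals.mean() - spec.mean) < 3 * spec.sd / np.sqrt(len(vals))

    def test_cell_counts_match_study_structure(self):
        meas, _ = simulate_cohort(reference_cohort_config(), seed=1)
        counts = meas.groupby(["group", "session", "measure"])["value"].count()
        assert counts.loc[("A", 1, "n100_latency")] == 52
        assert counts.loc[("A", 2, "n100_latency")] == 46
        assert counts.loc[("A", 1, "n400_amplitude")] == 38
        assert counts.loc[("A", 2, "n400_amplitude")] == 33
        assert counts.loc[("B", 1, "n100_latency")] == 134
        assert counts.loc[("B", 1, "p300_amplitude")] == 135

    def test_perfect_correlation_no_habituation_gives_identical_sessions(self):
        g = GroupSpec(name="A", n=20, sessions=2, age_mean=16.0, age_sd=0.8,
                      measures={"p300_latency": MeasureSpec(280.0, 40.0, retest_rho=1.0)})
        meas, _ = simulate_cohort(CohortConfig(groups=[g]), seed=2)
        wide = meas.pivot_table(index="participant_id", columns="session", values="value")
        assert np.allclose(wide[1], wide[2])

    def test_intraclass_correlation_recovered_at_large_n(self):
        g = GroupSpec(name="A", n=500, sessions=2, age_mean=30.0, age_sd=5.0,
                      measures={"p300_amplitude": MeasureSpec(10.0, 4.0, retest_rho=0.7)})
        meas, _ = simulate_cohort(CohortConfig(groups=[g]), seed=3)
        pairs = PairedMeasures.from_long(meas, "p300_amplitude")
        icc, _, _ = icc_two_way_absolute_single(pairs)
        assert abs(icc - 0.7) < 0.05

    def test_habituation_reduces_second_session_n400(self):
        meas, _ = simulate_cohort(reference_cohort_config(), seed=4)
        sub = meas[(meas.group == "A") & (meas.measure == "n400_amplitude")]
        m1 = sub[sub.session == 1]["value"].mean()
        m2 = sub[sub.session == 2]["value"].mean()
        assert m2 < m1

    def test_truth_table_retains_excluded_participants(self):
        meas, truth = simulate_cohort(reference_cohort_config(), seed=5)
        assert truth[truth.group == "A"]["participant_id"].nunique() == 58
        assert meas[(meas.group == "A") & (meas.session == 1)]["participant_id"].nunique() == 52

    def test_determinism(self):
        a, ta = simulate_cohort(reference_cohort_config(), seed=6)
        b, tb = simulate_cohort(reference_cohort_config(), seed=6)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)

    @pytest.mark.parametrize("bad", [dict(sd=0.0), dict(sd=-1.0)])
    def test_invalid_measure_spec_raises(self, bad):
        with pytest.raises(ValueError):
            MeasureSpec(mean=10.0, **bad)

    def test_invalid_correlation_raises(self):
        with pytest.raises(ValueError):
            MeasureSpec(mean=10.0, sd=1.0, retest_rho=1.5)
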