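import numpy as np
import pytest

from _oracles import band_power_oracle, brute_force_stability_score
from eegarousal.stability import arousal_stability_score
from eegarousal.stages import StageSequence
from eegarousal.synthetic import (
    CohortParams,
    SynthesisConfig,
    generate_cohort,
    generate_stage_script,
    matched_truncnorm,
    synthesize_eeg,
)
from eegarousal.synthetic.scripts import StageScript


class TestStageScripts:
    def test_hyperaroused_labels_only_0_a1(self):
        script = generate_stage_script("hyperaroused", seed=1)
        assert len(script) == 1200
        assert set(script.labels) <= {"0", "A1"}

    def test_hyperaroused_scores_14(self):
        for seed in range(5):
            script = generate_stage_script("hyperaroused", seed=seed)
            assert arousal_stability_score(StageSequence(script.labels)).score == 14

    def test_declining_b1_minute3_scores_9(self):
        script = generate_stage_script("declining", {"B1": 3}, seed=2)
        assert "B2/3" not in script.labels and "C" not in script.labels
        minute3 = script.labels[120:180]
        assert minute3.count("B1") >= 20  # >= 1/3 of the minute
        assert brute_force_stability_score(script.labels) == 9
        assert arousal_stability_score(StageSequence(script.labels)).score == 9

    def test_declining_single_c_minute18_scores_4(self):
        script = generate_stage_script("declining", {"C": 18}, seed=3)
        assert script.labels.count("C") == 1
        assert 60 * 17 <= script.labels.index("C") < 60 * 18
        assert arousal_stability_score(StageSequence(script.labels)).score == 4

    def test_unknown_profile(self):
        with pytest.raises(ValueError, match="unknown profile"):
            generate_stage_script("sleepy", seed=0)

    def test_declining_rejects_disorder(self):
        with pytest.raises(ValueError, match="order"):
            generate_stage_script("declining", {"B1": 10, "C": 5}, seed=0)

    def test_custom_allows_disorder(self):
        script = generate_stage_script("custom", {"B1": 10, "C": 5}, seed=0)
        assert 60 * 4 <= script.labels.index("C") < 60 * 5

    def test_minutes_out_of_range(self):
        with pytest.raises(ValueError, match="1..20"):
            generate_stage_script("declining", {"B1": 21}, seed=0)

    def test_script_invariant_length(self):
        with pytest.raises(ValueError, match="1200"):
            StageScript(["A1"] * 100, seed=0, profile_name="custom")

    def test_reproducible(self):
        a = generate_stage_script("declining", {"B1": 5, "B2/3": 9}, seed=7)
        b = generate_stage_script("declining", {"B1": 5, "B2/3": 9}, seed=7)
        assert a.labels == b.labels

    def test_scripts_match_scoring_oracle(self):
        # generated scripts score identically under implementation and oracle
        rng = np.random.default_rng(99)
        for _ in range(30):
            b1 = int(rng.integers(1, 15))
            params = {"B1": b1}
            if rng.random() < 0.5:
                params["B2/3"] = int(rng.integers(b1, 21))
            script = generate_stage_script("declining", params, seed=int(rng.integers(1e6)))
            assert arousal_stability_score(
                StageSequence(script.labels)
            ).score == brute_force_stability_score(script.labels)


class TestSynthesizeEEG:
    def test_occipital_alpha_beats_frontal_every_second(self, fast_config):
        labels = ["A1"] * 20
        rec = synthesize_eeg(labels, fast_config, seed=3)
        fs = int(rec.sampling_rate)
        occ = rec.channels_with_role("occipital")
        fro = rec.channels_with_role("frontal")
        for sec in range(20):
            sl = slice(sec * fs, (sec + 1) * fs)
            p_occ = np.mean(
                [band_power_oracle(rec.data[i, sl], fs, 8, 12) for i in occ]
            )
            p_fro = np.mean(
                [band_power_oracle(rec.data[i, sl], fs, 8, 12) for i in fro]
            )
            assert p_occ > p_fro

    def test_alpha_peak_at_configured_frequency(self, fast_config):
        import scipy.signal

        rec = synthesize_eeg(["A1"] * 10, fast_config, seed=4)
        fs = int(rec.sampling_rate)
        occ = rec.channels_with_role("occipital")[0]
        for sec in range(10):
            seg = rec.data[occ, sec * fs : (sec + 1) * fs]
            freqs, psd = scipy.signal.periodogram(seg, fs=fs)
            assert freqs[np.argmax(psd[1:]) + 1] == pytest.approx(10.0, abs=1.0)

    def test_bit_identical_given_seed(self, fast_config):
        labels = ["A1"] * 5 + ["B1"] * 5 + ["C"] * 2
        a = synthesize_eeg(labels, fast_config, seed=8)
        b = synthesize_eeg(labels, fast_config, seed=8)
        assert np.array_equal(a.data, b.data)
        c = synthesize_eeg(labels, fast_config, seed=9)
        assert not np.array_equal(a.data, c.data)

    def test_duration_and_rate(self, fast_config):
        rec = synthesize_eeg(["0"] * 7, fast_config, seed=0)
        assert rec.sampling_rate == fast_config.sampling_rate
        assert rec.n_samples == 7 * fast_config.sampling_rate

    def test_b1_has_slow_eog_sweep(self, fast_config):
        rec = synthesize_eeg(["B1"] * 10, fast_config, seed=1)
        fs = int(rec.sampling_rate)
        heog = rec.data[rec.channel_names.index("HEOG")]
        sweep_power = band_power_oracle(heog, fs, 0.1, 1.0)
        assert sweep_power > 100  # 120 µV sinusoid >> noise floor
        rec0 = synthesize_eeg(["0"] * 10, fast_config, seed=1)
        heog0 = rec0.data[rec0.channel_names.index("HEOG")]
        assert band_power_oracle(heog0, fs, 0.1, 1.0) < sweep_power / 50

    def test_b23_delta_theta_power(self, fast_config):
        rec = synthesize_eeg(["B2/3"] * 5, fast_config, seed=2)
        fs = int(rec.sampling_rate)
        row = rec.channels_with_role("central")[0]
        dt = band_power_oracle(rec.data[row], fs, 2, 7)
        alpha = band_power_oracle(rec.data[row], fs, 8, 12)
        assert dt > 10 * alpha

    def test_rejects_bad_labels(self, fast_config):
        with pytest.raises(ValueError):
            synthesize_eeg(["A1", "XX"], fast_config, seed=0)
        with pytest.raises(ValueError):
            synthesize_eeg([], fast_config, seed=0)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="sampling_rate"):
            SynthesisConfig(sampling_rate=100)
        with pytest.raises(ValueError, match="positive"):
            SynthesisConfig(noise_amp=0)


class TestCohort:
    def test_empty(self):
        table = generate_cohort(CohortParams(n_hyper=0, n_nonhyper=0))
        assert len(table) == 0
        assert {"id", "gender", "dx_class", "mfi_sum", "ids_sr_sum"} <= set(
            table.columns
        )

    def test_published_defaults_gender_counts(self):
        table = generate_cohort(CohortParams(seed=12))
        hyper = table[table.group == "hyperaroused"]
        non = table[table.group == "non_hyperaroused"]
        assert len(hyper) == 19 and len(non) == 41
        assert (hyper.gender == "f").sum() == 14
        assert (non.gender == "f").sum() == 19

    def test_truncation_bounds_held(self):
        for seed in range(5):
            table = generate_cohort(CohortParams(seed=seed))
            hyper = table[table.group == "hyperaroused"]
            non = table[table.group == "non_hyperaroused"]
            assert hyper.ids_sr_sum.between(10, 41).all()
            assert non.ids_sr_sum.between(1, 24).all()
            assert (table.mfi_sum > 40).all()
            assert table.psqi_total.between(0, 21).all()
            assert table.ess_total.between(0, 24).all()

    def test_monte_carlo_moments_at_10k(self):
        params = CohortParams(
            n_hyper=10_000, n_nonhyper=10_000,
            female_hyper=5000, female_non=5000, seed=42,
        )
        table = generate_cohort(params)
        hyper = table[table.group == "hyperaroused"].ids_sr_sum
        non = table[table.group == "non_hyperaroused"].ids_sr_sum
        se_h = 7.3 / np.sqrt(10_000)
        se_n = 6.2 / np.sqrt(10_000)
        assert abs(hyper.mean() - 20.6) < 3 * se_h
        assert abs(non.mean() - 12.6) < 3 * se_n

    def test_matched_truncnorm_moments(self):
        dist = matched_truncnorm(20.6, 7.3, 10, 41)
        assert dist.mean() == pytest.approx(20.6, abs=1e-6)
        assert dist.std() == pytest.approx(7.3, abs=1e-6)
        assert dist.support()[0] >= 10 and dist.support()[1] <= 41

    def test_reproducible(self):
        a = generate_cohort(CohortParams(seed=5))
        b = generate_cohort(CohortParams(seed=5))
        assert a.equals(b)

    def test_infeasible_truncation(self):
        with pytest.raises(ValueError, match="infeasible"):
            CohortParams(ids_min_hyper=42, ids_max_hyper=41)

    def test_female_count_validation(self):
        with pytest.raises(ValueError):
            CohortParams(n_hyper=3, female_hyper=4)
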