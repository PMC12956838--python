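import numpy as np
import pytest

from pupilvalence import (
    GeneratorConfig,
    WaveformParams,
    generate_clean_trace,
    generate_dataset,
    generate_stimulus_set,
    inject_artifacts,
    sample_trial,
)
from pupilvalence.preprocess import preprocess_trial
from pupilvalence.types import ValidationError


class TestStimulusSet:
    def test_default_counts_and_levels(self):
        stimuli = generate_stimulus_set(GeneratorConfig())
        assert sum(s.valence == "positive" for s in stimuli) == 25
        assert sum(s.valence == "negative" for s in stimuli) == 25
        assert {s.sf_level for s in stimuli} == {1, 2, 3, 4, 5}
        assert {s.arousal_level for s in stimuli} == {"low", "mid", "high"}
        assert all(abs(s.mean_luminance - 127.5) < 1.0 for s in stimuli)

    def test_minimal_set(self):
        stimuli = generate_stimulus_set(
            GeneratorConfig(n_positive=1, n_negative=1)
        )
        assert len(stimuli) == 2
        assert all(1 <= s.sf_level <= 5 for s in stimuli)

    def test_determinism(self):
        a = generate_stimulus_set(GeneratorConfig(seed=11))
        b = generate_stimulus_set(GeneratorConfig(seed=11))
        assert [vars(s) for s in a] == [vars(s) for s in b]


class TestCleanTrace:
    def test_null_parameters_give_constant_100(self):
        params = WaveformParams(
            constriction_depth=0, time_to_minimum=50, recovery_tau=100, plateau=100
        )
        np.testing.assert_allclose(generate_clean_trace(params, 360), 100.0)

    def test_closed_form_shape(self):
        params = WaveformParams(
            constriction_depth=20, time_to_minimum=50, recovery_tau=100, plateau=105
        )
        d = generate_clean_trace(params, 360)
        assert d[0] == pytest.approx(100.0)
        assert d.min() == pytest.approx(80.0)
        assert int(np.argmin(d)) + 1 == 50
        # exponential relaxation toward the plateau
        expected_finish = 105 + (80 - 105) * np.exp(-(360 - 50) / 100)
        assert d[-1] == pytest.approx(expected_finish, abs=1e-12)
        assert abs(d[-1] - 105) < 1.2

    def test_depth_linearity(self):
        def min_of(c):
            p = WaveformParams(
                constriction_depth=c, time_to_minimum=50, recovery_tau=100,
                plateau=105,
            )
            return generate_clean_trace(p, 360).min()

        assert 100 - min_of(20) == pytest.approx(2 * (100 - min_of(10)))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            WaveformParams(
                constriction_depth=30, time_to_minimum=50, recovery_tau=100,
                plateau=60,  # below baseline - depth
            )


class TestSampleTrial:
    def _meta(self, valence, sf=14.0, rating=4):
        from pupilvalence import assign_arousal_level, assign_sf_level

        cfg = GeneratorConfig(n_positive=1, n_negative=1)
        stimuli = generate_stimulus_set(cfg)
        m = stimuli[0] if valence == "positive" else stimuli[1]
        m.sf_value, m.arousal_rating = sf, rating
        m.sf_level = assign_sf_level(sf)
        m.arousal_level = assign_arousal_level(rating)
        return m

    def test_null_effect_traces_identical_across_valence(self):
        cfg = GeneratorConfig(valence_effect_size=0.0, noise_sd=0.0)
        pos = self._meta("positive")
        neg = self._meta("negative")
        a = sample_trial(pos, "p1", cfg, seed=5)
        b = sample_trial(neg, "p1", cfg, seed=5)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_valence_separates_aupc_in_population(self):
        # Monte-Carlo over >= 200 trials per class: positive stimuli carry a
        # larger area under the pupil curve at the default effect size
        cfg = GeneratorConfig()
        pos = self._meta("positive")
        neg = self._meta("negative")
        pos_aupc, neg_aupc = [], []
        for i in range(200):
            pid = f"p{i % 20}"
            pos_aupc.append(sample_trial(pos, pid, cfg, seed=2 * i).values.sum())
            neg_aupc.append(sample_trial(neg, pid, cfg, seed=2 * i + 1).values.sum())
        assert np.mean(pos_aupc) > np.mean(neg_aupc)

    def test_higher_sf_lowers_sustained_level(self):
        cfg = GeneratorConfig()
        means = []
        for sf in (6.0, 14.0, 30.0):
            meta = self._meta("positive", sf=sf)
            level = [
                np.mean(
                    100.0
                    * sample_trial(meta, f"p{i}", cfg, seed=i).values[50:]
                    / sample_trial(meta, f"p{i}", cfg, seed=i).baseline
                )
                for i in range(60)
            ]
            means.append(np.mean(level))
        assert means[0] > means[1] > means[2]

    def test_effect_separation_monotone_in_effect_size(self):
        # class separation of mean AUPC grows with the effect-size multiplier
        gaps = []
        for es in (0.5, 1.0, 2.0):
            cfg = GeneratorConfig(valence_effect_size=es)
            pos = self._meta("positive")
            neg = self._meta("negative")
            p = [sample_trial(pos, f"p{i}", cfg, seed=i).values.sum()
                 / sample_trial(pos, f"p{i}", cfg, seed=i).baseline
                 for i in range(200)]
            n = [sample_trial(neg, f"p{i}", cfg, seed=10_000 + i).values.sum()
                 / sample_trial(neg, f"p{i}", cfg, seed=10_000 + i).baseline
                 for i in range(200)]
            gaps.append(np.mean(p) - np.mean(n))
        assert gaps[0] < gaps[1] < gaps[2]


class TestArtifacts:
    def _clean_trial(self, cfg, seed=3):
        stimuli = generate_stimulus_set(cfg)
        return sample_trial(stimuli[0], "p1", cfg, seed=seed)

    def test_zero_rates_return_input_unchanged(self):
        cfg = GeneratorConfig(blink_rate=0.0, spike_rate=0.0)
        trial = self._clean_trial(cfg)
        out = inject_artifacts(trial, cfg, seed=9)
        np.testing.assert_array_equal(out.values, trial.values)

    @pytest.mark.parametrize("dur,valid", [(31, False), (10, True)])
    def test_dropout_duration_drives_exclusion(self, dur, valid):
        cfg = GeneratorConfig(noise_sd=0.5)
        trial = self._clean_trial(cfg)
        values = trial.values.copy()
        values[120 : 120 + dur] *= 0.2  # blink-like dropout below D_RATIO 40
        trial.values = values
        trace, _ = preprocess_trial(trial)
        assert trace.valid == valid

    def test_injected_missing_fraction_matches_rate(self):
        # expected missing fraction ~ blink_rate * mean duration / frames
        cfg = GeneratorConfig(blink_rate=1.5, spike_rate=0.0, noise_sd=0.0)
        trial = self._clean_trial(cfg)
        fracs = []
        for s in range(300):
            out = inject_artifacts(trial, cfg, seed=s)
            dropped = np.mean(out.values < 0.5 * trial.values)
            fracs.append(dropped)
        lo, hi = np.array(cfg.blink_duration_range)
        expected = cfg.blink_rate * (lo + hi) / 2.0 / cfg.frames_per_trial
        assert np.mean(fracs) == pytest.approx(expected, rel=0.2)

    def test_determinism(self):
        cfg = GeneratorConfig()
        trial = self._clean_trial(cfg)
        a = inject_artifacts(trial, cfg, seed=4)
        b = inject_artifacts(trial, cfg, seed=4)
        np.testing.assert_array_equal(a.values, b.values)


class TestDataset:
    def test_trial_count_matches_design(self):
        cfg = GeneratorConfig(n_participants=2, n_positive=2, n_negative=2)
        trials, stimuli = generate_dataset(cfg)
        assert len(trials) == 8 and len(stimuli) == 4

    def test_same_seed_reproduces_exactly(self):
        cfg = GeneratorConfig(n_participants=3, n_positive=3, n_negative=3, seed=77)
        t1, s1 = generate_dataset(cfg)
        t2, s2 = generate_dataset(cfg)
        assert [vars(a) for a in s1] == [vars(b) for b in s2]
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.values, b.values)
            assert a.baseline == b.baseline
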