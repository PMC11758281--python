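"""Generator structure, determinism, and planted-effect recoverability."""

import numpy as np

from eegrep import (
    GeneratorConfig,
    SubjectParams,
    draw_subject,
    erp_template,
    generate_epoch,
    generate_experiment,
    generate_trial,
    read_trials,
    simulate_answer,
    write_trials,
)
from eegrep.data_model import EMPTY
from eegrep.synthetic_data import attend_probability


def unit_subject(config, **overrides) -> SubjectParams:
    """A deterministic subject with no idiosyncrasies."""
    params = dict(
        channel_gains=np.ones(config.n_channels),
        latency_jitter_ms=0.0,
        noise_sd=0.0,
        p_attend_base=0.9,
        condition_effects={c: 0.0 for c in config.conditions},
        rhythm_helpfulness=0.0,
    )
    params.update(overrides)
    return SubjectParams(**params)


class TestDrawSubject:
    def test_deterministic_given_seed(self):
        config = GeneratorConfig(n_channels=8)
        a = draw_subject(config, 123)
        b = draw_subject(config, 123)
        np.testing.assert_array_equal(a.channel_gains, b.channel_gains)
        assert a.condition_effects == b.condition_effects

    def test_full_majority_makes_all_c3_effects_positive(self):
        config = GeneratorConfig(n_channels=4, c3_majority_fraction=1.0)
        effects = [draw_subject(config, s).condition_effects["C3"] for s in range(40)]
        assert all(e > 0 for e in effects)

    def test_rhythm_effect_has_mixed_sign_across_subjects(self):
        config = GeneratorConfig(n_channels=4)
        signs = {np.sign(draw_subject(config, s).condition_effects["C2"]) for s in range(60)}
        assert signs == {-1.0, 1.0}

    def test_zero_noise_config_gives_noiseless_subjects(self):
        config = GeneratorConfig(n_channels=4, noise_sd=0.0)
        assert draw_subject(config, 5).noise_sd == 0.0

    def test_attend_probability_clamped(self):
        config = GeneratorConfig(n_channels=4)
        subject = unit_subject(config, p_attend_base=0.999,
                               condition_effects={"C1": 50.0})
        assert attend_probability(subject, "C1") == 0.98


class TestGenerateTrial:
    def test_exactly_five_targets_and_five_distractors(self):
        config = GeneratorConfig(n_channels=4)
        subject = unit_subject(config)
        for seed in range(20):
            trial = generate_trial(subject, "C1", 0, config, seed)
            kinds = [k for _, k in trial.stimuli]
            assert kinds.count("Target") == 5
            assert kinds.count("Distractor") == 5

    def test_perfect_attention_reports_targets_in_order(self):
        config = GeneratorConfig(n_channels=4, intrusion_rate=0.0,
                                 attend_prob_clamp=(0.05, 1.0))
        subject = unit_subject(config, p_attend_base=1.0)
        trial = generate_trial(subject, "C1", 0, config, 3)
        assert trial.answer == "".join(str(d) for d in trial.targets)

    def test_zero_attention_gives_empty_answer(self):
        config = GeneratorConfig(n_channels=4, intrusion_rate=0.0,
                                 attend_prob_clamp=(0.0, 0.98))
        subject = unit_subject(config, p_attend_base=1e-12)
        trial = generate_trial(subject, "C1", 0, config, 3)
        assert trial.answer == ""
        assert not any(trial.attend_flags)

    def test_all_distractors_empty_when_forced(self):
        config = GeneratorConfig(n_channels=4, p_empty_distractor=1.0)
        trial = generate_trial(unit_subject(config), "C1", 0, config, 11)
        assert all(d == EMPTY for d in trial.distractors)


class TestSimulateAnswer:
    def test_omits_unattended_targets(self):
        stimuli = [(8, "Target"), (6, "Target"), (9, "Target"), (7, "Target"), (4, "Target")]
        flags = [True, True, True, False, True]
        assert simulate_answer(stimuli, flags, 0.0) == "8694"

    def test_no_intrusions_means_targets_only(self):
        rng = np.random.default_rng(0)
        stimuli = [(1, "Target"), (2, "Distractor"), (3, "Target"), (4, "Distractor")]
        flags = [True, False, True, False]
        assert simulate_answer(stimuli, flags, 0.0, rng) == "13"

    def test_certain_intrusion_inserts_at_relative_position(self):
        rng = np.random.default_rng(0)
        stimuli = [(1, "Target"), (2, "Distractor"), (3, "Target")]
        flags = [True, False, True]
        assert simulate_answer(stimuli, flags, 1.0, rng) == "123"


class TestGenerateEpoch:
    def test_null_model_ignores_kind_and_attention(self):
        config = GeneratorConfig(n_channels=8, p300_target_boost=0.0,
                                 p300_attention_scaling=0.0, noise_sd=0.0)
        subject = unit_subject(config)
        target = generate_epoch("Target", True, "C1", subject, config, 0)
        distractor = generate_epoch("Distractor", False, "C1", subject, config, 0)
        np.testing.assert_array_equal(target.values, distractor.values)

    def test_target_boost_raises_p3_window_peak(self):
        config = GeneratorConfig(n_channels=16, p300_target_boost=5.0,
                                 p300_attention_scaling=0.0, noise_sd=0.0)
        subject = unit_subject(config)
        target = generate_epoch("Target", False, "C1", subject, config, 0)
        distractor = generate_epoch("Distractor", False, "C1", subject, config, 0)
        p3_channel = 13  # near the parieto-occipital profile centre (0.85 * 15)
        window = slice(22, 36)
        assert target.values[p3_channel, window].max() > distractor.values[p3_channel, window].max()

    def test_mean_over_epochs_recovers_template(self):
        config = GeneratorConfig(n_channels=8, noise_sd=6.0)
        subject = unit_subject(config, noise_sd=6.0)
        n = 600
        epochs = np.stack([
            generate_epoch("Target", True, "C1", subject, config, [9, i]).values
            for i in range(n)
        ])
        template = erp_template("Target", True, subject, config)
        se = 6.0 / np.sqrt(n)
        deviation = np.abs(epochs.mean(axis=0) - template)
        # per-entry 3*SE covers ~99.7% of entries; allow the expected tail
        assert np.mean(deviation <= 3 * se) > 0.99
        assert deviation.max() <= 6 * se

    def test_different_seeds_differ_with_noise(self):
        config = GeneratorConfig(n_channels=4, noise_sd=5.0)
        subject = unit_subject(config, noise_sd=5.0)
        a = generate_epoch("Target", True, "C1", subject, config, 1)
        b = generate_epoch("Target", True, "C1", subject, config, 2)
        assert not np.array_equal(a.values, b.values)


class TestGenerateExperiment:
    def test_epoch_counts_and_shapes(self, small_config, small_experiment):
        epochset, trials = small_experiment
        per_participant = small_config.n_sequences * small_config.seq_length * len(small_config.conditions)
        assert len(epochset) == small_config.n_participants * per_participant
        assert per_participant == 160
        epoch, _ = epochset.epochs[0]
        assert epoch.values.shape == (small_config.n_channels, small_config.n_steps)
        assert len(trials) == small_config.n_participants * small_config.n_sequences * len(small_config.conditions)

    def test_same_seed_reproduces_exactly(self, small_config, small_experiment):
        epochset, trials = small_experiment
        again_set, again_trials = generate_experiment(small_config)
        np.testing.assert_array_equal(epochset.values_array(), again_set.values_array())
        assert trials == again_trials

    def test_metadata_attended_matches_trial_flags(self, small_experiment):
        epochset, trials = small_experiment
        by_key = {
            (t.participant_id, t.condition, t.sequence_index): t for t in trials
        }
        for _, meta in epochset:
            trial = by_key[(meta.participant_id, meta.condition, meta.sequence_index)]
            assert meta.attended == trial.attend_flags[meta.position - 1]
            assert meta.digit == trial.stimuli[meta.position - 1][0]

    def test_amplitudes_clipped(self, small_experiment):
        values = small_experiment[0].values_array()
        assert values.min() >= -50.0 and values.max() <= 50.0

    def test_exchangeable_when_all_effects_zero(self):
        """Permutation test: with no planted effects, Target and Distractor
        epochs are statistically indistinguishable (alpha = 0.01)."""
        config = GeneratorConfig(
            n_participants=1, n_sequences=10, n_channels=8,
            p300_target_boost=0.0, p300_attention_scaling=0.0, seed=21,
        )
        epochset, _ = generate_experiment(config)
        values = epochset.values_array()
        labels = np.array([meta.kind == "Target" for _, meta in epochset])
        assert len(labels) >= 200
        # statistic: mean P3-window amplitude difference between groups
        stat = values[:, :, 22:36].mean(axis=(1, 2))
        observed = abs(stat[labels].mean() - stat[~labels].mean())
        rng = np.random.default_rng(0)
        permuted = []
        for _ in range(500):
            shuffled = rng.permutation(labels)
            permuted.append(abs(stat[shuffled].mean() - stat[~shuffled].mean()))
        p_value = np.mean(np.asarray(permuted) >= observed)
        assert p_value > 0.01


class TestTrialIO:
    def test_round_trip(self, small_experiment, tmp_path):
        _, trials = small_experiment
        write_trials(trials, tmp_path / "trials.csv")
        assert read_trials(tmp_path / "trials.csv") == trials
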