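"""Session generator: condition grids, Poisson spiking, observer, eye traces."""

import numpy as np
import pytest

from motioncue.stimuli import make_trajectory
from motioncue.synthetic_data import (
    DEFAULT_CATEGORY_MIX,
    NeuronModel,
    ObserverModel,
    TaskConfig,
    plant_population,
    simulate_behavior,
    simulate_eye_trace,
    simulate_session,
)


class TestTaskConfig:
    def test_clarity_ladder_validated(self):
        with pytest.raises(ValueError):
            TaskConfig(clarity_levels=(0.1, 0.5, 1.0))
        with pytest.raises(ValueError):
            TaskConfig(clarity_levels=(0.0, 0.5, 0.3, 1.0))

    def test_motion_map_validated(self):
        with pytest.raises(ValueError):
            TaskConfig(motion_map={"blob": "circular", "spikey": "circular",
                                   "shared": "bimodal"})


class TestSessionStructure:
    def test_completed_active_trial_count(self, small_session, small_config):
        act = small_session.trials.query("phase == 'active' and not aborted")
        assert len(act) == small_config.blocks * small_config.trials_per_block

    def test_condition_balance_within_blocks(self, small_session):
        act = small_session.trials.query("phase == 'active' and not aborted")
        cells = act.groupby(["block", "shape_category", "clarity",
                             "motion_role"]).size()
        assert cells.nunique() == 1  # every cell its configured repetitions
        sides = act.groupby("correct_side").size()
        assert sides["left"] == sides["right"]

    def test_aborted_trials_reappear(self, small_session):
        act = small_session.trials.query("phase == 'active'")
        n_aborted = int(act["aborted"].sum())
        assert len(act) == len(act.query("not aborted")) + n_aborted

    def test_same_seed_is_bitwise_identical(self, small_config,
                                            planted_neurons):
        a = simulate_session(small_config, planted_neurons, seed=5,
                             simulate_eye=False)
        b = simulate_session(small_config, planted_neurons, seed=5,
                             simulate_eye=False)
        assert a.trials.equals(b.trials)
        for nid in a.spikes:
            for tid in a.spikes[nid]:
                np.testing.assert_array_equal(
                    a.spikes[nid][tid], b.spikes[nid][tid]
                )

    def test_spike_times_within_trial_bounds(self, small_session):
        cfg = small_session.config
        hi = cfg.target_ms + cfg.delay_ms
        for by_trial in small_session.spikes.values():
            for t in by_trial.values():
                if len(t):
                    assert t.min() >= -cfg.pre_window_ms
                    assert t.max() <= hi


class TestPoissonSpiking:
    def test_unit_gain_neuron_matches_poisson_mean(self):
        # all gains 1: counts in any window are Poisson(baseline * width)
        cfg = TaskConfig(blocks=0, passive_clarity_reps=100,
                         passive_motion_reps=0)
        neuron = NeuronModel(neuron_id=0, baseline_hz=20.0, visual_gain=1.0,
                             clarity_strength=0.0)
        s = simulate_session(cfg, [neuron], seed=3, simulate_eye=False)
        tids = s.trials.query("phase == 'passive_clarity'")["trial_id"]
        counts = np.array([
            np.count_nonzero((s.spikes[0][t] >= 0) & (s.spikes[0][t] < 300))
            for t in tids
        ])
        assert len(counts) == 1000
        mean_expected = 20.0 * 0.3
        se = np.sqrt(mean_expected / len(counts))
        assert abs(counts.mean() - mean_expected) <= 3 * se
        # Fano factor of a Poisson count is 1
        assert abs(counts.var(ddof=1) / counts.mean() - 1.0) < 0.2


class TestObserver:
    def test_forced_choice_extremes(self):
        obs = ObserverModel(motion_association=1.0, lapse=0.0)
        assert obs.p_correct(0.0, "predictive") == pytest.approx(1.0)
        obs2 = ObserverModel(lapse=0.0)
        assert obs2.p_correct(1.0, "static") == pytest.approx(1.0)
        assert obs2.p_correct(1.0, "shared") == pytest.approx(1.0)

    def test_zero_clarity_uninformative_is_chance(self):
        obs = ObserverModel(lapse=0.0)
        assert obs.p_correct(0.0, "shared") == pytest.approx(0.5)
        assert obs.p_correct(0.0, "static") == pytest.approx(0.5)

    def test_zero_clarity_reward_rule(self):
        cfg = TaskConfig()
        obs = ObserverModel()
        rng = np.random.default_rng(0)
        rewarded = [
            simulate_behavior(cfg, obs, 0.0, "static", "left", rng)[1]
            for _ in range(4000)
        ]
        frac = np.mean(rewarded)
        se = np.sqrt(0.25 / len(rewarded))
        assert abs(frac - 0.5) <= 3 * se

    def test_accuracy_monotone_in_clarity_for_uninformative_motion(self):
        obs = ObserverModel()
        ps = [obs.p_correct(c, "shared") for c in (0.0, 0.3, 0.5, 0.8, 1.0)]
        assert all(b >= a for a, b in zip(ps, ps[1:]))
        # predictive motion keeps accuracy near ceiling at all clarities
        pp = [obs.p_correct(c, "predictive") for c in (0.0, 0.5, 1.0)]
        assert min(pp) > 0.85


class TestEyeTraces:
    def test_perfect_pursuit_equals_lowpass_trajectory(self):
        tr = make_trajectory("circular")
        rng = np.random.default_rng(0)
        eye = simulate_eye_trace(tr, pursuit_gain=1.0, noise_sd_deg=0.0,
                                 drift_sd_deg=0.0, rng=rng)
        # reproduce the causal low-pass reference
        from motioncue.synthetic_data import _lowpass

        t = eye[:, 0]
        ref_x = _lowpass(np.interp(t, tr.t_ms, tr.positions[:, 0]),
                         1.0 / 200.0, 0.08)
        np.testing.assert_allclose(eye[:, 1], ref_x, atol=1e-12)

    def test_zero_gain_average_is_flat(self):
        tr = make_trajectory("circular")
        rng = np.random.default_rng(1)
        traces = [
            simulate_eye_trace(tr, 0.0, noise_sd_deg=0.2, drift_sd_deg=0.0,
                               rng=rng)[:, 1]
            for _ in range(300)
        ]
        mean = np.mean(traces, axis=0)
        assert np.ptp(mean) < 0.1  # flat up to averaged noise

    def test_gain_shrinks_with_clarity_schedule(self):
        obs = ObserverModel()
        assert obs.pursuit_gain(0.0) < obs.pursuit_gain(1.0)

    def test_invalid_gain_rejected(self):
        tr = make_trajectory("circular")
        with pytest.raises(ValueError):
            simulate_eye_trace(tr, pursuit_gain=1.5)


class TestPlantPopulation:
    def test_largest_remainder_rounding(self):
        props = {"A": 0.46, "B": 0.33, "C": 0.09, "D": 0.12}
        pop = plant_population(props, 50, seed=0)
        counts = {}
        for n in pop:
            counts[n.category] = counts.get(n.category, 0) + 1
        # independent largest-remainder oracle
        quotas = {k: v * 50 for k, v in props.items()}
        base = {k: int(np.floor(q)) for k, q in quotas.items()}
        rem = 50 - sum(base.values())
        order = sorted(props, key=lambda k: -(quotas[k] - base[k]))
        for k in order[:rem]:
            base[k] += 1
        assert counts == base

    def test_uniform_four(self):
        pop = plant_population({"A": 0.25, "B": 0.25, "C": 0.25, "D": 0.25},
                               4, seed=0)
        assert sorted(n.category for n in pop) == ["A", "B", "C", "D"]

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            plant_population({"A": 0.5, "B": 0.6}, 10, seed=0)

    def test_seeded_determinism(self):
        a = plant_population(DEFAULT_CATEGORY_MIX, 10, seed=4)
        b = plant_population(DEFAULT_CATEGORY_MIX, 10, seed=4)
        assert [n.baseline_hz for n in a] == [n.baseline_hz for n in b]


class TestRatePositivity:
    def test_no_negative_gains(self):
        n = NeuronModel(neuron_id=0, clarity_label="suppressed",
                        clarity_strength=2.0)  # would dip negative unrectified
        for c in (0.0, 0.3, 0.5, 0.8, 1.0):
            assert n.clarity_gain("blob", c) >= 0.0
            assert n.stimulus_gain("spikey", c) >= 0.0
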