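"""Clarity tuning metrics: curves, ECF, MI, principal values, screening."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import build_session, passive_clarity_trials
from motioncue.synthetic_data import (
    NeuronModel,
    TaskConfig,
    plant_population,
    simulate_session,
)
from motioncue.tuning import (
    ECFResult,
    classify_quadrant,
    compute_pvs,
    compute_tuning_curve,
    external_clarity_factor,
    modulation_index,
    population_clarity_metrics,
    relative_response,
    screen_task_relevant,
)

LEVELS = (0.0, 0.3, 0.5, 0.8, 1.0)


def _clarity_only_config(reps=50) -> TaskConfig:
    return TaskConfig(blocks=0, passive_clarity_reps=reps,
                      passive_motion_reps=0)


class TestTuningCurve:
    def test_hand_counted_rates(self):
        # 3 trials per cell with known spike counts in [0, 300)
        trials = passive_clarity_trials(LEVELS, reps=3)
        spike_map = {0: {}}
        expected = {}
        k = 0
        for tid, row in zip(trials["trial_id"],
                            trials.itertuples(index=False)):
            n_spk = k % 4  # 0..3 spikes inside the window
            spike_map[0][tid] = [10.0 + 5 * i for i in range(n_spk)] + [350.0]
            expected.setdefault((row.shape_category, row.clarity),
                                []).append(n_spk)
            k += 1
        s = build_session(spike_map, trials)
        curve = compute_tuning_curve(s, 0)
        for i, c in enumerate(curve.clarity_levels):
            for shape in ("blob", "spikey"):
                manual = np.mean(expected[(shape, c)]) / 0.3
                assert curve.rates[shape][i] == pytest.approx(manual)

    def test_zero_spikes_zero_rates(self):
        trials = passive_clarity_trials(LEVELS, reps=2)
        s = build_session({0: {}}, trials)
        curve = compute_tuning_curve(s, 0)
        for shape in ("blob", "spikey"):
            np.testing.assert_array_equal(curve.rates[shape], 0.0)

    def test_planted_enhancement_recovered(self):
        cfg = _clarity_only_config(reps=50)
        neuron = NeuronModel(neuron_id=0, clarity_label="enhanced",
                             clarity_strength=0.7)
        s = simulate_session(cfg, [neuron], seed=2, simulate_eye=False)
        curve = compute_tuning_curve(s, 0)
        from scipy.stats import spearmanr

        for shape in ("blob", "spikey"):
            rho = spearmanr(curve.rates[shape], curve.clarity_levels).statistic
            assert rho < 0  # rate rises as clarity falls


class TestRelativeResponse:
    def test_arithmetic(self):
        trials = passive_clarity_trials((0.0, 0.5, 1.0), reps=1)
        spike_map = {0: {}}
        per_clarity = {0.0: 2, 0.5: 5, 1.0: 4}  # spike counts -> rate/0.3
        for tid, row in zip(trials["trial_id"],
                            trials.itertuples(index=False)):
            n = per_clarity[row.clarity]
            spike_map[0][tid] = list(np.linspace(1, 299, n))
        cfg = TaskConfig(clarity_levels=(0.0, 0.5, 1.0))
        s = build_session(spike_map, trials, config=cfg)
        curve = compute_tuning_curve(s, 0)
        rel = relative_response(curve)
        for shape in ("blob", "spikey"):
            np.testing.assert_allclose(
                rel[shape] * 0.3, [-2.0, 1.0, 0.0], atol=1e-9
            )

    def test_flat_curve_all_zero_and_anchor(self):
        trials = passive_clarity_trials(LEVELS, reps=2)
        spike_map = {0: {int(t): [50.0, 150.0] for t in trials["trial_id"]}}
        s = build_session(spike_map, trials)
        rel = relative_response(compute_tuning_curve(s, 0))
        for shape in ("blob", "spikey"):
            np.testing.assert_array_equal(rel[shape], 0.0)


class TestECF:
    def test_argmax_of_absolute_deviation(self):
        dev = np.array([-1.0, 3.0, 2.0, 0.0])
        levels = np.array([0.0, 0.3, 0.7, 1.0])
        assert external_clarity_factor(dev, levels) == ECFResult(0.3, False)

    def test_monotone_curve_gives_lowest_clarity(self):
        dev = np.array([-4.0, -2.5, -1.0, 0.0])
        levels = np.array([0.0, 0.5, 0.8, 1.0])
        assert external_clarity_factor(dev, levels).clarity == 0.0

    def test_tie_broken_toward_lowest_clarity(self):
        dev = np.array([2.0, -2.0, 0.0])
        levels = np.array([0.0, 0.5, 1.0])
        assert external_clarity_factor(dev, levels).clarity == 0.0

    def test_no_modulation_flag(self):
        res = external_clarity_factor(np.zeros(5), np.array(LEVELS))
        assert res.no_modulation and res.clarity == 1.0


class TestModulationIndex:
    def test_hand_integration(self):
        dev = np.array([2.0, 2.0, 0.0])
        levels = np.array([0.0, 0.5, 1.0])
        assert modulation_index(dev, levels) == pytest.approx(1.5)

    def test_flat_zero(self):
        assert modulation_index(np.zeros(5), np.array(LEVELS)) == 0.0

    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=5))
    def test_linearity_under_negation(self, dev):
        dev = np.array(dev)
        levels = np.array(LEVELS)
        assert modulation_index(-dev, levels) == pytest.approx(
            -modulation_index(dev, levels)
        )


class TestPVs:
    def test_identical_curves_single_component(self):
        dev = np.tile([3.0, 2.0, 1.0, 0.5, 0.0], (6, 1))
        pvs = compute_pvs(dev, np.array(LEVELS))
        assert np.allclose(pvs, pvs[0])
        # one component carries all structure: projections reconstruct rows
        assert pvs[0] != 0.0

    def test_planted_sign_recovery(self):
        rng = np.random.default_rng(0)
        base = np.array([4.0, 3.0, 2.0, 1.0, 0.0])
        enhanced = base + rng.normal(0, 0.4, size=(10, 5))
        suppressed = -base + rng.normal(0, 0.4, size=(10, 5))
        dev = np.vstack([enhanced, suppressed])
        dev[:, -1] = 0.0  # anchored at full clarity
        pvs = compute_pvs(dev, np.array(LEVELS))
        labels = np.r_[np.ones(10), -np.ones(10)]
        assert (np.sign(pvs) == labels).sum() >= 18

    def test_sign_is_deterministic_and_mi_aligned(self):
        rng = np.random.default_rng(1)
        dev = rng.normal(size=(12, 5))
        dev[:, -1] = 0.0
        a = compute_pvs(dev, np.array(LEVELS))
        b = compute_pvs(dev, np.array(LEVELS))
        np.testing.assert_array_equal(a, b)
        mi = [modulation_index(row, np.array(LEVELS)) for row in dev]
        assert np.corrcoef(a, mi)[0, 1] > 0

    def test_zero_row_assigned_zero(self):
        dev = np.array([[1.0, 0.5, 0.0], [0.0, 0.0, 0.0], [-1.0, -0.5, 0.0]])
        pvs = compute_pvs(dev, np.array([0.0, 0.5, 1.0]))
        assert pvs[1] == 0.0

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ValueError):
            compute_pvs(np.array([[1.0, 0.0]]), np.array([0.0, 1.0]))


class TestQuadrants:
    @pytest.mark.parametrize("pv_b,pv_s,cat", [
        (0.3, 0.2, "A"),
        (-0.1, -0.4, "B"),
        (0.2, -0.3, "C"),
        (-0.2, 0.3, "D"),
        (0.0, 0.1, "D"),   # exact zero counts as negative
        (0.1, 0.0, "C"),
        (0.0, 0.0, "B"),
    ])
    def test_quadrant_rule(self, pv_b, pv_s, cat):
        assert classify_quadrant(pv_b, pv_s) == cat

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_quadrant(np.nan, 0.1)


class TestInvariance:
    def test_constant_rate_offset_leaves_metrics_unchanged(self):
        # deviations subtract the full-clarity response, so a uniform rate
        # shift cancels in ECF, MI and PVs
        rng = np.random.default_rng(2)
        dev = rng.normal(size=(8, 5))
        dev[:, -1] = 0.0
        rates = dev + 10.0
        shifted = rates + 7.5
        d1 = rates - rates[:, -1:]
        d2 = shifted - shifted[:, -1:]
        np.testing.assert_allclose(d1, d2)
        np.testing.assert_allclose(
            compute_pvs(d1, np.array(LEVELS)), compute_pvs(d2, np.array(LEVELS))
        )


class TestPopulationMetrics:
    def test_category_recovery_on_planted_population(self):
        cfg = _clarity_only_config(reps=30)
        pop = plant_population(
            {"A": 0.25, "B": 0.25, "C": 0.25, "D": 0.25}, 24, seed=3
        )
        s = simulate_session(cfg, pop, seed=7, simulate_eye=False)
        curves = [compute_tuning_curve(s, n.neuron_id) for n in pop]
        table = population_clarity_metrics(curves)
        planted = [n.category for n in pop]
        agree = (table["category"].to_numpy() == planted).mean()
        assert agree >= 0.85


class TestScreening:
    def test_planted_visual_response_is_relevant(self, small_session):
        relevant, pvals = screen_task_relevant(small_session, 0)
        assert relevant
        assert len(pvals) == 5
        assert min(pvals.values()) < 0.008

    def test_silent_neuron_not_relevant(self):
        trials = []
        import pandas as pd

        rows = []
        for tid in range(20):
            rows.append(dict(
                trial_id=tid, phase="active", block=0, shape_category="blob",
                pair_id=0, clarity=1.0, motion_kind="static",
                motion_role="static", correct_side="left",
                response_side="left", correct=True, rewarded=True,
                reaction_ms=500.0, aborted=False,
            ))
        s = build_session({0: {}}, pd.DataFrame(rows))
        relevant, pvals = screen_task_relevant(s, 0)
        assert not relevant
        assert all(p == 1.0 for p in pvals.values())

    def test_null_false_positive_rate_calibrated(self):
        # flat Poisson neuron: P(any of 5 windows < alpha) ~ 5 * alpha
        from scipy import stats

        rng = np.random.default_rng(4)
        n_rep, n_trials, alpha = 2000, 100, 0.008
        # rates in 150 ms windows at 20 Hz and the 200 ms baseline
        flagged = 0
        base = rng.poisson(4.0, size=(n_rep, n_trials)) / 0.2
        for w in range(5):
            resp = rng.poisson(3.0, size=(n_rep, n_trials)) / 0.15
            p = stats.ttest_ind(resp, base, axis=1, equal_var=False).pvalue
            flagged = flagged | (p < alpha) if w else (p < alpha)
        frac = flagged.mean()
        expected = 1 - (1 - alpha) ** 5
        se = np.sqrt(expected * (1 - expected) / n_rep)
        assert abs(frac - expected) <= 3 * se
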