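"""Repeatability analysis: temporal-resolution estimation."""

import numpy as np
import pytest
from scipy import stats

from spiketexture.data_model import AnalysisWindow, SpikeTrain
from spiketexture.metrics import VpCost
from spiketexture.precision import (
    PrecisionModel,
    cross_repeat_distance,
    estimate_resolution,
    estimate_resolution_from_curve,
    rate_normalized_comparison,
    select_jitter_base,
    xintercept_resolution,
)
from spiketexture.surrogates import default_jitter_grid, poisson_surrogate
from spiketexture.synthetic import NeuronSpec, StudyConfig, TrialSimulator, make_templates, simulate_study

W = AnalysisWindow(start=0.0)


def _train(times, rep=0):
    return SpikeTrain("n", "t", rep, 80.0, np.asarray(times, dtype=float))


class TestCrossRepeatDistance:
    def test_identical_repeats_zero(self):
        t = _train([10.0, 50.0])
        assert cross_repeat_distance([t, _train([10.0, 50.0], 1)]) == 0.0

    def test_mean_over_all_unique_pairs(self):
        # 5 repeats -> C(5,2) = 10 pairs; distances are 0/1 by count diff at q=0
        reps = [_train([1.0] * 1 if i < 4 else [1.0, 2.0], i) for i in range(5)]
        # 4 singles + 1 double: 6 pairs distance 0, 4 pairs distance 1
        got = cross_repeat_distance(reps, VpCost(0))
        assert got == pytest.approx(4 / 10)

    def test_requires_two_repeats(self):
        with pytest.raises(ValueError):
            cross_repeat_distance([_train([1.0])])

    def test_monotone_in_planted_jitter(self):
        tpl = make_templates(2, 41)[0]
        out = {}
        for sigma in (2.0, 20.0):
            vals = []
            for i in range(50):
                spec = NeuronSpec("n", 60.0, 10.0, sigma, 0.9, (0.3, 0.3, 0.4))
                sim = TrialSimulator(spec, tpl, [80.0], [41, 4, i, 0], rate_offset=0.0)
                vals.append(cross_repeat_distance([sim.trial(80.0, k) for k in range(5)]))
            out[sigma] = np.array(vals)
        assert out[2.0].mean() < out[20.0].mean()


class TestBracketingRule:
    def test_printed_worked_example(self):
        est, flag = estimate_resolution_from_curve(15.0, [1.0, 2.0], [13.0, 21.0])
        assert est == 1.5 and flag == ""

    def test_censoring_below_grid(self):
        est, flag = estimate_resolution_from_curve(1.0, [1.0, 2.0, 4.0], [5.0, 9.0, 14.0])
        assert est == 1.0 and flag == "low"

    def test_censoring_above_grid(self):
        est, flag = estimate_resolution_from_curve(99.0, [1.0, 2.0, 4.0], [5.0, 9.0, 14.0])
        assert est == 4.0 and flag == "high"

    def test_first_crossing_on_nonmonotone_curve(self):
        est, _ = estimate_resolution_from_curve(10.0, [1, 2, 4, 8], [8, 12, 9, 15])
        assert est == 1.5  # first bracket [8, 12]

    def test_base_selection_max_count_lowest_index_tie(self):
        reps = [_train([1.0, 2.0], 0), _train([1.0, 2.0], 1), _train([1.0], 2)]
        assert select_jitter_base(reps).repeat_index == 0
        assert select_jitter_base(reps, policy="add").repeat_index == 2


class TestResolutionRecovery:
    @pytest.mark.parametrize("sigma", [1.0, 5.0, 20.0])
    def test_recovers_planted_jitter_within_one_grid_step(self, sigma):
        grid = default_jitter_grid()  # 12 log-spaced levels, ratio ~2
        step = np.log(grid[1] / grid[0])
        tpls = make_templates(8, 51)
        spec = NeuronSpec("n", 60.0, 10.0, sigma, 0.9, (0.3, 0.3, 0.4))
        ests = []
        for j, tpl in enumerate(tpls):
            sim = TrialSimulator(spec, tpl, [80.0], [51, 4, 0, j], rate_offset=0.0)
            reps = [sim.trial(80.0, k) for k in range(5)]
            est, _ = estimate_resolution(reps, grid, seed=j, window=W)
            ests.append(est)
        med = np.median(ests)
        assert abs(np.log(med / sigma)) <= step + 1e-9

    def test_poisson_estimates_worse_than_patterned(self):
        """Rate-matched Poisson data yield systematically larger (worse)
        resolutions than patterned data with sigma <= 5 ms."""
        grid = default_jitter_grid()
        tpls = make_templates(5, 61)
        rng = np.random.default_rng(61)
        patterned, poisson = [], []
        for i in range(30):
            spec = NeuronSpec(
                f"n{i}", float(rng.uniform(30, 90)), 10.0,
                float(rng.uniform(0.5, 5.0)), 0.85, (0.3, 0.3, 0.4),
            )
            sim = TrialSimulator(spec, tpls[i % 5], [80.0], [61, 4, 0, i])
            reps = [sim.trial(80.0, k) for k in range(5)]
            est, _ = estimate_resolution(reps, grid, seed=i, window=W)
            patterned.append(est)
            rate = np.mean([len(t) for t in reps]) / 0.5
            preps = [poisson_surrogate(rate, W, rng, repeat_index=k) for k in range(5)]
            est_p, _ = estimate_resolution(preps, grid, seed=i, window=W)
            poisson.append(est_p)
        assert np.median(poisson) > np.median(patterned)
        assert stats.wilcoxon(poisson, patterned, alternative="greater").pvalue < 0.01

    def test_count_doubling_shifts_estimate_by_at_most_one_step(self):
        """Superposing two independent draws of the same neuron leaves the
        recovered resolution within one grid step."""
        grid = default_jitter_grid()
        step = np.log(grid[1] / grid[0])
        tpls = make_templates(6, 71)
        spec = NeuronSpec("n", 50.0, 10.0, 4.0, 0.9, (0.3, 0.3, 0.4))
        e1, e2 = [], []
        for j, tpl in enumerate(tpls):
            sim_a = TrialSimulator(spec, tpl, [80.0], [71, 4, 0, j], rate_offset=0.0)
            sim_b = TrialSimulator(spec, tpl, [80.0], [71, 4, 1, j], rate_offset=0.0)
            reps, doubled = [], []
            for k in range(5):
                a, b = sim_a.trial(80.0, k), sim_b.trial(80.0, k)
                reps.append(a)
                merged = np.unique(np.concatenate([a.times, b.times]))
                doubled.append(SpikeTrain("n", "t", k, 80.0, merged))
            est1, _ = estimate_resolution(reps, grid, seed=j, window=W)
            est2, _ = estimate_resolution(doubled, grid, seed=j, window=W)
            e1.append(est1)
            e2.append(est2)
        assert abs(np.log(np.median(e2) / np.median(e1))) <= step + 1e-9


class TestRateNormalizedComparison:
    def test_difference_is_rate_normalized_gap(self):
        """The curve equals (simulated - measured)/rate per level and is 0
        where the surrogate distance matches the measured one."""
        from spiketexture.precision import surrogate_distance_curve

        tpl = make_templates(2, 80)[0]
        spec = NeuronSpec("n", 60.0, 10.0, 3.0, 0.9, (0.3, 0.3, 0.4))
        sim = TrialSimulator(spec, tpl, [80.0], [80, 4, 0, 0], rate_offset=0.0)
        reps = [sim.trial(80.0, k) for k in range(5)]
        grid = np.array([1.0, 5.0, 25.0])
        curve = rate_normalized_comparison(reps, grid, seed=7, window=W)
        surr = surrogate_distance_curve(
            reps, grid, VpCost(500), np.random.default_rng(7), window=W
        )
        rate = np.mean([len(t) for t in reps]) / 0.5
        measured = cross_repeat_distance(reps)
        expected = surr / rate - measured / rate
        assert np.allclose(curve["difference"].to_numpy(), expected)
        assert np.allclose(
            curve["difference"].to_numpy() * rate + measured, surr
        )  # zero difference exactly where surr == measured

    def test_monotone_curve_and_xintercept(self):
        tpl = make_templates(2, 81)[0]
        spec = NeuronSpec("n", 60.0, 10.0, 2.0, 0.9, (0.3, 0.3, 0.4))
        sim = TrialSimulator(spec, tpl, [80.0], [81, 4, 0, 0], rate_offset=0.0)
        reps = [sim.trial(80.0, k) for k in range(5)]
        grid = default_jitter_grid()
        curve = rate_normalized_comparison(reps, grid, seed=0, window=W)
        d = curve["difference"].to_numpy()
        assert d[0] < 0 < d[-1]  # tight jitter more reliable, loose less
        x = xintercept_resolution(curve)
        assert grid[0] <= x <= grid[-1]

    def test_poisson_crosses_at_coarse_jitter(self):
        rng = np.random.default_rng(91)
        grid = default_jitter_grid()
        xs = []
        for i in range(12):
            rate = rng.uniform(30, 90)
            reps = [poisson_surrogate(rate, W, rng, repeat_index=k) for k in range(5)]
            curve = rate_normalized_comparison(reps, grid, seed=i, window=W)
            xs.append(xintercept_resolution(curve))
        assert np.median(xs) > 20.0

    def test_zero_rate_flagged(self):
        reps = [_train([], rep=k) for k in range(3)]
        with pytest.raises(ValueError, match="zero mean rate"):
            rate_normalized_comparison(reps, default_jitter_grid(), window=W)


class TestPrecisionModel:
    def test_neuron_resolution_is_median_across_textures(self):
        rs, _ = simulate_study(StudyConfig(n_neurons=2, n_textures=5, n_repeats=5), 5)
        res = PrecisionModel(rs, jitter_grid=default_jitter_grid(6)).fit(seed=0)
        for nid, med in res.per_neuron.items():
            ests = res.per_texture.query("neuron_id == @nid")["estimate_ms"]
            assert med == np.median(ests)
        assert "median neuron resolution" in res.summary()


def test_results_plot_smoke(small_study):
    import matplotlib

    matplotlib.use("Agg")
    rs, _ = small_study
    res = PrecisionModel(rs, jitter_grid=np.array([1.0, 10.0, 100.0])).fit(seed=0)
    ax = res.plot_distribution()
    assert ax.get_xlabel() == "temporal resolution (ms)"
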