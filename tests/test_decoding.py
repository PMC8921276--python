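"""Nearest-neighbor texture decoding: rate, timing, combination, population."""

from itertools import product

import numpy as np
import pytest

from spiketexture.data_model import AnalysisWindow, RateResponse, SpikeTrain, spike_rate
from spiketexture.decoding import (
    DistanceTable,
    TextureDecoder,
    classify_table,
    combine_rate_timing,
    combined_table,
    permutation_compare,
    population_classify,
    rate_distance_table,
    rate_nn_classify,
    sweep_resolutions,
    timing_distance_table,
    timing_nn_classify,
)
from spiketexture.surrogates import poisson_surrogate
from spiketexture.synthetic import NeuronSpec, StudyConfig, TrialSimulator, make_templates, simulate_study

W = AnalysisWindow(start=0.0)


def _rates(values_by_texture, n_rep):
    out = []
    for t, vals in values_by_texture.items():
        for r in range(n_rep):
            out.append(RateResponse("n", t, r, 80.0, vals[r]))
    return out


class TestRateClassifier:
    def test_disjoint_rate_supports_perfect(self):
        rates = _rates({"a": [10.0, 11.0], "b": [50.0, 52.0]}, 2)
        assert rate_nn_classify(rates).accuracy == 1.0

    def test_identical_rates_are_pure_tie_breaking(self):
        rates = _rates({"a": [5.0] * 5, "b": [5.0] * 5, "c": [5.0] * 5, "d": [5.0] * 5}, 5)
        accs = [rate_nn_classify(rates, rng=s).accuracy for s in range(40)]
        assert abs(np.mean(accs) - 0.25) < 0.08  # chance of 4 textures

    def test_confusion_rows_sum_to_trials(self):
        rates = _rates({"a": [10.0, 30.0, 9.0], "b": [50.0, 52.0, 20.0]}, 3)
        res = rate_nn_classify(rates)
        assert res.confusion.sum(axis=1).tolist() == [3, 3]

    def test_vector_rate_signature(self):
        # the Euclidean form accepts multi-dimensional rate vectors
        rng = np.random.default_rng(0)
        labels = np.repeat(np.arange(3), 4)
        repeats = np.tile(np.arange(4), 3)
        R = rng.normal(size=(12, 2)) + labels[:, None] * 5.0
        table = rate_distance_table(R, labels, repeats, ["a", "b", "c"])
        assert classify_table(table).accuracy == 1.0


class TestTimingClassifier:
    def test_poisson_trains_at_chance(self):
        rng = np.random.default_rng(1)
        trains = []
        for j in range(10):
            r = rng.uniform(20, 100)
            for k in range(5):
                trains.append(
                    poisson_surrogate(r, W, rng, texture_id=f"t{j}", repeat_index=k)
                )
        accs = [timing_nn_classify(trains, 2.0, rng=s).accuracy for s in range(3)]
        assert abs(np.mean(accs) - 0.1) < 0.09

    def test_patterned_neuron_beats_chance_at_fine_resolution(self):
        tpls = make_templates(10, 90)
        spec = NeuronSpec("n", 60.0, 10.0, 1.0, 0.8, (0.05, 0.05, 0.9))
        trains = []
        for j, tpl in enumerate(tpls):
            sim = TrialSimulator(spec, tpl, [80.0], [90, 4, 0, j])
            trains += [sim.trial(80.0, k) for k in range(5)]
        res = timing_nn_classify(trains, 2.0)
        assert res.accuracy > 0.5

    def test_accuracy_invariant_to_constant_rate_offset(self):
        """Demeaning: adding the same near-uniform spikes to every train
        leaves timing classification accuracy approximately unchanged."""
        tpls = make_templates(8, 91)
        spec = NeuronSpec("n", 40.0, 10.0, 2.0, 0.8, (0.05, 0.05, 0.9))
        trains = []
        for j, tpl in enumerate(tpls):
            sim = TrialSimulator(spec, tpl, [80.0], [91, 4, 0, j])
            trains += [sim.trial(80.0, k) for k in range(5)]
        lift = np.linspace(3.0, 497.0, 25)
        lifted = [
            SpikeTrain(t.neuron_id, t.texture_id, t.repeat_index, t.speed,
                       np.unique(np.concatenate([t.times, lift])))
            for t in trains
        ]
        a = timing_nn_classify(trains, 5.0, rng=0).accuracy
        b = timing_nn_classify(lifted, 5.0, rng=0).accuracy
        assert abs(a - b) <= 0.10


class TestResolutionSweep:
    def test_tie_goes_to_smallest_kernel(self):
        # two textures, perfectly separated at any resolution -> constant
        # accuracy -> smallest kernel SD wins
        trains = []
        for j, offset in enumerate((50.0, 300.0)):
            for k in range(3):
                trains.append(
                    SpikeTrain("n", f"t{j}", k, 80.0, np.array([offset, offset + 30.0]))
                )
        res = sweep_resolutions(trains, [1.0, 5.0, 20.0])
        assert res.resolution_curve["accuracy"].nunique() == 1
        assert res.resolution_ms == 1.0

    def test_single_point_grid(self):
        trains = [
            SpikeTrain("n", f"t{j}", k, 80.0, np.array([50.0 + 100 * j]))
            for j in range(2)
            for k in range(2)
        ]
        res = sweep_resolutions(trains, [5.0])
        assert res.resolution_ms == 5.0

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_resolutions([], [5.0, 1.0])


def _zscored_tables_for_neuron(trains, kernel_sd=2.0):
    texture_ids = list(dict.fromkeys(t.texture_id for t in trains))
    order = {t: i for i, t in enumerate(texture_ids)}
    labels = np.array([order[t.texture_id] for t in trains])
    repeats = np.array([t.repeat_index for t in trains])
    rates = np.array([spike_rate(t, W).rate for t in trains])
    rt = rate_distance_table(rates, labels, repeats, texture_ids).zscore()
    tt = timing_distance_table(trains, labels, texture_ids, kernel_sd).zscore()
    return rt, tt


@pytest.fixture(scope="module")
def informative_neuron_trains():
    tpls = make_templates(10, 92)
    spec = NeuronSpec("n", 60.0, 20.0, 1.5, 0.7, (0.3, 0.2, 0.5))
    trains = []
    for j, tpl in enumerate(tpls):
        sim = TrialSimulator(spec, tpl, [80.0], [92, 4, 0, j])
        trains += [sim.trial(80.0, k) for k in range(5)]
    return trains


class TestCombinedClassifier:
    def test_endpoints_reproduce_pure_schemes_exactly(self, informative_neuron_trains):
        rt, tt = _zscored_tables_for_neuron(informative_neuron_trains)
        res = combine_rate_timing(rt, tt, [0.0, 0.25, 0.5, 0.75, 1.0])
        curve = dict(zip(res.weight_curve["weight"], res.weight_curve["accuracy"]))
        assert curve[1.0] == classify_table(rt).accuracy
        assert curve[0.0] == classify_table(tt).accuracy
        assert res.accuracy >= max(curve[0.0], curve[1.0])

    def test_requires_zscored_tables(self, informative_neuron_trains):
        rt, tt = _zscored_tables_for_neuron(informative_neuron_trains)
        raw = DistanceTable(rt.values, rt.labels, rt.texture_ids, "rate")
        with pytest.raises(ValueError, match="z-scored"):
            combine_rate_timing(raw, tt)

    def test_interior_weight_on_neurons_with_both_signals(self, pop_study):
        """Neurons carrying independent rate and timing information are best
        decoded by an intermediate weight."""
        rs, gt = pop_study
        dec = TextureDecoder(rs, scheme="combined", resolutions=[1, 2, 5, 10, 20])
        out = dec.fit(seed=0)
        informative = out.per_neuron.query("accuracy > 0.1")
        interior = informative["weight"].between(0.049, 0.951)
        assert interior.mean() >= 0.8


class TestPermutationTest:
    def test_identical_distributions_p_near_half(self):
        rng = np.random.default_rng(5)
        ps = []
        for s in range(30):
            a = rng.normal(size=20)
            b = rng.normal(size=20)
            ps.append(permutation_compare(a, b, 1000, seed=s))
        assert 0.3 < np.mean(ps) < 0.7

    def test_large_shift_gives_zero_proportion(self):
        rng = np.random.default_rng(6)
        b = rng.normal(0, 0.01, size=20)
        a = b + 10.0
        assert permutation_compare(a, b, 1000, seed=0) == 0.0

    def test_matches_exhaustive_sign_enumeration(self):
        """Monte-Carlo p agrees with the exact p over all 2^8 paired sign
        assignments."""
        rng = np.random.default_rng(7)
        a = rng.normal(0.5, 1.0, size=8)
        b = rng.normal(0.0, 1.0, size=8)
        d = a - b
        obs = d.mean()
        exact = np.mean(
            [np.mean(np.array(signs) * d) >= obs for signs in product([-1, 1], repeat=8)]
        )
        mc = permutation_compare(a, b, 20_000, seed=1)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_minimum_shuffles_enforced(self):
        with pytest.raises(ValueError):
            permutation_compare([1.0], [0.0], 10)


class TestPopulationDecoding:
    def test_single_neuron_population_matches_single_cell(self, pop_study):
        rs, _ = pop_study
        dec = TextureDecoder(rs, scheme="rate")
        out = dec.fit(seed=0)
        tables = [out.tables[n] for n in out.per_neuron["neuron_id"]]
        pop = population_classify(tables, 1, n_iter=300, seed=0)
        assert abs(pop.mean - out.per_neuron["accuracy"].mean()) < 0.03

    def test_accuracy_nondecreasing_with_population_size(self, pop_study):
        rs, _ = pop_study
        out = TextureDecoder(rs, scheme="rate").fit(seed=0)
        tables = list(out.tables.values())
        curve = [
            population_classify(tables, n, n_iter=150, seed=1).mean for n in (1, 5, 15, 35)
        ]
        assert all(b >= a - 0.02 for a, b in zip(curve, curve[1:]))

    def test_population_requires_zscored(self, informative_neuron_trains):
        rt, _ = _zscored_tables_for_neuron(informative_neuron_trains)
        raw = DistanceTable(rt.values, rt.labels, rt.texture_ids, "rate")
        with pytest.raises(ValueError, match="z-scored"):
            population_classify([raw], 1, 100)

    def test_equal_weight_population_close_to_optimal(self, pop_study):
        """A 50/50 rate-timing population classifier performs within 3
        accuracy points of the optimally weighted one."""
        rs, _ = pop_study
        dec = TextureDecoder(rs, scheme="combined", resolutions=[1, 2, 5, 10, 20])
        out = dec.fit(seed=0)
        opt_tables = list(out.tables.values())  # per-neuron optimal weights
        eq_tables = []
        for nid in rs.neuron_ids:
            parts = dec._neuron_tables(nid, np.random.default_rng(0))
            eq_tables.append(
                combined_table(parts["rate"].zscore(), parts["timing"].zscore(), 0.5)
            )
        n = len(opt_tables)
        acc_opt = population_classify(opt_tables, n, n_iter=30, seed=2).mean
        acc_eq = population_classify(eq_tables, n, n_iter=30, seed=2).mean
        assert abs(acc_opt - acc_eq) <= 0.03


class TestNoTimingInformationLimit:
    def test_rate_and_combined_agree_and_timing_at_chance(self):
        """With pattern_strength = 0 everywhere, timing decodes at chance and
        the combined scheme reduces to rate."""
        cfg = StudyConfig(n_neurons=6, n_textures=10, n_repeats=5)
        rs, gt = simulate_study(cfg, 77)
        # rebuild all neurons with no temporal patterning
        from dataclasses import replace as dc_replace

        trains = []
        for i, spec in enumerate(gt.neuron_specs):
            spec0 = NeuronSpec(
                spec.neuron_id, spec.base_rate, spec.rate_tuning_sd, 5.0, 0.0,
                spec.submodality_weights,
            )
            for j, tpl in enumerate(gt.templates):
                sim = TrialSimulator(
                    spec0, tpl, [80.0], [77, 4, i, j],
                    rate_offset=gt.rate_offsets.iloc[i, j],
                )
                trains += [sim.trial(80.0, k) for k in range(5)]
        rs0 = dc_replace(rs, trains=trains)
        rs0.__post_init__()
        timing = TextureDecoder(rs0, scheme="timing", resolutions=[2, 10, 50]).fit(seed=0)
        rate = TextureDecoder(rs0, scheme="rate").fit(seed=0)
        comb = TextureDecoder(rs0, scheme="combined", resolutions=[2, 10, 50]).fit(seed=0)
        n_trials = 10 * 5 * 6
        se = np.sqrt(0.1 * 0.9 / n_trials)
        assert abs(timing.per_neuron["accuracy"].mean() - 0.1) < 4 * se
        assert abs(
            comb.per_neuron["accuracy"].mean() - rate.per_neuron["accuracy"].mean()
        ) < 0.05
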