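"""Greedy minimax-entropy input selection, the entropy-drop estimate, and n*."""

import numpy as np
import pytest

import directdeps as dd
from directdeps.maxent import LN2


class TestDeltaEntropyEstimate:
    def test_already_predicted_candidate_scores_zero(self):
        raster, _ = dd.gen_logic_gate(dd.LogicGateSpec("XOR", 0.1))
        model = dd.fit(raster, 0, ())
        # parity: Delta = <y x_c> - <y><x_c> = 0 for both inputs
        assert dd.delta_entropy_estimate(model, raster, 1) == pytest.approx(0.0, abs=1e-12)
        assert dd.delta_entropy_estimate(model, raster, 2) == pytest.approx(0.0, abs=1e-12)

    def test_estimate_tracks_exact_refit_drop_for_small_errors(self):
        # second-order estimate vs exact-refit oracle on random sampled
        # 4-neuron instances, restricted to small prediction errors
        rng = np.random.default_rng(21)
        checked = 0
        for _ in range(40):
            raster, truth = dd.gen_logistic_network(
                4, (1, 2), (1.0, -1.0), -1.0, 0.4, 2000, seed=int(rng.integers(2**31))
            )
            model = dd.fit(raster, 0, (1, 2), tolerance=1e-10)
            stats = dd.empirical_stats(raster, 0, (3,))
            delta = stats.pair_corrs[0] - dd.predict_pairwise(model, raster, 3)
            if abs(delta) > 0.5 * stats.pair_sigmas[0] or 3 not in dd.eligible_inputs(raster, 0):
                continue
            est = dd.delta_entropy_estimate(model, raster, 3, tolerance=1e-10)
            refit = dd.fit(raster, 0, (1, 2, 3), tolerance=1e-10)
            exact = dd.model_entropy(refit, raster) - dd.model_entropy(model, raster)
            assert est <= 0
            assert est == pytest.approx(exact, rel=0.25, abs=1e-9)
            checked += 1
        assert checked >= 10

    def test_saturated_model_falls_back_to_exact_refit(self):
        # p is exactly 0/1 wherever the candidate fires -> chi = 0, Delta != 0
        values = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [1, 0, 1, 0]], dtype=np.uint8
        )
        raster = dd.BinaryRaster(values, dt=1.0)
        model = dd.DirectModel(0, (1,), bias=-50.0, weights=np.array([100.0]),
                               converged=True, max_violation=0.0)
        est = dd.delta_entropy_estimate(model, raster, 2)
        refit = dd.fit(raster, 0, (1, 2), init=(model.bias, np.array([model.weights[0], 0.0])))
        exact = dd.model_entropy(refit, raster) - dd.model_entropy(model, raster)
        assert est == pytest.approx(exact, abs=1e-9)

    def test_candidate_validation(self, planted_raster, planted_model):
        raster, _ = planted_raster
        with pytest.raises(ValueError, match="already"):
            dd.delta_entropy_estimate(planted_model, raster, 2)
        with pytest.raises(ValueError, match="output"):
            dd.delta_entropy_estimate(planted_model, raster, 0)


class TestGreedySelect:
    def test_planted_inputs_found_first(self, planted_raster):
        raster, truth = planted_raster
        trace = dd.greedy_select(raster, 0)
        assert set(trace.chosen[:3]) == set(truth.planted_inputs)
        assert trace.n_star == 3 and trace.stop_reason == "predicted_all"
        # entropy must fall monotonically along the greedy path
        assert np.all(np.diff(trace.s_dir_per_step) <= 1e-9)

    def test_xor_offers_no_pairwise_progress(self):
        raster, _ = dd.gen_logic_gate(dd.LogicGateSpec("XOR", 0.0))
        trace = dd.greedy_select(raster, 0, budget=2, use_stopping=False)
        assert trace.s_dir_per_step == pytest.approx([1.0, 1.0, 1.0])
        assert np.allclose(trace.delta_estimates, 0.0, atol=1e-12)

    def test_exact_and_approx_agree_on_first_pick(self):
        raster, _ = dd.gen_logistic_network(5, (2, 4), (2.0, -1.5), -1.0, 0.4, 200, seed=13)
        first_exact = dd.greedy_select(raster, 0, budget=1, mode="exact", use_stopping=False)
        first_approx = dd.greedy_select(raster, 0, budget=1, mode="approx", use_stopping=False)
        assert first_exact.chosen == first_approx.chosen

    def test_budget_zero_returns_independent_model_only(self, planted_raster):
        raster, _ = planted_raster
        trace = dd.greedy_select(raster, 0, budget=0, use_stopping=False)
        assert trace.chosen == [] and len(trace.s_dir_per_step) == 1
        assert trace.stop_reason == "budget"
        assert trace.model.inputs == ()

    def test_exhausts_small_pool(self):
        raster, _ = dd.gen_logic_gate(
            dd.LogicGateSpec("AND", 0.1), mode="sampled", L=2000, seed=3
        )
        trace = dd.greedy_select(raster, 0, use_stopping=False)
        assert trace.stop_reason == "exhausted"
        assert set(trace.chosen) == {1, 2}

    def test_trace_serialization(self, tmp_path, planted_raster):
        raster, _ = planted_raster
        trace = dd.greedy_select(raster, 0, budget=2, use_stopping=False)
        trace.save(tmp_path / "trace")
        tsv = (tmp_path / "trace.tsv").read_text()
        assert tsv.count("\n") == 4  # header + 3 steps
        assert "n_star" in (tmp_path / "trace.json").read_text()


class TestStoppingRule:
    def test_independent_population_stops_at_zero(self):
        # an independent model already predicts all correlations of an
        # independent population in the majority of replicates
        rng = np.random.default_rng(17)
        passes = 0
        reps = 40
        for _ in range(reps):
            values = (rng.random((8, 10_000)) < 0.2).astype(np.uint8)
            raster = dd.BinaryRaster(values, dt=1.0)
            model = dd.fit(raster, 0, ())
            passes += dd.stopping_rule(model, raster).passes
        assert passes / reps > 0.5

    def test_planted_network_needs_exactly_its_inputs(self, planted_raster, planted_model):
        raster, _ = planted_raster
        check = dd.stopping_rule(planted_model, raster)
        assert check.passes
        partial = dd.fit(raster, 0, (2, 5))
        assert not dd.stopping_rule(partial, raster).passes

    def test_vacuous_pass_when_nothing_remains(self):
        values = np.array([[1, 0, 1], [1, 1, 0]], dtype=np.uint8)
        raster = dd.BinaryRaster(values, dt=1.0)
        model = dd.fit(raster, 0, (1,))
        check = dd.stopping_rule(model, raster)
        assert check.passes and check.worst_neuron is None


class TestRandomBaseline:
    def test_zero_inputs_is_independent_model(self, planted_raster):
        raster, _ = planted_raster
        model = dd.random_baseline(raster, 0, 0, seed=1)
        assert model.inputs == ()

    def test_deterministic_given_seed(self, planted_raster):
        raster, _ = planted_raster
        a = dd.random_baseline(raster, 0, 3, seed=42)
        b = dd.random_baseline(raster, 0, 3, seed=42)
        assert a.inputs == b.inputs

    def test_too_many_inputs_rejected(self):
        values = np.array([[1, 1, 0], [1, 0, 1], [0, 1, 1]], dtype=np.uint8)
        raster = dd.BinaryRaster(values, dt=1.0)
        with pytest.raises(ValueError, match="eligible"):
            dd.random_baseline(raster, 0, 5, seed=0)

    def test_greedy_dominates_random_inputs(self, planted_raster):
        raster, _ = planted_raster
        greedy = dd.greedy_select(raster, 0, budget=3, use_stopping=False)
        s_greedy = greedy.s_dir_per_step[-1]
        s_random = [
            dd.model_entropy(dd.random_baseline(raster, 0, 3, seed=s), raster)
            for s in range(12)
        ]
        assert s_greedy <= np.median(s_random)
        # and against nearly every single draw on this strongly planted network
        assert np.mean([s_greedy <= s for s in s_random]) >= 0.95
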