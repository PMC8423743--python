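import itertools
import warnings

import numpy as np
import pytest

import interactreg as ir
from interactreg.errors import FitError, InteractRegError
from conftest import two_axis_folds


def noise_panel(n=120, p=6, seed=0, signal=None, noise_sd=0.3, counties=6):
    """Panel of independent uniform weather columns with optional linear signal."""
    rng = np.random.default_rng(seed)
    names = [f"W_v{i}" for i in range(p)]
    catalogue = ir.VariableCatalogue.from_columns(names)
    X = rng.uniform(0.0, 1.0, size=(n, p))
    rows = [(f"c{i % counties:03d}", 2000 + i // counties) for i in range(n)]
    y = np.full(n, 5.0)
    for j, beta in (signal or {}).items():
        y = y + beta * X[:, j]
    y = y + rng.normal(0.0, noise_sd, size=n)
    return ir.SamplePanel(rows=rows, X=X, catalogue=catalogue, y=y)


class TestPrescreen:
    def test_recovers_planted_variable_across_replicates(self):
        """One true effect among 20 noise variables, low noise: the elastic
        net shortlist should almost always contain the true variable."""
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            panel = noise_panel(n=500, p=21, seed=seed, signal={0: 1.0},
                                noise_sd=0.1, counties=10)
            selected = ir.elastic_net_prescreen(panel, "weather", seed=seed)
            hits += "W_v0" in selected
        assert hits >= int(0.95 * n_rep)

    def test_constant_response_selects_nothing(self):
        panel = noise_panel(n=50, p=4, seed=1, noise_sd=0.0)
        panel.y = np.full(panel.n, 7.0)
        assert ir.elastic_net_prescreen(panel, "weather") == []

    def test_cap_bounds_selection_size(self):
        panel = noise_panel(n=200, p=10, seed=2,
                            signal={i: 1.0 for i in range(8)}, noise_sd=0.05)
        assert len(ir.elastic_net_prescreen(panel, "weather", cap=3)) <= 3

    def test_missing_yield_rejected(self):
        panel = noise_panel(n=30, p=3, seed=0)
        panel.y = None
        with pytest.raises(FitError):
            ir.elastic_net_prescreen(panel, "weather")


class TestRobustnessScore:
    def test_aggregate_is_mean_of_folds(self, small_panel):
        panel, truth = small_panel
        folds = two_axis_folds(panel, n_blocks=3)
        report = ir.robustness_score(list(truth.effects), truth.terms, panel, folds)
        assert report.aggregate == pytest.approx(np.mean(report.per_fold))
        assert len(report.per_fold) == len(folds.folds)

    def test_exact_model_scores_zero(self):
        panel = noise_panel(n=60, p=2, seed=3, signal={0: 2.0}, noise_sd=0.0)
        folds = ir.make_folds(panel, "temporal_blocks", n_blocks=3)
        report = ir.robustness_score(["W_v0"], [], panel, folds, metric="RMSE")
        assert report.aggregate == pytest.approx(0.0, abs=1e-8)

    def test_single_fold_aggregate(self):
        panel = noise_panel(n=40, p=2, seed=4, signal={0: 1.0})
        folds = ir.make_folds(panel, "temporal_blocks", n_blocks=2)
        report = ir.robustness_score(["W_v0"], [], panel, folds)
        assert report.aggregate == report.per_fold[0]

    def test_insufficient_training_rows_rejected(self):
        panel = noise_panel(n=12, p=6, seed=5, counties=6)
        folds = ir.make_folds(panel, "temporal_blocks", n_blocks=2)
        with pytest.raises(FitError, match="fewer features"):
            ir.robustness_score([f"W_v{i}" for i in range(6)], [], panel, folds)

    def test_validation_rows_never_influence_fold_fits(self, small_panel):
        """Instrumented anti-leakage check: corrupting validation-row data
        leaves every fold's fitted coefficients bit-identical."""
        panel, truth = small_panel
        folds = two_axis_folds(panel, n_blocks=3)
        features = list(truth.effects)
        _, details = ir.robustness_score(features, truth.terms, panel, folds,
                                         return_details=True)
        for k, fold in enumerate(folds.folds):
            corrupted = ir.SamplePanel(
                rows=list(panel.rows), X=panel.X.copy(),
                catalogue=panel.catalogue, y=panel.y.copy(),
            )
            val = list(fold.validation_rows)
            corrupted.y[val] += 1000.0
            corrupted.X[val] *= 1.7
            _, details2 = ir.robustness_score(features, truth.terms, corrupted,
                                              folds, return_details=True)
            np.testing.assert_array_equal(details[k]["coefficients"],
                                          details2[k]["coefficients"])


class TestForwardStepwise:
    def test_max_added_zero_is_identity(self):
        panel = noise_panel(n=60, p=3, seed=6, signal={0: 2.0})
        folds = ir.make_folds(panel, "temporal_blocks", n_blocks=3)
        out = ir.forward_stepwise(["W_v0", "W_v1"], None, panel, folds,
                                  max_added=0)
        assert out.features == [] and out.terms == []

    def test_pure_noise_candidates_not_added_beyond_tolerance(self):
        rejected = 0
        n_rep = 20
        for seed in range(n_rep):
            panel = noise_panel(n=120, p=8, seed=seed, noise_sd=0.3)
            folds = ir.make_folds(panel, "temporal_blocks", n_blocks=3)
            out = ir.forward_stepwise([f"W_v{i}" for i in range(8)], None,
                                      panel, folds, tol=0.5)
            rejected += not out.features
        assert rejected >= int(0.9 * n_rep)

    def test_accepted_steps_improve_by_at_least_tol(self, small_panel):
        panel, truth = small_panel
        folds = two_axis_folds(panel, n_blocks=3)
        tol = 0.15
        out = ir.forward_stepwise(list(truth.effects), None, panel, folds, tol=tol)
        scores = [t["score"] for t in out.trajectory if t["action"] == "add"]
        base = ir.robustness_score([], [], panel, folds).aggregate
        previous = base
        for s in scores:
            assert previous - s >= tol - 1e-9
            previous = s

    def test_greedy_matches_exhaustive_best_subset_on_orthogonal_signals(self):
        """With orthogonalized candidate columns the greedy 2-step selection
        attains the exhaustive best-2-subset validation score."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, p = 120, 8
            raw = rng.normal(size=(n, p))
            Q, _ = np.linalg.qr(raw - raw.mean(axis=0))
            X = (Q - Q.min(axis=0)) / (Q.max(axis=0) - Q.min(axis=0))
            names = [f"W_v{i}" for i in range(p)]
            catalogue = ir.VariableCatalogue.from_columns(names)
            rows = [(f"c{i % 6:03d}", 2000 + i // 6) for i in range(n)]
            y = 5.0 + 3.0 * X[:, 2] + 2.0 * X[:, 5] + rng.normal(0, 0.05, n)
            panel = ir.SamplePanel(rows=rows, X=X, catalogue=catalogue, y=y)
            folds = ir.make_folds(panel, "temporal_blocks", n_blocks=3)

            greedy = ir.forward_stepwise(names, None, panel, folds, tol=0.0,
                                         max_added=2)
            greedy_score = ir.robustness_score(greedy.features, [], panel,
                                               folds).aggregate
            best = min(
                ir.robustness_score(list(pair), [], panel, folds).aggregate
                for pair in itertools.combinations(names, 2)
            )
            assert greedy_score == pytest.approx(best, abs=1e-9)


class TestBackwardEliminate:
    def test_empty_input_is_empty_output(self, small_panel):
        panel, _ = small_panel
        folds = two_axis_folds(panel, n_blocks=3)
        out = ir.backward_eliminate(ir.SelectionResult(), panel, folds)
        assert out.features == [] and out.terms == []

    def test_infinite_tolerance_removes_everything(self, small_panel):
        panel, truth = small_panel
        folds = two_axis_folds(panel, n_blocks=3)
        start = ir.SelectionResult(features=list(truth.effects))
        out = ir.backward_eliminate(start, panel, folds, tol=np.inf)
        assert out.features == [] and out.terms == []

    def test_noise_term_pruned_from_planted_model(self):
        pruned = 0
        n_rep = 20
        for seed in range(n_rep):
            panel = noise_panel(n=150, p=6, seed=100 + seed, signal={0: 3.0},
                                noise_sd=0.3)
            folds = ir.make_folds(panel, "temporal_blocks", n_blocks=3)
            start = ir.SelectionResult(features=["W_v0", "W_v3"])
            out = ir.backward_eliminate(start, panel, folds, tol=0.15)
            pruned += out.features == ["W_v0"]
        assert pruned >= int(0.9 * n_rep)

    def test_result_is_subset_of_input(self, small_panel):
        panel, truth = small_panel
        folds = two_axis_folds(panel, n_blocks=3)
        start = ir.SelectionResult(features=list(truth.effects),
                                   terms=list(truth.terms))
        out = ir.backward_eliminate(start, panel, folds, tol=0.15)
        assert set(out.features) <= set(start.features)
        assert set(out.terms) <= set(start.terms)


class TestSearch:
    def test_zero_cycles_returns_prescreen_only(self, small_panel):
        panel, _ = small_panel
        folds = two_axis_folds(panel, n_blocks=3)
        config = ir.SearchConfig(max_cycles=0, seed=0)
        result = ir.search_robust_interactions(panel, folds, config=config)
        assert result.terms == []
        expected = []
        for cat in ("weather", "soil", "management"):
            expected += ir.elastic_net_prescreen(
                panel, cat, cap=config.caps.get(cat), seed=0
            )
        assert sorted(result.features) == sorted(expected)

    def test_deterministic_given_seed(self, small_panel):
        panel, _ = small_panel
        folds = two_axis_folds(panel, n_blocks=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = ir.search_robust_interactions(
                panel, folds, config=ir.SearchConfig(seed=5))
            b = ir.search_robust_interactions(
                panel, folds, config=ir.SearchConfig(seed=5))
        assert a.to_json() == b.to_json()

    def test_recovers_planted_interactions_on_reference_scenario(self):
        for seed in (0, 1, 2):
            panel, truth = ir.generate_panel(ir.reference_config(seed=seed))
            folds = two_axis_folds(panel, n_blocks=4)
            result = ir.search_robust_interactions(
                panel, folds, config=ir.SearchConfig(seed=seed))
            score = ir.score_recovery(truth, result)
            assert score.recall == 1.0
            assert score.false_discovery_rate == 0.0

    def test_null_scenario_selects_no_interactions(self):
        """Reference conditions with no planted interactions: the search
        should return an empty interaction set at the default tolerance."""
        empty = 0
        n_rep = 10
        for seed in range(n_rep):
            config = ir.SynthConfig(true_interactions=[], seed=seed)
            panel, _ = ir.generate_panel(config)
            folds = two_axis_folds(panel, n_blocks=4)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = ir.search_robust_interactions(
                    panel, folds, config=ir.SearchConfig(seed=seed))
            empty += not result.terms
        assert empty >= int(0.9 * n_rep)

    def test_selection_serializes_with_config_echo(self, small_panel):
        import json

        panel, _ = small_panel
        folds = two_axis_folds(panel, n_blocks=3)
        config = ir.SearchConfig(max_cycles=0, seed=9)
        result = ir.search_robust_interactions(panel, folds, config=config)
        parsed = json.loads(result.to_json())
        assert parsed["seed"] == 9
        assert parsed["config"]["tol_forward"] == config.tol_forward
        assert set(parsed["features_by_category"]) <= {
            "weather", "soil", "management"
        }
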