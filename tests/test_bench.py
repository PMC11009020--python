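"""Metric identities, model contracts, repeated-CV behaviour, cross-domain
protocol and paired selector comparison."""

import numpy as np
import pandas as pd
import pytest

from conftest import toy_dataset
from litrx.bench import (
    CVProtocol,
    ModelSpec,
    compare_selectors,
    compute_metrics,
    run_cross_domain,
    run_cv,
    train_model,
    validate_benchmark_invariants,
)
from litrx.featsel import SelectorConfig
from litrx.synth import PharmacoSpec, generate_pharmaco_pair, gene_id


class TestMetrics:
    def test_identity_prediction(self):
        y = np.array([0.1, 0.5, 0.9, 0.3])
        m = compute_metrics(y, y)
        assert m["pearson"] == m["spearman"] == m["kendall"] == 1.0
        assert m["rmse"] == m["mse"] == m["mae"] == 0.0

    def test_total_reversal(self):
        m = compute_metrics([1, 2, 3], [3, 2, 1])
        assert m["kendall"] == -1.0 and m["spearman"] == -1.0

    def test_hand_computed_errors(self):
        m = compute_metrics([0, 0.5, 1], [0.1, 0.4, 0.9])
        assert m["mae"] == pytest.approx(0.1)
        assert m["mse"] == pytest.approx(0.01)
        assert m["rmse"] == pytest.approx(0.1)

    def test_constant_vector_flags_undefined(self):
        m = compute_metrics([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert m["undefined_correlations"]
        assert np.isnan(m["pearson"])
        assert m["rmse"] > 0  # error metrics still defined

    def test_error_metric_inequalities_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            yt, yp = rng.random(15), rng.random(15)
            m = compute_metrics(yt, yp)
            assert m["rmse"] ** 2 == pytest.approx(m["mse"], abs=1e-10)
            assert m["mae"] <= m["rmse"] + 1e-12


class TestTrainModel:
    def test_elastic_net_recovers_linear_signal(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(200, 10))
        y = np.clip(0.5 + 0.2 * x[:, 0] - 0.15 * x[:, 1] + 0.1 * x[:, 2]
                    + 0.01 * rng.normal(size=200), 0, 1)
        model = train_model(ModelSpec("elastic_net", seed=0), x[:150], y[:150])
        pred = model.predict(x[150:])
        r = np.corrcoef(pred, y[150:])[0, 1]
        assert r > 0.95

    def test_constant_target_predicts_constant(self):
        x = np.random.default_rng(2).normal(size=(30, 4))
        y = np.full(30, 0.4)
        model = train_model(ModelSpec("elastic_net", seed=0), x, y)
        assert np.allclose(model.predict(x), 0.4, atol=1e-6)

    def test_mlp_predictions_bounded_to_unit_interval(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(60, 5))
        y = np.clip(0.5 + 0.3 * x[:, 0], 0, 1)
        spec = ModelSpec(
            "mlp",
            hyper_grid={"hidden_layer_sizes": [(16, 8)]},
            mlp_params={"restarts": 2, "epochs": 10},
            seed=0,
        )
        model = train_model(spec, x, y)
        wild = rng.normal(0, 50, size=(20, 5))
        pred = model.predict(wild)
        assert (pred >= 0).all() and (pred <= 1).all()

    def test_mlp_learns_monotone_signal(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(300, 3))
        y = 1 / (1 + np.exp(-(1.5 * x[:, 0] - x[:, 1])))
        spec = ModelSpec(
            "mlp",
            hyper_grid={"hidden_layer_sizes": [(32, 16)]},
            mlp_params={"restarts": 2},
            seed=0,
        )
        model = train_model(spec, x[:240], y[:240])
        r = np.corrcoef(model.predict(x[240:]), y[240:])[0, 1]
        assert r > 0.8

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            train_model(ModelSpec("elastic_net"), np.zeros((2, 3)), np.zeros(2))


def _quick_protocol(n_repeats=1, seed=0):
    return CVProtocol(n_folds=4, n_repeats=n_repeats, tune_folds=3, seed=seed)


def _signal_pair(seed=0, n_train=120, n_test=80, n_genes=60):
    spec = PharmacoSpec(
        n_samples_train=n_train,
        n_samples_test=n_test,
        n_genes=n_genes,
        signal_genes=[gene_id(i) for i in range(5)],
        effect_sizes=[1.0, -0.8, 0.9, -1.1, 0.7],
        noise_sd=0.3,
        domain_shift_sd=0.3,
        seed=seed,
    )
    return generate_pharmaco_pair(spec)


class TestRunCV:
    def test_same_seed_identical_result(self):
        tr, _ = _signal_pair()
        cfg = SelectorConfig("cor_500", k=10)
        spec = ModelSpec("elastic_net", hyper_grid={"alpha": [0.01], "l1_ratio": [0.5]})
        a = run_cv(tr, cfg, spec, _quick_protocol())
        b = run_cv(tr, cfg, spec, _quick_protocol())
        pd.testing.assert_frame_equal(a, b)

    def test_permuted_responses_give_null_performance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(300, 20))
        y = rng.permutation(np.linspace(0.05, 0.95, 300))
        ds = toy_dataset(x, y)
        cfg = SelectorConfig("cor_500", k=20)
        spec = ModelSpec("elastic_net", hyper_grid={"alpha": [0.01], "l1_ratio": [0.5]})
        res = run_cv(ds, cfg, spec, _quick_protocol(n_repeats=2))
        assert -0.1 < res["pearson"].iloc[0] < 0.1

    def test_result_satisfies_metric_invariants(self):
        tr, _ = _signal_pair()
        cfg = SelectorConfig("cor_500", k=10)
        spec = ModelSpec("elastic_net", hyper_grid={"alpha": [0.01], "l1_ratio": [0.5]})
        res = run_cv(tr, cfg, spec, _quick_protocol())
        validate_benchmark_invariants(res)
        assert (res["split_kind"] == "within").all()


class TestCrossDomain:
    def test_no_shift_strong_signal_close_to_within(self):
        spec = PharmacoSpec(
            n_samples_train=150, n_samples_test=100, n_genes=40,
            signal_genes=[gene_id(0), gene_id(1)],
            effect_sizes=[1.2, -1.0], noise_sd=0.15,
            domain_shift_sd=0.0, seed=3,
        )
        tr, te = generate_pharmaco_pair(spec)
        cfg = SelectorConfig("oracle")
        mspec = ModelSpec("elastic_net", hyper_grid={"alpha": [0.01], "l1_ratio": [0.5]})
        within = run_cv(tr, cfg, mspec, _quick_protocol())["pearson"].iloc[0]
        cross = run_cross_domain(tr, te, cfg, mspec, _quick_protocol())["pearson"].iloc[0]
        assert abs(within - cross) < 0.1

    def test_independent_test_responses_give_null_cross_r(self):
        tr, te = _signal_pair(seed=7)
        rng = np.random.default_rng(8)
        te_null = te
        te_null.responses["aac"] = rng.permutation(te.responses["aac"].to_numpy())
        cfg = SelectorConfig("oracle")
        mspec = ModelSpec("elastic_net", hyper_grid={"alpha": [0.01], "l1_ratio": [0.5]})
        cross = run_cross_domain(tr, te_null, cfg, mspec, _quick_protocol())
        assert abs(cross["pearson"].iloc[0]) < 3 / np.sqrt(100)

    def test_oracle_beats_variance_selector_on_planted_data(self):
        tr, te = _signal_pair(seed=9, n_genes=100)
        mspec = ModelSpec("elastic_net", hyper_grid={"alpha": [0.01], "l1_ratio": [0.5]})
        proto = _quick_protocol()
        r_oracle = run_cross_domain(tr, te, SelectorConfig("oracle"), mspec, proto)[
            "pearson"
        ].iloc[0]
        r_var = run_cross_domain(tr, te, SelectorConfig("var_100"), mspec, proto)[
            "pearson"
        ].iloc[0]
        assert r_oracle >= r_var

    def test_leakage_guard_corrupting_test_changes_nothing_within(self):
        """Corrupting test-domain responses must change no within-domain
        metric and no selected feature set."""
        tr, te = _signal_pair(seed=10)
        cfg = SelectorConfig("cor_500", k=10)
        mspec = ModelSpec("elastic_net", hyper_grid={"alpha": [0.01], "l1_ratio": [0.5]})
        proto = _quick_protocol()
        from litrx.featsel import apply_selector

        fs_before = apply_selector(cfg, tr, tr.drugs[0])
        within_before = run_cv(tr, cfg, mspec, proto)
        te.responses["aac"] = 1.0 - te.responses["aac"]  # corrupt
        fs_after = apply_selector(cfg, tr, tr.drugs[0])
        within_after = run_cv(tr, cfg, mspec, proto)
        assert fs_before.genes == fs_after.genes
        pd.testing.assert_frame_equal(within_before, within_after)


class TestCompareSelectors:
    def _frame(self, vals_a, vals_b):
        rows = []
        for i, (va, vb) in enumerate(zip(vals_a, vals_b)):
            rows.append({"drug": f"D{i}", "selector": "A", "model_family": "m",
                         "split_kind": "cross", "pearson": va})
            rows.append({"drug": f"D{i}", "selector": "B", "model_family": "m",
                         "split_kind": "cross", "pearson": vb})
        return pd.DataFrame(rows)

    def test_hand_computed_t_statistic(self):
        """Differences [1,2,3]: t = mean/se = 2/(1/sqrt(3)) = 3.464, df=2."""
        res = compare_selectors(
            self._frame([1.0, 2.0, 3.0], [0.0, 0.0, 0.0]), "pearson", "A", "B"
        )
        assert res.t_statistic == pytest.approx(2.0 * np.sqrt(3.0), rel=1e-6)
        assert res.df == 2

    def test_self_comparison_zero_difference(self):
        res = compare_selectors(
            self._frame([0.5, 0.6, 0.7], [0.5, 0.6, 0.7]), "pearson", "A", "B"
        )
        assert res.mean_difference == 0.0
        assert res.zero_variance and res.p_value == 1.0

    def test_direction_matches_sign_permutation_oracle(self):
        rng = np.random.default_rng(11)
        a = rng.random(10) + 0.5
        b = rng.random(10)
        res = compare_selectors(self._frame(a, b), "pearson", "A", "B")
        diff = a - b
        # sign-flip permutation p-value for the mean difference
        flips = rng.choice([-1, 1], size=(10000, 10))
        perm_means = (flips * diff).mean(axis=1)
        perm_p = float(np.mean(np.abs(perm_means) >= abs(diff.mean())))
        assert (res.p_value < 0.05) == (perm_p < 0.05)
        assert np.sign(res.mean_difference) == np.sign(res.t_statistic)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            compare_selectors(self._frame([1, 2], [0, 0]), "pearson", "A", "B")
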