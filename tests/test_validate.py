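"""Univariate biomarker statistics and survival-based validation: t-test
arithmetic, KM product-limit values, log-rank against hand computation and
a permutation null, and the end-to-end PDX-style check."""

import numpy as np
import pandas as pd
import pytest

from conftest import toy_dataset
from litrx.synth import (
    PharmacoSpec,
    generate_pdx_cohort,
    generate_pharmaco_pair,
    gene_id,
)
from litrx.validate import (
    SurvivalRecord,
    dichotomize,
    km_estimate,
    logrank_test,
    pdx_style_validation,
    univariate_analysis,
)


class TestUnivariate:
    def test_hand_computed_pooled_t(self):
        """|r| groups {0.9, 0.8} vs {0.1, 0.2}: pooled two-sample t = 9.9."""
        from scipy import stats

        t, _ = stats.ttest_ind([0.9, 0.8], [0.1, 0.2], equal_var=True)
        # pooled variance s2 = 0.005, se = sqrt(0.005*(1/2+1/2)) → t = 0.7/se
        assert t == pytest.approx(0.7 / np.sqrt(0.005), rel=1e-10)

    def test_planted_signal_in_tm_group_detected(self):
        spec = PharmacoSpec(
            n_samples_train=400, n_samples_test=10, n_genes=100,
            signal_genes=[gene_id(i) for i in range(6)],
            effect_sizes=[1.2, -1.2, 1.0, -1.0, 1.1, -1.1],
            noise_sd=0.15, seed=12,
        )
        tr, _ = generate_pharmaco_pair(spec)
        tm = [gene_id(i) for i in range(10)]  # includes all signal genes
        rep = univariate_analysis(tr, "D01", tm)
        assert rep.mean_r_tm > rep.mean_r_other
        assert rep.p_value < 0.01
        assert np.sign(rep.t_statistic) == np.sign(rep.mean_r_tm - rep.mean_r_other)

    def test_random_labels_give_null_t(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(150, 60))
        y = np.clip(0.5 + 0.1 * rng.normal(size=150), 0, 1)
        ds = toy_dataset(x, y)
        pvals = []
        for rep in range(20):
            tm = list(rng.choice(ds.genes, size=20, replace=False))
            pvals.append(univariate_analysis(ds, "D", tm).p_value)
        assert min(pvals) > 0.001  # no spurious strong signal
        assert max(pvals) > 0.2  # p spreads as a null should

    def test_paired_across_drugs_detects_planted_signal(self, small_pharmaco_pair):
        from litrx.validate import univariate_across_drugs

        spec, (tr, _) = small_pharmaco_pair
        tm = sorted({g for d in tr.truth.values() for g in d["genes"]})
        df, t, p = univariate_across_drugs(tr, tm)
        assert len(df) == len(tr.drugs)
        assert (df["mean_r_tm"] > df["mean_r_other"]).all()
        assert t > 0 and p < 0.05

    def test_report_groups_partition_universe(self, small_pharmaco_pair):
        _, (tr, _) = small_pharmaco_pair
        drug = tr.drugs[0]
        rep = univariate_analysis(tr, drug, tr.truth[drug]["genes"])
        assert set(rep.group.index) == set(tr.genes)
        assert set(rep.group.unique()) == {"text-mining", "other"}
        assert ((rep.r_abs >= 0) & (rep.r_abs <= 1)).all()


class TestDichotomize:
    def test_even_split(self):
        groups = dichotomize({"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4})
        assert groups == {"a": "low", "b": "low", "c": "high", "d": "high"}

    def test_odd_n_median_goes_high(self):
        groups = dichotomize({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0, "e": 5.0})
        assert sum(v == "high" for v in groups.values()) == 3

    def test_degenerate_identical_predictions_rejected(self):
        with pytest.raises(ValueError):
            dichotomize({"a": 0.5, "b": 0.5, "c": 0.5})


def _recs(times_a, events_a, times_b, events_b):
    recs = [
        SurvivalRecord(f"a{i}", t, e, "high")
        for i, (t, e) in enumerate(zip(times_a, events_a))
    ]
    recs += [
        SurvivalRecord(f"b{i}", t, e, "low")
        for i, (t, e) in enumerate(zip(times_b, events_b))
    ]
    return recs


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        recs = [SurvivalRecord(f"s{i}", 10.0 + i, 0, "high") for i in range(5)]
        curves = km_estimate(recs)
        assert (curves["high"]["survival"] == 1.0).all()

    def test_product_limit_hand_values(self):
        """Events at 1,2,3 with no censoring: S = 2/3, 1/3, 0."""
        recs = [SurvivalRecord(f"s{i}", float(i + 1), 1, "high") for i in range(3)]
        surv = km_estimate(recs)["high"].set_index("time")["survival"]
        assert surv.loc[1.0] == pytest.approx(2 / 3)
        assert surv.loc[2.0] == pytest.approx(1 / 3)
        assert surv.loc[3.0] == pytest.approx(0.0)

    def test_censoring_shrinks_risk_set_without_dropping_curve(self):
        recs = [
            SurvivalRecord("s1", 1.0, 1, "high"),
            SurvivalRecord("s2", 2.0, 0, "high"),  # censored
            SurvivalRecord("s3", 3.0, 1, "high"),
        ]
        surv = km_estimate(recs)["high"].set_index("time")["survival"]
        assert surv.loc[1.0] == pytest.approx(2 / 3)
        assert surv.loc[2.0] == pytest.approx(2 / 3)  # censoring: no drop
        assert surv.loc[3.0] == pytest.approx(0.0)  # risk set was 1

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(14)
        times = rng.exponential(10, size=40).round(3)
        recs = [SurvivalRecord(f"s{i}", t, 1, "high") for i, t in enumerate(times)]
        surv = km_estimate(recs)["high"]
        for t, s in zip(surv["time"], surv["survival"]):
            if t == 0:
                continue
            emp = np.mean(times > t)
            assert s == pytest.approx(emp, abs=1e-12)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalRecord("s", 0.0, 1, "high")


def oracle_logrank_chi2(records):
    """Hand log-rank: U = sum(d1 - e1), V = sum hypergeometric variances."""
    groups = sorted({r.group for r in records})
    times = sorted({r.time for r in records if r.event})
    u = 0.0
    v = 0.0
    for t in times:
        at_risk = [r for r in records if r.time >= t]
        n = len(at_risk)
        n1 = sum(r.group == groups[0] for r in at_risk)
        d = sum(r.event for r in records if r.time == t)
        d1 = sum(
            r.event for r in records if r.time == t and r.group == groups[0]
        )
        u += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return u * u / v


class TestLogrank:
    def test_identical_groups_give_chi2_zero(self):
        recs = _recs([1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 1, 1])
        chi2, p = logrank_test(recs)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_hypergeometric_sums(self):
        recs = _recs([1, 2], [1, 1], [3, 4], [1, 1])
        chi2, _ = logrank_test(recs)
        assert chi2 == pytest.approx(oracle_logrank_chi2(recs), rel=1e-9)

    def test_matches_oracle_with_censoring(self):
        recs = _recs([2, 5, 7, 9], [1, 0, 1, 1], [1, 3, 6, 8], [1, 1, 0, 1])
        chi2, _ = logrank_test(recs)
        assert chi2 == pytest.approx(oracle_logrank_chi2(recs), rel=1e-9)

    def test_invariant_to_group_label_swap(self):
        recs = _recs([1, 4, 6], [1, 1, 0], [2, 3, 8], [1, 1, 1])
        chi2_a, _ = logrank_test(recs)
        swapped = [
            SurvivalRecord(r.subject_id, r.time,
                           r.event, "low" if r.group == "high" else "high")
            for r in recs
        ]
        chi2_b, _ = logrank_test(swapped)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-12)

    def test_agrees_with_permutation_null(self):
        rng = np.random.default_rng(15)
        times = rng.exponential(10, size=20)
        events = rng.random(20) < 0.8
        labels = np.array(["high"] * 10 + ["low"] * 10)
        recs = [
            SurvivalRecord(f"s{i}", float(times[i]), int(events[i]), labels[i])
            for i in range(20)
        ]
        chi2_obs, p_obs = logrank_test(recs)
        perm_stats = []
        for _ in range(2000):
            lab = rng.permutation(labels)
            perm = [
                SurvivalRecord(f"s{i}", float(times[i]), int(events[i]), lab[i])
                for i in range(20)
            ]
            perm_stats.append(oracle_logrank_chi2(perm))
        perm_p = float(np.mean(np.asarray(perm_stats) >= chi2_obs))
        se = np.sqrt(perm_p * (1 - perm_p) / 2000) + 1e-3
        assert abs(p_obs - perm_p) < max(5 * se, 0.08)


class TestPdxValidation:
    def _setup(self, seed=0, hazard_coef=4.0):
        spec = PharmacoSpec(
            n_samples_train=150, n_samples_test=10, n_genes=120,
            signal_genes=[gene_id(i) for i in range(6)],
            effect_sizes=[1.2, -1.0, 1.1, -0.9, 1.0, -1.2],
            noise_sd=0.2, seed=21,
        )
        tr, _ = generate_pharmaco_pair(spec)
        expr, surv, _ = generate_pdx_cohort(
            spec, "D01", n_subjects=24, hazard_coef=hazard_coef, seed=seed
        )
        tm = [gene_id(i) for i in range(12)]
        return tr, tm, expr, surv

    def test_planted_hazard_detected(self):
        tr, tm, expr, surv = self._setup(seed=5)
        rep = pdx_style_validation(
            tr, "D01", tm, expr, surv, n_estimators=100, seed=0
        )
        assert rep.p_value < 0.05
        assert rep.n_high + rep.n_low == 24

    def test_same_seed_identical_report(self):
        tr, tm, expr, surv = self._setup(seed=5)
        a = pdx_style_validation(tr, "D01", tm, expr, surv, n_estimators=50, seed=0)
        b = pdx_style_validation(tr, "D01", tm, expr, surv, n_estimators=50, seed=0)
        assert a.predictions == b.predictions
        assert a.chi_square == b.chi_square

    def test_null_hazard_rarely_significant(self):
        """Survival independent of response: small p-values appear at
        roughly the nominal rate."""
        tr, tm, expr, surv = self._setup(seed=5, hazard_coef=0.0)
        rng = np.random.default_rng(30)
        pvals = []
        for rep in range(15):
            shuffled = surv.copy()
            idx = rng.permutation(len(surv))
            shuffled[["time_days", "event"]] = surv[["time_days", "event"]].to_numpy()[idx]
            out = pdx_style_validation(
                tr, "D01", tm, expr, shuffled, n_estimators=30, seed=0
            )
            pvals.append(out.p_value)
        assert np.mean(np.array(pvals) < 0.05) <= 0.3
        assert max(pvals) > 0.3
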