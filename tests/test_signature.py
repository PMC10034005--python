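import itertools

import numpy as np
import pandas as pd
import pytest

from epidrug import signature, synthetic
from conftest import logrank_oracle


def _surv(times, events, samples=None):
    samples = samples or [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"time": times, "event": events}, index=pd.Index(samples, name="sample"))


class TestLassoFrequency:
    def test_planted_genes_top_frequencies(self, survival_cohort):
        expr, surv = survival_cohort["expr"], survival_cohort["survival"]
        freq = signature.lasso_frequency_selection(expr, surv, n_runs=30, cv_folds=10, seed=7)
        top3 = set(freq.counts.sort_values(ascending=False).index[:3])
        assert top3 == set(survival_cohort["true_genes"])

    def test_seed_determinism_and_gene_order_invariance(self, survival_cohort):
        expr, surv = survival_cohort["expr"], survival_cohort["survival"]
        sub = expr.iloc[:12]
        a = signature.lasso_frequency_selection(sub, surv, n_runs=5, cv_folds=5, seed=3)
        b = signature.lasso_frequency_selection(sub, surv, n_runs=5, cv_folds=5, seed=3)
        assert a.counts.equals(b.counts)
        shuffled = sub.iloc[::-1]
        c = signature.lasso_frequency_selection(shuffled, surv, n_runs=5, cv_folds=5, seed=3)
        assert a.counts.sort_index().equals(c.counts.sort_index())

    def test_all_null_expression_no_stable_gene(self):
        rng = np.random.default_rng(0)
        hits = []
        for seed in range(5):
            expr = pd.DataFrame(
                rng.normal(7, 1, size=(20, 120)),
                index=[f"G{i}" for i in range(20)],
                columns=[f"s{i}" for i in range(120)],
            )
            surv = _surv(rng.exponential(5, 120), np.ones(120))
            freq = signature.lasso_frequency_selection(expr, surv, n_runs=20, cv_folds=5, seed=seed)
            hits.append(freq.counts.max() / freq.n_runs)
        assert np.mean([h > 0.8 for h in hits]) <= 0.2

    def test_invalid_inputs_rejected(self, survival_cohort):
        expr, surv = survival_cohort["expr"], survival_cohort["survival"]
        with pytest.raises(ValueError):
            signature.lasso_frequency_selection(expr, surv, n_runs=0)
        dead = surv.copy()
        dead["event"] = 0
        with pytest.raises(ValueError, match="events"):
            signature.lasso_frequency_selection(expr, dead, n_runs=2)


class TestSelectTopGenes:
    def _freq(self, counts):
        return signature.SelectionFrequency(
            counts=pd.Series(counts), n_runs=max(counts.values(), default=1)
        )

    def test_flat_curve_keeps_all_selected_up_to_cap(self):
        freq = self._freq({"a": 20, "b": 20, "c": 20, "d": 0})
        assert signature.select_top_genes(freq, cap=3) == ["a", "b", "c"]

    def test_elbow_cuts_at_largest_drop(self):
        freq = self._freq({"a": 90, "b": 88, "c": 30, "d": 28})
        assert signature.select_top_genes(freq, cap=3) == ["a", "b"]

    def test_cap_limits_selection(self):
        freq = self._freq({c: 50 for c in "abcdef"})
        assert len(signature.select_top_genes(freq, cap=3)) == 3

    def test_nothing_selected(self):
        assert signature.select_top_genes(self._freq({"a": 0, "b": 0})) == []


class TestStepwiseAIC:
    def test_single_candidate_univariate(self, survival_cohort):
        expr, surv = survival_cohort["expr"], survival_cohort["survival"]
        g = survival_cohort["true_genes"][0]
        coefs = signature.stepwise_aic_cox(expr, surv, candidates=[g])
        assert list(coefs.index) == [g]
        assert coefs[g] > 0

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_planted_signal_over_nulls(self, seed):
        cfg = synthetic.CohortConfig(n_tumor=300, n_normal=2, n_genes=8, planted_dmeg={}, seed=seed)
        expr = synthetic.generate_expression(cfg, synthetic.GroundTruth())
        expr = expr[[c for c in expr.columns if c.startswith("T")]]
        true_genes = list(expr.index[:3])
        scfg = synthetic.SurvivalConfig(true_genes=true_genes, true_coefs=[1.0] * 3, seed=seed)
        surv = synthetic.generate_survival(expr, scfg)
        coefs = signature.stepwise_aic_cox(expr, surv)
        assert set(true_genes) <= set(coefs.index)
        assert all(coefs[g] > 0 for g in true_genes)

    def test_within_one_move_of_exhaustive_minimum(self, survival_cohort):
        expr, surv = survival_cohort["expr"], survival_cohort["survival"]
        candidates = list(expr.index[:3]) + list(expr.index[10:13])  # 3 signal + 3 null
        sub = expr.loc[candidates].iloc[:, :150]
        ssub = surv.loc[sub.columns]
        chosen = signature.stepwise_aic_cox(sub, ssub, candidates=candidates)
        df = sub.T.join(ssub)
        best_aic = np.inf
        best_subset: tuple = ()
        for r in range(0, len(candidates) + 1):
            for combo in itertools.combinations(candidates, r):
                aic, _ = signature._cox_fit(df, list(combo))
                if aic < best_aic:
                    best_aic, best_subset = aic, combo
        found_aic, _ = signature._cox_fit(df, list(chosen.index))
        # stepwise may stop at a local optimum one move from the global one
        assert found_aic <= best_aic + 2.5

    def test_missing_candidate_rejected(self, survival_cohort):
        with pytest.raises(ValueError, match="absent"):
            signature.stepwise_aic_cox(
                survival_cohort["expr"], survival_cohort["survival"], candidates=["NOPE"]
            )


class TestRiskScore:
    def _model(self):
        return signature.SignatureModel(
            genes=["S100P", "LY6D", "WFDC13"], coefficients=[0.44, 0.147, 0.29]
        )

    @pytest.mark.parametrize(
        "values,expected",
        [((1, 1, 1), 0.877), ((0, 0, 0), 0.0), ((2, 1, 0), 1.027)],
    )
    def test_linear_combination(self, values, expected):
        expr = pd.DataFrame(
            {"s1": values}, index=["S100P", "LY6D", "WFDC13"]
        )
        score = signature.risk_score(expr, self._model())
        assert score["s1"] == pytest.approx(expected, abs=1e-12)

    def test_missing_gene_named(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["S100P"])
        with pytest.raises(ValueError, match="LY6D"):
            signature.risk_score(expr, self._model())


class TestOptimalCutpoint:
    def test_cutoff_between_separated_clusters(self):
        rng = np.random.default_rng(1)
        low = rng.uniform(0, 1, 25)
        high = rng.uniform(4, 5, 25)
        scores = pd.Series(np.concatenate([low, high]), index=[f"s{i}" for i in range(50)])
        times = np.concatenate([rng.uniform(10, 20, 25), rng.uniform(1, 2, 25)])
        surv = _surv(times, np.ones(50), list(scores.index))
        cut = signature.optimal_cutpoint(scores, surv)
        assert low.max() < cut < high.min()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 30))
        scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        surv = _surv(rng.exponential(3, n), rng.random(n) < 0.8, list(scores.index))
        cut = signature.optimal_cutpoint(scores, surv, min_group_fraction=0.1)
        # oracle: enumerate every split with the hand-tabulated log-rank
        vals = np.sort(scores.unique())
        min_n = max(1, int(np.ceil(0.1 * n)))
        best_stat, best_high = -np.inf, None
        for c in (vals[:-1] + vals[1:]) / 2:
            high = scores.to_numpy() > c
            if high.sum() < min_n or (~high).sum() < min_n:
                continue
            stat = logrank_oracle(surv["time"], surv["event"], high.astype(int))
            if stat > best_stat + 1e-12:
                best_stat, best_high = stat, high
        assert ((scores.to_numpy() > cut) == best_high).all()

    def test_constant_scores_rejected(self):
        scores = pd.Series([1.0] * 10, index=[f"s{i}" for i in range(10)])
        surv = _surv(np.arange(1, 11), np.ones(10), list(scores.index))
        with pytest.raises(ValueError):
            signature.optimal_cutpoint(scores, surv)


class TestKMLogrank:
    def test_identical_groups_null_statistic(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        surv = _surv(times, events)
        groups = {f"s{i}": ("high" if i < 4 else "low") for i in range(8)}
        ev = signature.km_logrank(groups, surv)
        assert ev.logrank_stat == pytest.approx(0.0, abs=1e-9)
        assert ev.p == pytest.approx(1.0)

    def test_hand_worked_six_subject_example(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 1, 1, 0, 1]
        groups = {f"s{i}": ("high" if i < 3 else "low") for i in range(6)}
        surv = _surv(times, events)
        ev = signature.km_logrank(groups, surv)
        expected = logrank_oracle(times, events, [1, 1, 1, 0, 0, 0])
        assert ev.logrank_stat == pytest.approx(expected, rel=1e-9)

    def test_label_swap_inverts_hazard_ratio(self):
        rng = np.random.default_rng(2)
        times = np.concatenate([rng.exponential(1, 30), rng.exponential(3, 30)])
        surv = _surv(times, np.ones(60))
        g1 = {f"s{i}": ("high" if i < 30 else "low") for i in range(60)}
        g2 = {k: ("low" if v == "high" else "high") for k, v in g1.items()}
        e1 = signature.km_logrank(g1, surv)
        e2 = signature.km_logrank(g2, surv)
        assert e1.logrank_stat == pytest.approx(e2.logrank_stat, rel=1e-9)
        assert e1.hazard_ratio == pytest.approx(1 / e2.hazard_ratio, rel=1e-6)

    def test_no_events_convention(self):
        surv = _surv([1, 2, 3, 4], [0, 0, 0, 0])
        groups = {f"s{i}": ("high" if i < 2 else "low") for i in range(4)}
        ev = signature.km_logrank(groups, surv)
        assert (ev.logrank_stat, ev.p) == (0.0, 1.0)


class TestTimeDependentROC:
    def test_perfect_ordering_auc_one(self):
        n = 40
        times = np.linspace(1, 10, n)
        scores = pd.Series(-times, index=[f"s{i}" for i in range(n)])  # higher score = earlier death
        surv = _surv(times, np.ones(n), list(scores.index))
        aucs = signature.time_dependent_roc(scores, surv, [2.0, 5.0])
        assert aucs[2.0] == pytest.approx(1.0)
        assert aucs[5.0] == pytest.approx(1.0)

    def test_no_censoring_reduces_to_binary_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        n = 200
        times = rng.exponential(5, n)
        scores = pd.Series(-np.log(times) + rng.normal(0, 0.5, n),
                           index=[f"s{i}" for i in range(n)])
        surv = _surv(times, np.ones(n), list(scores.index))
        h = 4.0
        aucs = signature.time_dependent_roc(scores, surv, [h])
        plain = roc_auc_score((times <= h).astype(int), scores)
        assert aucs[h] == pytest.approx(plain, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_uninformative_scores_near_half(self, seed):
        rng = np.random.default_rng(seed)
        n = 500
        times = rng.exponential(5, n)
        scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        surv = _surv(np.minimum(times, 12), (times <= 12).astype(int),
                     list(scores.index))
        aucs = signature.time_dependent_roc(scores, surv, [3.0])
        assert aucs[3.0] == pytest.approx(0.5, abs=0.1)

    def test_horizon_without_events_missing(self):
        surv = _surv([5, 6, 7, 8], [1, 1, 1, 1])
        scores = pd.Series([1, 2, 3, 4.0], index=[f"s{i}" for i in range(4)])
        aucs = signature.time_dependent_roc(scores, surv, [1.0])
        assert np.isnan(aucs[1.0])


class TestValidation:
    def test_empty_cohort_list(self):
        model = signature.SignatureModel(genes=["g"], coefficients=[1.0])
        assert signature.validate_signature(model, []) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_generalizes_to_fresh_cohort_with_same_truth(self, seed):
        def cohort(s):
            cfg = synthetic.CohortConfig(n_tumor=200, n_normal=2, n_genes=5, planted_dmeg={}, seed=s)
            expr = synthetic.generate_expression(cfg, synthetic.GroundTruth())
            expr = expr[[c for c in expr.columns if c.startswith("T")]]
            genes = list(expr.index[:2])
            scfg = synthetic.SurvivalConfig(true_genes=genes, true_coefs=[1.0, 1.0], seed=s)
            return expr, synthetic.generate_survival(expr, scfg), genes

        expr, surv, genes = cohort(seed)
        coefs = signature.stepwise_aic_cox(expr, surv, candidates=genes)
        model = signature.SignatureModel(genes=list(coefs.index), coefficients=list(coefs))
        raw = signature.risk_score(expr, model)
        model.z_mean, model.z_sd = float(raw.mean()), float(raw.std(ddof=0))
        vexpr, vsurv, _ = cohort(seed + 1000)
        [ev] = signature.validate_signature(model, [(vexpr, vsurv)])
        assert ev.hazard_ratio > 1
        assert ev.p < 0.05

    def test_null_cohort_not_significant(self):
        sig = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            expr = pd.DataFrame(rng.normal(7, 1, (3, 150)), index=["a", "b", "c"],
                                columns=[f"s{i}" for i in range(150)])
            surv = _surv(rng.exponential(5, 150), np.ones(150), list(expr.columns))
            model = signature.SignatureModel(genes=["a", "b"], coefficients=[1.0, 1.0],
                                             z_mean=14.0, z_sd=1.5)
            [ev] = signature.validate_signature(model, [(expr, surv)])
            sig += ev.p < 0.01
        assert sig <= 1


def test_model_json_roundtrip(tmp_path):
    model = signature.SignatureModel(
        genes=["a", "b"], coefficients=[0.5, -0.2], z_mean=1.0, z_sd=2.0, cutoff=0.3
    )
    model.to_json(tmp_path / "m.json")
    loaded = signature.SignatureModel.from_json(tmp_path / "m.json")
    assert loaded == model
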