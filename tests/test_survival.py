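"""Cox risk score, median split, log-rank test and age classification."""

import numpy as np
import pandas as pd
import pytest

from crconset.simulate import SimulationSpec, simulate_survival
from crconset.survivalrisk import (
    RiskModel,
    classify_age_days,
    compute_risk_score,
    fit_cox,
    logrank_test,
    median_split,
)


class TestAgeClassification:
    @pytest.mark.parametrize(
        "days,expected",
        [(18250, "early"), (18251, "late"), (10000, "early"), (0, "early")],
    )
    def test_day_threshold(self, days, expected):
        assert classify_age_days(days) == expected

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            classify_age_days(-1)


class TestRiskScore:
    def test_zero_coefficients_zero_scores(self):
        model = RiskModel(["a", "b"], np.zeros(2))
        expr = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["a", "b"],
                            columns=["s1", "s2"])
        assert (compute_risk_score(model, expr) == 0).all()

    def test_linear_combination(self):
        model = RiskModel(["a", "b"], np.array([1.0, -1.0]))
        expr = pd.DataFrame({"s": [5.0, 3.0]}, index=["a", "b"])
        assert compute_risk_score(model, expr)["s"] == 2.0

    def test_missing_gene_named(self):
        model = RiskModel(["a", "zz"], np.ones(2))
        expr = pd.DataFrame({"s": [5.0]}, index=["a"])
        with pytest.raises(KeyError, match="zz"):
            compute_risk_score(model, expr)

    def test_matches_loop_dot_product(self, rng):
        genes = [f"g{i}" for i in range(6)]
        model = RiskModel(genes, rng.normal(size=6))
        expr = pd.DataFrame(rng.normal(size=(6, 9)), index=genes,
                            columns=[f"s{i}" for i in range(9)])
        scores = compute_risk_score(model, expr)
        for s in expr.columns:
            manual = sum(
                c * expr.loc[g, s] for g, c in zip(genes, model.coefficients)
            )
            assert scores[s] == pytest.approx(manual)

    def test_affine_equivariance(self, rng):
        genes = ["a", "b"]
        model = RiskModel(genes, rng.normal(size=2))
        expr = pd.DataFrame(rng.normal(size=(2, 5)), index=genes)
        assert np.allclose(
            compute_risk_score(model, expr * 3.0), 3.0 * compute_risk_score(model, expr)
        )


class TestMedianSplit:
    def test_even_n_midpoint(self):
        groups = median_split(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert list(groups) == ["low", "low", "high", "high"]

    def test_score_at_median_goes_high(self):
        groups = median_split(pd.Series([1.0, 2.0, 3.0]))
        assert groups.iloc[1] == "high"

    def test_all_equal_scores_all_high(self):
        assert (median_split(pd.Series([2.0, 2.0, 2.0])) == "high").all()


class TestLogRank:
    def test_identical_groups_null(self):
        surv = pd.DataFrame(
            {"time": [1, 2, 3, 1, 2, 3], "event": [True] * 6},
            index=list("abcdef"),
        )
        groups = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
        stat, p = logrank_test(groups, surv)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_computed_case(self):
        """Alternating event times 1..6, group A = {1,3,5}.  Walking the risk
        tables by hand: O-E contributions 1/2, -2/5, 1/2, -1/3, 1/2, 0 sum to
        23/30; variances 1/4, 6/25, 1/4, 2/9, 1/4 sum to 1091/900; the
        statistic is (23/30)^2 / (1091/900) = 529/1091."""
        surv = pd.DataFrame(
            {"time": [1, 3, 5, 2, 4, 6], "event": [True] * 6},
            index=list("abcdef"),
        )
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=list("abcdef"))
        stat, _ = logrank_test(groups, surv)
        assert stat == pytest.approx(529 / 1091)

    def test_agrees_with_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        n = 80
        time = rng.exponential(10, size=n)
        event = rng.random(n) < 0.8
        surv = pd.DataFrame({"time": time, "event": event},
                            index=[f"s{i}" for i in range(n)])
        groups = pd.Series(np.where(rng.random(n) < 0.5, "a", "b"), index=surv.index)
        stat, p = logrank_test(groups, surv)
        mask = (groups == "a").to_numpy()
        ref = ll_logrank(time[mask], time[~mask], event[mask], event[~mask])
        assert stat == pytest.approx(ref.test_statistic, rel=1e-8)
        assert p == pytest.approx(ref.p_value, rel=1e-8)

    def test_null_type_one_error(self):
        """Rejection rate at alpha=0.05 stays near nominal over 500 null reps."""
        rej = 0
        n_reps = 500
        for i in range(n_reps):
            spec = SimulationSpec(seed=20_000 + i)
            surv = simulate_survival(spec, pd.Series(np.zeros(60)))
            groups = pd.Series(
                np.where(np.arange(60) < 30, "a", "b"), index=surv.index
            )
            _, p = logrank_test(groups, surv)
            rej += p < 0.05
        assert 0.02 <= rej / n_reps <= 0.08


class TestCoxFit:
    def _simulate(self, spec, n, k=8):
        rng = np.random.default_rng(spec.seed + 99)
        genes = [f"g{i}" for i in range(k)]
        expr = pd.DataFrame(
            rng.normal(size=(k, n)), index=genes, columns=[f"s{i}" for i in range(n)]
        )
        beta = np.asarray(spec.true_coefficients[:k])
        scores = pd.Series(beta @ expr.to_numpy(), index=expr.columns)
        return expr, simulate_survival(spec, scores), beta

    def test_recovers_known_coefficients(self, spec):
        expr, surv, beta = self._simulate(spec, n=500)
        model = fit_cox(expr, surv)
        assert np.all(np.abs(model.coefficients - beta) < 0.2)

    def test_null_simulation_centers_on_zero(self):
        """With expression independent of survival the fits scatter around 0."""
        betas = []
        for i in range(200):
            s = SimulationSpec(seed=40_000 + i)
            rng = np.random.default_rng(s.seed + 99)
            expr = pd.DataFrame(rng.normal(size=(2, 80)),
                                index=["a", "b"],
                                columns=[f"s{i}" for i in range(80)])
            surv = simulate_survival(s, pd.Series(np.zeros(80), index=expr.columns))
            betas.append(fit_cox(expr, surv).coefficients)
        betas = np.array(betas)
        assert np.all(np.abs(betas.mean(axis=0)) < 3 * betas.std(axis=0) / np.sqrt(200))

    def test_duplicated_covariate_rejected(self, spec):
        expr, surv, _ = self._simulate(spec, n=100, k=2)
        expr.loc["g1"] = expr.loc["g0"]
        with pytest.raises(ValueError, match="singular|collinear"):
            fit_cox(expr, surv)

    def test_too_few_events_rejected(self, spec):
        expr, surv, _ = self._simulate(spec, n=30, k=2)
        surv["event"] = False
        surv.iloc[:5, surv.columns.get_loc("event")] = True
        with pytest.raises(ValueError, match="events"):
            fit_cox(expr, surv)

    def test_agrees_with_independent_partial_likelihood_fit(self, spec):
        """Tie-free data: our Breslow Newton fit matches lifelines."""
        from lifelines import CoxPHFitter

        expr, surv, _ = self._simulate(spec, n=150, k=3)
        model = fit_cox(expr, surv)
        df = surv.copy()
        for g in expr.index:
            df[g] = expr.loc[g]
        cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
        assert np.allclose(
            model.coefficients, cph.params_[list(expr.index)].to_numpy(), atol=1e-4
        )
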