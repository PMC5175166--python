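import math

import numpy as np
import pandas as pd
import pytest

from tftea.io import ClinicalTable
from tftea.personalized import SampleActivityMatrix
from tftea.simulate import simulate_survival_data
from tftea.survival import (cox_fit, cox_stepwise, km_logrank, logrank_screen,
                            _logrank_two_sample)


def hand_logrank(time, event, in_high):
    """Textbook O-E / hypergeometric-variance computation, scalar loops."""
    o_minus_e = 0.0
    var = 0.0
    for t in sorted({tt for tt, ee in zip(time, event) if ee == 1}):
        at_risk = [i for i, tt in enumerate(time) if tt >= t]
        n = len(at_risk)
        n1 = sum(1 for i in at_risk if in_high[i])
        deaths = [i for i, (tt, ee) in enumerate(zip(time, event))
                  if tt == t and ee == 1]
        d = len(deaths)
        d1 = sum(1 for i in deaths if in_high[i])
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e * o_minus_e / var if var > 0 else 0.0


def activity_matrix(values: dict[str, dict[str, float]]) -> SampleActivityMatrix:
    act = pd.DataFrame(values).T
    return SampleActivityMatrix(activity=act, p=act * math.nan,
                                adj_p=act * math.nan)


class TestLogrank:
    def test_six_subject_hand_computation(self, toy_clinical):
        # groups: s1-s3 high, s4-s6 low
        act = pd.Series([1.0, 1.0, 1.0, -1.0, -1.0, -1.0],
                        index=[f"s{i}" for i in range(1, 7)])
        res = km_logrank(act, toy_clinical, min_events=4)
        time = toy_clinical.data["time"].tolist()
        event = toy_clinical.data["event"].tolist()
        expected = hand_logrank(time, event, [True] * 3 + [False] * 3)
        assert res.logrank_stat == pytest.approx(expected, abs=1e-10)
        assert res.n_events == 4

    def test_exchangeable_groups_stat_zero(self):
        # identical survival experience mirrored across the two groups
        cl = ClinicalTable(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(8)],
            "time": [1, 2, 3, 4, 1, 2, 3, 4],
            "event": [1, 1, 1, 0, 1, 1, 1, 0]}))
        act = pd.Series([1, 1, 1, 1, -1, -1, -1, -1],
                        index=[f"s{i}" for i in range(8)], dtype=float)
        res = km_logrank(act, cl, min_events=4)
        assert res.logrank_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_below_min_events_untested(self, toy_clinical):
        act = pd.Series([1.0, 1.0, 1.0, -1.0, -1.0, -1.0],
                        index=[f"s{i}" for i in range(1, 7)])
        res = km_logrank(act, toy_clinical, min_events=10)
        assert not res.tested
        assert res.n_events == 4

    def test_constant_activity_untested(self, toy_clinical):
        act = pd.Series(0.5, index=[f"s{i}" for i in range(1, 7)])
        assert not km_logrank(act, toy_clinical, min_events=2).tested

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(23)
        n = 60
        ids = [f"s{i}" for i in range(n)]
        cl = ClinicalTable(pd.DataFrame({
            "sample_id": ids,
            "time": rng.exponential(10, n).round(2),
            "event": rng.integers(0, 2, n)}))
        act = pd.Series(rng.normal(size=n), index=ids)
        r1 = km_logrank(act, cl, min_events=5)
        r2 = km_logrank(np.exp(3 * act), cl, min_events=5)
        assert r1.logrank_stat == pytest.approx(r2.logrank_stat, abs=1e-12)
        assert (r1.n_high, r1.n_low) == (r2.n_high, r2.n_low)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(4)
        for _ in range(5):
            n = 50
            t = rng.exponential(8, n).round(1)
            e = rng.integers(0, 2, n)
            g = rng.integers(0, 2, n).astype(bool)
            if e.sum() == 0 or g.all() or not g.any():
                continue
            stat, p = _logrank_two_sample(t, e, g)
            ref = logrank_test(t[g], t[~g], e[g], e[~g])
            assert stat == pytest.approx(ref.test_statistic, abs=1e-10)
            assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_screen_bh_over_tested_only(self):
        rng = np.random.default_rng(6)
        n = 40
        ids = [f"s{i}" for i in range(n)]
        cl = ClinicalTable(pd.DataFrame({
            "sample_id": ids,
            "time": rng.exponential(5, n).round(2),
            "event": rng.integers(0, 2, n)}))
        vals = {f"TF{i}": dict(zip(ids, rng.normal(size=n))) for i in range(4)}
        vals["flat"] = dict(zip(ids, np.zeros(n)))  # untestable: no split
        results = logrank_screen(activity_matrix(vals), cl, min_events=5)
        tested = [r for r in results if r.tested]
        assert len(tested) == 4
        flat = next(r for r in results if r.tf_name == "flat")
        assert math.isnan(flat.adj_p)


class TestCoxFit:
    def test_matches_lifelines_without_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(9)
        n = 120
        X = pd.DataFrame(rng.standard_normal((n, 2)), columns=["a", "b"])
        t = rng.exponential(1 / np.exp(0.7 * X["a"].to_numpy()))
        e = rng.integers(0, 2, n)
        e[0] = 1
        coefs, ll = cox_fit(X, t, e)
        df = X.assign(T=t, E=e)
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(coefs["coef"], cph.params_, atol=1e-4)
        np.testing.assert_allclose(coefs["se"], cph.standard_errors_, atol=1e-4)
        assert ll == pytest.approx(cph.log_likelihood_, abs=1e-4)

    def test_null_model_loglik(self):
        # with no covariates the Breslow partial likelihood is
        # -sum over event times of d_t * log(n at risk)
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 1])
        _, ll = cox_fit(pd.DataFrame(index=range(4)), t, e)
        expected = -(math.log(4) + math.log(3) + math.log(1))
        assert ll == pytest.approx(expected, abs=1e-12)


class TestCoxStepwise:
    def test_single_candidate_reduces_to_aic_comparison(self):
        X, cl = simulate_survival_data(120, ["TFA"], {"TFA": 1.0}, seed=42)
        model = cox_stepwise(X, cl)
        design = X.T.copy()
        t = cl.data["time"].to_numpy()
        e = cl.data["event"].to_numpy()
        _, ll0 = cox_fit(design[[]], t, e)
        _, ll1 = cox_fit(design[["TFA"]], t, e)
        aic0, aic1 = -2 * ll0, -2 * ll1 + 2
        if aic1 < aic0:
            assert model.selected_variables == ["TFA"]
            assert model.aic == pytest.approx(aic1)
        else:
            assert model.selected_variables == []
        assert model.null_aic == pytest.approx(aic0)

    def test_final_aic_never_above_null(self):
        X, cl = simulate_survival_data(150, [f"TF{i}" for i in range(4)],
                                       {"TF1": 0.8}, seed=7)
        model = cox_stepwise(X, cl)
        assert model.aic <= model.null_aic + 1e-9

    def test_planted_variable_recovered(self):
        X, cl = simulate_survival_data(300, [f"TF{i}" for i in range(5)],
                                       {"TF2": 1.0}, seed=11)
        model = cox_stepwise(X, cl)
        assert "TF2" in model.selected_variables
        assert model.coefficients.loc["TF2", "coef"] == pytest.approx(1.0, abs=0.35)

    def test_collinear_candidate_dropped(self):
        X, cl = simulate_survival_data(100, ["TFA"], {"TFA": 1.2}, seed=3)
        X.loc["TFB"] = 2.0 * X.loc["TFA"]  # perfectly collinear
        model = cox_stepwise(X, cl)
        assert "TFA" in model.selected_variables
        assert "TFB" not in model.selected_variables
        assert any("TFB" in w for w in model.warnings)

    def test_purity_enters_candidates_when_requested(self):
        X, cl = simulate_survival_data(200, ["TFA"], {}, seed=8, purity=True)
        # make purity strongly prognostic: rebuild times from purity
        rng = np.random.default_rng(1)
        pur = cl.data["purity"].to_numpy()
        death = rng.exponential(1.0 / (0.1 * np.exp(3.0 * (pur - pur.mean()))))
        cl2 = ClinicalTable(cl.data.assign(time=death, event=1))
        model = cox_stepwise(X, cl2, include_purity=True)
        assert "PURITY" in model.selected_variables

    def test_no_events_rejected(self):
        X, cl = simulate_survival_data(30, ["TFA"], {}, seed=2)
        cl0 = ClinicalTable(cl.data.assign(event=0))
        with pytest.raises(ValueError, match="no events"):
            cox_stepwise(X, cl0)
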