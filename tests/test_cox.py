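import numpy as np
import pandas as pd
import pytest

from trialemu import CoxTimeVarying, fit_cox, hazard_ratio, score_test_null
from trialemu.cox import ConvergenceError, CoxResults

from oracles import (
    breslow_loglik,
    efron_loglik,
    maximize_partial_likelihood,
)


def _df(start, stop, event, x, w=None, pid=None):
    n = len(stop)
    return pd.DataFrame(
        {
            "patient_id": pid if pid is not None else np.arange(n),
            "start": start, "stop": stop, "event": event, "x": x,
            "weight": w if w is not None else np.ones(n),
        }
    )


# oracle toys: (start, stop, event, x, w); n <= 8, with and without ties
ORACLE_TOYS = [
    ([0] * 6, [1, 2, 3, 4, 5, 6], [1] * 6, [1, 0, 1, 0, 1, 0], [1.0] * 6),
    ([0] * 6, [2, 2, 3, 3, 5, 6], [1] * 6, [1, 0, 1, 0, 1, 0], [1.0] * 6),
    ([0] * 8, [1, 1, 2, 2, 3, 3, 4, 5], [1, 1, 1, 0, 1, 1, 0, 1],
     [1, 1, 0, 0, 1, 0, 1, 0], [1.0] * 8),
    ([0, 0, 1, 1, 0, 2], [3, 4, 4, 5, 6, 7], [1, 1, 0, 1, 1, 1],
     [0, 1, 1, 0, 1, 0], [1.0] * 6),
    ([0] * 7, [2, 2, 2, 4, 4, 6, 7], [1, 1, 0, 1, 1, 1, 0],
     [1, 0, 1, 0, 1, 0, 1], [2.0, 1.0, 1.0, 3.0, 1.0, 1.0, 2.0]),
]


class TestAgainstBruteForceOracle:
    @pytest.mark.parametrize("toy", ORACLE_TOYS)
    @pytest.mark.parametrize(
        "ties,loglik", [("breslow", breslow_loglik), ("efron", efron_loglik)]
    )
    def test_coefficient_matches_enumerated_likelihood_argmax(
        self, toy, ties, loglik
    ):
        start, stop, event, x, w = toy
        beta_oracle = maximize_partial_likelihood(
            loglik, start, stop, event, x, w
        )
        fit = fit_cox(_df(start, stop, event, x, w), ["x"], ties=ties,
                      robust=False)
        assert fit.converged
        assert abs(fit.params["x"] - beta_oracle) < 1e-6

    def test_loglik_value_matches_oracle_at_fit(self):
        start, stop, event, x, w = ORACLE_TOYS[1]
        fit = fit_cox(_df(start, stop, event, x, w), ["x"], ties="efron",
                      robust=False)
        ll = efron_loglik(start, stop, event, x, w, fit.params["x"])
        assert fit.loglik == pytest.approx(ll, abs=1e-9)


class TestInvariances:
    def test_label_symmetric_groups_give_zero_coefficient(self):
        # identical event-time multisets in both groups
        stop = [1, 1, 2, 2, 3, 3]
        x = [0, 1, 0, 1, 0, 1]
        fit = fit_cox(_df([0] * 6, stop, [1] * 6, x), ["x"], robust=False)
        assert abs(fit.params["x"]) < 1e-10

    def test_time_shift_and_id_relabel_invariance(self):
        rng = np.random.default_rng(4)
        stop = rng.integers(1, 12, 40)
        event = rng.random(40) < 0.7
        x = rng.standard_normal(40)
        base = fit_cox(_df([0] * 40, stop, event, x), ["x"], robust=False)
        shifted = fit_cox(
            _df([10] * 40, stop + 10, event, x, pid=rng.permutation(40)),
            ["x"], robust=False,
        )
        assert base.params["x"] == pytest.approx(shifted.params["x"], abs=1e-10)

    def test_efron_equals_breslow_without_ties(self):
        stop = [1, 3, 4, 7, 9, 12]
        x = [1, 0, 0, 1, 1, 0]
        e = fit_cox(_df([0] * 6, stop, [1, 1, 0, 1, 1, 1], x), ["x"],
                    ties="efron", robust=False)
        b = fit_cox(_df([0] * 6, stop, [1, 1, 0, 1, 1, 1], x), ["x"],
                    ties="breslow", robust=False)
        assert e.params["x"] == pytest.approx(b.params["x"], abs=1e-12)
        assert e.loglik == pytest.approx(b.loglik, abs=1e-12)

    def test_unit_weights_equal_omitted_weights(self):
        rng = np.random.default_rng(9)
        stop = rng.integers(1, 10, 30)
        event = rng.random(30) < 0.6
        x = rng.standard_normal(30)
        df = _df([0] * 30, stop, event, x)
        a = fit_cox(df, ["x"], robust=False)
        b = CoxTimeVarying(df, ["x"], weight_col=None).fit(robust=False)
        assert a.params["x"] == pytest.approx(b.params["x"], abs=1e-12)

    def test_breslow_integer_weights_equal_replication(self):
        start, stop, event, x, w = ORACLE_TOYS[4]
        wi = np.array(w, dtype=int)
        rep = _df(
            np.repeat(start, wi), np.repeat(stop, wi), np.repeat(event, wi),
            np.repeat(x, wi),
        )
        a = fit_cox(_df(start, stop, event, x, w), ["x"], ties="breslow",
                    robust=False)
        b = fit_cox(rep, ["x"], ties="breslow", robust=False)
        assert a.params["x"] == pytest.approx(b.params["x"], abs=1e-9)


class TestVariancesAgainstSurvivalPackage:
    """Frozen reference values computed with R survival::coxph (v3.8)."""

    @staticmethod
    def _dataset():
        rng = np.random.default_rng(3)
        n = 300
        stop = rng.integers(1, 20, n).astype(float)
        event = (rng.random(n) < 0.7).astype(int)
        x1 = rng.standard_normal(n)
        x2 = (rng.random(n) < 0.5).astype(float)
        return pd.DataFrame(
            {
                "patient_id": np.arange(n), "start": 0.0, "stop": stop,
                "event": event, "x1": x1, "x2": x2, "weight": 1.0,
            }
        )

    def test_efron_coefficients_and_both_variances(self):
        fit = fit_cox(self._dataset(), ["x1", "x2"], ties="efron")
        np.testing.assert_allclose(
            fit.params.to_numpy(), [-0.06593276, -0.15914592], atol=5e-7
        )
        np.testing.assert_allclose(
            fit.bse.to_numpy(), [0.07175207, 0.13840838], atol=5e-7
        )
        np.testing.assert_allclose(
            fit.robust_bse.to_numpy(), [0.06834889, 0.13776497], atol=5e-7
        )

    def test_breslow_robust_variance(self):
        fit = fit_cox(self._dataset(), ["x1", "x2"], ties="breslow")
        np.testing.assert_allclose(
            fit.robust_bse.to_numpy(), [0.06480514, 0.13036316], atol=5e-7
        )

    def test_lifelines_agrees_on_coefficients(self):
        lifelines = pytest.importorskip("lifelines")
        df = self._dataset()
        fit = fit_cox(df, ["x1", "x2"], robust=False)
        cph = lifelines.CoxPHFitter()
        cph.fit(
            df[["stop", "event", "x1", "x2"]], "stop", "event"
        )
        np.testing.assert_allclose(
            fit.params.to_numpy(), cph.params_.to_numpy(), atol=1e-6
        )


class TestHazardRatio:
    def test_closed_form_wald_interval(self):
        idx = pd.Index(["x"])
        res = CoxResults(
            params=pd.Series([0.0], index=idx),
            cov=pd.DataFrame([[0.01]], index=idx, columns=idx),
            robust_cov=None, loglik=0.0, n_iter=1, converged=True,
            ties="efron", n_events=10, n_obs=10,
            monotone=pd.Series([False], index=idx),
        )
        hr, lo, hi = hazard_ratio(res, "x")
        assert hr == pytest.approx(1.0)
        assert lo == pytest.approx(np.exp(-1.959963984540054 * 0.1), abs=1e-9)
        assert hi == pytest.approx(np.exp(1.959963984540054 * 0.1), abs=1e-9)
        assert lo < hr < hi

    def test_log_two_coefficient_doubles_hazard(self):
        idx = pd.Index(["x"])
        res = CoxResults(
            params=pd.Series([np.log(2.0)], index=idx),
            cov=pd.DataFrame([[0.04]], index=idx, columns=idx),
            robust_cov=None, loglik=0.0, n_iter=1, converged=True,
            ties="efron", n_events=10, n_obs=10,
            monotone=pd.Series([False], index=idx),
        )
        assert res.hazard_ratio("x")[0] == pytest.approx(2.0)

    def test_unknown_name_rejected(self):
        fit = fit_cox(_df([0] * 4, [1, 2, 3, 4], [1, 1, 1, 1], [1, 0, 1, 0]),
                      ["x"], robust=False)
        with pytest.raises(KeyError):
            fit.hazard_ratio("nope")


class TestDegenerateInputs:
    def test_constant_covariate_raises_convergence_error(self):
        with pytest.raises(ConvergenceError):
            fit_cox(_df([0] * 4, [1, 2, 3, 4], [1, 1, 1, 1], [1, 1, 1, 1]),
                    ["x"])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            fit_cox(_df([0] * 3, [1, 2, 3], [0, 0, 0], [1, 0, 1]), ["x"])

    def test_monotone_likelihood_flagged_and_capped(self):
        # group 1 always fails first: likelihood increases without bound
        stop = [1, 2, 3, 11, 12, 13]
        x = [1, 1, 1, 0, 0, 0]
        fit = fit_cox(_df([0] * 6, stop, [1] * 6, x), ["x"], robust=False)
        assert fit.monotone["x"]
        assert np.isfinite(fit.params["x"])


class TestScoreTest:
    def test_symmetric_data_statistic_near_zero(self):
        stop = [1, 1, 2, 2, 3, 3]
        x = [0, 1, 0, 1, 0, 1]
        stat = score_test_null(_df([0] * 6, stop, [1] * 6, x), "x")
        assert stat < 1e-20

    def test_equals_gradient_squared_over_information(self):
        """Score statistic vs numerical differentiation of the likelihood."""
        start, stop, event, x, w = ORACLE_TOYS[3]
        df = _df(start, stop, event, x, w)
        stat = score_test_null(df, "x", ties="breslow")
        # standardized covariate as the engine uses internally
        xs = (np.array(x) - np.mean(x)) / np.std(x)
        h = 1e-5
        ll = lambda b: breslow_loglik(start, stop, event, xs, w, b)
        g = (ll(h) - ll(-h)) / (2 * h)
        info = -(ll(h) - 2 * ll(0.0) + ll(-h)) / h**2
        assert stat == pytest.approx(g**2 / info, rel=1e-4)

    def test_monotone_in_group_imbalance(self):
        stats = []
        for k in (1, 2, 3):
            # k early events in group 1 vs late events in group 0
            stop = [1] * k + [10, 11, 12, 13]
            x = [1] * k + [0, 0, 0, 0]
            stats.append(
                score_test_null(
                    _df([0] * (k + 4), stop, [1] * (k + 4), x), "x"
                )
            )
        assert stats[0] < stats[1] < stats[2]
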