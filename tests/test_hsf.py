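import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tundratrack import hsf


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        # k ones of n: intercept = log(k/(n-k)), logLik = k log(k/n) +
        # (n-k) log(1-k/n)
        n, k = 50, 18
        y = np.zeros(n)
        y[:k] = 1
        fit = hsf.fit_logistic(pd.DataFrame(index=range(n)), y)
        assert fit.coef("const") == pytest.approx(np.log(k / (n - k)))
        expected_ll = k * np.log(k / n) + (n - k) * np.log(1 - k / n)
        assert fit.loglik == pytest.approx(expected_ll)

    def test_two_by_two_log_odds_ratio(self):
        # balanced 2x2 table: slope equals the table's log odds ratio
        a, b, c, d = 30, 10, 15, 25  # y=1|x=1, y=0|x=1, y=1|x=0, y=0|x=0
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        fit = hsf.fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.coef("x") == pytest.approx(np.log(a * d / (b * c)))

    def test_separation_raises(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(float)
        with pytest.raises(hsf.SeparationError):
            hsf.fit_logistic(pd.DataFrame({"x": x}), y)

    def test_rank_deficiency_raises(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = rng.integers(0, 2, 30).astype(float)
        with pytest.raises(ValueError):
            hsf.fit_logistic(X, y)

    def test_grid_search_mle_agreement(self, rng):
        """ML estimates match a brute-force likelihood grid search."""
        x = rng.normal(size=120)
        y = (rng.uniform(size=120) < 1 / (1 + np.exp(-(0.3 + 0.9 * x))))
        fit = hsf.fit_logistic(pd.DataFrame({"x": x}), y.astype(float))

        def nll(b0, b1):
            eta = b0 + b1 * x
            return -(y * eta - np.logaddexp(0, eta)).sum()

        b0g = np.linspace(fit.coef("const") - 0.5, fit.coef("const") + 0.5,
                          201)
        b1g = np.linspace(fit.coef("x") - 0.5, fit.coef("x") + 0.5, 201)
        grid = np.array([[nll(a, b) for b in b1g] for a in b0g])
        i, j = np.unravel_index(grid.argmin(), grid.shape)
        assert b0g[i] == pytest.approx(fit.coef("const"), abs=1e-2)
        assert b1g[j] == pytest.approx(fit.coef("x"), abs=1e-2)


class TestAicc:
    def test_arithmetic_example(self):
        assert hsf.aicc(0.0, 1, 3) == pytest.approx(6.0)

    def test_limits_to_aic(self):
        k = 2
        ll = -100.0
        aic = -2 * ll + 2 * k
        assert abs(hsf.aicc(ll, k, 10**6) - aic) < 1e-5 * k

    def test_independent_formula(self, rng):
        for _ in range(10):
            ll = rng.uniform(-500, 0)
            k = int(rng.integers(1, 8))
            n = int(rng.integers(k + 2, 500))
            expected = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            assert hsf.aicc(ll, k, n) == pytest.approx(expected)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            hsf.aicc(0.0, 3, 4)


class TestAkaikeWeights:
    def test_two_model_closed_form(self):
        w = hsf.akaike_weights([0.0, 2.0])
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1.0)))
        assert w[1] == pytest.approx(np.exp(-1.0) / (1 + np.exp(-1.0)))

    def test_single_model(self):
        assert hsf.akaike_weights([0.0])[0] == 1.0

    def test_sum_to_one(self, rng):
        w = hsf.akaike_weights(rng.uniform(0, 40, size=12))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


class TestInformativeCheck:
    def make_fit(self, est, se):
        return hsf.FitResult(names=["const", "x"],
                             params=np.array([0.0, est]),
                             bse=np.array([1.0, se]),
                             cov=np.eye(2), loglik=0.0, k=2, n=100,
                             converged=True)

    def test_zero_estimate_uninformative(self):
        assert not hsf.informative_check(self.make_fit(0.0, 0.5))["x"]

    def test_tight_estimate_informative(self):
        # z_0.925 = 1.4395...; CI = 1 +- 0.144 excludes 0
        z = stats.norm.ppf(0.925)
        assert z == pytest.approx(1.4395, abs=1e-4)
        assert hsf.informative_check(self.make_fit(1.0, 0.1))["x"]

    def test_wide_estimate_uninformative(self):
        assert not hsf.informative_check(self.make_fit(1.0, 1.0))["x"]


class TestVif:
    def test_orthogonal_columns_unity(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame({"a": np.cos(2 * np.pi * t / n),
                          "b": np.sin(2 * np.pi * t / n)})
        vifs = hsf.vif(X)
        for v in vifs.values():
            assert v == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_column_errors(self, rng):
        x = rng.normal(size=50)
        with pytest.raises(ValueError):
            hsf.vif(pd.DataFrame({"a": x, "b": x}))

    def test_correlated_pair_closed_form(self, rng):
        # two predictors with correlation r: VIF = 1/(1-r^2)
        n = 10_000
        r = 0.9
        a = rng.normal(size=n)
        b = r * a + np.sqrt(1 - r**2) * rng.normal(size=n)
        vifs = hsf.vif(pd.DataFrame({"a": a, "b": b}))
        assert vifs["a"] == pytest.approx(1 / (1 - 0.81), rel=0.05)

    def test_high_vif_warns(self, rng):
        n = 500
        a = rng.normal(size=n)
        b = 0.995 * a + 0.1 * rng.normal(size=n)
        with pytest.warns(UserWarning):
            hsf.vif(pd.DataFrame({"a": a, "b": b}))


class TestLogRss:
    def make_fit(self, rng):
        x = rng.normal(size=400)
        w = rng.normal(size=400)
        eta = -0.5 + 1.2 * x - 0.7 * w
        y = (rng.uniform(size=400) < 1 / (1 + np.exp(-eta))).astype(float)
        return hsf.fit_logistic(pd.DataFrame({"x": x, "w": w}), y)

    def test_equal_profiles_zero(self, rng):
        fit = self.make_fit(rng)
        est, (lo, hi) = hsf.log_rss(fit, {"x": 1.0}, {"x": 1.0})
        assert est == 0.0
        assert lo <= 0.0 <= hi

    def test_unit_difference_equals_coefficient(self, rng):
        fit = self.make_fit(rng)
        est, _ = hsf.log_rss(fit, {"x": 1.0}, {"x": 0.0})
        assert est == pytest.approx(fit.coef("x"))

    def test_matches_linear_predictor_difference(self, rng):
        fit = self.make_fit(rng)
        x1 = {"x": 0.7, "w": -1.1}
        x2 = {"x": -0.2, "w": 0.4}
        est, _ = hsf.log_rss(fit, x1, x2)
        direct = (fit.coef("x") * (x1["x"] - x2["x"])
                  + fit.coef("w") * (x1["w"] - x2["w"]))
        assert est == pytest.approx(direct, abs=1e-12)

    def test_unknown_variable_rejected(self, rng):
        fit = self.make_fit(rng)
        with pytest.raises(ValueError):
            hsf.log_rss(fit, {"zz": 1.0}, {})


class TestRankModels:
    def simulate(self, rng, n=300, beta_x=1.0):
        tab = pd.DataFrame({
            "x": rng.normal(size=n),
            "u": rng.normal(size=n),
            "v": rng.normal(size=n),
        })
        eta = -0.3 + beta_x * tab["x"]
        tab["used"] = (rng.uniform(size=n)
                       < 1 / (1 + np.exp(-eta))).astype(float)
        return tab

    def test_weights_sum_to_one_and_best_is_zero(self, rng):
        tab = self.simulate(rng)
        ranking = hsf.rank_models(tab, "used", ["x", "u", "v"])
        assert ranking.table["w"].sum() == pytest.approx(1.0, abs=1e-12)
        assert ranking.table["dAICc"].iloc[0] == 0.0

    def test_true_predictor_in_supported_set(self, rng):
        """With a 1-sd effect, the supported set contains the true model
        in >= 90% of replicates."""
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            tab = self.simulate(rng, n=300, beta_x=1.0)
            ranking = hsf.rank_models(tab, "used", ["x", "u", "v"])
            supported = ranking.table[ranking.table["supported"]]["model"]
            hits += any(("x" in m.split(" + ")) or m.startswith("x")
                        for m in supported)
        assert hits / n_rep >= 0.9

    def test_retained_is_parsimonious(self, rng):
        tab = self.simulate(rng, n=600, beta_x=1.5)
        ranking = hsf.rank_models(tab, "used", ["x", "u", "v"])
        # the retained model should be the single-term true model
        assert ranking.retained == "x"
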