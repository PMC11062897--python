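import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from tundratrack import lsd
from tundratrack import hsf


def simulate_glmm(rng, n_groups=12, n_per=60, beta=(-0.4, 0.7, -0.3),
                  random_sd=0.8):
    rows = []
    for g in range(n_groups):
        b = rng.normal(0, random_sd)
        X = rng.normal(size=(n_per, len(beta) - 1))
        eta = beta[0] + X @ np.array(beta[1:]) + b
        y = rng.uniform(size=n_per) < 1 / (1 + np.exp(-eta))
        for i in range(n_per):
            rows.append({"individual_id": f"g{g}", "stopover": int(y[i]),
                         "x0": X[i, 0], "x1": X[i, 1]})
    return pd.DataFrame(rows)


class TestGlmm:
    def test_zero_random_sd_matches_plain_logistic(self, rng):
        """In the sd -> 0 limit the marginal GLMM likelihood reduces to
        the plain logistic likelihood; the free fit on sd-0 data stays
        near-singular with close coefficients."""
        df = simulate_glmm(rng, random_sd=0.0, n_groups=10, n_per=80)
        plain = hsf.fit_logistic(df[["x0", "x1"]],
                                 df["stopover"].to_numpy(float))
        fixed = lsd.fit_glmm_logistic(df, ["x0", "x1"],
                                      fixed_random_sd=1e-8)
        np.testing.assert_allclose(fixed.params, plain.params, atol=1e-3)
        assert fixed.loglik == pytest.approx(plain.loglik, abs=1e-6)
        free = lsd.fit_glmm_logistic(df, ["x0", "x1"])
        assert free.random_sd < 0.3
        np.testing.assert_allclose(free.params, plain.params, atol=0.05)

    def test_single_group_rejected(self, rng):
        df = simulate_glmm(rng, n_groups=1)
        with pytest.raises(ValueError):
            lsd.fit_glmm_logistic(df, ["x0"])

    def test_loglik_at_least_plain_logistic(self, rng):
        df = simulate_glmm(rng, random_sd=0.6)
        fit = lsd.fit_glmm_logistic(df, ["x0", "x1"])
        plain = hsf.fit_logistic(df[["x0", "x1"]],
                                 df["stopover"].to_numpy(float))
        assert fit.loglik >= plain.loglik - 1e-6

    def test_odds_ratios_exact_transform(self, rng):
        df = simulate_glmm(rng)
        fit = lsd.fit_glmm_logistic(df, ["x0", "x1"])
        ors = fit.odds_ratios()
        for _, row in ors.iterrows():
            b = fit.coef(row["variable"])
            se = fit.se(row["variable"])
            assert row["or"] == np.exp(b)
            assert row["lo"] == pytest.approx(np.exp(b - 1.959964 * se),
                                              rel=1e-5)
            assert row["hi"] == pytest.approx(np.exp(b + 1.959964 * se),
                                              rel=1e-5)
            assert row["lo"] <= row["or"] <= row["hi"]

    def test_matches_lme4_oracle(self, rng, tmp_path):
        """Independent cross-check against R lme4 glmer with the same
        adaptive quadrature order."""
        df = simulate_glmm(rng, n_groups=8, n_per=50, random_sd=1.0)
        fit = lsd.fit_glmm_logistic(df, ["x0", "x1"])
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(stopover ~ x0 + x1 + (1|individual_id), data=d,
                       family=binomial, nAGQ=15)
            cat(fixef(m), sqrt(unlist(VarCorr(m))), as.numeric(logLik(m)),
                sep="\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=240)
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.strip().split("\n")]
        r_beta, r_sd, r_ll = vals[:3], vals[3], vals[4]
        np.testing.assert_allclose(fit.params, r_beta, atol=2e-3)
        assert fit.random_sd == pytest.approx(r_sd, abs=2e-2)
        assert fit.loglik == pytest.approx(r_ll, abs=1e-2)


class TestBuildTable:
    def make_decoded(self, terrain_stack, n=60, stop_ratio=2):
        rng = np.random.default_rng(3)
        states = (["stopover"] * stop_ratio + ["travel"]) * (
            n // (stop_ratio + 1))
        n = len(states)
        return pd.DataFrame({
            "individual_id": np.repeat(["a", "b"], n // 2),
            "x": rng.uniform(3000, 17_000, n),
            "y": rng.uniform(3000, 17_000, n),
            "argos_class": rng.choice(["3", "2"], n),
            "state": states,
        })

    def test_two_to_one_ratio_gives_two_thirds(self, terrain_stack):
        decoded = self.make_decoded(terrain_stack)
        table, meta = lsd.build_lsd_table(decoded, terrain_stack)
        assert table["stopover"].mean() == pytest.approx(2 / 3, abs=0.02)

    def test_counts_match_decoded_totals(self, terrain_stack):
        decoded = self.make_decoded(terrain_stack)
        table, _ = lsd.build_lsd_table(decoded, terrain_stack)
        assert table["stopover"].sum() <= (decoded["state"]
                                           == "stopover").sum()
        assert set(lsd.LSD_COVARIATES) <= set(table.columns)

    def test_standardized_columns(self, terrain_stack):
        table, meta = lsd.build_lsd_table(self.make_decoded(terrain_stack),
                                          terrain_stack)
        for col in lsd.LSD_COVARIATES:
            assert table[col].mean() == pytest.approx(0.0, abs=1e-10)
            assert table[col].std(ddof=1) == pytest.approx(1.0, rel=1e-10)

    def test_missing_state_column_rejected(self, terrain_stack):
        with pytest.raises(ValueError):
            lsd.build_lsd_table(pd.DataFrame({"x": [1.0]}), terrain_stack)


class TestSelectModel:
    def test_interaction_requires_mains(self, rng):
        df = simulate_glmm(rng)
        df["SAVI_mean"] = df.pop("x0")
        df["Elevation_mean"] = df.pop("x1")
        with pytest.raises(ValueError):
            lsd.select_lsd_model(
                df, candidates=[["SAVI_mean", "SAVI_mean:Elevation_mean"]])

    def test_true_interaction_recovered(self, rng):
        """A true SAVI x elevation interaction is retained most of the
        time at n=800."""
        hits = 0
        n_rep = 12
        for _ in range(n_rep):
            rows = []
            for g in range(8):
                b = rng.normal(0, 0.3)
                s = rng.normal(size=100)
                e = rng.normal(size=100)
                eta = 0.2 + 0.3 * s + 0.3 * e + 0.5 * s * e + b
                y = rng.uniform(size=100) < 1 / (1 + np.exp(-eta))
                for i in range(100):
                    rows.append({"individual_id": f"g{g}",
                                 "stopover": int(y[i]),
                                 "SAVI_mean": s[i],
                                 "Elevation_mean": e[i]})
            df = pd.DataFrame(rows)
            cands = [[], ["SAVI_mean", "Elevation_mean"],
                     ["SAVI_mean", "Elevation_mean",
                      "SAVI_mean:Elevation_mean"]]
            ranking = lsd.select_lsd_model(df, candidates=cands)
            hits += "SAVI_mean:Elevation_mean" in ranking.retained
        assert hits / n_rep >= 0.8


class TestInteractionCurves:
    def make_fit(self, b_savi, b_int):
        names = ["const", "SAVI_mean", "Elevation_mean",
                 "SAVI_mean:Elevation_mean"]
        return lsd.LsdFit(
            names=names,
            params=np.array([0.0, b_savi, 0.2, b_int]),
            bse=np.full(4, 0.05), cov=np.eye(4) * 0.0025,
            loglik=0.0, k=5, n=500, converged=True, random_sd=0.3)

    meta = {"SAVI_mean": {"mean": 0.15, "sd": 0.05},
            "Elevation_mean": {"mean": 500.0, "sd": 200.0}}

    def test_zero_interaction_parallel(self):
        fit = self.make_fit(0.5, 0.0)
        curves = lsd.interaction_curves(fit, self.meta)
        slopes = curves.groupby("elevation_m").apply(
            lambda d: np.polyfit(d["savi"], d["log_odds"], 1)[0],
            include_groups=False)
        assert slopes.max() - slopes.min() == pytest.approx(0.0, abs=1e-9)

    def test_positive_interaction_sign_pattern(self):
        # positive interaction: steepest positive slope at high elevation,
        # negative at low
        fit = self.make_fit(0.0, 0.6)
        curves = lsd.interaction_curves(fit, self.meta)
        slopes = curves.groupby("elevation_m").apply(
            lambda d: np.polyfit(d["savi"], d["log_odds"], 1)[0],
            include_groups=False)
        assert slopes[900.0] > 0 > slopes[100.0]
        assert slopes[900.0] > slopes[500.0] > slopes[100.0]

    def test_zero_main_flat_at_mean_elevation(self):
        fit = self.make_fit(0.0, 0.6)
        curves = lsd.interaction_curves(fit, self.meta,
                                        elevations_m=(500.0,))
        assert np.allclose(curves["log_odds"], 0.0)

    def test_missing_interaction_rejected(self, rng):
        df = simulate_glmm(rng)
        fit = lsd.fit_glmm_logistic(df, ["x0"])
        with pytest.raises(ValueError):
            lsd.interaction_curves(fit, self.meta)


class TestBootstrapAuc:
    def test_perfect_predictor_auc_one(self):
        n = 200
        df = pd.DataFrame({
            "individual_id": np.repeat(["a", "b"], n // 2),
            "stopover": np.tile([0, 1], n // 2),
            "x0": np.tile([-2.0, 2.0], n // 2),
        })
        fit = lsd.LsdFit(names=["const", "x0"],
                         params=np.array([0.0, 5.0]),
                         bse=np.ones(2), cov=np.eye(2), loglik=0.0, k=3,
                         n=n, converged=True, random_sd=0.0)
        mean, sd, _ = lsd.bootstrap_auc(fit, df, B=50, seed=0)
        assert mean == 1.0
        assert sd == 0.0

    def test_noise_predictor_near_half(self, rng):
        n = 1000
        df = pd.DataFrame({
            "individual_id": np.repeat([f"g{i}" for i in range(10)], 100),
            "stopover": rng.integers(0, 2, n),
            "x0": rng.normal(size=n),
        })
        fit = lsd.fit_glmm_logistic(df, ["x0"])
        mean, sd, _ = lsd.bootstrap_auc(fit, df, B=199, seed=1)
        assert abs(mean - 0.5) < 0.03

    def test_default_is_999_repetitions(self):
        import inspect
        assert inspect.signature(
            lsd.bootstrap_auc).parameters["B"].default == 999
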