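"""Latent selection difference between stopover and traveling locations.

Decoded relocation fixes are contrasted with a mixed-effect logistic
regression: stopover is the outcome (1), traveling the exposure (0), with
a random intercept among individuals. The marginal likelihood integrates
the normal random intercept by adaptive Gauss-Hermite quadrature (15 nodes
by default; one node is the Laplace approximation). Positive coefficients
mean stronger selection at stopovers than while traveling; odds ratios
whose 95% CI overlaps 1 indicate no substantial difference between states.
Candidate models may include the mean-SAVI x mean-elevation interaction
(only with both main effects present) and are ranked by AICc with the same
support/uninformative-parameter rules as the residency analysis.
Goodness-of-fit is a bootstrap ROC AUC (999 resamples, drawn within
individuals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.metrics import roc_auc_score

from .covariates import BUFFER_RADIUS_M, buffer_stats, standardize
from .hsf import FitResult, SeparationError, aicc, akaike_weights, \
    fit_logistic, informative_check

__all__ = [
    "LsdFit",
    "LsdRanking",
    "build_lsd_table",
    "fit_glmm_logistic",
    "select_lsd_model",
    "interaction_curves",
    "bootstrap_auc",
]

LSD_COVARIATES = ["SAVI_mean", "SAVI_sd", "Elevation_mean", "Slope_mean",
                  "Northness", "Eastness"]


def build_lsd_table(decoded: pd.DataFrame, stack,
                    radius_map: dict | None = None,
                    ddof: int = 1) -> tuple[pd.DataFrame, dict]:
    """One row per decoded relocation fix.

    Covariates are means (and the SAVI sd) over a circular buffer whose
    radius matches the fix's Argos error class; the response is 1 for
    stopover, 0 for traveling. Fixes whose buffer covers no valid cells
    are dropped and counted. Covariates are standardized pooled over both
    states; the (mean, sd) metadata is returned for back-transformation.
    """
    if "state" not in decoded.columns:
        raise ValueError("decoded tracks need a 'state' column "
                         "(stopover/travel)")
    radius_map = BUFFER_RADIUS_M if radius_map is None else radius_map
    rows, dropped = [], 0
    for _, fix in decoded.iterrows():
        try:
            savi = buffer_stats(stack.savi, fix.x, fix.y, fix.argos_class,
                                radius_map)
            row = {
                "individual_id": fix.individual_id,
                "stopover": 1 if str(fix.state) in ("1", "stopover") else 0,
                "SAVI_mean": savi["mean"],
                "SAVI_sd": savi["sd"],
            }
            for col, rast in (("Elevation_mean", stack.elevation),
                              ("Slope_mean", stack.slope),
                              ("Northness", stack.northness),
                              ("Eastness", stack.eastness)):
                row[col] = buffer_stats(rast, fix.x, fix.y, fix.argos_class,
                                        radius_map, which=("mean",))["mean"]
        except ValueError:
            dropped += 1
            continue
        rows.append(row)
    if dropped:
        warnings.warn(f"{dropped} fixes dropped (buffer covered no valid "
                      "cells)")
    table = pd.DataFrame(rows)
    table, meta = standardize(table, LSD_COVARIATES, ddof=ddof)
    return table, meta


# ---------------------------------------------------------------------------
# Mixed-effect logistic regression (adaptive Gauss-Hermite quadrature)
# ---------------------------------------------------------------------------

@dataclass
class LsdFit(FitResult):
    """Fixed effects plus the random-intercept sd of the GLMM.

    ``k`` counts fixed effects plus the random-effect variance parameter;
    ``singular`` marks a fit with the random sd at the zero boundary.
    """

    random_sd: float = 0.0
    aicc: float = np.nan
    singular: bool = False
    n_groups: int = 0

    def odds_ratios(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2.0)
        rows = []
        for name, b, se in zip(self.names, self.params, self.bse):
            if name == "const":
                continue
            rows.append({"variable": name, "or": float(np.exp(b)),
                         "lo": float(np.exp(b - z * se)),
                         "hi": float(np.exp(b + z * se))})
        return pd.DataFrame(rows)


def _glmm_nll_factory(X: np.ndarray, y: np.ndarray, g: np.ndarray,
                      n_groups: int, n_quad: int):
    nodes, wts = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(wts)

    def group_logpost(eta, b, sigma):
        """f_j(b) summed within groups, for a (G,) vector b."""
        lin = eta + b[g]
        ll_rows = y * lin - np.logaddexp(0.0, lin)
        ll = np.bincount(g, weights=ll_rows, minlength=n_groups)
        return ll - 0.5 * b**2 / sigma**2 - np.log(sigma) \
            - 0.5 * np.log(2 * np.pi)

    def nll(theta):
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        eta = X @ beta
        # Newton for the per-group posterior mode
        b = np.zeros(n_groups)
        for _ in range(50):
            p = 1.0 / (1.0 + np.exp(-(eta + b[g])))
            grad = np.bincount(g, weights=y - p, minlength=n_groups) \
                - b / sigma**2
            hess = -np.bincount(g, weights=p * (1 - p),
                                minlength=n_groups) - 1.0 / sigma**2
            step = grad / hess
            b -= step
            if np.max(np.abs(step)) < 1e-10:
                break
        p = 1.0 / (1.0 + np.exp(-(eta + b[g])))
        hess = -np.bincount(g, weights=p * (1 - p),
                            minlength=n_groups) - 1.0 / sigma**2
        tau = 1.0 / np.sqrt(-hess)
        # adaptive GH: integral = sqrt(2) tau sum_k w_k e^{x_k^2} e^{f(b+sqrt2 tau x_k)}
        terms = np.empty((n_quad, n_groups))
        for k in range(n_quad):
            bk = b + np.sqrt(2.0) * tau * nodes[k]
            terms[k] = log_w[k] + nodes[k] ** 2 + group_logpost(eta, bk, sigma)
        m = terms.max(axis=0)
        ll = m + np.log(np.exp(terms - m).sum(axis=0)) \
            + 0.5 * np.log(2.0) + np.log(tau)
        total = ll.sum()
        return -total if np.isfinite(total) else 1e12

    return nll


def fit_glmm_logistic(table: pd.DataFrame, fixed: list[str],
                      response: str = "stopover",
                      group: str = "individual_id",
                      n_quad: int = 15, label: str = "",
                      fixed_random_sd: float | None = None) -> LsdFit:
    """Logistic GLMM with a single normal random intercept.

    Fixed effects and the random sd are estimated by maximizing the
    AGQ-approximated marginal likelihood; standard errors come from the
    inverse numerical Hessian. A fit whose random sd collapses to the zero
    boundary is reported as singular (it then equals the plain logistic
    fit) rather than hidden. At least 2 groups are required.
    ``fixed_random_sd`` holds the random sd at a given value (only the
    fixed effects are optimized); as it approaches 0 the model reduces to
    plain logistic regression.
    """
    from statsmodels.tools.numdiff import approx_hess

    fixed = [f for f in fixed]
    groups, g = np.unique(table[group].to_numpy(), return_inverse=True)
    if len(groups) < 2:
        raise ValueError("random intercept needs at least 2 groups")
    y = table[response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(table))]
                        + [table[c].to_numpy(dtype=float) for c in fixed])
    names = ["const"] + fixed
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    start = fit_logistic(table[fixed] if fixed else table[[]], y)
    nll = _glmm_nll_factory(X, y, g, len(groups), n_quad)
    if fixed_random_sd is not None:
        ls = np.log(max(fixed_random_sd, 1e-8))
        theta0 = np.append(start.params, ls)
        bounds = [(None, None)] * X.shape[1] + [(ls, ls)]
    else:
        theta0 = np.append(start.params, np.log(0.5))
        bounds = [(None, None)] * X.shape[1] + [(-8.0, 3.0)]
    res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 300})
    theta = res.x
    sigma = float(np.exp(theta[-1]))
    singular = sigma < 5e-3
    ll = -float(res.fun)
    k = X.shape[1] + 1  # fixed effects + random-effect variance
    if singular:
        # boundary fit: SEs of the fixed effects from the plain logistic
        beta, bse, cov = start.params, start.bse, start.cov
    else:
        H = approx_hess(theta, nll)
        try:
            cov_all = np.linalg.inv(H)
            se_all = np.sqrt(np.clip(np.diag(cov_all), 0, None))
        except np.linalg.LinAlgError:
            cov_all = np.full((len(theta), len(theta)), np.nan)
            se_all = np.full(len(theta), np.nan)
        beta = theta[:-1]
        bse = se_all[:-1]
        cov = cov_all[:-1, :-1]
    return LsdFit(
        names=names, params=np.asarray(beta), bse=np.asarray(bse),
        cov=np.asarray(cov), loglik=ll, k=k, n=len(y),
        converged=bool(res.success), random_sd=sigma,
        aicc=aicc(ll, k, len(y)), singular=singular,
        n_groups=len(groups),
        model_label=label or (" + ".join(fixed) or "Null") + " + (1 | ID)")


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def _with_interactions(table: pd.DataFrame, terms: list[str]) -> tuple:
    """Materialize 'A:B' product columns; enforce mains-with-interaction."""
    cols, out = [], table.copy()
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            if a not in terms or b not in terms:
                raise ValueError(f"interaction {t!r} requires both main "
                                 "effects in the model")
            out[t] = out[a] * out[b]
        cols.append(t)
    return out, cols


def default_lsd_candidates() -> list[list[str]]:
    """Candidate fixed-effect sets for the stopover-vs-travel contrast:
    nested main-effect models plus the SAVI x elevation interaction
    variants (the interaction always accompanies both mains)."""
    inter = "SAVI_mean:Elevation_mean"
    base = ["SAVI_mean", "SAVI_sd", "Elevation_mean"]
    return [
        [],
        ["SAVI_mean"],
        ["SAVI_sd"],
        ["Elevation_mean"],
        ["SAVI_mean", "SAVI_sd"],
        ["SAVI_sd", "Elevation_mean"],
        ["SAVI_mean", "Elevation_mean"],
        base,
        base + ["Northness", "Eastness"],
        base + [inter],
        base + ["Northness", inter],
        base + ["Eastness", inter],
        base + ["Northness", "Eastness", inter],
        base + ["Slope_mean", "Northness", "Eastness", inter],
    ]


@dataclass
class LsdRanking:
    table: pd.DataFrame
    fits: dict[str, LsdFit]
    retained: str

    @property
    def retained_fit(self) -> LsdFit:
        return self.fits[self.retained]


def select_lsd_model(table: pd.DataFrame,
                     candidates: list[list[str]] | None = None,
                     response: str = "stopover",
                     group: str = "individual_id",
                     n_quad: int = 15, level: float = 0.85) -> LsdRanking:
    """AICc ranking of candidate GLMMs and the retained parsimonious model.

    Same rules as the residency ranking: dAICc < 2 defines support; among
    supported models those with any 85% CI overlapping zero are flagged;
    the retained model has the fewest parameters, then the lowest dAICc.
    """
    candidates = default_lsd_candidates() if candidates is None else candidates
    fits: dict[str, LsdFit] = {}
    for terms in candidates:
        tab, cols = _with_interactions(table, list(terms))
        label = " + ".join(terms) or "Null"
        try:
            fits[label] = fit_glmm_logistic(tab, cols, response=response,
                                            group=group, n_quad=n_quad,
                                            label=label)
        except SeparationError:
            warnings.warn(f"model {label!r} dropped: perfect separation")
    if not fits:
        raise RuntimeError("no candidate model converged")
    rows = [{"model": lab, "K": f.k, "-LL": -f.loglik, "AICc": f.aicc}
            for lab, f in fits.items()]
    tab = pd.DataFrame(rows).sort_values("AICc").reset_index(drop=True)
    tab["dAICc"] = tab["AICc"] - tab["AICc"].iloc[0]
    tab["w"] = akaike_weights(tab["dAICc"].to_numpy())
    tab["supported"] = tab["dAICc"] < 2.0
    tab["has_uninformative"] = [
        any(not ok for ok in informative_check(fits[lab], level).values())
        for lab in tab["model"]]
    ok = tab[tab["supported"] & ~tab["has_uninformative"]]
    if len(ok) == 0:
        warnings.warn("every supported model carries an uninformative "
                      "variable; retaining the lowest-AICc supported model")
        ok = tab[tab["supported"]]
    retained = str(ok.sort_values(["K", "dAICc"]).iloc[0]["model"])
    return LsdRanking(table=tab, fits=fits, retained=retained)


def interaction_curves(fit: LsdFit, std_meta: dict,
                       elevations_m=(100.0, 500.0, 900.0),
                       savi_grid=None, level: float = 0.95) -> pd.DataFrame:
    """Relative log-odds of stopping vs SAVI at fixed elevations.

    Curves are relative to the mean SAVI (0 on the standardized scale) at
    each elevation, so the elevation main effect cancels: the slope in
    standardized SAVI is beta_SAVI + beta_int * z(elevation). With a
    positive interaction the slope rises with elevation (steepest positive
    at high elevation, negative at low), the signature pattern of
    state-dependent selection. Elevations outside roughly +-3 sd of the
    training data trigger a warning.
    """
    inter = "SAVI_mean:Elevation_mean"
    if inter not in fit.names:
        raise ValueError("fit does not contain the SAVI x elevation "
                         "interaction")
    if savi_grid is None:
        savi_grid = np.linspace(0.0, 0.4, 41)
    ms, me = std_meta["SAVI_mean"], std_meta["Elevation_mean"]
    i_s, i_i = fit.names.index("SAVI_mean"), fit.names.index(inter)
    z = stats.norm.ppf(0.5 + level / 2.0)
    rows = []
    for elev in elevations_m:
        ze = (elev - me["mean"]) / me["sd"]
        if abs(ze) > 3:
            warnings.warn(f"elevation {elev} m is outside the training "
                          "range; extrapolated curve")
        slope = fit.params[i_s] + fit.params[i_i] * ze
        var = (fit.cov[i_s, i_s] + ze**2 * fit.cov[i_i, i_i]
               + 2 * ze * fit.cov[i_s, i_i])
        se_slope = np.sqrt(max(var, 0.0))
        for savi in np.asarray(savi_grid, dtype=float):
            zs = (savi - ms["mean"]) / ms["sd"]
            est = slope * zs
            half = z * se_slope * abs(zs)
            rows.append({"elevation_m": elev, "savi": savi,
                         "log_odds": float(est), "lo": float(est - half),
                         "hi": float(est + half)})
    return pd.DataFrame(rows)


def bootstrap_auc(fit: LsdFit, table: pd.DataFrame,
                  response: str = "stopover", group: str = "individual_id",
                  B: int = 999, seed=None, max_redraws: int = 100):
    """Bootstrap ROC AUC of the fixed-effect linear predictor.

    Rows are resampled with replacement within individual (respecting the
    grouping structure); resamples with a single response class are redrawn
    and counted. Returns (mean, sd, n_redrawn).
    """
    rng = np.random.default_rng(seed)
    tab, cols = _with_interactions(
        table, [n for n in fit.names if n != "const"])
    X = np.column_stack([np.ones(len(tab))]
                        + [tab[c].to_numpy(dtype=float) for c in cols])
    score = X @ fit.params
    y = tab[response].to_numpy(dtype=int)
    g = tab[group].to_numpy()
    group_idx = {k: np.flatnonzero(g == k) for k in np.unique(g)}
    aucs = np.empty(B)
    redrawn = 0
    for b in range(B):
        for _ in range(max_redraws):
            idx = np.concatenate([
                rng.choice(ix, size=len(ix), replace=True)
                for ix in group_idx.values()])
            if 0 < y[idx].sum() < len(idx):
                break
            redrawn += 1
        else:
            raise RuntimeError("could not draw a two-class bootstrap sample")
        aucs[b] = roc_auc_score(y[idx], score[idx])
    return float(aucs.mean()), float(aucs.std(ddof=1)), redrawn
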