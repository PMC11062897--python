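"""Habitat-selection functions and AICc multimodel inference.

Used (observed home ranges) vs available (random home ranges) units are
contrasted with plain logistic regression — no random effects, since each
individual contributes a single home range per season. Candidate models
(all subsets of the pruned covariates, capped at ``max_terms``, plus the
null) are ranked by AICc; models with dAICc < 2 have substantial support,
and within that set models carrying uninformative variables (85% Wald CI
overlapping 0) are flagged. The retained model is the most parsimonious
(fewest parameters, then lowest dAICc) supported model without
uninformative variables. A coefficient of the fitted logit is the log of
the relative selection strength (log-RSS) per 1-sd covariate change.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SeparationError",
    "FitResult",
    "ModelRanking",
    "fit_logistic",
    "aicc",
    "akaike_weights",
    "rank_models",
    "informative_check",
    "vif",
    "log_rss",
    "log_rss_curve",
]


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation: ML estimates diverge."""


@dataclass
class FitResult:
    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    cov: np.ndarray
    loglik: float
    k: int               # estimated parameters, intercept included
    n: int
    converged: bool
    model_label: str = ""

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[self.names.index(name)])


def fit_logistic(X: pd.DataFrame, y, add_intercept: bool = True,
                 label: str = "") -> FitResult:
    """Binomial GLM with logit link, fitted by IRLS.

    Raises ``SeparationError`` on (quasi-)perfect separation instead of
    returning silently diverged estimates, and ValueError on rank-deficient
    design matrices.
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")
    Xd = X.copy()
    if add_intercept:
        Xd = sm.add_constant(Xd, has_constant="add")
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        raise ValueError("design matrix is rank deficient")
    from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                                 PerfectSeparationWarning)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=PerfectSeparationWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        try:
            res = sm.GLM(y, Xd, family=sm.families.Binomial()).fit()
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(str(exc)) from exc
    params = np.asarray(res.params)
    mu = np.asarray(res.fittedvalues)
    if np.max(np.abs(params)) > 30 or np.max(np.abs(mu - y)) < 1e-8:
        raise SeparationError("perfect separation detected "
                              "(diverging coefficients)")
    return FitResult(
        names=list(Xd.columns), params=params, bse=np.asarray(res.bse),
        cov=np.asarray(res.cov_params()), loglik=float(res.llf),
        k=Xd.shape[1], n=len(y), converged=bool(res.converged),
        model_label=label or " + ".join(c for c in X.columns) or "Null")


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample AIC: -2 logLik + 2K + 2K(K+1)/(n-K-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(delta: np.ndarray) -> np.ndarray:
    """Evidence weights exp(-d/2), normalized over the candidate set."""
    rel = np.exp(-0.5 * np.asarray(delta, dtype=float))
    return rel / rel.sum()


def informative_check(fit: FitResult, level: float = 0.85) -> dict[str, bool]:
    """Per-variable informativeness: the Wald ``level`` CI excludes 0.

    The 85% level matches AIC-based selection: AIC keeps a variable when
    roughly its 85% CI excludes zero.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = {}
    for name, b, se in zip(fit.names, fit.params, fit.bse):
        if name == "const":
            continue
        out[name] = bool(abs(b) - z * se > 0)
    return out


@dataclass
class ModelRanking:
    table: pd.DataFrame          # one row per candidate, ranked by AICc
    fits: dict[str, FitResult]
    retained: str                # label of the retained model
    level: float = 0.85

    @property
    def retained_fit(self) -> FitResult:
        return self.fits[self.retained]


def _fit_subset(table, response, varset, label=None):
    X = table[list(varset)] if varset else table[[]]
    return fit_logistic(X, table[response].to_numpy(),
                        label=label or (" + ".join(varset) or "Null"))


def rank_models(table: pd.DataFrame, response: str, candidate_vars,
                max_terms: int | None = None, level: float = 0.85,
                fitter=None) -> ModelRanking:
    """Fit and rank all candidate subsets plus the null model.

    ``fitter(table, response, varset, label)`` may be supplied to swap the
    fitting routine (the mixed-model analysis reuses this ranking logic).
    """
    candidate_vars = list(candidate_vars)
    if max_terms is None:
        max_terms = len(candidate_vars)
    fitter = fitter or _fit_subset
    subsets = [()]
    for r in range(1, max_terms + 1):
        subsets.extend(itertools.combinations(candidate_vars, r))
    full = tuple(candidate_vars)
    if full not in subsets:
        subsets.append(full)
    fits: dict[str, FitResult] = {}
    for vs in subsets:
        label = " + ".join(vs) or "Null"
        if vs == full and vs:
            label += " (Full)"
        try:
            fits[label] = fitter(table, response, vs, label)
        except SeparationError:
            warnings.warn(f"model {label!r} dropped: perfect separation")
        except ValueError as exc:
            # e.g. aliased designs (all aspect-class proportions sum to 1)
            warnings.warn(f"model {label!r} dropped: {exc}")
    if not fits:
        raise RuntimeError("no candidate model converged")
    rows = []
    for label, f in fits.items():
        rows.append({"model": label, "K": f.k, "-LL": -f.loglik,
                     "AICc": aicc(f.loglik, f.k, f.n)})
    tab = pd.DataFrame(rows).sort_values("AICc").reset_index(drop=True)
    tab["dAICc"] = tab["AICc"] - tab["AICc"].iloc[0]
    tab["w"] = akaike_weights(tab["dAICc"].to_numpy())
    tab["supported"] = tab["dAICc"] < 2.0
    uninformative = []
    for label in tab["model"]:
        flags = informative_check(fits[label], level=level)
        uninformative.append(any(not ok for ok in flags.values()))
    tab["has_uninformative"] = uninformative
    ok = tab[tab["supported"] & ~tab["has_uninformative"]]
    if len(ok) == 0:
        warnings.warn("every supported model carries an uninformative "
                      "variable; retaining the lowest-AICc supported model")
        ok = tab[tab["supported"]]
    retained = ok.sort_values(["K", "dAICc"]).iloc[0]["model"]
    return ModelRanking(table=tab, fits=fits, retained=str(retained),
                        level=level)


def vif(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors, 1/(1 - R^2_j) of each predictor on the
    others. Values above 5 trigger a warning; perfect collinearity is an
    error."""
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs at least 2 predictors")
    out = {}
    for j, col in enumerate(cols):
        others = sm.add_constant(X.drop(columns=[col]), has_constant="add")
        r2 = sm.OLS(X[col].to_numpy(dtype=float), others).fit().rsquared
        if r2 > 1 - 1e-12:
            raise ValueError(f"perfect collinearity: VIF of {col!r} is "
                             "infinite")
        out[col] = float(1.0 / (1.0 - r2))
        if out[col] > 5:
            warnings.warn(f"VIF of {col!r} exceeds 5 ({out[col]:.2f})")
    return out


def log_rss(fit: FitResult, x1: dict, x2: dict, level: float = 0.95):
    """Log relative selection strength between two habitat profiles.

    Profiles are dicts on the fit's (standardized) covariate scale;
    unmentioned variables default to 0 (the sample mean). Returns
    (log-RSS, (lo, hi)) with a Wald CI from the linear combination's
    variance; the intercept cancels.
    """
    d = np.zeros(len(fit.names))
    for prof, sign in ((x1, 1.0), (x2, -1.0)):
        for var, val in prof.items():
            if var not in fit.names:
                raise ValueError(f"variable {var!r} not in the fitted model")
            d[fit.names.index(var)] += sign * val
    if "const" in fit.names:
        d[fit.names.index("const")] = 0.0
    est = float(d @ fit.params)
    se = float(np.sqrt(d @ fit.cov @ d))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return est, (est - z * se, est + z * se)


def log_rss_curve(fit: FitResult, var: str, grid, level: float = 0.95
                  ) -> pd.DataFrame:
    """log-RSS of profiles varying one covariate against the sample mean
    (0 on the standardized scale), as plotted effect curves."""
    rows = []
    for v in np.asarray(grid, dtype=float):
        est, (lo, hi) = log_rss(fit, {var: v}, {var: 0.0}, level=level)
        rows.append({"x": v, "log_rss": est, "lo": lo, "hi": hi})
    return pd.DataFrame(rows)
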