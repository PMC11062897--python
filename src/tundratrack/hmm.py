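"""Two-state hidden Markov movement model.

Daily movement paths are summarized as step lengths (km) and turning angles
(radians). Each behavioral state emits steps from a gamma distribution
(mean/sd parameterization) and turns from a wrapped Cauchy distribution;
states evolve by a first-order Markov chain. State 1 ("stopover") is, by
convention, the state with the smaller fitted step mean; state 2 ("travel")
the larger. The model is fitted by direct numerical maximization of the
joint log-likelihood over all individuals (shared parameters, one forward
pass per individual), from several random starting points drawn in
behaviorally plausible ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, gammaln, logit

__all__ = [
    "HmmParameters",
    "HmmFit",
    "StepSeries",
    "steps_and_angles",
    "wrapped_cauchy_pdf",
    "sample_wrapped_cauchy",
    "emission_density",
    "hmm_loglik",
    "fit_hmm",
    "viterbi_decode",
    "pseudo_residuals",
    "stationary_distribution",
]

STATE_NAMES = {1: "stopover", 2: "travel"}


def wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    out = np.mod(np.asarray(theta, dtype=float) + np.pi, 2 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out)


def wrapped_cauchy_pdf(theta, mu, rho):
    """Density (1/2pi)(1-rho^2)/(1+rho^2-2 rho cos(theta-mu)) on (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"wrapped Cauchy concentration must be in [0,1), got {rho}")
    return (1.0 - rho**2) / (2 * np.pi * (1 + rho**2 - 2 * rho * np.cos(theta - mu)))


def sample_wrapped_cauchy(rng: np.random.Generator, mu: float, rho: float, size=None):
    """Draw wrapped Cauchy variates by wrapping a linear Cauchy.

    A Cauchy(0, gamma) wrapped onto the circle is wrapped Cauchy with
    concentration rho = exp(-gamma); rho = 0 degenerates to circular uniform.
    """
    if rho < 1e-12:
        return wrap_angle(rng.uniform(-np.pi, np.pi, size=size))
    gamma = -np.log(rho)
    x = gamma * np.tan(np.pi * (rng.uniform(size=size) - 0.5))
    return wrap_angle(mu + x)


@dataclass
class HmmParameters:
    """State-dependent emission and transition parameters.

    step_mean, step_sd : km/day, per state (gamma, mean/sd parameterization)
    angle_mean         : radians in (-pi, pi], per state
    angle_conc         : wrapped Cauchy concentration rho in [0, 1), per state
    tpm                : transition probability matrix, rows sum to 1
    delta              : initial state distribution
    """

    step_mean: np.ndarray
    step_sd: np.ndarray
    angle_mean: np.ndarray
    angle_conc: np.ndarray
    tpm: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        for name in ("step_mean", "step_sd", "angle_mean", "angle_conc",
                     "tpm", "delta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.n_states
        if np.any(self.step_mean <= 0) or np.any(self.step_sd <= 0):
            raise ValueError("gamma step parameters must be positive")
        if np.any(self.angle_conc < 0) or np.any(self.angle_conc >= 1):
            raise ValueError("angle concentration must be in [0, 1)")
        if self.tpm.shape != (n, n):
            raise ValueError("transition matrix shape mismatch")
        if np.any(self.tpm < 0) or not np.allclose(self.tpm.sum(axis=1), 1.0,
                                                   atol=1e-8):
            raise ValueError("transition matrix rows must sum to 1")
        if self.delta.shape != (n,) or not np.isclose(self.delta.sum(), 1.0):
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.step_mean)

    @property
    def gamma_shape(self) -> np.ndarray:
        return (self.step_mean / self.step_sd) ** 2

    @property
    def gamma_scale(self) -> np.ndarray:
        return self.step_sd**2 / self.step_mean

    def n_parameters(self, stationary_delta: bool = False) -> int:
        """Free parameters: 2n gamma + 2n wrapped Cauchy + n(n-1) transition
        + (n-1) initial (0 when the initial distribution is the stationary
        one implied by the transition matrix)."""
        n = self.n_states
        k = 4 * n + n * (n - 1)
        if not stationary_delta:
            k += n - 1
        return k

    def relabelled(self) -> "HmmParameters":
        """Permute states so step means are ascending (state 1 = stopover)."""
        order = np.argsort(self.step_mean)
        return HmmParameters(
            step_mean=self.step_mean[order],
            step_sd=self.step_sd[order],
            angle_mean=self.angle_mean[order],
            angle_conc=self.angle_conc[order],
            tpm=self.tpm[np.ix_(order, order)],
            delta=self.delta[order],
        )


def stationary_distribution(tpm: np.ndarray) -> np.ndarray:
    """Left eigenvector of the transition matrix for eigenvalue 1."""
    tpm = np.asarray(tpm, dtype=float)
    vals, vecs = np.linalg.eig(tpm.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    return pi / pi.sum()


@dataclass
class StepSeries:
    """Steps/turns of one regularized daily trajectory.

    steps  : km between consecutive daily fixes (length n_fixes - 1)
    angles : signed heading change at each step, NaN where undefined
             (first step, or a zero-length neighbor)
    interpolated : flag per step (True when either endpoint was interpolated)
    """

    individual_id: str
    steps: np.ndarray
    angles: np.ndarray
    interpolated: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.steps), dtype=bool)
        if len(self.angles) != len(self.steps):
            raise ValueError("angles must align with steps (NaN-padded)")

    def __len__(self) -> int:
        return len(self.steps)


def steps_and_angles(track: pd.DataFrame, individual_id: str | None = None
                     ) -> StepSeries:
    """Build step lengths (km) and turning angles from daily fixes.

    ``track`` needs columns x, y (m), ordered in time; an optional
    ``interpolated`` column is carried onto steps. Turning angle t is the
    signed change of heading between steps t-1 and t, counterclockwise
    positive; undefined (NaN) at the first step and next to zero-length
    steps.
    """
    if len(track) < 3:
        raise ValueError("need at least 3 fixes to form steps and a turn")
    x = track["x"].to_numpy(dtype=float)
    y = track["y"].to_numpy(dtype=float)
    dx, dy = np.diff(x), np.diff(y)
    steps = np.hypot(dx, dy) / 1000.0
    heading = np.arctan2(dy, dx)
    heading = np.where(steps == 0, np.nan, heading)
    angles = np.full(len(steps), np.nan)
    angles[1:] = wrap_angle(heading[1:] - heading[:-1])
    interp = None
    if "interpolated" in track.columns:
        fl = track["interpolated"].to_numpy(dtype=bool)
        interp = fl[:-1] | fl[1:]
        # linear interpolation makes consecutive segments exactly
        # collinear; an exactly-zero turn at an interpolated fix is an
        # artifact (a continuous turn distribution puts zero probability
        # on it, so a near-unit concentration could otherwise blow up the
        # likelihood) and is treated as missing
        artifact = np.zeros(len(steps), dtype=bool)
        artifact[1:] = ((interp[1:] | interp[:-1])
                        & (np.abs(angles[1:]) < 1e-9))
        angles[artifact] = np.nan
    if individual_id is None:
        individual_id = str(track["individual_id"].iloc[0]) \
            if "individual_id" in track.columns else "?"
    return StepSeries(individual_id, steps, angles, interp)


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def _log_emissions(params: HmmParameters, series: StepSeries) -> np.ndarray:
    """(T, n_states) matrix of log emission densities; missing parts
    contribute log 1 = 0."""
    T, n = len(series), params.n_states
    out = np.zeros((T, n))
    shape, scale = params.gamma_shape, params.gamma_scale
    s_ok = np.isfinite(series.steps) & (series.steps > 0)
    a_ok = np.isfinite(series.angles)
    s = series.steps[s_ok, None]
    for j in range(n):
        out[s_ok, j] += ((shape[j] - 1) * np.log(s[:, 0]) - s[:, 0] / scale[j]
                         - shape[j] * np.log(scale[j]) - gammaln(shape[j]))
        out[a_ok, j] += np.log(wrapped_cauchy_pdf(
            series.angles[a_ok], params.angle_mean[j], params.angle_conc[j]))
    return out


def emission_density(params: HmmParameters, state: int, step, angle) -> float:
    """Joint emission density of one (step, angle) pair for a 1-based state.

    NaN components contribute a factor of 1.
    """
    j = state - 1
    dens = 1.0
    if step is not None and np.isfinite(step):
        dens *= stats.gamma.pdf(step, a=params.gamma_shape[j],
                                scale=params.gamma_scale[j])
    if angle is not None and np.isfinite(angle):
        dens *= wrapped_cauchy_pdf(angle, params.angle_mean[j],
                                   params.angle_conc[j])
    return float(dens)


def _forward(params: HmmParameters, series: StepSeries,
             return_pred: bool = False):
    """Scaled forward pass; returns loglik (and one-step-ahead state
    probabilities before seeing each observation, if requested)."""
    logb = _log_emissions(params, series)
    m = logb.max(axis=1, keepdims=True)
    b = np.exp(logb - m)  # rescaled emissions, max 1 per time
    T = len(series)
    pred = np.empty((T, params.n_states)) if return_pred else None
    alpha = params.delta.copy()
    ll = 0.0
    for t in range(T):
        if return_pred:
            pred[t] = alpha / alpha.sum()
        alpha = alpha * b[t]
        c = alpha.sum()
        if c <= 0 or not np.isfinite(c):
            return (-np.inf, pred) if return_pred else -np.inf
        ll += np.log(c) + m[t, 0]
        alpha = (alpha / c) @ params.tpm
    return (ll, pred) if return_pred else ll


class _Packed:
    """Series stacked into (S, T_max) arrays, trailing steps padded with
    NaN. Padded observations emit a unit factor, which leaves each series'
    likelihood unchanged (the transition matrix rows sum to 1), so one
    vectorized forward pass serves all individuals."""

    def __init__(self, series: list[StepSeries]):
        tmax = max(len(s) for s in series)
        S = len(series)
        self.steps = np.full((S, tmax), np.nan)
        self.angles = np.full((S, tmax), np.nan)
        for i, s in enumerate(series):
            self.steps[i, :len(s)] = s.steps
            self.angles[i, :len(s)] = s.angles
        self.s_ok = np.isfinite(self.steps) & (self.steps > 0)
        self.a_ok = np.isfinite(self.angles)
        self.log_steps = np.where(self.s_ok, np.log(
            np.where(self.s_ok, self.steps, 1.0)), 0.0)

    def log_emissions(self, params: HmmParameters) -> np.ndarray:
        S, T = self.steps.shape
        n = params.n_states
        out = np.zeros((S, T, n))
        shape, scale = params.gamma_shape, params.gamma_scale
        st = np.where(self.s_ok, self.steps, 1.0)
        an = np.where(self.a_ok, self.angles, 0.0)
        for j in range(n):
            gj = ((shape[j] - 1) * self.log_steps - st / scale[j]
                  - shape[j] * np.log(scale[j]) - gammaln(shape[j]))
            out[:, :, j] += np.where(self.s_ok, gj, 0.0)
            wj = np.log(wrapped_cauchy_pdf(an, params.angle_mean[j],
                                           params.angle_conc[j]))
            out[:, :, j] += np.where(self.a_ok, wj, 0.0)
        return out

    def loglik(self, params: HmmParameters) -> float:
        logb = self.log_emissions(params)
        m = logb.max(axis=2)
        b = np.exp(logb - m[:, :, None])
        S, T = self.steps.shape
        alpha = np.broadcast_to(params.delta, (S, params.n_states)).copy()
        ll = np.zeros(S)
        for t in range(T):
            alpha = alpha * b[:, t]
            c = alpha.sum(axis=1)
            if np.any(c <= 0) or not np.all(np.isfinite(c)):
                return -np.inf
            ll += np.log(c) + m[:, t]
            alpha = (alpha / c[:, None]) @ params.tpm
        return float(ll.sum())


def hmm_loglik(params: HmmParameters, series) -> float:
    """Joint log-likelihood; ``series`` is a StepSeries or a list of them
    (independent individuals, shared parameters)."""
    if isinstance(series, StepSeries):
        series = [series]
    return _Packed(series).loglik(params)


# ---------------------------------------------------------------------------
# Fitting (direct numerical maximization on unconstrained working scales)
# ---------------------------------------------------------------------------

def _unpack(theta: np.ndarray, n_states: int) -> HmmParameters:
    i = 0
    mu = np.exp(theta[i:i + n_states]); i += n_states
    sd = np.exp(theta[i:i + n_states]); i += n_states
    u = theta[i:i + n_states]; i += n_states
    v = theta[i:i + n_states]; i += n_states
    ang = np.arctan2(v, u)
    # concentration bounded away from 1: a near-degenerate wrapped Cauchy
    # otherwise chases point masses in the angle data
    rho = 0.999 * expit(theta[i:i + n_states]); i += n_states
    if n_states == 1:
        tpm = np.ones((1, 1))
        delta = np.ones(1)
    else:
        off = expit(theta[i:i + 2]); i += 2  # P(1->2), P(2->1)
        tpm = np.array([[1 - off[0], off[0]], [off[1], 1 - off[1]]])
        delta = np.array([expit(theta[i]), 1 - expit(theta[i])]); i += 1
    return HmmParameters(mu, sd, ang, np.minimum(rho, 1 - 1e-10), tpm, delta)


def _pack(params: HmmParameters) -> np.ndarray:
    parts = [np.log(params.step_mean), np.log(params.step_sd),
             np.cos(params.angle_mean), np.sin(params.angle_mean),
             logit(np.clip(params.angle_conc / 0.999, 1e-10,
                           1 - 1e-10))]
    if params.n_states == 2:
        parts.append(logit(np.clip([params.tpm[0, 1], params.tpm[1, 0]],
                                   1e-10, 1 - 1e-10)))
        parts.append([logit(np.clip(params.delta[0], 1e-10, 1 - 1e-10))])
    return np.concatenate(parts)


def _random_start(rng: np.random.Generator, n_states: int) -> HmmParameters:
    """Behaviorally plausible random inits: short clustered stopover steps,
    long directional traveling steps."""
    if n_states == 1:
        mu = np.array([rng.uniform(0.1, 10.0)])
        sd = np.array([rng.uniform(0.1, 5.0)])
        return HmmParameters(mu, sd, np.zeros(1),
                             np.array([rng.uniform(0.0, 0.95)]),
                             np.ones((1, 1)), np.ones(1))
    mu = np.array([rng.uniform(0.1, 2.0), rng.uniform(3.0, 15.0)])
    sd = rng.uniform(0.1, 5.0, size=2)
    rho = rng.uniform(0.0, 0.95, size=2)
    stay = rng.uniform(0.7, 0.95, size=2)
    tpm = np.array([[stay[0], 1 - stay[0]], [1 - stay[1], stay[1]]])
    return HmmParameters(mu, sd, np.zeros(2), rho, tpm,
                         np.array([0.5, 0.5]))


@dataclass
class HmmFit:
    params: HmmParameters
    loglik: float
    n_obs: int
    aic: float                 # K with estimated initial distribution
    aic_stationary: float      # K with delta taken as the stationary dist.
    n_states: int
    converged: bool
    start_logliks: list


def fit_hmm(series, n_states: int = 2, n_starts: int = 10,
            seed=None, maxiter: int = 500) -> HmmFit:
    """Fit an n-state HMM to pooled step series by numerical ML.

    The best of ``n_starts`` random initializations is kept; the fit is
    flagged converged when the optimizer converged and at least two starts
    agree on the best log-likelihood within 1e-3 (or only one start was
    requested).
    """
    if isinstance(series, StepSeries):
        series = [series]
    if n_states not in (1, 2):
        raise ValueError("only 1- or 2-state models are supported")
    rng = np.random.default_rng(seed)
    n_obs = int(sum(len(s) for s in series))
    packed = _Packed(series)

    def nll(theta):
        try:
            p = _unpack(theta, n_states)
        except ValueError:
            return 1e12
        ll = packed.loglik(p)
        return -ll if np.isfinite(ll) else 1e12

    results = []
    for _ in range(n_starts):
        theta0 = _pack(_random_start(rng, n_states))
        res = optimize.minimize(nll, theta0, method="L-BFGS-B",
                                options={"maxiter": maxiter})
        if np.isfinite(res.fun):
            results.append(res)
    if not results:
        raise RuntimeError("all HMM starts failed to produce a finite "
                           "likelihood")
    lls = sorted(-r.fun for r in results)[::-1]
    best = min(results, key=lambda r: r.fun)
    params = _unpack(best.x, n_states).relabelled()
    ll = -best.fun
    agree = len(lls) == 1 or (len(lls) > 1 and lls[0] - lls[1] < 1e-3)
    k_est = params.n_parameters(stationary_delta=False)
    k_st = params.n_parameters(stationary_delta=True)
    return HmmFit(params=params, loglik=ll, n_obs=n_obs,
                  aic=2 * k_est - 2 * ll, aic_stationary=2 * k_st - 2 * ll,
                  n_states=n_states, converged=bool(best.success and agree),
                  start_logliks=[-r.fun for r in results])


def viterbi_decode(params: HmmParameters, series: StepSeries) -> np.ndarray:
    """Jointly most probable state path (1-based), in log space."""
    logb = _log_emissions(params, series)
    T, n = logb.shape
    with np.errstate(divide="ignore"):
        log_tpm = np.log(params.tpm)
        log_delta = np.log(params.delta)
    dp = np.empty((T, n))
    back = np.zeros((T, n), dtype=int)
    dp[0] = log_delta + logb[0]
    for t in range(1, T):
        cand = dp[t - 1][:, None] + log_tpm
        back[t] = np.argmax(cand, axis=0)
        dp[t] = cand[back[t], np.arange(n)] + logb[t]
    states = np.empty(T, dtype=int)
    states[-1] = int(np.argmax(dp[-1]))
    for t in range(T - 2, -1, -1):
        states[t] = back[t + 1][states[t + 1]]
    return states + 1


def pseudo_residuals(params: HmmParameters, series):
    """One-step-ahead forecast pseudo-residuals of step lengths.

    Each step's forecast CDF (state-probability-weighted gamma CDF, with
    state probabilities conditioned on the past) is mapped through the
    standard normal quantile function; under a correct model the residuals
    are standard normal. A Kolmogorov-Smirnov comparison with N(0,1) is
    reported.
    """
    if isinstance(series, StepSeries):
        series = [series]
    zs = []
    for s in series:
        ll, pred = _forward(params, s, return_pred=True)
        ok = np.isfinite(s.steps) & (s.steps > 0)
        u = np.zeros(ok.sum())
        for j in range(params.n_states):
            u += pred[ok, j] * stats.gamma.cdf(
                s.steps[ok], a=params.gamma_shape[j],
                scale=params.gamma_scale[j])
        zs.append(stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12)))
    z = np.concatenate(zs)
    ks = stats.kstest(z, "norm")
    return z, {"ks_statistic": float(ks.statistic), "ks_pvalue": float(ks.pvalue)}
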