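import itertools

import numpy as np
import pytest
from scipy import integrate, stats

from tundratrack import hmm as H
from tundratrack import synthetic as syn
from tundratrack.evaluation import simulate_hmm_series


@pytest.fixture()
def params():
    return syn.default_hmm_params()


@pytest.fixture()
def short_series(rng, params):
    steps = rng.gamma(2.0, 1.0, size=6)
    angles = np.append(np.nan, rng.uniform(-3, 3, 5))
    return H.StepSeries("t", steps, angles)


def brute_force_loglik(params, series):
    T = len(series)
    total = 0.0
    for path in itertools.product(range(1, params.n_states + 1), repeat=T):
        p = params.delta[path[0] - 1]
        for t in range(1, T):
            p *= params.tpm[path[t - 1] - 1, path[t] - 1]
        for t in range(T):
            p *= H.emission_density(params, path[t], series.steps[t],
                                    series.angles[t])
        total += p
    return np.log(total)


class TestStepsAndAngles:
    def test_collinear_steps_zero_angles(self, track_factory):
        traj = track_factory([(0, 0), (1, 0), (2, 0), (3, 0)])
        s = H.steps_and_angles(traj)
        np.testing.assert_allclose(s.steps, 1.0)
        np.testing.assert_allclose(s.angles[1:], 0.0)
        assert np.isnan(s.angles[0])

    def test_left_turn_positive(self, track_factory):
        traj = track_factory([(0, 0), (1, 0), (1, 1)])
        s = H.steps_and_angles(traj)
        np.testing.assert_allclose(s.steps, [1.0, 1.0])
        assert s.angles[1] == pytest.approx(np.pi / 2)

    def test_zero_step_angle_missing(self, track_factory):
        traj = track_factory([(0, 0), (1, 0), (1, 0), (2, 0)])
        s = H.steps_and_angles(traj)
        assert s.steps[1] == 0.0
        assert np.isnan(s.angles[1]) and np.isnan(s.angles[2])

    def test_too_short_rejected(self, track_factory):
        with pytest.raises(ValueError):
            H.steps_and_angles(track_factory([(0, 0), (1, 1)]))


class TestWrappedCauchy:
    def test_zero_concentration_uniform(self):
        theta = np.linspace(-3, 3, 7)
        np.testing.assert_allclose(H.wrapped_cauchy_pdf(theta, 0.0, 0.0),
                                   1 / (2 * np.pi))

    def test_integrates_to_one(self):
        for rho in (0.2, 0.8, 0.95):
            val, _ = integrate.quad(
                lambda th: H.wrapped_cauchy_pdf(th, 0.7, rho),
                -np.pi, np.pi, limit=200)
            assert val == pytest.approx(1.0, abs=1e-8)

    def test_sampler_matches_density(self, rng):
        """Sampled angles agree with the density via a chi-square test."""
        rho, mu = 0.6, 1.0
        draws = H.sample_wrapped_cauchy(rng, mu, rho, size=20_000)
        edges = np.linspace(-np.pi, np.pi, 25)
        obs, _ = np.histogram(draws, bins=edges)
        probs = [integrate.quad(lambda th: H.wrapped_cauchy_pdf(th, mu, rho),
                                a, b)[0] for a, b in zip(edges, edges[1:])]
        assert stats.chisquare(obs, 20_000 * np.array(probs)).pvalue > 0.01


class TestEmission:
    def test_gamma_reduces_to_exponential(self, params):
        p = H.HmmParameters([2.0], [2.0], [0.0], [0.0], [[1.0]], [1.0])
        # shape 1: density at 0+ equals 1/mu
        assert H.emission_density(p, 1, 1e-9, None) == pytest.approx(
            0.5, rel=1e-4)

    def test_missing_parts_unit_factor(self, params):
        assert H.emission_density(params, 1, np.nan, np.nan) == 1.0


class TestForward:
    def test_t1_is_delta_weighted_mixture(self, params):
        s = H.StepSeries("t", [2.5], [np.nan])
        ll = H.hmm_loglik(params, s)
        mix = sum(params.delta[j] * H.emission_density(params, j + 1, 2.5,
                                                       None)
                  for j in range(2))
        assert ll == pytest.approx(np.log(mix), abs=1e-12)

    def test_matches_exhaustive_enumeration(self, params, short_series):
        ll = H.hmm_loglik(params, short_series)
        assert ll == pytest.approx(brute_force_loglik(params, short_series),
                                   abs=1e-10)

    def test_identical_states_factorize(self, short_series):
        p = H.HmmParameters([2.0, 2.0], [1.5, 1.5], [0.3, 0.3], [0.5, 0.5],
                            [[0.7, 0.3], [0.4, 0.6]], [0.5, 0.5])
        ll = H.hmm_loglik(p, short_series)
        direct = sum(np.log(H.emission_density(p, 1, st, an))
                     for st, an in zip(short_series.steps,
                                       short_series.angles))
        assert ll == pytest.approx(direct, abs=1e-10)

    def test_relabelling_invariance(self, params, short_series):
        swapped = H.HmmParameters(
            params.step_mean[::-1], params.step_sd[::-1],
            params.angle_mean[::-1], params.angle_conc[::-1],
            params.tpm[::-1, ::-1], params.delta[::-1])
        assert H.hmm_loglik(params, short_series) == pytest.approx(
            H.hmm_loglik(swapped, short_series), abs=1e-10)

    def test_packed_equals_per_series(self, params, rng):
        series = simulate_hmm_series(rng, params, 5, 30)
        packed = H.hmm_loglik(params, series)
        single = sum(H._forward(params, s) for s in series)
        assert packed == pytest.approx(single, abs=1e-8)


class TestViterbi:
    def test_t1_argmax(self, params):
        s = H.StepSeries("t", [5.0], [np.nan])
        dec = H.viterbi_decode(params, s)
        probs = [params.delta[j] * H.emission_density(params, j + 1, 5.0,
                                                      None)
                 for j in range(2)]
        assert dec[0] == np.argmax(probs) + 1

    def test_matches_exhaustive_argmax(self, params, rng):
        for _ in range(5):
            T = 8
            steps = rng.gamma(1.5, 2.0, size=T)
            angles = np.append(np.nan, rng.uniform(-3, 3, T - 1))
            s = H.StepSeries("t", steps, angles)
            best, best_p = None, -np.inf
            for path in itertools.product((1, 2), repeat=T):
                p = np.log(params.delta[path[0] - 1])
                for t in range(1, T):
                    p += np.log(params.tpm[path[t - 1] - 1, path[t] - 1])
                for t in range(T):
                    p += np.log(H.emission_density(params, path[t],
                                                   steps[t], angles[t]))
                if p > best_p:
                    best, best_p = path, p
            np.testing.assert_array_equal(H.viterbi_decode(params, s),
                                          best)

    def test_well_separated_states_accurate(self, params, rng):
        st = syn.simulate_state_sequence(rng, params.tpm, 300, 1)
        steps = rng.gamma(params.gamma_shape[st - 1],
                          params.gamma_scale[st - 1])
        angles = np.array([syn.sample_wrapped_cauchy(
            rng, 0.0, params.angle_conc[s - 1]) for s in st])
        angles[0] = np.nan
        dec = H.viterbi_decode(params, H.StepSeries("t", steps, angles))
        assert np.mean(dec == st) >= 0.9


class TestFit:
    def test_one_state_recovers_exponential_mean(self, rng):
        # MLE of an exponential mean is the sample mean
        steps = rng.exponential(3.0, size=2000)
        angles = np.full(2000, np.nan)
        fit = H.fit_hmm(H.StepSeries("t", steps, angles), n_states=1,
                        n_starts=3, seed=0)
        assert fit.params.step_mean[0] == pytest.approx(steps.mean(),
                                                        rel=0.05)

    def test_parameter_count_conventions(self, params):
        assert params.n_parameters() == 11
        assert params.n_parameters(stationary_delta=True) == 10

    def test_invalid_tpm_rejected(self):
        with pytest.raises(ValueError):
            H.HmmParameters([1, 2], [1, 1], [0, 0], [0.1, 0.1],
                            [[0.9, 0.2], [0.1, 0.9]], [0.5, 0.5])


class TestPseudoResiduals:
    def test_median_observation_residual_near_zero(self, rng):
        steps = rng.gamma(4.0, 1.0, size=501)
        angles = np.full(501, np.nan)
        s = H.StepSeries("t", steps, angles)
        fit = H.fit_hmm(s, n_states=1, n_starts=3, seed=0)
        z, rep = H.pseudo_residuals(fit.params, s)
        med_idx = np.argsort(steps)[len(steps) // 2]
        assert abs(z[med_idx]) < 0.1

    def test_correct_model_residuals_normal(self, params, rng):
        series = simulate_hmm_series(rng, params, 10, 100)
        fit = H.fit_hmm(series, n_states=2, n_starts=4, seed=1)
        z, rep = H.pseudo_residuals(fit.params, series)
        assert rep["ks_pvalue"] > 0.01

    def test_misspecified_model_rejected(self, rng):
        # heavy-tailed lognormal steps fitted with a single gamma state
        steps = rng.lognormal(0.0, 1.3, size=1500)
        angles = np.full(1500, np.nan)
        s = H.StepSeries("t", steps, angles)
        fit = H.fit_hmm(s, n_states=1, n_starts=3, seed=0)
        z, rep = H.pseudo_residuals(fit.params, s)
        assert rep["ks_pvalue"] < 0.01
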