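"""Posterior sampling: likelihood, priors, sampler engine and diagnostics."""

import inspect
import math

import numpy as np
import pytest

from nernstfit.fitting import ParameterTransform, params_to_vector
from nernstfit.io import TimeActivityCurve
from nernstfit.mcmc import (
    ChainSet,
    adaptive_metropolis,
    combine_errors,
    gelman_rubin,
    log_likelihood,
    log_prior,
    posterior_summary,
    run_chains,
)
from nernstfit.simulate import simulation_study_truth


def _flat_params(baseline):
    x = np.zeros(12)
    x[2], x[4] = 0.05, 0.1
    x[5], x[6], x[7] = 1.0, 12.0, 4.0
    x[9] = x[10] = 0.3
    x[11] = baseline
    return x


class TestLogLikelihood:
    def test_single_point_hand_value(self):
        """y = 2 counts, mu = 3 -> 2 ln 3 - 3 - ln 2."""
        tac = TimeActivityCurve([0.0], [2.0], metadata={})
        ll = log_likelihood(_flat_params(3.0), tac, count_scale=1.0)
        assert ll == pytest.approx(2 * math.log(3) - 3 - math.log(2), rel=1e-12)

    def test_matched_amplitude_beats_rescaled_amplitude(self, study_tac):
        """The Poisson likelihood peaks near the amplitude that matches the data."""
        cs = study_tac.metadata["count_scale"]
        x = params_to_vector(simulation_study_truth(kf=2.0))
        # map the ground-truth amplitude onto the peak-normalized count scale
        x[8] *= study_tac.metadata["scale_factor"] / cs
        ll0 = log_likelihood(x, study_tac, cs)
        assert np.isfinite(ll0)
        for factor in (0.9, 1.1):
            x2 = x.copy()
            x2[8] *= factor  # rescale amplitude only
            assert log_likelihood(x2, study_tac, cs) < ll0

    def test_zero_mean_with_positive_count_is_impossible(self):
        tac = TimeActivityCurve([0.0], [5.0], metadata={})
        assert log_likelihood(_flat_params(0.0), tac, 1.0) == -np.inf

    def test_count_scale_must_be_positive(self):
        tac = TimeActivityCurve([0.0], [1.0], metadata={})
        with pytest.raises(ValueError):
            log_likelihood(_flat_params(1.0), tac, 0.0)


class TestLogPrior:
    def test_maximum_at_center(self):
        c = np.zeros(4)
        assert log_prior(c, c) == 0.0
        assert log_prior(c + 0.3, c) < 0.0

    def test_symmetry(self):
        c = np.array([1.0, -2.0])
        d = np.array([0.2, 0.4])
        assert log_prior(c + d, c) == pytest.approx(log_prior(c - d, c))

    def test_one_sigma_drop(self):
        c = np.zeros(1)
        assert log_prior(c + 1.3, c, width=1.3) == pytest.approx(-0.5)


class TestSamplerEngine:
    def test_recovers_standard_gaussian(self):
        """Known 2-D target: mean ~ 0 and unit variance at 60k total draws."""
        def logp(z):
            return -0.5 * float(z @ z)

        chains = run_chains(
            logp,
            [np.array([1.0, -1.0]), np.array([-2.0, 0.5]), np.array([0.0, 2.0])],
            n_iter=20_000,
            burn_in=2_000,
            seed=0,
        )
        kept = chains.retained().reshape(-1, 2)
        assert np.abs(kept.mean(axis=0)).max() < 0.06
        assert kept.var(axis=0) == pytest.approx([1.0, 1.0], rel=0.1)
        assert np.all(gelman_rubin(chains.retained()) < 1.05)

    def test_seed_determinism(self):
        def logp(z):
            return -0.5 * float(z @ z)

        starts = [np.zeros(2), np.ones(2)]
        a = run_chains(logp, starts, n_iter=500, burn_in=100, seed=42)
        b = run_chains(logp, starts, n_iter=500, burn_in=100, seed=42)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.log_post, b.log_post)

    def test_default_protocol_matches_reference(self):
        sig = inspect.signature(adaptive_metropolis)
        assert sig.parameters["n_iter"].default == 10_000
        assert sig.parameters["n_chains"].default == 3
        assert sig.parameters["burn_in"].default == 1_000

    def test_acceptance_rate_in_working_range(self, study_chains):
        for rate in study_chains.acceptance_rates:
            assert 0.05 < rate < 0.7


class TestGelmanRubin:
    def test_matches_hand_computed_formula(self):
        rng = np.random.default_rng(3)
        chains = rng.normal(size=(2, 12)) + np.array([[0.0], [1.5]])
        # scalar oracle: classical potential scale reduction factor
        m, n = chains.shape
        means = chains.mean(axis=1)
        w = sum(((c - c.mean()) ** 2).sum() / (n - 1) for c in chains) / m
        b_over_n = ((means - means.mean()) ** 2).sum() / (m - 1)
        expected = math.sqrt(((n - 1) / n * w + b_over_n) / w)
        assert gelman_rubin(chains) == pytest.approx(expected, rel=1e-12)

    def test_converged_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(3, 5000))
        assert gelman_rubin(chains) < 1.05

    def test_divergent_chains_flagged(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(2, 500))
        chains[1] += 10.0
        assert gelman_rubin(chains) > 3.0

    def test_degenerate_chains_warn(self):
        chains = np.ones((2, 50))
        with pytest.warns(RuntimeWarning):
            assert gelman_rubin(chains) == 1.0


def _dummy_chainset(draws, burn_in=0, thin=1):
    n_chains, n_iter, d = draws.shape
    return ChainSet(
        draws=draws,
        log_post=np.zeros((n_chains, n_iter)),
        acceptance_rates=np.full(n_chains, 0.3),
        burn_in=burn_in,
        thin=thin,
        seeds=tuple(range(n_chains)),
        transform=ParameterTransform(),
    )


class TestPosteriorSummary:
    def test_reference_protocol_retains_27000_draws(self):
        draws = np.zeros((3, 10_000, 2))
        cs = _dummy_chainset(draws, burn_in=1_000)
        assert cs.retained().reshape(-1, 2).shape[0] == 27_000

    def test_constant_chains_collapse_to_point(self):
        import dataclasses

        tr = ParameterTransform()
        truth = dataclasses.replace(simulation_study_truth(kf=1.0), b=0.05)
        z = tr.to_unconstrained(params_to_vector(truth))
        draws = np.tile(z, (2, 60, 1))
        summ = posterior_summary(_dummy_chainset(draws))
        assert summ.mean["Em"] == pytest.approx(-50.0, rel=1e-9)
        assert summ.mean["Em"] == summ.median["Em"] == summ.map["Em"]
        assert summ.sd["Em"] == 0.0

    def test_pooling_is_chain_permutation_invariant(self):
        import dataclasses

        rng = np.random.default_rng(5)
        tr = ParameterTransform()
        truth = dataclasses.replace(simulation_study_truth(kf=1.0), b=0.05)
        z = tr.to_unconstrained(params_to_vector(truth))
        draws = z + 0.01 * rng.normal(size=(3, 40, len(z)))
        a = posterior_summary(_dummy_chainset(draws))
        b = posterior_summary(_dummy_chainset(draws[::-1].copy()))
        assert a.mean == pytest.approx(b.mean)
        assert a.sd == pytest.approx(b.sd)

    def test_voltages_reported_negative_in_mv(self, study_summary):
        assert -150.0 < study_summary.mean["Em"] < -10.0
        assert -200.0 < study_summary.mean["dPsi_m"] < -20.0
        assert study_summary.sd["Em"] > 0.0


class TestCombineErrors:
    def test_pythagorean_case(self):
        assert combine_errors(3.0, 4.0) == 5.0

    def test_zero_component_is_identity(self):
        assert combine_errors(0.0, 2.7) == 2.7
        assert combine_errors(2.7, 0.0) == 2.7

    def test_symmetric(self):
        assert combine_errors(1.2, 3.4) == combine_errors(3.4, 1.2)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            combine_errors(-1.0, 1.0)
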