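import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regimeshift import (
    HazardPrior,
    NormalGammaPrior,
    ParticleSet,
    SMCSettings,
    UniformPriorBounds,
    fit_posterior,
    hazard_transition,
    normal_density,
    predictive_density,
    smc_update,
)
from regimeshift.conjugate import log_predictive
from regimeshift.smc import DegenerateUpdateWarning, UniformBoxPrior


class TestHazard:
    @pytest.mark.parametrize(
        "lam,shift,grow", [(25.0, 0.04, 0.96), (10.0, 0.1, 0.9)]
    )
    def test_constant_hazard_probabilities(self, lam, shift, grow):
        tr = hazard_transition(5, HazardPrior(lam))
        assert tr["shift"] == pytest.approx(shift)
        assert tr["grow"] == pytest.approx(grow)
        assert tr["other"] == 0.0

    @given(st.floats(min_value=1.0001, max_value=1e6), st.integers(0, 1000))
    @settings(max_examples=50, derandomize=True)
    def test_transition_is_proper_and_independent_of_run_length(self, lam, r):
        tr = hazard_transition(r, HazardPrior(lam))
        assert tr["shift"] + tr["grow"] == pytest.approx(1.0)
        assert 0 < tr["shift"] < 1

    def test_invalid_hazard(self):
        with pytest.raises(ValueError):
            HazardPrior(1.0)
        with pytest.raises(ValueError):
            hazard_transition(-1, HazardPrior(10))


class TestNormalDensity:
    def test_reference_values(self):
        assert normal_density(0.0, 0.0, 1.0) == pytest.approx(0.3989423, abs=1e-7)
        assert normal_density(1.0, 0.0, 1.0) == pytest.approx(0.2419707, abs=1e-7)

    @given(
        st.floats(-50, 50), st.floats(-50, 50), st.floats(0.01, 100)
    )
    @settings(max_examples=100, derandomize=True)
    def test_symmetry_about_the_mean(self, y, mu, sigma):
        assert normal_density(y, mu, sigma) == pytest.approx(
            normal_density(2 * mu - y, mu, sigma), rel=1e-12
        )

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            normal_density(0.0, 0.0, 0.0)


class TestPredictiveDensity:
    def test_single_particle(self):
        ps = ParticleSet(
            np.array([0.0]), np.array([1.0]), np.array([0.0]),
            UniformBoxPrior(UniformPriorBounds(-5, 5, 0.1, 5)),
        )
        assert predictive_density(ps, 0.0) == pytest.approx(0.3989423, abs=1e-6)

    def test_two_symmetric_particles(self):
        ps = ParticleSet(
            np.array([-1.0, 1.0]), np.array([1.0, 1.0]),
            np.full(2, -np.log(2.0)),
            UniformBoxPrior(UniformPriorBounds(-5, 5, 0.1, 5)),
        )
        assert predictive_density(ps, 0.0) == pytest.approx(0.2419707, abs=1e-6)

    def test_prior_particles_match_quadrature_within_one_percent(self):
        bounds = UniformPriorBounds(-10, 10, 0.1, 10.0)
        prior = UniformBoxPrior(bounds)
        ps = ParticleSet.from_prior(bounds, 100_000, np.random.default_rng(0))
        for y in (0.0, 2.5, -7.0):
            mc = predictive_density(ps, y)
            exact = np.exp(prior.log_prior_predictive(y))
            assert mc == pytest.approx(exact, rel=0.01)

    def test_degenerate_weights_rejected(self):
        ps = ParticleSet(
            np.array([0.0, 1.0]), np.array([1.0, 1.0]),
            np.array([-np.inf, -np.inf]),
            UniformBoxPrior(UniformPriorBounds(-5, 5, 0.1, 5)),
        )
        with pytest.raises(ValueError, match="degenerate"):
            predictive_density(ps, 0.0)


class TestSMCUpdate:
    def test_posterior_mean_recovery(self):
        # 200 draws from Normal(5, 2): posterior mean of mu within 3 * 2/sqrt(200)
        data = np.random.default_rng(8).normal(5, 2, 200)
        ps = fit_posterior(
            data, UniformPriorBounds(-50, 50, 0.01, 50),
            SMCSettings(n_particles=2000), np.random.default_rng(4),
        )
        assert abs(ps.posterior_mean_mu() - 5.0) < 3.0 * 2.0 / np.sqrt(200)
        assert abs(ps.posterior_mean_sigma() - 2.0) < 0.5

    def test_constant_observations_concentrate_on_their_value(self):
        data = np.full(50, 3.7)
        ps = fit_posterior(
            data, UniformPriorBounds(0, 8, 0.001, 2.0),
            SMCSettings(n_particles=2000), np.random.default_rng(1),
        )
        assert ps.posterior_mean_mu() == pytest.approx(3.7, abs=0.01)

    def test_matches_dense_grid_posterior(self):
        # independent oracle: 400x400 grid posterior over (mu, sigma)
        data = np.random.default_rng(11).normal(1.2, 0.9, 30)
        bounds = UniformPriorBounds(-5, 5, 0.05, 5.0)
        mu_g = np.linspace(bounds.mu_low, bounds.mu_high, 400)
        sg_g = np.linspace(bounds.s_low, bounds.s_high, 400)
        MU, SG = np.meshgrid(mu_g, sg_g, indexing="ij")
        n, s1, s2 = len(data), data.sum(), (data**2).sum()
        ll = -n * np.log(SG) - (s2 - 2 * MU * s1 + n * MU**2) / (2 * SG**2)
        w = np.exp(ll - ll.max())
        w /= w.sum()
        mu_grid, sg_grid = float((w * MU).sum()), float((w * SG).sum())
        ps = fit_posterior(
            data, bounds, SMCSettings(n_particles=2000), np.random.default_rng(3)
        )
        assert abs(ps.posterior_mean_mu() - mu_grid) < 0.05 * 0.9
        assert abs(ps.posterior_mean_sigma() - sg_grid) < 0.05 * 0.9

    def test_degenerate_update_reinitializes_with_warning(self):
        bounds = UniformPriorBounds(-1, 1, 0.5, 1.0)
        ps = ParticleSet.from_prior(bounds, 100, np.random.default_rng(0))
        # observation so extreme every particle log-likelihood underflows
        with pytest.warns(DegenerateUpdateWarning):
            smc_update(ps, 1e200, SMCSettings(n_particles=100), np.random.default_rng(1))
        assert np.all(np.isfinite(ps.log_weights))


class TestConjugatePredictive:
    def test_fresh_regime_predictive_is_student_t(self):
        # r=0 emission at y=m0: Student-t density at zero over the prior scale
        from scipy import stats

        ng = NormalGammaPrior(m0=2.0, kappa0=1.5, alpha0=2.0, beta0=3.0)
        scale = np.sqrt(ng.beta0 * (ng.kappa0 + 1) / (ng.alpha0 * ng.kappa0))
        expected = stats.t.logpdf(0.0, df=2 * ng.alpha0) - np.log(scale)
        assert log_predictive(2.0, ng) == pytest.approx(expected, abs=1e-12)

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            NormalGammaPrior(0.0, -1.0, 1.0, 1.0)
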