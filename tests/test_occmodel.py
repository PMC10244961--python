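import itertools

import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import norm

import occutrends as ot
from occutrends.occmodel import ModelData, PriorConfig, log_posterior_kernel


def tiny_params(data, rng):
    return {
        "b": rng.normal(0, 1, size=(data.n_regions, data.n_years)),
        "u": rng.normal(0, 1, size=data.n_sites),
        "a": rng.normal(0, 1, size=data.n_years),
        "beta1": rng.normal(),
        "beta2": rng.normal(),
        "sigma_u": float(rng.uniform(0.3, 2.0)),
        "sigma_rw": float(rng.uniform(0.1, 1.0)),
        "mu_a": rng.normal(),
        "sigma_a": float(rng.uniform(0.3, 2.0)),
    }


class TestLinkFunctions:
    def test_state_logit_zero_gives_half(self, tiny_model_data):
        params = {"b": np.zeros((2, 2)), "u": np.zeros(2)}
        eta = ot.state_logit(params, tiny_model_data, 0, 0)
        assert expit(eta) == 0.5

    def test_state_logit_additivity(self, tiny_model_data):
        params = {"b": np.array([[1.0, 0.0], [5.0, 5.0]]), "u": np.array([-1.0, 0.0])}
        assert ot.state_logit(params, tiny_model_data, 0, 0) == 0.0

    def test_other_region_year_effect_is_inert(self, tiny_model_data):
        """Changing b of a region holding no focal site leaves all psi unchanged."""
        rng = np.random.default_rng(0)
        params = tiny_params(tiny_model_data, rng)
        baseline = [
            ot.state_logit(params, tiny_model_data, i, t)
            for i in range(2)
            for t in range(2)
        ]
        perturbed = {**params, "b": params["b"].copy()}
        # site 0 is in region 0, site 1 in region 1; add a phantom region row
        data3 = ModelData(
            region=np.array([0, 1]),
            vsite=tiny_model_data.vsite,
            vyear=tiny_model_data.vyear,
            vdt=tiny_model_data.vdt,
            vy=tiny_model_data.vy,
            n_years=2,
            region_names=("high", "low", "none"),
        )
        params3 = {**params, "b": np.vstack([params["b"], [0.0, 0.0]])}
        before = [
            ot.state_logit(params3, data3, i, t) for i in range(2) for t in range(2)
        ]
        params3["b"][2] += 100.0
        after = [
            ot.state_logit(params3, data3, i, t) for i in range(2) for t in range(2)
        ]
        assert before == after == baseline

    @pytest.mark.parametrize(
        "datatype, expected",
        [("single", 0.0), ("short", 1.0), ("long", 2.5)],
    )
    def test_obs_logit_offsets(self, datatype, expected):
        params = {"a": np.array([0.0]), "beta1": 1.0, "beta2": 2.5}
        assert ot.obs_logit(params, 0, datatype) == expected

    def test_obs_logit_monotone_in_effort(self):
        params = {"a": np.array([-0.3]), "beta1": 0.5, "beta2": 1.2}
        p = [expit(ot.obs_logit(params, 0, d)) for d in ("single", "short", "long")]
        assert p[0] < p[1] < p[2]


class TestKernel:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_marginalized_matches_z_enumeration(self, tiny_model_data, seed):
        """Summing the augmented kernel over all latent configurations must
        reproduce the marginalised kernel exactly."""
        rng = np.random.default_rng(seed)
        params = tiny_params(tiny_model_data, rng)
        priors = PriorConfig()
        marg = log_posterior_kernel(params, tiny_model_data, priors)
        terms = []
        for bits in itertools.product([0, 1], repeat=4):
            z = np.array(bits).reshape(2, 2)
            terms.append(
                log_posterior_kernel(params, tiny_model_data, priors, z=z)
            )
        # log-sum-exp over the enumeration; prior factors appear in every term
        prior_part = log_posterior_kernel(
            params,
            ModelData(
                region=tiny_model_data.region,
                vsite=np.array([], dtype=int),
                vyear=np.array([], dtype=int),
                vdt=np.array([], dtype=int),
                vy=np.array([], dtype=int),
                n_years=2,
                region_names=("high", "low"),
            ),
        )
        from scipy.special import logsumexp

        # each term includes the prior once; the z-likelihood priors cancel
        lik_terms = np.array(terms)
        finite = np.isfinite(lik_terms)
        assert finite.any()
        total = logsumexp(lik_terms[finite] - prior_part)
        # marg = prior + log sum_z exp(loglik(z)); the state prior on z is
        # inside each term so nothing further is needed
        assert total + prior_part == pytest.approx(marg, abs=1e-9)

    def test_detection_forces_occupancy(self, tiny_model_data):
        rng = np.random.default_rng(5)
        params = tiny_params(tiny_model_data, rng)
        z = np.zeros((2, 2), dtype=int)  # site 0 year 0 has a detection
        assert log_posterior_kernel(params, tiny_model_data, z=z) == -np.inf

    def test_no_visits_reduces_to_prior_plus_state(self):
        data = ModelData(
            region=np.array([0]),
            vsite=np.array([], dtype=int),
            vyear=np.array([], dtype=int),
            vdt=np.array([], dtype=int),
            vy=np.array([], dtype=int),
            n_years=1,
            region_names=("high",),
        )
        rng = np.random.default_rng(7)
        params = tiny_params(data, rng)
        # marginalising a site-year with no visits contributes log(psi + 1-psi) = 0
        marg = log_posterior_kernel(params, data)
        aug0 = log_posterior_kernel(params, data, z=np.array([[0]]))
        aug1 = log_posterior_kernel(params, data, z=np.array([[1]]))
        assert np.logaddexp(aug0, aug1) == pytest.approx(marg, abs=1e-10)

    def test_nonfinite_parameter_rejected(self, tiny_model_data):
        rng = np.random.default_rng(9)
        params = tiny_params(tiny_model_data, rng)
        params["beta1"] = np.nan
        assert log_posterior_kernel(params, tiny_model_data) == -np.inf


class TestGelmanRubin:
    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(21)
        chains = rng.normal(size=(4, 2000))
        assert ot.gelman_rubin(chains) < 1.05

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(22)
        chains = rng.normal(size=(2, 500))
        chains[1] += 100.0
        assert ot.gelman_rubin(chains) > 1.1

    def test_constant_chains_undefined(self):
        assert np.isnan(ot.gelman_rubin(np.ones((3, 100))))

    def test_matches_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(23)
        chains = rng.normal(size=(4, 250)) + rng.normal(size=(4, 1)) * 0.2
        ours = ot.gelman_rubin(chains)
        theirs = float(az.rhat(chains[None].transpose(1, 2, 0)[..., 0], method="split"))
        assert ours == pytest.approx(theirs, abs=1e-8)


class TestConvergenceFilter:
    def test_threshold_rule(self):
        reports = [
            {"species": "a", "rhat_first": 1.05, "rhat_last": 1.08},
            {"species": "b", "rhat_first": 1.05, "rhat_last": 1.2},
            {"species": "c", "rhat_first": np.nan, "rhat_last": 1.0},
            {"species": "d", "rhat_last": 1.0},
        ]
        retained, flagged = ot.convergence_filter(reports)
        assert retained == ["a"]
        assert flagged == ["b", "c", "d"]

    def test_empty(self):
        assert ot.convergence_filter([]) == ([], [])


class TestRetainedDraws:
    def test_published_mcmc_settings_give_999(self):
        assert ot.retained_draws(3, 32000, 30000, 6) == 999

    def test_simple_case(self):
        assert ot.retained_draws(1, 100, 50, 1) == 50

    def test_invalid(self):
        with pytest.raises(ValueError):
            ot.retained_draws(3, 100, 100, 1)


def _simple_data(rng, n_sites=30, n_years=6, visits_per=3):
    region = np.zeros(n_sites, dtype=int)
    vsite = np.repeat(np.arange(n_sites), n_years * visits_per)
    vyear = np.tile(np.repeat(np.arange(n_years), visits_per), n_sites)
    vdt = rng.integers(0, 3, size=vsite.size)
    z = rng.random((n_sites, n_years)) < 0.5
    p = expit(-0.5 + 0.6 * vdt)
    vy = (z[vsite, vyear] & (rng.random(vsite.size) < p)).astype(int)
    return ModelData(
        region=region, vsite=vsite, vyear=vyear, vdt=vdt, vy=vy,
        n_years=n_years, region_names=("high",),
    ).validate()


class TestSampler:
    def test_draw_count_and_shapes(self):
        rng = np.random.default_rng(31)
        data = _simple_data(rng)
        model = ot.OccupancyModel(
            chains=1, iterations=100, burnin=50, thin=1, seed=2
        ).fit(data)
        assert model.n_draws_ == 50
        assert model.occupancy_.shape == (50, 1, 6)
        assert model.draws_["b"].shape == (50, 1, 6)

    def test_bit_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(32)
        data = _simple_data(rng)
        kw = dict(chains=2, iterations=200, burnin=100, thin=2, seed=7)
        m1 = ot.OccupancyModel(**kw).fit(data)
        m2 = ot.OccupancyModel(**kw).fit(data)
        for k in m1.draws_:
            np.testing.assert_array_equal(m1.draws_[k], m2.draws_[k])
        m3 = ot.OccupancyModel(**{**kw, "seed": 8}).fit(data)
        assert not np.array_equal(m1.occupancy_, m3.occupancy_)

    def test_random_walk_prior_predictive(self):
        """With no detections and everything but b fixed, the chain targets
        the prior: successive year-effect differences have sd sigma_rw."""
        n_sites, n_years = 1, 12
        data = ModelData(
            region=np.zeros(1, dtype=int),
            vsite=np.array([0]),
            vyear=np.array([0]),
            vdt=np.array([0]),
            vy=np.array([0]),
            n_years=n_years,
            region_names=("high",),
        ).validate()
        sigma_rw = 0.5
        model = ot.OccupancyModel(
            chains=2,
            iterations=6000,
            burnin=1000,
            thin=2,
            seed=5,
            priors=PriorConfig(b0=("normal", 0.0, 1.0)),
            # detection forced to zero so the single non-detection is inert
            fixed={
                "u": 0.0,
                "sigma_u": 1.0,
                "a": -30.0,
                "beta1": 0.0,
                "beta2": 0.0,
                "sigma_rw": sigma_rw,
            },
        ).fit(data)
        diffs = np.diff(model.draws_["b"][:, 0, :], axis=1)
        assert abs(diffs.mean()) < 0.05
        assert diffs.std() == pytest.approx(sigma_rw, abs=0.06)

    def test_conjugate_beta_bernoulli_oracle(self):
        """Perfect detection + logistic prior on the year effect collapses the
        model to a Beta-Bernoulli posterior for occupancy."""
        rng = np.random.default_rng(40)
        n = 40
        z_true = rng.random(n) < 0.3
        data = ModelData(
            region=np.zeros(n, dtype=int),
            vsite=np.arange(n),
            vyear=np.zeros(n, dtype=int),
            vdt=np.zeros(n, dtype=int),
            vy=z_true.astype(int),
            n_years=1,
            region_names=("high",),
        ).validate()
        model = ot.OccupancyModel(
            chains=3,
            iterations=4000,
            burnin=1000,
            thin=3,
            seed=9,
            priors=PriorConfig(b0=("logistic", 0.0, 1.0)),
            fixed={"u": 0.0, "sigma_u": 1.0, "a": 15.0, "beta1": 0.0, "beta2": 0.0},
        ).fit(data)
        psi = expit(model.draws_["b"][:, 0, 0])
        k = int(z_true.sum())
        post_mean = (k + 1) / (n + 2)
        post_sd = np.sqrt((k + 1) * (n - k + 1) / ((n + 2) ** 2 * (n + 3)))
        mc_se = psi.std() / np.sqrt(200)  # generous ESS guess
        assert psi.mean() == pytest.approx(post_mean, abs=4 * mc_se + 0.01)
        assert psi.std() == pytest.approx(post_sd, rel=0.2)

    def test_rhat_reported_for_first_and_last_year(self):
        rng = np.random.default_rng(33)
        data = _simple_data(rng)
        model = ot.OccupancyModel(
            chains=2, iterations=400, burnin=200, thin=2, seed=3
        ).fit(data)
        assert "occ_high_first" in model.rhat_
        assert "occ_high_last" in model.rhat_
        assert np.isfinite(model.rhat_occ_first_)
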