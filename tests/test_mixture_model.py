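import math

import numpy as np
import pytest

from survbma import mixture, weibull
from survbma.core import SurvivalDataset, WeibullLaw, weibull_logpdf, weibull_logsurv
from survbma.mcmc import ChainConfig, PosteriorChain
from survbma.mixture import (
    AllocationState,
    MixtureParams,
    allocation_step,
    mixture_logdensity,
    observed_loglik,
    reorder_chain,
    weight_update,
)


def two_component_params():
    return MixtureParams(
        weights=[0.3, 0.7],
        alphas=[4.0, 0.8],
        betas=[[-3.0, -0.4], [-1.0, 0.3]],
    )


class TestMixtureLogdensity:
    def test_k1_equals_single_weibull(self):
        params = MixtureParams([1.0], [1.3], [[-0.5, 0.2]])
        x = np.array([1.0, 0.7])
        law = WeibullLaw(1.3, float(x @ np.array([-0.5, 0.2])))
        assert mixture_logdensity(0.9, x, params) == pytest.approx(
            weibull_logpdf(0.9, law), abs=1e-12
        )

    def test_identical_components_collapse(self):
        params = MixtureParams([0.5, 0.5], [1.3, 1.3], [[-0.5, 0.2], [-0.5, 0.2]])
        x = np.array([1.0, -0.3])
        law = WeibullLaw(1.3, float(x @ np.array([-0.5, 0.2])))
        assert mixture_logdensity(2.0, x, params) == pytest.approx(
            weibull_logpdf(2.0, law), abs=1e-12
        )

    def test_direct_two_term_sum(self):
        params = two_component_params()
        x = np.array([1.0, 0.5])
        t = 1.0
        expected = math.log(
            0.3 * math.exp(weibull_logpdf(t, WeibullLaw(4.0, float(x @ [-3.0, -0.4]))))
            + 0.7 * math.exp(weibull_logpdf(t, WeibullLaw(0.8, float(x @ [-1.0, 0.3]))))
        )
        assert mixture_logdensity(t, x, params) == pytest.approx(expected, abs=1e-12)

    def test_extreme_lam_no_overflow(self):
        params = MixtureParams([0.5, 0.5], [1.0, 1.0], [[50.0], [-50.0]])
        val = mixture_logdensity(1.0, np.array([1.0]), params)
        assert np.isfinite(val)

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError):
            MixtureParams([0.5, 0.6], [1.0, 1.0], [[0.0], [0.0]])


class TestObservedLoglik:
    def test_empty_data(self):
        data = SurvivalDataset(np.empty(0), np.empty(0, dtype=int), np.empty((0, 2)))
        assert observed_loglik(data, two_component_params()) == 0.0

    def test_identical_components_reduce_to_single(self, five_record_data):
        params = MixtureParams(
            [0.4, 0.6], [1.7, 1.7],
            [[-0.5, 0.3, -0.2], [-0.5, 0.3, -0.2]],
        )
        single = weibull.loglik(
            five_record_data,
            weibull.WeibullRegressionParams(1.7, np.array([-0.5, 0.3, -0.2])),
        )
        assert observed_loglik(five_record_data, params) == pytest.approx(
            single, abs=1e-10
        )

    def test_termwise_oracle(self, five_record_data):
        params = MixtureParams(
            [0.3, 0.7], [1.7, 0.9],
            [[-0.5, 0.3, -0.2], [0.2, -0.1, 0.4]],
        )
        expected = 0.0
        for rec in five_record_data.records:
            terms = []
            for w, a, b in zip(params.weights, params.alphas, params.betas):
                law = WeibullLaw(a, float(rec.covariates @ b))
                lp = (
                    weibull_logpdf(rec.time, law)
                    if rec.event
                    else weibull_logsurv(rec.time, law)
                )
                terms.append(w * math.exp(lp))
            expected += math.log(sum(terms))
        assert observed_loglik(five_record_data, params) == pytest.approx(
            expected, abs=1e-10
        )

    def test_permutation_invariance_exact(self, five_record_data):
        params = MixtureParams(
            [0.3, 0.7], [1.7, 0.9],
            [[-0.5, 0.3, -0.2], [0.2, -0.1, 0.4]],
        )
        flipped = MixtureParams(
            [0.7, 0.3], [0.9, 1.7],
            [[0.2, -0.1, 0.4], [-0.5, 0.3, -0.2]],
        )
        assert observed_loglik(five_record_data, params) == observed_loglik(
            five_record_data, flipped
        )

    def test_degenerate_weight_limit(self, five_record_data):
        eps = 1e-9
        params = MixtureParams(
            [1.0 - eps, eps], [1.7, 0.9],
            [[-0.5, 0.3, -0.2], [0.2, -0.1, 0.4]],
        )
        single = weibull.loglik(
            five_record_data,
            weibull.WeibullRegressionParams(1.7, np.array([-0.5, 0.3, -0.2])),
        )
        assert observed_loglik(five_record_data, params) == pytest.approx(
            single, abs=1e-6
        )


class TestAllocationStep:
    def test_degenerate_weight(self, five_record_data, rng):
        params = MixtureParams(
            [1.0, 0.0], [1.0, 2.0], [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]
        )
        state = allocation_step(five_record_data, params, rng)
        assert np.all(state.z == 0)

    def test_identical_components_uniform(self, rng):
        n = 4000
        data = SurvivalDataset(np.full(n, 1.0), np.ones(n, dtype=int), np.ones((n, 1)))
        params = MixtureParams([0.5, 0.5], [1.0, 1.0], [[0.0], [0.0]])
        state = allocation_step(data, params, rng)
        assert state.counts(2)[0] / n == pytest.approx(0.5, abs=0.05)

    def test_well_separated_posterior_probability(self, rng):
        # component 0: sharp Weibull around t~0.05; component 1: around t~5
        params = MixtureParams([0.5, 0.5], [3.0, 3.0], [[9.0], [-5.0]])
        data = SurvivalDataset([0.05], [1], [[1.0]])
        # direct posterior membership computation
        lp0 = math.log(0.5) + weibull_logpdf(0.05, WeibullLaw(3.0, 9.0))
        lp1 = math.log(0.5) + weibull_logpdf(0.05, WeibullLaw(3.0, -5.0))
        p0 = 1.0 / (1.0 + math.exp(lp1 - lp0))
        assert p0 > 0.99
        draws = [allocation_step(data, params, rng).z[0] for _ in range(200)]
        assert np.mean(np.array(draws) == 0) > 0.95


class TestWeightUpdate:
    def test_empty_counts_uniform_mean(self):
        rng = np.random.default_rng(0)
        z = AllocationState(np.empty(0, dtype=int))
        draws = np.array([weight_update(z, 2, 1.0, rng) for _ in range(4000)])
        assert np.allclose(draws.mean(axis=0), [0.5, 0.5], atol=0.02)

    def test_dirichlet_mean_formula(self):
        rng = np.random.default_rng(1)
        z = AllocationState(np.array([0] * 98 + [1] * 2))
        draws = np.array([weight_update(z, 2, 1.0, rng) for _ in range(4000)])
        # E[w] = (phi + n_m) / (K phi + n) = (99/102, 3/102)
        assert np.allclose(draws.mean(axis=0), [99 / 102, 3 / 102], atol=0.01)

    def test_single_component(self, rng):
        z = AllocationState(np.zeros(5, dtype=int))
        assert weight_update(z, 1, 1.0, rng) == pytest.approx(1.0)


def _swapped_chain(n_draws=400, seed=0):
    """Chain whose component labels are swapped on a random half of draws."""
    rng = np.random.default_rng(seed)
    names = ["alpha.1", "beta0.1", "alpha.2", "beta0.2", "w.1", "w.2"]
    a1 = rng.normal(4.0, 0.1, n_draws)
    b1 = rng.normal(-3.0, 0.1, n_draws)
    a2 = rng.normal(0.8, 0.05, n_draws)
    b2 = rng.normal(-1.0, 0.1, n_draws)
    w1 = rng.normal(0.3, 0.02, n_draws)
    draws = np.column_stack([a1, b1, a2, b2, w1, 1 - w1])
    lp = rng.normal(-100, 1, n_draws)
    swap = rng.uniform(size=n_draws) < 0.5
    lp[~swap] += 2.0  # ensure the MAP draw is an unswapped one
    draws[swap] = draws[swap][:, [2, 3, 0, 1, 5, 4]]
    return PosteriorChain(draws, names, lp, np.full(n_draws, -50.0)), swap


class TestReorderChain:
    def test_k1_identity(self):
        chain = PosteriorChain([[1.0]], ["alpha.1"], [0.0], [0.0])
        assert reorder_chain(chain, 1) is chain

    def test_aligned_chain_unchanged(self):
        rng = np.random.default_rng(3)
        names = ["alpha.1", "alpha.2", "w.1", "w.2"]
        draws = np.column_stack(
            [rng.normal(4, 0.1, 50), rng.normal(1, 0.1, 50),
             np.full(50, 0.3), np.full(50, 0.7)]
        )
        chain = PosteriorChain(draws, names, np.zeros(50), np.zeros(50))
        out = reorder_chain(chain, 2)
        assert np.array_equal(out.draws, chain.draws)

    def test_swapped_half_restored(self):
        chain, swap = _swapped_chain()
        out = reorder_chain(chain, 2)
        # component-1 marginal unimodal at its true location
        assert out.column("alpha.1").std() < 0.2
        assert out.column("alpha.1").mean() == pytest.approx(4.0, abs=0.1)
        assert out.column("alpha.2").mean() == pytest.approx(0.8, abs=0.1)
        assert out.column("w.1").mean() == pytest.approx(0.3, abs=0.05)
        # log-likelihood column untouched
        assert np.array_equal(out.log_likelihood, chain.log_likelihood)
        assert np.array_equal(out.log_posterior, chain.log_posterior)

    def test_malformed_blocks_rejected(self):
        chain = PosteriorChain(
            [[1.0, 2.0]], ["alpha.1", "w.1"], [0.0], [0.0]
        )
        with pytest.raises(ValueError):
            reorder_chain(chain, 2)


@pytest.fixture(scope="module")
def mixture_sim():
    from survbma.simulate import GeneratorConfig, gen_from_mixture

    cfg = GeneratorConfig(
        model="mixture", n=400, p=1, seed=5,
        weights=[0.3, 0.7], alphas=[4.0, 0.8],
        betas=[[-3.0, -0.4], [-1.0, -0.3]],
        censoring="horizon", censoring_target=0.2,
    )
    return gen_from_mixture(cfg)


class TestFit:
    def test_recovery_well_separated(self, mixture_sim):
        data, truth = mixture_sim
        mf = mixture.fit(data, K=2, config=ChainConfig(n_iter=6000, burn_in=1500, seed=6))
        s = mf.summary()
        # match fitted components to truth by shape
        order = np.argsort([s.loc["alpha.1", "mean"], s.loc["alpha.2", "mean"]])
        truth_order = np.argsort(truth["alphas"])
        for fitted_m, true_m in zip(order, truth_order):
            m = fitted_m + 1
            zw = abs(
                s.loc[f"w.{m}", "mean"] - truth["weights"][true_m]
            ) / s.loc[f"w.{m}", "sd"]
            assert zw < 3
            za = abs(
                s.loc[f"alpha.{m}", "mean"] - truth["alphas"][true_m]
            ) / s.loc[f"alpha.{m}", "sd"]
            assert za < 3.5

    def test_k1_matches_single_weibull(self, five_record_data):
        n = 120
        rng = np.random.default_rng(8)
        t = rng.weibull(1.4, n) * 1.5
        data = SurvivalDataset(t, np.ones(n, dtype=int))
        cfg = ChainConfig(n_iter=4000, burn_in=1000, seed=9)
        smix = mixture.fit(data, K=1, config=cfg).summary()
        swei = weibull.fit(data, config=cfg).summary()
        # same posterior in distribution: means agree within joint MC error
        assert smix.loc["alpha.1", "mean"] == pytest.approx(
            swei.loc["alpha", "mean"],
            abs=3 * (smix.loc["alpha.1", "sd"] + swei.loc["alpha", "sd"]) / 10,
        )
        assert smix.loc["beta0.1", "mean"] == pytest.approx(
            swei.loc["beta0", "mean"],
            abs=3 * (smix.loc["beta0.1", "sd"] + swei.loc["beta0", "sd"]) / 10,
        )

    def test_seed_determinism(self, mixture_sim):
        data, _ = mixture_sim
        cfg = ChainConfig(n_iter=500, burn_in=100, seed=10)
        a = mixture.fit(data, K=2, config=cfg).chain.draws
        b = mixture.fit(data, K=2, config=cfg).chain.draws
        assert np.array_equal(a, b)

    def test_too_few_subjects_rejected(self):
        data = SurvivalDataset([1.0], [1])
        with pytest.raises(ValueError):
            mixture.fit(data, K=2)

    def test_empty_component_warns(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(size=30)
        data = SurvivalDataset(t, np.ones(30, dtype=int))
        with pytest.warns(RuntimeWarning, match="empty"):
            mixture.fit(
                data, K=4,
                config=ChainConfig(n_iter=400, burn_in=100, seed=12),
                empty_warn_fraction=0.0,
            )


class TestPredictiveDraws:
    def test_reduces_to_component(self, rng):
        names = ["alpha.1", "beta0.1", "alpha.2", "beta0.2", "w.1", "w.2"]
        draws = np.tile([1.0, 0.0, 5.0, 3.0, 1.0, 0.0], (30, 1))
        chain = PosteriorChain(draws, names, np.zeros(30), np.zeros(30))
        d = mixture.predictive_draws(chain, 2, np.array([1.0]), 5000, rng)
        assert d.mean() == pytest.approx(1.0, abs=0.06)  # exponential(1)
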