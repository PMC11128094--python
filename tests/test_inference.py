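"""Likelihood, prior, sampler and diagnostics tests."""

import math

import numpy as np
import pytest

from rtfbayes import (
    PriorEntry,
    PriorSpec,
    RunConfig,
    TimeSeriesDataset,
    default_priors,
    effective_sample_size,
    gelman_rubin,
    get_model,
    log_likelihood,
    log_posterior,
    parallel_tempering,
    sample_posterior,
)
from rtfbayes.models import ModelSpec, register_model

from conftest import make_dataset

CONST_FIXED = dict(
    Asus=0.0, t1=1.0, Atrans=0.0, t11=1.0, t2=1.0, Tshift=-2.0, Trange=1.0
)


def _const_dataset(values, times=None):
    values = np.asarray(values, dtype=float)
    times = np.asarray(
        times if times is not None else np.arange(len(values)) % 2, dtype=float
    )
    return TimeSeriesDataset("c", "o", times, np.arange(len(values)).astype(str), values)


def _naive_loglik(dataset, params, sigma, model):
    total = 0.0
    for t, m in zip(dataset.times, dataset.values):
        s = float(model.evaluate(np.array([t]), params)[0])
        total += -math.log(sigma * math.sqrt(2 * math.pi)) - (s - m) ** 2 / (2 * sigma**2)
    return total


class TestLogLikelihood:
    def test_zero_residual_single_point(self):
        # model curve passes exactly through the single measured value
        ds = _const_dataset([0.5, 0.5], times=[0.0, 1.0])
        ll = log_likelihood(ds, dict(CONST_FIXED, p0=0.5), 1.0, get_model("rtf"))
        assert ll == pytest.approx(2 * -0.9189385332046727, abs=1e-12)

    def test_hand_computed_residuals(self):
        ds = _const_dataset([1.0, 2.0], times=[0.0, 1.0])
        ll = log_likelihood(ds, dict(CONST_FIXED, p0=0.0), 1.0, get_model("rtf"))
        assert ll == pytest.approx(-4.337877066409345, abs=1e-12)

    def test_sigma_normalization(self):
        ds = _const_dataset([0.5] * 10, times=[0.0, 1.0] * 5)
        params = dict(CONST_FIXED, p0=0.5)
        l1 = log_likelihood(ds, params, 1.0, get_model("rtf"))
        l2 = log_likelihood(ds, params, 2.0, get_model("rtf"))
        assert l1 - l2 == pytest.approx(10 * math.log(2), rel=1e-12)

    def test_matches_naive_loop(self):
        model = get_model("rtf")
        rng = np.random.default_rng(3)
        for _ in range(20):
            ds = make_dataset(rng, T=4, N=3)
            params = dict(
                Asus=rng.normal(), t1=rng.uniform(0.1, 5),
                Atrans=rng.normal(), t11=rng.uniform(0.1, 5),
                t2=rng.uniform(0.1, 5), Tshift=-2.0,
                p0=rng.normal(), Trange=10.0,
            )
            sigma = rng.uniform(0.2, 3)
            fast = log_likelihood(ds, params, sigma, model)
            slow = _naive_loglik(ds, params, sigma, model)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_nonfinite_model_output_rejected(self):
        bad = ModelSpec(
            model_id="bad_nan",
            parameter_names=("a",),
            evaluator=lambda g, p: np.full(len(np.atleast_1d(g)), np.nan),
        )
        ds = _const_dataset([1.0, 2.0])
        assert log_likelihood(ds, {"a": 1.0}, 1.0, bad) == -np.inf

    def test_invalid_sigma(self):
        ds = _const_dataset([1.0, 2.0])
        with pytest.raises(ValueError):
            log_likelihood(ds, dict(CONST_FIXED, p0=0.0), 0.0, get_model("rtf"))


class TestDefaultPriors:
    def _dataset_0_10(self):
        return _const_dataset([0.0, 10.0, 3.0, 7.0], times=[0, 5, 2, 3])

    def test_stated_rule(self):
        priors = default_priors(self._dataset_0_10(), get_model("rtf"), trange=5.0)
        by_name = {e.name: e for e in priors.entries}
        assert (by_name["p0"].lower, by_name["p0"].upper) == (-10.0, 20.0)
        assert by_name["t1"].scale == "log10"
        assert (by_name["t1"].lower, by_name["t1"].upper) == (0.05, 50.0)
        assert (by_name["Asus"].lower, by_name["Asus"].upper) == (-20.0, 20.0)
        assert by_name["sigma"].scale == "log10"
        assert (by_name["sigma"].lower, by_name["sigma"].upper) == (0.01, 20.0)
        assert ("t11", "t2") in priors.constraints

    def test_envelope_contained(self):
        ds = self._dataset_0_10()
        priors = default_priors(ds, get_model("rtf"), trange=5.0)
        p0 = {e.name: e for e in priors.entries}["p0"]
        assert p0.lower <= ds.values.min() <= ds.values.max() <= p0.upper

    def test_constant_data_rejected(self):
        ds = _const_dataset([2.0, 2.0, 2.0], times=[0, 1, 2])
        with pytest.raises(ValueError, match="constant"):
            default_priors(ds, get_model("rtf"), trange=5.0)

    def test_tshift_excluded_by_default(self):
        priors = default_priors(self._dataset_0_10(), get_model("rtf"), trange=5.0)
        assert "Tshift" not in priors.names


class TestLogPosterior:
    def setup_method(self):
        self.ds = _const_dataset([1.0, 2.0], times=[0.0, 1.0])
        self.priors = PriorSpec([PriorEntry("p0", -5, 5, "lin")])
        self.model = get_model("rtf")

    def _lp(self, x):
        return log_posterior(
            np.array([x]), self.ds, self.priors, self.model,
            fixed=CONST_FIXED, sigma_value=1.0,
        )

    def test_in_bounds_equals_likelihood_plus_constant(self):
        ll = log_likelihood(self.ds, dict(CONST_FIXED, p0=1.0), 1.0, self.model)
        assert self._lp(1.0) == pytest.approx(ll, abs=1e-12)

    def test_out_of_bounds(self):
        assert self._lp(6.0) == -np.inf

    def test_posterior_ratio_is_likelihood_ratio(self):
        la = log_likelihood(self.ds, dict(CONST_FIXED, p0=1.0), 1.0, self.model)
        lb = log_likelihood(self.ds, dict(CONST_FIXED, p0=2.0), 1.0, self.model)
        assert self._lp(1.0) - self._lp(2.0) == pytest.approx(la - lb, abs=1e-12)

    def test_ordering_constraint_restricts_support(self):
        priors = PriorSpec(
            [PriorEntry("t11", 0.01, 10, "log10"), PriorEntry("t2", 0.01, 10, "log10")],
            constraints=[("t11", "t2")],
        )
        assert priors.contains(np.log10([0.1, 1.0]))
        assert not priors.contains(np.log10([1.0, 0.1]))


def _conjugate_setup(seed=0, n=50, sigma=0.5, mu=2.0):
    rng = np.random.default_rng(seed)
    times = np.repeat([0.0, 1.0], n // 2)
    values = mu + rng.normal(0, sigma, n)
    ds = TimeSeriesDataset("c", "o", times, np.arange(n).astype(str), values)
    priors = PriorSpec([PriorEntry("p0", -50, 50, "lin")])
    return ds, priors, values


class TestSamplePosterior:
    def test_conjugate_normal_recovery(self):
        # with everything but the baseline fixed the model is a constant, so
        # the posterior of p0 is N(sample mean, sigma^2/n) under a wide prior
        sigma = 0.5
        ds, priors, values = _conjugate_setup(sigma=sigma)
        cfg = RunConfig(seed=3, chain_length=8000, n_chains=2,
                        estimate_sigma=False, sigma_value=sigma)
        s = sample_posterior(ds, priors, get_model("rtf"), cfg, CONST_FIXED)
        draws = s.priors.to_linear(s.draws_sampling)[:, 0]
        ess = s.diagnostics["parameters"]["p0"]["ess"]
        assert ess >= 500
        mcse = draws.std() / math.sqrt(ess)
        assert abs(draws.mean() - values.mean()) < 3 * mcse
        assert abs(draws.std() - sigma / math.sqrt(len(values))) < 3 * mcse

    def test_deterministic_given_seed(self):
        ds, priors, _ = _conjugate_setup()
        cfg = RunConfig(seed=11, chain_length=500, n_chains=2,
                        estimate_sigma=False, sigma_value=0.5)
        a = sample_posterior(ds, priors, get_model("rtf"), cfg, CONST_FIXED)
        b = sample_posterior(ds, priors, get_model("rtf"), cfg, CONST_FIXED)
        np.testing.assert_array_equal(a.draws_sampling, b.draws_sampling)
        np.testing.assert_array_equal(a.log_posterior, b.log_posterior)

    def test_draws_within_prior_bounds(self):
        ds, priors, _ = _conjugate_setup()
        cfg = RunConfig(seed=11, chain_length=500, n_chains=1,
                        estimate_sigma=False, sigma_value=0.5)
        s = sample_posterior(ds, priors, get_model("rtf"), cfg, CONST_FIXED)
        assert np.all(s.draws_sampling >= priors.lo)
        assert np.all(s.draws_sampling <= priors.hi)
        assert np.all(np.isfinite(s.log_posterior))

    def test_initialization_failure(self):
        bad = ModelSpec(
            model_id="always_nan",
            parameter_names=("a",),
            evaluator=lambda g, p: np.full(len(np.atleast_1d(g)), np.nan),
        )
        ds = _const_dataset([1.0, 2.0])
        priors = PriorSpec([PriorEntry("a", 0, 1, "lin")])
        cfg = RunConfig(seed=1, chain_length=500, n_chains=1,
                        estimate_sigma=False, sigma_value=1.0)
        with pytest.raises(RuntimeError, match="initialize"):
            sample_posterior(ds, priors, bad, cfg, {})


class TestParallelTempering:
    def test_single_temperature_matches_plain_sampler(self):
        ds, priors, _ = _conjugate_setup()
        cfg = RunConfig(seed=11, chain_length=500, n_chains=1,
                        estimate_sigma=False, sigma_value=0.5,
                        temperature_ladder=[1.0])
        pt = parallel_tempering(ds, priors, get_model("rtf"), cfg, CONST_FIXED)
        plain = sample_posterior(ds, priors, get_model("rtf"), cfg, CONST_FIXED)
        np.testing.assert_array_equal(pt.draws_sampling, plain.draws_sampling)

    def test_ladder_validation(self):
        ds, priors, _ = _conjugate_setup()
        model = get_model("rtf")
        for ladder in ([2.0, 4.0], [1.0, 4.0, 2.0], []):
            cfg_kwargs = dict(seed=1, chain_length=500, n_chains=1,
                              estimate_sigma=False, sigma_value=0.5)
            cfg = RunConfig(**cfg_kwargs, temperature_ladder=ladder or None)
            with pytest.raises(ValueError):
                parallel_tempering(ds, priors, model, cfg, CONST_FIXED)

    def test_bimodal_target_mode_hopping(self):
        # posterior of A under a |A| observation model has symmetric modes at
        # +-3; a single cold chain cannot cross the barrier at 0 within the
        # budget, the tempered ladder can
        try:
            register_model(ModelSpec(
                model_id="absconst",
                parameter_names=("A",),
                evaluator=lambda g, p: np.full(len(np.atleast_1d(g)), abs(p["A"])),
            ))
        except ValueError:
            pass
        rng = np.random.default_rng(1)
        vals = 3.0 + rng.normal(0, 1.0, 20)
        ds = TimeSeriesDataset("c", "o", np.repeat([0.0, 1.0], 10),
                               np.arange(20).astype(str), vals)
        priors = PriorSpec([PriorEntry("A", -10, 10, "lin")])
        model = ModelSpec(
            model_id="absconst_local",
            parameter_names=("A",),
            evaluator=lambda g, p: np.full(len(np.atleast_1d(g)), abs(p["A"])),
        )
        base = dict(seed=5, chain_length=5000, n_chains=1,
                    estimate_sigma=False, sigma_value=1.0)
        am = sample_posterior(ds, priors, model, RunConfig(**base), {})
        am_draws = am.priors.to_linear(am.draws_sampling)[:, 0]
        pt = parallel_tempering(
            ds, priors, model,
            RunConfig(**base, temperature_ladder=[1.0, 3.0, 9.0, 27.0, 81.0]),
            {}, swap_interval=1,
        )
        pt_draws = pt.priors.to_linear(pt.draws_sampling)[:, 0]
        am_neg = (am_draws < 0).mean()
        pt_neg = (pt_draws < 0).mean()
        assert min(am_neg, 1 - am_neg) < 0.01  # stuck in one mode
        assert 0.2 < pt_neg < 0.8              # both modes visited
        assert "swap_rates" in pt.diagnostics


class TestDiagnostics:
    def test_ess_iid(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(10_000)
        ess = effective_sample_size(x)
        assert abs(ess - 10_000) / 10_000 < 0.2

    def test_ess_ar1(self):
        # AR(1) with phi=0.5 has integrated autocorrelation 3, so ESS ~ P/3
        rng = np.random.default_rng(8)
        n, phi = 100_000, 0.5
        eps = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        ess = effective_sample_size(x)
        assert abs(ess - n / 3) / (n / 3) < 0.25

    def test_ess_cross_check_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(9)
        n, phi = 20_000, 0.7
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        ours = effective_sample_size(x)
        theirs = float(az.ess(x[None, :]))
        assert abs(ours - theirs) / theirs < 0.2

    def test_ess_constant_chain(self):
        with pytest.warns(UserWarning, match="constant"):
            assert effective_sample_size(np.ones(500)) == 0.0

    def test_ess_short_chain_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.arange(50))

    def test_rhat_same_distribution(self):
        rng = np.random.default_rng(10)
        chains = [rng.standard_normal(2000) for _ in range(4)]
        assert gelman_rubin(chains) < 1.05

    def test_rhat_disjoint_chains(self):
        rng = np.random.default_rng(11)
        a = rng.standard_normal(2000)
        b = 10.0 + rng.standard_normal(2000)
        assert gelman_rubin([a, b]) > 1.1

    def test_rhat_duplicated_chain(self):
        rng = np.random.default_rng(12)
        a = rng.standard_normal(2000)
        assert gelman_rubin([a, a.copy()]) == pytest.approx(1.0, abs=0.01)

    def test_rhat_unequal_lengths_truncated(self, caplog):
        rng = np.random.default_rng(13)
        with caplog.at_level("INFO", logger="rtfbayes.inference"):
            val = gelman_rubin([rng.standard_normal(2000), rng.standard_normal(1500)])
        assert val < 1.1

    def test_rhat_needs_two_chains(self):
        with pytest.raises(ValueError):
            gelman_rubin([np.arange(200.0)])
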