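"""Tests for priors, likelihood, the MH sampler and convergence diagnostics."""

import math

import numpy as np
import pytest

from qsoc.calibrate import (
    MCMCConfig,
    ObservationSeries,
    ParameterSet,
    SiteDataset,
    gelman_rubin,
    interpolate_annual,
    log_likelihood,
    parameter_set_from_row,
    rmse,
    run_mcmc,
    summarize_posterior,
)
from qsoc.model import GenericKinetics, LocalParams, effective_beta, soc_stock
from qsoc.priors import build_priors


class TestInterpolateAnnual:
    def test_midpoint_of_a_line(self):
        years, vals = interpolate_annual(np.array([0.0, 10.0]), np.array([60.0, 50.0]))
        assert vals[list(years).index(5.0)] == pytest.approx(55.0)

    def test_inclusive_year_count_and_endpoints(self):
        years, vals = interpolate_annual(np.array([0.0, 10.0]), np.array([60.0, 50.0]))
        assert years.size == 11
        assert vals[0] == 60.0 and vals[-1] == 50.0

    def test_non_integer_endpoints_preserved(self):
        years, vals = interpolate_annual(
            np.array([0.5, 3.0]), np.array([10.0, 5.0])
        )
        assert years[0] == 0.5 and vals[0] == 10.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            interpolate_annual(np.array([0.0]), np.array([60.0]))


class TestPriors:
    def test_truncation_bounds(self):
        priors = build_priors()
        assert priors["eta11"].logpdf(0.8) == -math.inf  # above 2 x 0.36
        assert priors["q0"].logpdf(0.4) == -math.inf  # below the 0.5 cut
        assert priors["u0"].logpdf(0.99) == -math.inf
        assert priors["beta0"].logpdf(0.4) == -math.inf

    def test_e0_mode_at_centre(self):
        e0 = build_priors()["e0"]
        assert e0.logpdf(0.3) > e0.logpdf(0.25)
        assert e0.logpdf(0.3) > e0.logpdf(0.35)

    def test_densities_normalised(self):
        """Numerical integral of each prior density over its bounds is 1."""
        for spec in build_priors().values():
            x = np.linspace(spec.lower + 1e-9, spec.upper - 1e-9, 20001)
            dens = np.exp([spec.logpdf(v) for v in x])
            assert np.trapezoid(dens, x) == pytest.approx(1.0, abs=1e-3)

    def test_samples_respect_bounds(self):
        rng = np.random.default_rng(0)
        for spec in build_priors().values():
            s = spec.sample(rng, size=500)
            assert np.all((s >= spec.lower) & (s <= spec.upper))

    def test_override(self):
        priors = build_priors(
            {"u0": {"family": "uniform", "loc": 0.1, "scale": 0.0, "lower": 0.0, "upper": 0.2}}
        )
        assert priors["u0"].upper == 0.2


def _make_site(noise=0.0, sd=2.0, with_pf=False):
    gk = GenericKinetics(u0=0.05, eta11=0.36)
    lp = LocalParams(q0=1.08, e0=0.3, beta0=0.7)
    clay, css, re = 17.0, 65.5, 1.0
    t = np.arange(0.0, 21.0)
    beta = effective_beta(lp.beta0, clay)
    soc = soc_stock(t, css, lp.q0, beta, gk.eta11, gk.u0, lp.e0, re) + noise
    series = ObservationSeries(times=t, soc=soc, sd=sd)
    site = SiteDataset("s1", clay, css, re, series)
    params = ParameterSet(generic=gk, locals={"s1": lp})
    return params, site


class TestLogLikelihood:
    def test_perfect_fit_attains_maximum(self):
        params, site = _make_site()
        n = 21
        expected = -n * math.log(2.0 * math.sqrt(2.0 * math.pi))
        assert log_likelihood(params, [site]) == pytest.approx(expected)

    def test_offset_strictly_decreases(self):
        params, site = _make_site()
        best = log_likelihood(params, [site])
        worse = log_likelihood(params, [_make_site(noise=1.0)[1]])
        assert worse < best

    def test_doubling_sigma_closed_form(self):
        """ll(2s) - ll(s) = -n log 2 + (3/8) sum r^2 / s^2 (Gaussian algebra)."""
        params, site = _make_site(noise=1.5, sd=2.0)
        wide = SiteDataset(
            site.site_id,
            site.clay_percent,
            site.css,
            site.re,
            ObservationSeries(
                times=site.observations.times, soc=site.observations.soc, sd=4.0
            ),
        )
        ll1 = log_likelihood(params, [site])
        ll2 = log_likelihood(params, [wide])
        n = 21
        sum_r2 = n * 1.5**2
        assert ll2 - ll1 == pytest.approx(-n * math.log(2) + 3 / 8 * sum_r2 / 4.0)

    def test_invalid_parameters_give_minus_inf(self):
        params, site = _make_site()
        bad = ParameterSet(
            generic=params.generic,
            locals={"s1": LocalParams(q0=1.08, e0=0.95, beta0=0.7)},
        )
        assert log_likelihood(bad, [site]) == -math.inf


class TestRmse:
    def test_perfect_fit_zero(self):
        params, site = _make_site()
        assert rmse(params, site) == pytest.approx(0.0, abs=1e-10)

    def test_constant_residual(self):
        params, site = _make_site(noise=2.5)
        assert rmse(params, site) == pytest.approx(2.5)

    def test_hand_value(self):
        # residuals {3, 4} -> sqrt((9+16)/2)
        assert math.sqrt((9 + 16) / 2) == pytest.approx(3.5355339)


class TestSampler:
    def test_determinism_and_length(self, network4):
        _, datasets, _ = network4
        cfg = MCMCConfig(n_chains=2, n_iter=400, burn_in=100, seed=42)
        a = run_mcmc(datasets[:2], cfg)
        b = run_mcmc(datasets[:2], cfg)
        for ca, cb in zip(a, b):
            assert len(ca) == 400
            np.testing.assert_array_equal(ca.draws, cb.draws)
            np.testing.assert_array_equal(ca.rmse, cb.rmse)

    def test_draws_respect_bounds_and_validity(self, quick_chains, network4):
        """Retained samples never violate truncation bounds or the model
        validity rules at any site."""
        _, datasets, _ = network4
        priors = build_priors()
        for chain in quick_chains:
            for name in chain.param_names:
                key = name.split("[")[0]
                col = chain.parameter(name, post_burn=False)
                assert np.all(col >= priors[key].lower)
                assert np.all(col <= priors[key].upper)
            for ds in datasets:
                q0 = chain.parameter(f"q0[{ds.site_id}]", post_burn=False)
                e0 = chain.parameter(f"e0[{ds.site_id}]", post_burn=False)
                beta0 = chain.parameter(f"beta0[{ds.site_id}]", post_burn=False)
                eta11 = chain.parameter("eta11", post_burn=False)
                beta = beta0 + 0.01 * ds.clay_percent
                assert np.all((1 - e0) / (eta11 * e0) - beta > 0)
                assert np.all(1 - e0 - eta11 * e0 * beta > 0)

    def test_rmse_recorded_nonnegative(self, quick_chains):
        for chain in quick_chains:
            assert np.all(chain.rmse >= 0)

    def test_requires_observations(self, network4):
        _, datasets, _ = network4
        ds = datasets[0]
        single = SiteDataset(
            ds.site_id,
            ds.clay_percent,
            ds.css,
            ds.re,
            ObservationSeries(
                times=np.array([0.0, 1.0]), soc=np.array([60.0, 59.0]), sd=1.0
            ),
        )
        with pytest.raises(ValueError):
            run_mcmc([], MCMCConfig(n_chains=1, n_iter=10, burn_in=0))

    def test_parameter_set_roundtrip(self, quick_chains):
        chain = quick_chains[0]
        row = dict(zip(chain.param_names, chain.draws[-1]))
        ps = parameter_set_from_row(row, chain.site_ids)
        assert ps.generic.u0 == row["u0"]
        assert ps.locals[chain.site_ids[0]].q0 == row[f"q0[{chain.site_ids[0]}]"]


class TestGelmanRubin:
    def _chain(self, draws):
        from qsoc.calibrate import PosteriorChain

        draws = np.asarray(draws, dtype=float)[:, None]
        return PosteriorChain(
            chain_id=0,
            param_names=("x",),
            site_ids=(),
            draws=draws,
            log_post=np.zeros(len(draws)),
            rmse=np.zeros((len(draws), 0)),
            burn_in=0,
        )

    def test_exact_copies_give_one(self):
        x = np.sin(np.arange(200.0))
        chains = [self._chain(x), self._chain(x)]
        assert gelman_rubin(chains, "x") == pytest.approx(1.0, abs=5e-3)

    def test_gross_nonmixing_detected(self):
        rng = np.random.default_rng(0)
        chains = [
            self._chain(rng.normal(0.0, 1.0, 200)),
            self._chain(rng.normal(100.0, 1.0, 200)),
        ]
        assert gelman_rubin(chains, "x") > 10.0

    def test_hand_formula_small_dataset(self):
        """Direct evaluation of Vhat = (n-1)/n W + B/n on 2 chains x 10."""
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        b = a + 0.5
        w = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
        b_over_n = np.var([a.mean(), b.mean()], ddof=1)
        expected = math.sqrt(((len(a) - 1) / len(a) * w + b_over_n) / w)
        got = gelman_rubin([self._chain(a), self._chain(b)], "x")
        assert got == pytest.approx(expected, rel=1e-12)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin([self._chain(np.arange(20.0))], "x")

    def test_agrees_with_arviz_on_mixed_chains(self):
        """Independent cross-check against arviz's rank-normalised R-hat on
        well-mixed chains, where both estimators sit near 1."""
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(1)
        data = rng.normal(size=(4, 500))
        ours = gelman_rubin([self._chain(row) for row in data], "x")
        theirs = float(arviz.rhat(data))
        assert ours == pytest.approx(theirs, abs=0.05)


def test_summary_contains_all_parameters(quick_chains):
    summary = summarize_posterior(quick_chains)
    assert {"u0", "eta11"} <= set(summary.index)
    assert (summary["ci_lower"] <= summary["median"]).all()
    assert (summary["median"] <= summary["ci_upper"]).all()
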