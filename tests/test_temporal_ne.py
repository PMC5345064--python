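"""Temporal Ne machinery: drift model, pseudo-likelihood, MCMC, summaries."""

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import dirichlet_multinomial, kstest

from popdrift import (
    MCMCSettings,
    NePosterior,
    bayes_factor,
    classify_bayes_factor,
    drift_accumulation,
    gelman_rubin,
    hpd,
    posterior_summary,
    prepare_temporal_counts,
    rate_of_change,
    run_mcmc,
    temporal_log_likelihood,
)
from popdrift.temporal_ne import (
    TemporalCounts,
    _dirmult_logpmf,
    make_log_likelihood,
)

from conftest import make_random_dataset


def toy_counts(seed=0, n_times=3, n_loci=2, k=3, n_genes=60):
    rng = np.random.default_rng(seed)
    counts = [rng.multinomial(n_genes, rng.dirichlet(np.ones(k)), size=n_times)
              for _ in range(n_loci)]
    return TemporalCounts(site="toy", sample_gens=np.arange(n_times),
                          counts=[c.astype(np.int64) for c in counts],
                          locus_names=[f"L{j}" for j in range(n_loci)])


class TestDriftAccumulation:
    def test_zero_generations(self):
        assert drift_accumulation(500, 500, 3, [0])[0] == 0.0

    def test_constant_ne_closed_form(self):
        f = drift_accumulation(500, 500, 3)[3]
        assert f == pytest.approx(1 - (1 - 1 / 1000) ** 3, rel=1e-12)

    def test_swap_invariance_over_full_span(self):
        """The exponential trajectory a->b visits the same Ne values as
        b->a in reverse, so total drift is direction-free."""
        for a, b, t in [(500, 50, 4), (20, 2000, 6), (77, 77, 3)]:
            fab = drift_accumulation(a, b, t)[t]
            fba = drift_accumulation(b, a, t)[t]
            assert fab == pytest.approx(fba, rel=1e-10)

    def test_monotone_in_time(self):
        f = drift_accumulation(300, 30, 5)
        assert np.all(np.diff(f) > 0)


class TestLikelihood:
    def test_closure_matches_reference(self):
        data = toy_counts(seed=3)
        f = make_log_likelihood(data)
        for nb, na in [(500.0, 500.0), (100.0, 10.0), (4000.0, 60.0),
                       (5.0, 4800.0)]:
            assert f(nb, na) == pytest.approx(
                temporal_log_likelihood(data, nb, na), rel=1e-10)

    def test_additive_over_loci(self):
        data = toy_counts(seed=5, n_loci=2)
        one = TemporalCounts("toy", data.sample_gens, [data.counts[0]], ["L0"])
        two = TemporalCounts("toy", data.sample_gens, [data.counts[1]], ["L1"])
        total = temporal_log_likelihood(data, 200.0, 40.0)
        assert total == pytest.approx(
            temporal_log_likelihood(one, 200.0, 40.0)
            + temporal_log_likelihood(two, 200.0, 40.0), rel=1e-12)

    def test_identical_samples_prefer_large_ne(self):
        """No observed frequency change: likelihood rises along the
        N_before = N_after ray (less drift fits better)."""
        y = np.array([[30, 20, 10]] * 3)
        data = TemporalCounts("toy", np.arange(3), [y], ["L0"])
        vals = [temporal_log_likelihood(data, n, n)
                for n in (10.0, 100.0, 1000.0, 5000.0)]
        assert np.all(np.diff(vals) > 0)

    def test_dirmult_term_matches_scipy(self):
        y = np.array([3, 1, 0])
        alpha = np.array([2.0, 1.5, 0.5])
        assert _dirmult_logpmf(y, alpha) == pytest.approx(
            float(dirichlet_multinomial.logpmf(y, alpha, int(y.sum()))),
            rel=1e-12)

    def test_dirmult_term_matches_brute_force_integration(self):
        """2-allele toy, n=4 genes: Monte-Carlo integration of the
        multinomial over Dirichlet-distributed drifted frequencies."""
        rng = np.random.default_rng(7)
        y = np.array([3, 1])
        alpha = np.array([1.8, 1.2])
        q = rng.dirichlet(alpha, size=100_000)
        vals = np.exp(gammaln(5) - gammaln(y + 1).sum()
                      + (y * np.log(q)).sum(axis=1))
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - np.exp(_dirmult_logpmf(y, alpha))) < 3 * se


class TestPrepareTemporalCounts:
    def test_same_generation_years_are_pooled(self):
        ds = make_random_dataset(
            {("s", 2005): 5, ("s", 2012): 4, ("s", 2013): 6}, n_loci=2, seed=1)
        data = prepare_temporal_counts(ds, "s", generation_time=3,
                                       anchor_year=2015)
        # 2012 and 2013 both fall 1 generation before the 2015 anchor
        assert list(data.sample_gens) == [0, 2]
        assert data.counts[0][1].sum() == 2 * (4 + 6)

    def test_endpoints_only(self):
        ds = make_random_dataset(
            {("s", 2005): 5, ("s", 2010): 5, ("s", 2015): 5}, n_loci=1, seed=2)
        data = prepare_temporal_counts(ds, "s", endpoints_only=True)
        assert data.counts[0].shape[0] == 2

    def test_single_generation_rejected(self):
        ds = make_random_dataset({("s", 2014): 5, ("s", 2015): 5}, seed=3)
        with pytest.raises(ValueError, match="2 sampling times"):
            prepare_temporal_counts(ds, "s", generation_time=3)


class TestRunMCMC:
    def test_fixed_seed_reproducible(self):
        data = toy_counts(seed=11)
        s = MCMCSettings(iterations=2000, n_runs=2, thinning=10, seed=21)
        a = run_mcmc(data, s)
        b = run_mcmc(data, s)
        assert np.array_equal(a.draws, b.draws)
        assert a.draws.shape == (2, 100, 2)

    def test_draws_respect_prior_box(self):
        data = toy_counts(seed=13)
        s = MCMCSettings(iterations=4000, n_runs=2, thinning=10, seed=22)
        post = run_mcmc(data, s)
        assert post.draws.min() >= 2.0 and post.draws.max() <= 5000.0

    def test_prior_only_run_recovers_log_uniform(self):
        """Likelihood == 0: the marginal of ln Ne must be uniform."""
        s = MCMCSettings(iterations=240_000, n_runs=2, thinning=300, seed=23)
        post = run_mcmc(None, s, log_likelihood=lambda nb, na: 0.0)
        ln = np.log(post.combined()).ravel()
        lo, hi = np.log(2.0), np.log(5000.0)
        assert kstest((ln - lo) / (hi - lo), "uniform").pvalue > 0.01


def symmetric_posterior(seed=0, n=4000):
    rng = np.random.default_rng(seed)
    a = rng.lognormal(4, 1, size=(1, n))
    draws = np.stack([np.concatenate([a, a], axis=1),
                      np.concatenate([a, a], axis=1)[:, ::-1]], axis=2)
    # exact mirror: every (x, y) has a twin (y, x)
    return NePosterior(draws=draws, acceptance_rates=[0.5],
                       settings=MCMCSettings(iterations=100, n_runs=1))


class TestBayesFactor:
    def test_symmetric_draws_give_bf_one(self):
        v = bayes_factor(symmetric_posterior())
        assert v.bayes_factor == pytest.approx(1.0)
        assert v.category == "none"

    def test_swap_inverts_bf_and_mirrors_category(self):
        # 120 draws with decline, 10 with growth: BF = 12 ("strong");
        # swapping every draw must give BF = 1/12 ("false_detection")
        nb = np.concatenate([np.full(120, 300.0), np.full(10, 30.0)])
        na = np.concatenate([np.full(120, 30.0), np.full(10, 300.0)])
        draws = np.stack([nb, na], axis=1)[None, :, :]
        post = NePosterior(draws=draws, acceptance_rates=[0.5],
                           settings=MCMCSettings(iterations=100, n_runs=1))
        swapped = NePosterior(draws=draws[:, :, ::-1],
                              acceptance_rates=[0.5],
                              settings=post.settings)
        v, w = bayes_factor(post), bayes_factor(swapped)
        assert v.bayes_factor == pytest.approx(12.0)
        assert w.bayes_factor == pytest.approx(1.0 / v.bayes_factor)
        assert (v.category, w.category) == ("strong", "false_detection")

    def test_zero_denominator_is_strong_support(self):
        draws = np.stack([np.full((1, 50), 100.0), np.full((1, 50), 10.0)],
                         axis=2)
        v = bayes_factor(NePosterior(draws=draws, acceptance_rates=[0.5],
                                     settings=MCMCSettings(iterations=100,
                                                           n_runs=1)))
        assert np.isinf(v.bayes_factor) and v.category == "strong"


class TestJeffreysClassification:
    @pytest.mark.parametrize("bf, cat", [
        (128.9, "strong"), (3.3, "substantial"), (2.4, "none"), (1.0, "none"),
        (0.4, "none"), (0.2, "false_detection"),
    ])
    def test_thresholds(self, bf, cat):
        assert classify_bayes_factor(bf) == cat


class TestHPD:
    def test_uniform_width(self):
        rng = np.random.default_rng(8)
        draws = rng.uniform(2, 3, size=(1, 30000, 2))
        post = NePosterior(draws=draws, acceptance_rates=[0.5],
                           settings=MCMCSettings(iterations=100, n_runs=1))
        lo, hi = hpd(post, (0.9,))[0.9]["n_before"]
        assert (hi - lo) == pytest.approx(0.9, abs=0.02)

    def test_point_mass(self):
        draws = np.full((1, 100, 2), 42.0)
        post = NePosterior(draws=draws, acceptance_rates=[0.5],
                           settings=MCMCSettings(iterations=100, n_runs=1))
        lo, hi = hpd(post, (0.5,))[0.5]["n_after"]
        assert lo == hi == 42.0

    def test_nesting_across_levels(self):
        rng = np.random.default_rng(9)
        draws = rng.lognormal(3, 0.7, size=(2, 2000, 2))
        post = NePosterior(draws=draws, acceptance_rates=[0.5, 0.5],
                           settings=MCMCSettings(iterations=100, n_runs=2))
        levels = hpd(post, (0.1, 0.5, 0.9))
        for p in ("n_before", "n_after"):
            for small, big in [(0.1, 0.5), (0.5, 0.9)]:
                assert levels[big][p][0] <= levels[small][p][0]
                assert levels[big][p][1] >= levels[small][p][1]


class TestGelmanRubin:
    def test_copied_chains_converge(self):
        rng = np.random.default_rng(10)
        chain = rng.normal(size=(1, 400))
        copies = np.repeat(chain, 4, axis=0)[:, :, None]
        r = gelman_rubin(copies)["param_0"]
        assert abs(r - 1.0) <= 1.0 / 400  # classical PSRF: sqrt((n-1)/n)

    def test_disjoint_chains_flagged(self):
        a = np.linspace(0, 1, 200)
        chains = np.stack([a, a + 10])[:, :, None]
        assert gelman_rubin(chains)["param_0"] > 1.1

    def test_matches_arviz_identity(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(12)
        chains = rng.normal(size=(3, 400)) + np.array([[0.0], [0.2], [0.1]])
        mine = gelman_rubin(chains[:, :, None])["param_0"]
        ref = float(az.rhat(az.convert_to_dataset(chains),
                            method="identity")["x"])
        assert mine == pytest.approx(ref, abs=1e-6)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100, 2)))


class TestPointEstimates:
    @pytest.mark.parametrize("pre, post, expected", [
        (75.4, 29.9, -60.3), (25.4, 28.9, 13.8), (137.4, 16.9, -87.7),
        (100.0, 100.0, 0.0),
    ])
    def test_rate_of_change(self, pre, post, expected):
        assert rate_of_change(pre, post) == expected

    def test_posterior_summary_orders_estimators(self):
        rng = np.random.default_rng(14)
        draws = rng.lognormal(np.log(100), 0.3, size=(1, 4000, 2))
        post = NePosterior(draws=draws, acceptance_rates=[0.4],
                           settings=MCMCSettings(iterations=100, n_runs=1))
        s = posterior_summary(post)
        for p in ("n_before", "n_after"):
            assert 60 < s[p]["mode"] < 170
            assert s[p]["median"] < s[p]["mean"]  # lognormal skew
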