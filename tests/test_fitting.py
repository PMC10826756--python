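"""Threshold selection, MLE, KS distance and the GoF bootstrap."""

import numpy as np
import pytest
from scipy import special

from outbreaklaw import (
    DegenerateDataError,
    DiscreteExponential,
    PowerLaw,
    compare_families,
    fit_alpha,
    gof_bootstrap,
    ks_distance,
    select_xmin,
)
from outbreaklaw.fitting import fit_exponential, fit_lognormal
from outbreaklaw.io import SizeFrequencyTable


def grid_search_alpha(hist, xmin, grid=np.arange(1.01, 6.0, 0.0005)):
    """Independent likelihood oracle: dense grid over the exponent."""
    m = hist.sizes >= xmin
    counts, sizes = hist.counts[m], hist.sizes[m]
    n = counts.sum()
    slog = float(np.dot(counts, np.log(sizes)))
    ll = -grid * slog - n * np.log(special.zeta(grid, xmin))
    return float(grid[np.argmax(ll)])


def exhaustive_ks(hist, model):
    """Independent KS oracle: loop every integer, CDFs built by summation."""
    sizes = hist.sizes[hist.sizes >= model.xmin]
    counts = hist.counts[hist.sizes >= model.xmin]
    n = counts.sum()
    lookup = dict(zip(sizes.tolist(), counts.tolist()))
    best, cum_obs, cum_mod = 0.0, 0, 0.0
    for x in range(model.xmin, int(sizes[-1]) + 1):
        cum_obs += lookup.get(x, 0)
        cum_mod += float(model.pmf(x))
        best = max(best, abs(cum_obs / n - cum_mod))
    return best


class TestFitAlpha:
    def test_matches_grid_oracle(self, pl_hist):
        a_hat, _ = fit_alpha(pl_hist, 1)
        assert abs(a_hat - grid_search_alpha(pl_hist, 1)) <= 0.0005

    def test_matches_grid_oracle_above_threshold(self, pl_hist):
        a_hat, _ = fit_alpha(pl_hist, 4)
        assert abs(a_hat - grid_search_alpha(pl_hist, 4)) <= 0.0005

    def test_loglik_is_maximal(self, pl_hist):
        a_hat, ll = fit_alpha(pl_hist, 1)
        for delta in (-0.05, 0.05):
            m = pl_hist.sizes >= 1
            n = pl_hist.counts[m].sum()
            slog = float(np.dot(pl_hist.counts[m], np.log(pl_hist.sizes[m])))
            other = -(a_hat + delta) * slog - n * np.log(special.zeta(a_hat + delta, 1))
            assert ll >= other

    def test_single_size_degenerate(self):
        h = SizeFrequencyTable(np.array([5]), np.array([100]), (2000, 2000))
        with pytest.raises(DegenerateDataError):
            fit_alpha(h, 5)


class TestKsDistance:
    def test_zero_for_exact_match(self):
        # histogram exactly proportional to the truncated model pmf
        model = DiscreteExponential(0.8, 1)
        xs = np.arange(1, 8)
        p = model.pmf(xs)
        p = p / p.sum()
        counts = np.round(p * 10_000_000).astype(int)
        h = SizeFrequencyTable(xs, counts, (2000, 2000))

        class Truncated:
            xmin = 1

            def pmf(self, x):
                return p[np.asarray(x) - 1]

        assert ks_distance(h, Truncated()) == pytest.approx(0.0, abs=1e-4)

    def test_matches_exhaustive_oracle_small(self, tiny_hist):
        model = PowerLaw(2.0, 1)
        assert ks_distance(tiny_hist, model) == pytest.approx(
            exhaustive_ks(tiny_hist, model), abs=1e-12
        )

    def test_matches_exhaustive_oracle_large(self, pl_hist):
        model = PowerLaw(2.15, 1)
        assert ks_distance(pl_hist, model) == pytest.approx(
            exhaustive_ks(pl_hist, model), abs=1e-10
        )
        model4 = PowerLaw(2.3, 4)
        assert ks_distance(pl_hist, model4) == pytest.approx(
            exhaustive_ks(pl_hist, model4), abs=1e-10
        )


class TestSelectXmin:
    def test_uncensored_sample_selects_small_threshold(self):
        # without censoring the whole range is power law, so xmin stays small
        hits = 0
        for rep in range(10):
            s = PowerLaw(2.5, 1).sample(10_000, np.random.default_rng(100 + rep))
            fit = select_xmin(SizeFrequencyTable.from_sizes(s, (2000, 2000)))
            hits += fit.xmin <= 3
        assert hits >= 8

    def test_scale_invariance_of_counts(self, pl_hist):
        fit1 = select_xmin(pl_hist)
        h2 = SizeFrequencyTable(pl_hist.sizes, pl_hist.counts * 7, pl_hist.period)
        fit2 = select_xmin(h2)
        assert fit2.xmin == fit1.xmin
        assert fit2.model.alpha == pytest.approx(fit1.model.alpha, abs=1e-9)
        assert fit2.ks_distance == pytest.approx(fit1.ks_distance, abs=1e-12)

    def test_censoring_pushes_threshold_up(self, pl_sample_sizes):
        # deleting most small outbreaks forces the selected threshold upward
        rng = np.random.default_rng(3)
        keep = rng.uniform(size=pl_sample_sizes.size) < np.minimum(
            1.0, 0.1 + 0.9 * (pl_sample_sizes - 1) / 9
        )
        censored = SizeFrequencyTable.from_sizes(pl_sample_sizes[keep], (2000, 2000))
        full = SizeFrequencyTable.from_sizes(pl_sample_sizes, (2000, 2000))
        assert select_xmin(censored).xmin > select_xmin(full).xmin

    def test_degenerate_data(self):
        h = SizeFrequencyTable(np.array([3]), np.array([50]), (2000, 2000))
        with pytest.raises(DegenerateDataError):
            select_xmin(h)

    def test_n_tail_bounded_by_total(self, pl_hist):
        fit = select_xmin(pl_hist)
        assert 0 < fit.n_tail <= pl_hist.total


class TestGofBootstrap:
    def test_p_one_when_observed_d_zero(self, pl_hist):
        from outbreaklaw.fitting import TailFit

        fit0 = select_xmin(pl_hist)
        fake = TailFit(model=fit0.model, n_tail=fit0.n_tail,
                       ks_distance=0.0, log_likelihood=fit0.log_likelihood)
        g = gof_bootstrap(pl_hist, fake, n_boot=19, seed=5)
        assert g.p_value == 1.0

    def test_p_monotone_in_observed_d(self, pl_hist):
        from outbreaklaw.fitting import TailFit

        fit = select_xmin(pl_hist)
        g = gof_bootstrap(pl_hist, fit, n_boot=49, seed=5)
        d_star = g.replicate_d
        # recompute p for increasing observed D with replicates held fixed
        ps = [np.mean(d_star >= d) for d in np.linspace(0, d_star.max() * 1.1, 20)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_seed_reproducibility(self, pl_hist):
        fit = select_xmin(pl_hist)
        g1 = gof_bootstrap(pl_hist, fit, n_boot=19, seed=12)
        g2 = gof_bootstrap(pl_hist, fit, n_boot=19, seed=12)
        assert g1.p_value == g2.p_value
        assert np.array_equal(g1.replicate_d, g2.replicate_d)

    def test_smoothed_estimator_option(self, pl_hist):
        fit = select_xmin(pl_hist)
        g = gof_bootstrap(pl_hist, fit, n_boot=19, seed=12, smoothed=True)
        r = int(np.sum(g.replicate_d >= fit.ks_distance))
        assert g.p_value == pytest.approx((r + 1) / (g.replicate_d.size + 1))


class TestCompareFamilies:
    def test_single_family_subset(self, pl_hist):
        cmp = compare_families(pl_hist, families=("power_law",))
        assert set(cmp.fits) == {"power_law"}

    def test_exponential_fits_exponential_data(self):
        # geometric data: the exponential family's own GoF does not reject
        # it at the 0.05 level in at least 90% of simulation replicates
        not_rejected = 0
        for rep in range(50):
            rng = np.random.default_rng(200 + rep)
            s = DiscreteExponential(0.25, 1).sample(800, rng)
            h = SizeFrequencyTable.from_sizes(s, (2000, 2000))
            fit = select_xmin(h, "exponential")
            g = gof_bootstrap(h, fit, n_boot=49, seed=rep)
            not_rejected += g.p_value >= 0.05
        assert not_rejected >= 45

    def test_errors_do_not_abort_other_families(self, tiny_hist):
        cmp = compare_families(tiny_hist, min_distinct_tail=2)
        # all three families fit this tiny but valid histogram
        assert set(cmp.fits) | set(cmp.errors) == {"power_law", "lognormal", "exponential"}

    def test_closed_form_exponential_mle(self, pl_hist):
        model, ll = fit_exponential(pl_hist, 1)
        # analytic MLE: q = m/(1+m) with m the mean excess over xmin
        m = np.dot(pl_hist.counts, pl_hist.sizes - 1) / pl_hist.total
        assert np.exp(-model.lam) == pytest.approx(m / (1 + m), rel=1e-12)

    def test_lognormal_mle_beats_moment_start(self, pl_hist):
        model, ll = fit_lognormal(pl_hist, 1)
        logs = np.log(pl_hist.sizes.astype(float))
        mu0 = float(np.dot(pl_hist.counts, logs)) / pl_hist.total
        sd0 = float(np.sqrt(np.dot(pl_hist.counts, (logs - mu0) ** 2) / pl_hist.total))
        from outbreaklaw import DiscreteLogNormal

        start = DiscreteLogNormal(mu0, sd0, 1)
        ll_start = float(np.dot(pl_hist.counts, start.logpmf(pl_hist.sizes)))
        assert ll >= ll_start - 1e-6
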