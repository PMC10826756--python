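"""Expected-line extrapolation and deficit estimates."""

import math

import numpy as np
import pytest

from outbreaklaw import (
    DivergentTailError,
    OutbreakLawError,
    PowerLaw,
    estimate_deficits,
    expected_line,
    hurwitz_zeta,
    select_xmin,
)
from outbreaklaw.deficit import observed_expected_table
from outbreaklaw.fitting import TailFit
from outbreaklaw.io import SizeFrequencyTable


def make_fit(alpha, xmin, n_tail, hist):
    model = PowerLaw(alpha, xmin)
    return TailFit(model=model, n_tail=n_tail, ks_distance=0.0, log_likelihood=0.0)


@pytest.fixture
def simple_hist():
    # observed counts at sizes 1..12 plus two large outbreaks
    sizes = np.arange(1, 13)
    counts = np.array([30, 15, 7, 5, 3, 3, 2, 2, 1, 1, 1, 1])
    sizes = np.append(sizes, [150, 400])
    counts = np.append(counts, [1, 1])
    return SizeFrequencyTable(sizes, counts, (2001, 2004))


class TestExpectedLine:
    def test_anchor_value(self, simple_hist):
        fit = make_fit(2.0, 1, 100, simple_hist)
        line = expected_line(fit, simple_hist)
        assert line.expected(1) == pytest.approx(100 / (math.pi**2 / 6), rel=1e-12)

    def test_tail_total_is_n_tail(self, simple_hist):
        fit = make_fit(2.3, 3, 57, simple_hist)
        line = expected_line(fit, simple_hist)
        assert line.expected_count_at_least(3) == pytest.approx(57, rel=1e-9)

    def test_pure_power_ratio(self, simple_hist):
        fit = make_fit(2.15, 1, 100, simple_hist)
        line = expected_line(fit, simple_hist)
        for x in (1, 5, 17, 60):
            assert line.expected(2 * x) / line.expected(x) == pytest.approx(
                2**-2.15, rel=1e-12
            )

    def test_rejects_non_power_law(self, simple_hist):
        from outbreaklaw import DiscreteExponential

        fit = TailFit(model=DiscreteExponential(0.5, 1), n_tail=10,
                      ks_distance=0.0, log_likelihood=0.0)
        with pytest.raises(OutbreakLawError):
            expected_line(fit, simple_hist)

    def test_divergent_case_tail_requires_cap(self, simple_hist):
        fit = make_fit(1.9, 1, 100, simple_hist)
        line = expected_line(fit, simple_hist)
        with pytest.raises(DivergentTailError):
            line.expected_cases_at_least(100, cap=None)
        capped = line.expected_cases_at_least(100, cap=50_000)
        assert capped > 0


class TestDeficits:
    def test_hand_computed_small_stratum(self, simple_hist):
        # spreadsheet-style oracle: sum over x=1..9 of (C x^-2 - n(x))
        fit = make_fit(2.0, 1, 100, simple_hist)
        line = expected_line(fit, simple_hist)
        C = 100 / hurwitz_zeta(2.0, 1)
        obs = {1: 30, 2: 15, 3: 7, 4: 5, 5: 3, 6: 3, 7: 2, 8: 2, 9: 1}
        manual_out = sum(C * x**-2.0 - obs[x] for x in range(1, 10))
        manual_ill = sum(x * (C * x**-2.0 - obs[x]) for x in range(1, 10))
        d = estimate_deficits(line, simple_hist)
        assert d.small_outbreak_deficit_total == pytest.approx(manual_out, rel=1e-12)
        assert d.small_illness_deficit_total == pytest.approx(manual_ill, rel=1e-12)

    def test_large_stratum_closed_form(self, simple_hist):
        fit = make_fit(2.5, 1, 100, simple_hist)
        line = expected_line(fit, simple_hist)
        d = estimate_deficits(line, simple_hist)
        C = 100 / hurwitz_zeta(2.5, 1)
        assert d.large_outbreak_deficit_total == pytest.approx(
            C * hurwitz_zeta(2.5, 100) - 2, rel=1e-9
        )
        assert d.large_illness_deficit_total == pytest.approx(
            C * hurwitz_zeta(1.5, 100) - 550, rel=1e-9
        )

    def test_observed_points_only_variant(self, simple_hist):
        fit = make_fit(2.5, 1, 100, simple_hist)
        line = expected_line(fit, simple_hist)
        d = estimate_deficits(line, simple_hist, large_closed_form=False)
        expected = float(line.expected(150) + line.expected(400)) - 2
        assert d.large_outbreak_deficit_total == pytest.approx(expected, rel=1e-12)

    def test_self_difference_is_near_zero(self):
        # observed small-stratum counts set to the rounded expected line:
        # the small deficit reduces to rounding error (< 0.5 per size)
        fit = make_fit(2.15, 1, 10_000, None)
        C = 10_000 / hurwitz_zeta(2.15, 1)
        xs = np.arange(1, 50)
        counts = np.round(C * xs**-2.15).astype(int)
        keep = counts > 0
        hist = SizeFrequencyTable(xs[keep], counts[keep], (2000, 2000))
        d = estimate_deficits(expected_line(fit, hist), hist)
        assert abs(d.small_outbreak_deficit_total) < 5

    def test_censoring_small_sizes_increases_small_deficit(self, simple_hist):
        fit = make_fit(2.0, 10, 4, simple_hist)
        line = expected_line(fit, simple_hist)
        base = estimate_deficits(line, simple_hist).small_outbreak_deficit_total
        counts = simple_hist.counts.copy()
        counts[simple_hist.sizes < 10] -= 1  # delete one outbreak at each small size
        censored = SizeFrequencyTable(simple_hist.sizes, counts, simple_hist.period)
        worse = estimate_deficits(line, censored).small_outbreak_deficit_total
        assert worse > base

    def test_annualization_linearity(self, simple_hist):
        fit = make_fit(2.0, 1, 100, simple_hist)
        line = expected_line(fit, simple_hist)
        d1 = estimate_deficits(line, simple_hist)
        doubled = SizeFrequencyTable(
            simple_hist.sizes, simple_hist.counts, (2001, 2008)
        )
        d2 = estimate_deficits(line, doubled)
        assert d2.small_outbreak_deficit_annual == pytest.approx(
            d1.small_outbreak_deficit_annual / 2, rel=1e-12
        )
        assert d2.large_illness_deficit_annual == pytest.approx(
            d1.large_illness_deficit_annual / 2, rel=1e-12
        )

    def test_negative_deficit_not_clipped(self):
        # far more observed small outbreaks than the line expects
        sizes = np.arange(1, 30)
        counts = np.full(sizes.size, 500)
        hist = SizeFrequencyTable(sizes, counts, (2000, 2000))
        fit = make_fit(3.0, 1, 100, hist)
        d = estimate_deficits(expected_line(fit, hist), hist)
        assert d.small_outbreak_deficit_total < 0


def test_deficit_unbiased_without_censoring():
    """Samples drawn from the fitted model show no systematic small deficit."""
    totals = []
    for rep in range(30):
        rng = np.random.default_rng(700 + rep)
        s = PowerLaw(2.15, 1).sample(10_000, rng)
        hist = SizeFrequencyTable.from_sizes(s, (2000, 2000))
        fit = select_xmin(hist)
        d = estimate_deficits(expected_line(fit, hist), hist)
        totals.append(d.small_outbreak_deficit_total)
    totals = np.array(totals)
    se = totals.std(ddof=1) / math.sqrt(totals.size)
    assert abs(totals.mean()) < 2.5 * se + 5


def test_observed_expected_table_columns(simple_hist):
    fit = make_fit(2.0, 1, 100, simple_hist)
    tab = observed_expected_table(expected_line(fit, simple_hist), simple_hist)
    assert list(tab.columns) == ["size", "observed", "expected"]
    assert (tab["size"].values == simple_hist.sizes).all()
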