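"""Underdetection estimates: expected power-law line vs observed counts.

The fitted tail model is extrapolated across *all* sizes ``x >= 1`` as an
"expected line" ``E(x) = C x^(-alpha)``, anchored so that the expected and
observed totals agree on the validated tail (``C = n_tail / zeta(alpha,
xmin)``).  Below the threshold the line is an extrapolation — precisely the
reference against which underdetection of small outbreaks is measured.

Deficits are expected-minus-observed counts in two size strata: "small"
outbreaks (< 10 confirmed cases by default) and "large" ones (>= 100).
Positive values mean fewer outbreaks were observed than the power law
predicts; negative values (more observed than expected) are reported as-is,
never clipped.  Annual figures divide by the number of surveillance years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .errors import DivergentTailError, OutbreakLawError
from .fitting import TailFit
from .io import SizeFrequencyTable

logger = logging.getLogger(__name__)

SMALL_CUTOFF = 10   # "small" outbreak: fewer than this many confirmed cases
LARGE_CUTOFF = 100  # "large" outbreak: at least this many confirmed cases

__all__ = ["ExpectedLine", "DeficitEstimate", "expected_line",
           "outbreak_deficit", "illness_deficit", "estimate_deficits"]


@dataclass(frozen=True)
class ExpectedLine:
    """The fitted power law extrapolated over all integer sizes >= 1."""

    alpha: float
    constant: float       # C = n_tail / zeta(alpha, xmin)
    source_fit: TailFit

    def expected(self, x):
        """Expected outbreak count at size x: E(x) = C x^(-alpha)."""
        return self.constant * np.power(np.asarray(x, dtype=float), -self.alpha)

    def expected_count_at_least(self, x0: int) -> float:
        """Closed-form expected number of outbreaks of size >= x0."""
        return self.constant * float(special.zeta(self.alpha, x0))

    def expected_cases_at_least(self, x0: int, cap: int | None = None) -> float:
        """Expected total cases in outbreaks of size >= x0.

        ``sum_{x>=x0} x E(x) = C zeta(alpha - 1, x0)``, finite only for
        alpha > 2.  For alpha <= 2 the sum is truncated at ``cap`` (logged);
        with no cap configured a :class:`DivergentTailError` is raised.
        """
        if self.alpha > 2.0:
            return self.constant * float(special.zeta(self.alpha - 1.0, x0))
        if cap is None:
            raise DivergentTailError(
                f"expected case tail diverges for alpha={self.alpha:.3f} <= 2; "
                "configure a truncation cap"
            )
        logger.debug(
            "alpha=%.3f <= 2: truncating expected case tail at size %d", self.alpha, cap
        )
        xs = np.arange(x0, cap + 1, dtype=float)
        return self.constant * float(np.sum(xs ** (1.0 - self.alpha)))

    def table(self, max_size: int) -> pd.DataFrame:
        xs = np.arange(1, max_size + 1)
        return pd.DataFrame({"size": xs, "expected": self.expected(xs)})


@dataclass(frozen=True)
class DeficitEstimate:
    """Expected-minus-observed outbreak and illness counts by size stratum."""

    small_outbreak_deficit_total: float
    large_outbreak_deficit_total: float
    small_illness_deficit_total: float
    large_illness_deficit_total: float
    n_years: int
    small_cutoff: int = SMALL_CUTOFF
    large_cutoff: int = LARGE_CUTOFF

    @property
    def small_outbreak_deficit_annual(self) -> float:
        return self.small_outbreak_deficit_total / self.n_years

    @property
    def large_outbreak_deficit_annual(self) -> float:
        return self.large_outbreak_deficit_total / self.n_years

    @property
    def small_illness_deficit_annual(self) -> float:
        return self.small_illness_deficit_total / self.n_years

    @property
    def large_illness_deficit_annual(self) -> float:
        return self.large_illness_deficit_total / self.n_years

    def to_dict(self) -> dict:
        d = {
            f: float(getattr(self, f))
            for f in (
                "small_outbreak_deficit_total", "small_outbreak_deficit_annual",
                "large_outbreak_deficit_total", "large_outbreak_deficit_annual",
                "small_illness_deficit_total", "small_illness_deficit_annual",
                "large_illness_deficit_total", "large_illness_deficit_annual",
            )
        }
        d.update(n_years=self.n_years, small_cutoff=self.small_cutoff,
                 large_cutoff=self.large_cutoff)
        return d


def expected_line(fit: TailFit, hist: SizeFrequencyTable) -> ExpectedLine:
    """Anchor the fitted power law to the observed tail total.

    ``C = n_tail / zeta(alpha, xmin)`` guarantees
    ``sum_{x >= xmin} E(x) = n_tail`` exactly.
    """
    if fit.family != "power_law":
        raise OutbreakLawError(
            f"expected line requires a power-law fit, got {fit.family}"
        )
    alpha = fit.model.alpha
    C = fit.n_tail / float(special.zeta(alpha, fit.xmin))
    return ExpectedLine(alpha=alpha, constant=C, source_fit=fit)


def _observed_on(hist: SizeFrequencyTable, lo: int, hi: int) -> np.ndarray:
    """Observed counts on the dense integer grid [lo, hi]."""
    out = np.zeros(hi - lo + 1, dtype=float)
    m = (hist.sizes >= lo) & (hist.sizes <= hi)
    out[hist.sizes[m] - lo] = hist.counts[m]
    return out


def estimate_deficits(
    line: ExpectedLine,
    hist: SizeFrequencyTable,
    small_cutoff: int = SMALL_CUTOFF,
    large_cutoff: int = LARGE_CUTOFF,
    large_closed_form: bool = True,
    illness_tail_cap: int | None = 100_000,
) -> DeficitEstimate:
    """Small- and large-stratum outbreak and illness deficits.

    Small stratum: ``sum_{x=1}^{small_cutoff-1} (E(x) - n(x))`` and the
    case-weighted analogue for illnesses.

    Large stratum: expected tail mass over *all* integers ``x >= large_cutoff``
    (closed form, ``C zeta(alpha, cutoff)``) minus the observed tail count.
    ``large_closed_form=False`` restricts the expectation to observed sizes
    only — a sensitivity variant, since zero-count sizes above the cutoff
    still carry expected mass under the model.
    """
    xs_small = np.arange(1, small_cutoff, dtype=float)
    obs_small = _observed_on(hist, 1, small_cutoff - 1)
    e_small = line.expected(xs_small)
    small_out = float(np.sum(e_small - obs_small))
    small_ill = float(np.sum(xs_small * (e_small - obs_small)))

    obs_large_n = hist.count_at_least(large_cutoff)
    obs_large_cases = hist.cases_at_least(large_cutoff)
    if large_closed_form:
        exp_large_n = line.expected_count_at_least(large_cutoff)
        exp_large_cases = line.expected_cases_at_least(large_cutoff, cap=illness_tail_cap)
    else:
        m = hist.sizes >= large_cutoff
        xs_l = hist.sizes[m].astype(float)
        exp_large_n = float(np.sum(line.expected(xs_l)))
        exp_large_cases = float(np.sum(xs_l * line.expected(xs_l)))
    large_out = exp_large_n - obs_large_n
    large_ill = exp_large_cases - obs_large_cases

    return DeficitEstimate(
        small_outbreak_deficit_total=small_out,
        large_outbreak_deficit_total=large_out,
        small_illness_deficit_total=small_ill,
        large_illness_deficit_total=large_ill,
        n_years=hist.n_years,
        small_cutoff=small_cutoff,
        large_cutoff=large_cutoff,
    )


def outbreak_deficit(line, hist, **kwargs) -> DeficitEstimate:
    """Alias of :func:`estimate_deficits` (outbreak counts are the headline)."""
    return estimate_deficits(line, hist, **kwargs)


def illness_deficit(line, hist, **kwargs):
    """(small, large) annual illness deficits; see :func:`estimate_deficits`."""
    d = estimate_deficits(line, hist, **kwargs)
    return d.small_illness_deficit_annual, d.large_illness_deficit_annual


def observed_expected_table(line: ExpectedLine, hist: SizeFrequencyTable) -> pd.DataFrame:
    """Plot-ready (size, observed, expected) table on the observed support."""
    return pd.DataFrame(
        {
            "size": hist.sizes,
            "observed": hist.counts,
            "expected": line.expected(hist.sizes),
        }
    )
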