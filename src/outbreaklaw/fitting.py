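"""Tail fitting: MLE, KS-minimizing threshold selection, GoF bootstrap.

The estimation strategy is the standard one for discrete heavy-tailed data:

1. For each candidate minimum threshold ``xmin`` (every distinct observed
   size, excluding candidates that leave too few distinct tail sizes), fit the
   family's parameters by exact discrete maximum likelihood on the tail
   ``x >= xmin``.
2. Measure the Kolmogorov-Smirnov distance ``D`` between the empirical and
   fitted tail CDFs, scanning every integer in ``[xmin, max observed size]``
   (discrete CDF gaps can peak at unobserved sizes).
3. Keep the fit minimizing ``D``; ties break toward the smaller threshold.

Goodness of fit uses the semi-parametric bootstrap: replicates draw from the
fitted model above the threshold and resample the observed sub-threshold data
below it, re-estimate (xmin, parameters) on each replicate, and compare the
replicate KS distances with the observed one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .distributions import DiscreteExponential, DiscreteLogNormal, PowerLaw
from .errors import DegenerateDataError, OutbreakLawError
from .io import SizeFrequencyTable

logger = logging.getLogger(__name__)

FAMILIES = ("power_law", "lognormal", "exponential")

ALPHA_BOUNDS = (1.01, 10.0)
ALPHA_XTOL = 1e-6

__all__ = [
    "TailFit",
    "GofResult",
    "FamilyComparison",
    "fit_alpha",
    "fit_exponential",
    "fit_lognormal",
    "ks_distance",
    "select_xmin",
    "gof_bootstrap",
    "compare_families",
]


@dataclass(frozen=True)
class TailFit:
    """A fitted tail model with its KS distance and log-likelihood."""

    model: object
    n_tail: int
    ks_distance: float
    log_likelihood: float

    @property
    def xmin(self) -> int:
        return self.model.xmin

    @property
    def family(self) -> str:
        return self.model.family

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "xmin": int(self.xmin),
            "params": {k: float(v) for k, v in self.model.params.items()},
            "n_tail": int(self.n_tail),
            "ks_distance": float(self.ks_distance),
            "log_likelihood": float(self.log_likelihood),
        }


@dataclass(frozen=True)
class GofResult:
    """Bootstrap goodness-of-fit: ``p_value`` = fraction of replicate KS
    distances at least as large as the observed one."""

    observed_d: float
    p_value: float
    n_boot: int
    seed: int | None
    n_failures: int = 0
    replicate_d: np.ndarray | None = field(default=None, compare=False)

    def to_dict(self) -> dict:
        return {
            "observed_d": float(self.observed_d),
            "p_value": float(self.p_value),
            "n_boot": int(self.n_boot),
            "seed": self.seed,
            "n_failures": int(self.n_failures),
        }


def _tail_arrays(hist: SizeFrequencyTable, xmin: int):
    m = hist.sizes >= xmin
    sizes = hist.sizes[m]
    counts = hist.counts[m]
    if sizes.size < 2:
        raise DegenerateDataError(
            f"need >= 2 distinct sizes at or above xmin={xmin}, found {sizes.size}"
        )
    return sizes, counts


def fit_alpha(hist: SizeFrequencyTable, xmin: int):
    """Exact discrete MLE of the power-law exponent on the tail ``x >= xmin``.

    Maximizes ``sum_x n(x) [-alpha ln x - ln zeta(alpha, xmin)]`` by bounded
    one-dimensional optimization (no continuous-approximation formula, which
    is biased when tail sizes are small integers).

    Returns
    -------
    (alpha_hat, log_likelihood)
    """
    sizes, counts = _tail_arrays(hist, xmin)
    n = counts.sum()
    slog = float(np.dot(counts, np.log(sizes)))

    def negll(a):
        return a * slog + n * math.log(special.zeta(a, xmin))

    res = optimize.minimize_scalar(
        negll, bounds=ALPHA_BOUNDS, method="bounded", options={"xatol": ALPHA_XTOL}
    )
    return float(res.x), -float(res.fun)


def fit_exponential(hist: SizeFrequencyTable, xmin: int):
    """MLE of the geometric (discretized exponential) tail; closed form.

    With pmf (1-q) q^(x-xmin), the MLE is q_hat = m / (1 + m) for
    m = mean(x - xmin).
    """
    sizes, counts = _tail_arrays(hist, xmin)
    n = counts.sum()
    m = float(np.dot(counts, sizes - xmin)) / n
    q = m / (1.0 + m)
    lam = -math.log(q) if q > 0 else 50.0
    model = DiscreteExponential(lam=lam, xmin=xmin)
    ll = float(np.dot(counts, model.logpmf(sizes)))
    return model, ll


def fit_lognormal(hist: SizeFrequencyTable, xmin: int):
    """MLE of the discrete log-normal tail by Nelder-Mead over (mu, ln sigma)."""
    sizes, counts = _tail_arrays(hist, xmin)
    logs = np.log(sizes.astype(float))
    n = counts.sum()
    mu0 = float(np.dot(counts, logs)) / n
    sd0 = math.sqrt(max(float(np.dot(counts, (logs - mu0) ** 2)) / n, 1e-4))

    def negll(theta):
        mu, logsig = theta
        sig = math.exp(logsig)
        if sig > 50:
            return 1e12
        model = DiscreteLogNormal(mu=mu, sigma=sig, xmin=xmin)
        return -float(np.dot(counts, model.logpmf(sizes)))

    res = optimize.minimize(
        negll,
        x0=[mu0, math.log(sd0)],
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 300},
    )
    mu, sig = float(res.x[0]), math.exp(float(res.x[1]))
    model = DiscreteLogNormal(mu=mu, sigma=sig, xmin=xmin)
    return model, -float(res.fun)


def ks_distance(hist: SizeFrequencyTable, model) -> float:
    """KS distance between the empirical and model tail CDFs.

    Both CDFs condition on ``x >= model.xmin``; the maximum absolute gap is
    taken over every integer in ``[xmin, max observed size]``.
    """
    sizes, counts = _tail_arrays(hist, model.xmin)
    n = counts.sum()
    xs = np.arange(model.xmin, sizes[-1] + 1, dtype=np.int64)
    obs = np.zeros(xs.size, dtype=np.int64)
    obs[sizes - model.xmin] = counts
    emp_cdf = np.cumsum(obs) / n
    # model CDF on the dense grid by cumulative pmf (one normalizer
    # evaluation instead of a special-function call per integer)
    mod_cdf = np.cumsum(model.pmf(xs))
    return float(np.max(np.abs(emp_cdf - mod_cdf)))


_FITTERS = {
    "power_law": lambda hist, xmin: _fit_pl_model(hist, xmin),
    "lognormal": fit_lognormal,
    "exponential": fit_exponential,
}


def _fit_pl_model(hist, xmin):
    alpha, ll = fit_alpha(hist, xmin)
    return PowerLaw(alpha=alpha, xmin=xmin), ll


def _fit_at(hist, xmin, family):
    model, ll = _FITTERS[family](hist, xmin)
    d = ks_distance(hist, model)
    n_tail = int(hist.counts[hist.sizes >= xmin].sum())
    return TailFit(model=model, n_tail=n_tail, ks_distance=d, log_likelihood=ll)


def candidate_xmins(hist: SizeFrequencyTable, min_distinct_tail: int = 10) -> np.ndarray:
    """Candidate thresholds: distinct observed sizes, excluding the largest
    and any candidate leaving fewer than ``min_distinct_tail`` distinct tail
    sizes (which would make the KS distance erratically small).  If the rule
    eliminates everything (tiny datasets), it relaxes to requiring 2 distinct
    tail sizes."""
    sizes = hist.sizes
    if sizes.size < 2:
        raise DegenerateDataError("need >= 2 distinct sizes to select a threshold")
    n_distinct_tail = sizes.size - np.arange(sizes.size)
    for floor in (max(min_distinct_tail, 2), 2):
        cand = sizes[n_distinct_tail >= floor]
        if cand.size:
            return cand
    raise DegenerateDataError("no valid threshold candidate")  # pragma: no cover


def select_xmin(
    hist: SizeFrequencyTable,
    family: str = "power_law",
    min_distinct_tail: int = 10,
) -> TailFit:
    """Select the minimum threshold by KS minimization.

    Fits the family at every candidate threshold and returns the fit with the
    smallest KS distance; ties break toward the smaller threshold (retains
    more data, deterministic).
    """
    if family not in _FITTERS:
        raise OutbreakLawError(f"unknown family {family!r}; choose from {FAMILIES}")
    best = None
    for xmin in candidate_xmins(hist, min_distinct_tail):
        try:
            fit = _fit_at(hist, int(xmin), family)
        except (DegenerateDataError, FloatingPointError):  # pragma: no cover
            continue
        if best is None or fit.ks_distance < best.ks_distance:
            best = fit
    if best is None:
        raise DegenerateDataError("no candidate threshold could be fitted")
    return best


def gof_bootstrap(
    hist: SizeFrequencyTable,
    fit: TailFit,
    n_boot: int = 1000,
    seed=None,
    min_distinct_tail: int = 10,
    smoothed: bool = False,
    store_replicates: bool = True,
) -> GofResult:
    """Semi-parametric bootstrap goodness-of-fit p-value.

    Each replicate draws N observations: with probability ``n_tail / N`` from
    the fitted tail model, otherwise uniformly from the observed
    sub-threshold values; (xmin, parameters) are re-estimated on the
    replicate and its KS distance recorded.  ``p`` is the plain fraction of
    replicate distances >= the observed one (``smoothed=True`` applies the
    (r+1)/(n+1) estimator instead).
    """
    if n_boot < 1:
        raise OutbreakLawError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    N = hist.total
    below_mask = hist.sizes < fit.xmin
    below = np.repeat(hist.sizes[below_mask], hist.counts[below_mask])
    if below.size == 0 and fit.xmin > hist.sizes[0]:  # pragma: no cover
        logger.info("no sub-threshold mass: falling back to fully parametric bootstrap")
    p_tail = fit.n_tail / N
    d_star, failures = [], 0
    for _ in range(n_boot):
        k_tail = rng.binomial(N, p_tail) if below.size else N
        draw_tail = fit.model.sample(k_tail, rng)
        if below.size:
            draw_below = rng.choice(below, size=N - k_tail, replace=True)
            sample = np.concatenate([draw_tail, draw_below])
        else:
            sample = draw_tail
        rep_hist = SizeFrequencyTable.from_sizes(sample, hist.period)
        try:
            rep_fit = select_xmin(rep_hist, fit.family, min_distinct_tail)
        except DegenerateDataError:
            failures += 1
            continue
        d_star.append(rep_fit.ks_distance)
    d_star = np.array(d_star)
    if failures:
        logger.warning("gof_bootstrap: %d/%d replicates degenerate", failures, n_boot)
    n_ok = d_star.size
    if n_ok == 0:
        raise DegenerateDataError("all bootstrap replicates degenerate")
    r = int(np.sum(d_star >= fit.ks_distance))
    p = (r + 1) / (n_ok + 1) if smoothed else r / n_ok
    seed_out = seed if isinstance(seed, (int, np.integer)) else None
    return GofResult(
        observed_d=fit.ks_distance,
        p_value=float(p),
        n_boot=n_boot,
        seed=seed_out,
        n_failures=failures,
        replicate_d=d_star if store_replicates else None,
    )


@dataclass
class FamilyComparison:
    """Per-family fits with optional GoF results; fitting errors are captured
    per family rather than aborting the others."""

    fits: dict
    gof: dict
    errors: dict

    def rejected(self, alpha_level: float = 0.05) -> dict:
        """Family -> whether its GoF p-value falls below ``alpha_level``."""
        return {
            fam: (g.p_value < alpha_level) for fam, g in self.gof.items()
        }

    def to_dict(self) -> dict:
        return {
            "fits": {f: fit.to_dict() for f, fit in self.fits.items()},
            "gof": {f: g.to_dict() for f, g in self.gof.items()},
            "errors": {f: str(e) for f, e in self.errors.items()},
            "rejected_at_0.05": self.rejected(),
        }


def compare_families(
    hist: SizeFrequencyTable,
    families=FAMILIES,
    gof_families=(),
    n_boot: int = 1000,
    seed=None,
    min_distinct_tail: int = 10,
) -> FamilyComparison:
    """Fit each candidate family (own threshold selection per family) and
    optionally run the GoF bootstrap for a subset of them."""
    rng = np.random.default_rng(seed)
    fits, gof, errors = {}, {}, {}
    for fam in families:
        try:
            fits[fam] = select_xmin(hist, fam, min_distinct_tail)
        except OutbreakLawError as exc:
            logger.warning("family %s failed to fit: %s", fam, exc)
            errors[fam] = exc
    for fam in gof_families:
        if fam in fits:
            gof[fam] = gof_bootstrap(
                hist, fits[fam], n_boot=n_boot,
                seed=rng.integers(2**31), min_distinct_tail=min_distinct_tail,
            )
    return FamilyComparison(fits=fits, gof=gof, errors=errors)
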