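"""Probability kernels on the positive integers.

Three families are used to model outbreak size (number of laboratory-confirmed
cases per outbreak), each supported on integers ``x >= xmin``:

* :class:`PowerLaw` — pmf(x) = x^(-alpha) / zeta(alpha, xmin), normalized by
  the Hurwitz zeta function.  This is the heavy-tailed null model of the
  analysis: on log-log axes its pmf is exactly linear with slope ``-alpha``.
* :class:`DiscreteLogNormal` — the continuous log-normal density evaluated at
  integer points and renormalized over the support.
* :class:`DiscreteExponential` — a geometric law, pmf(x) proportional to
  exp(-lam * x); the light-tailed competitor.

All families expose ``pmf``, ``logpmf``, ``survival`` (P(X >= x)), ``cdf``
(P(X <= x)) and an exact integer sampler (inverse-CDF; no continuous
approximation and rounding).

The discretization convention for the log-normal and exponential competitors
is *density at integer points, renormalized* (not CDF differencing).  It is
documented in docs/methods.md and held fixed throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .errors import ConfigurationError

__all__ = [
    "hurwitz_zeta",
    "PowerLaw",
    "DiscreteLogNormal",
    "DiscreteExponential",
]


def hurwitz_zeta(alpha, xmin=1):
    """Hurwitz zeta ``zeta(alpha, xmin) = sum_{k>=xmin} k**(-alpha)``.

    Parameters
    ----------
    alpha : float or array-like
        Exponent, must be > 1 (the series diverges otherwise).
    xmin : int or array-like
        Lower summation bound, >= 1.

    Returns
    -------
    float or ndarray
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 1.0):
        raise ValueError("hurwitz_zeta requires alpha > 1 (series diverges)")
    out = special.zeta(alpha, xmin)
    if out.ndim == 0:
        return float(out)
    return out


class DiscreteDistribution:
    """Common interface for integer-supported size distributions."""

    xmin: int

    # subclasses implement logpmf() on arrays and survival() on arrays
    def pmf(self, x):
        return np.exp(self.logpmf(x))

    def logpmf(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def survival(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def cdf(self, x):
        """P(X <= x) for integer x >= xmin."""
        x = np.asarray(x)
        return 1.0 - self.survival(x + 1)

    _SAMPLE_TABLE = 4096  # dense survival table; far-tail draws fall back to bisection

    def sample(self, n, rng):
        """Draw ``n`` i.i.d. integers by exact inverse-CDF inversion."""
        if n < 0:
            raise ValueError("n must be >= 0")
        if n == 0:
            return np.empty(0, dtype=np.int64)
        rng = np.random.default_rng(rng)
        u = rng.uniform(size=n)
        # answer = smallest x >= xmin with survival(x + 1) <= u; resolve the
        # bulk against a dense table, bisect only draws beyond it
        T = self._SAMPLE_TABLE
        surv = self.survival(np.arange(self.xmin + 1, self.xmin + T + 2))
        # count of table survivals > u, via the reversed (ascending) table
        c = surv.size - np.searchsorted(surv[::-1], u, side="right")
        out = self.xmin + c.astype(np.int64)
        far = c == surv.size
        if np.any(far):
            out[far] = self._inverse_survival(u[far], lo_start=int(out[far].min()))
        return out

    def _inverse_survival(self, u, lo_start=None):
        """Smallest integer x >= xmin with ``survival(x + 1) <= u``.

        Bracket by doubling, then bisect; exact to the integer because the
        survival function is evaluated on integers only.
        """
        u = np.asarray(u, dtype=float)
        lo = np.full(u.shape, self.xmin if lo_start is None else lo_start, dtype=np.int64)
        # doubling search for an upper bracket; CAP truncates astronomically
        # rare draws (survival < 1e-12 for any alpha >= 1.2) before int64 overflow
        CAP = np.int64(2) ** 40
        hi = lo + 1
        for _ in range(64):
            need = (self.survival(hi + 1) > u) & (hi < CAP)
            if not np.any(need):
                break
            hi = np.where(need, np.minimum(hi * 2, CAP), hi)
        # bisection: invariant survival(hi+1) <= u < survival(lo+1) or lo==answer
        while True:
            gap = hi - lo
            if not np.any(gap > 0):
                break
            mid = lo + gap // 2
            take_upper = self.survival(mid + 1) > u
            lo = np.where(take_upper, mid + 1, lo)
            hi = np.where(take_upper, hi, mid)
        return lo


def _check_xmin(xmin):
    if int(xmin) != xmin or xmin < 1:
        raise ConfigurationError(f"xmin must be an integer >= 1, got {xmin!r}")
    return int(xmin)


@dataclass(frozen=True)
class PowerLaw(DiscreteDistribution):
    """Discrete power law (zeta distribution shifted to ``x >= xmin``).

    pmf(x) = x^(-alpha) / zeta(alpha, xmin),
    survival(x) = zeta(alpha, x) / zeta(alpha, xmin).
    """

    alpha: float
    xmin: int = 1

    def __post_init__(self):
        if not self.alpha > 1.0:
            raise ConfigurationError(f"power law needs alpha > 1, got {self.alpha}")
        object.__setattr__(self, "xmin", _check_xmin(self.xmin))
        object.__setattr__(self, "_norm", float(special.zeta(self.alpha, self.xmin)))

    @property
    def family(self):
        return "power_law"

    @property
    def params(self):
        return {"alpha": self.alpha}

    def logpmf(self, x):
        x = np.asarray(x, dtype=float)
        self._check_support(x)
        return -self.alpha * np.log(x) - math.log(self._norm)

    def survival(self, x):
        # x at or below xmin has full mass; clipping keeps vectorized bisection safe
        x = np.asarray(x, dtype=float)
        return special.zeta(self.alpha, np.clip(x, self.xmin, None)) / self._norm

    def _check_support(self, x):
        if np.any(x < self.xmin):
            raise ValueError(f"x below support (xmin={self.xmin})")


@dataclass(frozen=True)
class DiscreteExponential(DiscreteDistribution):
    """Geometric law on ``x >= xmin``: pmf(x) = (1 - q) q^(x - xmin), q = exp(-lam)."""

    lam: float
    xmin: int = 1

    def __post_init__(self):
        if not self.lam > 0:
            raise ConfigurationError(f"exponential rate must be > 0, got {self.lam}")
        object.__setattr__(self, "xmin", _check_xmin(self.xmin))

    @property
    def family(self):
        return "exponential"

    @property
    def params(self):
        return {"lam": self.lam}

    def logpmf(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x < self.xmin):
            raise ValueError(f"x below support (xmin={self.xmin})")
        q = math.exp(-self.lam)
        return math.log1p(-q) - self.lam * (x - self.xmin)

    def survival(self, x):
        x = np.asarray(x, dtype=float)
        return np.exp(-self.lam * (np.clip(x, self.xmin, None) - self.xmin))


@dataclass(frozen=True)
class DiscreteLogNormal(DiscreteDistribution):
    """Log-normal density evaluated at integers ``x >= xmin``, renormalized.

    pmf(x) = w(x) / Z with w(x) = exp(-(ln x - mu)^2 / (2 sigma^2)) / x and
    Z = sum_{k >= xmin} w(k).  The normalizer is computed by direct summation
    with an analytic integral bound for the truncated tail (the summand is the
    continuous log-normal density up to the sqrt(2 pi) sigma factor, so the
    tail sum is controlled by the normal survival function).
    """

    mu: float
    sigma: float
    xmin: int = 1
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if not self.sigma > 0:
            raise ConfigurationError(f"sigma must be > 0, got {self.sigma}")
        object.__setattr__(self, "xmin", _check_xmin(self.xmin))

    @property
    def family(self):
        return "lognormal"

    @property
    def params(self):
        return {"mu": self.mu, "sigma": self.sigma}

    # -- weight table ------------------------------------------------------
    def _log_w(self, x):
        x = np.asarray(x, dtype=float)
        z = (np.log(x) - self.mu) / self.sigma
        return -0.5 * z * z - np.log(x)

    def _table_limit(self):
        # beyond K only ~Phi-bar(5) of the mass remains and the midpoint
        # integral approximates it to ~1e-3 relative, i.e. ~1e-10 of Z
        k = int(math.ceil(math.exp(self.mu + 5.0 * self.sigma)))
        return min(max(k, self.xmin + 256), 20_000)

    def _cumweights(self):
        """(first size, scaled cumulative weights, scaled Z, log scale).

        Weights are stored relative to the largest table weight so the
        normalizer survives parameter excursions where absolute weights
        underflow; log Z = scale + log(scaled Z).
        """
        tab = self._cache.get("cw")
        if tab is None:
            K = self._table_limit()
            ks = np.arange(self.xmin, K + 1, dtype=float)
            logw = self._log_w(ks)
            scale = float(np.max(logw))
            cw = np.cumsum(np.exp(logw - scale))
            # midpoint-rule estimate of the neglected tail sum_{k>K} w(k):
            # integral of the summand from K + 1/2 (w is eventually decreasing)
            log_tail = (
                math.log(self.sigma * math.sqrt(2 * math.pi))
                + float(special.log_ndtr(-(math.log(K + 0.5) - self.mu) / self.sigma))
            )
            tail_scaled = math.exp(min(log_tail - scale, 700.0))
            tab = (ks[0], cw, float(cw[-1] + tail_scaled), scale)
            self._cache["cw"] = tab
        return tab

    @property
    def log_norm(self):
        _, _, z, scale = self._cumweights()
        return scale + math.log(z)

    @property
    def _norm(self):
        return math.exp(self.log_norm)

    def logpmf(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x < self.xmin):
            raise ValueError(f"x below support (xmin={self.xmin})")
        return self._log_w(x) - self.log_norm

    def survival(self, x):
        first, cw, Z, scale = self._cumweights()
        x = np.clip(np.asarray(x, dtype=float), self.xmin, None)
        idx = (x - first).astype(np.int64)  # number of support points strictly below x
        below = np.where(idx > 0, cw[np.clip(idx - 1, 0, len(cw) - 1)], 0.0)
        # beyond the table, fall back to the integral tail approximation
        over = idx > len(cw)
        s = np.clip((Z - below) / Z, 0.0, 1.0)
        if np.any(over):
            xo = x[np.asarray(over).nonzero()]
            log_tail = (
                math.log(self.sigma * math.sqrt(2 * math.pi))
                + special.log_ndtr(-(np.log(xo) - self.mu) / self.sigma)
            )
            s = np.asarray(s)
            s[np.asarray(over).nonzero()] = np.exp(
                np.minimum(log_tail - scale, 700.0)
            ) / Z
        return s if np.ndim(x) else float(s)
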