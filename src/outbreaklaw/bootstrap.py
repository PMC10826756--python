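"""Case-resampling bootstrap of the full estimation pipeline.

Uncertainty in every reported quantity — the minimum threshold, the scaling
exponent and the deficits — comes from a nonparametric bootstrap over
outbreak records: each replicate resamples the N outbreaks with replacement
and reruns threshold selection, MLE, line extrapolation and deficit
computation from scratch.  Re-selecting the threshold per replicate is what
gives the threshold itself a bootstrap distribution.

Summaries are medians with 90% credible intervals, defined as the 5th and
95th percentiles of the replicate values under the linear-interpolation
quantile rule.  Per-replicate random streams are derived from the top-level
seed by counter-based spawning, so results are bit-identical for a given
(seed, n_boot) regardless of execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deficit import LARGE_CUTOFF, SMALL_CUTOFF, estimate_deficits, expected_line
from .errors import DegenerateDataError, OutbreakLawError
from .fitting import select_xmin
from .io import SizeFrequencyTable

logger = logging.getLogger(__name__)

QUANTITIES = (
    "xmin",
    "alpha",
    "small_outbreak_deficit_annual",
    "large_outbreak_deficit_annual",
    "small_illness_deficit_annual",
    "large_illness_deficit_annual",
)

__all__ = ["BootstrapSummary", "bootstrap_pipeline", "summarize", "replicate_statistics"]


def summarize(values):
    """(median, 5th percentile, 95th percentile) with linear interpolation."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise OutbreakLawError("cannot summarize an empty list")
    med, lo, hi = np.percentile(values, [50.0, 5.0, 95.0])
    return float(med), float(lo), float(hi)


@dataclass(frozen=True)
class BootstrapSummary:
    """Median and 90% credible interval of one quantity across replicates."""

    quantity: str
    values: np.ndarray
    n_boot: int
    seed: int | None
    n_failures: int = 0

    @property
    def median(self) -> float:
        return summarize(self.values)[0]

    @property
    def cri_low(self) -> float:
        return summarize(self.values)[1]

    @property
    def cri_high(self) -> float:
        return summarize(self.values)[2]

    def to_dict(self) -> dict:
        med, lo, hi = summarize(self.values)
        return {
            "quantity": self.quantity,
            "median": med,
            "cri_low": lo,
            "cri_high": hi,
            "n_boot": int(self.n_boot),
            "n_failures": int(self.n_failures),
            "seed": self.seed,
        }


def replicate_statistics(
    sizes,
    period,
    small_cutoff: int = SMALL_CUTOFF,
    large_cutoff: int = LARGE_CUTOFF,
    min_distinct_tail: int = 10,
    illness_tail_cap: int | None = 100_000,
) -> dict:
    """Run the full point-estimate pipeline on one multiset of sizes.

    This is exactly the computation each bootstrap replicate performs; running
    it on the original data yields the point estimates themselves.
    """
    hist = SizeFrequencyTable.from_sizes(np.asarray(sizes, dtype=np.int64), period)
    fit = select_xmin(hist, "power_law", min_distinct_tail)
    line = expected_line(fit, hist)
    d = estimate_deficits(
        line, hist, small_cutoff=small_cutoff, large_cutoff=large_cutoff,
        illness_tail_cap=illness_tail_cap,
    )
    return {
        "xmin": float(fit.xmin),
        "alpha": float(fit.model.alpha),
        "small_outbreak_deficit_annual": d.small_outbreak_deficit_annual,
        "large_outbreak_deficit_annual": d.large_outbreak_deficit_annual,
        "small_illness_deficit_annual": d.small_illness_deficit_annual,
        "large_illness_deficit_annual": d.large_illness_deficit_annual,
    }


def bootstrap_pipeline(
    records,
    period,
    n_boot: int = 5000,
    seed=None,
    small_cutoff: int = SMALL_CUTOFF,
    large_cutoff: int = LARGE_CUTOFF,
    min_distinct_tail: int = 10,
    illness_tail_cap: int | None = 100_000,
) -> dict[str, BootstrapSummary]:
    """Bootstrap the whole pipeline; returns quantity -> summary.

    Each replicate resamples the in-period outbreaks with replacement and
    reruns threshold selection, exponent MLE and deficit estimation.
    Degenerate replicates (unfittable resamples) are recorded as failures and
    excluded; a warning fires if they exceed 1% of ``n_boot``.
    """
    if n_boot < 1:
        raise OutbreakLawError("n_boot must be >= 1")
    first, last = int(period[0]), int(period[1])
    sizes = np.array(
        [r.size for r in records if first <= r.year <= last], dtype=np.int64
    )
    if sizes.size == 0:
        raise OutbreakLawError(f"no records in period {first}-{last}")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_boot)
    draws = {q: [] for q in QUANTITIES}
    failures = 0
    for child in child_seeds:
        rng = np.random.default_rng(child)
        resample = sizes[rng.integers(0, sizes.size, sizes.size)]
        try:
            stats = replicate_statistics(
                resample, (first, last), small_cutoff, large_cutoff,
                min_distinct_tail, illness_tail_cap,
            )
        except DegenerateDataError:
            failures += 1
            continue
        for q in QUANTITIES:
            draws[q].append(stats[q])
    if failures > 0.01 * n_boot:
        logger.warning("bootstrap: %d/%d replicates failed", failures, n_boot)
    seed_out = seed if isinstance(seed, (int, np.integer)) else None
    return {
        q: BootstrapSummary(
            quantity=q,
            values=np.asarray(draws[q]),
            n_boot=n_boot,
            seed=seed_out,
            n_failures=failures,
        )
        for q in QUANTITIES
    }


def summary_table(summaries: dict[str, BootstrapSummary]) -> pd.DataFrame:
    """TSV-ready table (quantity, median, cri_low, cri_high, n_boot, failures)."""
    rows = [s.to_dict() for s in summaries.values()]
    return pd.DataFrame(rows)[
        ["quantity", "median", "cri_low", "cri_high", "n_boot", "n_failures"]
    ]
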