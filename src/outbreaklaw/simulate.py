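"""Synthetic surveillance datasets with known ground truth.

The generator emulates the structure of national foodborne-outbreak
surveillance: true outbreaks occur at a Poisson yearly rate with sizes drawn
from a discrete power law, but small outbreaks are systematically harder to
detect.  Detection is Bernoulli with a size-dependent probability

    d(x) = min(1, p1 + (1 - p1) * (x - 1) / (s - 1)),

a linear ramp from a floor ``p1`` at single-case outbreaks up to certain
detection at the saturation size ``s``.  Eras (e.g. before/after the roll-out
of whole-genome sequencing) can differ in rate, true exponent and detection
curve, which is what produces an era contrast in the estimated deficit.

Because the generator knows which outbreaks were suppressed, it ships the
ground truth (true and detected counts by size and stratum) alongside the
records, so pipeline estimates can be compared against construction rather
than re-derived.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._util import json_default
from .deficit import LARGE_CUTOFF, SMALL_CUTOFF
from .distributions import PowerLaw
from .errors import ConfigurationError
from .io import OutbreakRecord, write_outbreaks_csv

__all__ = [
    "DetectionCurve",
    "EraConfig",
    "SimulationConfig",
    "generate",
    "default_config",
    "write_dataset",
]


@dataclass(frozen=True)
class DetectionCurve:
    """Linear-ramp detection probability: floor at size 1, certain at >= saturation."""

    floor: float = 0.2
    saturation: int = 10

    def __post_init__(self):
        if not (0.0 < self.floor <= 1.0):
            raise ConfigurationError(f"detection floor must be in (0, 1], got {self.floor}")
        if self.saturation < 2:
            raise ConfigurationError(f"saturation size must be >= 2, got {self.saturation}")

    def prob(self, x):
        x = np.asarray(x, dtype=float)
        return np.minimum(
            1.0, self.floor + (1.0 - self.floor) * (x - 1.0) / (self.saturation - 1.0)
        )


@dataclass(frozen=True)
class EraConfig:
    """One surveillance era: inclusive year range, true exponent, yearly rate,
    and (optionally) its own detection curve."""

    first_year: int
    last_year: int
    alpha: float
    rate: float  # true outbreaks per year
    detection: DetectionCurve | None = None

    def __post_init__(self):
        if self.last_year < self.first_year:
            raise ConfigurationError("era year range is empty")
        if not self.rate > 0:
            raise ConfigurationError("era rate must be > 0")

    @property
    def years(self):
        return range(self.first_year, self.last_year + 1)


@dataclass(frozen=True)
class SimulationConfig:
    eras: tuple
    detection: DetectionCurve = field(default_factory=DetectionCurve)
    xmin_true: int = 1
    seed: int | None = None

    def __post_init__(self):
        spans = sorted((e.first_year, e.last_year) for e in self.eras)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise ConfigurationError("era year ranges must be disjoint")


def default_config(seed: int | None = None) -> SimulationConfig:
    """The package's reference study conditions.

    Two eras spanning 1998-2019 with a fixed true exponent of 2.15 and 1,200
    true outbreaks/year; detection of single-case outbreaks improves from 20%
    to 50% in the second (sequencing) era, saturating at 10 cases.  Yields
    on the order of 10^4 detected outbreaks with a realistic sub-threshold
    flattening of the size-frequency curve.
    """
    return SimulationConfig(
        eras=(
            EraConfig(1998, 2017, alpha=2.15, rate=1200.0,
                      detection=DetectionCurve(floor=0.2, saturation=10)),
            EraConfig(2018, 2019, alpha=2.15, rate=1200.0,
                      detection=DetectionCurve(floor=0.5, saturation=10)),
        ),
        seed=seed,
    )


def _stratum_counts(sizes, small_cutoff, large_cutoff):
    sizes = np.asarray(sizes)
    return {
        "n": int(sizes.size),
        "n_small": int(np.sum(sizes < small_cutoff)),
        "n_large": int(np.sum(sizes >= large_cutoff)),
        "cases": int(sizes.sum()),
        "cases_small": int(sizes[sizes < small_cutoff].sum()),
        "cases_large": int(sizes[sizes >= large_cutoff].sum()),
    }


def generate(
    config: SimulationConfig,
    rng=None,
    small_cutoff: int = SMALL_CUTOFF,
    large_cutoff: int = LARGE_CUTOFF,
):
    """Simulate detected outbreak records plus the full ground truth.

    For every era-year: draw the true outbreak count from a Poisson at the
    era rate, draw sizes i.i.d. from the era's power law, then retain each
    outbreak independently with probability ``d(size)``.

    Returns
    -------
    (records, truth) : (list of OutbreakRecord, dict)
        ``truth`` holds, per era and overall: true/detected stratum counts,
        the censored (missed) small and large outbreak and illness totals,
        and the annualized censored-small figures.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    records = []
    truth = {"eras": {}, "config": _config_dict(config)}
    for era in config.eras:
        model = PowerLaw(alpha=era.alpha, xmin=config.xmin_true)
        curve = era.detection or config.detection
        true_sizes_all, kept_sizes_all = [], []
        for year in era.years:
            n_true = rng.poisson(era.rate)
            sizes = model.sample(n_true, rng)
            keep = rng.uniform(size=n_true) < curve.prob(sizes)
            kept = sizes[keep]
            true_sizes_all.append(sizes)
            kept_sizes_all.append(kept)
            records.extend(OutbreakRecord(year, int(s)) for s in kept)
        true_sizes = np.concatenate(true_sizes_all) if true_sizes_all else np.empty(0, int)
        kept_sizes = np.concatenate(kept_sizes_all) if kept_sizes_all else np.empty(0, int)
        t = _stratum_counts(true_sizes, small_cutoff, large_cutoff)
        d = _stratum_counts(kept_sizes, small_cutoff, large_cutoff)
        n_years = era.last_year - era.first_year + 1
        truth["eras"][f"{era.first_year}-{era.last_year}"] = {
            "true": t,
            "detected": d,
            "censored_small_outbreaks": t["n_small"] - d["n_small"],
            "censored_large_outbreaks": t["n_large"] - d["n_large"],
            "censored_small_illnesses": t["cases_small"] - d["cases_small"],
            "censored_small_outbreaks_annual": (t["n_small"] - d["n_small"]) / n_years,
            "n_years": n_years,
        }
    overall_true = sum(e["true"]["n"] for e in truth["eras"].values())
    overall_detected = sum(e["detected"]["n"] for e in truth["eras"].values())
    truth["overall"] = {
        "true_outbreaks": overall_true,
        "detected_outbreaks": overall_detected,
        "censored_small_outbreaks": sum(
            e["censored_small_outbreaks"] for e in truth["eras"].values()
        ),
        "censored_small_illnesses": sum(
            e["censored_small_illnesses"] for e in truth["eras"].values()
        ),
    }
    return records, truth


def _config_dict(config: SimulationConfig) -> dict:
    return {
        "xmin_true": config.xmin_true,
        "seed": config.seed,
        "default_detection": {
            "floor": config.detection.floor,
            "saturation": config.detection.saturation,
        },
        "eras": [
            {
                "first_year": e.first_year,
                "last_year": e.last_year,
                "alpha": e.alpha,
                "rate": e.rate,
                "detection": None
                if e.detection is None
                else {"floor": e.detection.floor, "saturation": e.detection.saturation},
            }
            for e in config.eras
        ],
    }


def write_dataset(records, truth, csv_path, truth_path=None) -> None:
    """Write records in the CSV dialect the reader expects, truth as JSON."""
    write_outbreaks_csv(records, csv_path)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True, default=json_default)
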