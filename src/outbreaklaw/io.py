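"""Outbreak tables and size-frequency histograms.

An outbreak record is (year, size) where size is the number of
laboratory-confirmed cases (>= 1; outbreaks with a single confirmed case are
included).  Input is a comma-separated file with a header row; column names
are configurable because supplementary tables rarely agree on a schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyPeriodError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_YEAR_COL = "year"
DEFAULT_SIZE_COL = "confirmed_cases"

__all__ = [
    "OutbreakRecord",
    "SizeFrequencyTable",
    "read_outbreaks",
    "make_histogram",
    "write_outbreaks_csv",
]


@dataclass(frozen=True, order=True)
class OutbreakRecord:
    """One reported outbreak: calendar year and confirmed-case count (>= 1)."""

    year: int
    size: int

    def __post_init__(self):
        if self.size < 1:
            raise ValidationError(f"outbreak size must be >= 1, got {self.size}")


@dataclass(frozen=True)
class SizeFrequencyTable:
    """Histogram of outbreak size -> observed frequency over a year range.

    ``sizes`` is the sorted array of distinct observed sizes and ``counts``
    the matching frequencies; ``total`` is the number of outbreaks; the period
    is closed on both ends and ``n_years = last - first + 1``.
    """

    sizes: np.ndarray
    counts: np.ndarray
    period: tuple[int, int]

    def __post_init__(self):
        sizes = np.asarray(self.sizes, dtype=np.int64)
        counts = np.asarray(self.counts, dtype=np.int64)
        if sizes.shape != counts.shape:
            raise ConfigurationError("sizes and counts must align")
        if sizes.size and (np.any(sizes < 1) or np.any(np.diff(sizes) <= 0)):
            raise ConfigurationError("sizes must be strictly increasing positive integers")
        if np.any(counts < 0):
            raise ConfigurationError("counts must be non-negative")
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_years(self) -> int:
        return self.period[1] - self.period[0] + 1

    @property
    def max_size(self) -> int:
        return int(self.sizes[-1]) if self.sizes.size else 0

    def as_dict(self) -> dict[int, int]:
        return {int(s): int(c) for s, c in zip(self.sizes, self.counts)}

    def expand(self) -> np.ndarray:
        """Back to the multiset of sizes (sorted)."""
        return np.repeat(self.sizes, self.counts)

    def count_at_least(self, x0: int) -> int:
        return int(self.counts[self.sizes >= x0].sum())

    def cases_at_least(self, x0: int) -> int:
        m = self.sizes >= x0
        return int((self.sizes[m] * self.counts[m]).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"size": self.sizes, "count": self.counts})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_sizes(cls, sizes, period) -> "SizeFrequencyTable":
        sizes = np.asarray(sizes, dtype=np.int64)
        uniq, cnt = np.unique(sizes, return_counts=True)
        return cls(uniq, cnt, (int(period[0]), int(period[1])))


def read_outbreaks(
    source,
    year_col: str = DEFAULT_YEAR_COL,
    size_col: str = DEFAULT_SIZE_COL,
    on_invalid: str = "raise",
) -> list[OutbreakRecord]:
    """Read an outbreak table from a CSV file with a header row.

    Parameters
    ----------
    source : path or file-like
    year_col, size_col : str
        Column names holding the calendar year and the confirmed-case count.
    on_invalid : {"raise", "drop"}
        Rows whose size is missing, non-integer or < 1 either abort the read
        with a :class:`ValidationError` listing the rows, or are dropped with
        each offence logged.  They are never silently accepted.
    """
    if on_invalid not in ("raise", "drop"):
        raise ConfigurationError(f"on_invalid must be 'raise' or 'drop', got {on_invalid!r}")
    df = pd.read_csv(source)
    for col in (year_col, size_col):
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} not found; available: {list(df.columns)}"
            )
    year = pd.to_numeric(df[year_col], errors="coerce")
    size = pd.to_numeric(df[size_col], errors="coerce")
    bad = (
        size.isna()
        | year.isna()
        | (size != np.floor(size.fillna(0)))
        | (size < 1)
        | (year != np.floor(year.fillna(0)))
    )
    if bad.any():
        offenders = [
            (int(i), df[size_col].iloc[j])
            for j, i in enumerate(df.index)
            if bool(bad.iloc[j])
        ]
        msg = f"{len(offenders)} row(s) failed validation (size must be an integer >= 1)"
        if on_invalid == "raise":
            raise ValidationError(f"{msg}: rows {offenders[:20]}", rows=offenders)
        for idx, val in offenders:
            logger.warning("dropping row %d: invalid size %r", idx, val)
    keep = ~bad
    return [
        OutbreakRecord(int(y), int(s))
        for y, s in zip(year[keep], size[keep])
    ]


def write_outbreaks_csv(
    records,
    path,
    year_col: str = DEFAULT_YEAR_COL,
    size_col: str = DEFAULT_SIZE_COL,
) -> None:
    """Write records in the same CSV dialect :func:`read_outbreaks` reads."""
    pd.DataFrame(
        {year_col: [r.year for r in records], size_col: [r.size for r in records]}
    ).to_csv(path, index=False)


def make_histogram(records, period) -> SizeFrequencyTable:
    """Build a :class:`SizeFrequencyTable` from records within ``period``.

    ``period`` is an inclusive (first_year, last_year) pair.  A period
    containing no records raises :class:`EmptyPeriodError` so the caller can
    decide whether an empty table is meaningful.
    """
    first, last = int(period[0]), int(period[1])
    if last < first:
        raise ConfigurationError(f"period {period} is empty (last < first)")
    sizes = np.array([r.size for r in records if first <= r.year <= last], dtype=np.int64)
    if sizes.size == 0:
        raise EmptyPeriodError(f"no records in period {first}-{last}")
    return SizeFrequencyTable.from_sizes(sizes, (first, last))
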