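"""Core data types for sperm whale coda analysis.

A *coda* is a short stereotyped burst of clicks (typically 3-40, generally
under two seconds in total) produced by a sperm whale.  Its temporal
structure is fully described by the vector of inter-click intervals (ICIs):
for a coda of k clicks there are k-1 positive ICIs, and their sum is the
coda *duration*.  Two derived representations matter throughout the
package:

* the **standardised (absolute) ICI** vector -- each ICI divided by the
  coda duration.  It sums to one and captures the coda's *rhythm*
  independently of how fast it was produced;
* the **cumulative ICI** vector -- time of each click relative to the
  first click.  Standardised, its last element is exactly one.

Codas are grouped into an :class:`ExchangeDataset`.  Datasets come in two
styles: an unordered repertoire (ICIs only) and an ordered exchange record
in which every coda additionally carries a speaker identity and the onset
time of its first click, enabling conversational analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger("codakit")

__all__ = [
    "Coda",
    "ExchangeDataset",
    "InvalidCodaError",
    "ParameterError",
    "UnorderedDatasetError",
    "InsufficientDataError",
    "duration",
    "standardize_ici",
    "cumulative_ici",
    "filter_clicks",
    "MIN_ANALYSIS_CLICKS",
    "MAX_ANALYSIS_CLICKS",
]

#: Codas with fewer clicks are accepted at I/O (with a warning) but are not
#: valid analysis units; the literature treats 3 clicks as the minimum coda.
MIN_ANALYSIS_CLICKS = 3

#: Rare long codas (more than 10 clicks, under 5% of recordings) are
#: conventionally excluded from analysis.
MAX_ANALYSIS_CLICKS = 10


class InvalidCodaError(ValueError):
    """Raised when click/ICI data cannot form a valid coda."""


class ParameterError(ValueError):
    """Raised for out-of-range analysis parameters."""


class UnorderedDatasetError(ValueError):
    """Raised when an operation needs temporal order / speaker identities."""


class InsufficientDataError(RuntimeError):
    """Raised when a statistical test has no qualifying units."""


@dataclass(frozen=True)
class Coda:
    """A single coda: an identifier, its ICI vector, and optional context.

    Parameters
    ----------
    coda_id
        Opaque unique identifier.
    ici
        Ordered inter-click intervals in seconds; all strictly positive.
        Length k-1 for a k-click coda (so at least one element).
    whale_id
        Speaker identity, if known (ordered datasets).
    onset_time
        Time of the first click in seconds from the recording start, if
        known (ordered datasets).
    """

    coda_id: str
    ici: np.ndarray
    whale_id: str | None = None
    onset_time: float | None = None

    def __post_init__(self) -> None:
        ici = np.asarray(self.ici, dtype=float)
        if ici.ndim != 1 or ici.size < 1:
            raise InvalidCodaError(
                f"coda {self.coda_id!r}: need >=1 inter-click interval "
                "(a single click is not a coda)"
            )
        if not np.all(np.isfinite(ici)) or np.any(ici <= 0):
            raise InvalidCodaError(
                f"coda {self.coda_id!r}: all ICIs must be finite and > 0"
            )
        ici.setflags(write=False)
        object.__setattr__(self, "ici", ici)
        if self.onset_time is not None:
            object.__setattr__(self, "onset_time", float(self.onset_time))

    # -- basic quantities -------------------------------------------------

    @property
    def click_count(self) -> int:
        """Number of clicks (one more than the number of ICIs)."""
        return self.ici.size + 1

    @property
    def duration(self) -> float:
        """Coda duration: the sum of its absolute ICIs, in seconds."""
        return float(self.ici.sum())

    @property
    def termination(self) -> float:
        """Time of the last click (onset + duration); requires onset."""
        if self.onset_time is None:
            raise InvalidCodaError(f"coda {self.coda_id!r} has no onset time")
        return self.onset_time + self.duration

    def click_times(self) -> np.ndarray:
        """Absolute times of all clicks, strictly increasing."""
        if self.onset_time is None:
            raise InvalidCodaError(f"coda {self.coda_id!r} has no onset time")
        return self.onset_time + np.concatenate(([0.0], np.cumsum(self.ici)))

    def drop_final_click(self) -> "Coda":
        """Coda with the last click (last ICI) removed; id gains a suffix."""
        if self.ici.size < 2:
            raise InvalidCodaError(
                f"coda {self.coda_id!r}: cannot truncate a 2-click coda"
            )
        return Coda(
            coda_id=f"{self.coda_id}~trunc",
            ici=self.ici[:-1].copy(),
            whale_id=self.whale_id,
            onset_time=self.onset_time,
        )


def duration(coda: Coda) -> float:
    """Duration of *coda* in seconds (sum of absolute ICIs)."""
    return coda.duration


def standardize_ici(coda: Coda) -> np.ndarray:
    """Standardised absolute ICI vector: each ICI over the coda duration.

    The result sums to one and is invariant under uniform time-scaling of
    the coda, isolating rhythm from tempo.
    """
    return np.asarray(coda.ici) / coda.duration


def cumulative_ici(coda: Coda, standardized: bool = False) -> np.ndarray:
    """Cumulative ICI vector (time of clicks 2..k relative to click 1).

    With ``standardized=True`` the vector is divided by the coda duration
    so its final element is exactly 1.
    """
    cum = np.cumsum(coda.ici)
    if standardized:
        cum = cum / coda.duration
    return cum


@dataclass
class ExchangeDataset:
    """A collection of codas, optionally in conversational order.

    ``ordered=True`` asserts the Dataset-2 style contract: every coda has a
    ``whale_id`` and an ``onset_time`` and codas are sorted by onset.
    """

    codas: list[Coda]
    ordered: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codas = list(self.codas)
        ids = [c.coda_id for c in self.codas]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate coda_id {dup!r} in dataset")
        if self.ordered:
            for c in self.codas:
                if c.whale_id is None or c.onset_time is None:
                    raise UnorderedDatasetError(
                        f"coda {c.coda_id!r} lacks whale_id/onset_time in an "
                        "ordered dataset"
                    )
            onsets = [c.onset_time for c in self.codas]
            if any(b < a for a, b in zip(onsets, onsets[1:])):  # type: ignore[operator]
                raise UnorderedDatasetError("onset times are not non-decreasing")

    def __len__(self) -> int:
        return len(self.codas)

    def __iter__(self) -> Iterator[Coda]:
        return iter(self.codas)

    def __getitem__(self, i: int) -> Coda:
        return self.codas[i]

    def get(self, coda_id: str) -> Coda:
        for c in self.codas:
            if c.coda_id == coda_id:
                return c
        raise KeyError(coda_id)

    @property
    def whale_ids(self) -> list[str]:
        """Distinct whale ids in first-appearance order."""
        out: list[str] = []
        for c in self.codas:
            if c.whale_id is not None and c.whale_id not in out:
                out.append(c.whale_id)
        return out

    def by_whale(self) -> dict[str, list[Coda]]:
        """Codas grouped by whale, preserving dataset order."""
        groups: dict[str, list[Coda]] = {}
        for c in self.codas:
            if c.whale_id is None:
                continue
            groups.setdefault(c.whale_id, []).append(c)
        return groups

    def require_ordered(self, operation: str) -> None:
        if not self.ordered:
            raise UnorderedDatasetError(
                f"{operation} requires an ordered dataset with whale ids "
                "and onset times"
            )

    def subset(self, keep: Iterable[Coda]) -> "ExchangeDataset":
        keep_list = list(keep)
        return ExchangeDataset(keep_list, ordered=self.ordered,
                               metadata=dict(self.metadata))


def filter_clicks(dataset: ExchangeDataset,
                  max_clicks: int = MAX_ANALYSIS_CLICKS) -> ExchangeDataset:
    """Drop rare long codas with more than *max_clicks* clicks.

    Order is preserved; the number removed is logged.  ``max_clicks`` below
    2 would remove every possible coda and raises :class:`ParameterError`.
    """
    if max_clicks < 2:
        raise ParameterError(f"max_clicks must be >= 2, got {max_clicks}")
    kept = [c for c in dataset.codas if c.click_count <= max_clicks]
    removed = len(dataset) - len(kept)
    if removed:
        logger.info("filter_clicks: removed %d codas with > %d clicks",
                    removed, max_clicks)
    return dataset.subset(kept)
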