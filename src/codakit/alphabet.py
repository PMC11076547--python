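"""The coda "phonetic alphabet": rhythm x tempo with annotations.

Every typed coda occupies one cell of a rhythm x tempo matrix; per-cell
tallies of rubato (codas inside increasing/decreasing sequences vs
constant ones) and ornamentation show how the four features combine.
Counting the distinct (rhythm, tempo, ornamented, rubato-class)
combinations that occur at least ``min_count`` times gives the size of
the realised inventory, whose base-2 logarithm bounds the information a
single coda could carry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .discretization import DiscreteType
from .model import ExchangeDataset, ParameterError, logger

__all__ = [
    "AlphabetCell",
    "Alphabet",
    "build_alphabet",
    "count_realized",
    "realized_sweep",
    "capacity_bits",
    "feature_capacity",
]


@dataclass
class AlphabetCell:
    """Tallies for one rhythm x tempo combination."""

    rhythm_type: str
    tempo_type: int
    count: int = 0
    rubato_with: int = 0
    rubato_without: int = 0
    ornament_count: int = 0

    def validate(self) -> None:
        if min(self.count, self.rubato_with, self.rubato_without,
               self.ornament_count) < 0:
            raise ValueError("negative cell tally")
        if self.count < self.rubato_with or self.count < self.ornament_count:
            raise ValueError("cell tallies exceed cell count")


@dataclass
class Alphabet:
    """The full matrix plus the per-coda feature tuples behind it."""

    cells: dict[tuple[str, int], AlphabetCell]
    combos: list[tuple[str, int, bool, str]] = field(repr=False,
                                                     default_factory=list)
    n_typed: int = 0
    n_untyped: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(c) for c in sorted(
            self.cells.values(), key=lambda c: (c.tempo_type, c.rhythm_type))]
        return pd.DataFrame(rows, columns=[
            "rhythm_type", "tempo_type", "count",
            "rubato_with", "rubato_without", "ornament_count"])


def build_alphabet(dataset: ExchangeDataset,
                   types: dict[str, DiscreteType | None],
                   ornament_ids: set[str] | None = None,
                   rubato_class_by_coda: dict[str, str] | None = None,
                   ) -> Alphabet:
    """Tally every typed coda into its rhythm x tempo cell.

    ``rubato_class_by_coda`` maps a coda id to the rubato label of its
    call sequence ("increasing"/"decreasing"/"constant"); codas in
    increasing or decreasing sequences count as "with rubato".  Untyped
    codas are excluded and their number logged.
    """
    ornament_ids = ornament_ids or set()
    rubato_class_by_coda = rubato_class_by_coda or {}
    cells: dict[tuple[str, int], AlphabetCell] = {}
    combos: list[tuple[str, int, bool, str]] = []
    n_untyped = 0
    for coda in dataset:
        t = types.get(coda.coda_id)
        if t is None:
            n_untyped += 1
            continue
        key = (t.rhythm_type, t.tempo_type)
        cell = cells.setdefault(key, AlphabetCell(*key))
        cell.count += 1
        rub = rubato_class_by_coda.get(coda.coda_id, "constant")
        if rub in ("increasing", "decreasing"):
            cell.rubato_with += 1
        else:
            cell.rubato_without += 1
        orn = coda.coda_id in ornament_ids
        if orn:
            cell.ornament_count += 1
        combos.append((t.rhythm_type, t.tempo_type, orn, rub))
    if n_untyped:
        logger.info("build_alphabet: %d untyped codas excluded", n_untyped)
    for cell in cells.values():
        cell.validate()
    return Alphabet(cells=cells, combos=combos,
                    n_typed=len(dataset) - n_untyped, n_untyped=n_untyped)


def count_realized(alphabet: Alphabet, min_count: int = 5,
                   include_features: bool = True) -> int:
    """Number of feature combinations realised at least ``min_count`` times.

    With ``include_features=True`` a combination is the full tuple
    (rhythm, tempo, ornamented?, rubato class); otherwise just the
    rhythm x tempo cell.
    """
    tally: dict = {}
    for combo in alphabet.combos:
        key = combo if include_features else combo[:2]
        tally[key] = tally.get(key, 0) + 1
    return sum(1 for v in tally.values() if v >= min_count)


def realized_sweep(alphabet: Alphabet, thresholds=range(1, 21),
                   include_features: bool = True) -> pd.DataFrame:
    """Realised-combination count as a function of the count threshold."""
    rows = [{"min_count": m,
             "n_realized": count_realized(alphabet, m, include_features)}
            for m in thresholds]
    return pd.DataFrame(rows)


def capacity_bits(n_types: int) -> tuple[float, int]:
    """Information capacity of a repertoire of ``n_types`` symbols.

    Returns ``(log2(n_types), ceil(log2(n_types)))`` -- the exact rate in
    bits per coda and its whole-bit ceiling.
    """
    if n_types < 1:
        raise ParameterError("n_types must be >= 1")
    exact = math.log2(n_types)
    return exact, math.ceil(exact)


def feature_capacity(n_rhythm: int = 18, n_tempo: int = 5,
                     ornament_levels: int = 2,
                     rubato_levels: int = 3) -> float:
    """Capacity in bits if all feature combinations were realisable:
    log2 of the product of the factor cardinalities."""
    for v in (n_rhythm, n_tempo, ornament_levels, rubato_levels):
        if v < 1:
            raise ParameterError("all factor cardinalities must be >= 1")
    return math.log2(n_rhythm * n_tempo * ornament_levels * rubato_levels)
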