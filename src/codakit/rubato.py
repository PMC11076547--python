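"""Rubato: smooth, controlled modulation of coda duration.

Whales modulate the duration of successive codas gradually ("tempo
drift"), sustain the trend across several codas, and match their
interlocutors' durations when chorusing.  Three statistics establish
this against nulls in which duration depends only on a coda's discrete
(rhythm x tempo) type:

1. **Adjacent-drift test** -- the mean absolute drift between adjacent
   same-type codas of one whale is compared with random same-type pairs
   from the same whale (permutation test, one-sided: adjacent smaller).
2. **Triple correlation** -- over consecutive same-type coda triples,
   Spearman correlation between the first and second pairwise drifts
   (positive correlation = sustained trend).
3. **Chorus-matching test** -- the mean absolute duration difference of
   overlapping cross-whale pairs is compared with random non-overlapping
   same-type cross-whale pairs (one-sided: overlapping closer).

"Adjacent" here means consecutive codas of the *same* whale inside a
call sequence (8 s rule); the cross-whale 2 s turn-taking relation plays
no role in the drift test.

Both permutation tests use a within-pool shuffle as the null: coda
durations are resampled without replacement (permuted) among all codas
of the same discrete type -- and, for the drift test, the same whale --
and the observed statistic is recomputed over the unchanged pair
structure.  Durations are exchangeable within those pools under the
null hypothesis that duration depends only on discrete type, so the
test is exactly calibrated.  When ornament annotations are supplied,
drift and duration matching are measured on de-ornamented durations
(the ornament click is an independent feature, not part of the tempo).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .discretization import DiscreteType
from .model import Coda, ExchangeDataset, InsufficientDataError, ParameterError
from .segmentation import CallSequence, call_sequences, cross_whale_links
from .stats import TestResult, permutation_test, spearman_correlation

__all__ = [
    "DriftRecord",
    "RubatoClass",
    "tempo_drift",
    "adjacent_drift_test",
    "triple_correlation",
    "chorus_matching_test",
    "classify_rubato",
]

DEFAULT_RUBATO_THRESHOLD_S = 0.05


@dataclass(frozen=True)
class DriftRecord:
    """Signed duration change between two codas of one whale."""

    first_coda: str
    second_coda: str
    drift: float
    same_type: bool
    adjacent: bool


@dataclass(frozen=True)
class RubatoClass:
    """Per-sequence rubato label: increasing / decreasing / constant."""

    label: str
    threshold_s: float
    net_change_s: float


def tempo_drift(c1: Coda, c2: Coda) -> float:
    """Signed tempo drift: duration(c2) - duration(c1), in seconds."""
    return c2.duration - c1.duration


# --------------------------------------------------------------------------
# helpers


def _type_of(types: dict[str, DiscreteType | None], coda: Coda):
    return types.get(coda.coda_id)


def _sequence_runs(dataset: ExchangeDataset,
                   gap_s: float) -> list[list[Coda]]:
    """Codas of each call sequence, in order, as Coda objects."""
    seqs = call_sequences(dataset, gap_s=gap_s)
    return [[dataset.get(cid) for cid in s.coda_ids] for s in seqs]


def _base_duration(coda: Coda, ornament_ids: set[str]) -> float:
    """Coda duration with a detected ornament's final ICI removed."""
    if coda.coda_id in ornament_ids and coda.ici.size >= 2:
        return float(coda.ici[:-1].sum())
    return coda.duration


class _PooledPairs:
    """Observed pairs over per-pool duration slots, with a within-pool
    permutation resampler.

    Pools collect exchangeable codas (same discrete type, optionally
    same whale).  Each observed pair references two slots; a resample
    permutes every pool's durations and re-evaluates the mean absolute
    difference over the unchanged pair structure, i.e. it resamples
    durations without replacement under the null of within-pool
    exchangeability.
    """

    def __init__(self) -> None:
        self._slots: dict = {}          # pool key -> {coda_id: slot}
        self._durations: dict = {}      # pool key -> list of durations
        self._pairs: list = []          # (key_a, slot_a, key_b, slot_b)

    def add_coda(self, key, coda_id: str, duration: float) -> int:
        slots = self._slots.setdefault(key, {})
        if coda_id not in slots:
            slots[coda_id] = len(slots)
            self._durations.setdefault(key, []).append(duration)
        return slots[coda_id]

    def add_pair(self, key_a, slot_a: int, key_b, slot_b: int) -> None:
        self._pairs.append((key_a, slot_a, key_b, slot_b))

    @property
    def n_pairs(self) -> int:
        return len(self._pairs)

    def finalize(self):
        keys = sorted(self._durations, key=repr)
        sizes = [len(self._durations[k]) for k in keys]
        offsets = dict(zip(keys, np.concatenate(([0], np.cumsum(sizes)[:-1]))))
        values = np.concatenate([self._durations[k] for k in keys])
        ga = np.array([offsets[k] + s for k, s, _, _ in self._pairs])
        gb = np.array([offsets[k] + s for _, _, k, s in self._pairs])
        # only pools that pairs actually touch need permuting
        touched = sorted({k for k, _, _, _ in self._pairs}
                         | {k for _, _, k, _ in self._pairs}, key=repr)
        spans = [(offsets[k], offsets[k] + len(self._durations[k]))
                 for k in touched]

        observed = float(np.mean(np.abs(values[ga] - values[gb])))

        def null_statistic(rng: np.random.Generator) -> float:
            permuted = values.copy()
            for lo, hi in spans:
                permuted[lo:hi] = values[lo + rng.permutation(hi - lo)]
            return float(np.mean(np.abs(permuted[ga] - permuted[gb])))

        return observed, null_statistic


# --------------------------------------------------------------------------
# tests


def adjacent_drift_test(dataset: ExchangeDataset,
                        types: dict[str, DiscreteType | None],
                        n_resamples: int = 10_000,
                        seed: int | None = None,
                        gap_s: float = 8.0,
                        null_scope: str = "same_whale",
                        ornament_ids: set[str] | None = None) -> TestResult:
    """Is drift between adjacent same-type codas smaller than chance?

    Observed: mean |drift| over consecutive same-whale, same-type coda
    pairs within call sequences.  Null: durations permuted (resampled
    without replacement) among each whale's codas of that type across
    the whole dataset (``null_scope="same_whale"``; ``"any_whale"``
    pools across whales) with the pair structure fixed.  One-sided:
    observed smaller.
    """
    dataset.require_ordered("adjacent_drift_test")
    if null_scope not in ("same_whale", "any_whale"):
        raise ParameterError(f"unknown null_scope {null_scope!r}")
    orn = ornament_ids or set()

    def key(c: Coda):
        t = _type_of(types, c)
        return (c.whale_id, t) if null_scope == "same_whale" else (t,)

    pooled = _PooledPairs()
    for c in dataset:
        if _type_of(types, c) is not None:
            pooled.add_coda(key(c), c.coda_id, _base_duration(c, orn))
    for run in _sequence_runs(dataset, gap_s):
        for a, b in zip(run, run[1:]):
            ta, tb = _type_of(types, a), _type_of(types, b)
            if ta is not None and ta == tb:
                pooled.add_pair(key(a), pooled.add_coda(key(a), a.coda_id, 0),
                                key(b), pooled.add_coda(key(b), b.coda_id, 0))
    if pooled.n_pairs == 0:
        raise InsufficientDataError("no adjacent same-type coda pairs")

    observed, null_statistic = pooled.finalize()
    return permutation_test(
        observed, null_statistic,
        n_resamples=n_resamples, alternative="less", seed=seed,
        method="adjacent_drift_permutation", n=pooled.n_pairs,
    )


def triple_correlation(dataset: ExchangeDataset,
                       types: dict[str, DiscreteType | None],
                       gap_s: float = 8.0,
                       ornament_ids: set[str] | None = None) -> TestResult:
    """Spearman correlation of consecutive drifts over same-type triples.

    For every run of three consecutive same-whale, same-type codas inside
    a call sequence, correlates drift(c1,c2) with drift(c2,c3);
    two-sided p.
    """
    dataset.require_ordered("triple_correlation")
    orn = ornament_ids or set()
    d12, d23 = [], []
    for run in _sequence_runs(dataset, gap_s):
        for a, b, c in zip(run, run[1:], run[2:]):
            ta = _type_of(types, a)
            if ta is not None and ta == _type_of(types, b) == _type_of(types, c):
                da, db, dc = (_base_duration(x, orn) for x in (a, b, c))
                d12.append(db - da)
                d23.append(dc - db)
    if len(d12) < 10:
        raise InsufficientDataError(
            f"only {len(d12)} same-type triples; need >= 10")
    res = spearman_correlation(d12, d23)
    return TestResult(method="triple_drift_spearman", observed=res.observed,
                      p_value=res.p_value, n=res.n, alternative="two-sided")


def chorus_matching_test(dataset: ExchangeDataset,
                         types: dict[str, DiscreteType | None],
                         n_resamples: int = 10_000,
                         seed: int | None = None,
                         turn_window_s: float = 2.0,
                         ornament_ids: set[str] | None = None) -> TestResult:
    """Do overlapping codas match durations beyond shared type?

    Observed: mean |duration difference| over overlapping cross-whale
    pairs.  Null: durations permuted (resampled without replacement)
    among all codas of the same discrete type -- any whale, overlapping
    or not -- with the pair structure fixed, embodying the hypothesis
    that chorusing whales match only discrete coda type.  One-sided:
    observed smaller.  Codas whose type is unassigned keep their own
    duration (singleton pools).
    """
    dataset.require_ordered("chorus_matching_test")
    orn = ornament_ids or set()
    overlaps = [l for l in cross_whale_links(dataset, turn_window_s)
                if l.relation == "overlapping"]
    if not overlaps:
        raise InsufficientDataError("no overlapping cross-whale pairs")

    def key(c: Coda):
        t = _type_of(types, c)
        return t if t is not None else ("untyped", c.coda_id)

    pooled = _PooledPairs()
    for c in dataset:
        pooled.add_coda(key(c), c.coda_id, _base_duration(c, orn))
    for link in overlaps:
        a = dataset.get(link.first_coda)
        b = dataset.get(link.second_coda)
        pooled.add_pair(key(a), pooled.add_coda(key(a), a.coda_id, 0),
                        key(b), pooled.add_coda(key(b), b.coda_id, 0))

    observed, null_statistic = pooled.finalize()
    return permutation_test(
        observed, null_statistic,
        n_resamples=n_resamples, alternative="less", seed=seed,
        method="chorus_matching_permutation", n=pooled.n_pairs,
    )


def classify_rubato(sequence: CallSequence, dataset: ExchangeDataset,
                    threshold_s: float = DEFAULT_RUBATO_THRESHOLD_S,
                    types: dict[str, DiscreteType | None] | None = None,
                    ) -> RubatoClass | None:
    """Label a call sequence's rubato as increasing/decreasing/constant.

    The net duration change from the sequence's first to last coda is
    compared with ``threshold_s``.  If *types* is given, only codas of
    the sequence's modal discrete type are considered (rubato is defined
    within a type).  Returns None when fewer than two qualifying codas
    remain.
    """
    codas = [dataset.get(cid) for cid in sequence.coda_ids]
    if types is not None:
        typed = [c for c in codas if _type_of(types, c) is not None]
        if not typed:
            return None
        tally: dict = {}
        for c in typed:
            tally[_type_of(types, c)] = tally.get(_type_of(types, c), 0) + 1
        modal = max(sorted(tally, key=repr), key=lambda t: tally[t])
        codas = [c for c in typed if _type_of(types, c) == modal]
    if len(codas) < 2:
        return None
    net = codas[-1].duration - codas[0].duration
    if net > threshold_s:
        label = "increasing"
    elif net < -threshold_s:
        label = "decreasing"
    else:
        label = "constant"
    return RubatoClass(label=label, threshold_s=threshold_s, net_change_s=net)
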