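"""Ornaments: extra final clicks and the tests that validate them.

An **ornament** is the final click of a coda that contains exactly one
more click than the nearest preceding or following coda within a ten
second window (about twice the average response time).  Four analyses
establish ornaments as an independent feature rather than noise:

1. **Centroid-MSE test** -- with the ornament retained, the coda is
   compared (mean squared distance on standardised ICIs) with the
   centroid of its own assigned rhythm type; with the ornament removed,
   with the centroids of same-whale adjacent codas' rhythm types.  A
   one-sided paired permutation test asks whether the ornament-removed
   distance is smaller.
2. **Final-ICI test** -- the statistic (last ICI - penultimate ICI) /
   penultimate ICI is compared between ornamented and unornamented codas
   of the same click counts (two-sample Kolmogorov-Smirnov).
3. **Positional tests** -- Fisher's exact tests for enrichment of
   ornaments at the first and at the last position of call sequences.
4. **Chorus-change test** -- Fisher's exact test for whether a leading
   whale's ornamented codas are disproportionately followed by a change
   in the follower's chorusing behaviour (begins chorusing, pauses, or
   ceases vocalising).

"Pauses chorusing" is operationalised as: the follower's next coda comes
more than the call-sequence gap (8 s) after the leader's coda ends, but
the follower vocalises again later; "ceases" means no further follower
codas in the recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discretization import (
    DiscreteType,
    RhythmModel,
    assign_rhythm,
    rhythm_distance,
)
from .model import Coda, ExchangeDataset, InsufficientDataError
from .segmentation import Chorus, call_sequences, choruses, leader_follower
from .stats import TestResult, fisher_exact, ks_two_sample, permutation_test

__all__ = [
    "OrnamentRecord",
    "detect_ornaments",
    "ornament_fraction",
    "ornament_centroid_test",
    "final_ici_stat",
    "final_ici_ks_test",
    "positional_tests",
    "chorus_change_test",
]

DEFAULT_ORNAMENT_WINDOW_S = 10.0


@dataclass(frozen=True)
class OrnamentRecord:
    """A detected ornament: the flagged coda and its comparison coda."""

    coda_id: str
    comparison_coda_id: str
    ornament_click_index: int  # position of the extra (final) click
    window_s: float


def _nearest_neighbours(i: int, codas: list[Coda], window_s: float,
                        scope: str) -> list[Coda]:
    """Nearest preceding and nearest following coda within the window.

    Symmetric in time: reversing the time axis swaps the two roles but
    selects the same pair of neighbours.
    """
    me = codas[i]
    before: Coda | None = None
    after: Coda | None = None
    d_before = d_after = np.inf
    for j, other in enumerate(codas):
        if j == i:
            continue
        if scope == "same_whale" and other.whale_id != me.whale_id:
            continue
        d = abs(other.onset_time - me.onset_time)  # type: ignore[operator]
        if d > window_s:
            continue
        if other.onset_time < me.onset_time or (  # type: ignore[operator]
                other.onset_time == me.onset_time and j < i):
            if d < d_before:
                before, d_before = other, d
        elif d < d_after:
            after, d_after = other, d
    return [nb for nb in (before, after) if nb is not None]


def detect_ornaments(dataset: ExchangeDataset,
                     window_s: float = DEFAULT_ORNAMENT_WINDOW_S,
                     scope: str = "same_whale",
                     refine: bool = True) -> list[OrnamentRecord]:
    """Flag codas with one more click than a nearest neighbouring coda.

    A coda is ornamented when it contains exactly one more click than
    the nearest preceding or the nearest following coda within the
    window (either side qualifies, so a run of two ornamented codas is
    still recognised from its far sides).  With ``refine=True`` the rule
    is iterated to a fixed point using neighbours' *de-ornamented* click
    counts, so an ornamented coda standing next to an already-flagged
    one is still caught.  *scope* restricts candidate neighbours to the
    same whale (default; an ornament is defined against the caller's own
    pattern) or to any whale (``"any_whale"``).
    """
    dataset.require_ordered("detect_ornaments")
    if scope not in ("same_whale", "any_whale"):
        raise ValueError(f"unknown scope {scope!r}")
    codas = dataset.codas
    flagged: dict[str, OrnamentRecord] = {}
    for _ in range(10):  # fixed point reached in a couple of passes
        changed = False
        for i, coda in enumerate(codas):
            if coda.coda_id in flagged:
                continue
            for nb in _nearest_neighbours(i, codas, window_s, scope):
                nb_clicks = nb.click_count - (1 if nb.coda_id in flagged else 0)
                if coda.click_count == nb_clicks + 1:
                    flagged[coda.coda_id] = OrnamentRecord(
                        coda_id=coda.coda_id,
                        comparison_coda_id=nb.coda_id,
                        ornament_click_index=coda.click_count - 1,
                        window_s=window_s,
                    )
                    changed = True
                    break
        if not changed or not refine:
            break
    order = {c.coda_id: i for i, c in enumerate(codas)}
    return sorted(flagged.values(), key=lambda r: order[r.coda_id])


def ornament_fraction(dataset: ExchangeDataset,
                      records: list[OrnamentRecord]) -> float:
    """Fraction of the dataset's codas flagged as ornamented."""
    if len(dataset) == 0:
        return 0.0
    return len(records) / len(dataset)


# --------------------------------------------------------------------------
# centroid-MSE test


def ornament_centroid_test(dataset: ExchangeDataset,
                           rhythm_model: RhythmModel,
                           types: dict[str, DiscreteType | None],
                           records: list[OrnamentRecord],
                           n_resamples: int = 10_000,
                           seed: int | None = None,
                           gap_s: float = 8.0) -> TestResult:
    """Do ornamented codas match their neighbours once de-ornamented?

    For each ornamented coda with at least one same-whale adjacent coda
    (its neighbours within the call sequence):

    * A -- MSE between the standardised coda (ornament retained) and the
      centroid of its own assigned rhythm type;
    * B -- MSE between the standardised, ornament-removed coda and the
      centroids of its adjacent codas' rhythm types (averaged).

    The one-sided permutation p tests mean(B) < mean(A) by randomly
    swapping the A/B labels within pairs.  ``observed`` is mean(B) and
    ``null_value`` the permutation-null mean; the per-pair values are
    attached for reporting.
    """
    seqs = call_sequences(dataset, gap_s=gap_s)
    neighbour_map: dict[str, list[str]] = {}
    for s in seqs:
        ids = list(s.coda_ids)
        for k, cid in enumerate(ids):
            nbs = []
            if k > 0:
                nbs.append(ids[k - 1])
            if k + 1 < len(ids):
                nbs.append(ids[k + 1])
            neighbour_map[cid] = nbs

    a_vals, b_vals = [], []
    for rec in records:
        coda = dataset.get(rec.coda_id)
        if coda.ici.size < 2:
            continue
        # quantity A treats the ornament as an ordinary click: the full
        # coda is assigned a rhythm type at its raw click count
        own_rid = assign_rhythm(coda, rhythm_model)
        if own_rid is None:
            continue
        nb_ids = neighbour_map.get(coda.coda_id, [])
        nb_types = [types.get(nid) for nid in nb_ids]
        nb_types = [t for t in nb_types if t is not None]
        if not nb_types:
            continue
        a = rhythm_distance(coda, rhythm_model.centroids[own_rid],
                            rhythm_model.distance)
        trunc = coda.drop_final_click()
        b_parts = []
        for t in nb_types:
            centroid = rhythm_model.centroids[t.rhythm_type]
            if centroid.size == trunc.ici.size:
                b_parts.append(rhythm_distance(trunc, centroid,
                                               rhythm_model.distance))
        if not b_parts:
            continue
        a_vals.append(a)
        b_vals.append(float(np.mean(b_parts)))

    if not a_vals:
        raise InsufficientDataError(
            "no ornamented codas with usable same-whale adjacent codas")
    a_arr, b_arr = np.asarray(a_vals), np.asarray(b_vals)
    observed = float(b_arr.mean())

    def null_stat(rng: np.random.Generator) -> float:
        flip = rng.random(a_arr.size) < 0.5
        return float(np.where(flip, a_arr, b_arr).mean())

    res = permutation_test(observed, null_stat, n_resamples=n_resamples,
                           alternative="less", seed=seed,
                           method="ornament_centroid_permutation",
                           n=a_arr.size)
    # report mean(B) as the statistic and mean(A) as the reference value
    return TestResult(method=res.method, observed=observed,
                      p_value=res.p_value, n=res.n, alternative="less",
                      null_value=float(a_arr.mean()),
                      n_resamples=n_resamples, seed=seed)


# --------------------------------------------------------------------------
# final-ICI distribution


def final_ici_stat(coda: Coda) -> float:
    """(last ICI - penultimate ICI) / penultimate ICI.

    Defined for codas with at least three ICIs; invariant to uniform
    time-scaling, which removes most rubato-driven variance.
    """
    if coda.ici.size < 3:
        raise InsufficientDataError(
            f"coda {coda.coda_id!r}: final-ICI statistic needs >= 3 ICIs")
    return float((coda.ici[-1] - coda.ici[-2]) / coda.ici[-2])


def final_ici_ks_test(dataset: ExchangeDataset,
                      records: list[OrnamentRecord]) -> TestResult:
    """KS test of the final-ICI statistic, ornamented vs unornamented.

    Unornamented codas are restricted to the click counts seen among the
    ornamented ones, so the groups are compared like for like.
    """
    flagged = {r.coda_id for r in records}
    orn_counts = {dataset.get(cid).click_count for cid in flagged}
    orn, plain = [], []
    for coda in dataset:
        if coda.ici.size < 3:
            continue
        if coda.coda_id in flagged:
            orn.append(final_ici_stat(coda))
        elif coda.click_count in orn_counts:
            plain.append(final_ici_stat(coda))
    if not orn or not plain:
        raise InsufficientDataError("need both ornamented and unornamented codas")
    return ks_two_sample(orn, plain)


# --------------------------------------------------------------------------
# position within call sequences


def positional_tests(dataset: ExchangeDataset,
                     records: list[OrnamentRecord],
                     gap_s: float = 8.0,
                     include_singletons: bool = False,
                     ) -> tuple[TestResult, TestResult]:
    """Fisher tests for ornament enrichment at sequence boundaries.

    Builds two 2x2 tables over codas in call sequences (singleton
    sequences excluded by default): ornamented x sequence-initial and
    ornamented x sequence-final.  Returns (initial, final) results.
    """
    flagged = {r.coda_id for r in records}
    tables = {"initial": np.zeros((2, 2), dtype=int),
              "final": np.zeros((2, 2), dtype=int)}
    for s in call_sequences(dataset, gap_s=gap_s):
        if len(s) < 2 and not include_singletons:
            continue
        for k, cid in enumerate(s.coda_ids):
            is_orn = cid in flagged
            at = {"initial": k == 0, "final": k == len(s.coda_ids) - 1}
            for which, here in at.items():
                tables[which][0 if is_orn else 1][0 if here else 1] += 1
    out = []
    for which in ("initial", "final"):
        res = fisher_exact(tables[which])
        out.append(TestResult(method=f"ornament_{which}_{res.method}",
                              observed=res.observed, p_value=res.p_value,
                              n=res.n, alternative="two-sided"))
    return out[0], out[1]


# --------------------------------------------------------------------------
# chorus-change prediction


def _follower_change(leader_coda: Coda, follower_codas: list[Coda],
                     turn_window_s: float, gap_s: float) -> bool:
    """Did the follower's chorusing behaviour change after this coda?

    ``follower_codas`` is the follower's full timeline in the recording.
    Change = begins chorusing (the follower answers this coda after
    having been silent for more than ``gap_s``), pauses (the follower's
    next coda comes more than ``gap_s`` after this coda ends but it
    resumes later in the recording), or ceases (no further follower
    codas in the recording).
    """
    t_end = leader_coda.termination
    before = [c for c in follower_codas
              if c.onset_time < leader_coda.onset_time]  # type: ignore[operator]
    after = [c for c in follower_codas
             if c.onset_time >= leader_coda.onset_time]  # type: ignore[operator]
    if not after:
        return True  # ceases vocalising for the remainder of the recording
    answers_now = after[0].onset_time < t_end + turn_window_s  # type: ignore[operator]
    silent_before = (not before
                     or leader_coda.onset_time - before[-1].termination > gap_s)  # type: ignore[operator]
    if answers_now and silent_before:
        return True  # begins chorusing
    gap_to_next = after[0].onset_time - t_end  # type: ignore[operator]
    return gap_to_next > gap_s  # pauses, resumes later


def chorus_change_test(dataset: ExchangeDataset,
                       records: list[OrnamentRecord],
                       turn_window_s: float = 2.0,
                       gap_s: float = 8.0) -> TestResult:
    """Do a leader's ornamented codas precede follower behaviour changes?

    For every chorus with an identified leader and follower, each leader
    coda is scored for whether the follower's chorusing behaviour
    changes next; Fisher's exact test compares ornamented vs
    unornamented leader codas.
    """
    flagged = {r.coda_id for r in records}
    table = np.zeros((2, 2), dtype=int)
    n_leader_codas = 0
    # merge link-choruses separated by less than the sequence gap into
    # exchanges: a leader coda left unanswered (e.g. because the follower
    # fell silent) still belongs to the surrounding exchange and must be
    # scored, or silence-inducing codas would select themselves out
    merged: list[list[Chorus]] = []
    for chorus in choruses(dataset, turn_window_s):
        if merged and chorus.start - merged[-1][-1].end <= gap_s:
            merged[-1].append(chorus)
        else:
            merged.append([chorus])
    for group in merged:
        exchange = Chorus(
            start=group[0].start,
            end=max(ch.end for ch in group),
            whale_ids=frozenset().union(*(ch.whale_ids for ch in group)),
            coda_ids=tuple(cid for ch in group for cid in ch.coda_ids),
            links=tuple(l for ch in group for l in ch.links),
        )
        roles = leader_follower(exchange, dataset)
        leaders = [w for w, r in roles.items() if r == "leader"]
        followers = [w for w, r in roles.items() if r == "follower"]
        if len(leaders) != 1 or not followers:
            continue
        follower_codas = [c for c in dataset.codas
                          if c.whale_id in followers]
        # a coda that silences the follower extends past the last linked
        # coda, so the scoring window runs one sequence gap beyond the end
        for coda in dataset.codas:
            if (coda.whale_id != leaders[0]
                    or not (exchange.start <= coda.onset_time  # type: ignore[operator]
                            <= exchange.end + gap_s)):
                continue
            n_leader_codas += 1
            change = _follower_change(coda, follower_codas,
                                      turn_window_s, gap_s)
            table[0 if coda.coda_id in flagged else 1][0 if change else 1] += 1
    if n_leader_codas == 0:
        raise InsufficientDataError("no leader codas in any chorus")
    res = fisher_exact(table)
    return TestResult(method=f"chorus_change_{res.method}",
                      observed=res.observed, p_value=res.p_value,
                      n=n_leader_codas, alternative="two-sided")
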