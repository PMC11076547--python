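"""Conversational structure of multi-whale exchanges.

Ordered datasets are segmented along two axes:

* **call sequences** -- maximal runs of one whale's codas in which every
  consecutive pair falls within an 8 s gap (twice the average ~4 s
  response time);
* **pairwise links** between codas -- a later coda is *overlapping* if its
  onset falls inside the earlier coda, *adjacent* (turn-taking) if its
  onset falls within 2 s after the earlier coda's termination, and
  unrelated otherwise.

A *chorus* is a maximal episode in which at least two whales' codas are
tied together by cross-whale links; within each linked cross-whale pair
the earlier-onset whale is the *leader*, and a whale's chorus-level role
is its modal pairwise role.

Boundary conventions: gaps are measured onset-to-onset by default
(``anchor="termination"`` switches to termination-to-onset); an onset
exactly at the earlier termination is adjacent with gap 0; a gap of
exactly the turn window is still adjacent (closed interval).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .model import Coda, ExchangeDataset, ParameterError

__all__ = [
    "CallSequence",
    "CodaPairLink",
    "Chorus",
    "call_sequences",
    "classify_pair",
    "cross_whale_links",
    "choruses",
    "leader_follower",
]

#: Simultaneity tolerance below which leader/follower roles are undefined.
ROLE_TIE_TOLERANCE_S = 1e-3


@dataclass(frozen=True)
class CallSequence:
    """A maximal single-whale run of codas under the gap rule."""

    whale_id: str
    coda_ids: tuple[str, ...]
    start: float
    end: float

    def __len__(self) -> int:
        return len(self.coda_ids)


@dataclass(frozen=True)
class CodaPairLink:
    """Temporal relation between an ordered pair of codas."""

    first_coda: str
    second_coda: str
    relation: str  # "overlapping" | "adjacent" | "none"
    gap: float  # second onset - first termination (negative if overlapping)


@dataclass(frozen=True)
class Chorus:
    """A maximal multi-whale episode of linked codas."""

    start: float
    end: float
    whale_ids: frozenset[str]
    coda_ids: tuple[str, ...]
    links: tuple[CodaPairLink, ...] = field(repr=False, default=())


def call_sequences(dataset: ExchangeDataset, gap_s: float = 8.0,
                   anchor: str = "onset") -> list[CallSequence]:
    """Partition each whale's codas into maximal call sequences.

    Consecutive codas of one whale belong to the same sequence when their
    gap is at most *gap_s* seconds.  With ``anchor="onset"`` the gap is the
    difference of onsets; with ``anchor="termination"`` it is the later
    onset minus the earlier termination.
    """
    dataset.require_ordered("call_sequences")
    if anchor not in ("onset", "termination"):
        raise ParameterError(f"unknown anchor {anchor!r}")
    if gap_s <= 0:
        raise ParameterError("gap_s must be positive")

    sequences: list[CallSequence] = []
    for whale, codas in dataset.by_whale().items():
        run: list[Coda] = []
        for coda in codas:
            if run:
                prev = run[-1]
                ref = prev.onset_time if anchor == "onset" else prev.termination
                if coda.onset_time - ref > gap_s:  # type: ignore[operator]
                    sequences.append(_seal(whale, run))
                    run = []
            run.append(coda)
        if run:
            sequences.append(_seal(whale, run))
    sequences.sort(key=lambda s: s.start)
    return sequences


def _seal(whale: str, run: list[Coda]) -> CallSequence:
    return CallSequence(
        whale_id=whale,
        coda_ids=tuple(c.coda_id for c in run),
        start=run[0].onset_time,  # type: ignore[arg-type]
        end=run[-1].termination,
    )


def classify_pair(first: Coda, second: Coda,
                  turn_window_s: float = 2.0) -> CodaPairLink:
    """Classify the relation of *second* (the later onset) to *first*.

    Exactly one of ``overlapping``/``adjacent``/``none`` is assigned; see
    the module docstring for the boundary conventions.
    """
    if second.onset_time < first.onset_time:  # type: ignore[operator]
        raise ValueError("classify_pair expects second onset >= first onset")
    gap = second.onset_time - first.termination  # type: ignore[operator]
    if gap < 0 and second.onset_time > first.onset_time:  # type: ignore[operator]
        relation = "overlapping"
    elif 0 <= gap <= turn_window_s:
        relation = "adjacent"
    else:
        relation = "none"
    return CodaPairLink(first.coda_id, second.coda_id, relation, gap)


def cross_whale_links(dataset: ExchangeDataset,
                      turn_window_s: float = 2.0) -> list[CodaPairLink]:
    """All overlapping/adjacent links between codas of *different* whales."""
    dataset.require_ordered("cross_whale_links")
    codas = dataset.codas
    links: list[CodaPairLink] = []
    for i, first in enumerate(codas):
        horizon = first.termination + turn_window_s
        for second in codas[i + 1:]:
            if second.onset_time > horizon:  # type: ignore[operator]
                break
            if second.whale_id == first.whale_id:
                continue
            link = classify_pair(first, second, turn_window_s)
            if link.relation != "none":
                links.append(link)
    return links


def choruses(dataset: ExchangeDataset,
             turn_window_s: float = 2.0) -> list[Chorus]:
    """Maximal multi-whale episodes: connected components of the
    cross-whale link graph that involve at least two whales."""
    dataset.require_ordered("choruses")
    links = cross_whale_links(dataset, turn_window_s)

    parent: dict[str, str] = {c.coda_id: c.coda_id for c in dataset.codas}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for link in links:
        ra, rb = find(link.first_coda), find(link.second_coda)
        if ra != rb:
            parent[rb] = ra

    components: dict[str, list[Coda]] = {}
    for coda in dataset.codas:
        components.setdefault(find(coda.coda_id), []).append(coda)

    out: list[Chorus] = []
    for members in components.values():
        whales = {c.whale_id for c in members}
        if len(whales) < 2:
            continue
        ids = {c.coda_id for c in members}
        out.append(Chorus(
            start=min(c.onset_time for c in members),  # type: ignore[type-var]
            end=max(c.termination for c in members),
            whale_ids=frozenset(whales),  # type: ignore[arg-type]
            coda_ids=tuple(c.coda_id for c in members),
            links=tuple(l for l in links
                        if l.first_coda in ids and l.second_coda in ids),
        ))
    out.sort(key=lambda ch: ch.start)
    return out


def leader_follower(chorus: Chorus,
                    dataset: ExchangeDataset) -> dict[str, str]:
    """Chorus-level roles: each whale's modal pairwise role.

    Within every linked cross-whale pair the earlier-onset whale leads.
    Pairs whose onsets coincide within :data:`ROLE_TIE_TOLERANCE_S` are
    excluded; whales with equally many lead and follow pairs, or a
    single-whale interval, get no role.
    """
    lead_counts: Counter[str] = Counter()
    follow_counts: Counter[str] = Counter()
    for link in chorus.links:
        first = dataset.get(link.first_coda)
        second = dataset.get(link.second_coda)
        dt = second.onset_time - first.onset_time  # type: ignore[operator]
        if abs(dt) < ROLE_TIE_TOLERANCE_S:
            continue
        lead_counts[first.whale_id] += 1  # type: ignore[index]
        follow_counts[second.whale_id] += 1  # type: ignore[index]

    roles: dict[str, str] = {}
    for whale in chorus.whale_ids:
        leads, follows = lead_counts[whale], follow_counts[whale]
        if leads > follows:
            roles[whale] = "leader"
        elif follows > leads:
            roles[whale] = "follower"
    return roles
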