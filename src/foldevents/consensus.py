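"""Replicate consensus calling, concurrency grouping, and lagged-pair mining."""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

from foldevents.events import Event, EventTable, LaggedPair


def _lower_median(values: Sequence[int]) -> int:
    xs = sorted(values)
    return xs[(len(xs) - 1) // 2]


def _overlaps(a: Event, b: Event, tol: int) -> bool:
    """True when b's interval, padded by tol, overlaps a's interval."""
    return b.start_length - tol <= a.end_length and a.start_length <= b.end_length + tol


def _best_match(e: Event, table: EventTable, tol: int) -> Event | None:
    candidates = [
        c
        for c in table
        if c.nucleotide == e.nucleotide
        and c.class_ == e.class_
        and c.direction == e.direction
        and _overlaps(e, c, tol)
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda c: (abs(c.start_length - e.start_length), c.start_length))


def consensus(tables: Sequence[EventTable], tol: int = 3) -> EventTable:
    """Keep only events supported, within ``tol`` lengths, by every replicate.

    An event from the first replicate is retained iff each other replicate
    holds an event of the same nucleotide, class, and direction whose
    interval padded by ``tol`` overlaps it.  The consensus interval takes
    the lower median of the matched starts and ends; the magnitude is the
    mean of matched magnitudes.
    """
    if not tables:
        raise ValueError("consensus requires at least one event table")
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if len(tables) == 1:
        return tables[0].with_events(
            replace(e, n_replicates_supporting=1) for e in tables[0]
        )
    out: list[Event] = []
    for e in tables[0]:
        matched = [e]
        for other in tables[1:]:
            m = _best_match(e, other, tol)
            if m is None:
                break
            matched.append(m)
        if len(matched) < len(tables):
            continue
        start = _lower_median([m.start_length for m in matched])
        end = _lower_median([m.end_length for m in matched])
        end = max(end, start)  # medians of starts/ends can cross on odd overlaps
        magnitude = sum(m.magnitude for m in matched) / len(matched)
        out.append(
            Event(
                nucleotide=e.nucleotide,
                class_=e.class_,
                direction=e.direction,
                start_length=start,
                end_length=end,
                magnitude=magnitude,
                n_replicates_supporting=len(tables),
                category=e.category,
            )
        )
    return EventTable(out).sorted()


def group_concurrent(t: EventTable, max_start_gap: int = 2) -> EventTable:
    """Label connected components of events with near-coincident onsets.

    Two events (any nucleotides, any class) connect when they share a
    direction and their start lengths differ by at most ``max_start_gap``.
    Components of size >= 2 receive ids ``g1, g2, ...`` ordered by
    (earliest start, smallest nucleotide); singletons get no id.
    """
    events = sorted(t.events, key=lambda e: e.sort_key)
    n = len(events)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(n):
        for j in range(i + 1, n):
            if events[i].direction != events[j].direction:
                continue
            if abs(events[i].start_length - events[j].start_length) <= max_start_gap:
                union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)
    multi = [
        sorted(idx)
        for idx in components.values()
        if len(idx) >= 2
    ]
    multi.sort(key=lambda idx: (min(events[i].start_length for i in idx),
                                min(events[i].nucleotide for i in idx)))
    labels: dict[int, str] = {}
    for g, idx in enumerate(multi, start=1):
        for i in idx:
            labels[i] = f"g{g}"
    out = [replace(e, group_id=labels.get(i)) for i, e in enumerate(events)]
    return t.with_events(out)


def find_lagged_pairs(
    t: EventTable, min_lag: int = 8, max_lag: int = 16
) -> list[LaggedPair]:
    """Mine upswing-then-downswing pairs at the same nucleotide.

    For each downswing (ascending start order), the nearest preceding
    unconsumed upswing with lag in ``[min_lag, max_lag]`` is paired; ties
    on distance take the earlier upswing.  Each event joins at most one
    pair.
    """
    if min_lag <= 0 or max_lag < min_lag:
        raise ValueError("need 0 < min_lag <= max_lag")
    pairs: list[LaggedPair] = []
    swings = [e for e in t if e.class_ == "swing"]
    by_nuc: dict[int, list[Event]] = {}
    for e in swings:
        by_nuc.setdefault(e.nucleotide, []).append(e)
    for nuc in sorted(by_nuc):
        ups = sorted(
            (e.start_length for e in by_nuc[nuc] if e.direction == "up")
        )
        downs = sorted(
            (e.start_length for e in by_nuc[nuc] if e.direction == "down")
        )
        used: set[int] = set()
        for d in downs:
            candidates = [
                (d - u, i, u)
                for i, u in enumerate(ups)
                if i not in used and min_lag <= d - u <= max_lag
            ]
            if not candidates:
                continue
            _, i, u = min(candidates)  # nearest up; equal-lag tie -> earlier up
            used.add(i)
            pairs.append(LaggedPair(nucleotide=nuc, up_start=u, down_start=d))
    return pairs


def write_lagged_pairs(pairs: Sequence[LaggedPair], path) -> None:
    """TSV with columns nucleotide, up_start, down_start, lag."""
    with open(path, "w") as fh:
        fh.write("nucleotide\tup_start\tdown_start\tlag\n")
        for p in sorted(pairs, key=lambda p: (p.nucleotide, p.up_start)):
            fh.write(f"{p.nucleotide}\t{p.up_start}\t{p.down_start}\t{p.lag}\n")
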