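"""Ground-truth reactivity simulation and benchmark scoring.

A :class:`StructureTrajectory` records the pairing state of every
nucleotide at every transcript length.  The simulator draws per-cell
reactivities from per-state gamma distributions, averages many draws,
and renormalizes each transcript-length row to mean 1 -- emulating the
per-length normalization of rho reactivities.  The trailing ``footprint``
nucleotides of every transcript are forced to the paired distribution to
mimic polymerase protection.

Ground-truth events follow from state changes down each column:
a drop in expected reactivity is a ``down`` event, a rise an ``up``
event.  Each truth event carries a ``category``:

* ``footprint_exit`` -- the position leaves the polymerase footprint and
  becomes unpaired (expected upswing),
* ``pairing`` -- unpaired -> paired/helix-end (expected downswing),
* ``unpairing`` -- paired/helix-end -> unpaired (expected upswing);

categories involving a helix end are suffixed ``:helix_end``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from foldevents.events import Event, EventTable
from foldevents.io import ReactivityMatrix

logger = logging.getLogger(__name__)

UNPAIRED, PAIRED, HELIX_END, FOOTPRINT, ABSENT = 0, 1, 2, 3, -1
STATE_NAMES = {
    UNPAIRED: "unpaired",
    PAIRED: "paired",
    HELIX_END: "helix_end",
    FOOTPRINT: "footprint",
    ABSENT: "absent",
}
DEFAULT_FOOTPRINT = 14

SCENARIOS = (
    "hairpin_formation",
    "hairpin_rearrangement",
    "static_unpaired",
    "static_paired",
    "custom",
)


@dataclass(frozen=True)
class TernaryModelParams:
    """Gamma sampling parameters per pairing state.

    ``footprint`` cells are drawn from the paired distribution.  Means
    must be ordered unpaired > helix_end > paired.
    """

    unpaired_mean: float = 1.5
    helix_end_mean: float = 1.0
    paired_mean: float = 0.05
    shape: float = 1.0
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.unpaired_mean > self.helix_end_mean > self.paired_mean > 0:
            raise ValueError("state means must satisfy unpaired > helix_end > paired > 0")
        if self.shape <= 0:
            raise ValueError("shape must be > 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def mean_of(self, state: int) -> float:
        if state in (PAIRED, FOOTPRINT):
            return self.paired_mean
        if state == HELIX_END:
            return self.helix_end_mean
        if state == UNPAIRED:
            return self.unpaired_mean
        raise ValueError(f"no sampling distribution for state {state}")


@dataclass
class StructureTrajectory:
    """Pairing state per (transcript length, nucleotide position).

    ``state[i, j]`` holds the state of position ``j + 1`` at length
    ``lengths[i]``; positions beyond the transcript are ``ABSENT`` and
    the trailing ``footprint`` positions of each transcript are
    ``FOOTPRINT``.
    """

    lengths: np.ndarray
    n_positions: int
    state: np.ndarray
    footprint: int = DEFAULT_FOOTPRINT
    truth: EventTable = field(default_factory=EventTable)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=int)
        self.state = np.asarray(self.state, dtype=np.int8)
        if self.state.shape != (self.lengths.size, self.n_positions):
            raise ValueError("state grid shape mismatch")
        if np.any(np.diff(self.lengths) <= 0):
            raise ValueError("lengths must be strictly increasing")
        pos = np.arange(1, self.n_positions + 1)
        absent = pos[None, :] > self.lengths[:, None]
        if not np.array_equal(self.state == ABSENT, absent):
            raise ValueError("ABSENT must mark exactly the positions beyond each length")
        in_fp = ~absent & (pos[None, :] > (self.lengths[:, None] - self.footprint))
        if not np.array_equal(self.state == FOOTPRINT, in_fp):
            raise ValueError(
                f"FOOTPRINT must mark exactly the trailing {self.footprint} positions"
            )

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, self.n_positions + 1)


def _finalize_states(
    base: np.ndarray, lengths: np.ndarray, footprint: int
) -> np.ndarray:
    """Overlay the footprint and absent regions onto a base state grid."""
    state = base.astype(np.int8).copy()
    pos = np.arange(1, state.shape[1] + 1)
    in_fp = (pos[None, :] > (lengths[:, None] - footprint)) & (
        pos[None, :] <= lengths[:, None]
    )
    state[in_fp] = FOOTPRINT
    state[pos[None, :] > lengths[:, None]] = ABSENT
    return state


def _truth_from_states(
    state: np.ndarray, lengths: np.ndarray, p: TernaryModelParams | None = None
) -> EventTable:
    """Derive ground-truth events from expected-reactivity changes."""
    p = p or TernaryModelParams()
    events: list[Event] = []
    n_len, n_pos = state.shape
    for j in range(n_pos):
        prev = None
        for i in range(n_len):
            s = int(state[i, j])
            if s == ABSENT:
                continue
            if prev is not None:
                old, new = prev, s
                delta = p.mean_of(new) - p.mean_of(old)
                if delta != 0.0:
                    if old == FOOTPRINT and new == UNPAIRED:
                        category = "footprint_exit"
                    elif old in (UNPAIRED,) and new in (PAIRED, HELIX_END):
                        category = "pairing"
                    elif old in (PAIRED, HELIX_END, FOOTPRINT) and new == UNPAIRED:
                        category = "unpairing" if old != FOOTPRINT else "footprint_exit"
                    else:
                        category = "shift"
                    if HELIX_END in (old, new):
                        category += ":helix_end"
                    events.append(
                        Event(
                            nucleotide=j + 1,
                            class_="swing",
                            direction="up" if delta > 0 else "down",
                            start_length=int(lengths[i]),
                            end_length=int(lengths[i]),
                            magnitude=float(delta),
                            category=category,
                        )
                    )
            prev = s
    return EventTable(events).sorted()


def make_trajectory(
    scenario: str,
    n_positions: int = 40,
    lengths: Sequence[int] | None = None,
    footprint: int = DEFAULT_FOOTPRINT,
    stem5: tuple[int, int] = (8, 13),
    loop: tuple[int, int] = (14, 19),
    stem3: tuple[int, int] = (20, 25),
    fold_length: int = 46,
    rearrange_length: int | None = None,
    custom_states: np.ndarray | None = None,
    params: TernaryModelParams | None = None,
) -> StructureTrajectory:
    """Build a trajectory from a scenario template.

    ``hairpin_formation``: everything starts unpaired; at ``fold_length``
    the two stems pair (outermost and loop-closing pairs as helix ends)
    while the loop stays unpaired.  ``hairpin_rearrangement`` adds a
    second transition at ``rearrange_length`` where the former loop pairs
    into a continuous helix.  ``static_unpaired``/``static_paired`` hold
    a single state; ``custom`` accepts a pre-footprint state grid.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if lengths is None:
        # start well inside the footprint so early positions accrue enough
        # history before their transitions (short transcripts are still
        # fully footprint-protected, so their rows are flat)
        lengths = np.arange(5, n_positions + footprint + 7)
    lengths = np.asarray(lengths, dtype=int)
    n_len = lengths.size
    base = np.full((n_len, n_positions), UNPAIRED, dtype=np.int8)

    def cols(span: tuple[int, int]) -> slice:
        return slice(span[0] - 1, span[1])

    if scenario == "static_paired":
        base[:] = PAIRED
    elif scenario in ("hairpin_formation", "hairpin_rearrangement"):
        if not stem5[0] <= stem5[1] < loop[0] <= loop[1] < stem3[0] <= stem3[1]:
            raise ValueError("need stem5 < loop < stem3 in position order")
        folded = lengths >= fold_length
        for span in (stem5, stem3):
            base[np.ix_(folded, range(span[0] - 1, span[1]))] = PAIRED
        # helix ends: the outermost pair and the loop-closing pair
        for pos in (stem5[0], stem3[1], stem5[1], stem3[0]):
            base[folded, pos - 1] = HELIX_END
        if scenario == "hairpin_rearrangement":
            if rearrange_length is None:
                rearrange_length = int(lengths[-1] - max(2, n_len // 6))
            re = lengths >= rearrange_length
            base[np.ix_(re, range(stem5[0] - 1, stem3[1]))] = PAIRED
            base[re, stem5[0] - 1] = HELIX_END
            base[re, stem3[1] - 1] = HELIX_END
    elif scenario == "custom":
        if custom_states is None:
            raise ValueError("custom scenario requires custom_states")
        custom_states = np.asarray(custom_states, dtype=np.int8)
        if custom_states.shape != base.shape:
            raise ValueError(
                f"custom_states shape {custom_states.shape} != {base.shape}"
            )
        base = custom_states

    state = _finalize_states(base, lengths, footprint)
    truth = _truth_from_states(state, lengths, params)
    return StructureTrajectory(
        lengths=lengths,
        n_positions=n_positions,
        state=state,
        footprint=footprint,
        truth=truth,
    )


def simulate_reactivities(
    traj: StructureTrajectory, p: TernaryModelParams | None = None
) -> ReactivityMatrix:
    """Average ``n_reps`` gamma draws per defined cell, then set row means to 1.

    Each transcript-length row has its own deterministic random substream
    derived from ``p.seed``, so the output is reproducible regardless of
    evaluation order.
    """
    p = p or TernaryModelParams()
    n_len, n_pos = traj.state.shape
    values = np.full((n_len, n_pos), np.nan)
    for i in range(n_len):
        present = traj.state[i] != ABSENT
        if not np.any(present):
            continue
        means = np.array([p.mean_of(int(s)) for s in traj.state[i][present]])
        rng = np.random.default_rng(np.random.SeedSequence([p.seed, int(traj.lengths[i])]))
        draws = rng.standard_gamma(p.shape, size=(means.size, p.n_reps))
        scale = means / p.shape
        values[i, present] = draws.mean(axis=1) * scale
        row_mean = values[i, present].mean()
        if row_mean == 0.0:
            warnings.warn(
                f"row at length {traj.lengths[i]} is all zero; renormalization skipped"
            )
            continue
        values[i, present] /= row_mean
    return ReactivityMatrix(
        lengths=traj.lengths.copy(),
        positions=traj.positions,
        values=values,
        replicate_id=f"sim-seed{p.seed}",
    )


@dataclass
class BenchmarkResult:
    """Detection accuracy against ground truth."""

    recall: float
    precision: float
    category_recall: dict[str, float]
    matched: list[tuple[Event, Event]]
    unmatched_truth: list[Event]
    unmatched_detected: list[Event]


def benchmark(detected: EventTable, truth: EventTable, tol: int = 3) -> BenchmarkResult:
    """Greedy one-to-one matching of detected events to truth events.

    Pairs must share nucleotide and direction with start lengths within
    ``tol``; closest pairs match first, ties going to the earlier truth
    event.  Precision is NaN (with a warning) when nothing was detected.
    """
    det = list(detected)
    tru = list(truth)
    candidates = []
    for di, d in enumerate(det):
        for ti, t in enumerate(tru):
            if d.nucleotide != t.nucleotide or d.direction != t.direction:
                continue
            dist = abs(d.start_length - t.start_length)
            if dist <= tol:
                candidates.append((dist, t.start_length, ti, di))
    matched_pairs: list[tuple[Event, Event]] = []
    used_d: set[int] = set()
    used_t: set[int] = set()
    for dist, _, ti, di in sorted(candidates):
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        matched_pairs.append((det[di], tru[ti]))
    recall = len(used_t) / len(tru) if tru else float("nan")
    if det:
        precision = len(used_d) / len(det)
    else:
        warnings.warn("no detected events; precision undefined")
        precision = float("nan")
    cat_recall: dict[str, float] = {}
    cats = {t.category for t in tru if t.category}
    for cat in sorted(cats):
        total = [ti for ti, t in enumerate(tru) if t.category == cat]
        hit = sum(1 for ti in total if ti in used_t)
        cat_recall[cat] = hit / len(total)
    return BenchmarkResult(
        recall=recall,
        precision=precision,
        category_recall=cat_recall,
        matched=matched_pairs,
        unmatched_truth=[t for ti, t in enumerate(tru) if ti not in used_t],
        unmatched_detected=[d for di, d in enumerate(det) if di not in used_d],
    )
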