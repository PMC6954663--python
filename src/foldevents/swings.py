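"""Swing detection: rapid per-nucleotide reactivity changes.

Each nucleotide column is treated as a series over transcript lengths.
After centered moving-average smoothing, three causal signals are derived
at every length ``t`` (row index within a contiguous defined run):

* proportional ``e_t = s_t - b_t`` with baseline
  ``b_t = mean(s over the i_length rows before t)``,
* integral ``g_t = sum of e over the trailing i_length rows``,
* relative ``rel_t = s_t / max(b_t, eps)``.

A cell up-flags when all three signals clear their up thresholds and
down-flags symmetrically.  Runs of same-direction flags become events
after gap merging, a minimum-duration filter, and a minimum absolute
change (``m_floor``) filter.

Automated threshold selection scales a base threshold set over a grid,
counts consensus flagged cells at each scale, and picks the scale whose
min-max-normalized (scale, count) point lies closest to the origin --
the elbow of the rapidly decreasing count curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from foldevents.events import Event, EventTable
from foldevents.io import ReactivityMatrix

logger = logging.getLogger(__name__)

EPS = 1e-6

#: names of the seven swing (PIR) thresholds, in canonical order
PIR_NAMES = ("p_up", "p_down", "i_up", "i_down", "r_up", "r_down", "m_floor")

#: structural parameters that are not part of the seven-threshold family
STRUCTURAL_NAMES = ("w_smooth", "i_length", "min_duration", "merge_gap")


@dataclass(frozen=True)
class ThresholdSet:
    """The seven swing thresholds plus structural parameters.

    ``p_*`` bound the proportional term, ``i_*`` the integral term,
    ``r_*`` the relative fold change, and ``m_floor`` the minimum
    absolute smoothed change across an event.
    """

    p_up: float
    p_down: float
    i_up: float
    i_down: float
    r_up: float
    r_down: float
    m_floor: float = 0.1
    w_smooth: int = 3
    i_length: int = 5
    min_duration: int = 2
    merge_gap: int = 1

    def __post_init__(self) -> None:
        for name in PIR_NAMES[:-1]:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.m_floor < 0:
            raise ValueError("m_floor must be >= 0")
        if self.w_smooth < 1 or self.w_smooth % 2 == 0:
            raise ValueError("w_smooth must be an odd integer >= 1")
        if self.i_length < 1:
            raise ValueError("i_length must be >= 1")
        if self.min_duration < 1:
            raise ValueError("min_duration must be >= 1")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")

    def scaled(self, alpha: float) -> "ThresholdSet":
        """Scale all seven swing thresholds by ``alpha`` (structure unchanged)."""
        if alpha <= 0:
            raise ValueError("alpha must be > 0")
        return replace(self, **{name: getattr(self, name) * alpha for name in PIR_NAMES})

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in PIR_NAMES + STRUCTURAL_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        known = set(PIR_NAMES) | set(STRUCTURAL_NAMES)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SwingSignal:
    """Per-cell signal grids aligned with the source matrix (NaN = undefined)."""

    lengths: np.ndarray
    positions: np.ndarray
    smoothed: np.ndarray
    baseline: np.ndarray
    proportional: np.ndarray
    integral: np.ndarray
    relative: np.ndarray


def _runs(defined: np.ndarray) -> Iterable[tuple[int, int]]:
    """Yield (start, stop) of maximal contiguous True runs of a 1-D mask."""
    idx = np.flatnonzero(defined)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    yield from zip(starts.tolist(), stops.tolist())


def smooth(series: np.ndarray, w_smooth: int) -> np.ndarray:
    """Centered moving average with edge-truncated windows.

    Undefined (NaN) cells split the series into independent runs; the
    output is defined exactly where the input is.
    """
    if w_smooth < 1 or w_smooth % 2 == 0:
        raise ValueError("w_smooth must be an odd integer >= 1")
    series = np.asarray(series, dtype=float)
    if w_smooth == 1:
        return series.copy()
    out = np.full(series.shape, np.nan)
    half = w_smooth // 2
    for start, stop in _runs(~np.isnan(series)):
        run = series[start:stop]
        n = run.size
        csum = np.concatenate(([0.0], np.cumsum(run)))
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        out[start:stop] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def _column_signals(series: np.ndarray, ts: ThresholdSet) -> tuple[np.ndarray, ...]:
    """smoothed, baseline, proportional, integral, relative for one column."""
    n = series.size
    s = smooth(series, ts.w_smooth)
    b = np.full(n, np.nan)
    e = np.full(n, np.nan)
    g = np.full(n, np.nan)
    rel = np.full(n, np.nan)
    L = ts.i_length
    for start, stop in _runs(~np.isnan(s)):
        run = s[start:stop]
        m = run.size
        if m <= L:
            continue
        csum = np.concatenate(([0.0], np.cumsum(run)))
        # baseline over the L rows immediately before t (t >= L within run)
        t = np.arange(L, m)
        b_run = (csum[t] - csum[t - L]) / L
        b[start + L : stop] = b_run
        e_run = run[L:] - b_run
        e[start + L : stop] = e_run
        rel[start + L : stop] = run[L:] / np.maximum(b_run, EPS)
        # integral: trailing sum of L consecutive e values, all defined
        if e_run.size >= L:
            ecsum = np.concatenate(([0.0], np.cumsum(e_run)))
            k = np.arange(L, e_run.size + 1)
            g[start + L + k - 1] = ecsum[k] - ecsum[k - L]
    return s, b, e, g, rel


def compute_signals(m: ReactivityMatrix, ts: ThresholdSet) -> SwingSignal:
    """Derive the smoothed/baseline/proportional/integral/relative grids."""
    shape = m.values.shape
    grids = [np.full(shape, np.nan) for _ in range(5)]
    for j in range(m.positions.size):
        col = _column_signals(m.values[:, j], ts)
        for grid, vec in zip(grids, col):
            grid[:, j] = vec
    return SwingSignal(m.lengths, m.positions, *grids)


def flag_cells(
    m: ReactivityMatrix, ts: ThresholdSet, signal: SwingSignal | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (up, down) flag grids; undefined signals never flag."""
    sig = compute_signals(m, ts) if signal is None else signal
    e, g, rel = sig.proportional, sig.integral, sig.relative
    with np.errstate(invalid="ignore"):
        up = (e >= ts.p_up) & (g >= ts.i_up) & (rel >= 1.0 + ts.r_up)
        down = (-e >= ts.p_down) & (-g >= ts.i_down) & (rel <= 1.0 / (1.0 + ts.r_down))
    up &= ~np.isnan(e) & ~np.isnan(g) & ~np.isnan(rel)
    down &= ~np.isnan(e) & ~np.isnan(g) & ~np.isnan(rel)
    return up, down


def _group_flag_indices(
    flagged: np.ndarray, defined: np.ndarray, merge_gap: int
) -> Iterable[list[int]]:
    """Group flagged indices of one column into candidate events.

    Gaps of up to ``merge_gap`` defined-but-unflagged cells are bridged;
    undefined cells always split groups.
    """
    for start, stop in _runs(defined):
        idx = [i for i in range(start, stop) if flagged[i]]
        if not idx:
            continue
        group = [idx[0]]
        for i in idx[1:]:
            if i - group[-1] - 1 <= merge_gap:
                group.append(i)
            else:
                yield group
                group = [i]
        yield group


def detect_swings(m: ReactivityMatrix, ts: ThresholdSet) -> EventTable:
    """Detect swing events in every nucleotide column of ``m``."""
    sig = compute_signals(m, ts)
    up, down = flag_cells(m, ts, sig)
    events: list[Event] = []
    for j, nuc in enumerate(m.positions):
        defined = ~np.isnan(sig.proportional[:, j])
        for direction, flags in (("up", up[:, j]), ("down", down[:, j])):
            for group in _group_flag_indices(flags, defined, ts.merge_gap):
                if len(group) < ts.min_duration:
                    continue
                i0, i1 = group[0], group[-1]
                b0 = sig.baseline[i0, j]
                span = sig.smoothed[i0 : i1 + 1, j]
                if np.nanmax(np.abs(span - b0)) < ts.m_floor:
                    continue
                magnitude = float(sig.smoothed[i1, j] - b0)
                # smoothing edge effects can make the endpoint delta tiny;
                # clamp to the direction's sign so the record stays valid
                if direction == "up":
                    magnitude = max(magnitude, 0.0)
                else:
                    magnitude = min(magnitude, 0.0)
                events.append(
                    Event(
                        nucleotide=int(nuc),
                        class_="swing",
                        direction=direction,
                        start_length=int(m.lengths[i0]),
                        end_length=int(m.lengths[i1]),
                        magnitude=magnitude,
                    )
                )
    table = EventTable(events, {"replicate_id": m.replicate_id})
    return table.sorted()


def base_thresholds_from_data(
    matrices: Sequence[ReactivityMatrix],
    quantile: float = 0.6,
    r: float = 0.3,
    m_floor: float = 0.1,
    **structural,
) -> ThresholdSet:
    """Data-adaptive starting thresholds for the automated search.

    ``p`` thresholds are the ``quantile`` of pooled ``|e|``, ``i`` of
    pooled ``|g|``; relative and floor thresholds are fixed defaults.
    """
    probe = ThresholdSet(1, 1, 1, 1, 1, 1, **structural)
    abs_e, abs_g = [], []
    for m in matrices:
        sig = compute_signals(m, probe)
        abs_e.append(np.abs(sig.proportional[~np.isnan(sig.proportional)]))
        abs_g.append(np.abs(sig.integral[~np.isnan(sig.integral)]))
    e_all = np.concatenate(abs_e) if abs_e else np.array([])
    g_all = np.concatenate(abs_g) if abs_g else np.array([])
    p = float(np.quantile(e_all, quantile)) if e_all.size else 0.1
    i = float(np.quantile(g_all, quantile)) if g_all.size else 0.2
    p = max(p, EPS)
    i = max(i, EPS)
    return ThresholdSet(p, p, i, i, r, r, m_floor, **structural)


def default_alpha_grid(n: int = 21, lo: float = 0.25, hi: float = 4.0) -> np.ndarray:
    """Logarithmically spaced threshold scale factors."""
    return np.geomspace(lo, hi, n)


def consensus_flag_count(
    matrices: Sequence[ReactivityMatrix], ts: ThresholdSet
) -> int:
    """Number of (cell, direction) pairs flagged in *every* replicate."""
    up_all: np.ndarray | None = None
    down_all: np.ndarray | None = None
    for m in matrices:
        up, down = flag_cells(m, ts)
        up_all = up if up_all is None else up_all & up
        down_all = down if down_all is None else down_all & down
    assert up_all is not None and down_all is not None
    return int(up_all.sum() + down_all.sum())


def closest_to_origin(alphas: np.ndarray, counts: np.ndarray) -> int:
    """Index of the min-max-normalized (alpha, count) point nearest the origin.

    Ties break toward the smaller alpha; a constant axis normalizes to 0.
    """
    alphas = np.asarray(alphas, dtype=float)
    counts = np.asarray(counts, dtype=float)

    def norm(x: np.ndarray) -> np.ndarray:
        span = x.max() - x.min()
        if span == 0:
            return np.zeros_like(x)
        return (x - x.min()) / span

    d = np.hypot(norm(alphas), norm(counts))
    return int(np.argmin(d))  # argmin returns the first (smallest alpha) tie


def autotune(
    m_list: Sequence[ReactivityMatrix],
    grid: Sequence[float] | None = None,
    base: ThresholdSet | None = None,
    return_curve: bool = False,
):
    """Select swing thresholds by the closest-to-origin elbow criterion.

    Scales ``base`` over ``grid``, counts consensus flagged cells per
    scale, and returns ``base`` scaled by the elbow scale factor.
    """
    if not m_list:
        raise ValueError("autotune needs at least one matrix")
    alphas = np.asarray(default_alpha_grid() if grid is None else grid, dtype=float)
    if alphas.size < 3 or np.any(alphas <= 0) or np.any(np.diff(alphas) <= 0):
        raise ValueError("grid must hold >= 3 strictly increasing positive factors")
    if base is None:
        base = base_thresholds_from_data(m_list)
    counts = np.array(
        [consensus_flag_count(m_list, base.scaled(a)) for a in alphas], dtype=float
    )
    if np.all(counts == 0):
        logger.warning("no flagged cells at any threshold scale; returning smallest")
        best = 0
    else:
        best = closest_to_origin(alphas, counts)
    chosen = base.scaled(float(alphas[best]))
    logger.info(
        "autotune: alpha=%.4g, consensus flagged cells=%d", alphas[best], int(counts[best])
    )
    if return_curve:
        return chosen, alphas, counts
    return chosen
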