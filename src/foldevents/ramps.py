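"""Ramp detection: gradual reactivity trends via sliding-window OLS."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from foldevents.events import Event, EventTable
from foldevents.io import ReactivityMatrix


@dataclass(frozen=True)
class RampThresholds:
    """Window length and cutoffs for sliding-window regression.

    A window flags when |slope| >= ``slope_min``, the fit's R^2 >=
    ``fit_min``, and the fitted net change over the window >= ``net_min``.
    """

    w_ramp: int = 15
    slope_min: float = 0.01
    fit_min: float = 0.5
    net_min: float = 0.15

    def __post_init__(self) -> None:
        if self.w_ramp < 3:
            raise ValueError("w_ramp must be >= 3")
        if self.slope_min <= 0:
            raise ValueError("slope_min must be > 0")
        if not 0.0 <= self.fit_min <= 1.0:
            raise ValueError("fit_min must be in [0, 1]")
        if self.net_min < 0:
            raise ValueError("net_min must be >= 0")


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(y) == 0.0:
        return 0.0, 0.0  # degenerate: constant window
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2)


def window_fit(
    series: np.ndarray, t: int, w_ramp: int, lengths: np.ndarray | None = None
) -> tuple[float, float] | None:
    """OLS (slope, R^2) of reactivity against length over ``[t, t+w_ramp-1]``.

    Returns ``None`` when any cell in the window is undefined.  ``lengths``
    defaults to the row indices (unit spacing).
    """
    series = np.asarray(series, dtype=float)
    if t < 0 or t + w_ramp > series.size:
        return None
    y = series[t : t + w_ramp]
    if np.any(np.isnan(y)):
        return None
    x = (
        np.arange(t, t + w_ramp, dtype=float)
        if lengths is None
        else np.asarray(lengths, dtype=float)[t : t + w_ramp]
    )
    return _ols(x, y)


def detect_ramps(
    m: ReactivityMatrix, rt: RampThresholds, mask_3prime: int = 0
) -> EventTable:
    """Detect ramp events in every nucleotide column of ``m``.

    ``mask_3prime`` > 0 skips windows whose first row lies within that
    many nucleotides of the position's emergence from the polymerase
    footprint (3'-proximal upramps are often experimental artifacts).
    """
    w = rt.w_ramp
    events: list[Event] = []
    x_all = m.lengths.astype(float)
    for j, nuc in enumerate(m.positions):
        col = m.values[:, j]
        flagged: list[tuple[int, int, int]] = []  # (start, end, sign)
        for t in range(m.lengths.size - w + 1):
            if mask_3prime > 0 and m.lengths[t] - nuc < mask_3prime:
                continue
            fit = window_fit(col, t, w, lengths=m.lengths)
            if fit is None:
                continue
            slope, r2 = fit
            net = slope * (x_all[t + w - 1] - x_all[t])
            if slope >= rt.slope_min and r2 >= rt.fit_min and net >= rt.net_min:
                flagged.append((t, t + w - 1, +1))
            elif -slope >= rt.slope_min and r2 >= rt.fit_min and -net >= rt.net_min:
                flagged.append((t, t + w - 1, -1))
        for sign in (+1, -1):
            spans = [(a, b) for a, b, s in flagged if s == sign]
            for a, b in _merge_overlapping(spans):
                slope, _ = _ols(x_all[a : b + 1], col[a : b + 1])
                magnitude = slope * (x_all[b] - x_all[a])
                direction = "up" if sign > 0 else "down"
                if sign > 0:
                    magnitude = max(magnitude, 0.0)
                else:
                    magnitude = min(magnitude, 0.0)
                events.append(
                    Event(
                        nucleotide=int(nuc),
                        class_="ramp",
                        direction=direction,
                        start_length=int(m.lengths[a]),
                        end_length=int(m.lengths[b]),
                        magnitude=float(magnitude),
                    )
                )
    return EventTable(events, {"replicate_id": m.replicate_id}).sorted()


def _merge_overlapping(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of overlapping (inclusive) index intervals, input sorted by start."""
    merged: list[tuple[int, int]] = []
    for a, b in sorted(spans):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged
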