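"""Threshold perturbation scenarios and the pairwise sensitivity cohort.

"Stringent" doubles all seven swing thresholds, "lenient" halves them.
The pairwise cohort enumerates every unordered pair of the seven
thresholds under the four direction variants (up/up, up/down, down/up,
down/down), i.e. C(7,2) * 4 = 84 perturbed detection runs, and records
per-cell flag agreement across the cohort.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from foldevents.consensus import consensus, _best_match
from foldevents.events import Event, EventTable
from foldevents.io import ReactivityMatrix
from foldevents.swings import PIR_NAMES, STRUCTURAL_NAMES, ThresholdSet, detect_swings, flag_cells

UP_FACTOR = 2.0  # "100% increase"
DOWN_FACTOR = 0.5  # "50% decrease"

VARIANTS = (("up", "up"), ("up", "down"), ("down", "up"), ("down", "down"))

_DIR_FACTOR = {"up": UP_FACTOR, "down": DOWN_FACTOR}


def perturb(
    ts: ThresholdSet,
    kind: str,
    param: str | None = None,
    factor: float | None = None,
    param_a: str | None = None,
    dir_a: str | None = None,
    param_b: str | None = None,
    dir_b: str | None = None,
    structural: bool = False,
) -> ThresholdSet:
    """Apply one perturbation scenario to a threshold set.

    ``kind`` is one of ``stringent`` (x2 on all seven swing thresholds),
    ``lenient`` (x0.5 on all seven), ``single`` (one parameter by
    ``factor``) or ``pair`` (two named thresholds, each x2 for "up" or
    x0.5 for "down").  ``single`` on a structural parameter
    (e.g. ``i_length``) requires ``structural=True``; scaled structural
    values round to the nearest legal integer.
    """
    if kind == "stringent":
        return ts.scaled(UP_FACTOR)
    if kind == "lenient":
        return ts.scaled(DOWN_FACTOR)
    if kind == "single":
        if param is None or factor is None:
            raise ValueError("single perturbation needs param and factor")
        return _scale_param(ts, param, factor, structural)
    if kind == "pair":
        if None in (param_a, dir_a, param_b, dir_b):
            raise ValueError("pair perturbation needs param_a/dir_a/param_b/dir_b")
        if param_a == param_b:
            raise ValueError("pair perturbation needs two distinct thresholds")
        out = _scale_param(ts, param_a, _DIR_FACTOR[dir_a], structural=False)
        return _scale_param(out, param_b, _DIR_FACTOR[dir_b], structural=False)
    raise ValueError(f"unknown perturbation kind {kind!r}")


def _scale_param(ts: ThresholdSet, name: str, factor: float, structural: bool) -> ThresholdSet:
    if name in PIR_NAMES:
        return replace(ts, **{name: getattr(ts, name) * factor})
    if name in STRUCTURAL_NAMES:
        if not structural:
            raise ValueError(
                f"{name} is a structural parameter, not one of the seven swing "
                "thresholds; pass structural=True to perturb it"
            )
        value = max(1, round(getattr(ts, name) * factor))
        if name == "w_smooth" and value % 2 == 0:
            value += 1
        if name == "merge_gap":
            value = max(0, round(getattr(ts, name) * factor))
        return replace(ts, **{name: value})
    raise ValueError(f"unknown parameter {name!r}")


def enumerate_pairwise(ts: ThresholdSet) -> list[tuple[str, ThresholdSet]]:
    """The 84-run cohort: every threshold pair under every direction variant."""
    cohort = []
    for a, b in itertools.combinations(PIR_NAMES, 2):
        for da, db in VARIANTS:
            desc = f"{a}:{da},{b}:{db}"
            cohort.append(
                (desc, perturb(ts, "pair", param_a=a, dir_a=da, param_b=b, dir_b=db))
            )
    return cohort


@dataclass
class SensitivityReport:
    """Flag agreement across a cohort of perturbed detection runs."""

    lengths: np.ndarray
    positions: np.ndarray
    up_agreement: np.ndarray
    down_agreement: np.ndarray
    cohort: list[tuple[str, EventTable]]
    baseline: EventTable


def _consensus_masks(
    m_list: Sequence[ReactivityMatrix], ts: ThresholdSet
) -> tuple[np.ndarray, np.ndarray]:
    up_all = down_all = None
    for m in m_list:
        up, down = flag_cells(m, ts)
        up_all = up if up_all is None else up_all & up
        down_all = down if down_all is None else down_all & down
    return up_all, down_all


def pairwise_cohort(
    m_list: Sequence[ReactivityMatrix], ts: ThresholdSet, tol: int = 3
) -> SensitivityReport:
    """Run the 84 pairwise-perturbed detections and aggregate agreement.

    Agreement is the fraction of cohort runs whose replicate-consensus
    flag mask marks each (nucleotide, length, direction) cell; it is
    computed on flagged cells before event merging.
    """
    if not m_list:
        raise ValueError("pairwise_cohort needs at least one matrix")
    ref = m_list[0]
    up_sum = np.zeros(ref.values.shape)
    down_sum = np.zeros(ref.values.shape)
    cohort_tables: list[tuple[str, EventTable]] = []
    runs = enumerate_pairwise(ts)
    for desc, ts_p in runs:
        up, down = _consensus_masks(m_list, ts_p)
        up_sum += up
        down_sum += down
        tables = [detect_swings(m, ts_p) for m in m_list]
        cohort_tables.append((desc, consensus(tables, tol=tol)))
    baseline = consensus([detect_swings(m, ts) for m in m_list], tol=tol)
    n = len(runs)
    return SensitivityReport(
        lengths=ref.lengths.copy(),
        positions=ref.positions.copy(),
        up_agreement=up_sum / n,
        down_agreement=down_sum / n,
        cohort=cohort_tables,
        baseline=baseline,
    )


def compare_runs(a: EventTable, b: EventTable, tol: int = 3) -> dict[str, list[Event]]:
    """Partition two runs' events into kept / lost / gained.

    ``kept`` holds events of ``a`` matched in ``b`` (same nucleotide,
    class, direction; intervals overlap within ``tol``), ``lost`` the
    rest of ``a``, ``gained`` the events of ``b`` unmatched in ``a``.
    """
    kept: list[Event] = []
    lost: list[Event] = []
    for e in a:
        if _best_match(e, b, tol) is not None:
            kept.append(e)
        else:
            lost.append(e)
    gained = [e for e in b if _best_match(e, a, tol) is None]
    return {"kept": kept, "lost": lost, "gained": gained}
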