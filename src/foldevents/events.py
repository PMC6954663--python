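"""Event records shared by the detectors, consensus calling, and I/O."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

CLASSES = ("swing", "ramp")
DIRECTIONS = ("up", "down")

#: sort key that puts "up" before "down" (the documented row order)
_DIR_ORDER = {"up": 0, "down": 1}


@dataclass(frozen=True)
class Event:
    """One detected reactivity transition at a single nucleotide.

    ``start_length``/``end_length`` are inclusive transcript lengths (nt).
    ``magnitude`` is the signed smoothed-reactivity change; its sign must
    match ``direction``.  ``category`` is optional ground-truth metadata
    used by the simulator/benchmark and is not serialized.
    """

    nucleotide: int
    class_: str
    direction: str
    start_length: int
    end_length: int
    magnitude: float
    n_replicates_supporting: int = 1
    group_id: Optional[str] = None
    category: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.class_ not in CLASSES:
            raise ValueError(f"unknown event class {self.class_!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown event direction {self.direction!r}")
        if self.start_length > self.end_length:
            raise ValueError(
                f"start_length {self.start_length} > end_length {self.end_length}"
            )
        if self.direction == "up" and self.magnitude < 0:
            raise ValueError("up event with negative magnitude")
        if self.direction == "down" and self.magnitude > 0:
            raise ValueError("down event with positive magnitude")

    @property
    def sort_key(self) -> tuple:
        return (
            self.nucleotide,
            self.start_length,
            self.class_,
            _DIR_ORDER[self.direction],
            self.end_length,
        )


@dataclass
class EventTable:
    """An ordered collection of :class:`Event` rows plus provenance."""

    events: list[Event] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def sorted(self) -> "EventTable":
        return EventTable(sorted(self.events, key=lambda e: e.sort_key), dict(self.provenance))

    def filter(self, **attrs) -> "EventTable":
        """Subset by exact attribute values, e.g. ``filter(class_="swing")``."""
        out = [
            e
            for e in self.events
            if all(getattr(e, k) == v for k, v in attrs.items())
        ]
        return EventTable(out, dict(self.provenance))

    def with_events(self, events: Iterable[Event]) -> "EventTable":
        return EventTable(list(events), dict(self.provenance))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return sorted(self.events, key=lambda e: e.sort_key) == sorted(
            other.events, key=lambda e: e.sort_key
        )


@dataclass(frozen=True)
class LaggedPair:
    """An upswing followed by a downswing at the same nucleotide."""

    nucleotide: int
    up_start: int
    down_start: int

    @property
    def lag(self) -> int:
        return self.down_start - self.up_start

    def __post_init__(self) -> None:
        if self.down_start <= self.up_start:
            raise ValueError("down_start must follow up_start")


def strip_groups(table: EventTable) -> EventTable:
    """Return a copy with all group ids cleared."""
    return table.with_events(replace(e, group_id=None) for e in table.events)
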