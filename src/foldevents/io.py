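"""Reading, validation, and writing of reactivity matrices and event tables.

On-disk layout of a matrix file (TSV or CSV)::

    length  1     2     3
    10      0.5   1.2   0.0
    11      0.4   NA    0.1

The first column holds transcript lengths, the header row holds 1-based
nucleotide positions.  Undefined cells (untranscribed positions ``n > l``
or missing measurements) are written as ``NA``.  Lines starting with ``#``
are provenance comments and are skipped on read.

Event tables are TSVs with the fixed column order
``nucleotide, class, direction, start_length, end_length, magnitude,
n_replicates_supporting, group_id`` and a deterministic row order
(nucleotide, start_length, class, then up before down).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from foldevents.events import Event, EventTable

NA_TOKEN = "NA"
_DIALECT_SEP = {"tsv": "\t", "csv": ","}

EVENT_COLUMNS = (
    "nucleotide",
    "class",
    "direction",
    "start_length",
    "end_length",
    "magnitude",
    "n_replicates_supporting",
    "group_id",
)


class MatrixFormatError(ValueError):
    """Structural problem in a matrix file (header, ordering, shape)."""


class MatrixValueError(ValueError):
    """A defined cell holds a negative, non-finite, or non-numeric value."""


@dataclass
class ReactivityMatrix:
    """A (transcript length x nucleotide position) grid of reactivities.

    ``values[i, j]`` is the reactivity of position ``positions[j]`` at
    transcript length ``lengths[i]``; ``NaN`` marks undefined cells.
    Cells with ``position > length`` are always undefined.
    """

    lengths: np.ndarray
    positions: np.ndarray
    values: np.ndarray
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=int)
        self.positions = np.asarray(self.positions, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.values.shape != (self.lengths.size, self.positions.size):
            raise MatrixFormatError(
                f"value grid shape {self.values.shape} does not match "
                f"{self.lengths.size} lengths x {self.positions.size} positions"
            )
        if self.lengths.size and np.any(np.diff(self.lengths) <= 0):
            raise MatrixFormatError("transcript lengths must be strictly increasing")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise MatrixFormatError("nucleotide positions must be strictly increasing")
        # untranscribed cells are undefined no matter what was supplied
        if self.values.size:
            untranscribed = self.positions[None, :] > self.lengths[:, None]
            self.values[untranscribed] = np.nan
            defined = ~np.isnan(self.values)
            bad = defined & (~np.isfinite(self.values) | (self.values < 0))
            if np.any(bad):
                i, j = np.argwhere(bad)[0]
                raise MatrixValueError(
                    f"invalid reactivity {self.values[i, j]} at "
                    f"length {self.lengths[i]}, position {self.positions[j]}"
                )

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of defined cells."""
        return ~np.isnan(self.values)

    def n_defined(self) -> int:
        return int(self.defined.sum())

    def column(self, position: int) -> np.ndarray:
        """Per-length series for one nucleotide position (NaN = undefined)."""
        j = int(np.searchsorted(self.positions, position))
        if j >= self.positions.size or self.positions[j] != position:
            raise KeyError(f"position {position} not in matrix")
        return self.values[:, j]

    def copy(self, replicate_id: str | None = None) -> "ReactivityMatrix":
        return ReactivityMatrix(
            self.lengths.copy(),
            self.positions.copy(),
            self.values.copy(),
            self.replicate_id if replicate_id is None else replicate_id,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactivityMatrix):
            return NotImplemented
        return (
            np.array_equal(self.lengths, other.lengths)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


def _sep_for(dialect: str) -> str:
    try:
        return _DIALECT_SEP[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'") from None


def _parse_int(token: str, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise MatrixFormatError(f"non-integer {what}: {token!r}") from None


def read_matrix(
    path: Union[str, Path], dialect: str = "tsv", replicate_id: str | None = None
) -> ReactivityMatrix:
    """Parse a matrix file; see the module docstring for the layout."""
    sep = _sep_for(dialect)
    path = Path(path)
    rows: list[list[str]] = []
    with path.open() as fh:
        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split(sep))
    if not rows:
        raise MatrixFormatError(f"{path}: empty file")
    header = rows[0]
    if header[0] != "length":
        raise MatrixFormatError(f"{path}: first header field must be 'length', got {header[0]!r}")
    positions = np.array([_parse_int(tok, "position header") for tok in header[1:]], dtype=int)
    lengths = np.empty(len(rows) - 1, dtype=int)
    values = np.full((len(rows) - 1, positions.size), np.nan)
    for i, fields in enumerate(rows[1:]):
        if len(fields) != len(header):
            raise MatrixFormatError(
                f"{path}: row {i + 2} has {len(fields)} fields, expected {len(header)}"
            )
        lengths[i] = _parse_int(fields[0], "transcript length")
        for j, tok in enumerate(fields[1:]):
            if tok in ("", NA_TOKEN):
                continue
            try:
                v = float(tok)
            except ValueError:
                raise MatrixValueError(
                    f"{path}: non-numeric value {tok!r} at row {i + 2}, "
                    f"column {positions[j]}"
                ) from None
            if not math.isfinite(v) or v < 0:
                raise MatrixValueError(
                    f"{path}: invalid reactivity {v} at row {i + 2}, column {positions[j]}"
                )
            values[i, j] = v
    try:
        return ReactivityMatrix(
            lengths, positions, values,
            replicate_id=path.stem if replicate_id is None else replicate_id,
        )
    except MatrixFormatError as exc:
        raise MatrixFormatError(f"{path}: {exc}") from None


def _fmt(v: float) -> str:
    """Shortest decimal representation that round-trips the float."""
    return format(v, ".17g") if v != int(v) else str(int(v))


def write_matrix(
    m: ReactivityMatrix, path: Union[str, Path], dialect: str = "tsv",
    provenance: dict | None = None,
) -> None:
    """Write ``m`` so that :func:`read_matrix` recovers an equal matrix."""
    sep = _sep_for(dialect)
    path = Path(path)
    with path.open("w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write(sep.join(["length", *map(str, m.positions)]) + "\n")
        for i, length in enumerate(m.lengths):
            cells = [
                NA_TOKEN if np.isnan(v) else _fmt(v) for v in m.values[i]
            ]
            fh.write(sep.join([str(length), *cells]) + "\n")


def write_events(
    t: EventTable, path: Union[str, Path], provenance: dict | None = None
) -> None:
    """Write an event table as TSV with deterministic row order."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in {**t.provenance, **(provenance or {})}.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("\t".join(EVENT_COLUMNS) + "\n")
        for e in t.sorted():
            fh.write(
                "\t".join(
                    [
                        str(e.nucleotide),
                        e.class_,
                        e.direction,
                        str(e.start_length),
                        str(e.end_length),
                        _fmt(e.magnitude),
                        str(e.n_replicates_supporting),
                        "" if e.group_id is None else str(e.group_id),
                    ]
                )
                + "\n"
            )


def read_events(path: Union[str, Path]) -> EventTable:
    """Inverse of :func:`write_events` (provenance comments are dropped)."""
    path = Path(path)
    events: list[Event] = []
    with path.open() as fh:
        header: list[str] | None = None
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if tuple(header) != EVENT_COLUMNS:
                    raise MatrixFormatError(
                        f"{path}: unexpected event columns {header}"
                    )
                continue
            rec = dict(zip(header, fields))
            events.append(
                Event(
                    nucleotide=int(rec["nucleotide"]),
                    class_=rec["class"],
                    direction=rec["direction"],
                    start_length=int(rec["start_length"]),
                    end_length=int(rec["end_length"]),
                    magnitude=float(rec["magnitude"]),
                    n_replicates_supporting=int(rec["n_replicates_supporting"]),
                    group_id=rec["group_id"] or None,
                )
            )
    if header is None:
        raise MatrixFormatError(f"{path}: empty event file")
    return EventTable(events)
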