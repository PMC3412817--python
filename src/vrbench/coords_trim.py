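"""Reference-coordinate mapping and hypervariable-window trimming.

16S positions are conventionally cited in *E. coli* numbering.  A
:class:`CoordinateMap` translates those 1-based reference positions into
alignment columns by walking the (gapped) reference row; datasets are then
trimmed to closed windows such as V3 = [338, 534].

Some curated reference numberings prepend virtual positions before the
first base of the deposited sequence; the ``offset`` parameter (default 0
here, 9 for the adjusted numbering convention) accounts for that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_core import GAP, GappedAlignment

logger = logging.getLogger(__name__)


class CoordinateError(KeyError):
    """A reference position cannot be resolved to an alignment column."""


@dataclass(frozen=True)
class RegionWindow:
    """Closed 1-based interval [start, end] in reference numbering."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid window {self.name}: [{self.start}, {self.end}]")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


#: the four hypervariable trim windows, in E. coli numbering
WINDOWS: dict[str, RegionWindow] = {
    "V3": RegionWindow("V3", 338, 534),
    "V4": RegionWindow("V4", 515, 700),
    "V5": RegionWindow("V5", 786, 926),
    "V6": RegionWindow("V6", 1052, 1193),
}

REGION_NAMES = tuple(WINDOWS)


@dataclass
class CoordinateMap:
    """Bijection between defined reference positions and alignment columns.

    ``positions[i]`` (1-based reference numbering) maps to ``columns[i]``
    (1-based alignment column).  Positions ``<= offset`` map to nothing.
    """

    positions: np.ndarray
    columns: np.ndarray
    offset: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.columns = np.asarray(self.columns, dtype=int)
        if self.positions.shape != self.columns.shape:
            raise ValueError("positions and columns differ in length")
        if np.any(np.diff(self.columns) <= 0):
            raise ValueError("column indices must be strictly increasing")
        self._col_of = {int(p): int(c) for p, c in zip(self.positions, self.columns)}
        self._pos_of = {int(c): int(p) for p, c in zip(self.positions, self.columns)}

    @property
    def n_positions(self) -> int:
        return self.positions.size

    @property
    def last_position(self) -> int:
        return int(self.positions[-1])

    def column_of(self, position: int) -> int:
        try:
            return self._col_of[position]
        except KeyError:
            raise CoordinateError(
                f"reference position {position} is not defined "
                f"(defined range: {int(self.positions[0])}..{self.last_position})"
            ) from None

    def position_of(self, column: int) -> int | None:
        """Reference position of a 1-based alignment column, or None on
        reference-gap columns."""
        return self._pos_of.get(column)


def build_coordinate_map(aln: GappedAlignment, offset: int = 9) -> CoordinateMap:
    """Map reference numbering onto alignment columns.

    Position ``p`` (for ``p > offset``) maps to the column holding the
    ``(p - offset)``-th non-gap character of the reference row.
    """
    ref = np.frombuffer(aln.reference_row.encode("ascii"), dtype=np.uint8)
    nongap_cols = np.flatnonzero(ref != ord(GAP)) + 1  # 1-based
    if nongap_cols.size == 0:
        raise ValueError(f"reference row {aln.reference_id!r} is all gaps")
    positions = offset + np.arange(1, nongap_cols.size + 1)
    return CoordinateMap(positions=positions, columns=nongap_cols, offset=offset)


@dataclass
class TrimResult:
    """A window-trimmed alignment plus the ids that became all-gap."""

    alignment: GappedAlignment
    excluded_ids: list[str]
    window: RegionWindow


def trim_to_window(
    aln: GappedAlignment, cmap: CoordinateMap, window: RegionWindow
) -> TrimResult:
    """Retain the alignment columns spanning ``window`` (inclusive).

    Rows that are entirely gaps inside the window are excluded from the
    returned alignment (the reference row is always kept) and reported in
    ``excluded_ids``.
    """
    c0 = cmap.column_of(window.start)
    c1 = cmap.column_of(window.end)
    ids: list[str] = []
    rows: list[str] = []
    excluded: list[str] = []
    for sid, row in zip(aln.ids, aln.rows):
        piece = row[c0 - 1 : c1]
        if sid != aln.reference_id and piece.count(GAP) == len(piece):
            excluded.append(sid)
        else:
            ids.append(sid)
            rows.append(piece)
    if excluded:
        logger.info(
            "window %s: excluded %d all-gap rows", window.name, len(excluded)
        )
    return TrimResult(
        alignment=GappedAlignment(ids, rows, aln.reference_id),
        excluded_ids=excluded,
        window=window,
    )


def degap(row: str) -> tuple[str, int]:
    """Remove gap characters; return the ungapped sequence and its length."""
    seq = row.replace(GAP, "").replace(".", "")
    return seq, len(seq)


def mask_to_reference(
    aln: GappedAlignment, cmap: CoordinateMap
) -> tuple[np.ndarray, np.ndarray]:
    """Encoded sub-matrix restricted to reference-defined columns.

    Returns ``(matrix, positions)`` where ``matrix`` has one column per
    defined reference position (reference-gap columns removed from all
    rows) and ``positions`` carries the matching reference numbering.
    """
    m = aln.encoded()[:, cmap.columns - 1]
    return m, cmap.positions.copy()
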