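"""Readers and writers for the external formats the pipeline touches.

Aligned FASTA and taxonomy tables come in; PHYLIP square distance matrices,
newick trees and TSV report tables go out.  The two central in-memory
containers, :class:`GappedAlignment` and :class:`TaxonomyTable`, live here
because every downstream module consumes them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import skbio

logger = logging.getLogger(__name__)

GAP = "-"
N_RANKS = 6
UNCLASSIFIED = "unclassified"
RANK_NAMES = ("domain", "phylum", "class", "order", "family", "genus")

#: integer codes used by the vectorised column operations
A, C, G, T, GAP_CODE = 0, 1, 2, 3, 4

_ENCODE_LUT = np.arange(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE_LUT[_b] = _i
_ENCODE_LUT[ord("-")] = GAP_CODE
_ENCODE_LUT[ord(".")] = GAP_CODE


class AlignmentError(ValueError):
    """Malformed alignment input (ragged rows, duplicate ids, ...)."""


class TaxonomyError(ValueError):
    """Malformed taxonomy input."""


class DistanceMatrixError(ValueError):
    """Malformed distance matrix (asymmetric, nonzero diagonal, ...)."""


def _normalize_row(row: str) -> str:
    return row.upper().replace(".", GAP)


@dataclass
class GappedAlignment:
    """Equal-length gapped sequences with one designated numbering reference.

    Rows are uppercase strings over ``{A, C, G, T, -}``; other IUPAC
    ambiguity letters are tolerated and passed through (downstream
    operations decide how to treat them).  ``.`` is normalised to ``-``.
    """

    ids: list[str]
    rows: list[str]
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if not self.ids:
            raise AlignmentError("alignment is empty")
        seen: set[str] = set()
        for sid in self.ids:
            if sid in seen:
                raise AlignmentError(f"duplicate sequence id: {sid!r}")
            seen.add(sid)
        self.rows = [_normalize_row(r) for r in self.rows]
        width = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise AlignmentError(
                    f"ragged alignment: sequence {sid!r} has length "
                    f"{len(row)}, expected {width}"
                )
        if self.reference_id not in seen:
            raise AlignmentError(
                f"reference id {self.reference_id!r} not present in alignment"
            )
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        return self.rows[self._index[seq_id]]

    @property
    def reference_row(self) -> str:
        return self.row(self.reference_id)

    def encoded(self) -> np.ndarray:
        """(n_sequences, n_columns) uint8 matrix; A..T -> 0..3, gap -> 4,
        any other character keeps its ASCII code (so it never collides
        with the base/gap codes and literal equality is preserved)."""
        buf = np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8)
        return _ENCODE_LUT[buf].reshape(self.n_sequences, self.n_columns)

    def subset(self, ids: Sequence[str], reference_id: str | None = None) -> "GappedAlignment":
        ref = reference_id or self.reference_id
        keep = list(ids)
        if ref not in keep:
            keep = [ref, *keep]
        return GappedAlignment(keep, [self.row(i) for i in keep], ref)


def encode_rows(rows: Iterable[str]) -> np.ndarray:
    rows = [_normalize_row(r) for r in rows]
    buf = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[buf].reshape(len(rows), -1)


def read_alignment(path: str | Path, reference_id: str | None = None) -> GappedAlignment:
    """Read an aligned FASTA file.

    The numbering reference defaults to the first record unless
    ``reference_id`` is given.
    """
    path = Path(path)
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise AlignmentError(f"empty record {rec.id!r} in {path}")
        ids.append(rec.id)
        rows.append(str(rec.seq))
    if not ids:
        raise AlignmentError(f"no FASTA records in {path}")
    return GappedAlignment(ids, rows, reference_id or ids[0])


def write_alignment(aln: GappedAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.ids, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class TaxonomyTable:
    """Map from sequence id to a 6-rank lineage (domain..genus).

    Shorter lineages are padded with ``"unclassified"``.
    """

    lineages: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        fixed: dict[str, tuple[str, ...]] = {}
        for sid, lin in self.lineages.items():
            lin = tuple(lin)
            if len(lin) > N_RANKS:
                raise TaxonomyError(
                    f"lineage for {sid!r} has {len(lin)} ranks (max {N_RANKS})"
                )
            if not lin or any(not name for name in lin):
                raise TaxonomyError(f"empty taxon name in lineage for {sid!r}")
            fixed[sid] = lin + (UNCLASSIFIED,) * (N_RANKS - len(lin))
        self.lineages = fixed

    @property
    def ids(self) -> list[str]:
        return list(self.lineages)

    def lineage(self, seq_id: str) -> tuple[str, ...]:
        return self.lineages[seq_id]

    def phylum(self, seq_id: str) -> str:
        return self.lineages[seq_id][1]

    def subset(self, ids: Sequence[str]) -> "TaxonomyTable":
        return TaxonomyTable({i: self.lineages[i] for i in ids})


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a tab-separated ``ID<TAB>Rank1;Rank2;...`` taxonomy file."""
    lineages: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0]:
                raise TaxonomyError(f"line {lineno}: expected 'ID<TAB>lineage'")
            sid, lineage_field = parts
            names = [n.strip() for n in lineage_field.rstrip(";").split(";")]
            if not lineage_field.strip() or any(not n for n in names):
                raise TaxonomyError(f"line {lineno}: empty lineage field")
            if sid in lineages:
                raise TaxonomyError(f"line {lineno}: duplicate id {sid!r}")
            lineages[sid] = tuple(names)
    return TaxonomyTable(lineages)


def write_taxonomy(table: TaxonomyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, lin in table.lineages.items():
            fh.write(f"{sid}\t{';'.join(lin)}\n")


def write_distance_matrix(
    matrix: np.ndarray, ids: Sequence[str], path: str | Path, tol: float = 1e-9
) -> None:
    """Write a square symmetric distance matrix in PHYLIP square format."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(ids):
        raise DistanceMatrixError("matrix must be square and match ids")
    if np.max(np.abs(m - m.T)) > tol:
        raise DistanceMatrixError(f"matrix asymmetric beyond {tol}")
    if np.max(np.abs(np.diag(m))) > tol:
        raise DistanceMatrixError("nonzero diagonal")
    with open(path, "w") as fh:
        fh.write(f"{len(ids)}\n")
        for sid, row in zip(ids, m):
            vals = " ".join(f"{v:.12g}" for v in row)
            fh.write(f"{sid}  {vals}\n")


def read_distance_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        header = fh.readline().strip()
        n = int(header)
        ids: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if len(ids) != n or any(len(r) != n for r in rows):
        raise DistanceMatrixError(f"expected {n} x {n} matrix in {path}")
    return np.array(rows, dtype=float), ids


def write_tree(tree: "skbio.TreeNode", path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_tree(path: str | Path) -> "skbio.TreeNode":
    return skbio.TreeNode.read(str(path), format="newick")


def load_config(path: str | Path) -> dict:
    """Load a plain-text TOML config file into a flat dict."""
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)
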