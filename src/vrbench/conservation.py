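"""Conservation profiling of a 16S alignment.

Per-position Shannon entropy (bits, 4-state base alphabet), 20-position
windowed entropy means, IUPAC-degenerate consensus sequences at a
conservation cutoff, conserved-site (candidate priming site) discovery,
hypervariable-stretch calling, and degapped amplicon-length distributions.

Policy notes
------------
* Gaps are excluded from the entropy/consensus frequency denominator (the
  entropy of a column is over observed bases, so 0 <= H' <= 2 bits); the
  gap fraction is tracked separately and drives the lower-case rule of the
  consensus (a position is lower-cased when gaps exceed 10% of rows).
* IUPAC ambiguity letters in input rows encode uncertainty, not
  observations, and are excluded from column counts altogether.
* The entropy logarithm base is 2 (bits) and windowed means step by one
  position, anchored at the first position of each window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .coords_trim import CoordinateMap, RegionWindow, mask_to_reference
from .io_core import GAP_CODE, GappedAlignment

logger = logging.getLogger(__name__)

#: minimal IUPAC letter for each non-empty base set
IUPAC_CODES: dict[frozenset, str] = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

_BASES = "ACGT"


def _base_counts(matrix: np.ndarray) -> np.ndarray:
    """(4, n_columns) counts of A, C, G, T per column of an encoded matrix."""
    return np.stack([(matrix == b).sum(axis=0) for b in range(4)])


def column_entropy(column: Iterable[str] | str) -> float:
    """Shannon entropy H' (bits) of one alignment column.

    Gaps and ambiguity letters are excluded; an empty column after those
    exclusions yields ``nan`` (undefined, deliberately not 0).
    """
    counts = np.array([sum(1 for ch in column if ch.upper() == b) for b in _BASES],
                      dtype=float)
    return _entropy_from_counts(counts)


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return math.nan
    f = counts[counts > 0] / total
    return float(-(f * np.log2(f)).sum())


@dataclass
class EntropyProfile:
    """Per-reference-position entropy and its windowed means."""

    positions: np.ndarray
    entropy: np.ndarray
    window_size: int
    windowed_positions: np.ndarray
    windowed: np.ndarray


def entropy_profile(
    aln: GappedAlignment, cmap: CoordinateMap, window_size: int = 20
) -> EntropyProfile:
    """Entropy over reference-defined columns plus sliding-window means.

    Only columns where the reference holds a base are scored (reference-gap
    columns are removed from all rows first).  Windowed values are means of
    ``window_size`` consecutive positions, anchored at the window's first
    position, stepping by one.
    """
    matrix, positions = mask_to_reference(aln, cmap)
    counts = _base_counts(matrix).astype(float)
    totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(totals > 0, counts / np.where(totals > 0, totals, 1), 0.0)
        terms = np.where(f > 0, -f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    h = terms.sum(axis=0)
    h[totals == 0] = np.nan

    n = h.size
    if n < window_size:
        logger.warning(
            "only %d positions for window size %d; single partial window",
            n, window_size,
        )
        wpos = positions[:1]
        wvals = np.array([float(np.mean(h))])
    else:
        windows = np.lib.stride_tricks.sliding_window_view(h, window_size)
        wvals = windows.mean(axis=1)
        wpos = positions[: n - window_size + 1]
    return EntropyProfile(
        positions=positions,
        entropy=h,
        window_size=window_size,
        windowed_positions=wpos,
        windowed=wvals,
    )


@dataclass
class ConsensusSequence:
    """Per-position IUPAC consensus with gap-driven casing.

    ``base_sets[i]`` is the minimal base set whose summed frequency (over
    observed bases) reaches the cutoff; ``sequence`` renders it as IUPAC
    letters, lower-cased where the gap fraction exceeds the threshold.
    """

    base_sets: list[frozenset]
    gap_fractions: np.ndarray
    cutoff: float
    gap_case_threshold: float
    positions: np.ndarray | None = None

    @property
    def sequence(self) -> str:
        out = []
        for s, g in zip(self.base_sets, self.gap_fractions):
            letter = IUPAC_CODES[s]
            out.append(letter.lower() if g > self.gap_case_threshold else letter)
        return "".join(out)

    def __len__(self) -> int:
        return len(self.base_sets)


def _minimal_base_set(counts: np.ndarray, cutoff: float) -> frozenset:
    """Greedy minimal base set reaching ``cutoff`` of the observed bases.

    Bases are added in order of decreasing count, ties broken
    alphabetically; this yields, among all minimal-size qualifying sets,
    the one with maximal total frequency and alphabetically-first
    composition.  Counts are compared as integers to keep the cutoff
    test exact.
    """
    total = counts.sum()
    if total == 0:
        return frozenset(_BASES)
    order = sorted(range(4), key=lambda b: (-counts[b], _BASES[b]))
    need = cutoff * total
    acc = 0
    chosen: list[str] = []
    for b in order:
        chosen.append(_BASES[b])
        acc += counts[b]
        if acc >= need - 1e-9:
            break
    return frozenset(chosen)


def consensus(
    aln: GappedAlignment,
    cutoff: float = 0.90,
    gap_case_threshold: float = 0.10,
    cmap: CoordinateMap | None = None,
) -> ConsensusSequence:
    """IUPAC consensus at a conservation cutoff.

    With ``cmap`` given, only reference-defined columns are scored and the
    result carries reference positions.
    """
    if cmap is not None:
        matrix, positions = mask_to_reference(aln, cmap)
    else:
        matrix, positions = aln.encoded(), None
    counts = _base_counts(matrix)
    gap_fractions = (matrix == GAP_CODE).mean(axis=0)
    sets = [_minimal_base_set(counts[:, j], cutoff) for j in range(matrix.shape[1])]
    return ConsensusSequence(
        base_sets=sets,
        gap_fractions=gap_fractions,
        cutoff=cutoff,
        gap_case_threshold=gap_case_threshold,
        positions=positions,
    )


@dataclass
class ConservedSite:
    """A candidate priming window in reference coordinates."""

    start: int
    end: int
    length: int
    degeneracies: int
    coverage: float


def find_conserved_sites(
    aln: GappedAlignment,
    cons: ConsensusSequence,
    min_length: int = 18,
    max_degeneracies: int = 3,
    cmap: CoordinateMap | None = None,
) -> list[ConservedSite]:
    """Maximal upper-case consensus runs usable as priming sites.

    A run qualifies when it is at least ``min_length`` long and contains at
    most ``max_degeneracies`` degenerate letters.  ``coverage`` is the
    fraction of sequences whose characters fall inside the consensus base
    set at every position of the site (a gap anywhere in the site fails).
    """
    seq = cons.sequence
    if cons.positions is not None:
        positions = cons.positions
        matrix = mask_to_reference(aln, cmap)[0] if cmap is not None else None
    else:
        positions = np.arange(1, len(seq) + 1)
        matrix = aln.encoded()
    if matrix is None:
        matrix = aln.encoded()
        if matrix.shape[1] != len(seq):  # consensus was reference-masked
            raise ValueError("pass cmap so site coverage can be recomputed")

    sites: list[ConservedSite] = []
    i = 0
    n = len(seq)
    while i < n:
        if not seq[i].isupper():
            i += 1
            continue
        j = i
        while j < n and seq[j].isupper():
            j += 1
        run = seq[i:j]
        degen = sum(1 for ch in run if ch not in _BASES)
        if len(run) >= min_length and degen <= max_degeneracies:
            cols = range(i, j)
            ok = np.ones(matrix.shape[0], dtype=bool)
            for col in cols:
                allowed = [_BASES.index(b) for b in cons.base_sets[col]]
                ok &= np.isin(matrix[:, col], allowed)
            sites.append(
                ConservedSite(
                    start=int(positions[i]),
                    end=int(positions[j - 1]),
                    length=len(run),
                    degeneracies=degen,
                    coverage=float(ok.mean()),
                )
            )
        i = j
    return sites


def hypervariable_stretches(
    profile: EntropyProfile,
    threshold: float = 0.5,
    merge_slack: int = 0,
) -> list[tuple[int, int, int]]:
    """Maximal runs of windowed entropy above a fraction of its maximum.

    ``threshold`` is a fraction of the profile's maximum windowed entropy.
    Runs separated by at most ``merge_slack`` positions are merged.  Each
    stretch is returned as ``(start, end, length)`` in reference
    positions, where the end extends to the last base covered by the final
    window.
    """
    w = profile.windowed
    if w.size == 0 or np.all(np.isnan(w)) or np.nanmax(w) <= 0:
        return []
    cut = threshold * np.nanmax(w)
    above = w >= cut
    runs: list[list[int]] = []
    for i, flag in enumerate(above):
        if not flag:
            continue
        if runs and i - runs[-1][1] - 1 <= merge_slack:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    out = []
    for i0, i1 in runs:
        start = int(profile.windowed_positions[i0])
        end = int(profile.windowed_positions[i1]) + profile.window_size - 1
        out.append((start, end, end - start + 1))
    return out


@dataclass
class AmpliconLengths:
    """Degapped per-sequence lengths inside a trim window."""

    window: RegionWindow
    lengths: dict[str, int]
    cutoffs: tuple[int, ...]
    fractions: dict[int, float]

    @property
    def sorted_lengths(self) -> np.ndarray:
        return np.sort(np.fromiter(self.lengths.values(), dtype=int))


def amplicon_length_distribution(
    aln: GappedAlignment,
    cmap: CoordinateMap,
    window: RegionWindow,
    cutoffs: Sequence[int] = (150, 200, 226),
) -> AmpliconLengths:
    """Degapped amplicon lengths per sequence inside ``window``.

    ``fractions[c]`` is the fraction of sequences (reference excluded)
    whose degapped length is strictly below cutoff ``c``.
    """
    c0 = cmap.column_of(window.start)
    c1 = cmap.column_of(window.end)
    sub = aln.encoded()[:, c0 - 1 : c1]
    lens = (sub != GAP_CODE).sum(axis=1)
    lengths = {
        sid: int(l)
        for sid, l in zip(aln.ids, lens)
        if sid != aln.reference_id
    }
    vals = np.fromiter(lengths.values(), dtype=int)
    fractions = {int(c): float((vals < c).mean()) for c in cutoffs}
    return AmpliconLengths(
        window=window, lengths=lengths, cutoffs=tuple(int(c) for c in cutoffs),
        fractions=fractions,
    )
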