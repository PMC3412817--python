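"""Pairwise sequence distances and V-region vs full-length concordance.

Distances are mismatch fractions over comparable alignment columns.  Gap
handling follows the convention of the classic OTU-pipeline ecosystem:
columns gapped in both sequences are skipped, terminal gap overhangs are
ignored, and (under the default ``"onegap"`` policy) a contiguous run of
gap columns in one sequence counts as a single difference event.  The
``"percolumn"`` policy instead charges every single-gap column.

Concordance between a region's distances and the full-length distances is
summarised by a Pearson correlation, an ordinary least-squares line and a
LOWESS curve (tri-cube weighted local linear fits, 3 robustifying
iterations), mirroring how trimmed-region fidelity is usually judged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .io_core import GAP_CODE, GappedAlignment, encode_rows

logger = logging.getLogger(__name__)

GAP_POLICIES = ("onegap", "percolumn")


def _pair_counts(x: np.ndarray, y: np.ndarray, onegap: bool) -> tuple[int, int]:
    """(differences, comparable events) for one encoded row pair."""
    gx = x == GAP_CODE
    gy = y == GAP_CODE
    nx = np.flatnonzero(~gx)
    ny = np.flatnonzero(~gy)
    if nx.size == 0 or ny.size == 0:
        return 0, 0
    s = max(nx[0], ny[0])
    e = min(nx[-1], ny[-1])
    if e < s:
        return 0, 0
    x, y, gx, gy = x[s : e + 1], y[s : e + 1], gx[s : e + 1], gy[s : e + 1]
    bb = ~gx & ~gy
    mismatches = int(((x != y) & bb).sum())
    events = int(bb.sum())
    ga = gx & ~gy
    gb = gy & ~gx
    if onegap:
        runs_a = int((ga & ~np.concatenate(([False], ga[:-1]))).sum())
        runs_b = int((gb & ~np.concatenate(([False], gb[:-1]))).sum())
        gap_events = runs_a + runs_b
    else:
        gap_events = int(ga.sum() + gb.sum())
    return mismatches + gap_events, events + gap_events


def pairwise_distance(row_a: str, row_b: str, gap_policy: str = "onegap") -> float:
    """Distance in [0, 1] between two aligned rows; ``nan`` when no
    comparable columns remain."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal aligned length")
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    enc = encode_rows([row_a, row_b])
    d, n = _pair_counts(enc[0], enc[1], gap_policy == "onegap")
    return d / n if n else math.nan


def pairwise_distance_matrix(
    aln: GappedAlignment,
    ids: list[str] | None = None,
    gap_policy: str = "onegap",
) -> tuple[np.ndarray, list[str]]:
    """Square distance matrix over ``ids`` (default: all non-reference rows)."""
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    if ids is None:
        ids = [i for i in aln.ids if i != aln.reference_id]
    enc = encode_rows([aln.row(i) for i in ids])
    onegap = gap_policy == "onegap"
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d, c = _pair_counts(enc[i], enc[j], onegap)
            m[i, j] = m[j, i] = d / c if c else math.nan
    return m, ids


@dataclass
class PairedDistanceSample:
    """Matched (full-length, region) distances for sampled id pairs."""

    pairs: list[tuple[str, str]]
    fl: np.ndarray
    region: np.ndarray
    seed: int | None
    n_resampled: int = 0


def _decode_pair(code: int, n: int) -> tuple[int, int]:
    """Map a flat index in [0, C(n,2)) to an (i, j) pair, i < j."""
    # i is the largest row whose triangle offset does not exceed code
    i = int((2 * n - 1 - math.sqrt((2 * n - 1) ** 2 - 8 * code)) // 2)
    offset = i * (2 * n - i - 1) // 2
    j = i + 1 + (code - offset)
    return i, j


def sample_paired_distances(
    fl_aln: GappedAlignment,
    region_aln: GappedAlignment,
    n_pairs: int,
    seed: int | None = None,
    exclude: set[str] | frozenset[str] = frozenset(),
    gap_policy: str = "onegap",
) -> PairedDistanceSample:
    """Sample random id pairs (without replacement) and compute both the
    full-length and the region distance on each.

    Pairs whose region distance is undefined (no comparable columns) are
    skipped and resampled; the count is recorded in ``n_resampled``.
    """
    ids = [
        i
        for i in fl_aln.ids
        if i != fl_aln.reference_id and i not in exclude
    ]
    region_ids = {
        i for i in region_aln.ids if i != region_aln.reference_id and i not in exclude
    }
    if set(ids) != region_ids:
        raise ValueError("full-length and region alignments must share ids")
    n = len(ids)
    total = n * (n - 1) // 2
    if n_pairs > total:
        raise ValueError(f"n_pairs {n_pairs} exceeds available pairs {total}")
    fl_enc = encode_rows([fl_aln.row(i) for i in ids])
    rg_enc = encode_rows([region_aln.row(i) for i in ids])
    onegap = gap_policy == "onegap"
    rng = np.random.default_rng(seed)

    chosen: set[int] = set()
    pairs: list[tuple[str, str]] = []
    fl_d: list[float] = []
    rg_d: list[float] = []
    n_resampled = 0
    if n_pairs == total:
        codes: list[int] = list(range(total))
    else:
        codes = []
        while len(codes) < n_pairs:
            c = int(rng.integers(total))
            if c not in chosen:
                chosen.add(c)
                codes.append(c)
    k = 0
    while k < len(codes):
        i, j = _decode_pair(codes[k], n)
        df, nf = _pair_counts(fl_enc[i], fl_enc[j], onegap)
        dr, nr = _pair_counts(rg_enc[i], rg_enc[j], onegap)
        if nf == 0 or nr == 0:
            n_resampled += 1
            # resample a replacement code if any remain
            replacement = None
            if len(chosen) < total:
                while True:
                    c = int(rng.integers(total))
                    if c not in chosen:
                        chosen.add(c)
                        replacement = c
                        break
            if replacement is not None:
                codes[k] = replacement
                continue
            k += 1
            continue
        pairs.append((ids[i], ids[j]))
        fl_d.append(df / nf)
        rg_d.append(dr / nr)
        k += 1
    if n_resampled:
        logger.info("resampled %d pairs with undefined distances", n_resampled)
    return PairedDistanceSample(
        pairs=pairs,
        fl=np.array(fl_d),
        region=np.array(rg_d),
        seed=seed,
        n_resampled=n_resampled,
    )


@dataclass
class ConcordanceResult:
    """Pearson/OLS/LOWESS summary of a paired distance sample."""

    r: float
    p_value: float
    slope: float
    intercept: float
    r_squared: float
    lowess: np.ndarray  # (m, 2) columns (x, fitted)
    n: int


def concordance(
    sample: PairedDistanceSample,
    lowess_span: float = 2.0 / 3.0,
    lowess_iterations: int = 3,
) -> ConcordanceResult:
    """Concordance of region vs full-length distances.

    ``x`` is the full-length distance, ``y`` the region distance.  Returns
    ``nan`` statistics when either coordinate has zero variance.
    """
    x = sample.fl
    y = sample.region
    if x.size < 3 or np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct full-length distances")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        nanrow = np.column_stack([x, np.full_like(x, np.nan)])
        return ConcordanceResult(
            r=math.nan, p_value=math.nan, slope=math.nan, intercept=math.nan,
            r_squared=math.nan, lowess=nanrow, n=x.size,
        )
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    smooth = _sm_lowess(
        y, x, frac=lowess_span, it=lowess_iterations, return_sorted=True
    )
    return ConcordanceResult(
        r=float(r),
        p_value=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r) ** 2,
        lowess=np.asarray(smooth),
        n=x.size,
    )
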