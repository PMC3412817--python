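"""Synthetic 16S-like alignments, taxonomies and virtual communities.

The generator emulates the statistical structure the benchmark assumes of
real data: a gapped multiple alignment with conserved flanks and a handful
of hypervariable windows, a skewed hierarchical taxonomy (a few large
phyla, many rare ones), and per-sample read counts drawn from log-normal
abundance profiles at pyrosequencing-era depths.

The evolutionary model is deliberately simple: a root sequence is evolved
down a balanced taxonomy-shaped tree under Jukes-Cantor-style uniform
substitution among the three alternative bases, with a per-position rate
multiplier that is high inside the hypervariable windows and low in the
flanks.  Indel columns are inserted by gapping a random subset of rows.
No secondary structure, chimeras or rate heterogeneity beyond the window
multipliers are modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_core import GappedAlignment, TaxonomyTable, N_RANKS

logger = logging.getLogger(__name__)

REFERENCE_ID = "REF"

_RANK_PREFIXES = ("d", "p", "c", "o", "f", "g")


@dataclass(frozen=True)
class WindowSpec:
    """One hypervariable window of the generator's region profile."""

    name: str
    start: int
    end: int
    multiplier: float = 1.0


@dataclass
class RegionProfile:
    """Substitution-rate geography of the synthetic reference gene.

    Positions inside a window mutate at ``base rate x multiplier``;
    flanking positions at ``base rate x flank_multiplier``.  The default
    windows are the hypervariable cores of the four benchmark regions
    (non-overlapping, nested inside the V3/V4/V5/V6 trim windows), with
    the two long regions more variable than the two short ones.
    """

    length: int = 1400
    windows: list[WindowSpec] = field(
        default_factory=lambda: [
            WindowSpec("V3w", 340, 510, 1.0),
            WindowSpec("V4w", 540, 700, 1.0),
            WindowSpec("V5w", 790, 925, 0.5),
            WindowSpec("V6w", 1055, 1190, 0.4),
        ]
    )
    flank_multiplier: float = 0.05
    gap_probability: float = 0.02

    def __post_init__(self) -> None:
        if self.flank_multiplier < 0:
            raise ValueError("flank multiplier must be >= 0")
        spans = []
        for w in self.windows:
            if not (1 <= w.start <= w.end <= self.length):
                raise ValueError(
                    f"window {w.name} [{w.start}, {w.end}] outside 1..{self.length}"
                )
            if w.multiplier <= 0:
                raise ValueError(f"window {w.name}: multiplier must be > 0")
            spans.append((w.start, w.end, w.name))
        spans.sort()
        for (s0, e0, n0), (s1, e1, n1) in zip(spans, spans[1:]):
            if s1 <= e0:
                raise ValueError(f"windows {n0} and {n1} overlap")

    def multipliers(self) -> np.ndarray:
        """Per-position rate multiplier (index 0 = reference position 1)."""
        m = np.full(self.length, self.flank_multiplier, dtype=float)
        for w in self.windows:
            m[w.start - 1 : w.end] = w.multiplier
        return m

    def in_window(self, position: int) -> bool:
        return any(w.start <= position <= w.end for w in self.windows)


def _mutate(seq: np.ndarray, prob: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position with probability ``prob`` (uniform choice
    among the three alternative bases)."""
    out = seq.copy()
    mask = rng.random(seq.size) < prob
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return out


def generate_reference_alignment(
    n_sequences: int = 800,
    profile: RegionProfile | None = None,
    taxonomy_shape: tuple[int, ...] = (1, 6, 2, 2, 2, 3),
    skew: float = 1.2,
    seed: int | None = None,
    base_rate: float = 0.08,
    within_rate: float = 0.004,
    rank_rate_factors: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 0.05),
) -> tuple[GappedAlignment, TaxonomyTable]:
    """Evolve a taxonomy-shaped synthetic alignment.

    Parameters
    ----------
    n_sequences : number of non-reference rows.
    profile : substitution-rate geography (default :class:`RegionProfile`).
    taxonomy_shape : per-rank branching factors (6 ranks, domain..genus);
        the first factor is normally 1 (a single domain).
    skew : Pareto shape for taxon-size draws; smaller values give heavier
        skew (a few large phyla, many rare ones).
    base_rate : per-position substitution probability per taxonomy edge,
        before the window multiplier.
    within_rate : leaf-level rate from each genus ancestor to each
        sequence.
    rank_rate_factors : per-rank scaling of ``base_rate``; the small
        default genus factor makes sibling genera closely related, so the
        discriminating signal between them lives almost entirely in the
        hypervariable windows -- short trimmed fragments then genuinely
        lose taxonomic resolution, as real partial reads do.

    Returns the alignment (including one ungapped reference row, id
    ``"REF"``) and the matching taxonomy table.
    """
    if len(taxonomy_shape) != N_RANKS:
        raise ValueError(f"taxonomy_shape must have {N_RANKS} factors")
    if len(rank_rate_factors) != N_RANKS:
        raise ValueError(f"rank_rate_factors must have {N_RANKS} factors")
    profile = profile or RegionProfile()
    rng = np.random.default_rng(seed)
    mult = profile.multipliers()
    leaf_prob = np.clip(within_rate * mult, 0.0, 0.75)

    root = rng.integers(0, 4, size=profile.length, dtype=np.int64)

    # grow the balanced taxonomy tree, evolving one ancestor per node
    nodes: list[tuple[tuple[str, ...], np.ndarray]] = [((), root)]
    counters = [0] * N_RANKS
    for rank, factor in enumerate(taxonomy_shape):
        edge_prob = np.clip(base_rate * rank_rate_factors[rank] * mult, 0.0, 0.75)
        nxt: list[tuple[tuple[str, ...], np.ndarray]] = []
        for lineage, anc in nodes:
            for _ in range(factor):
                counters[rank] += 1
                name = (
                    "Bacteria"
                    if rank == 0 and taxonomy_shape[0] == 1
                    else f"{_RANK_PREFIXES[rank]}{counters[rank]:03d}"
                )
                nxt.append((lineage + (name,), _mutate(anc, edge_prob, rng)))
        nodes = nxt
    genera = nodes  # leaves: (6-rank lineage, ancestor sequence)

    # skewed leaf sizes: Pareto weight per phylum times per genus
    n_phyla = taxonomy_shape[1]
    genera_per_phylum = len(genera) // n_phyla
    phylum_w = rng.pareto(skew, size=n_phyla) + 0.05
    genus_w = rng.pareto(skew, size=len(genera)) + 0.05
    weights = np.repeat(phylum_w, genera_per_phylum) * genus_w
    sizes = rng.multinomial(n_sequences, weights / weights.sum())

    ids: list[str] = [REFERENCE_ID]
    seqs: list[np.ndarray] = [root]
    lineages: dict[str, tuple[str, ...]] = {REFERENCE_ID: ("Bacteria",)}
    i = 0
    for (lineage, anc), size in zip(genera, sizes):
        for _ in range(int(size)):
            sid = f"seq{i:05d}"
            ids.append(sid)
            seqs.append(_mutate(anc, leaf_prob, rng))
            lineages[sid] = lineage
            i += 1

    matrix = np.stack(seqs)

    # indel columns: gap a random row subset, never the reference
    gap_cols = np.flatnonzero(rng.random(profile.length) < profile.gap_probability)
    for col in gap_cols:
        frac = rng.uniform(0.05, 0.5)
        rows = 1 + np.flatnonzero(rng.random(matrix.shape[0] - 1) < frac)
        matrix[rows, col] = 4

    lut = np.frombuffer(b"ACGT-", dtype=np.uint8)
    rows = [bytes(lut[r]).decode("ascii") for r in matrix]
    aln = GappedAlignment(ids, rows, REFERENCE_ID)
    return aln, TaxonomyTable(lineages)


@dataclass
class SyntheticCommunity:
    """Per-sample read counts over sequence ids."""

    samples: dict[str, dict[str, int]]
    depth_range: tuple[int, int]

    @property
    def sample_names(self) -> list[str]:
        return list(self.samples)

    def depth(self, sample: str) -> int:
        return sum(self.samples[sample].values())

    def counts_frame(self, ids: list[str] | None = None):
        """samples x sequence-ids count DataFrame (zeros where absent)."""
        import pandas as pd

        if ids is None:
            ids = sorted({sid for s in self.samples.values() for sid in s})
        data = {
            name: [counts.get(sid, 0) for sid in ids]
            for name, counts in self.samples.items()
        }
        return pd.DataFrame(data, index=ids).T

    def restrict(self, ids: set[str]) -> "SyntheticCommunity":
        samples = {
            name: {sid: c for sid, c in counts.items() if sid in ids}
            for name, counts in self.samples.items()
        }
        return SyntheticCommunity(samples, self.depth_range)


def generate_virtual_samples(
    aln: GappedAlignment,
    n_samples: int = 9,
    depth_range: tuple[int, int] = (26000, 54000),
    sigma: float = 1.5,
    mu: float = 0.0,
    subset_fraction: float = 0.6,
    seed: int | None = None,
) -> SyntheticCommunity:
    """Draw a virtual community over the alignment's sequences.

    Each sample picks a random subset of the sequences, gives each member a
    log-normal(mu, sigma) abundance, and multinomially samples reads to a
    depth uniform in ``depth_range``.  Samples deliberately differ in
    composition (via the random subsets) so that downstream sample
    distances are informative.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    lo, hi = depth_range
    if lo > hi:
        raise ValueError(f"depth_range min {lo} > max {hi}")
    rng = np.random.default_rng(seed)
    ids = [i for i in aln.ids if i != aln.reference_id]
    n = len(ids)
    samples: dict[str, dict[str, int]] = {}
    for s in range(n_samples):
        mask = rng.random(n) < subset_fraction
        if not mask.any():
            mask[rng.integers(n)] = True
        member_idx = np.flatnonzero(mask)
        abund = rng.lognormal(mean=mu, sigma=sigma, size=member_idx.size)
        probs = abund / abund.sum()
        depth = int(rng.integers(lo, hi + 1))
        counts = rng.multinomial(depth, probs)
        samples[f"sample{s + 1:02d}"] = {
            ids[i]: int(c) for i, c in zip(member_idx, counts) if c > 0
        }
    return SyntheticCommunity(samples=samples, depth_range=(lo, hi))
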