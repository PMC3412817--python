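"""Bootstrap naive-Bayesian taxonomy classifier and information-loss tables.

The classifier is the classic word-based design used for ribosomal
taxonomy assignment: every training sequence is indexed by the set of
8-mers it contains (presence, not multiplicity), each genus gets smoothed
conditional word probabilities, and a query is assigned to the genus
maximising the summed log probability of its words.  Confidence per rank
comes from 100 bootstrap replicates, each re-scoring a random one-eighth
subsample (with replacement) of the query's words; the effective
assignment is the deepest rank whose confidence reaches the cutoff
(default 50%), "unclassified" below.

Smoothing: with ``n_w`` of ``N`` training sequences containing word ``w``,
the word prior is ``p_w = (n_w + 0.5) / (N + 1)`` and the genus
conditional is ``P(w | g) = (m_wg + p_w) / (M_g + 1)`` for a genus of
``M_g`` sequences, ``m_wg`` of which contain ``w``.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_core import N_RANKS, UNCLASSIFIED, TaxonomyTable

logger = logging.getLogger(__name__)


@dataclass
class WordModel:
    """Trained k-mer naive-Bayes genus model."""

    k: int
    vocabulary: dict[str, int]
    log_conditional: np.ndarray  # (n_genera, vocabulary size)
    genera: list[tuple[str, ...]]  # 6-rank lineage per genus
    genus_sizes: np.ndarray

    @property
    def n_genera(self) -> int:
        return len(self.genera)


def _word_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def train(
    sequences: Mapping[str, str],
    taxonomy: TaxonomyTable,
    k: int = 8,
) -> WordModel:
    """Train the genus word model on ungapped sequences.

    Sequences shorter than ``k`` are skipped with a log message.  Genera
    are identified by their full 6-rank lineage.
    """
    per_genus_ids: dict[tuple[str, ...], list[str]] = {}
    usable: dict[str, str] = {}
    for sid, seq in sequences.items():
        if len(seq) < k:
            logger.info("skipping %s: shorter than word size %d", sid, k)
            continue
        usable[sid] = seq
        per_genus_ids.setdefault(taxonomy.lineage(sid), []).append(sid)
    if len(per_genus_ids) < 2:
        raise ValueError("need at least 2 genera to train")

    vocab: dict[str, int] = {}
    word_sets: dict[str, np.ndarray] = {}
    for sid, seq in usable.items():
        idx = []
        for w in _word_set(seq, k):
            pos = vocab.setdefault(w, len(vocab))
            idx.append(pos)
        word_sets[sid] = np.array(idx, dtype=np.int64)

    V = len(vocab)
    N = len(usable)
    n_w = np.zeros(V)
    for idx in word_sets.values():
        n_w[idx] += 1
    prior = (n_w + 0.5) / (N + 1)

    genera = sorted(per_genus_ids)
    sizes = np.array([len(per_genus_ids[g]) for g in genera])
    log_cond = np.empty((len(genera), V))
    for gi, g in enumerate(genera):
        m = np.zeros(V)
        for sid in per_genus_ids[g]:
            m[word_sets[sid]] += 1
        log_cond[gi] = np.log((m + prior) / (sizes[gi] + 1))
    return WordModel(
        k=k,
        vocabulary=vocab,
        log_conditional=log_cond,
        genera=genera,
        genus_sizes=sizes,
    )


@dataclass
class RankedAssignment:
    """Per-rank taxon names with bootstrap confidences."""

    taxa: tuple[str, ...]  # best genus's full lineage
    confidences: np.ndarray  # (6,) in [0, 1]
    effective_depth: int  # deepest rank (1..6) meeting the cutoff; 0 = none
    cutoff: float

    @property
    def effective(self) -> tuple[str, ...]:
        d = self.effective_depth
        return self.taxa[:d] + (UNCLASSIFIED,) * (N_RANKS - d)


_UNCLASSIFIED_ASSIGNMENT_TAXA = (UNCLASSIFIED,) * N_RANKS


def _argmax_tiebreak(scores: np.ndarray, rng: np.random.Generator) -> int:
    best = np.flatnonzero(scores == scores.max())
    return int(best[0]) if best.size == 1 else int(rng.choice(best))


def classify(
    query: str,
    model: WordModel,
    n_bootstrap: int = 100,
    word_fraction: float = 0.125,
    cutoff: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> RankedAssignment:
    """Classify one ungapped query sequence.

    A query sharing no word with the training vocabulary is unclassified
    at every rank.  Ties in the genus argmax are broken uniformly at
    random under the supplied generator.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    words = sorted(_word_set(query, model.k) & model.vocabulary.keys())
    if not words:
        return RankedAssignment(
            taxa=_UNCLASSIFIED_ASSIGNMENT_TAXA,
            confidences=np.zeros(N_RANKS),
            effective_depth=0,
            cutoff=cutoff,
        )
    idx = np.fromiter((model.vocabulary[w] for w in words), dtype=np.int64)
    Lq = model.log_conditional[:, idx]  # (G, W)
    best = _argmax_tiebreak(Lq.sum(axis=1), rng)
    best_lineage = model.genera[best]

    W = idx.size
    n_draw = max(1, math.ceil(W * word_fraction))
    draws = rng.multinomial(n_draw, np.full(W, 1.0 / W), size=n_bootstrap)
    scores = Lq @ draws.T  # (G, n_bootstrap)
    winners = np.array(
        [_argmax_tiebreak(scores[:, b], rng) for b in range(n_bootstrap)]
    )

    # agreement depth of each genus with the best lineage
    agree = np.zeros(model.n_genera, dtype=int)
    for gi, lin in enumerate(model.genera):
        d = 0
        while d < N_RANKS and lin[d] == best_lineage[d]:
            d += 1
        agree[gi] = d
    win_depths = agree[winners]
    conf = np.array([(win_depths >= r).mean() for r in range(1, N_RANKS + 1)])

    depth = 0
    while depth < N_RANKS and conf[depth] >= cutoff:
        depth += 1
    return RankedAssignment(
        taxa=best_lineage,
        confidences=conf,
        effective_depth=depth,
        cutoff=cutoff,
    )


def classify_many(
    sequences: Mapping[str, str],
    model: WordModel,
    n_bootstrap: int = 100,
    word_fraction: float = 0.125,
    cutoff: float = 0.5,
    seed: int | None = None,
) -> dict[str, RankedAssignment]:
    """Classify a set of sequences with one shared, seeded generator."""
    rng = np.random.default_rng(seed)
    return {
        sid: classify(
            sequences[sid], model,
            n_bootstrap=n_bootstrap, word_fraction=word_fraction,
            cutoff=cutoff, rng=rng,
        )
        for sid in sequences
    }


def depth_table(
    assignments_by_dataset: Mapping[str, Mapping[str, RankedAssignment]],
) -> pd.DataFrame:
    """Fraction of queries classified at least to each rank, per dataset.

    Index: rank 1..6; columns: dataset names.  All datasets must cover the
    same query ids.
    """
    datasets = list(assignments_by_dataset)
    ref_ids = set(assignments_by_dataset[datasets[0]])
    for name in datasets[1:]:
        if set(assignments_by_dataset[name]) != ref_ids:
            raise ValueError(f"dataset {name!r} covers different query ids")
    out = {}
    for name in datasets:
        depths = np.array(
            [a.effective_depth for a in assignments_by_dataset[name].values()]
        )
        out[name] = [(depths >= r).mean() for r in range(1, N_RANKS + 1)]
    return pd.DataFrame(out, index=pd.Index(range(1, N_RANKS + 1), name="rank"))


def mean_depth(assignments: Mapping[str, RankedAssignment]) -> float:
    return float(np.mean([a.effective_depth for a in assignments.values()]))


def genus_accuracy(
    assignments: Mapping[str, RankedAssignment], taxonomy: TaxonomyTable
) -> float:
    """Fraction of queries whose effective genus-rank call matches the
    true genus (queries not classified to genus rank count as wrong)."""
    ok = 0
    for sid, a in assignments.items():
        true = taxonomy.lineage(sid)
        if a.effective_depth == N_RANKS and a.effective == true:
            ok += 1
    return ok / len(assignments)


def population_category(fl_count: int) -> str:
    """Phylum population category from full-length counts: A > 1000,
    C > 100, D <= 100 (B is reserved for the unclassified pool)."""
    if fl_count > 1000:
        return "A"
    if fl_count > 100:
        return "C"
    return "D"


def phylum_counts(assignments: Mapping[str, RankedAssignment]) -> Counter:
    """Counts of effective phylum-rank assignments; queries not reaching
    phylum rank pool under "unclassified"."""
    c: Counter = Counter()
    for a in assignments.values():
        c[a.taxa[1] if a.effective_depth >= 2 else UNCLASSIFIED] += 1
    return c


def representation_from_counts(
    fl_counts: Mapping[str, int],
    region_counts: Mapping[str, int],
) -> pd.DataFrame:
    """Per-phylum representation of a region dataset relative to FL.

    ``percent_difference`` is 100 x (region - FL) / FL; undefined (NaN)
    for phyla absent from FL but found in the region ("novel in region").
    Categories follow the population thresholds on FL counts, with the
    unclassified pool as category B.
    """
    phyla = sorted(set(fl_counts) | set(region_counts))
    rows = []
    for p in phyla:
        fl = int(fl_counts.get(p, 0))
        rg = int(region_counts.get(p, 0))
        if p == UNCLASSIFIED:
            cat = "B"
        else:
            cat = population_category(fl)
        pct = 100.0 * (rg - fl) / fl if fl > 0 else math.nan
        note = "novel in region" if fl == 0 and rg > 0 else ""
        rows.append((p, fl, rg, pct, cat, note))
    df = pd.DataFrame(
        rows,
        columns=["phylum", "full_length", "region", "percent_difference",
                 "category", "note"],
    ).set_index("phylum")
    return df.sort_values(
        ["category", "full_length"], ascending=[True, False], kind="stable"
    )


def representation(
    fl_assignments: Mapping[str, RankedAssignment],
    region_assignments: Mapping[str, RankedAssignment],
) -> pd.DataFrame:
    """Representation table computed from two sets of assignments."""
    return representation_from_counts(
        phylum_counts(fl_assignments), phylum_counts(region_assignments)
    )
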