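"""The virtual community experiment: OTUs, sample distances, UniFrac, PCA.

Each trimmed dataset (FL, V3..V6) yields per-sample feature matrices via
three routes -- taxonomy assignments, 3%-distance OTUs, and phylogenetic
placement on a neighbor-joining tree -- and sample-by-sample distance
matrices (Bray-Curtis on relative abundances, Jaccard on
presence/absence, weighted/unweighted UniFrac).  A PCA over the datasets,
with each dataset's vectorised sample-distance matrix as its feature
vector, places every region relative to the full-length gold standard.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import skbio
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass
class OTUPartition:
    """Flat clustering of sequences at a distance cutoff."""

    labels: dict[str, int]
    cutoff: float
    linkage: str

    @property
    def n_otus(self) -> int:
        return len(set(self.labels.values()))

    def as_sets(self) -> set[frozenset]:
        groups: dict[int, set] = {}
        for sid, lab in self.labels.items():
            groups.setdefault(lab, set()).add(sid)
        return {frozenset(g) for g in groups.values()}


def otu_cluster(
    dist: np.ndarray,
    ids: list[str],
    cutoff: float = 0.03,
    linkage: str = "average",
) -> OTUPartition:
    """Agglomerative OTU clustering: merge while the linkage distance is
    at or below the cutoff."""
    dist = np.asarray(dist, dtype=float)
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains NaN")
    if len(ids) == 1:
        return OTUPartition({ids[0]: 1}, cutoff, linkage)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    flat = hierarchy.fcluster(z, t=cutoff, criterion="distance")
    return OTUPartition(dict(zip(ids, (int(f) for f in flat))), cutoff, linkage)


def bray_curtis(u: np.ndarray, v: np.ndarray) -> float:
    """Bray-Curtis dissimilarity; NaN when both vectors are all zero."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    tot = (u + v).sum()
    if tot == 0:
        return math.nan
    return float(np.abs(u - v).sum() / tot)


def jaccard_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Jaccard distance on presence/absence; NaN when both are empty."""
    a = np.asarray(u) > 0
    b = np.asarray(v) > 0
    union = (a | b).sum()
    if union == 0:
        return math.nan
    return float(1.0 - (a & b).sum() / union)


def nj_tree(dist: np.ndarray, ids: list[str]) -> skbio.TreeNode:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0.

    Fewer than 3 taxa yield the trivial tree.
    """
    n = len(ids)
    if n == 1:
        return skbio.TreeNode.read([f"{ids[0]}:0;"])
    if n == 2:
        d = float(dist[0][1]) / 2
        return skbio.TreeNode.read([f"({ids[0]}:{d},{ids[1]}:{d});"])
    dm = skbio.DistanceMatrix(np.asarray(dist, dtype=float), ids)
    return skbio.tree.nj(dm)  # clamps negative branch lengths by default


def _branch_table(
    tree: skbio.TreeNode, leaf_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and a (branches x leaves) descendant-incidence
    matrix for every non-root node."""
    index = {sid: i for i, sid in enumerate(leaf_ids)}
    lengths: list[float] = []
    incidence: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        mask = np.zeros(len(leaf_ids), dtype=bool)
        if node.is_tip():
            if node.name not in index:
                raise ValueError(f"tree leaf {node.name!r} not in sample leaf set")
            mask[index[node.name]] = True
        else:
            for child in node.children:
                mask |= below[id(child)]
        below[id(node)] = mask
        if not node.is_root():
            lengths.append(float(node.length or 0.0))
            incidence.append(mask)
    return np.array(lengths), np.stack(incidence)


def unifrac_matrix(
    tree: skbio.TreeNode,
    counts: pd.DataFrame,
    weighted: bool = False,
    normalized: bool = True,
) -> np.ndarray:
    """All pairwise UniFrac distances between samples.

    ``counts`` is samples x leaf-ids.  Unweighted UniFrac is the branch
    length unique to one sample's leaf set over the branch length covered
    by either; weighted UniFrac is ``sum b |pA - pB|`` over branches,
    divided (when ``normalized``) by ``sum b (pA + pB)``.
    """
    leaf_ids = list(counts.columns)
    lengths, inc = _branch_table(tree, leaf_ids)
    c = counts.to_numpy(dtype=float)  # (S, L)
    node_counts = inc.astype(float) @ c.T  # (B, S)
    totals = c.sum(axis=1)
    S = c.shape[0]
    out = np.zeros((S, S))
    if weighted:
        if np.any(totals == 0):
            logger.warning("empty sample(s): distances undefined")
        with np.errstate(divide="ignore", invalid="ignore"):
            p = node_counts / totals  # (B, S)
        for i in range(S):
            for j in range(i + 1, S):
                if totals[i] == 0 or totals[j] == 0:
                    d = math.nan
                else:
                    raw = float(lengths @ np.abs(p[:, i] - p[:, j]))
                    if normalized:
                        denom = float(lengths @ (p[:, i] + p[:, j]))
                        d = raw / denom if denom > 0 else math.nan
                    else:
                        d = raw
                out[i, j] = out[j, i] = d
    else:
        present = node_counts > 0
        for i in range(S):
            for j in range(i + 1, S):
                if totals[i] == 0 or totals[j] == 0:
                    d = math.nan
                else:
                    either = present[:, i] | present[:, j]
                    unique = present[:, i] ^ present[:, j]
                    denom = float(lengths @ either)
                    d = float(lengths @ unique) / denom if denom > 0 else math.nan
                out[i, j] = out[j, i] = d
    return out


def unifrac(
    tree: skbio.TreeNode,
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    weighted: bool = False,
    normalized: bool = True,
) -> float:
    """UniFrac distance between two leaf->count maps."""
    leaves = sorted({t.name for t in tree.tips()})
    df = pd.DataFrame(
        [
            [counts_a.get(l, 0) for l in leaves],
            [counts_b.get(l, 0) for l in leaves],
        ],
        index=["a", "b"],
        columns=leaves,
    )
    return float(unifrac_matrix(tree, df, weighted=weighted, normalized=normalized)[0, 1])


def sample_feature_counts(
    sample_counts: Mapping[str, Mapping[str, int]],
    feature_of: Mapping[str, object],
) -> pd.DataFrame:
    """Aggregate per-sample sequence read counts into feature counts.

    ``feature_of`` maps a sequence id to its feature label (a taxon
    string, an OTU label, ...); reads of sequences without a feature are
    dropped.
    """
    features = sorted({str(f) for f in feature_of.values()})
    fidx = {f: i for i, f in enumerate(features)}
    data = np.zeros((len(sample_counts), len(features)))
    names = list(sample_counts)
    for si, name in enumerate(names):
        for sid, cnt in sample_counts[name].items():
            f = feature_of.get(sid)
            if f is not None:
                data[si, fidx[str(f)]] += cnt
    return pd.DataFrame(data, index=names, columns=features)


def sample_distance_matrix(counts: pd.DataFrame, metric: str = "braycurtis") -> np.ndarray:
    """Square sample-distance matrix from a samples x features table.

    ``braycurtis`` works on relative abundances (rows normalised to 1);
    ``jaccard`` on presence/absence.
    """
    x = counts.to_numpy(dtype=float)
    n = x.shape[0]
    if metric == "braycurtis":
        totals = x.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            x = np.where(totals > 0, x / np.where(totals > 0, totals, 1), 0.0)
        fn = bray_curtis
    elif metric == "jaccard":
        fn = jaccard_distance
    else:
        raise ValueError(f"unknown metric {metric!r}")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fn(x[i], x[j])
    return out


@dataclass
class PCAResult:
    """Dataset-level PCA of vectorised sample-distance matrices."""

    coordinates: pd.DataFrame  # datasets x [PC1, PC2]
    explained_variance_ratio: np.ndarray

    def distances_to(self, reference: str) -> pd.Series:
        ref = self.coordinates.loc[reference]
        d = np.sqrt(((self.coordinates - ref) ** 2).sum(axis=1))
        return d.drop(reference)


def dataset_pca(matrices: Mapping[str, np.ndarray]) -> PCAResult:
    """PCA over datasets, each represented by the upper triangle of its
    sample-distance matrix (columns mean-centred, no scaling)."""
    names = list(matrices)
    if len(names) < 2:
        raise ValueError("need at least 2 datasets")
    first = np.asarray(matrices[names[0]])
    iu = np.triu_indices(first.shape[0], k=1)
    X = np.stack([np.asarray(matrices[n])[iu] for n in names])
    if np.isnan(X).any():
        raise ValueError("distance matrices contain NaN")
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: first max-magnitude loading of each PC positive
    for c in range(s.size):
        lead = vt[c, np.argmax(np.abs(vt[c]))]
        if lead < 0:
            vt[c] *= -1
            u[:, c] *= -1
    scores = u * s
    coords = np.zeros((len(names), 2))
    k = min(2, scores.shape[1])
    coords[:, :k] = scores[:, :k]
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=names, columns=["PC1", "PC2"]),
        explained_variance_ratio=evr,
    )
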