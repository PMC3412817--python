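"""End-to-end orchestration of the two study arms.

The *database arm* profiles an aligned reference collection: entropy and
consensus along the gene, candidate priming sites, V-region trimming,
amplicon lengths, region-vs-full-length distance concordance, and the
taxonomy information loss of trimming (classification depth and phylum
representation).

The *simulation arm* runs the virtual community experiment: samples are
drawn over the sequence collection, every dataset (FL, V3..V6) is scored
through the taxonomy, OTU and UniFrac routes, and a dataset-level PCA
places each region relative to the full-length gold standard.

A single run seed fans out to per-stage child seeds by stable hashing of
stage names, so reproducibility is independent of stage order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .io_core import (
    GappedAlignment,
    TaxonomyTable,
    read_alignment,
    read_taxonomy,
    write_alignment,
    write_distance_matrix,
    write_taxonomy,
    write_tree,
)
from .coords_trim import WINDOWS, build_coordinate_map, degap, trim_to_window
from .conservation import (
    amplicon_length_distribution,
    consensus,
    entropy_profile,
    find_conserved_sites,
    hypervariable_stretches,
)
from .distance_concordance import (
    concordance,
    pairwise_distance_matrix,
    sample_paired_distances,
)
from .synthetic_data import (
    RegionProfile,
    SyntheticCommunity,
    generate_reference_alignment,
    generate_virtual_samples,
)
from .taxonomy_classifier import (
    classify_many,
    depth_table,
    genus_accuracy,
    mean_depth,
    representation,
    train,
)
from .community_comparison import (
    dataset_pca,
    nj_tree,
    otu_cluster,
    sample_distance_matrix,
    sample_feature_counts,
    unifrac_matrix,
)

logger = logging.getLogger(__name__)

FL = "FL"
ALL_METRIC_FAMILIES = (
    "taxonomy_braycurtis",
    "taxonomy_jaccard",
    "otu_braycurtis",
    "otu_jaccard",
    "unifrac_weighted",
    "unifrac_unweighted",
)


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed (< 2**31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All knobs of both arms, at the scaled-down default preset
    (800 sequences, 1400 columns, 9 samples at depths 2,600-5,400)."""

    seed: int = 0
    # synthetic inputs (ignored when alignment/taxonomy paths are given)
    n_sequences: int = 800
    taxonomy_shape: tuple[int, ...] = (1, 6, 2, 2, 2, 3)
    skew: float = 1.2
    base_rate: float = 0.08
    within_rate: float = 0.004
    alignment_path: str | None = None
    taxonomy_path: str | None = None
    numbering_offset: int = 0
    # conservation
    window_size: int = 20
    consensus_cutoff: float = 0.90
    primer_cutoff: float = 0.95
    gap_case_threshold: float = 0.10
    min_primer_length: int = 18
    max_degeneracies: int = 3
    # concordance
    n_pairs: int = 20000
    gap_policy: str = "onegap"
    lowess_span: float = 2.0 / 3.0
    # classifier
    word_size: int = 8
    n_bootstrap: int = 100
    confidence_cutoff: float = 0.5
    # community simulation
    n_samples: int = 9
    depth_min: int = 2600
    depth_max: int = 5400
    abundance_sigma: float = 1.5
    subset_fraction: float = 0.6
    otu_cutoff: float = 0.03

    @classmethod
    def full_scale(cls, **overrides) -> "PipelineConfig":
        """The full-scale study conditions (42,109 sequences; depths
        26,000-54,000)."""
        base = dict(n_sequences=42109, depth_min=26000, depth_max=54000,
                    n_pairs=1_000_000)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def tiny(cls, **overrides) -> "PipelineConfig":
        """Desk-test preset for the unit suite."""
        base = dict(n_sequences=80, n_pairs=500, depth_min=400, depth_max=800)
        base.update(overrides)
        return cls(**base)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_inputs(
    config: PipelineConfig,
) -> tuple[GappedAlignment, TaxonomyTable]:
    if config.alignment_path:
        if not config.taxonomy_path:
            raise FileNotFoundError("taxonomy file required alongside alignment")
        if not Path(config.taxonomy_path).exists():
            raise FileNotFoundError(
                f"stage inputs: taxonomy file {config.taxonomy_path} not found"
            )
        aln = read_alignment(config.alignment_path)
        tax = read_taxonomy(config.taxonomy_path)
        return aln, tax
    return generate_reference_alignment(
        n_sequences=config.n_sequences,
        taxonomy_shape=config.taxonomy_shape,
        skew=config.skew,
        base_rate=config.base_rate,
        within_rate=config.within_rate,
        seed=stage_seed(config.seed, "alignment"),
    )


def _degapped(aln: GappedAlignment, ids: Sequence[str]) -> dict[str, str]:
    return {sid: degap(aln.row(sid))[0] for sid in ids}


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g")


@dataclass
class DatabaseArmResult:
    profile: object
    consensus: object
    sites: list
    stretches: list
    trims: dict
    amplicons: dict
    concordances: dict
    assignments: dict
    depth: pd.DataFrame
    representations: dict
    genus_accuracy_fl: float
    mean_depths: dict
    shared_ids: list


def run_database_arm(
    config: PipelineConfig, outdir: str | Path | None = None
) -> DatabaseArmResult:
    """Run the database arm end to end; optionally write one TSV per
    figure-equivalent plus a run manifest."""
    aln, tax = _load_inputs(config)
    cmap = build_coordinate_map(aln, offset=config.numbering_offset)

    profile = entropy_profile(aln, cmap, window_size=config.window_size)
    cons90 = consensus(aln, cutoff=config.consensus_cutoff,
                       gap_case_threshold=config.gap_case_threshold, cmap=cmap)
    cons95 = consensus(aln, cutoff=config.primer_cutoff,
                       gap_case_threshold=config.gap_case_threshold, cmap=cmap)
    sites = find_conserved_sites(
        aln, cons95, min_length=config.min_primer_length,
        max_degeneracies=config.max_degeneracies, cmap=cmap,
    )
    stretches = hypervariable_stretches(profile)

    trims = {name: trim_to_window(aln, cmap, w) for name, w in WINDOWS.items()}
    amplicons = {
        name: amplicon_length_distribution(aln, cmap, w)
        for name, w in WINDOWS.items()
    }

    excluded = set().union(*(set(t.excluded_ids) for t in trims.values()))
    shared = [i for i in aln.ids if i != aln.reference_id and i not in excluded]

    concordances = {}
    for name, t in trims.items():
        sample = sample_paired_distances(
            aln, t.alignment, n_pairs=min(config.n_pairs,
                                          len(shared) * (len(shared) - 1) // 2),
            seed=stage_seed(config.seed, f"pairs:{name}"),
            exclude=excluded, gap_policy=config.gap_policy,
        )
        concordances[name] = concordance(sample, lowess_span=config.lowess_span)

    fl_seqs = _degapped(aln, shared)
    model = train(fl_seqs, tax, k=config.word_size)
    assignments = {
        FL: classify_many(
            fl_seqs, model, n_bootstrap=config.n_bootstrap,
            cutoff=config.confidence_cutoff,
            seed=stage_seed(config.seed, "classify:FL"),
        )
    }
    for name, t in trims.items():
        seqs = _degapped(t.alignment, shared)
        assignments[name] = classify_many(
            seqs, model, n_bootstrap=config.n_bootstrap,
            cutoff=config.confidence_cutoff,
            seed=stage_seed(config.seed, f"classify:{name}"),
        )
    depth = depth_table(assignments)
    representations = {
        name: representation(assignments[FL], assignments[name])
        for name in WINDOWS
    }
    acc = genus_accuracy(assignments[FL], tax)
    mean_depths = {name: mean_depth(a) for name, a in assignments.items()}

    result = DatabaseArmResult(
        profile=profile, consensus=cons90, sites=sites, stretches=stretches,
        trims=trims, amplicons=amplicons, concordances=concordances,
        assignments=assignments, depth=depth, representations=representations,
        genus_accuracy_fl=acc, mean_depths=mean_depths, shared_ids=shared,
    )
    if outdir is not None:
        _write_database_outputs(result, aln, tax, config, Path(outdir))
    return result


def _write_database_outputs(
    res: DatabaseArmResult,
    aln: GappedAlignment,
    tax: TaxonomyTable,
    config: PipelineConfig,
    outdir: Path,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    outputs: list[str] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        _write_tsv(df, outdir / name, h)
        outputs.append(name)

    p = res.profile
    ent = pd.DataFrame({"position": p.positions, "entropy_bits": p.entropy})
    wind = pd.Series(np.nan, index=ent.index)
    wind.iloc[: p.windowed.size] = p.windowed
    ent["windowed_entropy_bits"] = wind
    emit(ent.set_index("position"), "entropy.tsv")

    with open(outdir / "consensus.fasta", "w") as fh:
        fh.write(f">consensus_cutoff_{res.consensus.cutoff:g}\n")
        fh.write(res.consensus.sequence + "\n")
    outputs.append("consensus.fasta")

    emit(
        pd.DataFrame(
            [(s.start, s.end, s.length, s.degeneracies, s.coverage) for s in res.sites],
            columns=["start", "end", "length", "degeneracies", "coverage"],
        ),
        "conserved_sites.tsv",
    )
    emit(
        pd.DataFrame(res.stretches, columns=["start", "end", "length"]),
        "hypervariable_stretches.tsv",
    )
    for name, amp in res.amplicons.items():
        df = pd.DataFrame(
            sorted(amp.lengths.items()), columns=["id", "length"]
        ).set_index("id")
        emit(df, f"amplicon_lengths_{name}.tsv")
    emit(
        pd.DataFrame(
            [
                (name, c.r, c.p_value, c.slope, c.intercept, c.r_squared, c.n)
                for name, c in res.concordances.items()
            ],
            columns=["region", "r", "p_value", "slope", "intercept",
                     "r_squared", "n_pairs"],
        ).set_index("region"),
        "concordance.tsv",
    )
    emit(res.depth, "classification_depth.tsv")
    for name, rep in res.representations.items():
        emit(rep, f"representation_{name}.tsv")

    manifest = {
        "arm": "database",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": h,
        "inputs": _input_digests(config),
        "outputs": outputs,
        "n_sequences": aln.n_sequences - 1,
        "genus_accuracy_fl": res.genus_accuracy_fl,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _input_digests(config: PipelineConfig) -> dict:
    out = {}
    for label, path in (
        ("alignment", config.alignment_path),
        ("taxonomy", config.taxonomy_path),
    ):
        if path:
            out[label] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        else:
            out[label] = "synthetic"
    return out


@dataclass
class SimulationArmResult:
    community: SyntheticCommunity
    sample_matrices: dict  # family -> {dataset -> square matrix}
    pca: dict  # family -> PCAResult
    pc_distances: dict  # family -> {dataset -> distance to FL}
    assignments: dict
    trees: dict
    sample_names: list
    shared_ids: list


def run_simulation_arm(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    metric_families: Sequence[str] = ALL_METRIC_FAMILIES,
) -> SimulationArmResult:
    """Run the virtual experiment.

    ``metric_families`` selects which of the six sample-distance families
    (taxonomy/OTU/UniFrac x abundance/presence) to compute.
    """
    aln, tax = _load_inputs(config)
    cmap = build_coordinate_map(aln, offset=config.numbering_offset)
    community = generate_virtual_samples(
        aln,
        n_samples=config.n_samples,
        depth_range=(config.depth_min, config.depth_max),
        sigma=config.abundance_sigma,
        subset_fraction=config.subset_fraction,
        seed=stage_seed(config.seed, "community"),
    )

    trims = {name: trim_to_window(aln, cmap, w) for name, w in WINDOWS.items()}
    excluded = set().union(*(set(t.excluded_ids) for t in trims.values()))
    shared = [i for i in aln.ids if i != aln.reference_id and i not in excluded]
    community = community.restrict(set(shared))
    sample_counts = community.samples

    dataset_alns: dict[str, GappedAlignment] = {FL: aln.subset(shared)}
    for name, t in trims.items():
        dataset_alns[name] = t.alignment.subset(shared)

    need_tax = any(f.startswith("taxonomy") for f in metric_families)
    need_otu = any(f.startswith("otu") for f in metric_families)
    need_uni = any(f.startswith("unifrac") for f in metric_families)

    assignments: dict[str, dict] = {}
    if need_tax:
        model = train(_degapped(aln, shared), tax, k=config.word_size)
        for name, daln in dataset_alns.items():
            assignments[name] = classify_many(
                _degapped(daln, shared), model,
                n_bootstrap=config.n_bootstrap, cutoff=config.confidence_cutoff,
                seed=stage_seed(config.seed, f"sim-classify:{name}"),
            )

    dists: dict[str, tuple[np.ndarray, list[str]]] = {}
    if need_otu or need_uni:
        for name, daln in dataset_alns.items():
            dists[name] = pairwise_distance_matrix(
                daln, ids=shared, gap_policy=config.gap_policy
            )

    trees: dict[str, object] = {}
    if need_uni:
        for name in dataset_alns:
            trees[name] = nj_tree(*dists[name])

    counts_df = community.counts_frame(shared)

    sample_matrices: dict[str, dict[str, np.ndarray]] = {}
    for family in metric_families:
        per_dataset: dict[str, np.ndarray] = {}
        for name in dataset_alns:
            if family.startswith("taxonomy"):
                feature_of = {
                    sid: ";".join(a.effective)
                    for sid, a in assignments[name].items()
                }
                feats = sample_feature_counts(sample_counts, feature_of)
                metric = "braycurtis" if family.endswith("braycurtis") else "jaccard"
                per_dataset[name] = sample_distance_matrix(feats, metric)
            elif family.startswith("otu"):
                part = otu_cluster(*dists[name], cutoff=config.otu_cutoff)
                feats = sample_feature_counts(sample_counts, part.labels)
                metric = "braycurtis" if family.endswith("braycurtis") else "jaccard"
                per_dataset[name] = sample_distance_matrix(feats, metric)
            else:  # unifrac
                per_dataset[name] = unifrac_matrix(
                    trees[name], counts_df, weighted=family.endswith("weighted")
                    and not family.endswith("unweighted"),
                )
        sample_matrices[family] = per_dataset

    pca = {family: dataset_pca(mats) for family, mats in sample_matrices.items()}
    pc_distances = {
        family: res.distances_to(FL).to_dict() for family, res in pca.items()
    }

    result = SimulationArmResult(
        community=community,
        sample_matrices=sample_matrices,
        pca=pca,
        pc_distances=pc_distances,
        assignments=assignments,
        trees=trees,
        sample_names=community.sample_names,
        shared_ids=shared,
    )
    if outdir is not None:
        _write_simulation_outputs(result, config, Path(outdir))
    return result


def _write_simulation_outputs(
    res: SimulationArmResult, config: PipelineConfig, outdir: Path
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    outputs: list[str] = []
    for family, mats in res.sample_matrices.items():
        for name, m in mats.items():
            fname = f"sample_distances_{family}_{name}.phylip"
            write_distance_matrix(np.nan_to_num(m), res.sample_names, outdir / fname)
            outputs.append(fname)
    for name, tree in res.trees.items():
        fname = f"tree_{name}.nwk"
        write_tree(tree, outdir / fname)
        outputs.append(fname)
    for family, pca_res in res.pca.items():
        fname = f"pca_{family}.tsv"
        df = pca_res.coordinates.copy()
        df["distance_to_FL"] = [
            0.0 if n == FL else res.pc_distances[family][n] for n in df.index
        ]
        _write_tsv(df, outdir / fname, h)
        outputs.append(fname)
    manifest = {
        "arm": "simulation",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": h,
        "inputs": _input_digests(config),
        "outputs": outputs,
        "explained_variance_ratio": {
            family: [float(v) for v in p.explained_variance_ratio]
            for family, p in res.pca.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def write_synthetic_inputs(config: PipelineConfig, outdir: str | Path) -> dict:
    """Materialise the synthetic alignment, taxonomy and per-sample counts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln, tax = _load_inputs(config)
    community = generate_virtual_samples(
        aln,
        n_samples=config.n_samples,
        depth_range=(config.depth_min, config.depth_max),
        sigma=config.abundance_sigma,
        subset_fraction=config.subset_fraction,
        seed=stage_seed(config.seed, "community"),
    )
    write_alignment(aln, outdir / "alignment.fasta")
    write_taxonomy(tax, outdir / "taxonomy.tsv")
    counts = community.counts_frame()
    _write_tsv(counts, outdir / "sample_counts.tsv", config.config_hash())
    return {"alignment": "alignment.fasta", "taxonomy": "taxonomy.tsv",
            "sample_counts": "sample_counts.tsv"}
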