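# vrbench

Benchmarking single 16S rRNA hypervariable (V) regions against
full-length gene sequences.

Multi-million-read sequencers only cover short stretches of the 16S rRNA
gene, so microbial ecology studies must pick a single hypervariable
region (V3, V4, V5 or V6) as a proxy for the full-length (FL) marker.
`vrbench` quantifies what that choice costs, entirely in silico, for
anyone designing an amplicon survey or evaluating one:

* **Conservation profiling** — per-position Shannon entropy
  H′ = −Σ f_b log₂ f_b over an alignment, 20-position windowed means,
  IUPAC-degenerate consensus sequences at 90%/95% cutoffs, and candidate
  priming sites (≥ 18 bp upper-case runs with ≤ 3 degeneracies).
* **Coordinate-mapped trimming** — *E. coli*-numbered windows
  (V3 338–534, V4 515–700, V5 786–926, V6 1052–1193) resolved through
  the gapped reference row, plus degapped amplicon-length distributions.
* **Distance concordance** — Pearson r, OLS fit and LOWESS curve between
  region and FL pairwise distances on randomly sampled sequence pairs.
* **Taxonomy loss** — an 8-mer bootstrap naive-Bayes classifier (100
  replicates, ⌈W/8⌉-word subsamples, 50% confidence cutoff), per-rank
  classification-depth tables and phylum representation
  (100 × (region − FL)/FL with population categories A/B/C/D).
* **Virtual community experiment** — simulated samples scored through
  taxonomy, 3%-OTU and NJ-tree + weighted/unweighted UniFrac routes;
  Bray-Curtis/Jaccard sample distances per dataset; a dataset-level PCA
  placing every region relative to FL.

A synthetic-data generator (conserved flanks, four hypervariable
windows, skewed taxonomy, log-normal communities) makes every stage
testable without any database downloads. See `docs/methods.md` for the
models and their assumptions.

## Worked example

Run both arms on the synthetic preset:

```sh
vrb run-db  --seed 1 --n-sequences 120 --out db/
vrb run-sim --seed 1 --n-sequences 120 --metrics taxonomy --out sim/
```

prints

```
database arm done: 120 shared sequences, FL genus accuracy 1.000
taxonomy_braycurtis: PC distance to FL: V3=0.0000, V4=0.0091, V5=0.3862, V6=0.1411
taxonomy_jaccard: PC distance to FL: V3=0.0000, V4=0.1961, V5=0.2754, V6=0.4537
```

and `db/concordance.tsv` holds the region-vs-FL distance fits:

```
region  r             p_value  slope         intercept       r_squared     n_pairs
V3      0.9859560382  0        2.689058736   0.005123232438  0.9721093093  7140
V4      0.9811116922  0        1.953708747   -0.01327738955  0.9625801525  7140
V5      0.9802015095  0        1.505213474   0.007696953971  0.9607949992  7140
```

Reading the numbers: every sequence in this small community
self-classifies to genus rank from its full-length version (accuracy
1.000). Region distances correlate strongly with FL distances
(r ≈ 0.98) but V3's slope of 2.69 means V3 *over-estimates* distances —
its per-base variability is concentrated, so identical OTU cutoffs
resolve finer structure. In the community experiment the long regions
(V3, V4) sit closest to FL in PC space for the abundance-based taxonomy
matrices, while the short, less informative regions (V5, V6) drift away
— the core trade-off the benchmark exists to expose.

The database arm also writes `entropy.tsv`, `consensus.fasta`,
`conserved_sites.tsv`, per-region amplicon lengths,
`classification_depth.tsv` and `representation_*.tsv`; the simulation
arm writes per-dataset PHYLIP sample-distance matrices, newick trees and
`pca_*.tsv` tables. Rerunning with the same seed reproduces every TSV
byte for byte.

## Library use

```python
from vrbench import PipelineConfig, run_simulation_arm

res = run_simulation_arm(PipelineConfig(seed=1),
                         metric_families=("taxonomy_braycurtis",))
print(res.pc_distances["taxonomy_braycurtis"])
```

All module-level operations (`conservation.entropy_profile`,
`coords_trim.trim_to_window`, `taxonomy_classifier.classify`,
`community_comparison.unifrac`, ...) are importable directly.

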