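# Methods

`vrbench` is an in-silico benchmark of single 16S rRNA hypervariable (V)
regions against full-length (FL) gene sequences. This note records the
models, the numerical choices and the limits of what the synthetic tests
demonstrate.

## Coordinate mapping and trimming

V-region boundaries are cited in *E. coli* numbering. Given a gapped
alignment with a designated reference row, reference position *p* (for
*p* > offset) maps to the alignment column holding the (*p* − offset)-th
non-gap character of the reference. The offset (default 0; 9 under the
adjusted numbering convention some curated references use) models virtual
leading positions. Windows are closed 1-based intervals, the only
self-consistent reading of spans like "positions 338–534"; the four
presets are V3 = [338, 534], V4 = [515, 700], V5 = [786, 926],
V6 = [1052, 1193]. Rows that are entirely gaps inside a window are
excluded with a logged count rather than raising — partial reads make
this expected. No re-alignment is performed after trimming.

## Entropy and consensus

Per-position Shannon entropy is computed over the four bases with
H′ = −Σ f_b log₂ f_b (bits; 0 ≤ H′ ≤ 2). Gaps are excluded from the
frequency denominator and tracked separately; IUPAC ambiguity letters in
input rows encode uncertainty, not observations, and are excluded from
counts. Only reference-defined columns are scored. The plotted profile is
the mean of 20 consecutive positional values, anchored at the window's
first position, stepping by one (the step is not standardised anywhere;
step 1 is the information-maximal choice). The logarithm base (2) is
recorded in output metadata.

The consensus at cutoff *c* chooses, per column, the minimal base set
whose summed frequency over observed bases reaches *c*, adding bases in
order of decreasing count with alphabetical tie-break; the set is
rendered as its IUPAC letter, lower-cased when the column's gap fraction
exceeds 10%. Count sums are compared as integers so the cutoff test is
exact. Candidate priming sites are maximal upper-case consensus runs at
the 95% cutoff with length ≥ 18 and ≤ 3 degenerate letters; each site
reports the fraction of sequences matching the consensus sets at every
position. Hypervariable stretches are maximal runs of windowed entropy
above a configurable fraction (default 50%) of the profile maximum — no
absolute threshold is standard, so it is a parameter, not a guess.

## Sequence distances and concordance

Pairwise distance is mismatches over comparable columns. Columns gapped
in both rows are skipped and terminal gap overhangs are ignored. Under
the default `onegap` policy a contiguous gap run in one sequence counts
as a single difference event (the convention of the classic OTU-pipeline
ecosystem); `percolumn` charges every single-gap column. A pair with no
comparable columns is NaN, never 0.

Concordance between a region's distances and the FL distances, on
uniformly sampled id pairs without replacement, is summarised by Pearson
r, an OLS line, and a LOWESS curve (tri-cube weighted local linear fits,
span 2/3, 3 robustifying iterations — classical defaults). The default
sample is 20,000 pairs, a desk-scale stand-in for the 10⁶-pair design the
full-scale study used.

## Taxonomy classifier

The classifier is the standard word-based bootstrap naive-Bayes design
for ribosomal taxonomy: 8-mers indexed once per sequence (presence, not
multiplicity), word prior (n_w + 0.5)/(N + 1), genus conditional
(m_wg + prior)/(M_g + 1), genus score Σ log P(w|g). Confidence per rank
is the fraction of 100 bootstrap replicates — each re-scoring ⌈W/8⌉
words drawn with replacement — whose winning genus agrees with the
full-query winner at that rank. The effective assignment truncates at the
first rank whose confidence falls below the cutoff (default 50%).
Argmax ties are broken uniformly at random under the run seed. Word
size, replicate count, subsample fraction and cutoff are all exposed.
Training always strips gaps first: words are sequence features, not
alignment features.

Phylum representation compares region and FL classification counts as
100 × (region − FL)/FL, with population categories on FL counts
(A > 1000, C > 100, D ≤ 100; B is the pooled unclassified group). A
phylum absent from FL but present in a region is reported as "novel in
region" with an undefined percentage.

## Community comparison

OTUs come from average-linkage agglomerative clustering at a 3% distance
cutoff (complete/single exposed as options). Sample distances are
Bray-Curtis on relative abundances and Jaccard on presence/absence; the
phylogenetic route builds a neighbor-joining tree (standard Saitou–Nei
NJ; the original relaxed-NJ heuristic is a speed device, not a different
estimator, and standard NJ keeps the pipeline deterministic) and computes
weighted (normalised by Σ b(p_A + p_B)) and unweighted UniFrac via a
branch-incidence formulation.

"PCA on the distances" is ambiguous when datasets, not samples, are the
plotted points; here each dataset's feature vector is the vectorised
upper triangle of its sample-distance matrix, columns are mean-centred
without scaling, and datasets are projected on PC1/PC2. The Euclidean
distance from each region dataset to FL in that plane is the benchmark's
summary of fidelity. A sample-level PCA would answer a different
question (how samples separate), not how datasets resemble FL.

## Synthetic data: what it emulates and what it does not

The generator evolves a root sequence down a balanced 6-rank taxonomy
tree under Jukes–Cantor-style substitution (uniform choice among the
three alternative bases), with a per-position rate multiplier: 1.0 in
the V3/V4-like windows, 0.5/0.4 in the V5/V6-like windows, 0.05 in the
flanks. This reproduces the entropy geography the benchmark exploits —
conserved flanks usable as priming sites, variable windows carrying the
taxonomic signal — with the two long regions more informative than the
two short ones. The genus-level edge rate is scaled down (factor 0.05)
so sibling genera are closely related and their discriminating signal
lives almost entirely inside the windows; short trimmed fragments then
genuinely lose classification confidence, which is the mechanism behind
region-dependent taxonomy loss in real partial reads. Leaf counts follow
Pareto draws per phylum and per genus, giving a few large and many rare
taxa. Indels are emulated as columns gapped in a random subset of
non-reference rows; the reference row stays ungapped.

Virtual communities draw, per sample, a random 60% subset of sequences,
log-normal(0, 1.5) abundances, and a multinomial read sample at a depth
uniform in the configured range. The default preset uses 800 sequences,
1400 columns and 9 samples at depths 2,600–5,400 — a desk-scale mirror
of the full-scale design (42,109 sequences; 9 samples of 26,000–54,000
reads), chosen so that both arms complete in minutes on one CPU. The
`scripts/acceptance.py` report runs the database arm at 800 sequences
and the simulation arm (all six distance families) at 300.

Not modelled: 16S secondary structure, chimeras, sequencing error,
amplification bias, rate heterogeneity beyond the window multipliers.
Passing tests therefore demonstrate the correctness and internal
consistency of the machinery and the qualitative region ordering under
the stated generative assumptions — not quantitative agreement with any
particular environmental dataset.

## Numerical conventions

Undefined quantities (empty columns, zero-variance correlations,
distances with no comparable columns, all-zero abundance vectors, empty
UniFrac samples) are NaN markers, never silent zeros. Negative NJ branch
lengths are clamped to zero. PCA component signs are fixed by making
each component's largest-magnitude loading positive. One run seed fans
out to per-stage child seeds by stable SHA-256 hashing of stage names,
so stage order cannot affect reproducibility; rerunning a configuration
reproduces byte-identical TSV outputs.

## Known limitations

* Distances between heavily gapped trimmed rows depend on the gap
  policy; both policies are exposed but only `onegap` is the default.
* The classifier trains and self-classifies on the same synthetic
  collection; generalisation error on held-out queries is larger.
* With few datasets (five), PCA coordinates are exact linear algebra but
  the PC1/PC2 plane can rotate between nearby configurations; only
  relative distances to FL are interpreted.
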