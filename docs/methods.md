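# Methods

This note records the models and procedures `linksom` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## SOM training

Each data type (gene expression, peak accessibility) is a feature-by-cell
matrix; features are the vectors being clustered, cells are the dimensions.
The map is a rows×cols lattice with toroidal wraparound, so the lattice
metric is Euclidean on wrapped row/column deltas and no unit is an edge
case.

Training is classic online Kohonen learning. A trial samples
`floor(train_fraction · n_features)` features once, without replacement
(default 0.5: half the features train, the full matrix is scored
afterwards, so held-out features act as a soft sanity check on the map).
Each epoch visits every training vector once in a freshly shuffled order,
so the total step count is `epochs × n_training_vectors`. At step *t* of
*T*:

- learning rate `α(t) = alpha0 · (1 − t/T)`, default `alpha0 = 0.2`;
- neighborhood `h = exp(−d²/2σ(t)²)` with *d* the toroidal lattice distance
  to the best matching unit (BMU) and σ decaying linearly from
  `max(rows, cols)/2` to 0.5 — by the end of training only the BMU's
  immediate vicinity moves;
- every unit updates `w ← w + α·h·(v − w)`.

These schedules are standard Kohonen practice; they are configurable
because the method's robustness, not a specific schedule, is the point.
Weights initialize i.i.d. uniform over each cell-dimension's observed
[min, max]; trial *i* uses seed `seed + i`, so a run is bit-reproducible.
The fitting error used to pick the best of `n_trials` restarts is the mean
quantization error (mean Euclidean distance of training vectors to their
BMU) — the standard SOM fit criterion. BMU ties break row-major.

Full-scale presets (40×60 map, 1000 epochs, 100 trials, train on half the
features) are exposed but the package's own tests and benchmarks run 10×12
maps with 5 trials on the synthetic study, which is the scale those data
need.

Input values are used as provided (no transform); `log1p` and per-cell
total-count scaling are available as flags since expression units (FPKM-like)
are heavy-tailed and library sizes vary in real data.

## Metaclustering

Units are partitioned into *k* lattice-contiguous metaclusters:

1. ordinary k-means (k-means++, 10 restarts, seeded) on the unit weight
   vectors supplies centroids;
2. contiguity repair: each metacluster is seeded at the unclaimed unit
   nearest its centroid (ties row-major), then a single global priority
   queue repeatedly assigns the unassigned unit with the smallest
   weight-space distance to a centroid whose region it already touches
   (4-neighbor toroidal adjacency), until the lattice is covered.

Greedy priority growth guarantees every metacluster is connected (verified
by BFS in the tests) while staying close to the unconstrained k-means
solution. 4-neighbor (von Neumann) adjacency is the stricter reading of
"adjacent units" and is the default; 8-neighbor is a flag.

*k* is selected by scanning a range and minimizing

    AIC(k) = n·D·ln(RSS/n) + 2·k·D

with *n* the number of units, RSS the within-metacluster sum of squared
distances (floored at `1e-12·n` to keep the log finite on degenerate
grids), and *D* the "dimensionality": the number of clusters when an
average-linkage dendrogram of the unit vectors is cut at 30% of its maximum
merge height. This is the spherical-Gaussian k-means AIC. Note that *D*
multiplies both terms, so the argmin over *k* is invariant to it; *D* is
still computed and reported because the score itself is meaningful for
comparing maps. Average linkage was chosen for the dimensionality estimate
as robust to chaining; "30% of the total distance" is read as 30% of the
maximum merge height (the natural dendrogram cut), both configurable.
AIC ties go to the smaller *k*.

## Map statistics and trait enrichment

Per-cell maps average the cell's signal over the features assigned to each
unit; the summary map totals signal per unit; the difference map subtracts
trait-averaged cell maps (antisymmetric by construction); the U-matrix is
the mean weight distance to the 8 toroidal neighbors; the density map
counts features per unit.

Trait enrichment per metacluster: the representative profile is the
*mean* per-cell signal over member features — mean, not sum, so metacluster
size does not inflate the statistic. The statistic is the Pearson
correlation of that profile with the binary indicator of a trait level. The
p-value is a one-tailed permutation test over cell labels,
`p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm)`, because per-cell signals are
not Gaussian (dropout zeros, skew). Default `n_perm = 10,000` puts the
permutation floor at ~1e-4, matching the default `alpha = 1e-4`; an
optional Bonferroni flag divides alpha by the number of
(metacluster, level) tests. A metacluster with no features is reported
non-enriched with p = 1.

## Linking

Regulatory domains follow the one-closest rule: per chromosome, a gene's
domain runs from `tss − min(50 kb, left_gap)` to `tss + min(50 kb,
right_gap)`, where a gap is the distance to the midpoint with the
neighboring TSS (clipped at 0 on the left; unbounded at chromosome ends up
to the cutoff). Domains are therefore disjoint and at most 100 kb long.
Extension is strand-symmetric. Coincident TSSs collapse a domain to 1 bp
rather than zero.

A peak maps to a gene if it overlaps the gene's domain by ≥1 bp. A peak
straddling adjacent domains goes to the gene whose TSS is closer to the
peak midpoint, ties to the lexicographically smaller gene id — any
deterministic rule works here since the linker must be single-valued; this
one is symmetric and reproducible. Peaks on chromosomes without annotated
genes are unmapped with a warning.

All coordinates are 0-based half-open internally (BED convention); GTF is
converted on read, taking the 5′-most TSS per gene across transcript lines.

## Motif scanning and enrichment

Log-odds scores are `log2((p + pc·bg)/bg)` against the genome-wide
mononucleotide background (N excluded), pseudocount `pc = 0.1`. Exact
per-site p-values come from the discretized null distribution of the site
score under the background, built by positional convolution. Scores are
binned on a common width — the largest per-position score range divided by
`granularity − 1` (default granularity 1000 bins per position) — because
an additive dynamic program needs one bin width across positions.
Positions that are strictly unscorable (zero probability with zero
pseudocount) occupy a bin strictly below every finite score. The survival
function of the total binned score is the p-value table; windows containing
N are skipped; lowercase (repeat-masked) sequence is scanned as uppercase.

Scanning is per LM: both strands of every region are scanned, and
Benjamini-Hochberg correction is applied over all candidate sites within
one (motif, LM) pair; hits with `q < 0.05` are retained. Opposite-strand
hits at the same forward offset (palindromes) deduplicate to the
better-scoring one.

Enrichment per motif: `f_i` is the fraction of regions in LM *i* with at
least one passing hit, computed over LMs with at least `min_regions = 5`
regions (a floor for fraction stability on tiny LMs). The baseline is the
mean of `f_i` across **all** such LMs — not only the differential ones —
and `z_i = (f_i − mean)/SD` (sample SD) with a one-tailed normal p-value;
`p < 0.05` flags enrichment. Using all LMs as baseline gives the z-test a
real population to stand on; a flag restricts the baseline to a chosen LM
subset. If the SD is zero (all fractions equal) nothing is enriched. The
z-test is a population-level screen, approximately calibrated when the
baseline population is reasonably large; the null-calibration benchmark
quantifies this.

## Network assembly

For every enriched (motif, LM) pair whose LM is differential, each region
in the LM with a passing hit of that motif contributes an edge
TF → h(region); evidence (LM, region) pairs merge per (TF, target). The
TF-only subnetwork keeps targets that are themselves factors in the motif
database and sit in a trait-enriched RNA metacluster, restricted to the
weakly-connected component of a chosen root factor; edge direction labels
come from the target's enriched trait level given an ordered trait list
(earliest level → "down", later → "up"). Exports are an edge-list TSV and
GraphML.

## Synthetic study generator

The generator emulates a two-timepoint paired single-cell experiment with
planted structure at every level the pipeline tests:

- 400 genes in 12 co-regulated modules (round-robin membership), of which
  4 are dynamic: a 4-fold change between timepoints, alternating direction.
  The module count exceeds the dynamic count deliberately — real data has
  many non-dynamic clusters, and the motif z-test needs a baseline
  population of LMs to compare against.
- Module profiles are a log-normal-jittered base level (deterministically
  spread across modules so no two share a profile) plus additive Gaussian
  noise (sd 0.5), 30% Bernoulli dropout, clipped at zero. Genes and their
  promoter peaks share module membership, so RNA and ATAC structure
  co-vary; 200 decoy intergenic peaks carry a static background profile.
- Genes sit on a uniform-random genome at 130 kb spacing, so 50-kb domains
  never abut and each promoter peak links to its own gene by construction;
  decoys sit in the gaps outside all domains (linker true negatives).
- One information-rich 8-bp motif per dynamic module (consensus probability
  0.97 per position) is written into 90% of that module's promoter peaks at
  seeded random offsets; two decoy motifs are planted nowhere. The planted
  (motif → gene) pairs are the ground-truth regulatory edges.
- 60 cells per timepoint, i.i.d. across cells.

What it does **not** emulate: UMI/read-count discreteness, batch effects,
doublets, cell-type mixtures within a timepoint, correlated dropout,
dinucleotide genome composition, repeat structure, or motif variants
(only exact-consensus planting). Passing the recovery benchmark therefore
shows the pipeline's machinery is correct and sensitive under its own
assumptions; it does not certify performance on real data with those
complications.

The planted-block grid generator (used to test metaclustering in
isolation) builds contiguous row-bands of unit weights with the minimum
pairwise center separation fixed at 5× the within-block spread. Its weight
dimension defaults to 128 — larger than the unit count per block — because
with few points in many dimensions the top sample eigenvalue of pure noise
inflates, making noise splits look profitable to AIC; a high ratio of
dimension to block size keeps the noise effectively isotropic.

## Numerical conventions and degenerate inputs

- Seeds: every stochastic step (trial subsampling, weight init, k-means,
  permutations, generator) derives from an explicit integer seed.
- BMU and metacluster-seed ties break row-major; AIC ties to smaller k;
  straddling-peak ties to the lexicographically smaller gene id.
- RSS floor `1e-12·n`; enrichment SD ≤ 1e-12 treated as zero; MEME
  probability rows off by ≤1e-3 renormalized, worse is an error.
- Matrices must be finite, non-negative, ≥2×2 with unique ids; BED
  intervals must be non-empty; unknown strands are errors.

## Benchmark problem sizes

The validation benchmarks run at sizes chosen to exercise every code path
while staying desk-scale: 1,000 random BMU instances; 50 random 6×8 grids
× k ∈ [2,8] for contiguity; planted blocks b ∈ {3,5,8} on 8×10 grids;
20 random PWMs of length ≤ 6 against full 4^L enumeration; 100 LM-membership
shuffles of 100 LMs × 30 regions for z-test calibration; 10,000 label
permutations on a no-effect study for trait-test calibration; and the full
pipeline on the default synthetic study (10×12 SOMs, 5 trials).

## Known limitations

- The enrichment z-test assumes the per-LM hit fractions are roughly
  exchangeable and normal under the null; with very few analyzed LMs
  (< ~10) a single-LM signal cannot reach one-tailed significance at 0.05
  (the max attainable z is (n−1)/√n), so study designs need a baseline
  population of LMs.
- The linker implements only the one-closest rule; basal-plus-extension or
  two-closest domain definitions, and co-accessibility-based linking, are
  out of scope.
- Online SOM training is O(steps × units × cells) on one core; full-scale
  presets (40×60 × 1000 epochs × 100 trials) are hours of CPU, unchanged
  from the method's nature.
- The mononucleotide background ignores dinucleotide composition; repeat
  regions are scanned (uppercased) by design, matching the method's stated
  behavior.
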