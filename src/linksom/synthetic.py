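"""Fully synthetic multi-omic fixtures with planted structure.

The generator emulates the shape of a paired single-cell experiment over a
short time course: a gene-by-cell expression matrix, a peak-by-cell
accessibility matrix with peak coordinates, a gene annotation, a random
genome and a small motif database.  Structure is planted at three levels so
every pipeline stage has known ground truth:

* genes (and their promoter-proximal peaks) belong to co-regulated modules
  with a shared mean profile; a subset of modules is "dynamic", changing by
  a fold factor between the two trait levels (timepoints);
* each gene has one promoter peak inside its regulatory domain, plus decoy
  intergenic peaks outside every domain (linker true negatives);
* each dynamic module is assigned a transcription factor whose motif
  consensus is written into a fraction of that module's promoter peaks,
  defining the true TF -> gene regulatory edges.

Genes are spaced >= 120 kb apart so 50-kb regulatory domains never abut,
keeping the region -> gene linking unambiguous by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import PWM, ALPHABET, FeatureMatrix, GeneAnnotation, GenomicInterval, TraitLabels

__all__ = [
    "FixtureSpec",
    "Fixture",
    "make_genome",
    "make_annotation_and_peaks",
    "make_matrices",
    "make_pwms",
    "plant_motifs",
    "make_fixture",
    "make_planted_block_grid",
    "make_cluster_matrix",
]

GENE_SPACING = 130_000   # > 120 kb so 50-kb domains leave intergenic gaps
FIRST_TSS = 65_000
PEAK_HALF_WIDTH = 100    # promoter peaks are 200 bp


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic experiment.

    Defaults mirror a small two-timepoint single-cell study: 60 cells per
    timepoint, 400 genes in 12 co-regulated modules of which 4 are dynamic
    (4-fold change between timepoints, alternating direction), one promoter
    peak per gene plus 200 intergenic decoys, 30% dropout and additive
    Gaussian noise.  One information-rich 8-bp motif is planted in 90% of
    each dynamic module's promoter peaks; two decoy motifs are planted
    nowhere.
    """

    n_genes: int = 400
    n_peaks: int = 600
    n_cells_per_trait: int = 60
    n_traits: int = 2
    n_planted_modules: int = 12
    n_dynamic_modules: int = 4
    fold_change: float = 4.0
    dropout_rate: float = 0.30
    noise_sd: float = 0.50
    motif_length: int = 8
    plant_fraction: float = 0.90
    n_decoy_motifs: int = 2
    n_chroms: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0 <= self.plant_fraction <= 1:
            raise ValueError("plant_fraction must be in [0, 1]")
        if self.n_dynamic_modules > self.n_planted_modules:
            raise ValueError("more dynamic modules than modules")
        if self.n_peaks < self.n_genes:
            raise ValueError("need at least one peak per gene")

    @property
    def trait_levels(self) -> list[str]:
        return [f"t{i}" for i in range(self.n_traits)]


@dataclass
class Fixture:
    spec: FixtureSpec
    genome: dict[str, str]
    genes: list[GeneAnnotation]
    peaks: list[GenomicInterval]
    rna: FeatureMatrix
    atac: FeatureMatrix
    labels: TraitLabels
    pwms: list[PWM]
    tf_gene_map: dict[str, str]
    module_of_gene: dict[str, int]
    promoter_peak_of_gene: dict[str, str]
    planted_sites: dict[tuple[str, str], int]  # (motif_id, peak_id) -> offset
    true_edges: set[tuple[str, str]] = field(default_factory=set)

    @property
    def dynamic_modules(self) -> list[int]:
        return list(range(self.spec.n_dynamic_modules))


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def make_genome(n_chroms: int, chrom_len: int, seed: int) -> dict[str, str]:
    """i.i.d. uniform ACGT contigs, deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for i in range(n_chroms):
        codes = rng.integers(0, 4, size=chrom_len)
        genome[f"chr{i + 1}"] = lut[codes].tobytes().decode("ascii")
    return genome


def write_fasta(genome: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# annotation and peaks
# ---------------------------------------------------------------------------

def make_annotation_and_peaks(spec: FixtureSpec) -> tuple[
        list[GeneAnnotation], list[GenomicInterval], dict[str, int],
        dict[str, str], int]:
    """Place genes on evenly spaced TSSs, one promoter peak per gene inside
    its domain, and decoy peaks in the intergenic gaps outside all domains.

    Returns (genes, peaks, module_of_gene, promoter_peak_of_gene, chrom_len);
    module membership is round-robin over gene index.
    """
    per_chrom = math.ceil(spec.n_genes / spec.n_chroms)
    chrom_len = FIRST_TSS + per_chrom * GENE_SPACING

    genes: list[GeneAnnotation] = []
    peaks: list[GenomicInterval] = []
    module_of_gene: dict[str, int] = {}
    promoter_peak: dict[str, str] = {}
    gap_centers: list[tuple[str, int]] = []
    for g in range(spec.n_genes):
        chrom = f"chr{g // per_chrom + 1}"
        pos_on_chrom = g % per_chrom
        tss = FIRST_TSS + pos_on_chrom * GENE_SPACING
        gene_id = f"gene{g:04d}"
        strand = "+" if g % 2 == 0 else "-"
        genes.append(GeneAnnotation(gene_id, chrom, tss, strand))
        module_of_gene[gene_id] = g % spec.n_planted_modules
        peak_id = f"peak_{gene_id}"
        peaks.append(GenomicInterval(chrom, tss - PEAK_HALF_WIDTH,
                                     tss + PEAK_HALF_WIDTH, peak_id))
        promoter_peak[gene_id] = peak_id
        # gap midpoint between this TSS's domain (+50 kb) and the next (-50 kb)
        gap_centers.append((chrom, tss + GENE_SPACING // 2))

    n_decoys = spec.n_peaks - spec.n_genes
    if n_decoys > len(gap_centers):
        raise ValueError("not enough intergenic gaps for the requested decoys")
    for d in range(n_decoys):
        chrom, center = gap_centers[d]
        peaks.append(GenomicInterval(chrom, center - PEAK_HALF_WIDTH,
                                     center + PEAK_HALF_WIDTH, f"decoy{d:04d}"))
    return genes, peaks, module_of_gene, promoter_peak, chrom_len


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def _module_mean(module: int, trait_idx: int, spec: FixtureSpec,
                 base: np.ndarray) -> float:
    """Mean signal of a module in one trait level."""
    b = base[module]
    if module >= spec.n_dynamic_modules:
        return b
    # alternate direction: even dynamic modules rise over the course,
    # odd ones fall
    rising = module % 2 == 0
    last = spec.n_traits - 1
    boosted = trait_idx == (last if rising else 0)
    return b * spec.fold_change if boosted else b


def make_matrices(spec: FixtureSpec) -> tuple[FeatureMatrix, FeatureMatrix,
                                              TraitLabels]:
    """Expression and accessibility matrices plus trait labels.

    Genes and their promoter peaks share module membership, so RNA and ATAC
    modules co-vary; decoy peaks carry a static background profile.  Values
    are module mean + N(0, noise_sd), clipped at 0, with Bernoulli dropout.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes, peaks, module_of_gene, _, _ = make_annotation_and_peaks(spec)
    n_cells = spec.n_cells_per_trait * spec.n_traits
    cell_ids = [f"cell{c:04d}" for c in range(n_cells)]
    trait_of_cell = [spec.trait_levels[c // spec.n_cells_per_trait]
                     for c in range(n_cells)]
    trait_idx = np.array([c // spec.n_cells_per_trait for c in range(n_cells)])

    # per-module log-normal base level with deterministic spread across
    # modules so no two modules share a profile
    base = (1.5 + np.arange(spec.n_planted_modules)) * rng.lognormal(
        mean=0.0, sigma=0.15, size=spec.n_planted_modules)

    def fill(feature_modules: list[int | None], scale: float,
             r: np.random.Generator) -> np.ndarray:
        vals = np.empty((len(feature_modules), n_cells))
        for i, mod in enumerate(feature_modules):
            if mod is None:
                mean = np.full(n_cells, 2.0)
            else:
                mean = np.array([_module_mean(mod, t, spec, base)
                                 for t in trait_idx])
            row = scale * mean + r.normal(0.0, spec.noise_sd, n_cells)
            vals[i] = np.clip(row, 0.0, None)
        if spec.dropout_rate > 0:
            vals[r.random(vals.shape) < spec.dropout_rate] = 0.0
        return vals

    gene_mods: list[int | None] = [module_of_gene[g.gene_id] for g in genes]
    rna = FeatureMatrix([g.gene_id for g in genes], cell_ids,
                        fill(gene_mods, 1.0, rng), "gene")

    peak_mods: list[int | None] = []
    for p in peaks:
        if p.id.startswith("peak_"):
            peak_mods.append(module_of_gene[p.id[len("peak_"):]])
        else:
            peak_mods.append(None)
    atac = FeatureMatrix([p.id for p in peaks], cell_ids,
                         fill(peak_mods, 1.0, rng), "region")
    return rna, atac, TraitLabels(cell_ids, trait_of_cell)


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------

def make_pwms(n: int, length: int, seed: int,
              sharpness: float = 0.97) -> list[PWM]:
    """Information-rich PWMs: random consensus, ``sharpness`` probability on
    the consensus base, the remainder spread over the other three."""
    rng = np.random.default_rng(seed)
    pwms = []
    for i in range(n):
        cons = rng.integers(0, 4, size=length)
        mat = np.full((length, 4), (1.0 - sharpness) / 3.0)
        mat[np.arange(length), cons] = sharpness
        pwms.append(PWM(f"TFM{i:02d}", mat))
    return pwms


def plant_motifs(spec: FixtureSpec, genome: dict[str, str],
                 peaks: list[GenomicInterval], pwms: list[PWM],
                 module_of_gene: dict[str, int]) -> tuple[
                     dict[str, str], dict[tuple[str, str], int],
                     set[tuple[str, str]]]:
    """Write each dynamic module's motif consensus at a seeded random offset
    inside ``plant_fraction`` of that module's promoter peaks.

    Returns (modified genome, planted (motif, peak) -> offset,
    true (motif, gene) edge set).  Motif i targets dynamic module i.
    """
    rng = np.random.default_rng(spec.seed + 2)
    seqs = {c: bytearray(s, "ascii") for c, s in genome.items()}
    peaks_by_id = {p.id: p for p in peaks}
    planted: dict[tuple[str, str], int] = {}
    true_edges: set[tuple[str, str]] = set()
    for module in range(spec.n_dynamic_modules):
        pwm = pwms[module]
        cons = pwm.consensus.encode("ascii")
        module_genes = sorted(g for g, m in module_of_gene.items() if m == module)
        n_plant = int(round(spec.plant_fraction * len(module_genes)))
        chosen = rng.choice(len(module_genes), size=n_plant, replace=False)
        for gi in sorted(chosen):
            gene = module_genes[gi]
            peak = peaks_by_id[f"peak_{gene}"]
            offset = int(rng.integers(0, peak.end - peak.start - len(cons) + 1))
            start = peak.start + offset
            seqs[peak.chrom][start:start + len(cons)] = cons
            planted[(pwm.motif_id, peak.id)] = offset
            true_edges.add((pwm.motif_id, gene))
    return ({c: bytes(s).decode("ascii") for c, s in seqs.items()},
            planted, true_edges)


# ---------------------------------------------------------------------------
# planted grids and matrices for direct testing of downstream stages
# ---------------------------------------------------------------------------

def make_planted_block_grid(rows: int, cols: int, n_blocks: int,
                            dim: int = 128, noise: float = 0.2, seed: int = 0,
                            min_separation_ratio: float = 5.0):
    """A SOMGrid whose units form ``n_blocks`` contiguous row-bands of
    well-separated weight clusters; returns (grid, planted unit labels).

    Block centers are rescaled so the minimum pairwise center distance is
    ``min_separation_ratio`` times the within-block unit spread
    (noise * sqrt(2*dim), the typical distance between two same-block units).
    The default weight dimension (128, i.e. more cells than units per block)
    keeps the within-block noise nearly isotropic: with few points in many
    dimensions the top sample eigenvalue inflates, which would make k-means
    splits of pure noise look profitable to AIC.
    """
    from .som_core import SOMConfig, SOMGrid

    rng = np.random.default_rng(seed)
    centers = rng.normal(0, 1, (n_blocks, dim))
    dists = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
    min_d = dists[np.triu_indices(n_blocks, k=1)].min()
    spread = noise * np.sqrt(2 * dim)
    centers *= min_separation_ratio * spread / min_d
    bands = np.array_split(np.arange(rows), n_blocks)
    labels = np.empty(rows * cols, dtype=int)
    weights = np.empty((rows * cols, dim))
    for bi, rs in enumerate(bands):
        for r in rs:
            for c in range(cols):
                u = r * cols + c
                labels[u] = bi
                weights[u] = centers[bi] + rng.normal(0, noise, dim)
    grid = SOMGrid(rows, cols, weights,
                   SOMConfig(rows=rows, cols=cols), fit_error=0.0)
    return grid, labels


def make_cluster_matrix(n_per_cluster: int = 20, n_clusters: int = 4,
                        n_cells: int = 24, sep: float = 8.0,
                        noise: float = 0.3, seed: int = 0):
    """FeatureMatrix of well-separated Gaussian feature clusters; returns
    (matrix, per-feature cluster labels)."""
    rng = np.random.default_rng(seed)
    centers = rng.uniform(1.0, 1.0 + sep, (n_clusters, n_cells))
    rows, labels = [], []
    for k in range(n_clusters):
        block = centers[k] + rng.normal(0, noise, (n_per_cluster, n_cells))
        rows.append(np.clip(block, 0, None))
        labels.extend([k] * n_per_cluster)
    values = np.vstack(rows)
    m = FeatureMatrix(
        [f"f{i}" for i in range(len(values))],
        [f"c{j}" for j in range(n_cells)],
        values,
    )
    return m, np.array(labels)


# ---------------------------------------------------------------------------
# full fixture
# ---------------------------------------------------------------------------

def make_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Generate the complete synthetic study: genome, annotation, peaks,
    matrices, labels, motif database with planted sites, and ground truth."""
    spec = spec or FixtureSpec()
    genes, peaks, module_of_gene, promoter_peak, chrom_len = \
        make_annotation_and_peaks(spec)
    genome = make_genome(spec.n_chroms, chrom_len, spec.seed)
    pwms = make_pwms(spec.n_dynamic_modules + spec.n_decoy_motifs,
                     spec.motif_length, spec.seed + 3)
    genome, planted, true_edges = plant_motifs(spec, genome, peaks, pwms,
                                               module_of_gene)
    rna, atac, labels = make_matrices(spec)
    # each motif's factor is itself a gene of its module (first planted gene)
    tf_gene_map: dict[str, str] = {}
    for module in range(spec.n_dynamic_modules):
        module_genes = sorted(g for g, m in module_of_gene.items()
                              if m == module)
        tf_gene_map[pwms[module].motif_id] = module_genes[0]
    return Fixture(spec=spec, genome=genome, genes=genes, peaks=peaks,
                   rna=rna, atac=atac, labels=labels, pwms=pwms,
                   tf_gene_map=tf_gene_map, module_of_gene=module_of_gene,
                   promoter_peak_of_gene=promoter_peak,
                   planted_sites=planted, true_edges=true_edges)
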