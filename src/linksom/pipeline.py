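"""End-to-end orchestration: train both SOMs, metacluster, link, scan, build
the network.  This is the programmatic equivalent of chaining the CLI
subcommands and is what the worked example and the recovery benchmarks run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import FeatureMatrix, GenomicInterval, PWM, TraitLabels, GeneAnnotation
from .linker import (LinkedMetaclusters, LinkerMapping, build_domains,
                     build_linked_metaclusters, differential_lms, link_regions)
from .map_analysis import TraitEnrichment, trait_enrichment
from .metacluster import Metaclustering, select_metaclustering
from .motif import EnrichmentResult, MotifHit, enrichment_zscores, genome_background, scan_lms
from .network import GRN, RegulatoryEdge, build_edges
from .som_core import SOMConfig, SOMGrid, UnitAssignment, score_som, train_som

logger = logging.getLogger(__name__)

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineParams:
    """Defaults are sized for a small synthetic study (hundreds of features,
    ~120 cells); for full-scale data raise rows/cols/epochs/n_trials and the
    k ranges toward the 40x60 / 1000-epoch / 100-trial presets."""

    rows: int = 10
    cols: int = 12
    epochs: int = 50
    n_trials: int = 5
    train_fraction: float = 0.5
    rna_k_range: tuple[int, int] = (8, 16)
    atac_k_range: tuple[int, int] = (8, 16)
    domain_cutoff_bp: int = 50_000
    n_perm: int = 10_000
    trait_alpha: float = 1e-4
    motif_q: float = 0.05
    motif_alpha: float = 0.05
    min_regions: int = 5
    seed: int = 0


@dataclass
class PipelineResult:
    rna_grid: SOMGrid
    atac_grid: SOMGrid
    rna_assignment: UnitAssignment
    atac_assignment: UnitAssignment
    rna_mc: Metaclustering
    atac_mc: Metaclustering
    rna_enrichment: list[TraitEnrichment]
    atac_enrichment: list[TraitEnrichment]
    mapping: LinkerMapping
    lms: LinkedMetaclusters
    differential: list[tuple[int, int]]
    hits: list[MotifHit]
    motif_enrichment: list[EnrichmentResult]
    edges: list[RegulatoryEdge]

    @property
    def grn(self) -> GRN:
        return GRN(self.edges)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.tf, e.target) for e in self.edges}


def run_pipeline(rna: FeatureMatrix, atac: FeatureMatrix,
                 labels: TraitLabels, genes: list[GeneAnnotation],
                 peaks: list[GenomicInterval], genome, pwms: list[PWM],
                 params: PipelineParams = PipelineParams()) -> PipelineResult:
    """Run the full linked-SOM analysis.

    Steps: train a toroidal SOM per data type (best of n_trials), score all
    features, metacluster each map by AIC over its k range, test trait
    enrichment per metacluster, link peaks to genes through 50-kb regulatory
    domains, partition linked pairs into LMs, scan LM regions for motifs
    (BH within each motif/LM), z-test per-LM motif occupancy against the
    cross-LM baseline, and emit TF -> gene edges from enriched motifs in
    differential LMs.
    """
    p = params
    cfg = dict(rows=p.rows, cols=p.cols, epochs=p.epochs, n_trials=p.n_trials,
               train_fraction=p.train_fraction)
    logger.info("training RNA SOM (%d features)", rna.n_features)
    rna_grid = train_som(rna, SOMConfig(seed=p.seed, **cfg))
    logger.info("training ATAC SOM (%d features)", atac.n_features)
    atac_grid = train_som(atac, SOMConfig(seed=p.seed + 10_000, **cfg))
    rna_assignment = score_som(rna, rna_grid)
    atac_assignment = score_som(atac, atac_grid)

    rna_mc = select_metaclustering(rna_grid, *p.rna_k_range, seed=p.seed)
    atac_mc = select_metaclustering(atac_grid, *p.atac_k_range, seed=p.seed)
    logger.info("selected k_rna=%d (AIC=%.1f), k_atac=%d (AIC=%.1f)",
                rna_mc.k, rna_mc.aic, atac_mc.k, atac_mc.aic)

    rna_enrich = trait_enrichment(rna_assignment, rna, labels, rna_mc,
                                  n_perm=p.n_perm, seed=p.seed,
                                  alpha=p.trait_alpha)
    atac_enrich = trait_enrichment(atac_assignment, atac, labels, atac_mc,
                                   n_perm=p.n_perm, seed=p.seed,
                                   alpha=p.trait_alpha)

    domains = build_domains(genes, p.domain_cutoff_bp)
    mapping = link_regions(peaks, domains)
    lms = build_linked_metaclusters(mapping, atac_mc, atac_assignment,
                                    rna_mc, rna_assignment)
    differential = differential_lms(lms, atac_enrich, rna_enrich,
                                    min_regions=p.min_regions)
    logger.info("%d differential LMs of %d cells", len(differential), lms.n_cells)

    background = genome_background(genome)
    regions_by_id = {r.id: r for r in peaks}
    hits = scan_lms(lms, regions_by_id, genome, pwms,
                    min_regions=p.min_regions, q_threshold=p.motif_q,
                    background=background)
    enrichment = enrichment_zscores(hits, lms, alpha=p.motif_alpha,
                                    min_regions=p.min_regions,
                                    motif_ids=[m.motif_id for m in pwms])
    edges = build_edges(enrichment, hits, lms, differential=differential)
    logger.info("%d regulatory edges", len(edges))
    return PipelineResult(rna_grid, atac_grid, rna_assignment, atac_assignment,
                          rna_mc, atac_mc, rna_enrich, atac_enrich, mapping,
                          lms, differential, hits, enrichment, edges)
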