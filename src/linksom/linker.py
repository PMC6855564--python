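"""Region-to-gene linking and linked metaclusters.

Each gene gets a regulatory domain around its TSS in the style of GREAT's
OneClosest rule: the domain extends up to 50 kb on each side but stops at
the midpoint with the nearest neighboring TSS, so domains on a chromosome
are disjoint and at most 100 kb long.  Extension is strand-symmetric.

The linker mapping h sends an accessibility region (peak) to the gene whose
domain it overlaps; a region straddling two adjacent domains goes to the
gene whose TSS is nearer the region midpoint (ties to the lexicographically
smaller gene id), keeping h single-valued.  Regions overlapping no domain
are unmapped.

Given metaclusterings M (regions) and N (genes), the linked metaclusters
(LMs) are the cells of the induced partition of linked (region, gene) pairs:
pair (r, g) lies in LM (i, j) iff h(r) = g, r is in region-metacluster i and
g in gene-metacluster j.  An LM is "differential" when both of its parent
metaclusters are trait-enriched.
"""

from __future__ import annotations

import bisect
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GeneAnnotation, GenomicInterval
from .map_analysis import TraitEnrichment, enriched_metaclusters
from .metacluster import Metaclustering
from .som_core import UnitAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryDomain",
    "LinkerMapping",
    "LinkedMetaclusters",
    "build_domains",
    "link_regions",
    "build_linked_metaclusters",
    "differential_lms",
]

DEFAULT_CUTOFF_BP = 50_000


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    tss: int
    interval: GenomicInterval

    def __post_init__(self) -> None:
        iv = self.interval
        if not iv.start <= self.tss < max(iv.end, self.tss + 1):
            raise ValueError(f"domain of {self.gene_id} does not contain its TSS")


@dataclass
class LinkerMapping:
    """The partial function h: region_id -> gene_id."""

    mapping: dict[str, str]

    def __len__(self) -> int:
        return len(self.mapping)

    def __getitem__(self, region_id: str) -> str:
        return self.mapping[region_id]

    def get(self, region_id: str) -> str | None:
        return self.mapping.get(region_id)

    def items(self):
        return self.mapping.items()


@dataclass
class LinkedMetaclusters:
    """Partition of linked (region, gene) pairs into k_region x k_gene cells."""

    k_region: int
    k_gene: int
    cells: dict[tuple[int, int], list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i in range(self.k_region):
            for j in range(self.k_gene):
                self.cells.setdefault((i, j), [])

    @property
    def n_cells(self) -> int:
        return self.k_region * self.k_gene

    def regions_in(self, lm: tuple[int, int]) -> list[str]:
        return [r for r, _ in self.cells[lm]]

    def n_linked_pairs(self) -> int:
        return sum(len(v) for v in self.cells.values())

    def to_json(self, path: str) -> None:
        obj = {
            "k_region": self.k_region, "k_gene": self.k_gene,
            "cells": {f"{i},{j}": pairs for (i, j), pairs in self.cells.items()
                      if pairs},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path: str) -> "LinkedMetaclusters":
        with open(path) as fh:
            obj = json.load(fh)
        cells = {tuple(map(int, key.split(","))): [tuple(p) for p in pairs]
                 for key, pairs in obj["cells"].items()}
        return cls(obj["k_region"], obj["k_gene"], cells)


# ---------------------------------------------------------------------------
# regulatory domains
# ---------------------------------------------------------------------------

def build_domains(genes: list[GeneAnnotation],
                  cutoff_bp: int = DEFAULT_CUTOFF_BP) -> list[RegulatoryDomain]:
    """OneClosest-style regulatory domains: per chromosome, each gene's
    domain is [tss - min(cutoff, left_gap), tss + min(cutoff, right_gap))
    where a gap is the distance to the midpoint with the neighboring TSS
    (infinite at chromosome ends; left edge clipped at 0)."""
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    domains: list[RegulatoryDomain] = []
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: (g.tss, g.gene_id))
        for i, g in enumerate(gs):
            left = g.tss - cutoff_bp
            if i > 0:
                mid = (gs[i - 1].tss + g.tss) // 2
                left = max(left, mid)
            left = max(left, 0)
            right = g.tss + cutoff_bp
            if i + 1 < len(gs):
                mid = (g.tss + gs[i + 1].tss) // 2
                right = min(right, mid)
            if right <= left:  # coincident TSSs collapse the interval
                right = left + 1
            domains.append(RegulatoryDomain(
                g.gene_id, g.tss,
                GenomicInterval(chrom, left, right, g.gene_id)))
    return domains


# ---------------------------------------------------------------------------
# region -> gene linking
# ---------------------------------------------------------------------------

def link_regions(regions: list[GenomicInterval],
                 domains: list[RegulatoryDomain]) -> LinkerMapping:
    """Map each region to the gene whose domain it overlaps by >= 1 bp.

    A region overlapping several domains goes to the gene with the smallest
    |TSS - region midpoint|, ties to the lexicographically smaller gene id.
    """
    by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.interval.chrom, []).append(d)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda d: d.interval.start)
    starts = {chrom: [d.interval.start for d in ds]
              for chrom, ds in by_chrom.items()}

    mapping: dict[str, str] = {}
    warned: set[str] = set()
    for region in regions:
        ds = by_chrom.get(region.chrom)
        if ds is None:
            if region.chrom not in warned:
                logger.warning("chromosome %s has no annotated genes; "
                               "its regions are unmapped", region.chrom)
                warned.add(region.chrom)
            continue
        # domains are disjoint and sorted: candidates start before region.end
        hi = bisect.bisect_left(starts[region.chrom], region.end)
        overlapping = []
        i = hi - 1
        while i >= 0 and ds[i].interval.end > region.start:
            overlapping.append(ds[i])
            i -= 1
        if not overlapping:
            continue
        mid = region.midpoint
        best = min(overlapping, key=lambda d: (abs(d.tss - mid), d.gene_id))
        mapping[region.id] = best.gene_id
    return LinkerMapping(mapping)


# ---------------------------------------------------------------------------
# linked metaclusters
# ---------------------------------------------------------------------------

def _mc_of(assignment: UnitAssignment, mc: Metaclustering) -> dict[str, int]:
    mc_labels = mc.labels[assignment.units]
    return dict(zip(assignment.feature_ids, mc_labels.tolist()))


def build_linked_metaclusters(
    mapping: LinkerMapping,
    atac_mc: Metaclustering, atac_assignment: UnitAssignment,
    rna_mc: Metaclustering, rna_assignment: UnitAssignment,
) -> LinkedMetaclusters:
    """Place every linked (region, gene) pair into its LM cell (i, j); all
    k_atac x k_rna cells exist, possibly empty.  Pairs whose region or gene
    is absent from its SOM assignment are dropped with a warning."""
    region_mc = _mc_of(atac_assignment, atac_mc)
    gene_mc = _mc_of(rna_assignment, rna_mc)
    lms = LinkedMetaclusters(atac_mc.k, rna_mc.k)
    dropped = 0
    for region_id, gene_id in mapping.items():
        i = region_mc.get(region_id)
        j = gene_mc.get(gene_id)
        if i is None or j is None:
            dropped += 1
            continue
        lms.cells[(i, j)].append((region_id, gene_id))
    if dropped:
        logger.warning("%d linked pairs dropped (region or gene missing "
                       "from its SOM assignment)", dropped)
    logger.info("built %d LM cells holding %d linked pairs",
                lms.n_cells, lms.n_linked_pairs())
    return lms


def differential_lms(
    lms: LinkedMetaclusters,
    atac_enrich: list[TraitEnrichment],
    rna_enrich: list[TraitEnrichment],
    min_regions: int = 1,
) -> list[tuple[int, int]]:
    """LMs whose ATAC metacluster and RNA metacluster are both trait-enriched
    and that hold at least ``min_regions`` regions."""
    atac_hit = set(enriched_metaclusters(atac_enrich))
    rna_hit = set(enriched_metaclusters(rna_enrich))
    out = []
    for (i, j), pairs in sorted(lms.cells.items()):
        if i in atac_hit and j in rna_hit and len(pairs) >= min_regions:
            out.append((i, j))
    return out
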