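"""Assemble the predicted TF -> target-gene regulatory network.

An edge is emitted whenever a transcription factor's motif is enriched in a
linked metacluster (LM) and a region of that LM carries a passing hit of the
motif: the TF is predicted to regulate the gene the region is linked to.
Evidence (LM, region) pairs are merged per (TF, target).  The TF-only
subnetwork restricts targets to genes that are themselves factors in the
motif database and sit in a trait-enriched RNA metacluster, then keeps the
weakly-connected component containing a chosen root factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .linker import LinkedMetaclusters
from .map_analysis import TraitEnrichment, enriched_metaclusters
from .motif import EnrichmentResult, MotifHit

__all__ = ["RegulatoryEdge", "GRN", "build_edges", "tf_subnetwork",
           "export_network", "read_tf_gene_map"]


@dataclass
class RegulatoryEdge:
    tf: str                       # motif id / factor name
    target: str                   # gene id
    evidence: list[tuple[tuple[int, int], str]]  # (lm_id, region_id)
    direction_label: str | None = None  # "up" / "down" over the trait course


@dataclass
class GRN:
    edges: list[RegulatoryEdge] = field(default_factory=list)
    node_traits: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        out = set(self.node_traits)
        for e in self.edges:
            out.add(e.tf)
            out.add(e.target)
        return out

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.tf, e.target) for e in self.edges}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n, trait=self.node_traits.get(n, ""))
        for e in self.edges:
            g.add_edge(e.tf, e.target,
                       n_evidence=len(e.evidence),
                       direction=e.direction_label or "")
        return g


def build_edges(enrichment: list[EnrichmentResult], hits: list[MotifHit],
                lms: LinkedMetaclusters,
                differential: list[tuple[int, int]] | None = None) -> list[RegulatoryEdge]:
    """For every enriched (motif, LM) pair — optionally restricted to
    differential LMs — emit TF -> linked-gene edges for each region in that
    LM carrying a passing hit of the motif; evidence merges per (TF, target).
    """
    diff = set(differential) if differential is not None else None
    enriched_pairs = {(e.motif_id, e.lm_id) for e in enrichment
                      if e.enriched and (diff is None or e.lm_id in diff)}
    gene_of: dict[tuple[tuple[int, int], str], str] = {}
    for lm, pairs in lms.cells.items():
        for region_id, gene_id in pairs:
            gene_of[(lm, region_id)] = gene_id

    merged: dict[tuple[str, str], RegulatoryEdge] = {}
    seen_evidence: set[tuple[str, str, tuple[int, int], str]] = set()
    for h in hits:
        if h.lm is None or (h.motif_id, h.lm) not in enriched_pairs:
            continue
        gene = gene_of.get((h.lm, h.region_id))
        if gene is None:
            continue
        key = (h.motif_id, gene)
        ev_key = (h.motif_id, gene, h.lm, h.region_id)
        if ev_key in seen_evidence:
            continue
        seen_evidence.add(ev_key)
        if key not in merged:
            merged[key] = RegulatoryEdge(h.motif_id, gene, [])
        merged[key].evidence.append((h.lm, h.region_id))
    return sorted(merged.values(), key=lambda e: (e.tf, e.target))


def tf_subnetwork(grn: GRN, tf_gene_map: dict[str, str], root: str,
                  rna_enrich: list[TraitEnrichment],
                  gene_metacluster: dict[str, int],
                  trait_order: list[str] | None = None) -> GRN:
    """TF-only subnetwork rooted at ``root``.

    Targets are restricted to genes that are factors in the motif database
    (values of ``tf_gene_map``) and whose RNA metacluster is trait-enriched.
    The weakly-connected component containing the root is kept; each edge's
    direction_label comes from the target's enriched trait level: with
    ``trait_order`` = [earlier, ..., later], enrichment in the earliest level
    labels the edge "down" (decreasing over the course), anything later "up".
    """
    tf_genes = set(tf_gene_map.values())
    mc_trait = enriched_metaclusters(rna_enrich)
    gene_trait = {g: mc_trait[mc] for g, mc in gene_metacluster.items()
                  if mc in mc_trait}

    def direction(gene: str) -> str | None:
        trait = gene_trait.get(gene)
        if trait is None:
            return None
        if trait_order and trait == trait_order[0]:
            return "down"
        return "up"

    # translate motif-named sources to gene names, keep TF->TF edges on
    # trait-enriched targets
    kept: list[RegulatoryEdge] = []
    for e in grn.edges:
        tf_gene = tf_gene_map.get(e.tf, e.tf)
        if e.target not in tf_genes or e.target not in gene_trait:
            continue
        kept.append(RegulatoryEdge(tf_gene, e.target, list(e.evidence),
                                   direction(e.target)))

    known = tf_genes | set(tf_gene_map) | {e.tf for e in kept} \
        | {e.target for e in kept}
    if root not in known:
        raise ValueError(f"root {root!r} absent from the network")
    g = nx.DiGraph()
    g.add_node(root)
    for e in kept:
        g.add_edge(e.tf, e.target)
    component = nx.node_connected_component(g.to_undirected(), root)
    sub = GRN([e for e in kept if e.tf in component and e.target in component])
    sub.node_traits = {n: gene_trait.get(n, "") for n in sub.nodes | {root}}
    return sub


def export_network(grn: GRN, prefix: str) -> tuple[str, str]:
    """Write ``<prefix>.tsv`` (tf, target, n_evidence, lm_ids, direction) and
    ``<prefix>.graphml``; returns the two paths."""
    tsv = f"{prefix}.tsv"
    graphml = f"{prefix}.graphml"
    with open(tsv, "w") as fh:
        fh.write("tf\ttarget\tn_evidence\tlm_ids\tdirection\n")
        for e in sorted(grn.edges, key=lambda e: (e.tf, e.target)):
            lm_ids = ";".join(sorted({f"{i},{j}" for (i, j), _ in e.evidence}))
            fh.write(f"{e.tf}\t{e.target}\t{len(e.evidence)}\t{lm_ids}\t"
                     f"{e.direction_label or ''}\n")
    nx.write_graphml(grn.to_networkx(), graphml)
    return tsv, graphml


def read_tf_gene_map(path: str) -> dict[str, str]:
    """Two-column TSV mapping motif_id -> gene_id."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns")
            out[cols[0]] = cols[1]
    return out
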