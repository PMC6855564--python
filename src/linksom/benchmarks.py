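"""Validation benchmarks: each function regenerates its inputs from a seed,
runs one stage (or the whole pipeline) and measures it against an
independent oracle or planted ground truth.

These are the quantitative checks behind the package's correctness claims:
exhaustive-scan agreement for BMU search, formula re-evaluation for AIC,
4^L enumeration for motif p-values, permutation/shuffle calibration for the
two significance procedures, and planted-edge recovery for the end-to-end
pipeline.  The test suite asserts on them and the reproduction script
reports them.
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .io_formats import PWM
from .linker import LinkedMetaclusters, LinkerMapping, build_linked_metaclusters
from .map_analysis import trait_enrichment
from .metacluster import (aic_score, constrained_kmeans, is_contiguous,
                          select_metaclustering)
from .motif import MotifHit, enrichment_zscores, pwm_logodds, score_pvalue_distribution
from .pipeline import PipelineParams, run_pipeline
from .som_core import SOMConfig, SOMGrid, UnitAssignment, best_matching_unit, train_som, score_som
from .metacluster import Metaclustering
from .synthetic import FixtureSpec, make_fixture, make_planted_block_grid

__all__ = [
    "lm_cell_count",
    "bmu_oracle_agreement",
    "contiguity_check",
    "aic_formula_max_relative_error",
    "planted_block_recovery",
    "pwm_pvalue_max_abs_error",
    "enrichment_null_calibration",
    "trait_null_enriched_fraction",
    "end_to_end_recovery",
]


def lm_cell_count(k_atac: int = 107, k_rna: int = 39) -> int:
    """Number of LM cells produced for given metacluster counts (the grid of
    all ATAC x RNA metacluster combinations)."""
    atac_mc = Metaclustering(k=k_atac, centroids=np.zeros((k_atac, 2)),
                             labels=np.arange(k_atac), rows=1, cols=k_atac)
    rna_mc = Metaclustering(k=k_rna, centroids=np.zeros((k_rna, 2)),
                            labels=np.arange(k_rna), rows=1, cols=k_rna)
    lms = build_linked_metaclusters(
        LinkerMapping({}),
        atac_mc, UnitAssignment(["r0"], np.array([0]), 1, k_atac),
        rna_mc, UnitAssignment(["g0"], np.array([0]), 1, k_rna))
    return lms.n_cells


def bmu_oracle_agreement(n_instances: int = 1000, seed: int = 0) -> float:
    """Fraction of random (vector, grid) instances where best_matching_unit
    agrees with an exhaustive distance scan."""
    rng = np.random.default_rng(seed)
    agree = 0
    n_grids = 20
    per_grid = n_instances // n_grids
    for _ in range(n_grids):
        rows, cols = int(rng.integers(3, 9)), int(rng.integers(3, 9))
        dim = int(rng.integers(4, 16))
        grid = SOMGrid(rows, cols, rng.uniform(0, 1, (rows * cols, dim)),
                       SOMConfig(rows=rows, cols=cols), fit_error=0.0)
        for _ in range(per_grid):
            v = rng.uniform(0, 1, dim)
            d = np.linalg.norm(grid.weights - v, axis=1)
            oracle = divmod(int(np.argmin(d)), cols)
            agree += best_matching_unit(v, grid) == oracle
    return agree / (n_grids * per_grid)


def contiguity_check(n_grids: int = 50, seed: int = 0,
                     rows: int = 6, cols: int = 8,
                     k_range: tuple[int, int] = (2, 8)) -> float:
    """Fraction of metaclusterings across a k-scan on random grids that pass
    the BFS 4-adjacency connectivity check."""
    rng = np.random.default_rng(seed)
    ok = total = 0
    for g in range(n_grids):
        grid = SOMGrid(rows, cols, rng.uniform(0, 1, (rows * cols, 6)),
                       SOMConfig(rows=rows, cols=cols), fit_error=0.0)
        for k in range(k_range[0], k_range[1] + 1):
            mc = constrained_kmeans(grid, k, seed=seed + g)
            ok += is_contiguous(mc.labels, rows, cols)
            total += 1
    return ok / total


def aic_formula_max_relative_error(n_cases: int = 50, seed: int = 0) -> float:
    """Max relative deviation of aic_score from an independent evaluation of
    n*D*ln(RSS/n) + 2*k*D on random labelings."""
    rng = np.random.default_rng(seed)
    grid = SOMGrid(6, 8, rng.uniform(0, 1, (48, 10)),
                   SOMConfig(rows=6, cols=8), fit_error=0.0)
    worst = 0.0
    n = grid.n_units
    for _ in range(n_cases):
        k = int(rng.integers(1, 12))
        labels = rng.integers(0, k, n)
        D = int(rng.integers(1, 100))
        rss = 0.0
        for j in range(k):
            members = grid.weights[labels == j]
            if len(members):
                rss += float(((members - members.mean(axis=0)) ** 2).sum())
        expected = n * D * np.log(max(rss, 1e-12 * n) / n) + 2 * k * D
        got = aic_score(grid, labels, k, D)
        worst = max(worst, abs(got - expected) / max(abs(expected), 1e-300))
    return worst


def planted_block_recovery(n_blocks: int, seed: int = 0) -> tuple[int, float]:
    """Select k over [2, 2b] on a grid with b planted contiguous weight
    blocks; returns (selected k, adjusted Rand index vs planted labels)."""
    grid, truth = make_planted_block_grid(8, 10, n_blocks, seed=seed)
    mc = select_metaclustering(grid, 2, 2 * n_blocks, seed=seed)
    return mc.k, float(adjusted_rand_score(truth, mc.labels))


def pwm_pvalue_max_abs_error(n_pwms: int = 20, max_len: int = 6,
                             seed: int = 0) -> float:
    """Max |p_DP - p_enumeration| over all attainable score bins, across
    random PWMs of length <= max_len (enumeration over all 4^L words)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_pwms):
        L = int(rng.integers(1, max_len + 1))
        bg = rng.dirichlet([5, 5, 5, 5])
        pwm = PWM(f"m{i}", rng.dirichlet([1, 1, 1, 1], size=L))
        s = pwm_logodds(pwm, bg, pseudocount=0.1)
        table = score_pvalue_distribution(s, bg)
        q = table.int_scores
        mass: dict[int, float] = {}
        for word in itertools.product(range(4), repeat=L):
            total = int(sum(q[pos, b] for pos, b in enumerate(word)))
            p_word = float(np.prod([bg[b] for b in word]))
            mass[total] = mass.get(total, 0.0) + p_word
        totals = sorted(mass)
        tail = 0.0
        expected = {}
        for t in reversed(totals):
            tail += mass[t]
            expected[t] = tail
        for t in totals:
            worst = max(worst, abs(table.site_pvalue(t) - expected[t]))
    return worst


def enrichment_null_calibration(n_shuffles: int = 100, n_lms: int = 100,
                                n_regions_per_lm: int = 30,
                                hit_probability: float = 0.5,
                                alpha: float = 0.05,
                                seed: int = 0) -> tuple[float, float]:
    """Fraction of (motif, LM) pairs called enriched when LM membership is
    shuffled (exchangeable null), and the acceptance bound
    alpha + 2*sqrt(alpha*(1-alpha)/n_tests)."""
    rng = np.random.default_rng(seed)
    n_regions = n_lms * n_regions_per_lm
    hit_status = rng.random(n_regions) < hit_probability
    calls = total = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(n_regions)
        lms = LinkedMetaclusters(n_lms, 1)
        hits = []
        for slot, r in enumerate(perm):
            lm = (slot // n_regions_per_lm, 0)
            lms.cells[lm].append((f"r{r}", f"g{r}"))
            if hit_status[r]:
                hits.append(MotifHit("m", f"r{r}", 0, "+", 5.0, 1e-6, 1e-3, lm))
        res = enrichment_zscores(hits, lms, alpha=alpha, min_regions=5)
        calls += sum(r.enriched for r in res)
        total += len(res)
    bound = alpha + 2 * np.sqrt(alpha * (1 - alpha) / total)
    return calls / total, float(bound)


def trait_null_enriched_fraction(seed: int = 0, n_perm: int = 10_000,
                                 alpha: float = 1e-4) -> float:
    """Fraction of metaclusters called trait-enriched on synthetic data with
    no planted trait effect (fold change 1): should not exceed alpha."""
    spec = FixtureSpec(n_genes=200, n_peaks=300, n_cells_per_trait=40,
                       fold_change=1.0, plant_fraction=0.0,
                       n_chroms=2, seed=seed)
    from .synthetic import make_matrices
    rna, _, labels = make_matrices(spec)
    cfg = SOMConfig(rows=8, cols=10, epochs=20, n_trials=1, seed=seed)
    grid = train_som(rna, cfg)
    assignment = score_som(rna, grid)
    mc = select_metaclustering(grid, 6, 12, seed=seed)
    results = trait_enrichment(assignment, rna, labels, mc,
                               n_perm=n_perm, seed=seed, alpha=alpha)
    enriched_mcs = {r.metacluster for r in results if r.enriched}
    return len(enriched_mcs) / mc.k


def end_to_end_recovery(seed: int = 0) -> dict[str, float]:
    """Full pipeline on the default synthetic study; precision and recall of
    predicted TF -> gene edges against the planted edge set."""
    fx = make_fixture(FixtureSpec(seed=seed))
    res = run_pipeline(fx.rna, fx.atac, fx.labels, fx.genes, fx.peaks,
                       fx.genome, fx.pwms, PipelineParams(seed=seed))
    pred = res.edge_pairs()
    true = fx.true_edges
    tp = len(pred & true)
    return {
        "precision": tp / len(pred) if pred else 0.0,
        "recall": tp / len(true) if true else 0.0,
        "n_predicted": float(len(pred)),
        "n_true": float(len(true)),
        "k_rna": float(res.rna_mc.k),
        "k_atac": float(res.atac_mc.k),
        "n_differential_lms": float(len(res.differential)),
        "n_lm_cells": float(res.lms.n_cells),
    }
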