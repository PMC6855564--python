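"""Map algebra and per-metacluster trait-enrichment statistics.

A UnitMap is a rows x cols real matrix keyed to a trained grid: per-cell
slices, summary and difference maps, the U-matrix (mean weight distance to
lattice neighbors; ridges mark cluster boundaries) and the feature density
map.  Trait enrichment asks, per metacluster, whether its mean per-cell
signal correlates with membership in one trait level (e.g. a timepoint),
with significance from a one-tailed permutation test over cell labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import FeatureMatrix, TraitLabels
from .metacluster import Metaclustering, lattice_neighbors
from .som_core import SOMGrid, UnitAssignment

__all__ = [
    "TraitEnrichment",
    "cell_map",
    "summary_map",
    "difference_map",
    "umatrix",
    "density_map",
    "trait_enrichment",
    "enriched_metaclusters",
]


@dataclass
class TraitEnrichment:
    metacluster: int
    trait_level: str
    mean_in: float       # mean metacluster profile over cells with the trait
    mean_out: float      # mean over the remaining cells
    correlation: float   # Pearson r of profile with the trait indicator
    p_value: float       # one-tailed permutation p
    enriched: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value out of [0,1]")


def _check_match(assignment: UnitAssignment, m: FeatureMatrix) -> None:
    if assignment.feature_ids != m.feature_ids:
        raise ValueError("assignment and matrix feature ids differ")


# ---------------------------------------------------------------------------
# maps
# ---------------------------------------------------------------------------

def cell_map(assignment: UnitAssignment, m: FeatureMatrix,
             cell_id: str) -> np.ndarray:
    """Per-unit mean signal of one cell over the features assigned there;
    units with no features are 0."""
    _check_match(assignment, m)
    col = m.values[:, m.cell_ids.index(cell_id)]
    n_units = assignment.rows * assignment.cols
    total = np.bincount(assignment.units, weights=col, minlength=n_units)
    count = np.bincount(assignment.units, minlength=n_units)
    out = np.divide(total, count, out=np.zeros(n_units), where=count > 0)
    return out.reshape(assignment.rows, assignment.cols)


def summary_map(assignment: UnitAssignment, m: FeatureMatrix) -> np.ndarray:
    """Per-unit total signal over all cells and all features assigned there."""
    _check_match(assignment, m)
    totals = m.values.sum(axis=1)
    n_units = assignment.rows * assignment.cols
    out = np.bincount(assignment.units, weights=totals, minlength=n_units)
    return out.reshape(assignment.rows, assignment.cols)


def difference_map(assignment: UnitAssignment, m: FeatureMatrix,
                   labels: TraitLabels, a: str, b: str) -> np.ndarray:
    """Mean of cell maps over cells with trait ``a`` minus mean over ``b``."""
    lookup = labels.as_dict()
    cells_a = [c for c in m.cell_ids if lookup.get(c) == a]
    cells_b = [c for c in m.cell_ids if lookup.get(c) == b]
    if not cells_a or not cells_b:
        raise ValueError(f"no cells for trait level {a if not cells_a else b!r}")
    mean_a = np.mean([cell_map(assignment, m, c) for c in cells_a], axis=0)
    mean_b = np.mean([cell_map(assignment, m, c) for c in cells_b], axis=0)
    return mean_a - mean_b


def umatrix(grid: SOMGrid) -> np.ndarray:
    """Per-unit mean Euclidean weight distance to its 8 toroidal neighbors."""
    out = np.empty(grid.n_units)
    for u in range(grid.n_units):
        nbrs = lattice_neighbors(u, grid.rows, grid.cols, eight=True)
        out[u] = np.linalg.norm(grid.weights[nbrs] - grid.weights[u], axis=1).mean()
    return out.reshape(grid.rows, grid.cols)


def density_map(assignment: UnitAssignment) -> np.ndarray:
    """Per-unit feature count; entries sum to the number of features."""
    n_units = assignment.rows * assignment.cols
    return np.bincount(assignment.units, minlength=n_units).reshape(
        assignment.rows, assignment.cols)


# ---------------------------------------------------------------------------
# trait enrichment
# ---------------------------------------------------------------------------

def _pearson_against_indicators(profile: np.ndarray,
                                indicators: np.ndarray) -> np.ndarray:
    """Pearson r of one profile against each row of a 0/1 indicator matrix.

    Returns 0 where either side has zero variance.
    """
    p = profile - profile.mean()
    sp = np.sqrt((p ** 2).sum())
    ind = indicators - indicators.mean(axis=1, keepdims=True)
    si = np.sqrt((ind ** 2).sum(axis=1))
    denom = sp * si
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ind @ p) / denom
    return np.where(denom > 0, r, 0.0)


def trait_enrichment(assignment: UnitAssignment, m: FeatureMatrix,
                     labels: TraitLabels, mc: Metaclustering,
                     n_perm: int = 10000, seed: int = 0,
                     alpha: float = 1e-4,
                     bonferroni: bool = False) -> list[TraitEnrichment]:
    """Permutation test for trait enrichment of each metacluster.

    The representative profile of a metacluster is the per-cell mean over its
    member features (mean, not sum, so metacluster size does not inflate the
    statistic).  For each trait level the statistic is the Pearson
    correlation of that profile with the binary level indicator; the p-value
    is one-tailed over ``n_perm`` seeded label permutations,
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    """
    _check_match(assignment, m)
    if len(labels.levels) < 2:
        raise ValueError("need at least 2 trait levels")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n_cells = m.n_cells
    n_units = assignment.rows * assignment.cols
    unit_of_feature = assignment.units

    # per-metacluster per-cell mean profile
    k = mc.k
    mc_of_feature = mc.labels[unit_of_feature]
    profiles = np.zeros((k, n_cells))
    counts = np.zeros(k)
    for j in range(k):
        mask = mc_of_feature == j
        counts[j] = mask.sum()
        if counts[j]:
            profiles[j] = m.values[mask].mean(axis=0)

    # one shared permutation set (same null draws for all metaclusters/levels)
    perms = np.array([rng.permutation(n_cells) for _ in range(n_perm)])

    n_tests = k * len(labels.levels)
    eff_alpha = alpha / n_tests if bonferroni else alpha
    results: list[TraitEnrichment] = []
    for level in labels.levels:
        ind = labels.indicator(level, m.cell_ids)
        ind_perm = ind[perms]  # (n_perm, n_cells)
        for j in range(k):
            if counts[j] == 0:
                results.append(TraitEnrichment(j, level, np.nan, np.nan,
                                               np.nan, 1.0, False))
                continue
            prof = profiles[j]
            r_obs = float(_pearson_against_indicators(prof, ind[None, :])[0])
            r_null = _pearson_against_indicators(prof, ind_perm)
            p = (1.0 + np.sum(r_null >= r_obs)) / (1.0 + n_perm)
            in_mask = ind > 0
            results.append(TraitEnrichment(
                metacluster=j, trait_level=level,
                mean_in=float(prof[in_mask].mean()),
                mean_out=float(prof[~in_mask].mean()),
                correlation=r_obs, p_value=float(p),
                enriched=bool(p < eff_alpha),
            ))
    return results


def enriched_metaclusters(results: list[TraitEnrichment]) -> dict[int, str]:
    """Map each enriched metacluster to its (most significant) trait level."""
    best: dict[int, TraitEnrichment] = {}
    for r in results:
        if r.enriched and (r.metacluster not in best
                           or r.p_value < best[r.metacluster].p_value):
            best[r.metacluster] = r
    return {mc: r.trait_level for mc, r in best.items()}
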