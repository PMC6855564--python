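"""Toroidal self-organizing map: training, scoring, serialization.

A SOM projects high-dimensional feature vectors (per-feature signal across
cells) onto a 2D lattice of units, each carrying a weight vector in
cell-space.  The lattice wraps in both dimensions (toroid), so no unit is an
edge case.  Training follows the classic online Kohonen recipe: for each
training vector find the best matching unit (BMU) and pull every unit's
weights toward the vector, weighted by a Gaussian of the toroidal lattice
distance to the BMU.  The learning rate decays linearly over the run and the
neighborhood radius shrinks linearly to 0.5.

Several independent restarts ("trials") are trained on a feature subsample
and the grid with the lowest fitting error (mean quantization error of the
training vectors) is kept; the full matrix is then scored onto that grid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field

import numpy as np

from .io_formats import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SOMConfig",
    "SOMGrid",
    "UnitAssignment",
    "toroidal_grid_distance",
    "grid_distance_matrix",
    "best_matching_unit",
    "train_som",
    "score_som",
    "fit_error",
]


@dataclass(frozen=True)
class SOMConfig:
    rows: int = 40
    cols: int = 60
    epochs: int = 1000
    n_trials: int = 100
    alpha0: float = 0.2
    sigma0: float | None = None  # default max(rows, cols)/2
    seed: int = 0
    train_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("rows and cols must be >= 2")
        if self.epochs < 1 or self.n_trials < 1:
            raise ValueError("epochs and n_trials must be >= 1")
        if not 0 < self.alpha0 <= 1:
            raise ValueError("alpha0 must be in (0, 1]")
        if self.sigma0 is not None and self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        if not 0 < self.train_fraction <= 1:
            raise ValueError("train_fraction must be in (0, 1]")

    @property
    def sigma_start(self) -> float:
        return self.sigma0 if self.sigma0 is not None else max(self.rows, self.cols) / 2.0


@dataclass
class SOMGrid:
    rows: int
    cols: int
    weights: np.ndarray  # (rows*cols, n_cells), row-major unit order
    config: SOMConfig
    fit_error: float = 0.0
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape[0] != self.rows * self.cols:
            raise ValueError("weights must have rows*cols unit vectors")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weight")
        if self.fit_error < 0:
            raise ValueError("fit_error must be >= 0")

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def unit_index(self, r: int, c: int) -> int:
        return r * self.cols + c

    def unit_coords(self, idx: int) -> tuple[int, int]:
        return divmod(idx, self.cols)

    def to_json(self, path: str) -> None:
        obj = {
            "rows": self.rows,
            "cols": self.cols,
            "fit_error": self.fit_error,
            "cell_ids": self.cell_ids,
            "config": asdict(self.config),
            "weights": self.weights.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path: str) -> "SOMGrid":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            rows=obj["rows"], cols=obj["cols"],
            weights=np.array(obj["weights"]),
            config=SOMConfig(**obj["config"]),
            fit_error=obj["fit_error"],
            cell_ids=obj.get("cell_ids", []),
        )


@dataclass
class UnitAssignment:
    """Per-feature BMU assignment onto a grid."""

    feature_ids: list[str]
    units: np.ndarray  # (n_features,) flat row-major unit index
    rows: int
    cols: int

    def __post_init__(self) -> None:
        self.units = np.asarray(self.units, dtype=np.int64)
        if len(self.units) != len(self.feature_ids):
            raise ValueError("one unit index per feature required")

    def coords(self) -> np.ndarray:
        """(n_features, 2) array of (row, col) coordinates."""
        return np.stack(divmod(self.units, self.cols), axis=1)

    def unit_of(self, feature_id: str) -> tuple[int, int]:
        i = self.feature_ids.index(feature_id)
        return divmod(int(self.units[i]), self.cols)

    def to_frame(self):
        import pandas as pd
        r, c = divmod(self.units, self.cols)
        return pd.DataFrame({"feature": self.feature_ids, "row": r, "col": c})


# ---------------------------------------------------------------------------
# lattice geometry
# ---------------------------------------------------------------------------

def toroidal_grid_distance(u1: tuple[int, int], u2: tuple[int, int],
                           rows: int, cols: int) -> float:
    """Euclidean distance between lattice positions with wraparound."""
    dr = abs(u1[0] - u2[0])
    dr = min(dr, rows - dr)
    dc = abs(u1[1] - u2[1])
    dc = min(dc, cols - dc)
    return float(np.hypot(dr, dc))


def grid_distance_matrix(rows: int, cols: int) -> np.ndarray:
    """(n_units, n_units) toroidal lattice distances, row-major unit order."""
    r = np.arange(rows)
    c = np.arange(cols)
    dr = np.abs(r[:, None] - r[None, :])
    dr = np.minimum(dr, rows - dr)
    dc = np.abs(c[:, None] - c[None, :])
    dc = np.minimum(dc, cols - dc)
    # combine row and col deltas over the flat index
    d2 = (dr[:, None, :, None] ** 2 + dc[None, :, None, :] ** 2).astype(np.float64)
    return np.sqrt(d2).reshape(rows * cols, rows * cols)


# ---------------------------------------------------------------------------
# BMU search and scoring
# ---------------------------------------------------------------------------

def best_matching_unit(v: np.ndarray, grid: SOMGrid) -> tuple[int, int]:
    """Unit with the nearest weight vector (Euclidean); ties break row-major."""
    v = np.asarray(v, dtype=np.float64)
    if v.shape != (grid.weights.shape[1],):
        raise ValueError(
            f"vector length {v.shape} does not match weight dimension "
            f"{grid.weights.shape[1]}"
        )
    d2 = np.einsum("ij,ij->i", grid.weights - v, grid.weights - v)
    # argmin returns the first (row-major smallest) index on exact ties
    return grid.unit_coords(int(np.argmin(d2)))


def _bmu_indices(vectors: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Flat BMU index for each row of `vectors` (vectorized)."""
    # ||v-w||^2 = ||v||^2 - 2 v.w + ||w||^2 ; ||v||^2 constant per row
    d2 = (
        np.einsum("ij,ij->i", weights, weights)[None, :]
        - 2.0 * vectors @ weights.T
    )
    return np.argmin(d2, axis=1)


def fit_error(vectors: np.ndarray, weights: np.ndarray) -> float:
    """Mean quantization error: mean distance of vectors to their BMU."""
    bmu = _bmu_indices(vectors, weights)
    return float(np.linalg.norm(vectors - weights[bmu], axis=1).mean())


def score_som(m: FeatureMatrix, grid: SOMGrid) -> UnitAssignment:
    """Assign every feature (training and held-out) to its BMU."""
    if m.n_cells != grid.weights.shape[1]:
        raise ValueError(
            f"matrix has {m.n_cells} cells but grid weights have dimension "
            f"{grid.weights.shape[1]}"
        )
    units = _bmu_indices(m.values, grid.weights)
    n_empty = grid.n_units - len(np.unique(units))
    logger.info("scored %d features onto %dx%d grid; %d empty units",
                m.n_features, grid.rows, grid.cols, n_empty)
    return UnitAssignment(list(m.feature_ids), units, grid.rows, grid.cols)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _train_single(data: np.ndarray, cfg: SOMConfig, rng: np.random.Generator,
                  grid_dist: np.ndarray) -> tuple[np.ndarray, float]:
    n_vec, n_dim = data.shape
    lo = data.min(axis=0)
    hi = data.max(axis=0)
    weights = rng.uniform(lo, hi, size=(cfg.rows * cfg.cols, n_dim))

    total_steps = cfg.epochs * n_vec
    sigma_start = cfg.sigma_start
    sigma_end = 0.5
    t = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n_vec)
        for i in order:
            v = data[i]
            frac = t / total_steps
            alpha = cfg.alpha0 * (1.0 - frac)
            sigma = sigma_start + (sigma_end - sigma_start) * frac
            diff = v - weights
            bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
            h = np.exp(-(grid_dist[bmu] ** 2) / (2.0 * sigma * sigma))
            weights += (alpha * h)[:, None] * diff
            t += 1
    return weights, fit_error(data, weights)


def train_som(m: FeatureMatrix, cfg: SOMConfig) -> SOMGrid:
    """Train ``cfg.n_trials`` SOMs on a seeded feature subsample and return
    the grid with the lowest fitting error.

    Each trial draws ``floor(train_fraction * n_features)`` features without
    replacement (trial seed = ``cfg.seed + trial``), runs
    ``epochs * n_training_features`` online updates with linearly decaying
    learning rate and Gaussian neighborhood on the toroidal lattice, and
    reports the mean quantization error of its training vectors.
    """
    if m.n_cells < 2:
        raise ValueError("need at least 2 cells to train")
    n_train = int(cfg.train_fraction * m.n_features)
    if n_train < 1:
        raise ValueError("train_fraction leaves no training features")

    grid_dist = grid_distance_matrix(cfg.rows, cfg.cols)
    best_weights = None
    best_err = np.inf
    for trial in range(cfg.n_trials):
        rng = np.random.default_rng(cfg.seed + trial)
        subset = rng.choice(m.n_features, size=n_train, replace=False)
        weights, err = _train_single(m.values[subset], cfg, rng, grid_dist)
        logger.info("trial %d/%d: fit_error=%.6g", trial + 1, cfg.n_trials, err)
        if err < best_err:
            best_err = err
            best_weights = weights
    return SOMGrid(cfg.rows, cfg.cols, best_weights, cfg,
                   fit_error=best_err, cell_ids=list(m.cell_ids))
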