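import numpy as np
import pytest

from linksom.io_formats import FeatureMatrix, TraitLabels
from linksom.map_analysis import (cell_map, density_map, difference_map,
                                  summary_map, trait_enrichment, umatrix)
from linksom.metacluster import Metaclustering, constrained_kmeans
from linksom.som_core import SOMConfig, SOMGrid, UnitAssignment, score_som


@pytest.fixture
def setup():
    rng = np.random.default_rng(6)
    rows, cols, n_cells = 3, 4, 6
    m = FeatureMatrix([f"f{i}" for i in range(10)],
                      [f"c{j}" for j in range(n_cells)],
                      rng.uniform(0, 5, (10, n_cells)))
    assignment = UnitAssignment(list(m.feature_ids),
                                rng.integers(0, rows * cols, 10), rows, cols)
    return m, assignment


class TestCellMap:
    def test_all_zero_cell(self, setup):
        m, assignment = setup
        z = FeatureMatrix(m.feature_ids, m.cell_ids, np.zeros_like(m.values))
        assert np.all(cell_map(assignment, z, "c0") == 0)

    def test_matches_groupby_mean(self, setup):
        m, assignment = setup
        got = cell_map(assignment, m, "c2").ravel()
        for u in range(12):
            members = np.where(assignment.units == u)[0]
            expected = m.values[members, 2].mean() if len(members) else 0.0
            assert got[u] == pytest.approx(expected)

    def test_one_feature_per_unit_reshapes_column(self):
        m = FeatureMatrix([f"f{i}" for i in range(6)], ["a", "b"],
                          np.arange(12, dtype=float).reshape(6, 2))
        assignment = UnitAssignment(list(m.feature_ids), np.arange(6), 2, 3)
        np.testing.assert_allclose(cell_map(assignment, m, "a"),
                                   m.values[:, 0].reshape(2, 3))


class TestSummaryAndDensity:
    def test_summary_total_equals_grand_total(self, setup):
        m, assignment = setup
        assert summary_map(assignment, m).sum() == pytest.approx(m.values.sum())

    def test_summary_matches_groupby_sum(self, setup):
        m, assignment = setup
        got = summary_map(assignment, m).ravel()
        for u in range(12):
            members = assignment.units == u
            assert got[u] == pytest.approx(m.values[members].sum())

    def test_density_conserves_feature_count(self, setup):
        _, assignment = setup
        d = density_map(assignment)
        assert d.sum() == 10
        empty = set(range(12)) - set(assignment.units.tolist())
        for u in empty:
            assert d.ravel()[u] == 0


class TestDifferenceMap:
    @pytest.fixture
    def labels(self, setup):
        m, _ = setup
        return TraitLabels(list(m.cell_ids), ["x", "x", "x", "y", "y", "y"])

    def test_same_trait_gives_zero(self, setup, labels):
        m, assignment = setup
        assert np.allclose(difference_map(assignment, m, labels, "x", "x"), 0)

    def test_antisymmetry(self, setup, labels):
        m, assignment = setup
        xy = difference_map(assignment, m, labels, "x", "y")
        yx = difference_map(assignment, m, labels, "y", "x")
        np.testing.assert_allclose(xy, -yx)

    def test_hand_computed_two_plus_two(self):
        values = np.array([[1.0, 3.0, 10.0, 20.0],
                           [2.0, 4.0, 30.0, 40.0]])
        m = FeatureMatrix(["f0", "f1"], ["a1", "a2", "b1", "b2"], values)
        assignment = UnitAssignment(["f0", "f1"], np.array([0, 0]), 2, 2)
        labels = TraitLabels(m.cell_ids, ["A", "A", "B", "B"])
        d = difference_map(assignment, m, labels, "A", "B")
        # unit 0: mean over A of feature-mean (1.5, 3.5) minus B (20, 30)
        assert d[0, 0] == pytest.approx(2.5 - 25.0)


class TestUmatrix:
    def test_uniform_weights_give_zero(self):
        grid = SOMGrid(3, 4, np.ones((12, 5)), SOMConfig(rows=3, cols=4),
                       fit_error=0.0)
        assert np.all(umatrix(grid) == 0)

    def test_two_block_ridge_exceeds_interior(self):
        # columns 0-2 weight 0, columns 3-5 weight 10 on a 4x6 grid
        w = np.zeros((24, 2))
        for u in range(24):
            if u % 6 >= 3:
                w[u] = 10.0
        grid = SOMGrid(4, 6, w, SOMConfig(rows=4, cols=6), fit_error=0.0)
        um = umatrix(grid)
        boundary = um[:, [2, 3, 5, 0]].mean()  # columns flanking both seams
        interior = um[:, [1, 4]].mean()
        assert boundary > interior


class TestTraitEnrichment:
    def _run(self, profile_rows, indicator, n_perm=2000, alpha=0.05, seed=0):
        n_cells = len(indicator)
        profile_rows = list(profile_rows) * 2  # matrix needs >= 2 features
        values = np.clip(np.asarray(profile_rows, dtype=float), 0, None)
        m = FeatureMatrix([f"f{i}" for i in range(len(values))],
                          [f"c{j}" for j in range(n_cells)], values)
        assignment = UnitAssignment(list(m.feature_ids),
                                    np.zeros(len(values), dtype=int), 2, 2)
        mc = Metaclustering(k=1, centroids=np.zeros((1, n_cells)),
                            labels=np.zeros(4, dtype=int), rows=2, cols=2)
        labels = TraitLabels(list(m.cell_ids),
                             ["hi" if x else "lo" for x in indicator])
        return trait_enrichment(assignment, m, labels, mc, n_perm=n_perm,
                                seed=seed, alpha=alpha)

    def test_constant_profile_not_enriched(self):
        res = self._run([np.full(20, 3.0)], [1] * 10 + [0] * 10)
        for r in res:
            assert r.correlation == pytest.approx(0.0)
            assert not r.enriched

    def test_indicator_profile_hits_permutation_floor(self):
        ind = [1] * 10 + [0] * 10
        res = self._run([np.array(ind, dtype=float) * 5], ind,
                        n_perm=2000, alpha=1e-3)
        hi = next(r for r in res if r.trait_level == "hi")
        assert hi.correlation == pytest.approx(1.0)
        assert hi.p_value == pytest.approx(1 / 2001)
        assert hi.enriched

    def test_empty_metacluster_reports_p_one(self):
        rng = np.random.default_rng(0)
        n_cells = 12
        m = FeatureMatrix(["f0", "f1"], [f"c{j}" for j in range(n_cells)],
                          rng.uniform(0, 1, (2, n_cells)))
        assignment = UnitAssignment(["f0", "f1"], np.array([0, 0]), 2, 2)
        # metacluster 1 (units 2,3) holds no features
        mc = Metaclustering(k=2, centroids=np.zeros((2, n_cells)),
                            labels=np.array([0, 0, 1, 1]), rows=2, cols=2)
        labels = TraitLabels(list(m.cell_ids), ["a"] * 6 + ["b"] * 6)
        res = trait_enrichment(assignment, m, labels, mc, n_perm=100, seed=0)
        empties = [r for r in res if r.metacluster == 1]
        assert empties and all(r.p_value == 1.0 and not r.enriched
                               for r in empties)
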