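"""Surface approximators: binomial-sum least squares and regression tree."""

import numpy as np
import pytest

from pumpsweep.approximation import (BinomialSurface, design_matrix,
                                     eval_binomial, fit_binomial, fit_tree,
                                     monomial_exponents, predict_tree, rmse,
                                     split_train_test)


def grid_points(n=20, lo=0.0, hi=1.0):
    v = np.linspace(lo, hi, n)
    xx, yy = np.meshgrid(v, v, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()])


class TestDesignMatrix:
    def test_linear_row(self):
        np.testing.assert_allclose(design_matrix([(2.0, 3.0)], p=1),
                                   [[1.0, 2.0, 3.0]])

    def test_quadratic_row(self):
        np.testing.assert_allclose(design_matrix([(2.0, 3.0)], p=2),
                                   [[1.0, 2.0, 3.0, 4.0, 6.0, 9.0]])

    def test_degree_five_column_count(self):
        assert design_matrix([(0.5, 0.5)], p=5).shape == (1, 21)
        assert len(monomial_exponents(5)) == 21

    def test_exponent_ordering(self):
        assert monomial_exponents(2) == [(0, 0), (1, 0), (0, 1),
                                         (2, 0), (1, 1), (0, 2)]


class TestFitBinomial:
    def test_constant_recovery(self):
        pts = grid_points(6)
        cells = np.column_stack([pts, np.full(len(pts), 7.0)])
        surface = fit_binomial(cells, p=5)
        assert surface.coeffs[(0, 0)] == pytest.approx(7.0, abs=1e-9)
        others = [c for k, c in surface.coeffs.items() if k != (0, 0)]
        np.testing.assert_allclose(others, 0.0, atol=1e-9)

    def test_exact_linear_recovery(self):
        pts = grid_points(8)
        z = 1.0 + 2.0 * pts[:, 0] + 3.0 * pts[:, 1]
        surface = fit_binomial(np.column_stack([pts, z]), p=5)
        fitted = eval_binomial(surface, pts[:, 0], pts[:, 1])
        assert rmse(fitted, z) < 1e-8

    def test_normal_equations_on_random_grid(self):
        rng = np.random.default_rng(0)
        pts = grid_points(20)
        z = rng.normal(size=len(pts))
        surface = fit_binomial(np.column_stack([pts, z]), p=5)
        # residuals must be orthogonal to every design column (in the
        # fitter's standardized coordinates)
        xs = surface.x_scale.forward(pts[:, 0])
        ys = surface.y_scale.forward(pts[:, 1])
        A = design_matrix(np.column_stack([xs, ys]), p=5)
        residual = z - eval_binomial(surface, pts[:, 0], pts[:, 1])
        np.testing.assert_allclose(A.T @ residual, 0.0, atol=1e-6)

    def test_training_rmse_nonincreasing_in_degree(self):
        rng = np.random.default_rng(1)
        pts = grid_points(12)
        z = np.sin(3 * pts[:, 0]) + np.cos(2 * pts[:, 1]) \
            + 0.05 * rng.normal(size=len(pts))
        cells = np.column_stack([pts, z])
        errors = []
        for p in range(1, 6):
            s = fit_binomial(cells, p=p)
            errors.append(rmse(eval_binomial(s, pts[:, 0], pts[:, 1]), z))
        assert all(b <= a + 1e-12 for a, b in zip(errors, errors[1:]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_binomial(np.zeros((10, 3)), p=5)

    def test_json_round_trip(self, tmp_path):
        pts = grid_points(6, lo=0.2, hi=3.0)
        cells = np.column_stack([pts, pts[:, 0] * pts[:, 1]])
        surface = fit_binomial(cells, p=3)
        path = tmp_path / "surface.json"
        surface.to_json(path)
        back = BinomialSurface.from_json(path)
        assert back.p == surface.p
        x = np.array([0.7, 2.1])
        np.testing.assert_allclose(eval_binomial(back, x, x),
                                   eval_binomial(surface, x, x))


class TestEvalBinomial:
    def make(self, coeffs, p=1):
        full = {k: 0.0 for k in monomial_exponents(p)}
        full.update(coeffs)
        return BinomialSurface(p=p, coeffs=full)

    def test_zero_surface(self):
        assert eval_binomial(self.make({}), 3.0, 4.0) == 0.0

    def test_constant_surface(self):
        assert eval_binomial(self.make({(0, 0): 1.0}), 9.0, -2.0) == 1.0

    def test_matches_design_row_dot_product(self):
        rng = np.random.default_rng(2)
        coeffs = dict(zip(monomial_exponents(4), rng.normal(size=15)))
        surface = BinomialSurface(p=4, coeffs=coeffs)
        for x, y in rng.uniform(-2, 2, size=(20, 2)):
            row = design_matrix([(x, y)], p=4)[0]
            expected = row @ [coeffs[k] for k in monomial_exponents(4)]
            assert eval_binomial(surface, x, y) == pytest.approx(expected)


# --- regression tree --------------------------------------------------------

def brute_force_best_split(cells):
    """Exhaustive search over features and midpoint thresholds for the
    single split minimising total squared error."""
    cells = np.asarray(cells, dtype=float)
    X, z = cells[:, :2], cells[:, 2]
    best = (np.inf, None, None)
    for f in (0, 1):
        vals = np.unique(X[:, f])
        for lo, hi in zip(vals, vals[1:]):
            thr = (lo + hi) / 2
            left, right = z[X[:, f] <= thr], z[X[:, f] > thr]
            sse = (((left - left.mean()) ** 2).sum()
                   + ((right - right.mean()) ** 2).sum())
            if sse < best[0] - 1e-12:
                best = (sse, f, thr)
    return best[1], best[2]


class TestFitTree:
    def test_constant_targets_single_leaf(self):
        cells = [(0, 0, 5.0), (1, 0, 5.0), (0, 1, 5.0), (1, 1, 5.0)]
        tree = fit_tree(cells)
        assert tree.root.is_leaf and tree.root.value == 5.0

    def test_two_point_split(self):
        cells = [(0.0, 0.0, 0.0), (1.0, 0.0, 1.0)]
        tree = fit_tree(cells, max_leaf_nodes=2)
        assert tree.root.feature == 0
        assert tree.root.threshold == pytest.approx(0.5)
        assert tree.root.left.value == 0.0
        assert tree.root.right.value == 1.0

    def test_first_split_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            pts = rng.uniform(0, 1, size=(30, 2))
            z = np.where(pts[:, 0] > rng.uniform(0.2, 0.8), 1.0, 0.0) \
                + 0.01 * rng.normal(size=30)
            cells = np.column_stack([pts, z])
            tree = fit_tree(cells, max_leaf_nodes=2)
            f, thr = brute_force_best_split(cells)
            assert tree.root.feature == f
            assert tree.root.threshold == pytest.approx(thr)

    def test_memorization_with_enough_leaves(self):
        rng = np.random.default_rng(6)
        pts = grid_points(5)
        z = rng.normal(size=len(pts))
        tree = fit_tree(np.column_stack([pts, z]), max_leaf_nodes=len(pts))
        pred = [predict_tree(tree, x, y) for x, y in pts]
        assert rmse(pred, z) < 1e-12

    def test_training_rmse_monotone_in_leaf_budget(self):
        rng = np.random.default_rng(7)
        pts = grid_points(8)
        z = np.sin(4 * pts[:, 0]) * np.cos(3 * pts[:, 1]) \
            + 0.1 * rng.normal(size=len(pts))
        cells = np.column_stack([pts, z])
        errors = []
        for leaves in (2, 5, 10, 25, 50, 64):
            tree = fit_tree(cells, max_leaf_nodes=leaves)
            assert tree.n_leaves() <= leaves
            pred = [predict_tree(tree, x, y) for x, y in pts]
            errors.append(rmse(pred, z))
        assert all(b <= a + 1e-12 for a, b in zip(errors, errors[1:]))

    def test_prediction_is_axis_aligned_piecewise_constant(self):
        rng = np.random.default_rng(8)
        pts = grid_points(6)
        z = rng.normal(size=len(pts))
        tree = fit_tree(np.column_stack([pts, z]), max_leaf_nodes=8)
        # collect all thresholds; within a rectangle between adjacent
        # thresholds the prediction must be constant
        def thresholds(node, out):
            if not node.is_leaf:
                out[node.feature].add(node.threshold)
                thresholds(node.left, out)
                thresholds(node.right, out)
        cuts = {0: {-1.0, 2.0}, 1: {-1.0, 2.0}}
        thresholds(tree.root, cuts)
        xs, ys = sorted(cuts[0]), sorted(cuts[1])
        for x0, x1 in zip(xs, xs[1:]):
            for y0, y1 in zip(ys, ys[1:]):
                probes = [((x0 + x1) / 2 + dx, (y0 + y1) / 2 + dy)
                          for dx, dy in [(0, 0), ((x1 - x0) / 4, 0),
                                         (0, (y1 - y0) / 4)]]
                vals = {predict_tree(tree, x, y) for x, y in probes}
                assert len(vals) == 1

    def test_boundary_input_goes_left(self):
        cells = [(0.0, 0.0, 0.0), (1.0, 0.0, 1.0)]
        tree = fit_tree(cells, max_leaf_nodes=2)
        assert predict_tree(tree, tree.root.threshold, 0.0) == 0.0

    def test_rules_dump_uses_le_operator(self):
        cells = [(0.0, 0.0, 0.0), (1.0, 0.0, 1.0)]
        tree = fit_tree(cells, max_leaf_nodes=2, feature_names=("b", "theta"))
        assert "b <= 0.5" in tree.to_rules()

    def test_json_round_trip_structure(self, tmp_path):
        rng = np.random.default_rng(9)
        pts = grid_points(4)
        tree = fit_tree(np.column_stack([pts, rng.normal(size=len(pts))]),
                        max_leaf_nodes=5)
        text = tree.to_json(tmp_path / "tree.json")
        assert '"op": "<="' in text


class TestTreeVsBinomialOnPlateauSurfaces:
    def test_tree_generalizes_better_on_terraced_surface(self):
        """On piecewise-plateau goodness surfaces (the shape rule-based
        suspension logic produces), a 100-leaf tree out-predicts the
        degree-5 polynomial on held-out cells."""
        pts = grid_points(28, lo=0.2, hi=3.0)
        # terraced surface: broad flat steps with a gentle trend
        z = (np.floor(3.0 * pts[:, 0]) + 2.0 * np.floor(1.5 * pts[:, 1])
             + 0.05 * pts[:, 0])
        cells = list(map(tuple, np.column_stack([pts, z])))
        train, test = split_train_test(cells, 0.33, seed=1)
        train, test = np.asarray(train), np.asarray(test)
        surface = fit_binomial(train, p=5)
        tree = fit_tree(train, max_leaf_nodes=100)
        bs = rmse(eval_binomial(surface, test[:, 0], test[:, 1]), test[:, 2])
        dt = rmse([predict_tree(tree, x, y) for x, y, _ in test], test[:, 2])
        assert dt < bs


class TestSplitAndRmse:
    def test_split_sizes(self):
        cells = [(i, 0, 0) for i in range(100)]
        train, test = split_train_test(cells, 0.33, seed=0)
        assert len(test) == 33 and len(train) == 67

    def test_partition_exhaustive_and_disjoint(self):
        cells = [(i, i, i) for i in range(57)]
        train, test = split_train_test(cells, 0.33, seed=3)
        assert sorted(train + test) == sorted(cells)
        assert not set(train) & set(test)

    def test_deterministic_per_seed(self):
        cells = [(i, 0, 0) for i in range(40)]
        assert split_train_test(cells, 0.33, 5) == split_train_test(cells, 0.33, 5)
        assert split_train_test(cells, 0.33, 5) != split_train_test(cells, 0.33, 6)

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            split_train_test([(0, 0, 0)], 0.33, 0)

    def test_rmse_examples(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5))
        assert rmse([3, 4], [0, 0]) == rmse([4, 3], [0, 0])

    def test_rmse_shape_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2, 3])
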