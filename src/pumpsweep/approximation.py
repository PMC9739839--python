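"""Continuous approximations of the discrete error surface.

Two approximators turn the evaluation table into a continuous
control-goodness function suitable for risk analysis:

* a **binomial-sum polynomial** ``z(x, y) = sum_{m+n<=p} c_{m,n} x^m y^n``
  fitted by ordinary least squares on the expanded monomial basis
  (default degree p = 5, i.e. 21 coefficients).  The raw nested form
  ``sum_i (A_i x + B_i y)^i`` is over-parameterised — the A/B pairs are
  not identifiable after expansion — so the fit is performed directly on
  the identifiable c-coefficients;

* a **regression tree** grown with squared-error splits and a leaf budget
  (default 100), every internal node a ``<parameter> <= <value>``
  conditional, the true branch on the left.  The tree is fitted with
  scikit-learn's CART implementation and converted to an explicit,
  JSON-serialisable node structure with thresholds in original parameter
  units.

The polynomial fit standardises inputs to [0, 1] per axis (conditioning
of the degree-5 design matrix); tree splits are invariant to monotone
input scaling, so the tree is fitted in original units directly.
Predictions and exported thresholds are always in original parameter
units.  Model quality is compared by RMSE on a random 33 % hold-out.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "BinomialSurface",
    "TreeNode",
    "RegressionTree",
    "monomial_exponents",
    "design_matrix",
    "fit_binomial",
    "eval_binomial",
    "fit_tree",
    "predict_tree",
    "split_train_test",
    "rmse",
]


def monomial_exponents(p: int) -> list[tuple[int, int]]:
    """(m, n) exponent pairs with m + n <= p, by total degree then m descending.

    Ordering matches the expanded binomial-sum basis:
    1, x, y, x^2, xy, y^2, x^3, ...
    """
    if p < 1:
        raise ValueError("degree p must be >= 1")
    return [(m, d - m) for d in range(p + 1) for m in range(d, -1, -1)]


def design_matrix(points, p: int) -> np.ndarray:
    """Design matrix: one row per point, one column per monomial x^m y^n."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, -1)
    x, y = pts[:, 0], pts[:, 1]
    cols = [x ** m * y ** n for m, n in monomial_exponents(p)]
    return np.column_stack(cols)


@dataclass(frozen=True)
class _AxisScale:
    """Affine map from original units to the fit's [0, 1] coordinates."""

    offset: float = 0.0
    scale: float = 1.0

    def forward(self, v):
        return (np.asarray(v, dtype=float) - self.offset) / self.scale


def _fit_scales(x, y) -> tuple[_AxisScale, _AxisScale]:
    def one(v):
        lo, hi = float(np.min(v)), float(np.max(v))
        return _AxisScale(lo, (hi - lo) or 1.0)
    return one(x), one(y)


@dataclass
class BinomialSurface:
    """Degree-p polynomial surface with coefficients keyed by (m, n)."""

    p: int
    coeffs: dict          # (m, n) -> c_{m,n}
    x_scale: _AxisScale = field(default_factory=_AxisScale)
    y_scale: _AxisScale = field(default_factory=_AxisScale)

    def __post_init__(self):
        expected = (self.p + 1) * (self.p + 2) // 2
        if len(self.coeffs) != expected:
            raise ValueError(f"expected {expected} coefficients for p={self.p},"
                             f" got {len(self.coeffs)}")
        if not all(math.isfinite(c) for c in self.coeffs.values()):
            raise ValueError("non-finite coefficient")

    def to_json(self, path=None) -> str:
        payload = {
            "degree": self.p,
            "coefficients": {f"{m},{n}": c for (m, n), c in self.coeffs.items()},
            "x_scale": {"offset": self.x_scale.offset, "scale": self.x_scale.scale},
            "y_scale": {"offset": self.y_scale.offset, "scale": self.y_scale.scale},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "BinomialSurface":
        try:
            payload = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                payload = json.load(fh)
        coeffs = {tuple(int(v) for v in k.split(",")): c
                  for k, c in payload["coefficients"].items()}
        return cls(p=payload["degree"], coeffs=coeffs,
                   x_scale=_AxisScale(**payload["x_scale"]),
                   y_scale=_AxisScale(**payload["y_scale"]))


def fit_binomial(cells, p: int = 5) -> BinomialSurface:
    """Ordinary least-squares fit of the degree-p surface to (x, y, z) cells.

    Minimum-norm solution if the design matrix is rank-deficient.  Inputs
    are standardised to [0, 1] per axis internally; ``eval_binomial``
    accepts original units.
    """
    cells = np.asarray(cells, dtype=float)
    n_coef = (p + 1) * (p + 2) // 2
    if cells.ndim != 2 or cells.shape[1] != 3:
        raise ValueError("cells must be an iterable of (x, y, z) triples")
    if cells.shape[0] < n_coef:
        raise ValueError(f"need at least {n_coef} points to fit degree {p}")
    xs, ys = _fit_scales(cells[:, 0], cells[:, 1])
    A = design_matrix(np.column_stack([xs.forward(cells[:, 0]),
                                       ys.forward(cells[:, 1])]), p)
    sol, *_ = np.linalg.lstsq(A, cells[:, 2], rcond=None)
    coeffs = dict(zip(monomial_exponents(p), (float(c) for c in sol)))
    return BinomialSurface(p=p, coeffs=coeffs, x_scale=xs, y_scale=ys)


def eval_binomial(surface: BinomialSurface, x, y):
    """Evaluate the surface at (x, y) in original parameter units."""
    xv = surface.x_scale.forward(x)
    yv = surface.y_scale.forward(y)
    out = np.zeros(np.broadcast(xv, yv).shape)
    for (m, n), c in surface.coeffs.items():
        out = out + c * xv ** m * yv ** n
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Regression tree

@dataclass
class TreeNode:
    """Internal ``feature <= threshold`` conditional or a leaf value.

    ``left`` is taken when the conditional is true.  Leaves carry
    ``value`` and have no children.
    """

    feature: int | None = None      # 0 = x, 1 = y; None for leaves
    threshold: float | None = None  # original units
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    value: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def __post_init__(self):
        if self.is_leaf:
            if self.value is None or self.left is not None or self.right is not None:
                raise ValueError("leaf must carry a value and no children")
        elif self.left is None or self.right is None:
            raise ValueError("internal node must have exactly two children")


@dataclass
class RegressionTree:
    """Binary regression tree over the two swept parameters."""

    root: TreeNode
    feature_names: tuple = ("x", "y")

    def n_leaves(self) -> int:
        def count(node):
            return 1 if node.is_leaf else count(node.left) + count(node.right)
        return count(self.root)

    def to_json(self, path=None) -> str:
        def encode(node):
            if node.is_leaf:
                return {"value": node.value}
            return {"feature": self.feature_names[node.feature],
                    "op": "<=", "threshold": node.threshold,
                    "left": encode(node.left), "right": encode(node.right)}
        text = json.dumps({"feature_names": list(self.feature_names),
                           "tree": encode(self.root)}, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_rules(self) -> str:
        """Indented-text rule dump: one ``<parameter> <= <value>`` per node."""
        lines = []

        def walk(node, depth):
            pad = "  " * depth
            if node.is_leaf:
                lines.append(f"{pad}value: {node.value:.6g}")
            else:
                name = self.feature_names[node.feature]
                lines.append(f"{pad}{name} <= {node.threshold:.6g}")
                walk(node.left, depth + 1)
                lines.append(f"{pad}{name} > {node.threshold:.6g}")
                walk(node.right, depth + 1)

        walk(self.root, 0)
        return "\n".join(lines)


def fit_tree(cells, max_leaf_nodes: int = 100,
             feature_names: tuple = ("x", "y")) -> RegressionTree:
    """Grow a squared-error regression tree on (x, y, z) cells.

    Best-first CART growth with candidate thresholds at midpoints of
    consecutive distinct feature values, stopping at ``max_leaf_nodes`` or
    pure leaves; leaf value = mean of its training targets.  Thresholds in
    the returned tree are in original parameter units.
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 2 or cells.shape[1] != 3 or cells.shape[0] < 1:
        raise ValueError("cells must be a non-empty iterable of (x, y, z)")
    X, z = cells[:, :2], cells[:, 2]
    est = DecisionTreeRegressor(criterion="squared_error",
                                max_leaf_nodes=max(2, max_leaf_nodes),
                                random_state=0)
    if max_leaf_nodes < 2 or len(np.unique(z)) == 1:
        return RegressionTree(root=TreeNode(value=float(np.mean(z))),
                              feature_names=tuple(feature_names))
    est.fit(X, z)
    t = est.tree_

    def convert(idx) -> TreeNode:
        if t.children_left[idx] == -1:
            return TreeNode(value=float(t.value[idx][0][0]))
        return TreeNode(feature=int(t.feature[idx]),
                        threshold=float(t.threshold[idx]),
                        left=convert(t.children_left[idx]),
                        right=convert(t.children_right[idx]))

    return RegressionTree(root=convert(0), feature_names=tuple(feature_names))


def predict_tree(tree: RegressionTree, x: float, y: float) -> float:
    """Root-to-leaf walk: inputs equal to a threshold take the left branch."""
    node = tree.root
    point = (x, y)
    while not node.is_leaf:
        node = node.left if point[node.feature] <= node.threshold else node.right
    return node.value


# ---------------------------------------------------------------------------
# Hold-out evaluation

def split_train_test(cells, test_fraction: float = 0.33, seed: int = 0):
    """Random disjoint train/test partition with |test| = round(f * n)."""
    cells = list(cells)
    if len(cells) < 2:
        raise ValueError("need at least 2 cells to split")
    if not 0 <= test_fraction < 1:
        raise ValueError("test_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cells))
    k = int(round(test_fraction * len(cells)))
    test = [cells[i] for i in sorted(order[:k])]
    train = [cells[i] for i in sorted(order[k:])]
    return train, test


def rmse(predictions, actuals) -> float:
    """Root mean squared error between two equal-length vectors."""
    p = np.asarray(predictions, dtype=float)
    a = np.asarray(actuals, dtype=float)
    if p.shape != a.shape or p.size == 0:
        raise ValueError("predictions and actuals must share a non-zero length")
    return float(np.sqrt(np.mean((p - a) ** 2)))
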