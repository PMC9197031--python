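"""Balanced classification forest with root-node introspection.

This is a CART-style random forest specialised for the survey design used
throughout the package:

* each tree's bag is *class-undersampled*: with m the minority-class count,
  m records are drawn per class (with replacement by default), so every
  tree sees balanced classes;
* ``mtry`` candidate predictors are drawn uniformly at each node (the
  headline configuration uses mtry = 1, which makes the root's split
  variable uniform over the predictors — the basis of the discriminative-
  range statistic);
* ``nodesize`` is a minimum *terminal* node size: a node is split only if
  both children can hold at least ``nodesize`` bag records;
* every node is retained, so root split-points can be read off directly.

The same tree grower doubles as a regression forest (variance-reduction
splits, mean leaves) for the iterative imputation module.

Conventions: continuous splits test ``x <= threshold`` (left); thresholds
are midpoints between consecutive distinct observed values; categorical
splits are bitmask subsets of level codes sent left.  Ties in impurity gain
are broken toward the lower variable index, then the lower threshold /
smaller subset mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import ModelDataset, PredictorSchema, ValidationError

__all__ = [
    "ForestParams",
    "Tree",
    "Forest",
    "undersample_bag",
    "best_split",
    "grow_tree",
    "train_forest",
    "predict_votes",
    "oob_predict",
]


@dataclass(frozen=True)
class ForestParams:
    """Forest hyperparameters.

    The full-scale configuration mirroring the source workflow is
    ntree=7000, mtry=1, nodesize=200; the package's desk-scale default is
    ntree=500, nodesize=50 (see docs/methods.md).
    """

    ntree: int = 500
    mtry: int = 1
    nodesize: int = 50
    seed: int = 0
    criterion: str = "gini"  # or "entropy"
    replace: bool = True  # within-class sampling with replacement

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValidationError("ntree must be >= 1")
        if self.mtry < 1:
            raise ValidationError("mtry must be >= 1")
        if self.nodesize < 1:
            raise ValidationError("nodesize must be >= 1")
        if self.criterion not in ("gini", "entropy"):
            raise ValidationError("criterion must be 'gini' or 'entropy'")


@dataclass(frozen=True)
class Split:
    """A candidate split: categorical iff ``cat_mask`` is not None."""

    feature: int
    threshold: float  # continuous only; NaN for categorical
    cat_mask: int | None  # bitmask of level codes going left
    gain: float


def _impurity_from_counts(counts: np.ndarray, criterion: str) -> np.ndarray:
    """Impurity per row of a (..., k) class-count array."""
    n = counts.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, counts / n, 0.0)
    if criterion == "gini":
        return 1.0 - (p**2).sum(axis=-1)
    logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -(p * logp).sum(axis=-1)


# ---------------------------------------------------------------------------
# Split search
# ---------------------------------------------------------------------------


def _class_counts(y: np.ndarray, k: int) -> np.ndarray:
    return np.bincount(y, minlength=k).astype(float)


def _best_continuous_split(
    x: np.ndarray, y: np.ndarray, k: int, min_child: int, criterion: str, task: str
) -> tuple[float, float] | None:
    """Best threshold for one continuous variable; returns (threshold, gain)."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    boundaries = np.nonzero(xs[1:] != xs[:-1])[0]  # split after position i
    if boundaries.size == 0:
        return None
    n_left = boundaries + 1
    ok = (n_left >= min_child) & (n - n_left >= min_child)
    boundaries = boundaries[ok]
    if boundaries.size == 0:
        return None
    n_left = boundaries + 1
    n_right = n - n_left
    if task == "classification":
        onehot = np.zeros((n, k))
        onehot[np.arange(n), ys] = 1.0
        cum = onehot.cumsum(axis=0)
        left_counts = cum[boundaries]
        right_counts = cum[-1] - left_counts
        parent = _impurity_from_counts(cum[-1], criterion)
        child = (
            n_left * _impurity_from_counts(left_counts, criterion)
            + n_right * _impurity_from_counts(right_counts, criterion)
        ) / n
        gains = parent - child
    else:  # regression: variance reduction
        yf = ys.astype(float)
        cs, cs2 = yf.cumsum(), (yf**2).cumsum()
        sl, sl2 = cs[boundaries], cs2[boundaries]
        sr, sr2 = cs[-1] - sl, cs2[-1] - sl2
        var_l = sl2 / n_left - (sl / n_left) ** 2
        var_r = sr2 / n_right - (sr / n_right) ** 2
        parent = cs2[-1] / n - (cs[-1] / n) ** 2
        gains = parent - (n_left * var_l + n_right * var_r) / n
    best = int(np.argmax(gains))  # first occurrence -> lowest threshold on ties
    if gains[best] <= 1e-12:
        return None
    b = boundaries[best]
    threshold = (xs[b] + xs[b + 1]) / 2.0
    return float(threshold), float(gains[best])


def _best_categorical_split(
    codes: np.ndarray, y: np.ndarray, k: int, min_child: int, criterion: str, task: str
) -> tuple[int, float] | None:
    """Exhaustive binary-partition search over observed levels.

    Returns (bitmask of level codes going left, gain).  The highest observed
    level is pinned to the right side, halving the enumeration; masks are
    scanned ascending so ties resolve to the smallest mask.
    """
    levels = np.unique(codes).astype(int)
    if levels.size < 2:
        return None
    n = len(codes)
    if task == "classification":
        stats = np.zeros((levels.size, k))
        for li, lev in enumerate(levels):
            stats[li] = _class_counts(y[codes == lev], k)
    else:
        yf = y.astype(float)
        stats = np.zeros((levels.size, 3))  # n, sum, sumsq
        for li, lev in enumerate(levels):
            sel = yf[codes == lev]
            stats[li] = (len(sel), sel.sum(), (sel**2).sum())
    total = stats.sum(axis=0)

    if task == "classification":
        parent = float(_impurity_from_counts(total, criterion))
    else:
        parent = total[2] / n - (total[1] / n) ** 2

    best_mask, best_gain = None, 1e-12
    free = levels[:-1]  # pin levels[-1] right
    for subset in range(1, 1 << len(free)):
        members = [free[b] for b in range(len(free)) if subset >> b & 1]
        left = stats[[int(np.where(levels == m)[0][0]) for m in members]].sum(axis=0)
        right = total - left
        if task == "classification":
            nl, nr = left.sum(), right.sum()
            if nl < min_child or nr < min_child:
                continue
            child = (
                nl * float(_impurity_from_counts(left, criterion))
                + nr * float(_impurity_from_counts(right, criterion))
            ) / n
        else:
            nl, nr = left[0], right[0]
            if nl < min_child or nr < min_child:
                continue
            var_l = left[2] / nl - (left[1] / nl) ** 2
            var_r = right[2] / nr - (right[1] / nr) ** 2
            child = (nl * var_l + nr * var_r) / n
        gain = parent - child
        if gain > best_gain:
            mask = 0
            for m in members:
                mask |= 1 << int(m)
            best_mask, best_gain = mask, gain
    if best_mask is None:
        return None
    return best_mask, float(best_gain)


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    rows: np.ndarray,
    feature: int,
    schema: PredictorSchema,
    k: int,
    min_child: int = 1,
    criterion: str = "gini",
    task: str = "classification",
) -> Split | None:
    """Best split of ``rows`` on one candidate ``feature``; None if no split
    strictly reduces impurity under the child-size constraint."""
    yv = y[rows]
    if task == "classification" and len(np.unique(yv)) < 2:
        return None
    xv = X[rows, feature]
    if schema.kinds[feature] == "continuous":
        res = _best_continuous_split(xv, yv, k, min_child, criterion, task)
        if res is None:
            return None
        thr, gain = res
        return Split(feature, thr, None, gain)
    res = _best_categorical_split(xv.astype(int), yv, k, min_child, criterion, task)
    if res is None:
        return None
    mask, gain = res
    return Split(feature, float("nan"), mask, gain)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class Tree:
    """Flat node arrays; node 0 is the root, feature == -1 marks a leaf.

    ``value[i]`` is the class-frequency vector of the bag rows in the node's
    subtree leaf (classification) or their mean response (regression).
    """

    feature: np.ndarray  # int, -1 for leaf
    threshold: np.ndarray  # float, NaN for categorical / leaf
    cat_mask: np.ndarray  # int64, 0 unless categorical split
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray  # (n_nodes, k) or (n_nodes,) for regression
    task: str = "classification"

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def is_leaf_only(self) -> bool:
        return self.feature[0] == -1

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf node index for every row of X (vectorised descent)."""
        idx = np.zeros(len(X), dtype=int)
        while True:
            f = self.feature[idx]
            live = f >= 0
            if not live.any():
                return idx
            nodes = idx[live]
            feats = f[live]
            xv = X[np.nonzero(live)[0], feats]
            is_cat = self.cat_mask[nodes] != 0
            go_left = np.empty(len(nodes), dtype=bool)
            go_left[~is_cat] = xv[~is_cat] <= self.threshold[nodes[~is_cat]]
            if is_cat.any():
                codes = xv[is_cat].astype(np.int64)
                go_left[is_cat] = (self.cat_mask[nodes[is_cat]] >> codes) & 1 == 1
            nxt = np.where(go_left, self.left[nodes], self.right[nodes])
            idx[live] = nxt

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.value[self.apply(X)]

    def root_split(self) -> tuple[int, float, int] | None:
        """(feature, threshold, cat_mask) of the root, or None for a stump."""
        if self.is_leaf_only():
            return None
        return int(self.feature[0]), float(self.threshold[0]), int(self.cat_mask[0])

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": [None if np.isnan(t) else t for t in self.threshold],
            "cat_mask": self.cat_mask.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "value": self.value.tolist(),
            "task": self.task,
        }


def undersample_bag(labels: np.ndarray, rng: np.random.Generator, replace: bool = True) -> np.ndarray:
    """Class-balanced bag: m = minority count; draw m records per class.

    Draws are with replacement by default (bootstrap within class).  The
    returned array holds record indices, grouped by class label order.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValidationError("undersampling needs at least 2 classes present")
    per_class = [np.nonzero(labels == c)[0] for c in classes]
    m = min(len(p) for p in per_class)
    if m == 0:
        raise ValidationError("a class has no records")
    parts = [rng.choice(p, size=m, replace=replace) for p in per_class]
    return np.concatenate(parts)


def grow_tree(
    X: np.ndarray,
    y0: np.ndarray,
    bag: np.ndarray,
    schema: PredictorSchema,
    params: ForestParams,
    rng: np.random.Generator,
    k: int,
    task: str = "classification",
) -> Tree:
    """Recursive partitioning of the bag rows.

    ``y0`` is zero-based for classification.  A node becomes a leaf when it
    is pure, holds fewer than 2*nodesize bag records, or none of the mtry
    drawn candidates yields an improving split with both children >=
    nodesize.
    """
    feature: list[int] = []
    threshold: list[float] = []
    cat_mask: list[int] = []
    left: list[int] = []
    right: list[int] = []
    values: list = []
    p = schema.n_predictors
    mtry = min(params.mtry, p)

    def leaf_value(rows: np.ndarray):
        if task == "classification":
            counts = _class_counts(y0[rows], k)
            return counts / counts.sum()
        return float(y0[rows].mean())

    def build(rows: np.ndarray) -> int:
        node = len(feature)
        feature.append(-1)
        threshold.append(float("nan"))
        cat_mask.append(0)
        left.append(-1)
        right.append(-1)
        values.append(leaf_value(rows))
        pure = (
            len(np.unique(y0[rows])) < 2
            if task == "classification"
            else np.ptp(y0[rows].astype(float)) <= 0
        )
        if pure or len(rows) < 2 * params.nodesize:
            return node
        cand = rng.choice(p, size=mtry, replace=False)
        best: Split | None = None
        for j in sorted(int(c) for c in cand):
            s = best_split(
                X, y0, rows, j, schema, k,
                min_child=params.nodesize, criterion=params.criterion, task=task,
            )
            if s is not None and (best is None or s.gain > best.gain):
                best = s
        if best is None:
            return node
        xv = X[rows, best.feature]
        if best.cat_mask is None:
            go_left = xv <= best.threshold
        else:
            go_left = (best.cat_mask >> xv.astype(np.int64)) & 1 == 1
        feature[node] = best.feature
        threshold[node] = best.threshold
        cat_mask[node] = best.cat_mask or 0
        left[node] = build(rows[go_left])
        right[node] = build(rows[~go_left])
        return node

    build(np.asarray(bag))
    value = (
        np.array(values, dtype=float)
        if task == "classification"
        else np.array(values, dtype=float)
    )
    return Tree(
        feature=np.array(feature, dtype=int),
        threshold=np.array(threshold, dtype=float),
        cat_mask=np.array(cat_mask, dtype=np.int64),
        left=np.array(left, dtype=int),
        right=np.array(right, dtype=int),
        value=value,
        task=task,
    )


# ---------------------------------------------------------------------------
# Forest
# ---------------------------------------------------------------------------


@dataclass
class Forest:
    """A trained ensemble with per-tree bag records for OOB prediction."""

    trees: list[Tree]
    bags: list[np.ndarray]  # record indices drawn (with multiplicity)
    classes: np.ndarray  # original labels, ascending (classification)
    schema: PredictorSchema
    params: ForestParams
    n_records: int
    task: str = "classification"

    @property
    def ntree(self) -> int:
        return len(self.trees)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def predict_votes(self, X: np.ndarray) -> np.ndarray:
        """Soft votes: mean of leaf class distributions across trees, (n, k)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if np.isnan(X).any():
            raise ValidationError("missing predictor value; impute before predicting")
        acc = np.zeros((len(X), self.n_classes))
        for tree in self.trees:
            acc += tree.predict(X)
        return acc / self.ntree

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard labels: argmax of votes, ties to the lowest label index."""
        votes = self.predict_votes(X)
        return self.classes[np.argmax(votes, axis=1)]

    def predict_mean(self, X: np.ndarray) -> np.ndarray:
        """Regression prediction (mean of tree means)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        acc = np.zeros(len(X))
        for tree in self.trees:
            acc += tree.predict(X)
        return acc / self.ntree

    def oob_mask(self) -> np.ndarray:
        """(ntree, n_records) boolean: record out of bag for that tree."""
        mask = np.ones((self.ntree, self.n_records), dtype=bool)
        for t, bag in enumerate(self.bags):
            mask[t, np.unique(bag)] = False
        return mask

    def to_dict(self, include_bags: bool = True) -> dict:
        d = {
            "params": self.params.__dict__,
            "classes": self.classes.tolist(),
            "schema": {
                "names": list(self.schema.names),
                "kinds": list(self.schema.kinds),
                "n_levels": list(self.schema.n_levels),
            },
            "n_records": self.n_records,
            "task": self.task,
            "trees": [t.to_dict() for t in self.trees],
        }
        if include_bags:
            d["bags"] = [b.tolist() for b in self.bags]
        return d

    def to_json(self, include_bags: bool = True) -> str:
        return json.dumps(self.to_dict(include_bags), sort_keys=True)


def train_forest(ds: ModelDataset, params: ForestParams) -> Forest:
    """Train ``ntree`` undersampled-bag trees from a seeded stream."""
    classes = np.unique(ds.y)
    if classes.size < 2:
        raise ValidationError("need at least 2 classes to train")
    k = classes.size
    label_index = {c: i for i, c in enumerate(classes)}
    y0 = np.array([label_index[v] for v in ds.y], dtype=int)
    seeds = np.random.SeedSequence(params.seed).spawn(params.ntree)
    trees: list[Tree] = []
    bags: list[np.ndarray] = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        bag = undersample_bag(ds.y, rng, replace=params.replace)
        trees.append(grow_tree(ds.X, y0, bag, ds.schema, params, rng, k))
        bags.append(bag)
    return Forest(
        trees=trees,
        bags=bags,
        classes=classes,
        schema=ds.schema,
        params=params,
        n_records=ds.n_records,
    )


def predict_votes(forest: Forest, record: np.ndarray) -> np.ndarray:
    """Per-class voting fractions for a single complete record."""
    return forest.predict_votes(np.atleast_2d(record))[0]


def oob_predict(forest: Forest, ds: ModelDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Out-of-bag votes and labels.

    Returns (votes (n, k) with NaN rows where no tree left the record out,
    predicted labels with 0 marking uncovered records, covered mask).
    """
    n, k = ds.n_records, forest.n_classes
    acc = np.zeros((n, k))
    cnt = np.zeros(n)
    oob = forest.oob_mask()
    for t, tree in enumerate(forest.trees):
        rows = np.nonzero(oob[t])[0]
        if rows.size == 0:
            continue
        acc[rows] += tree.predict(ds.X[rows])
        cnt[rows] += 1
    covered = cnt > 0
    votes = np.full((n, k), np.nan)
    votes[covered] = acc[covered] / cnt[covered, None]
    labels = np.zeros(n, dtype=int)
    labels[covered] = forest.classes[np.argmax(votes[covered], axis=1)]
    return votes, labels, covered
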