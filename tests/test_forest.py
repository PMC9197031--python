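"""Forest mechanics: balanced bags, exact split search, OOB behaviour."""

import copy

import numpy as np
import pytest

from phytoranges.data_io import ModelDataset, PredictorSchema, ValidationError, default_schema
from phytoranges.evaluation import evaluate_forest_oob
from phytoranges.forest import (
    Forest,
    ForestParams,
    best_split,
    grow_tree,
    oob_predict,
    train_forest,
    undersample_bag,
)

from conftest import random_model_dataset


class TestUndersampling:
    def test_bag_sizes_forced_by_minority(self, rng):
        labels = np.repeat([1, 2, 3, 4], [500, 300, 100, 80])
        bag = undersample_bag(labels, rng)
        assert len(bag) == 4 * 80
        for c in (1, 2, 3, 4):
            assert (labels[bag] == c).sum() == 80

    def test_balanced_classes(self, rng):
        labels = np.repeat([1, 2], 50)
        bag = undersample_bag(labels, rng)
        assert len(bag) == 100
        assert (labels[bag] == 1).sum() == 50

    def test_bootstrap_unique_fraction(self, rng):
        # a class sampled at its own size with replacement keeps ~1-1/e unique
        labels = np.repeat([1, 2], 1000)
        bag = undersample_bag(labels, rng)
        uniq = len(np.unique(bag[:1000])) / 1000
        assert uniq == pytest.approx(1 - np.exp(-1), abs=0.05)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValidationError):
            undersample_bag(np.ones(10, dtype=int), rng)


def brute_force_gini_split(X, y, rows, j, kinds, min_child):
    """Exhaustive scorer re-deriving Gini for every candidate split."""

    def gini(labels):
        if len(labels) == 0:
            return 0.0
        _, c = np.unique(labels, return_counts=True)
        p = c / c.sum()
        return 1.0 - (p**2).sum()

    yv, xv = y[rows], X[rows, j]
    n = len(rows)
    parent = gini(yv)
    best = None
    if kinds[j] == "continuous":
        for t in np.unique(xv)[:-1]:
            left = xv <= t
            nl = left.sum()
            if nl < min_child or n - nl < min_child:
                continue
            gain = parent - (nl * gini(yv[left]) + (n - nl) * gini(yv[~left])) / n
            mid = (t + np.unique(xv)[np.searchsorted(np.unique(xv), t) + 1]) / 2
            if gain > 1e-12 and (best is None or gain > best[0] + 1e-12):
                best = (gain, mid)
    else:
        levels = np.unique(xv.astype(int))
        import itertools

        for r in range(1, len(levels)):
            for combo in itertools.combinations(levels, r):
                if levels[-1] in combo:
                    continue  # canonical side
                left = np.isin(xv.astype(int), combo)
                nl = left.sum()
                if nl < min_child or n - nl < min_child:
                    continue
                gain = parent - (nl * gini(yv[left]) + (n - nl) * gini(yv[~left])) / n
                mask = sum(1 << int(l) for l in combo)
                if gain > 1e-12 and (best is None or gain > best[0] + 1e-12):
                    best = (gain, mask)
    return best


class TestBestSplit:
    def test_pure_node_returns_none(self, rng):
        X = rng.random((20, 7))
        y = np.zeros(20, dtype=int)
        assert best_split(X, y, np.arange(20), 0, default_schema(), 2) is None

    def test_perfect_separation_splits_at_midpoint_between_boundaries(self):
        X = np.zeros((6, 7))
        X[:, 2] = [1.0, 2.0, 3.0, 7.0, 8.0, 9.0]
        y = np.array([0, 0, 0, 1, 1, 1])
        s = best_split(X, y, np.arange(6), 2, default_schema(), 2)
        assert s.threshold == pytest.approx(5.0)
        assert s.gain == pytest.approx(0.5)

    @pytest.mark.parametrize("feature,kind", [(3, "continuous"), (6, "categorical")])
    def test_matches_exhaustive_scorer_on_random_nodes(self, rng, feature, kind):
        schema = default_schema()
        for trial in range(60):
            n = int(rng.integers(10, 40))
            X = np.column_stack(
                [rng.normal(size=n) for _ in range(6)]
                + [rng.integers(0, 7, n).astype(float)]
            )
            y = rng.integers(0, 3, n)
            rows = np.arange(n)
            got = best_split(X, y, rows, feature, schema, 3, min_child=2)
            want = brute_force_gini_split(X, y, rows, feature, schema.kinds, 2)
            if want is None:
                assert got is None
                continue
            assert got is not None
            assert got.gain == pytest.approx(want[0])
            if kind == "continuous":
                assert got.threshold == pytest.approx(want[1])
            else:
                assert got.cat_mask == want[1]


class TestGrowTree:
    def test_huge_nodesize_yields_uniform_stump(self, dataset):
        params = ForestParams(ntree=1, mtry=7, nodesize=10**6, seed=0)
        f = train_forest(dataset, params)
        tree = f.trees[0]
        assert tree.is_leaf_only()
        # undersampled bag is class-balanced, so the stump votes uniformly
        np.testing.assert_allclose(tree.value[0], 0.25, atol=1e-9)

    def test_perfect_predictor_gives_depth_one_tree(self, rng):
        n = 200
        X = np.column_stack(
            [rng.normal(size=n) for _ in range(6)] + [rng.integers(0, 7, n).astype(float)]
        )
        y = 1 + (X[:, 0] > 0).astype(int)
        y[:2] = [1, 2]
        ds = ModelDataset(X, y, np.array(["a"] * n), np.array(["b"] * n), default_schema())
        f = train_forest(ds, ForestParams(ntree=1, mtry=7, nodesize=5, seed=1))
        tree = f.trees[0]
        assert tree.feature[0] == 0
        left, right = tree.left[0], tree.right[0]
        assert tree.feature[left] == -1 and tree.feature[right] == -1
        assert tree.value[left].max() == pytest.approx(1.0)

    def test_root_threshold_inside_observed_range(self, small_forest, dataset):
        names = small_forest.schema.names
        for tree in small_forest.trees:
            root = tree.root_split()
            if root is None:
                continue
            feat, thr, mask = root
            if small_forest.schema.kinds[feat] == "continuous":
                col = dataset.X[:, feat]
                assert col.min() < thr < col.max()


class TestForest:
    def test_same_seed_bitwise_identical(self, dataset):
        params = ForestParams(ntree=20, mtry=1, nodesize=50, seed=5)
        a = train_forest(dataset, params).to_json()
        b = train_forest(dataset, params).to_json()
        assert a == b

    def test_votes_normalised_and_single_tree_votes_are_leaf_values(self, dataset):
        f = train_forest(dataset, ForestParams(ntree=1, mtry=1, nodesize=50, seed=2))
        votes = f.predict_votes(dataset.X[:25])
        np.testing.assert_allclose(votes.sum(axis=1), 1.0)
        tree = f.trees[0]
        np.testing.assert_allclose(votes, tree.predict(dataset.X[:25]))

    def test_stump_forest_votes_uniform(self, dataset):
        f = train_forest(dataset, ForestParams(ntree=10, mtry=1, nodesize=10**6, seed=3))
        votes = f.predict_votes(dataset.X[:10])
        np.testing.assert_allclose(votes, 0.25, atol=1e-9)

    def test_missing_predictor_rejected_at_predict(self, small_forest, dataset):
        X = dataset.X[:3].copy()
        X[0, 0] = np.nan
        with pytest.raises(ValidationError, match="impute"):
            small_forest.predict_votes(X)

    def test_separable_signal_reaches_high_oob_accuracy(self, rng):
        ds = random_model_dataset(rng, n=900, n_classes=3, informative=True)
        f = train_forest(ds, ForestParams(ntree=300, mtry=1, nodesize=20, seed=4))
        m = evaluate_forest_oob(f, ds)
        assert m["accuracy"] >= 0.9

    def test_label_permutation_gives_null_kappa(self, dataset, rng):
        ds = copy.deepcopy(dataset)
        ds.y = rng.permutation(ds.y)
        f = train_forest(ds, ForestParams(ntree=300, mtry=1, nodesize=50, seed=6))
        m = evaluate_forest_oob(f, ds)
        assert abs(m["kappa"]) <= 0.05


class TestOOB:
    def test_single_tree_oob_is_bag_complement(self, dataset):
        f = train_forest(dataset, ForestParams(ntree=1, mtry=1, nodesize=50, seed=8))
        _, _, covered = oob_predict(f, dataset)
        in_bag = np.zeros(dataset.n_records, dtype=bool)
        in_bag[np.unique(f.bags[0])] = True
        np.testing.assert_array_equal(covered, ~in_bag)

    def test_oob_accuracy_below_in_bag_accuracy(self, dataset):
        f = train_forest(dataset, ForestParams(ntree=200, mtry=1, nodesize=50, seed=9))
        oob = evaluate_forest_oob(f, dataset)
        pred_in = f.predict(dataset.X)
        acc_in = (pred_in == dataset.y).mean()
        assert oob["accuracy"] <= acc_in + 1e-9

    def test_full_coverage_at_moderate_ntree(self, dataset):
        f = train_forest(dataset, ForestParams(ntree=200, mtry=1, nodesize=50, seed=10))
        _, _, covered = oob_predict(f, dataset)
        assert covered.all()

    def test_every_bag_is_class_balanced(self, small_forest, dataset):
        for bag in small_forest.bags:
            counts = np.bincount(dataset.y[bag], minlength=5)[1:]
            assert len(set(counts)) == 1


def test_kappa_stability_in_tree_count(recovery_bundle):
    """The OOB kappa plateau: doubling the forest hardly moves the estimate.

    Run on the larger survey so the comparison is not dominated by the
    metric's own sampling noise."""
    from phytoranges import assemble_model_dataset, build_presence_matrix, impute_median_mode

    pm = build_presence_matrix(recovery_bundle.occurrences, min_sites=25)
    complete, _ = impute_median_mode(recovery_bundle.sites)
    labels = {s: recovery_bundle.truth.group_of[s] for s in pm.species_ids}
    ds = assemble_model_dataset(pm, complete, labels)
    m2 = evaluate_forest_oob(
        train_forest(ds, ForestParams(ntree=2000, mtry=1, nodesize=200, seed=21)), ds
    )
    m4 = evaluate_forest_oob(
        train_forest(ds, ForestParams(ntree=4000, mtry=1, nodesize=200, seed=22)), ds
    )
    assert abs(m2["kappa"] - m4["kappa"]) < 0.02
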