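"""Metrics, splitting, kappa-thresholded group-count selection, CV."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from phytoranges.data_io import ValidationError
from phytoranges.evaluation import (
    ConfusionMatrix,
    accuracy,
    cohens_kappa,
    confusion,
    holdout_check,
    kappa_band,
    kfold_cv,
    select_n_groups,
    train_holdout_split,
)
from phytoranges.forest import ForestParams

from conftest import random_model_dataset


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        cm = confusion([1, 2, 3, 1], [1, 2, 3, 1])
        assert np.trace(cm.counts) == cm.total == 4

    def test_swapped_vectors_transpose(self, rng):
        a, b = rng.integers(1, 4, 50), rng.integers(1, 4, 50)
        labels = np.arange(1, 4)
        cm_ab = confusion(a, b, labels)
        cm_ba = confusion(b, a, labels)
        np.testing.assert_array_equal(cm_ab.counts.T, cm_ba.counts)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion([1, 2], [1])


class TestMetrics:
    def test_accuracy_trace_over_total(self):
        cm = ConfusionMatrix(np.array([[20, 5], [10, 15]]), np.array([1, 2]))
        assert accuracy(cm) == pytest.approx(0.70)
        assert accuracy(ConfusionMatrix(np.array([[0, 3], [4, 0]]), np.array([1, 2]))) == 0.0

    def test_kappa_hand_formula(self):
        # p_o = 0.70, p_e = 0.50 -> kappa = 0.40
        cm = ConfusionMatrix(np.array([[20, 5], [10, 15]]), np.array([1, 2]))
        assert cohens_kappa(cm) == pytest.approx(0.40)

    def test_kappa_zero_under_independent_marginals(self):
        cm = ConfusionMatrix(np.array([[9, 1], [81, 9]]), np.array([1, 2]))
        assert cohens_kappa(cm) == pytest.approx(0.0)

    def test_kappa_one_on_diagonal(self):
        cm = ConfusionMatrix(np.diag([5, 7, 9]), np.array([1, 2, 3]))
        assert cohens_kappa(cm) == 1.0

    def test_kappa_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(10):
            a, b = rng.integers(1, 5, 80), rng.integers(1, 5, 80)
            cm = confusion(a, b, np.arange(1, 5))
            assert cohens_kappa(cm) == pytest.approx(cohen_kappa_score(a, b))

    @given(st.permutations([1, 2, 3]))
    def test_kappa_invariant_to_label_permutation(self, perm):
        rng = np.random.default_rng(5)
        a, b = rng.integers(1, 4, 120), rng.integers(1, 4, 120)
        relabel = dict(zip([1, 2, 3], perm))
        k1 = cohens_kappa(confusion(a, b, np.arange(1, 4)))
        a2 = np.array([relabel[v] for v in a])
        b2 = np.array([relabel[v] for v in b])
        k2 = cohens_kappa(confusion(a2, b2, np.arange(1, 4)))
        assert k1 == pytest.approx(k2)

    @pytest.mark.parametrize(
        "value,band",
        [
            (-0.1, "poor agreement"),
            (0.0, "slight agreement"),
            (0.19, "slight agreement"),
            (0.20, "fair agreement"),
            (0.35, "fair agreement"),
            (0.40, "moderate agreement"),
            (0.60, "substantial agreement"),
            (0.79, "substantial agreement"),
            (0.80, "almost perfect agreement"),
            (1.0, "almost perfect agreement"),
        ],
    )
    def test_kappa_bands(self, value, band):
        assert kappa_band(value) == band


class TestSplit:
    def test_part_sizes_union_disjointness(self, rng):
        ds = random_model_dataset(rng, n=1000, n_classes=3)
        train, hold = train_holdout_split(ds, 0.8, seed=1)
        assert train.n_records == 800 and hold.n_records == 200
        assert set(np.unique(train.y)) == set(np.unique(hold.y)) == {1, 2, 3}

    def test_same_seed_same_split(self, rng):
        ds = random_model_dataset(rng, n=200, n_classes=2)
        a1, _ = train_holdout_split(ds, 0.8, seed=2)
        a2, _ = train_holdout_split(ds, 0.8, seed=2)
        np.testing.assert_array_equal(a1.X, a2.X)

    def test_tiny_group_rejected(self, rng):
        ds = random_model_dataset(rng, n=100, n_classes=2)
        ds.y[:] = 1
        ds.y[0] = 2
        with pytest.raises(ValidationError, match="fewer than 2"):
            train_holdout_split(ds, 0.8, seed=3)

    def test_stratified_split_keeps_proportions(self, rng):
        ds = random_model_dataset(rng, n=500, n_classes=2)
        train, hold = train_holdout_split(ds, 0.8, seed=4, stratify=True)
        for g in (1, 2):
            frac = (train.y == g).sum() / (ds.y == g).sum()
            assert frac == pytest.approx(0.8, abs=0.02)


class TestSelection:
    def test_stub_metric_sequence_first_drop_rule(self, presence, complete_sites):
        kappas = {2: 0.50, 3: 0.45, 4: 0.32, 5: 0.28, 6: 0.31}
        seen = []

        def stub(k, ga):
            seen.append(k)
            return {"accuracy": 0.5, "kappa": kappas[k]}

        trace = select_n_groups(
            presence, complete_sites, ForestParams(ntree=1), eval_fn=stub
        )
        assert trace.selected_k == 4
        assert seen == [2, 3, 4, 5]  # scan stops at the first drop
        assert [e["k"] for e in trace.entries] == [2, 3, 4, 5]

    def test_stub_below_threshold_at_two_selects_none(self, presence, complete_sites):
        trace = select_n_groups(
            presence,
            complete_sites,
            ForestParams(ntree=1),
            eval_fn=lambda k, ga: {"accuracy": 0.2, "kappa": 0.1},
        )
        assert trace.selected_k is None
        assert "k=2" in trace.reason

    def test_stub_never_dropping_reports_k_max(self, presence, complete_sites):
        trace = select_n_groups(
            presence,
            complete_sites,
            ForestParams(ntree=1),
            k_max=6,
            eval_fn=lambda k, ga: {"accuracy": 0.9, "kappa": 0.8},
        )
        assert trace.selected_k == 6
        assert "never dropped" in trace.reason


class TestHoldoutCheck:
    def test_identical_metrics_pass_with_zero_delta(self):
        ok, deltas = holdout_check({"accuracy": 0.5, "kappa": 0.3}, {"accuracy": 0.5, "kappa": 0.3})
        assert ok and deltas["accuracy"] == 0.0

    @pytest.mark.parametrize("delta,expected", [(0.04, True), (0.08, False)])
    def test_threshold_rule(self, delta, expected):
        ok, _ = holdout_check(
            {"accuracy": 0.5, "kappa": 0.3}, {"accuracy": 0.5 + delta, "kappa": 0.3}
        )
        assert ok is expected


class TestKFold:
    def test_fold_sizes_balanced_within_strata(self, rng):
        ds = random_model_dataset(rng, n=400, n_classes=2)
        out = kfold_cv(ds, ForestParams(ntree=20, mtry=1, nodesize=20, seed=1), n_folds=5, seed=2)
        fold_of = out["fold_of"]
        for g in (1, 2):
            sizes = np.bincount(fold_of[ds.y == g], minlength=5)
            assert sizes.max() - sizes.min() <= 1

    def test_same_seed_same_folds(self, rng):
        ds = random_model_dataset(rng, n=200, n_classes=2)
        p = ForestParams(ntree=10, mtry=1, nodesize=20, seed=3)
        a = kfold_cv(ds, p, n_folds=4, seed=5)
        b = kfold_cv(ds, p, n_folds=4, seed=5)
        np.testing.assert_array_equal(a["fold_of"], b["fold_of"])
        assert a["accuracy_mean"] == b["accuracy_mean"]

    def test_group_smaller_than_folds_rejected(self, rng):
        ds = random_model_dataset(rng, n=60, n_classes=2)
        ds.y[:] = 1
        ds.y[:3] = 2
        with pytest.raises(ValidationError, match="fewer than"):
            kfold_cv(ds, ForestParams(ntree=5), n_folds=10, seed=1)

    def test_cv_consistent_with_oob(self, dataset):
        from phytoranges.evaluation import evaluate_forest_oob
        from phytoranges.forest import train_forest

        params = ForestParams(ntree=200, mtry=1, nodesize=50, seed=11)
        oob = evaluate_forest_oob(train_forest(dataset, params), dataset)
        cv = kfold_cv(dataset, params, n_folds=10, seed=12)
        assert cv["accuracy_mean"] == pytest.approx(oob["accuracy"], abs=0.05)
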