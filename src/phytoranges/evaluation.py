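"""Model evaluation and group-count selection.

Accuracy and Cohen's kappa are computed on out-of-bag (OOB) predictions,
kappa being chance-corrected agreement

    kappa = (p_o - p_e) / (1 - p_e),
    p_o = trace / n,   p_e = sum_i row_i * col_i / n^2.

The number of species groups is selected by scanning cluster counts k = 2,
3, ... and stopping at the first k where OOB kappa drops below a threshold
(0.3 by default); the selected count is the last k before the drop.  A
holdout fraction guards against overfitting and stratified k-fold
cross-validation checks generalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .data_io import ModelDataset, PresenceMatrix, SiteTable, ValidationError, assemble_model_dataset
from .forest import Forest, ForestParams, oob_predict, train_forest
from .grouping import GroupAssignment, cut_dendrogram, jaccard_distances, ward_linkage

__all__ = [
    "ConfusionMatrix",
    "SelectionTrace",
    "confusion",
    "accuracy",
    "cohens_kappa",
    "kappa_band",
    "train_holdout_split",
    "evaluate_forest_oob",
    "select_n_groups",
    "holdout_check",
    "kfold_cv",
]


@dataclass
class ConfusionMatrix:
    """k x k counts; rows = true group, columns = predicted group."""

    counts: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValidationError("confusion matrix must be square")
        if (c < 0).any():
            raise ValidationError("confusion matrix counts must be non-negative")
        self.counts = c.astype(int)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(true: np.ndarray, predicted: np.ndarray, labels: np.ndarray | None = None) -> ConfusionMatrix:
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if len(true) != len(predicted):
        raise ValidationError("label vectors have different lengths")
    if labels is None:
        labels = np.unique(np.concatenate([true, predicted]))
    labels = np.asarray(labels)
    index = {c: i for i, c in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(true, predicted):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, labels)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of records on the diagonal."""
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement in [-1, 1]."""
    n = cm.total
    if n == 0:
        raise ValidationError("empty confusion matrix")
    p_o = np.trace(cm.counts) / n
    p_e = float((cm.counts.sum(axis=1) * cm.counts.sum(axis=0)).sum()) / n**2
    if p_e >= 1.0:
        raise ValidationError("degenerate confusion matrix: chance agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


_BANDS = [
    (0.80, "almost perfect agreement"),
    (0.60, "substantial agreement"),
    (0.40, "moderate agreement"),
    (0.20, "fair agreement"),
    (0.00, "slight agreement"),
]


def kappa_band(kappa: float) -> str:
    """Verbal interpretation band for a kappa value."""
    if not -1.0 - 1e-9 <= kappa <= 1.0 + 1e-9:
        raise ValidationError("kappa must lie in [-1, 1]")
    if kappa < 0:
        return "poor agreement"
    for lo, name in _BANDS:
        if kappa >= lo:
            return name
    return "slight agreement"


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def train_holdout_split(
    ds: ModelDataset,
    train_frac: float = 0.8,
    seed: int = 0,
    stratify: bool = False,
    max_redraws: int = 100,
) -> tuple[ModelDataset, ModelDataset]:
    """Record-level random partition into train/holdout.

    Both parts must contain every group; non-stratified draws are retried
    (with fresh sub-seeds) until that holds, erroring if a group is too
    small to ever appear in both parts.
    """
    if not 0 < train_frac < 1:
        raise ValidationError("train_frac must be in (0, 1)")
    n = ds.n_records
    n_train = int(round(train_frac * n))
    groups = np.unique(ds.y)
    for g in groups:
        if (ds.y == g).sum() < 2:
            raise ValidationError(f"group {g} has fewer than 2 records; cannot split")
    ss = np.random.SeedSequence(seed)
    if stratify:
        rng = np.random.default_rng(ss)
        train_idx: list[int] = []
        for g in groups:
            rows = np.nonzero(ds.y == g)[0]
            take = max(1, min(len(rows) - 1, int(round(train_frac * len(rows)))))
            train_idx.extend(rng.choice(rows, size=take, replace=False))
        tr = np.sort(np.array(train_idx))
    else:
        for attempt_ss in ss.spawn(max_redraws):
            rng = np.random.default_rng(attempt_ss)
            perm = rng.permutation(n)
            tr = np.sort(perm[:n_train])
            ho = perm[n_train:]
            if set(groups) <= set(ds.y[tr]) and set(groups) <= set(ds.y[ho]):
                break
        else:
            raise ValidationError("could not place every group in both parts")
    mask = np.zeros(n, dtype=bool)
    mask[tr] = True
    return ds.subset(np.nonzero(mask)[0]), ds.subset(np.nonzero(~mask)[0])


# ---------------------------------------------------------------------------
# OOB metrics and selection
# ---------------------------------------------------------------------------


def evaluate_forest_oob(forest: Forest, ds: ModelDataset) -> dict:
    """OOB accuracy and kappa; records OOB for zero trees are excluded."""
    _, labels, covered = oob_predict(forest, ds)
    if covered.sum() == 0:
        raise ValidationError("no record has OOB coverage; increase ntree")
    cm = confusion(ds.y[covered], labels[covered], labels=forest.classes)
    kap = cohens_kappa(cm)
    return {
        "accuracy": accuracy(cm),
        "kappa": kap,
        "band": kappa_band(kap),
        "n_scored": int(covered.sum()),
        "n_uncovered": int((~covered).sum()),
    }


def evaluate_predictions(true: np.ndarray, predicted: np.ndarray, labels: np.ndarray) -> dict:
    cm = confusion(true, predicted, labels=labels)
    kap = cohens_kappa(cm)
    return {"accuracy": accuracy(cm), "kappa": kap, "band": kappa_band(kap)}


@dataclass
class SelectionTrace:
    """Per-k OOB metrics from the group-count scan."""

    entries: list[dict] = field(default_factory=list)
    selected_k: int | None = None
    reason: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)


def select_n_groups(
    pm: PresenceMatrix,
    sites_complete: SiteTable,
    params: ForestParams,
    kappa_min: float = 0.3,
    k_min: int = 2,
    k_max: int | None = None,
    train_frac: float = 0.8,
    seed: int = 0,
    eval_fn: Callable[[int, GroupAssignment], dict] | None = None,
) -> SelectionTrace:
    """Scan cluster counts upward and stop at the first kappa drop.

    The dendrogram is built once on the full presence matrix; at each k the
    cut labels feed a record-level dataset, a forest is trained on the
    training fraction, and OOB kappa is recorded.  The selected count is
    the last k before kappa fell below ``kappa_min``; if the very first k
    already falls below, no count is selectable ("none").

    ``eval_fn(k, assignment) -> {"accuracy", "kappa"}`` may replace the
    model-fitting step (used for stubbed tests and custom model tracks).
    """
    dend = ward_linkage(jaccard_distances(pm))
    if k_max is None:
        k_max = min(pm.n_species, 20)
    split_ss, forest_ss = np.random.SeedSequence(seed).spawn(2)
    split_seed = int(split_ss.generate_state(1)[0] % (2**31))
    forest_seed = int(forest_ss.generate_state(1)[0] % (2**31))

    def default_eval(k: int, ga: GroupAssignment) -> dict:
        ds = assemble_model_dataset(pm, sites_complete, ga.mapping)
        train, _ = train_holdout_split(ds, train_frac=train_frac, seed=split_seed)
        p = ForestParams(
            ntree=params.ntree, mtry=params.mtry, nodesize=params.nodesize,
            seed=forest_seed, criterion=params.criterion, replace=params.replace,
        )
        forest = train_forest(train, p)
        return evaluate_forest_oob(forest, train)

    eval_fn = eval_fn or default_eval
    trace = SelectionTrace()
    last_ok: int | None = None
    for k in range(k_min, k_max + 1):
        ga = cut_dendrogram(dend, k)
        metrics = eval_fn(k, ga)
        kap = metrics["kappa"]
        trace.entries.append(
            {"k": k, "oob_accuracy": metrics.get("accuracy"), "oob_kappa": kap,
             "band": kappa_band(kap)}
        )
        if kap < kappa_min:
            if last_ok is None:
                trace.selected_k = None
                trace.reason = f"kappa below {kappa_min} already at k={k}"
            else:
                trace.selected_k = last_ok
                trace.reason = f"kappa dropped below {kappa_min} at k={k}"
            return trace
        last_ok = k
    trace.selected_k = last_ok
    trace.reason = f"kappa never dropped below {kappa_min} up to k_max={k_max}"
    return trace


def holdout_check(oob_metrics: dict, holdout_metrics: dict, tol: float = 0.05) -> tuple[bool, dict]:
    """Compare OOB and holdout accuracy; pass when they agree within ``tol``."""
    deltas = {
        key: abs(oob_metrics[key] - holdout_metrics[key])
        for key in ("accuracy", "kappa")
        if key in oob_metrics and key in holdout_metrics
    }
    return deltas.get("accuracy", np.inf) <= tol, deltas


def kfold_cv(
    ds: ModelDataset,
    params: ForestParams,
    n_folds: int = 10,
    seed: int = 0,
) -> dict:
    """Group-stratified k-fold cross-validation.

    Within each group, records are shuffled and dealt round-robin over the
    folds (fold sizes differ by at most one per stratum).  Each fold is
    scored by a forest trained on the remainder.
    """
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    groups = np.unique(ds.y)
    for g in groups:
        if (ds.y == g).sum() < n_folds:
            raise ValidationError(
                f"group {g} has fewer than {n_folds} records; use fewer folds"
            )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fold_of = np.zeros(ds.n_records, dtype=int)
    for g in groups:
        rows = np.nonzero(ds.y == g)[0]
        rows = rng.permutation(rows)
        fold_of[rows] = np.arange(len(rows)) % n_folds
    fold_metrics: list[dict] = []
    for f in range(n_folds):
        test = fold_of == f
        train = ds.subset(np.nonzero(~test)[0])
        held = ds.subset(np.nonzero(test)[0])
        p = ForestParams(
            ntree=params.ntree, mtry=params.mtry, nodesize=params.nodesize,
            seed=params.seed + f, criterion=params.criterion, replace=params.replace,
        )
        forest = train_forest(train, p)
        pred = forest.predict(held.X)
        fold_metrics.append(evaluate_predictions(held.y, pred, labels=forest.classes))
    acc = np.array([m["accuracy"] for m in fold_metrics])
    kap = np.array([m["kappa"] for m in fold_metrics])
    return {
        "folds": fold_metrics,
        "fold_of": fold_of,
        "accuracy_mean": float(acc.mean()),
        "accuracy_sd": float(acc.std(ddof=1)),
        "kappa_mean": float(kap.mean()),
        "kappa_sd": float(kap.std(ddof=1)),
    }
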