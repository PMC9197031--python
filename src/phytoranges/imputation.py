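"""Missing-value handling for the site table.

Two single-imputation strategies are provided and meant to be compared as
parallel model tracks:

* :func:`impute_median_mode` — column median (continuous) / most frequent
  category (substrate);
* :func:`impute_iterative_forest` — an iterative forest imputer in the
  missForest mould: initialise with median/mode, cycle through variables in
  order of increasing missingness, regress each on all others with a small
  forest (regression trees with mean leaves for continuous variables;
  classification trees with class-undersampled bags for the categorical
  one) and refresh its missing cells, stopping when the change statistic
  first increases and returning the previous state.

Observed cells are never altered; continuous predictions are floored at
zero (flagged in the report) so physical non-negativity is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (
    CONTINUOUS_VARIABLES,
    PREDICTOR_COLUMNS,
    SUBSTRATE_CATEGORIES,
    PredictorSchema,
    SiteTable,
    ValidationError,
)
from .forest import ForestParams, Tree, grow_tree, undersample_bag

__all__ = ["ImputationReport", "impute_median_mode", "impute_iterative_forest"]


@dataclass
class ImputationReport:
    method: str
    imputed_counts: dict[str, int]
    iterations: int = 0
    convergence_trace: list[dict[str, float]] = field(default_factory=list)
    floored_cells: int = 0

    def total_imputed(self) -> int:
        return sum(self.imputed_counts.values())

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "imputed_counts": self.imputed_counts,
            "iterations": self.iterations,
            "convergence_trace": self.convergence_trace,
            "floored_cells": self.floored_cells,
        }


def _check_observed(sites: SiteTable) -> None:
    for col in PREDICTOR_COLUMNS:
        if sites.data[col].isna().all():
            raise ValidationError(f"column {col!r} is fully missing; cannot impute")


def impute_median_mode(sites: SiteTable) -> tuple[SiteTable, ImputationReport]:
    """Substitute column medians (continuous) and the modal category."""
    _check_observed(sites)
    df = sites.data.copy()
    counts: dict[str, int] = {}
    for var in CONTINUOUS_VARIABLES:
        miss = df[var].isna()
        counts[var] = int(miss.sum())
        if counts[var]:
            df.loc[miss, var] = float(df[var].median())
    miss = df["substrate"].isna()
    counts["substrate"] = int(miss.sum())
    if counts["substrate"]:
        mode = df["substrate"].dropna().mode().iloc[0]
        df.loc[miss, "substrate"] = mode
    return SiteTable(df), ImputationReport("median_mode", counts)


# ---------------------------------------------------------------------------
# Iterative forest imputation
# ---------------------------------------------------------------------------


def _encode(df: pd.DataFrame) -> np.ndarray:
    """Site table -> float matrix; substrate as level codes."""
    X = df[list(CONTINUOUS_VARIABLES)].to_numpy(dtype=float)
    lookup = {c: i for i, c in enumerate(SUBSTRATE_CATEGORIES)}
    codes = np.array(
        [lookup[v] if v is not None else np.nan for v in df["substrate"]],
        dtype=float,
    )
    return np.column_stack([X, codes])


def _fit_predict_forest(
    X: np.ndarray,
    y: np.ndarray,
    X_missing: np.ndarray,
    schema: PredictorSchema,
    task: str,
    ntree: int,
    rng_seed: int,
    nodesize: int,
    mtry: int,
) -> np.ndarray:
    """Train a small internal forest of ``ntree`` trees and predict the
    missing rows.  Classification responses use class-undersampled bags."""
    params = ForestParams(ntree=ntree, mtry=mtry, nodesize=nodesize, seed=rng_seed)
    n = len(y)
    if task == "classification":
        classes = np.unique(y.astype(int))
        k = len(classes)
        index = {c: i for i, c in enumerate(classes)}
        y0 = np.array([index[v] for v in y.astype(int)])
    else:
        k = 1
        y0 = y.astype(float)
    acc = np.zeros((len(X_missing), k)) if task == "classification" else np.zeros(len(X_missing))
    seeds = np.random.SeedSequence(rng_seed).spawn(ntree)
    for ss in seeds:
        rng = np.random.default_rng(ss)
        if task == "classification" and k >= 2:
            bag = undersample_bag(y.astype(int), rng, replace=True)
        else:
            bag = rng.integers(0, n, size=n)
        tree: Tree = grow_tree(X, y0, bag, schema, params, rng, k, task=task)
        acc += tree.predict(X_missing)
    acc /= ntree
    if task == "classification":
        return classes[np.argmax(acc, axis=1)]
    return acc


def impute_iterative_forest(
    sites: SiteTable,
    ntree: int = 200,
    max_iter: int = 10,
    seed: int = 0,
    nodesize: int = 5,
) -> tuple[SiteTable, ImputationReport]:
    """Iterative forest imputation of the site table.

    Variables are refreshed in increasing-missingness order.  After each
    sweep the change statistics are compared with the previous sweep's —
    normalised squared change over continuous cells, disagreement fraction
    over categorical cells — and the loop stops (returning the previous
    state) as soon as either increases, or after ``max_iter`` sweeps.
    """
    _check_observed(sites)
    if len(PREDICTOR_COLUMNS) < 2:
        raise ValidationError("need at least 2 variables")
    df = sites.data.copy()
    miss_mask = {c: df[c].isna().to_numpy() for c in PREDICTOR_COLUMNS}
    counts = {c: int(m.sum()) for c, m in miss_mask.items()}
    if sum(counts.values()) == 0:
        return SiteTable(df), ImputationReport("iterative_forest", counts, iterations=0)

    # initialise
    current, _ = impute_median_mode(sites)
    cur = current.data

    order = sorted(
        [c for c in PREDICTOR_COLUMNS if counts[c] > 0], key=lambda c: counts[c]
    )
    p = len(PREDICTOR_COLUMNS) - 1
    mtry = int(np.ceil(p / 3))
    floored = 0
    trace: list[dict[str, float]] = []
    prev_cont, prev_cat = np.inf, np.inf
    best = cur.copy()
    seeds = np.random.SeedSequence(seed).spawn(max_iter)

    for it in range(max_iter):
        old = cur.copy()
        var_seeds = seeds[it].spawn(len(order))
        for var, vseed in zip(order, var_seeds):
            others = [c for c in PREDICTOR_COLUMNS if c != var]
            schema = PredictorSchema(
                names=tuple(others),
                kinds=tuple("categorical" if c == "substrate" else "continuous" for c in others),
                n_levels=tuple(len(SUBSTRATE_CATEGORIES) if c == "substrate" else 0 for c in others),
            )
            enc = _encode(cur)
            col_idx = [list(PREDICTOR_COLUMNS).index(c) for c in others]
            Xo = enc[:, col_idx]
            obs = ~miss_mask[var]
            if var == "substrate":
                y = np.array(
                    [SUBSTRATE_CATEGORIES.index(v) for v in cur.loc[obs, "substrate"]],
                    dtype=int,
                )
                task = "classification"
            else:
                y = cur.loc[obs, var].to_numpy(dtype=float)
                task = "regression"
            pred = _fit_predict_forest(
                Xo[obs], y, Xo[miss_mask[var]], schema, task,
                ntree=ntree, rng_seed=int(vseed.generate_state(1)[0] % (2**31)),
                nodesize=nodesize, mtry=mtry,
            )
            if var == "substrate":
                cur.loc[miss_mask[var], "substrate"] = [
                    SUBSTRATE_CATEGORIES[int(c)] for c in pred
                ]
            else:
                flo = pred < 0
                floored += int(flo.sum())
                cur.loc[miss_mask[var], var] = np.maximum(pred, 0.0)

        # change statistics over the imputed cells
        cont_num, cont_den = 0.0, 0.0
        for var in CONTINUOUS_VARIABLES:
            if counts[var] == 0:
                continue
            newv = cur.loc[miss_mask[var], var].to_numpy(dtype=float)
            oldv = old.loc[miss_mask[var], var].to_numpy(dtype=float)
            cont_num += float(((newv - oldv) ** 2).sum())
            cont_den += float((newv**2).sum())
        d_cont = cont_num / cont_den if cont_den > 0 else 0.0
        if counts["substrate"]:
            new_s = cur.loc[miss_mask["substrate"], "substrate"].to_numpy()
            old_s = old.loc[miss_mask["substrate"], "substrate"].to_numpy()
            d_cat = float((new_s != old_s).mean())
        else:
            d_cat = 0.0
        trace.append({"continuous": d_cont, "categorical": d_cat})
        if d_cont > prev_cont or d_cat > prev_cat:
            cur = old  # criterion increased: keep the previous sweep's state
            break
        best = cur.copy()
        prev_cont, prev_cat = d_cont, d_cat
    else:
        it += 1  # ran to max_iter without increase

    report = ImputationReport(
        "iterative_forest",
        counts,
        iterations=len(trace),
        convergence_trace=trace,
        floored_cells=floored,
    )
    return SiteTable(best), report
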