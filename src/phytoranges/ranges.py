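"""Discriminative ranges and partial dependence.

With one random candidate predictor per node, each predictor heads roughly
ntree / p of a forest's trees.  The thresholds those root nodes place on a
continuous variable concentrate where splitting best separates the species
groups; their spread — (min, mean, max) across trees — is the variable's
*discriminative range*.  Partial-dependence curves of the per-group voting
fractions show where along each gradient the model's predictions shift,
and the categorical substrate is summarised by the group most likely
predicted for each category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ModelDataset, SUBSTRATE_CATEGORIES, ValidationError
from .forest import Forest

__all__ = [
    "RootSplitTally",
    "SplitRangeSummary",
    "PDPCurve",
    "root_split_points",
    "discriminative_ranges",
    "partial_dependence",
    "substrate_top_group",
    "range_overlay_report",
    "plot_range_overlays",
]


@dataclass
class RootSplitTally:
    """Root-node inventory of a forest.

    ``thresholds[var]`` lists the root thresholds of trees rooting on that
    continuous variable; ``root_counts`` counts roots per predictor (all
    kinds) and ``leaf_roots`` counts trees that never split.
    """

    thresholds: dict[str, np.ndarray]
    root_counts: dict[str, int]
    leaf_roots: int
    ntree: int


def root_split_points(forest: Forest) -> RootSplitTally:
    """Inspect only the root of every tree and tally its split."""
    names = forest.schema.names
    kinds = forest.schema.kinds
    thresholds: dict[str, list[float]] = {
        n: [] for n, k in zip(names, kinds) if k == "continuous"
    }
    root_counts = {n: 0 for n in names}
    leaf_roots = 0
    for tree in forest.trees:
        root = tree.root_split()
        if root is None:
            leaf_roots += 1
            continue
        feat, thr, mask = root
        root_counts[names[feat]] += 1
        if kinds[feat] == "continuous":
            thresholds[names[feat]].append(thr)
    return RootSplitTally(
        thresholds={v: np.array(t) for v, t in thresholds.items()},
        root_counts=root_counts,
        leaf_roots=leaf_roots,
        ntree=forest.ntree,
    )


@dataclass
class SplitRangeSummary:
    """Per continuous variable: (count, min, mean, max) of root thresholds."""

    table: pd.DataFrame  # index: variable; columns count, min, mean, max
    thresholds: dict[str, np.ndarray]
    leaf_roots: int
    ntree: int

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def discriminative_ranges(forest: Forest) -> SplitRangeSummary:
    """Summarise root split-points into discriminative ranges.

    Variables that never head a root get count 0 and NaN range entries.
    """
    tally = root_split_points(forest)
    rows = {}
    for var, thr in tally.thresholds.items():
        if thr.size:
            rows[var] = (len(thr), float(thr.min()), float(thr.mean()), float(thr.max()))
        else:
            rows[var] = (0, np.nan, np.nan, np.nan)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["count", "min", "mean", "max"]
    )
    table.index.name = "variable"
    table["count"] = table["count"].astype(int)
    return SplitRangeSummary(table, tally.thresholds, tally.leaf_roots, tally.ntree)


# ---------------------------------------------------------------------------
# Partial dependence
# ---------------------------------------------------------------------------


@dataclass
class PDPCurve:
    """Mean voting fraction per group along a grid of one variable."""

    variable: str
    grid: np.ndarray
    fractions: np.ndarray  # (len(grid), k)
    group_labels: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.grid) > 0):
            raise ValidationError("PDP grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fractions, columns=[f"group{g}" for g in self.group_labels])
        df.insert(0, "grid", self.grid)
        return df


def default_grid(x: np.ndarray, n_grid: int = 25) -> np.ndarray:
    """Quantile-spaced grid between the 1st and 99th percentile."""
    qs = np.linspace(0.01, 0.99, n_grid)
    return np.unique(np.quantile(x, qs))


def partial_dependence(
    forest: Forest,
    ds: ModelDataset,
    variable: str,
    grid: np.ndarray | None = None,
    n_grid: int = 25,
) -> PDPCurve:
    """Substitute each grid value into every record and average the votes."""
    names = list(forest.schema.names)
    if variable not in names:
        raise ValidationError(f"unknown variable {variable!r}")
    j = names.index(variable)
    if forest.schema.kinds[j] != "continuous":
        raise ValidationError("partial dependence is defined for continuous variables")
    if grid is None:
        grid = default_grid(ds.X[:, j], n_grid)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("empty PDP grid")
    fractions = np.zeros((len(grid), forest.n_classes))
    for gi, g in enumerate(grid):
        Xg = ds.X.copy()
        Xg[:, j] = g
        fractions[gi] = forest.predict_votes(Xg).mean(axis=0)
    return PDPCurve(variable, grid, fractions, forest.classes)


def substrate_top_group(forest: Forest, ds: ModelDataset) -> pd.DataFrame:
    """Most likely predicted group per substrate category.

    Each category is substituted into every record; the argmax of the
    averaged votes is reported (ties resolve to the lowest group label and
    are flagged).
    """
    names = list(forest.schema.names)
    if "substrate" not in names:
        raise ValidationError("substrate is not a predictor of this forest")
    j = names.index("substrate")
    rows = []
    for code, cat in enumerate(SUBSTRATE_CATEGORIES):
        Xg = ds.X.copy()
        Xg[:, j] = float(code)
        votes = forest.predict_votes(Xg).mean(axis=0)
        best = int(np.argmax(votes))
        tie = bool(np.sum(np.isclose(votes, votes[best])) > 1)
        rows.append(
            {
                "category": cat,
                "top_group": int(forest.classes[best]),
                "vote_fraction": float(votes[best]),
                "tie": tie,
            }
        )
    return pd.DataFrame(rows)


def range_overlay_report(
    ranges: SplitRangeSummary, pdps: dict[str, PDPCurve]
) -> dict[str, dict]:
    """Combine PDP curves with their discriminative-range overlays.

    One entry per continuous predictor: the curve plus the (min, mean, max)
    overlay, or a "no root splits" marker where the variable never rooted.
    """
    range_vars = set(ranges.table.index)
    pdp_vars = set(pdps)
    if range_vars != pdp_vars:
        raise ValidationError(
            f"variable mismatch between ranges ({sorted(range_vars)}) and PDPs ({sorted(pdp_vars)})"
        )
    report: dict[str, dict] = {}
    for var in sorted(range_vars):
        row = ranges.table.loc[var]
        entry: dict = {"curve": pdps[var].to_frame()}
        if row["count"] == 0:
            entry["overlay"] = None
            entry["note"] = "no root splits"
        else:
            entry["overlay"] = {
                "min": float(row["min"]),
                "mean": float(row["mean"]),
                "max": float(row["max"]),
                "count": int(row["count"]),
            }
        report[var] = entry
    return report


def plot_range_overlays(report: dict[str, dict], log_x: bool = True):
    """Small-multiple PDP curves with dotted min/max and dashed mean lines.

    Returns the matplotlib figure; import is deferred so headless use of
    the numeric API never touches a plotting backend.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = len(report)
    ncol = min(3, n)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for ax, (var, entry) in zip(axes.ravel(), sorted(report.items())):
        curve = entry["curve"]
        for col in curve.columns[1:]:
            ax.plot(curve["grid"], curve[col], label=col)
        if entry["overlay"]:
            ov = entry["overlay"]
            ax.axvline(ov["min"], linestyle=":", color="grey")
            ax.axvline(ov["max"], linestyle=":", color="grey")
            ax.axvline(ov["mean"], linestyle="--", color="grey")
            ax.axvspan(ov["min"], ov["max"], color="grey", alpha=0.15)
        if log_x:
            ax.set_xscale("log")
        ax.set_title(var)
        ax.set_ylabel("voting fraction")
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    axes.ravel()[0].legend(fontsize=8)
    fig.tight_layout()
    return fig
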