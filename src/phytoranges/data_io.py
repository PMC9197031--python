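"""Typed tables and CSV I/O for river macrophyte survey data.

The pipeline works on two inputs: a *site table* holding six continuous
environmental variables plus a seven-level dominant-substrate category per
sampling site (any cell may be missing), and an *occurrence table* of
(site_id, species_id) presence records.  This module defines those tables,
the species x sites presence matrix derived from them, and the flat
modelling dataset (one row per occurrence record) fed to the forest.

Missing cells are encoded as the empty string or ``"NA"`` on disk and as
NaN (continuous) / None (substrate) in memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "SUBSTRATE_CATEGORIES",
    "CONTINUOUS_VARIABLES",
    "PREDICTOR_COLUMNS",
    "VARIABLE_UNITS",
    "SiteTable",
    "OccurrenceTable",
    "PresenceMatrix",
    "PredictorSchema",
    "ModelDataset",
    "read_site_table",
    "write_site_table",
    "read_occurrences",
    "write_occurrences",
    "build_presence_matrix",
    "assemble_model_dataset",
    "write_with_metadata",
]


class ValidationError(ValueError):
    """Raised when an input table violates the schema contracts."""


#: Closed vocabulary of dominant-substrate categories (coarsest fraction named
#: first inside each label; the tuple order is the fixed reporting order).
SUBSTRATE_CATEGORIES: tuple[str, ...] = (
    "Silt, sand and gravel",
    "Sand",
    "Gravel and boulder",
    "Gravel",
    "Silt and sand",
    "Sand and gravel",
    "Rock and gravel",
)

#: Continuous predictors, with units.
VARIABLE_UNITS: dict[str, str] = {
    "alkalinity": "meq CaCO3 L^-1",
    "velocity": "m s^-1",
    "nitrate": "mg L^-1",
    "total_phosphorus": "ug L^-1",
    "width": "m",
    "depth": "m",
}

CONTINUOUS_VARIABLES: tuple[str, ...] = tuple(VARIABLE_UNITS)

#: Variables that must be strictly positive when observed.
_STRICTLY_POSITIVE = frozenset({"width", "depth"})

PREDICTOR_COLUMNS: tuple[str, ...] = CONTINUOUS_VARIABLES + ("substrate",)

_NA_STRINGS = ["", "NA"]


# ---------------------------------------------------------------------------
# Site table
# ---------------------------------------------------------------------------


@dataclass
class SiteTable:
    """Per-site environmental predictors.

    ``data`` is indexed by ``site_id`` (unique strings) and has the six
    continuous columns (float, NaN = missing) plus ``substrate`` (object,
    one of :data:`SUBSTRATE_CATEGORIES` or None).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in PREDICTOR_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"site table missing columns: {missing_cols}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate site_id values: {dups[:5]}")
        for var in CONTINUOUS_VARIABLES:
            col = pd.to_numeric(df[var], errors="raise").astype(float)
            bad = col < 0 if var not in _STRICTLY_POSITIVE else col <= 0
            if bad.fillna(False).any():
                offending = df.index[bad.fillna(False)][0]
                bound = "positive" if var in _STRICTLY_POSITIVE else "non-negative"
                raise ValidationError(
                    f"{var} must be {bound}; site {offending!r} has {col[bad.fillna(False)].iloc[0]}"
                )
            df[var] = col
        sub = df["substrate"]
        legal = set(SUBSTRATE_CATEGORIES)
        observed = sub.dropna()
        unknown = sorted(set(observed) - legal)
        if unknown:
            raise ValidationError(
                f"unknown substrate value(s) {unknown}; legal categories are "
                f"{list(SUBSTRATE_CATEGORIES)}"
            )
        # normalise missing substrate to None for stable equality checks
        df["substrate"] = sub.where(sub.notna(), None)

    # -- convenience ------------------------------------------------------

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_sites(self) -> int:
        return len(self.data)

    def missing_counts(self) -> pd.Series:
        """Number of missing cells per predictor column."""
        return self.data[list(PREDICTOR_COLUMNS)].isna().sum()

    def is_complete(self) -> bool:
        return int(self.missing_counts().sum()) == 0

    def copy(self) -> "SiteTable":
        return SiteTable(self.data.copy())

    def substrate_codes(self) -> np.ndarray:
        """Substrate as integer codes into SUBSTRATE_CATEGORIES; -1 = missing."""
        lookup = {c: i for i, c in enumerate(SUBSTRATE_CATEGORIES)}
        return np.array(
            [lookup[v] if v is not None else -1 for v in self.data["substrate"]],
            dtype=int,
        )


def read_site_table(path: str | Path, substrate_synonyms: Mapping[str, str] | None = None) -> SiteTable:
    """Load ``sites.csv`` (header: site_id,<6 continuous>,substrate).

    Empty cells and ``"NA"`` parse as missing.  ``substrate_synonyms`` may
    remap local labels onto the closed seven-category vocabulary before
    validation.
    """
    df = pd.read_csv(
        path,
        dtype={"site_id": str, "substrate": str},
        na_values=_NA_STRINGS,
        keep_default_na=False,
    )
    if "site_id" not in df.columns:
        raise ValidationError("site table needs a site_id column")
    df = df.set_index("site_id")
    if substrate_synonyms:
        df["substrate"] = df["substrate"].replace(dict(substrate_synonyms))
    return SiteTable(df)


def write_site_table(table: SiteTable, path: str | Path) -> None:
    out = table.data.copy()
    out.index.name = "site_id"
    out.to_csv(path, na_rep="NA")


# ---------------------------------------------------------------------------
# Occurrence table
# ---------------------------------------------------------------------------


@dataclass
class OccurrenceTable:
    """Presence records; columns site_id, species_id and optionally a
    user-supplied boolean ``aquatic`` flag (True = high water-affinity)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        for col in ("site_id", "species_id"):
            if col not in df.columns:
                raise ValidationError(f"occurrence table needs a {col} column")
        dup = df.duplicated(subset=["site_id", "species_id"])
        if dup.any():
            pair = df.loc[dup, ["site_id", "species_id"]].iloc[0]
            raise ValidationError(
                "duplicate occurrence record "
                f"(site {pair['site_id']!r}, species {pair['species_id']!r}); "
                "one sample per site is assumed"
            )
        if "aquatic" in df.columns:
            df["aquatic"] = df["aquatic"].astype(bool)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def species_counts(self) -> pd.Series:
        return self.records["species_id"].value_counts()

    def validate_sites(self, sites: SiteTable) -> None:
        """Every record must reference a known site."""
        known = set(sites.site_ids)
        unknown = sorted(set(self.records["site_id"]) - known)
        if unknown:
            raise ValidationError(f"occurrence records reference unknown site(s): {unknown[:5]}")


def read_occurrences(path: str | Path) -> OccurrenceTable:
    df = pd.read_csv(
        path,
        dtype={"site_id": str, "species_id": str},
        na_values=_NA_STRINGS,
        keep_default_na=False,
    )
    return OccurrenceTable(df)


def write_occurrences(occ: OccurrenceTable, path: str | Path) -> None:
    occ.records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Presence matrix
# ---------------------------------------------------------------------------


@dataclass
class PresenceMatrix:
    """Boolean species x sites matrix after rarity filtering."""

    species_ids: list[str]
    site_ids: list[str]
    cells: np.ndarray  # bool, shape (n_species, n_sites)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)
        if self.cells.shape != (len(self.species_ids), len(self.site_ids)):
            raise ValidationError("presence matrix shape does not match id lists")
        if (self.cells.sum(axis=1) == 0).any():
            raise ValidationError("presence matrix contains an all-zero species row")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_records(self) -> int:
        return int(self.cells.sum())

    def to_occurrences(self) -> OccurrenceTable:
        """Flatten back to records (row-major: species outer, site inner)."""
        sp_idx, site_idx = np.nonzero(self.cells)
        df = pd.DataFrame(
            {
                "site_id": [self.site_ids[j] for j in site_idx],
                "species_id": [self.species_ids[i] for i in sp_idx],
            }
        )
        return OccurrenceTable(df)


def build_presence_matrix(
    occ: OccurrenceTable,
    min_sites: int = 25,
    aquatic_only: bool = False,
) -> PresenceMatrix:
    """Filter rare species and pivot records into a presence matrix.

    Species recorded at fewer than ``min_sites`` sites are removed (the
    boundary is "less than": a species at exactly ``min_sites`` stays).
    With ``aquatic_only`` species flagged non-aquatic are removed first.
    """
    if min_sites < 1:
        raise ValidationError("min_sites must be >= 1")
    df = occ.records
    if aquatic_only:
        if "aquatic" not in df.columns:
            raise ValidationError("aquatic_only requested but no aquatic column present")
        aquatic_species = df.groupby("species_id")["aquatic"].first()
        keep = set(aquatic_species[aquatic_species].index)
        df = df[df["species_id"].isin(keep)]
    counts = df["species_id"].value_counts()
    kept_species = sorted(counts[counts >= min_sites].index)
    if not kept_species:
        raise ValidationError("no species survive filter")
    df = df[df["species_id"].isin(kept_species)]
    site_ids = sorted(df["site_id"].unique())
    site_pos = {s: j for j, s in enumerate(site_ids)}
    sp_pos = {s: i for i, s in enumerate(kept_species)}
    cells = np.zeros((len(kept_species), len(site_ids)), dtype=bool)
    cells[
        [sp_pos[s] for s in df["species_id"]],
        [site_pos[s] for s in df["site_id"]],
    ] = True
    return PresenceMatrix(kept_species, site_ids, cells)


# ---------------------------------------------------------------------------
# Modelling dataset
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictorSchema:
    """Names and kinds of the forest's predictor columns.

    ``kinds[j]`` is ``"continuous"`` or ``"categorical"``; categorical
    columns carry integer level codes stored as floats in the X matrix.
    """

    names: tuple[str, ...]
    kinds: tuple[str, ...]
    n_levels: tuple[int, ...]  # 0 for continuous columns

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.kinds) == len(self.n_levels)):
            raise ValidationError("schema field lengths differ")

    @property
    def n_predictors(self) -> int:
        return len(self.names)

    def continuous_names(self) -> list[str]:
        return [n for n, k in zip(self.names, self.kinds) if k == "continuous"]


def default_schema() -> PredictorSchema:
    """The survey schema: six continuous variables plus substrate."""
    return PredictorSchema(
        names=PREDICTOR_COLUMNS,
        kinds=("continuous",) * 6 + ("categorical",),
        n_levels=(0,) * 6 + (len(SUBSTRATE_CATEGORIES),),
    )


@dataclass
class ModelDataset:
    """One row per occurrence record: the site's predictors and the
    species' group label (the forest target)."""

    X: np.ndarray  # float, shape (n, 7); substrate column holds level codes
    y: np.ndarray  # int labels in 1..k
    species_id: np.ndarray
    site_id: np.ndarray
    schema: PredictorSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if not (len(self.X) == len(self.y) == len(self.species_id) == len(self.site_id)):
            raise ValidationError("model dataset arrays have unequal lengths")
        if np.isnan(self.X).any():
            raise ValidationError("model dataset has missing predictor cells; impute first")
        if len(self.y) and self.y.min() < 1:
            raise ValidationError("labels must be 1-based")

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_classes(self) -> int:
        return int(self.y.max())

    def subset(self, idx: np.ndarray) -> "ModelDataset":
        return ModelDataset(
            self.X[idx], self.y[idx], self.species_id[idx], self.site_id[idx], self.schema
        )


def assemble_model_dataset(
    pm: PresenceMatrix,
    sites: SiteTable,
    labels: Mapping[str, int],
) -> ModelDataset:
    """Join the filtered records with a *complete* site table and group labels.

    ``labels`` maps species_id -> group label in 1..k (a GroupAssignment's
    ``mapping`` attribute is accepted directly).
    """
    labels = getattr(labels, "mapping", labels)
    if not sites.is_complete():
        raise ValidationError("site table has missing cells; impute before assembling")
    site_index = {s: i for i, s in enumerate(sites.site_ids)}
    cont = sites.data[list(CONTINUOUS_VARIABLES)].to_numpy(dtype=float)
    codes = sites.substrate_codes().astype(float)
    sp_idx, site_idx = np.nonzero(pm.cells)
    rows_site = np.array([site_index[pm.site_ids[j]] for j in site_idx])
    X = np.column_stack([cont[rows_site], codes[rows_site]])
    y = np.array([labels[pm.species_ids[i]] for i in sp_idx], dtype=int)
    return ModelDataset(
        X=X,
        y=y,
        species_id=np.array([pm.species_ids[i] for i in sp_idx]),
        site_id=np.array([pm.site_ids[j] for j in site_idx]),
        schema=default_schema(),
    )


def write_with_metadata(df: pd.DataFrame, path: str | Path, metadata: dict, index: bool = False) -> None:
    """Write a CSV plus a ``<name>.meta.json`` sidecar (schema version, settings, seed)."""
    path = Path(path)
    df.to_csv(path, index=index, na_rep="NA")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    payload = {"schema_version": 1, **metadata}
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
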