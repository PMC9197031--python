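"""Shared fixtures: small simulated surveys and trained forests.

Everything is generated at test time from fixed seeds; session scope keeps
the expensive objects (bundles, forests) built once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from phytoranges import (
    ForestParams,
    assemble_model_dataset,
    build_presence_matrix,
    impute_median_mode,
    make_survey_bundle,
    train_forest,
)
from phytoranges.data_io import ModelDataset, default_schema

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

#: Desk-scale survey: 400 sites, 24 species, 4 planted groups.
DESK_SEED = 0
#: Larger survey used where kappa estimates must be stable.
RECOVERY_SEED = 0
RECOVERY_SITES = 1000


@pytest.fixture(scope="session")
def bundle():
    return make_survey_bundle(DESK_SEED)


@pytest.fixture(scope="session")
def recovery_bundle():
    return make_survey_bundle(RECOVERY_SEED, n_sites=RECOVERY_SITES)


@pytest.fixture(scope="session")
def presence(bundle):
    return build_presence_matrix(bundle.occurrences, min_sites=10)


@pytest.fixture(scope="session")
def complete_sites(bundle):
    complete, _ = impute_median_mode(bundle.sites)
    return complete


@pytest.fixture(scope="session")
def dataset(bundle, presence, complete_sites):
    """Records labelled with the planted truth (k = 4)."""
    labels = {s: bundle.truth.group_of[s] for s in presence.species_ids}
    return assemble_model_dataset(presence, complete_sites, labels)


@pytest.fixture(scope="session")
def small_forest(dataset):
    return train_forest(dataset, ForestParams(ntree=60, mtry=1, nodesize=50, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_model_dataset(rng, n=300, n_classes=3, informative=True):
    """Ad-hoc dataset on the survey schema; label driven by TP and substrate
    when informative, pure noise otherwise."""
    X = np.column_stack(
        [rng.lognormal(0.5, 1.0, n) for _ in range(6)] + [rng.integers(0, 7, n).astype(float)]
    )
    if informative:
        y = 1 + (X[:, 3] > np.median(X[:, 3])).astype(int)
        if n_classes > 2:
            y = y + (n_classes - 2) * (X[:, 6] >= 4).astype(int)
    else:
        y = rng.integers(1, n_classes + 1, n)
    # make sure every class occurs
    y[: n_classes] = np.arange(1, n_classes + 1)
    return ModelDataset(X, y, np.array(["sp"] * n), np.array(["site"] * n), default_schema())
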