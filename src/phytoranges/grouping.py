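"""Species co-occurrence clustering.

Species are clustered on their presence/absence profiles across sites with
the Jaccard distance and Ward agglomeration in the ``ward.D`` convention:
the Lance-Williams update with Ward coefficients is applied to the input
dissimilarities *as given* (no squaring).  A ``squared=True`` switch gives
the ward.D2 variant (update on squared distances, heights square-rooted)
for sensitivity analysis; that variant coincides with SciPy's ``ward``.

Note on heights: ward.D on non-squared, non-Euclidean distances can produce
non-monotone merge heights (inversions).  Heights are recorded as computed
and no monotonicity is asserted; cutting is done by undoing merges, which is
well defined regardless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data_io import PresenceMatrix, ValidationError

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "GroupAssignment",
    "jaccard_distances",
    "ward_linkage",
    "cut_dendrogram",
    "scan_cluster_range",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise species distances in [0, 1]."""

    species_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.species_ids)
        if v.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if np.isnan(v).any():
            raise ValidationError("distance matrix contains NaN")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix not symmetric")
        if np.diag(v).any():
            raise ValidationError("distance matrix diagonal must be zero")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValidationError("Jaccard distances must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.species_ids)


@dataclass
class Dendrogram:
    """Agglomeration record in SciPy linkage convention.

    ``merges`` has one row per merge: (left id, right id, height, size).
    Leaves are ids 0..n-1 in ``species_ids`` order; merge i creates id n+i.
    """

    species_ids: list[str]
    merges: np.ndarray  # shape (n-1, 4)

    def __post_init__(self) -> None:
        n = len(self.species_ids)
        m = np.asarray(self.merges, dtype=float)
        if m.shape != (n - 1, 4):
            raise ValidationError("dendrogram must have n-1 merges")
        if (m[:, 2] < -1e-12).any():
            raise ValidationError("merge heights must be non-negative")
        self.merges = m

    @property
    def n_leaves(self) -> int:
        return len(self.species_ids)


@dataclass
class GroupAssignment:
    """Hard species -> group labelling for a given cluster count k."""

    k: int
    mapping: dict[str, int]

    def __post_init__(self) -> None:
        labels = set(self.mapping.values())
        if labels != set(range(1, self.k + 1)):
            raise ValidationError(f"expected labels 1..{self.k}, got {sorted(labels)}")

    def labels_for(self, species_ids: list[str]) -> np.ndarray:
        return np.array([self.mapping[s] for s in species_ids], dtype=int)


def jaccard_distances(pm: PresenceMatrix) -> DistanceMatrix:
    """d(a, b) = 1 - |sites(a) ∩ sites(b)| / |sites(a) ∪ sites(b)|."""
    if pm.n_species < 2:
        raise ValidationError("need at least 2 species to cluster")
    condensed = pdist(pm.cells.astype(bool), metric="jaccard")
    return DistanceMatrix(list(pm.species_ids), squareform(condensed))


def ward_linkage(d: DistanceMatrix, squared: bool = False) -> Dendrogram:
    """Agglomerate with the Ward Lance-Williams update.

    ``squared=False`` (default) is ward.D: the update runs on the distances
    as given.  ``squared=True`` is ward.D2: the update runs on squared
    distances and recorded heights are square roots.

    Ties in the minimal pairwise distance are broken by the smallest
    (left id, right id) pair, ids being creation order (leaves first).
    """
    n = d.n
    work = d.values.astype(float).copy()
    if squared:
        work = work**2
    size = 2 * n - 1
    big = np.full((size, size), np.inf)
    big[:n, :n] = work
    np.fill_diagonal(big, np.inf)
    sizes = np.zeros(size)
    sizes[:n] = 1
    active: list[int] = list(range(n))
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        ids = np.array(active)
        sub = big[np.ix_(ids, ids)]
        iu = np.triu_indices(len(ids), k=1)
        flat = sub[iu]
        best = int(np.argmin(flat))  # row-major first occurrence = smallest (i, j)
        i, j = int(ids[iu[0][best]]), int(ids[iu[1][best]])
        dij = big[i, j]
        new = n + step
        ni, nj = sizes[i], sizes[j]
        for k_id in active:
            if k_id in (i, j):
                continue
            nk = sizes[k_id]
            dnew = ((ni + nk) * big[i, k_id] + (nj + nk) * big[j, k_id] - nk * dij) / (
                ni + nj + nk
            )
            big[new, k_id] = big[k_id, new] = dnew
        sizes[new] = ni + nj
        active.remove(i)
        active.remove(j)
        active.append(new)
        height = np.sqrt(max(dij, 0.0)) if squared else dij
        merges[step] = (i, j, height, ni + nj)
    return Dendrogram(list(d.species_ids), merges)


def _leaf_sets(dend: Dendrogram) -> Iterator[tuple[int, list[int]]]:
    """Yield (cluster id, member leaves) for every internal node."""
    n = dend.n_leaves
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step, (a, b, _, _) in enumerate(dend.merges):
        members[n + step] = members[int(a)] + members[int(b)]
        yield n + step, members[n + step]


def cut_dendrogram(dend: Dendrogram, k: int) -> GroupAssignment:
    """Undo the last k-1 merges and label the remaining clusters.

    Labels 1..k are assigned by each cluster's first leaf in species order,
    so labelling is deterministic and stable under refinement.
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in 1..{n}, got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b, _, _ = dend.merges[step]
        new = n + step
        parent[find(int(a))] = new
        parent[find(int(b))] = new
    roots: dict[int, list[int]] = {}
    for leaf in range(n):
        roots.setdefault(find(leaf), []).append(leaf)
    clusters = sorted(roots.values(), key=lambda leaves: leaves[0])
    mapping: dict[str, int] = {}
    for label, leaves in enumerate(clusters, start=1):
        for leaf in leaves:
            mapping[dend.species_ids[leaf]] = label
    return GroupAssignment(k=k, mapping=mapping)


def scan_cluster_range(
    dend: Dendrogram, k_min: int = 2, k_max: int | None = None
) -> list[GroupAssignment]:
    """Cut at every k in [k_min, k_max]; assignments are nested by construction."""
    if k_min < 2:
        raise ValidationError("k_min must be >= 2")
    if k_max is None:
        k_max = dend.n_leaves
    return [cut_dendrogram(dend, k) for k in range(k_min, k_max + 1)]
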