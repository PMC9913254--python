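"""Per-patient complete-linkage dendrograms and tree-derived descriptors.

Each patient is represented by the agglomerative complete-linkage tree of the
Euclidean distances between their lesions' depth profiles. From the tree we
derive heterogeneity descriptors: number of lesions, total branch length,
dispersion of the profiles, and the number of distinct phenotypes obtained by
cutting the tree at the partition that optimises a cluster-validity index
(silhouette, Calinski-Harabasz or Davies-Bouldin).

Node encoding follows the scipy convention: leaves are ``0..n-1``; the m-th
merge (0-based) creates internal node ``n + m``. Ties in the linkage distance
are broken by the lexicographically smallest pair of minimal leaf indices, so
the tree is invariant to leaf input order up to that documented rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

logger = logging.getLogger("lesionforest")

ValidityIndex = Literal["silhouette", "ch", "db"]

#: Largest number of clusters evaluated when counting phenotypes.
MAX_PHENOTYPE_K = 8
#: Final merge height below which a tree is considered degenerate (all
#: profiles numerically identical).
DEGENERACY_HEIGHT = 1e-8


@dataclass
class PatientDendrogram:
    """Complete-linkage merge structure over one patient's lesions."""

    patient_id: str
    leaf_ids: list[str]
    merges: list[tuple[int, int, float]]  # (left node, right node, height)
    distance_matrix: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def node_height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else self.merges[node - n][2]

    def cut(self, k: int) -> np.ndarray:
        """Partition the leaves into exactly ``k`` clusters (height cut).

        Complete linkage is monotone, so stopping after ``n - k`` merges is
        the standard cut of the displayed tree. Returns 0-based labels,
        renumbered by first leaf occurrence.
        """
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"cannot cut {n}-leaf tree into {k} clusters")
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for m, (a, b, _h) in enumerate(self.merges[: n - k]):
            node = n + m
            members[node] = members.pop(a) + members.pop(b)
        labels = np.empty(n, dtype=int)
        clusters = sorted(members.values(), key=min)
        for c, leaves in enumerate(clusters):
            labels[leaves] = c
        return labels

    def to_newick(self) -> str:
        """Newick string with branch lengths (leaf names = lesion ids)."""
        n = self.n_leaves

        def render(node: int, parent_height: float) -> str:
            length = parent_height - self.node_height(node)
            if node < n:
                return f"{self.leaf_ids[node]}:{length:.10g}"
            a, b, h = self.merges[node - n]
            return f"({render(a, h)},{render(b, h)}):{length:.10g}"

        root = n + len(self.merges) - 1
        a, b, h = self.merges[-1]
        return f"({render(a, h)},{render(b, h)});"


@dataclass
class TreeDescriptors:
    """Heterogeneity descriptors derived from one patient's tree."""

    patient_id: str
    n_lesions: int
    sum_branch_lengths: float
    merge_height_total: float
    dispersion: float
    mean_pairwise_distance: float
    n_phenotypes_silhouette: int
    n_phenotypes_ch: int
    n_phenotypes_db: int


def pairwise_distance_matrix(profiles: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Symmetric zero-diagonal matrix of Euclidean distances between profiles."""
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2:
        raise ValueError("profiles must be a 2-D array (lesions x views)")
    D = cdist(X, X)
    np.fill_diagonal(D, 0.0)
    return D


def complete_linkage_tree(
    distance_matrix: np.ndarray, leaf_ids: Sequence[str], patient_id: str = ""
) -> PatientDendrogram:
    """Agglomerative complete-linkage clustering of one patient's lesions.

    At each step the two clusters with minimal maximum inter-cluster distance
    merge; equal linkage distances are resolved by the lexicographically
    smallest sorted pair of minimal leaf indices. Merge heights are
    non-decreasing (complete linkage is monotone).
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n < 2:
        raise ValueError("distance matrix must be square with n >= 2")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if len(leaf_ids) != n:
        raise ValueError("leaf_ids length does not match distance matrix")

    # active clusters: node id -> (min leaf index, member leaves)
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    link = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int, float]] = []

    def pair_key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    for m in range(n - 1):
        best = None
        for (a, b), dist in link.items():
            tie_key = tuple(sorted((min(active[a]), min(active[b]))))
            cand = (dist, tie_key, (a, b))
            if best is None or cand < best:
                best = cand
        dist, _tie, (a, b) = best
        node = n + m
        merges.append((a, b, dist))
        members = active.pop(a) + active.pop(b)
        for c in list(active):
            d_new = max(link.pop(pair_key(a, c)), link.pop(pair_key(b, c)))
            link[pair_key(node, c)] = d_new
        link.pop(pair_key(a, b))
        active[node] = members
    return PatientDendrogram(patient_id, list(leaf_ids), merges, D)


def sum_branch_lengths(dendrogram: PatientDendrogram) -> float:
    """Total edge length of the drawn tree, with leaves at height 0.

    Each merge at height ``h`` contributes ``(h - h_left) + (h - h_right)``
    for its two child edges. Zero iff all profiles are identical. The
    alternative reading (sum of merge heights) is exposed as
    :func:`merge_height_total`.
    """
    total = 0.0
    for node, (a, b, h) in enumerate(dendrogram.merges):
        total += (h - dendrogram.node_height(a)) + (h - dendrogram.node_height(b))
    return total


def merge_height_total(dendrogram: PatientDendrogram) -> float:
    """Sum of the merge heights (alternative branch-length total)."""
    return float(dendrogram.heights.sum())


def dispersion(profiles: np.ndarray | pd.DataFrame) -> float:
    """Root-mean-square Euclidean distance of the profiles to their centroid.

    Rotation invariant and O(n); equals ``d/2`` for two profiles at distance
    ``d`` and 0 iff all profiles are identical.
    """
    X = np.asarray(profiles, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("dispersion needs at least two profiles")
    centroid = X.mean(axis=0)
    return float(np.sqrt(((X - centroid) ** 2).sum(axis=1).mean()))


def mean_pairwise_distance(profiles: np.ndarray | pd.DataFrame) -> float:
    D = pairwise_distance_matrix(profiles)
    n = D.shape[0]
    return float(D[np.triu_indices(n, 1)].mean())


def _check_labels(labels: np.ndarray, n: int) -> None:
    g = len(np.unique(labels))
    if not 2 <= g <= n - 1:
        raise ValueError(f"validity indices need 2 <= clusters <= n-1, got {g} of {n}")


def silhouette_index(distance_matrix: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width on a precomputed distance matrix.

    Singleton clusters receive silhouette 0 (standard convention).
    """
    D = np.asarray(distance_matrix, dtype=float)
    _check_labels(np.asarray(labels), D.shape[0])
    return float(silhouette_score(D, labels, metric="precomputed"))


def davies_bouldin_index(profiles: np.ndarray, labels: np.ndarray) -> float:
    X = np.asarray(profiles, dtype=float)
    _check_labels(np.asarray(labels), X.shape[0])
    return float(davies_bouldin_score(X, labels))


def calinski_harabasz_index(profiles: np.ndarray, labels: np.ndarray) -> float:
    X = np.asarray(profiles, dtype=float)
    _check_labels(np.asarray(labels), X.shape[0])
    return float(calinski_harabasz_score(X, labels))


def count_phenotypes(
    dendrogram: PatientDendrogram,
    profiles: np.ndarray,
    index: ValidityIndex = "silhouette",
    k_max: int = MAX_PHENOTYPE_K,
    two_lesion_threshold: float = 0.0,
) -> int:
    """Number of distinct phenotypes among one patient's lesions.

    For each ``k`` in ``2..min(n-1, k_max)`` the tree is cut into ``k``
    clusters and the partition scored; the best ``k`` is returned (maximum
    for silhouette/Calinski-Harabasz, minimum for Davies-Bouldin). Validity
    indices are undefined for two lesions, so ``n = 2`` returns 2 when the
    single merge height exceeds ``two_lesion_threshold`` (typically the
    cohort median of first merge heights) and 1 otherwise. A tree whose final
    height is numerically zero counts as a single phenotype; near-degenerate
    trees are flagged with a warning but still scored.
    """
    n = dendrogram.n_leaves
    if n < 2:
        raise ValueError("count_phenotypes needs at least two lesions")
    final_height = dendrogram.merges[-1][2]
    if n == 2:
        return 2 if final_height > two_lesion_threshold else 1
    if final_height <= 0.0:
        return 1
    if final_height < DEGENERACY_HEIGHT:
        warnings.warn(
            f"patient {dendrogram.patient_id!r}: tree is near-degenerate "
            f"(final height {final_height:.3g}); phenotype count unreliable",
            stacklevel=2,
        )
    X = np.asarray(profiles, dtype=float)
    best_k, best_score = None, None
    for k in range(2, min(n - 1, k_max) + 1):
        labels = dendrogram.cut(k)
        if len(np.unique(labels)) != k:
            continue
        if index == "silhouette":
            score = silhouette_index(dendrogram.distance_matrix, labels)
        elif index == "ch":
            score = calinski_harabasz_index(X, labels)
        elif index == "db":
            score = -davies_bouldin_index(X, labels)
        else:
            raise ValueError(f"unknown validity index {index!r}")
        if best_score is None or score > best_score:
            best_k, best_score = k, score
    return int(best_k)


def build_patient_trees(frame: pd.DataFrame) -> dict[str, PatientDendrogram]:
    """Build one complete-linkage tree per patient from a profile frame.

    The frame is indexed by (patient_id, lesion_id) as produced by
    :func:`lesionforest.depth_transform.profiles_frame`.
    """
    trees = {}
    for pid, sub in frame.groupby(level="patient_id", sort=True):
        if len(sub) < 2:
            raise ValueError(f"patient {pid!r} has fewer than two lesions")
        D = pairwise_distance_matrix(sub.to_numpy())
        trees[pid] = complete_linkage_tree(
            D, [ix[1] for ix in sub.index], patient_id=pid
        )
    return trees


def tree_descriptor_table(
    frame: pd.DataFrame,
    k_max: int = MAX_PHENOTYPE_K,
    two_lesion_threshold: float | None = None,
) -> pd.DataFrame:
    """One row of tree descriptors per patient; deterministic.

    When ``two_lesion_threshold`` is None it is set to the cohort median of
    every patient's first merge height, the scale below which a two-lesion
    pair is considered a single phenotype.
    """
    trees = build_patient_trees(frame)
    if two_lesion_threshold is None:
        first = np.array([t.merges[0][2] for t in trees.values()])
        two_lesion_threshold = float(np.median(first))
    rows = []
    for pid, tree in trees.items():
        X = frame.xs(pid, level="patient_id").to_numpy(dtype=float)
        counts = {
            idx: count_phenotypes(
                tree, X, index=idx, k_max=k_max, two_lesion_threshold=two_lesion_threshold
            )
            for idx in ("silhouette", "ch", "db")
        }
        rows.append(
            TreeDescriptors(
                patient_id=pid,
                n_lesions=tree.n_leaves,
                sum_branch_lengths=sum_branch_lengths(tree),
                merge_height_total=merge_height_total(tree),
                dispersion=dispersion(X),
                mean_pairwise_distance=mean_pairwise_distance(X),
                n_phenotypes_silhouette=counts["silhouette"],
                n_phenotypes_ch=counts["ch"],
                n_phenotypes_db=counts["db"],
            )
        )
    out = pd.DataFrame([vars(r) for r in rows]).set_index("patient_id")
    out.attrs["two_lesion_threshold"] = two_lesion_threshold
    return out
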