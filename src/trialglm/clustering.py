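"""Clustering neurons by their relative-contribution profiles.

Each neuron with at least one selected task variable is summarised by its
relative-contribution vector over the 8 candidate variables.  Pairwise
dissimilarity is one minus the sample correlation between profiles;
agglomerative clustering uses unweighted average linkage (UPGMA), and flat
clusters come from cutting the tree at a height threshold, discarding
clusters with fewer than 3 neurons.

The cut threshold is chosen by cross-validating cluster generalisability:
trials are split in half, profiles refit on each half, both halves are
clustered at the candidate threshold, and the co-membership (partition)
matrix predicted from one half's cluster centroids is correlated with the
other half's own partition matrix (upper triangles, both directions
averaged).  A 2-D non-metric MDS embedding (Kruskal stress-1) of the
profiles supports visual inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import average as upgma_linkage
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import squareform
from sklearn.manifold import MDS

__all__ = [
    "contribution_distance_matrix",
    "upgma_tree",
    "cut_clusters",
    "partition_matrix",
    "partition_score",
    "generalisability",
    "crossval_cut_threshold",
    "mds_projection",
    "DEFAULT_THRESHOLD_GRID",
]

#: 21 cut heights spanning 0.5 .. 3.0
DEFAULT_THRESHOLD_GRID = np.linspace(0.5, 3.0, 21)


def contribution_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    """Pairwise dissimilarity ``1 - r_ij`` between profiles (rows).

    Entries lie in [0, 2] with a zero diagonal.  A zero-variance profile has
    no defined correlation with anything; that neuron is reported by index.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 2 or profiles.shape[1] < 2:
        raise ValueError("need at least 2 profiles with at least 2 variables")
    sd = profiles.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"zero-variance profile(s) at neuron index {flat.tolist()}"
        )
    corr = np.corrcoef(profiles)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def upgma_tree(distances: np.ndarray) -> np.ndarray:
    """Unweighted-average-linkage merge tree from a square dissimilarity
    matrix (scipy linkage format; merge heights are non-decreasing)."""
    distances = np.asarray(distances, dtype=float)
    return upgma_linkage(squareform(distances, checks=False))


def cut_clusters(
    tree: np.ndarray, thresh_cut: float, min_size: int = 3
) -> tuple[np.ndarray, list]:
    """Flat clusters from cutting the tree below ``thresh_cut``.

    Clusters smaller than ``min_size`` are discarded: their members get
    label -1 and are reported separately.  Returns (labels, clusters) where
    ``clusters`` lists the member indices of each kept cluster.
    """
    raw = fcluster(tree, t=thresh_cut, criterion="distance")
    labels = np.full(raw.size, -1, dtype=int)
    clusters = []
    for cluster_id in np.unique(raw):
        members = np.flatnonzero(raw == cluster_id)
        if members.size >= min_size:
            labels[members] = len(clusters)
            clusters.append(members)
    return labels, clusters


def partition_matrix(labels: np.ndarray) -> np.ndarray:
    """Binary co-membership matrix: 1 iff two neurons share a kept cluster.

    Discarded neurons (label -1) share a cluster with no one (their diagonal
    stays 1)."""
    labels = np.asarray(labels)
    same = (labels[:, None] == labels[None, :]) & (labels[:, None] >= 0)
    P = same.astype(int)
    np.fill_diagonal(P, 1)
    return P


def partition_score(P_test: np.ndarray, P_pred: np.ndarray) -> float:
    """Sample correlation between the upper triangles of two partition
    matrices.  NaN when either triangle is constant (a degenerate
    single-cluster or all-discarded partition has no co-membership
    structure to correlate)."""
    iu = np.triu_indices(P_test.shape[0], k=1)
    a = np.asarray(P_test)[iu].astype(float)
    b = np.asarray(P_pred)[iu].astype(float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _assign_to_centroids(profiles: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels under the clustering's correlation metric."""
    labels = np.empty(profiles.shape[0], dtype=int)
    for i, p in enumerate(profiles):
        d = np.array(
            [
                1.0 - np.corrcoef(p, c)[0, 1] if p.std() > 0 and c.std() > 0 else 2.0
                for c in centroids
            ]
        )
        labels[i] = int(np.argmin(d))
    return labels


def generalisability(
    profiles_a: np.ndarray,
    profiles_b: np.ndarray,
    thresh_cut: float,
    min_size: int = 3,
    *,
    shuffle_rng: np.random.Generator | None = None,
) -> float:
    """Cross-validated cluster agreement between split-half profiles.

    Both halves are clustered at ``thresh_cut``; half A's cluster centroids
    re-assign half B's profiles, and the induced partition matrix is
    correlated with B's own (upper triangles); both directions are averaged.
    NaN when either half yields no kept cluster or a degenerate partition.

    ``shuffle_rng`` computes the shuffle control instead: the test half's
    own cluster labels are permuted across neurons before building its
    partition matrix, breaking the correspondence with the
    centroid-transferred partition (expected score ~0).
    """
    scores = []
    for train, test in ((profiles_a, profiles_b), (profiles_b, profiles_a)):
        tree_train = upgma_tree(contribution_distance_matrix(train))
        tree_test = upgma_tree(contribution_distance_matrix(test))
        labels_train, clusters_train = cut_clusters(tree_train, thresh_cut, min_size)
        labels_test, _ = cut_clusters(tree_test, thresh_cut, min_size)
        if not clusters_train or (labels_test < 0).all():
            return np.nan
        centroids = np.stack([train[m].mean(axis=0) for m in clusters_train])
        transfer = _assign_to_centroids(test, centroids)
        if shuffle_rng is not None:
            labels_test = labels_test[shuffle_rng.permutation(labels_test.size)]
        scores.append(
            partition_score(partition_matrix(labels_test), partition_matrix(transfer))
        )
    return float(np.mean(scores))


@dataclass
class ThresholdSelection:
    thresh_cut: float
    grid: np.ndarray
    scores: np.ndarray
    shuffle_score: float


def crossval_cut_threshold(
    profiles_a: np.ndarray,
    profiles_b: np.ndarray,
    thresholds: np.ndarray = DEFAULT_THRESHOLD_GRID,
    min_size: int = 3,
    seed: int = 0,
) -> ThresholdSelection:
    """Choose the cut threshold maximising split-half generalisability.

    Also reports a shuffle control at the selected threshold: the test
    half's cluster labels are permuted before scoring (expected near
    zero)."""
    thresholds = np.asarray(thresholds, dtype=float)
    scores = np.array(
        [generalisability(profiles_a, profiles_b, t, min_size) for t in thresholds]
    )
    if np.isnan(scores).all():
        raise ValueError("no threshold produced kept clusters in both halves")
    best = int(np.nanargmax(scores))
    rng = np.random.default_rng(seed)
    shuffle = generalisability(
        profiles_a, profiles_b, thresholds[best], min_size, shuffle_rng=rng
    )
    return ThresholdSelection(
        thresh_cut=float(thresholds[best]),
        grid=thresholds,
        scores=scores,
        shuffle_score=float(shuffle) if np.isfinite(shuffle) else np.nan,
    )


def split_half_profiles(
    design,
    counts_by_unit: dict,
    selected_by_unit: dict,
    xi_by_unit: dict,
    seed: int = 0,
):
    """Relative-contribution profiles refit on two random halves of the
    trials, for cluster-threshold cross-validation.

    Each unit's selected variable set (and ridge strength) is taken as
    given; the model and its leave-one-variable-out reductions are refit on
    each half separately.  Units failing the refit on either half (e.g. a
    contribution sum of zero) are dropped and reported.

    Returns ``(profiles_a, profiles_b, unit_ids, dropped)`` with profiles
    as (units x 8) arrays in canonical variable order.
    """
    from .contributions import contribution_profile
    from .glm import fit_map

    rng = np.random.default_rng(seed)
    n_trials = int(design.bin_trial.max()) + 1
    perm = rng.permutation(n_trials)
    halves = (np.sort(perm[: n_trials // 2]), np.sort(perm[n_trials // 2 :]))

    unit_ids, rows_a, rows_b, dropped = [], [], [], []
    for unit, counts in counts_by_unit.items():
        variables = tuple(selected_by_unit[unit])
        if not variables:
            continue
        xi = float(xi_by_unit[unit])
        profiles = []
        try:
            for half in halves:
                row_mask = np.isin(design.bin_trial, half)
                fit = fit_map(
                    design, counts, xi, variables=variables, row_mask=row_mask
                )
                profile = contribution_profile(
                    design, counts, fit, row_mask=row_mask
                )
                profiles.append(profile.vector())
        except (ValueError, RuntimeError) as err:
            dropped.append((unit, str(err)))
            continue
        unit_ids.append(unit)
        rows_a.append(profiles[0])
        rows_b.append(profiles[1])
    return (
        np.asarray(rows_a),
        np.asarray(rows_b),
        unit_ids,
        dropped,
    )


def mds_projection(
    profiles: np.ndarray, seed: int = 0, metric: str = "euclidean"
) -> tuple[np.ndarray, float]:
    """Non-metric 2-D MDS embedding of the profiles.

    Dissimilarities are Euclidean by default (the embedding metric need not
    match the clustering metric).  Returns (N x 2 coordinates, Kruskal
    normalised stress-1)."""
    profiles = np.asarray(profiles, dtype=float)
    if metric == "euclidean":
        diff = profiles[:, None, :] - profiles[None, :, :]
        D = np.sqrt((diff**2).sum(axis=-1))
    elif metric == "correlation":
        D = contribution_distance_matrix(profiles)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    mds = MDS(
        n_components=2,
        metric_mds=False,
        dissimilarity="precomputed",
        random_state=seed,
        normalized_stress=True,
        n_init=4,
        max_iter=500,
    )
    coords = mds.fit_transform(D)
    return coords, float(mds.stress_)
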