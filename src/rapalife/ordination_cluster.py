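"""Classical multidimensional scaling, kNN graphs and heatmap row orderings.

Classical (Torgerson) scaling embeds samples so that Euclidean distances
between coordinates reproduce a given distance matrix: squared distances are
double-centered, B = −½·J·D²·J, and the top-k eigenvectors of B scaled by the
square root of their eigenvalues give the coordinates.  Signs are fixed by
making each axis's largest-magnitude loading positive, so the embedding is
fully deterministic.

Treated males are assigned to a control-like ("Rapa-1") or responder
("Rapa-2") subgroup by the nearest of two reference centroids (control males
vs treated females) in the retained MDS space — a reproducible formalization
of a split usually made by eye on the ordination plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform


@dataclass
class MDSResult:
    coordinates: pd.DataFrame     # samples × k
    eigenvalues: np.ndarray       # all, sorted descending
    proportion_variance: np.ndarray


@dataclass
class SubgroupLabels:
    labels: pd.Series             # per treated-male sample: "Rapa-1" / "Rapa-2"
    dist_control: pd.Series
    dist_treated_female: pd.Series
    ties: tuple = ()


@dataclass
class ClusterOrdering:
    order: np.ndarray             # permutation of row indices
    linkage: np.ndarray           # scipy linkage matrix


def classical_mds(data, k: int = 2, *, sample_ids=None,
                  is_distance: bool = False) -> MDSResult:
    """Torgerson classical scaling to k dimensions.

    ``data`` is either a probes × samples matrix (columns embedded using
    Euclidean distances) or a precomputed square distance matrix
    (``is_distance=True``).  If fewer than k positive eigenvalues exist the
    dimensionality is reduced with a warning.
    """
    if is_distance:
        D = np.asarray(data, dtype=float)
        if D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
    else:
        df = pd.DataFrame(data)
        if sample_ids is None:
            sample_ids = list(df.columns)
        D = squareform(pdist(df.to_numpy(float).T, metric="euclidean"))
    n = D.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples, got {n}")
    if sample_ids is None:
        sample_ids = list(range(n))

    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    idx = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[idx], eigvec[:, idx]

    n_pos = int(np.sum(eigval > 1e-10))
    if n_pos < k:
        warnings.warn(f"only {n_pos} positive eigenvalues; reducing k from {k}")
        k = max(n_pos, 1)
    coords = eigvec[:, :k] * np.sqrt(np.maximum(eigval[:k], 0.0))
    # deterministic sign: largest-magnitude loading on each axis is positive
    for j in range(k):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]

    pos_sum = np.sum(eigval[eigval > 0])
    prop = np.maximum(eigval, 0.0) / pos_sum if pos_sum > 0 else np.zeros_like(eigval)
    return MDSResult(
        coordinates=pd.DataFrame(coords, index=sample_ids,
                                 columns=[f"dim{j + 1}" for j in range(k)]),
        eigenvalues=eigval,
        proportion_variance=prop,
    )


def knn_graph(coordinates, k: int = 3) -> list[tuple]:
    """Directed k-nearest-neighbor edge list over rows of ``coordinates``.

    Every node gets exactly k out-edges; ties are broken by stable index
    order.  Duplicate points yield distance-zero edges; the graph need not be
    symmetric.
    """
    df = pd.DataFrame(coordinates)
    X = df.to_numpy(float)
    n = X.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    D = squareform(pdist(X))
    edges = []
    for i in range(n):
        d = D[i].copy()
        d[i] = np.inf
        nn = np.argsort(d, kind="stable")[:k]
        for j in nn:
            edges.append((df.index[i], df.index[j]))
    return edges


def assign_subgroups(mds: MDSResult, control_male: list, treated_female: list,
                     treated_male: list) -> SubgroupLabels:
    """Nearest-centroid subgroup call for each treated male in MDS space.

    A treated male closer to the control-male centroid is "Rapa-1"
    (control-like); closer to the treated-female centroid, "Rapa-2"
    (responder).  Exact ties go conservatively to Rapa-1 and are flagged.
    """
    if not control_male or not treated_female:
        raise ValueError("both reference groups must be non-empty")
    C = mds.coordinates
    cen_cm = C.loc[control_male].mean(axis=0).to_numpy()
    cen_tf = C.loc[treated_female].mean(axis=0).to_numpy()
    labels, d_cm_all, d_tf_all, ties = {}, {}, {}, []
    for s in treated_male:
        x = C.loc[s].to_numpy()
        d_cm = float(np.linalg.norm(x - cen_cm))
        d_tf = float(np.linalg.norm(x - cen_tf))
        if d_cm == d_tf:
            ties.append(s)
        labels[s] = "Rapa-1" if d_cm <= d_tf else "Rapa-2"
        d_cm_all[s], d_tf_all[s] = d_cm, d_tf
    return SubgroupLabels(
        labels=pd.Series(labels, dtype=object),
        dist_control=pd.Series(d_cm_all),
        dist_treated_female=pd.Series(d_tf_all),
        ties=tuple(ties),
    )


def hier_cluster_order(matrix, *, linkage: str = "average",
                       metric: str = "euclidean") -> ClusterOrdering:
    """Agglomerative clustering of matrix rows; returns the dendrogram leaf order.

    Used to order heatmap rows; the traversal puts, at each merge, the
    subtree containing the earlier-joined leaf on the left (scipy's
    deterministic convention).
    """
    X = pd.DataFrame(matrix).to_numpy(float)
    if X.shape[0] < 2:
        return ClusterOrdering(order=np.arange(X.shape[0]), linkage=np.empty((0, 4)))
    Z = hierarchy.linkage(X, method=linkage, metric=metric)
    order = hierarchy.leaves_list(Z)
    return ClusterOrdering(order=np.asarray(order), linkage=Z)
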