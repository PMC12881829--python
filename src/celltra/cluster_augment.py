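"""Prediction-augmented clustering.

Concatenating each cell's softmax-normalized prediction probabilities to
its expression profile injects label information learned elsewhere into an
unsupervised clustering — the transfer setting where a model trained on
healthy tissue helps subtype tumor-infiltrating cells. Neither block is
rescaled. Accuracy against a ground-truth partition uses the optimal
one-to-one cluster/class assignment (Hungarian optimum); when the counts
differ, unmatched clusters contribute nothing.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.neighbors import kneighbors_graph

__all__ = ["augment_features", "kmeans_cluster", "leiden_cluster",
           "clustering_accuracy"]


def augment_features(expression: np.ndarray,
                     probabilities: np.ndarray) -> np.ndarray:
    """Column-wise [expression | probabilities]; rows must align and each
    probability row must sum to 1 (within 1e-6)."""
    expression = np.atleast_2d(np.asarray(expression, dtype=np.float64))
    probabilities = np.atleast_2d(np.asarray(probabilities, dtype=np.float64))
    if expression.shape[0] != probabilities.shape[0]:
        raise ValueError(
            f"{expression.shape[0]} expression rows vs "
            f"{probabilities.shape[0]} probability rows")
    sums = probabilities.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    return np.hstack([expression, probabilities])


def kmeans_cluster(features: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Seeded k-means; labels in 0..k-1."""
    features = np.atleast_2d(features)
    if k > features.shape[0]:
        raise ValueError(f"k={k} exceeds {features.shape[0]} cells")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(features)


def leiden_cluster(features: np.ndarray, n_neighbors: int = 15,
                   resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Leiden communities on a Euclidean kNN graph of the features."""
    import igraph as ig
    import leidenalg

    features = np.atleast_2d(features)
    n = features.shape[0]
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < {n} cells")
    adjacency = kneighbors_graph(features, n_neighbors=n_neighbors,
                                 mode="connectivity")
    adjacency = adjacency.maximum(adjacency.T).tocoo()
    if np.unique(adjacency.row).size < n:
        raise ValueError("kNN graph has isolated cells")
    edges = list(zip(adjacency.row.tolist(), adjacency.col.tolist()))
    graph = ig.Graph(n=n, edges=edges, directed=False)
    graph.simplify()
    partition = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed)
    return np.asarray(partition.membership)


def clustering_accuracy(cluster_labels, truth_names) -> float:
    """Best one-to-one cluster/class matching accuracy.

    Builds the cluster x class contingency table and solves the assignment
    problem maximizing matched cells; accuracy = matched / total. Invariant
    to relabeling of cluster ids; when cluster and class counts differ the
    assignment covers the smaller side.
    """
    cluster_labels = np.asarray(list(cluster_labels))
    truth_names = np.asarray(list(truth_names))
    if cluster_labels.size != truth_names.size:
        raise ValueError("label vectors must be the same length")
    if cluster_labels.size == 0:
        raise ValueError("empty labels")
    clusters, cl_idx = np.unique(cluster_labels, return_inverse=True)
    classes, tr_idx = np.unique(truth_names, return_inverse=True)
    table = np.zeros((clusters.size, classes.size), dtype=np.int64)
    np.add.at(table, (cl_idx, tr_idx), 1)
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum() / cluster_labels.size)
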