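"""Unsupervised grouping of the aligned map ensemble.

Maps are clustered by K-means on their flattened pixel vectors — i.e. on
the densities alone, without any similarity-score feature — and projected
onto the leading principal components for display.  Because clustering
happens before the dimensionality reduction, classes separated along
third or higher components can overlap on the PC1–PC2 plane; this is a
known display limitation, not a clustering defect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "ClassAssignment",
    "kmeans_classify",
    "pca_project",
    "class_representatives",
    "landscape_coordinates",
]


@dataclass
class ClassAssignment:
    labels: np.ndarray        # per-map class index, 0-based
    centroids: np.ndarray     # (k, n_pixels) class mean vectors
    objective: float          # sum of squared distances to centroids
    k: int


def _stack(maps) -> np.ndarray:
    rows = [m.values.ravel() if hasattr(m, "values") else np.ravel(m) for m in maps]
    return np.asarray(rows)


def kmeans_classify(maps, k: int = 10, seed: int = 0, n_restarts: int = 10) -> ClassAssignment:
    """K-means on flattened aligned maps, best of ``n_restarts`` runs.

    The objective is the usual sum of squared distances between map
    vectors and their class centroids.
    """
    x = _stack(maps)
    if len(x) < k:
        raise ValueError(f"need at least k={k} maps, got {len(x)}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(x)
    return ClassAssignment(labels=labels, centroids=km.cluster_centers_,
                           objective=float(km.inertia_), k=k)


def pca_project(maps, n_components: int = 2):
    """Mean-centered PCA of flattened maps.

    Returns per-map coordinates ``(M, n_components)`` and the explained
    variance ratios.  Component signs are fixed by making the
    largest-magnitude loading positive.  Degenerate stacks (identical
    maps) yield zero coordinates and zero variance.
    """
    x = _stack(maps)
    if len(x) < 2:
        raise ValueError("pca_project needs at least 2 maps")
    n_components = min(n_components, len(x) - 1, x.shape[1])
    if np.allclose(x, x[0]):
        return np.zeros((len(x), n_components)), np.zeros(n_components)
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(x)
    for c in range(n_components):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, c] *= -1
    return coords, pca.explained_variance_ratio_


def class_representatives(assignment: ClassAssignment,
                          scores_vs_reference: np.ndarray) -> dict:
    """Per class, the member with the smallest score against the reference.

    Ties resolve to the lowest map index; empty classes are absent from
    the returned dict.
    """
    scores = np.asarray(scores_vs_reference, dtype=float)
    if len(scores) != len(assignment.labels):
        raise ValueError("labels and scores must cover the same maps")
    reps = {}
    for cls in range(assignment.k):
        members = np.flatnonzero(assignment.labels == cls)
        if members.size:
            reps[cls] = int(members[np.argmin(scores[members])])
    return reps


def landscape_coordinates(assignment: ClassAssignment,
                          pc_coords: np.ndarray,
                          scores_vs_reference: np.ndarray) -> pd.DataFrame:
    """Per-map (PC1, PC2, score) triples with class labels.

    These are the coordinates of the funnel-landscape representation: maps
    near the funnel bottom have small scores and cluster tightly in the
    PC plane.
    """
    scores = np.asarray(scores_vs_reference, dtype=float)
    pc = np.asarray(pc_coords, dtype=float)
    return pd.DataFrame({
        "map_index": np.arange(len(scores)),
        "pc1": pc[:, 0],
        "pc2": pc[:, 1] if pc.shape[1] > 1 else np.zeros(len(scores)),
        "score": scores,
        "class": assignment.labels,
    })
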