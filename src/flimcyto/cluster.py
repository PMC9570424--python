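"""Two-cluster unsupervised image classifier.

K-means (k-means++ seeding, best of ``n_init`` restarts) partitions the
PCA-reduced image features into two clusters; the cluster holding the
strict majority of the normal-group training images is labeled ``normal``
and the other ``abnormal``.  No image-level supervision is used — only the
patient-level group of the training samples enters, and only to orient the
two clusters.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from sklearn.cluster import KMeans

__all__ = ["ClusterModel", "LabelingError", "fit_kmeans", "label_clusters",
           "predict_labels", "save_model", "load_model"]

_FORMAT_VERSION = 1
NORMAL, ABNORMAL = "normal", "abnormal"


class LabelingError(RuntimeError):
    """Cluster orientation is ambiguous (exact tie in normal-group counts)."""


@dataclass
class ClusterModel:
    centroids: np.ndarray                 # (k, d)
    seed: int
    n_init: int
    inertia: float
    label_map: dict | None = None         # cluster index -> normal/abnormal
    k: int = 2

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count must equal k")
        if self.label_map is not None:
            if sorted(self.label_map.values()) != sorted([NORMAL, ABNORMAL]):
                raise ValueError("label_map must map onto {normal, abnormal}")

    def assign(self, X: np.ndarray) -> np.ndarray:
        """Nearest-centroid (Euclidean) cluster index per row."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.centroids.shape[1]:
            raise ValueError(
                f"dimension {X.shape[1]} does not match centroids "
                f"({self.centroids.shape[1]})")
        d2 = ((X[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


def fit_kmeans(reduced: np.ndarray, k: int = 2, seed: int = 0,
               n_init: int = 10) -> ClusterModel:
    """Fit k-means with k-means++ seeding; deterministic given the seed."""
    X = np.atleast_2d(np.asarray(reduced, dtype=np.float64))
    if len(np.unique(X, axis=0)) < k:
        raise ValueError(f"need at least {k} distinct points")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                random_state=seed, algorithm="lloyd")
    km.fit(X)
    return ClusterModel(centroids=km.cluster_centers_, seed=seed,
                        n_init=n_init, inertia=float(km.inertia_), k=k)


def label_clusters(model: ClusterModel, assignments: np.ndarray,
                   group_labels) -> ClusterModel:
    """Orient the clusters from the normal training group only.

    ``group_labels`` holds, per training image, the patient-level group:
    ``"normal"`` or a malignant-group value.  The cluster holding the
    strict majority of normal-group images becomes ``normal``; an exact
    tie raises :class:`LabelingError` rather than guessing.
    """
    assignments = np.asarray(assignments)
    is_normal = np.asarray([g == NORMAL for g in group_labels])
    if len(assignments) != len(is_normal):
        raise ValueError("assignments and group labels differ in length")
    counts = np.array([(is_normal & (assignments == c)).sum()
                       for c in range(model.k)])
    order = np.argsort(counts)
    if counts[order[-1]] == counts[order[-2]]:
        raise LabelingError(
            f"normal-group images split {counts.tolist()} across clusters; "
            "more training data is needed to orient them")
    normal_cluster = int(order[-1])
    label_map = {c: (NORMAL if c == normal_cluster else ABNORMAL)
                 for c in range(model.k)}
    return ClusterModel(centroids=model.centroids.copy(), seed=model.seed,
                        n_init=model.n_init, inertia=model.inertia,
                        label_map=label_map, k=model.k)


def predict_labels(model: ClusterModel, reduced: np.ndarray) -> list:
    """Nearest-centroid labels; exact ties resolve to ``normal``."""
    if model.label_map is None:
        raise ValueError("model is unlabeled; call label_clusters first")
    X = np.atleast_2d(np.asarray(reduced, dtype=np.float64))
    if X.shape[1] != model.centroids.shape[1]:
        raise ValueError("dimension mismatch with model centroids")
    d2 = ((X[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    labels = []
    for row in d2:
        tied = np.flatnonzero(row == row.min())
        if len(tied) > 1:
            labels.append(NORMAL)  # conservative: bias against false positives
        else:
            labels.append(model.label_map[int(tied[0])])
    return labels


def save_model(model: ClusterModel, path) -> None:
    """Persist as JSON metadata + HDF5 centroids under a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {"format_version": _FORMAT_VERSION, "k": model.k,
            "seed": model.seed, "n_init": model.n_init,
            "inertia": model.inertia,
            "label_map": ({str(k): v for k, v in model.label_map.items()}
                          if model.label_map is not None else None)}
    (path / "model.json").write_text(json.dumps(meta, indent=2))
    with h5py.File(path / "centroids.h5", "w") as f:
        f.create_dataset("centroids", data=model.centroids)


def load_model(path) -> ClusterModel:
    path = Path(path)
    try:
        meta = json.loads((path / "model.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read cluster model at {path}: {exc}") from exc
    if meta.get("format_version") != _FORMAT_VERSION:
        raise ValueError(
            f"model format version {meta.get('format_version')!r} is not "
            f"supported (expected {_FORMAT_VERSION})")
    try:
        with h5py.File(path / "centroids.h5", "r") as f:
            centroids = f["centroids"][()]
    except (OSError, KeyError) as exc:
        raise ValueError(f"cannot read centroids at {path}: {exc}") from exc
    label_map = meta["label_map"]
    if label_map is not None:
        label_map = {int(k): v for k, v in label_map.items()}
    return ClusterModel(centroids=centroids, seed=meta["seed"],
                        n_init=meta["n_init"], inertia=meta["inertia"],
                        label_map=label_map, k=meta["k"])
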