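"""k-means clustering of superposed frames and representative structures.

Frames are embedded as flattened Cartesian coordinates of the selection
(after superposition, the cpptraj convention); Lloyd iterations with
k-means++ seeding run through scikit-learn with a fixed random state so
results are deterministic.  The representative structure of a cluster is the
member frame closest (Euclidean) to the cluster centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import AnalysisError
from .trajectory import Ensemble, StructureModel, resolve_selection

__all__ = ["ClusterResult", "kmeans_frames", "representative_structure", "elbow_report"]


@dataclass
class ClusterResult:
    assignments: np.ndarray  # (F,) labels in [0, k)
    centroids: np.ndarray  # (k, 3*A_sel) flattened coordinates
    inertia: float
    representative_frames: np.ndarray  # (k,) frame index per cluster
    selection: str = ""

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def _features(ensemble: Ensemble, selection: str) -> np.ndarray:
    idx = resolve_selection(ensemble, selection)
    return ensemble.frames[:, idx, :].reshape(ensemble.n_frames, -1)


def kmeans_frames(
    ensemble: Ensemble,
    selection: str = "name CA",
    k: int = 5,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusterResult:
    """Cluster frames into k groups; deterministic for a fixed seed."""
    if k < 1:
        raise AnalysisError("k must be >= 1")
    if k > ensemble.n_frames:
        raise AnalysisError(f"k={k} exceeds frame count {ensemble.n_frames}")
    X = _features(ensemble, selection)
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter, tol=tol,
        random_state=seed, algorithm="lloyd",
    ).fit(X)
    labels = km.labels_.astype(int)
    reps = np.empty(k, dtype=int)
    for c in range(k):
        members = np.nonzero(labels == c)[0]
        if members.size == 0:
            raise AnalysisError(f"cluster {c} is empty after fitting")
        d = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        reps[c] = members[np.argmin(d)]
    return ClusterResult(labels, km.cluster_centers_, float(km.inertia_), reps, selection)


def representative_structure(
    result: ClusterResult, ensemble: Ensemble, cluster: int
) -> StructureModel:
    """Full-topology frame nearest to the centroid of ``cluster``."""
    if not (0 <= cluster < result.k):
        raise AnalysisError(f"cluster {cluster} outside [0, {result.k})")
    frame = int(result.representative_frames[cluster])
    return ensemble.frame_structure(frame, title=f"cluster {cluster} representative (frame {frame})")


def elbow_report(
    ensemble: Ensemble, selection: str = "name CA", ks: range | list[int] = range(1, 9),
    seed: int = 0,
) -> dict[int, float]:
    """Inertia as a function of k, for choosing the cluster count."""
    return {
        int(k): kmeans_frames(ensemble, selection, k=int(k), seed=seed).inertia
        for k in ks
        if 1 <= int(k) <= ensemble.n_frames
    }
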