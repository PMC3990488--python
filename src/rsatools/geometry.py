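"""Low-dimensional arrangements (metric-stress MDS) and hierarchical cluster
trees summarizing an RDM's representational geometry."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.manifold import MDS

from .rdm import RDM

__all__ = ["Arrangement2D", "ClusterTree", "mds_2d", "hierarchical_cluster"]

LINKAGES = ("average", "single", "complete")


@dataclass(frozen=True)
class Arrangement2D:
    """2D condition coordinates (arbitrary units) and the metric stress."""

    condition_labels: tuple[str, ...]
    coordinates: np.ndarray
    stress: float


def _metric_stress(coords: np.ndarray, target_vec: np.ndarray) -> float:
    d = pdist(coords)
    denom = float(np.sum(target_vec**2))
    if denom == 0:
        return float(np.sqrt(np.sum(d**2)))
    return float(np.sqrt(np.sum((d - target_vec) ** 2) / denom))


def mds_2d(rdm: RDM, seed: Optional[int] = None, n_restarts: int = 4) -> Arrangement2D:
    """Arrange conditions in 2D so distances reflect the dissimilarities.

    Minimizes the metric stress criterion from the best of ``n_restarts``
    seeded initializations.
    """
    if rdm.n_conditions < 3:
        raise ValueError(f"MDS needs >= 3 conditions, got {rdm.n_conditions}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    try:
        mds = MDS(
            n_components=2,
            metric="precomputed",
            init="random",
            n_init=n_restarts,
            random_state=seed,
            normalized_stress=False,
        )
        coords = mds.fit_transform(rdm.matrix)
    except (TypeError, ValueError):  # scikit-learn < 1.9 signature
        mds = MDS(
            n_components=2,
            dissimilarity="precomputed",
            n_init=n_restarts,
            random_state=seed,
            normalized_stress=False,
        )
        coords = mds.fit_transform(rdm.matrix)
    return Arrangement2D(
        condition_labels=rdm.condition_labels,
        coordinates=coords,
        stress=_metric_stress(coords, rdm.dissimilarities),
    )


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative merge sequence over the RDM's conditions.

    ``merges`` is a scipy-format linkage matrix: each row is
    ``(node_a, node_b, height, size)`` with heights in dissimilarity units.
    """

    condition_labels: tuple[str, ...]
    merges: np.ndarray
    linkage: str

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels for a cut producing ``n_clusters`` groups."""
        return hierarchy.fcluster(self.merges, n_clusters, criterion="maxclust")

    def to_newick(self) -> str:
        """Serialize the tree in Newick format with branch lengths."""
        tree = hierarchy.to_tree(self.merges)

        def render(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.condition_labels[node.id]}:{length:g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return render(tree, tree.dist) + ";"


def hierarchical_cluster(rdm: RDM, linkage: str = "average") -> ClusterTree:
    """Agglomerative clustering of the RDM's conditions."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    merges = hierarchy.linkage(rdm.dissimilarities, method=linkage)
    return ClusterTree(
        condition_labels=rdm.condition_labels, merges=merges, linkage=linkage
    )
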