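"""Distance-stratified classification of between-system edges.

Between-system edges are labeled short- or long-range relative to half the
maximum Euclidean node-to-node distance of the species' parcellation (the
half-max rule); the threshold is computed over ALL node pairs, not only
between-system ones, and is therefore a property of the parcellation alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .communities import Partition
from .networks import ConnectivityMatrix

logger = logging.getLogger(__name__)

UNASSIGNED = -1


def pairwise_distances(nodes: pd.DataFrame) -> np.ndarray:
    """Symmetric node x node Euclidean distances (mm) between centroids."""
    xyz = nodes[["x", "y", "z"]].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(xyz).all(axis=1))
    if bad.size:
        raise ValueError(f"missing/non-finite centroid for node(s) {bad.tolist()}")
    return squareform(pdist(xyz))


@dataclass
class DistanceClassification:
    """Short/long labels for between-system edges under the half-max rule."""

    edges: pd.DataFrame  # columns: i, j, distance_mm, label in {short, long}
    threshold: float
    max_distance: float

    @property
    def n_short(self) -> int:
        return int((self.edges["label"] == "short").sum())

    @property
    def n_long(self) -> int:
        return int((self.edges["label"] == "long").sum())


def classify_between_edges(nodes: pd.DataFrame, p: Partition) -> DistanceClassification:
    """Label every between-system edge short (< max/2) or long (>= max/2).

    The threshold is half the maximum pairwise distance over all nodes of the
    parcellation; boundary ties are labeled long.
    """
    if p.n_nodes != len(nodes):
        raise ValueError("partition and node table sizes differ")
    dist = pairwise_distances(nodes)
    max_d = float(dist.max())
    if max_d == 0:
        raise ValueError("degenerate parcellation: all centroids identical")
    threshold = max_d / 2.0

    labels = p.labels
    assigned = np.flatnonzero(labels != UNASSIGNED)
    if len(set(labels[assigned])) < 2:
        raise ValueError("need >= 2 systems to define between-system edges")

    rows = []
    for a_idx in range(len(assigned)):
        i = assigned[a_idx]
        for j in assigned[a_idx + 1 :]:
            if labels[i] == labels[j]:
                continue
            d = dist[i, j]
            rows.append((int(i), int(j), float(d), "short" if d < threshold else "long"))
    edges = pd.DataFrame(rows, columns=["i", "j", "distance_mm", "label"])
    return DistanceClassification(edges=edges, threshold=threshold, max_distance=max_d)


def distance_stratified_summary(
    m: ConnectivityMatrix,
    dc: DistanceClassification,
) -> dict[str, float | None]:
    """Proportions and negative-zeroed mean z of short vs long between edges."""
    total = len(dc.edges)
    if total == 0:
        raise ValueError("no between-system edges to summarize")
    out: dict[str, float | None] = {
        "prop_short": dc.n_short / total,
        "prop_long": dc.n_long / total,
    }
    for label, key in (("short", "mean_z_short"), ("long", "mean_z_long")):
        sub = dc.edges[dc.edges["label"] == label]
        if sub.empty:
            logger.warning("no %s-range between-system edges; mean emitted as null", label)
            out[key] = None
        else:
            z = m.values[sub["i"].to_numpy(), sub["j"].to_numpy()]
            out[key] = float(np.maximum(z, 0.0).mean())
    return out
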