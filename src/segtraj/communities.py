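"""Community detection on thresholded connectivity matrices.

Two objectives behind one interface: the two-level map equation (Infomap, the
default) and weighted Newman modularity (Leiden), each run with restarts and
the best partition kept by its own objective.  A consensus step dissolves
small communities from the reference-density partition and reassigns their
members by retained-edge-weight plurality.
"""

from __future__ import annotations

import logging
import math
import random as _pyrandom
from dataclasses import dataclass, field
from typing import Sequence

import igraph as ig
import leidenalg as la
import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .networks import ConnectivityMatrix, threshold_by_density

logger = logging.getLogger(__name__)

UNASSIGNED = -1


@dataclass
class Partition:
    """Node -> community assignment at one edge density.

    Labels are contiguous 1..k in descending community size; isolated or
    unassignable nodes carry the sentinel -1.
    """

    labels: np.ndarray
    density: float
    quality: float
    method: str
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def assigned(self) -> np.ndarray:
        return self.labels != UNASSIGNED

    @property
    def n_communities(self) -> int:
        return len(set(self.labels[self.assigned]))

    def sizes(self) -> dict[int, int]:
        lab, cnt = np.unique(self.labels[self.assigned], return_counts=True)
        return dict(zip(lab.tolist(), cnt.tolist()))


def relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel assigned communities 1..k by descending size (ties: first node)."""
    labels = np.asarray(labels, dtype=int)
    out = np.full_like(labels, UNASSIGNED)
    uniq = [l for l in dict.fromkeys(labels.tolist()) if l != UNASSIGNED]
    order = sorted(
        uniq,
        key=lambda l: (-int(np.sum(labels == l)), int(np.argmax(labels == l))),
    )
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


# ---------------------------------------------------------------------------
# objectives


def _graph_from_matrix(m: ConnectivityMatrix) -> ig.Graph:
    iu, ju = np.triu_indices(m.n_nodes, k=1)
    w = m.values[iu, ju]
    if np.any(w < 0):
        raise ValueError("thresholded matrix must have nonnegative weights")
    keep = w > 0
    g = ig.Graph(
        n=m.n_nodes,
        edges=list(zip(iu[keep].tolist(), ju[keep].tolist())),
    )
    g.es["weight"] = w[keep].tolist()
    return g


def modularity(m: ConnectivityMatrix, labels: np.ndarray) -> float:
    """Weighted Newman modularity of a labeling (unassigned nodes excluded)."""
    g = _graph_from_matrix(m)
    labels = np.asarray(labels, dtype=int)
    # igraph wants a membership for every vertex; park each unassigned node
    # in its own community (it has no edges in a valid thresholded graph use)
    memb = labels.copy()
    nxt = labels.max() + 1 if (labels != UNASSIGNED).any() else 1
    for i in np.flatnonzero(labels == UNASSIGNED):
        memb[i] = nxt
        nxt += 1
    return float(g.modularity(memb.tolist(), weights="weight"))


def map_equation_codelength(m: ConnectivityMatrix, labels: np.ndarray) -> float:
    """Two-level map-equation codelength (bits) of a labeling.

    Undirected flow: node visit rates are strength fractions; a module's exit
    rate is its cut weight over twice the total weight.  Lower is better.
    """
    labels = np.asarray(labels, dtype=int)
    A = np.where(m.values > 0, m.values, 0.0)
    strength = A.sum(axis=1)
    total = strength.sum()  # = 2 * total edge weight
    if total <= 0:
        raise ValueError("graph has no positive edges")
    active = strength > 0
    p = strength / total

    def plogp(x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        nz = x > 0
        out[nz] = x[nz] * np.log2(x[nz])
        return out

    modules = sorted(set(labels[active & (labels != UNASSIGNED)]))
    q = []
    module_term = 0.0
    for mlab in modules:
        members = np.flatnonzero((labels == mlab) & active)
        outside = np.setdiff1d(np.flatnonzero(active), members)
        cut = A[np.ix_(members, outside)].sum()
        q_m = cut / total
        q.append(q_m)
        p_circ = q_m + p[members].sum()
        inner = np.concatenate(([q_m], p[members]))
        module_term += p_circ * (-np.sum(plogp(inner / p_circ)))
    q = np.asarray(q)
    q_tot = q.sum()
    index_term = 0.0
    if q_tot > 0:
        index_term = q_tot * (-np.sum(plogp(q / q_tot)))
    return float(index_term + module_term)


# ---------------------------------------------------------------------------
# detection


def _restart_seeds(seed: int, n: int, salt: int = 0) -> list[int]:
    ss = np.random.SeedSequence([int(seed), salt])
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n, dtype=np.uint64)]


def detect_communities(
    m: ConnectivityMatrix,
    method: str = "map_equation",
    seed: int = 0,
    n_restarts: int = 20,
) -> Partition:
    """Best partition over restarts by the chosen objective.

    ``map_equation`` minimizes the two-level map-equation codelength (Infomap
    search); ``modularity`` maximizes weighted Newman modularity (Leiden
    search).  Isolated nodes are reported as unassigned.
    """
    g = _graph_from_matrix(m)
    if g.ecount() == 0:
        raise ValueError("empty edge set: nothing to detect communities on")
    degrees = np.asarray(g.degree())
    isolated = np.flatnonzero(degrees == 0)
    sub = g.subgraph(np.flatnonzero(degrees > 0).tolist())
    sub_to_full = np.flatnonzero(degrees > 0)

    best_labels: np.ndarray | None = None
    best_quality = None
    for rs in _restart_seeds(seed, n_restarts):
        if method == "map_equation":
            _pyrandom.seed(rs)
            memb = np.asarray(
                sub.community_infomap(edge_weights="weight", trials=1).membership
            )
        elif method == "modularity":
            memb = np.asarray(
                la.find_partition(
                    sub,
                    la.ModularityVertexPartition,
                    weights="weight",
                    seed=rs,
                    n_iterations=-1,
                ).membership
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        labels = np.full(m.n_nodes, UNASSIGNED, dtype=int)
        labels[sub_to_full] = memb + 1
        if method == "map_equation":
            qual = map_equation_codelength(m, labels)
            better = best_quality is None or qual < best_quality
        else:
            qual = modularity(m, labels)
            better = best_quality is None or qual > best_quality
        if better:
            best_quality, best_labels = qual, labels

    assert best_labels is not None
    best_labels[isolated] = UNASSIGNED
    density = float(m.meta.get("density", np.count_nonzero(m.upper_values()) / m.n_edges))
    return Partition(
        labels=relabel_by_size(best_labels),
        density=density,
        quality=float(best_quality),
        method=method,
        seed=seed,
        meta={"n_restarts": n_restarts, "n_isolated": int(isolated.size)},
    )


def density_sweep(
    m: ConnectivityMatrix,
    densities: Sequence[float],
    seed: int = 0,
    method: str = "map_equation",
    n_restarts: int = 20,
) -> list[Partition]:
    """Threshold at each density and detect communities; one Partition each."""
    densities = list(densities)
    if any(b <= a for a, b in zip(densities, densities[1:])):
        raise ValueError("densities must be strictly increasing")
    out = []
    for idx, d in enumerate(densities):
        thr = threshold_by_density(m, d)
        d_seed = _restart_seeds(seed, 1, salt=idx + 1)[0]
        out.append(detect_communities(thr, method=method, seed=d_seed, n_restarts=n_restarts))
        out[-1].density = d
    return out


def default_densities(lo: float = 0.005, hi: float = 0.20, step: float = 0.005) -> list[float]:
    """The standard sweep: 0.5% to 20% of edges in 0.5% increments."""
    n = int(round((hi - lo) / step)) + 1
    return [round(lo + k * step, 10) for k in range(n)]


# ---------------------------------------------------------------------------
# consensus


def consensus_partition(
    partitions: Sequence[Partition],
    matrix: ConnectivityMatrix,
    min_size: int = 4,
    reference_density: float = 0.07,
) -> Partition:
    """Final system labels: dissolve small communities at the reference density.

    Starting from the reference-density partition, every community smaller
    than ``min_size`` is dissolved and each of its members is reassigned to
    the surviving community holding the plurality of the member's retained
    edge weight at the reference density (ties go to the community containing
    the member's strongest single edge; a residual tie leaves the node
    unassigned).  Labels are renumbered by descending community size.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    ref = next(
        (p for p in partitions if math.isclose(p.density, reference_density, rel_tol=1e-9)),
        None,
    )
    if ref is None:
        raise ValueError(f"no partition at reference density {reference_density}")

    thr = threshold_by_density(matrix, reference_density)
    A = thr.values
    labels = ref.labels.copy()
    sizes = ref.sizes()
    keepers = {lab for lab, size in sizes.items() if size >= min_size}
    if not keepers:
        raise ValueError(
            f"all communities smaller than min_size={min_size}; no consensus possible"
        )

    keeper_members = {lab: np.flatnonzero(ref.labels == lab) for lab in keepers}
    for node in np.flatnonzero(ref.assigned):
        if labels[node] in keepers:
            continue
        weight_to = {lab: A[node, mem].sum() for lab, mem in keeper_members.items()}
        best = max(weight_to.values())
        if best <= 0:
            labels[node] = UNASSIGNED
            continue
        tied = sorted(lab for lab, w in weight_to.items() if w == best)
        if len(tied) > 1:
            strongest = {lab: A[node, keeper_members[lab]].max() for lab in tied}
            top = max(strongest.values())
            tied = sorted(lab for lab, w in strongest.items() if w == top)
        labels[node] = tied[0] if len(tied) == 1 else UNASSIGNED

    final = relabel_by_size(labels)
    return Partition(
        labels=final,
        density=reference_density,
        quality=ref.quality,
        method=ref.method,
        seed=ref.seed,
        meta={"consensus": True, "min_size": min_size, "from": ref.meta},
    )


# ---------------------------------------------------------------------------
# comparison


def partition_similarity(p1: Partition, p2: Partition) -> dict[str, float]:
    """Adjusted Rand index and normalized mutual information between labelings.

    Nodes unassigned in either partition are excluded pairwise.
    """
    if p1.n_nodes != p2.n_nodes:
        raise ValueError("partitions must cover the same node set")
    mask = p1.assigned & p2.assigned
    if not mask.any():
        raise ValueError("no co-assigned nodes to compare")
    a, b = p1.labels[mask], p2.labels[mask]
    return {
        "ari": float(adjusted_rand_score(a, b)),
        "nmi": float(normalized_mutual_info_score(a, b)),
    }
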