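"""Network construction: node timeseries to Fisher-z connectivity matrices.

Implements frame censoring/equating, per-scan Fisher-z correlation matrices
(diagonal zeroed), group averaging, and edge-density thresholding with a
deterministic tie-break.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: correlations are clipped to +/-(1 - R_CLIP_EPS) before atanh
R_CLIP_EPS = 1e-7


class ScanRejected(ValueError):
    """A scan failed a precondition (too few frames, zero-variance node...)."""


@dataclass
class SubjectTimeseries:
    """One scan's node x frame signal matrix with a frame-keep mask."""

    scan_id: str
    subject_id: str
    data: np.ndarray
    keep_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.keep_mask = np.asarray(self.keep_mask, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("timeseries data must be a 2-D node x frame matrix")
        if self.keep_mask.shape != (self.data.shape[1],):
            raise ValueError("keep_mask length must equal the number of frames")
        if not np.isfinite(self.data[:, self.keep_mask]).all():
            raise ValueError(f"scan {self.scan_id}: non-finite values among kept frames")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.keep_mask.sum())

    def kept_data(self) -> np.ndarray:
        return self.data[:, self.keep_mask]


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node Fisher-z matrix with a zero diagonal."""

    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity values must be square")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("connectivity diagonal must be exactly 0")
        if not np.isfinite(v[~np.eye(v.shape[0], dtype=bool)]).all():
            raise ValueError("off-diagonal entries must be finite")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    def upper_values(self) -> np.ndarray:
        """Edge weights in canonical (i < j) order."""
        return self.values[np.triu_indices(self.n_nodes, k=1)]


def censor_and_equate(
    ts: SubjectTimeseries,
    target_frames: int,
    method: str = "truncate",
    seed: int | None = 0,
) -> SubjectTimeseries:
    """Retain exactly ``target_frames`` kept frames, preserving frame order.

    ``truncate`` keeps the first kept frames; ``random_subsample`` draws them
    uniformly without replacement (deterministic given ``seed``), then sorts
    back into acquisition order.
    """
    kept = np.flatnonzero(ts.keep_mask)
    if len(kept) < target_frames:
        raise ScanRejected(
            f"scan {ts.scan_id}: {len(kept)} kept frames < target {target_frames}"
        )
    if method == "truncate":
        chosen = kept[:target_frames]
    elif method == "random_subsample":
        rng = np.random.default_rng(seed)
        chosen = np.sort(rng.choice(kept, size=target_frames, replace=False))
    else:
        raise ValueError(f"unknown equating method {method!r}")
    meta = dict(ts.meta, equate_method=method, target_frames=target_frames)
    return SubjectTimeseries(
        scan_id=ts.scan_id,
        subject_id=ts.subject_id,
        data=ts.data[:, chosen],
        keep_mask=np.ones(target_frames, dtype=bool),
        meta=meta,
    )


def connectivity_matrix(ts: SubjectTimeseries) -> ConnectivityMatrix:
    """Fisher-z Pearson correlation matrix over kept frames, diagonal 0.

    Perfect correlations are clipped to +/-(1 - 1e-7) before atanh so every
    edge stays finite; a warning is logged when clipping fires.
    """
    data = ts.kept_data()
    if data.shape[1] < 3:
        raise ScanRejected(f"scan {ts.scan_id}: need >= 3 kept frames")
    sd = data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ScanRejected(
            f"scan {ts.scan_id}: zero-variance node(s) {dead.tolist()}"
        )
    r = np.corrcoef(data)
    off = ~np.eye(r.shape[0], dtype=bool)
    limit = 1.0 - R_CLIP_EPS
    if np.any(np.abs(r[off]) >= limit):
        logger.warning("scan %s: |r|=1 off-diagonal clipped before atanh", ts.scan_id)
    z = np.arctanh(np.clip(r, -limit, limit))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    meta = dict(ts.meta, scan_id=ts.scan_id, subject_id=ts.subject_id)
    return ConnectivityMatrix(values=z, meta=meta)


def group_average(matrices: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Elementwise mean of matrices sharing a node order; diagonal 0."""
    if not matrices:
        raise ValueError("cannot average an empty list of matrices")
    n = matrices[0].n_nodes
    if any(m.n_nodes != n for m in matrices):
        raise ValueError("all matrices must share the same node order/size")
    mean = np.mean([m.values for m in matrices], axis=0)
    np.fill_diagonal(mean, 0.0)
    return ConnectivityMatrix(values=mean, meta={"group_size": len(matrices)})


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def threshold_by_density(m: ConnectivityMatrix, density: float) -> ConnectivityMatrix:
    """Keep the k = round(density * E) strongest positive edges, zero the rest.

    Ties at the cutoff break toward the lexicographically smaller (i, j) edge
    index, so the retained edge sets are nested across densities.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    n = m.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = m.values[iu, ju]
    k = _round_half_away(density * len(w))
    pos = np.flatnonzero(w > 0)
    if len(pos) < k:
        logger.warning(
            "density %.3f wants %d edges but only %d are positive; keeping all",
            density, k, len(pos),
        )
        k = len(pos)
    # sort by descending weight, then ascending (i, j)
    order = pos[np.lexsort((ju[pos], iu[pos], -w[pos]))][:k]
    out = np.zeros_like(m.values)
    out[iu[order], ju[order]] = w[order]
    out += out.T
    meta = dict(m.meta, density=density, n_retained=int(k))
    return ConnectivityMatrix(values=out, meta=meta)
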