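"""System segregation and companion summaries.

System segregation of a weighted network with system labels is

    (mean within-system z - mean between-system z) / mean within-system z,

computed after replacing negative Fisher-z values by zero.  Zeroing is a value
substitution, not edge removal: the denominators W and B stay the structural
counts of within- and between-system node pairs.  Nodes without a system label
are excluded entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .communities import Partition
from .networks import ConnectivityMatrix

UNASSIGNED = -1


@dataclass
class EdgeGroups:
    """Edges among assigned nodes split into within- and between-system sets."""

    within_edges: list[tuple[int, int, float]]
    between_edges: list[tuple[int, int, float]]

    @property
    def W(self) -> int:
        return len(self.within_edges)

    @property
    def B(self) -> int:
        return len(self.between_edges)

    def within_sum(self) -> float:
        return float(sum(z for _, _, z in self.within_edges))

    def between_sum(self) -> float:
        return float(sum(z for _, _, z in self.between_edges))


def edge_groups(
    m: ConnectivityMatrix,
    p: Partition,
    negatives: str = "zero",
) -> EdgeGroups:
    """Split edges among assigned nodes by same/different community.

    With ``negatives="zero"`` (default) negative z values contribute 0 to the
    sums but the edge still counts structurally.
    """
    if negatives not in ("zero", "keep"):
        raise ValueError("negatives must be 'zero' or 'keep'")
    if p.n_nodes != m.n_nodes:
        raise ValueError("partition and matrix node counts differ")
    labels = p.labels
    assigned = np.flatnonzero(labels != UNASSIGNED)
    if len(set(labels[assigned])) < 2:
        raise ValueError("need >= 2 communities over assigned nodes")

    within, between = [], []
    for a_idx in range(len(assigned)):
        i = assigned[a_idx]
        for j in assigned[a_idx + 1 :]:
            z = m.values[i, j]
            if negatives == "zero" and z < 0:
                z = 0.0
            (within if labels[i] == labels[j] else between).append((int(i), int(j), float(z)))
    return EdgeGroups(within_edges=within, between_edges=between)


def system_segregation(
    m: ConnectivityMatrix,
    p: Partition,
    negatives: str = "zero",
) -> float:
    """(mean within z - mean between z) / mean within z; at most 1."""
    groups = edge_groups(m, p, negatives=negatives)
    zw = groups.within_sum() / groups.W
    zb = groups.between_sum() / groups.B
    if zw <= 0:
        raise ValueError(
            f"mean within-system z must be positive (within={zw:.4g}, between={zb:.4g})"
        )
    return (zw - zb) / zw


def within_between_means(
    m: ConnectivityMatrix,
    p: Partition,
    negatives: str = "zero",
) -> tuple[float, float]:
    """Mean within- and between-system z (negative-zeroed by default)."""
    groups = edge_groups(m, p, negatives=negatives)
    return groups.within_sum() / groups.W, groups.between_sum() / groups.B


# ---------------------------------------------------------------------------
# edgewise group comparison


def edgewise_group_test(
    group_a: list[ConnectivityMatrix],
    group_b: list[ConnectivityMatrix],
    correction: str = "bh_fdr",
) -> pd.DataFrame:
    """Independent pooled-variance t test per upper-triangle edge.

    Returns one row per edge with columns i, j, t, p and (with
    ``correction="bh_fdr"``) Benjamini-Hochberg q values over all edges.
    Edges with zero variance in both groups get null t/p markers.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 matrices per group")
    n = group_a[0].n_nodes
    if any(m.n_nodes != n for m in group_a + group_b):
        raise ValueError("all matrices must share node order")
    A = np.stack([m.upper_values() for m in group_a])
    B = np.stack([m.upper_values() for m in group_b])
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(A, B, axis=0, equal_var=True)
    degenerate = (A.var(axis=0) == 0) & (B.var(axis=0) == 0)
    t = np.where(degenerate & np.isnan(t), np.nan, t)
    p = np.where(degenerate & np.isnan(p), np.nan, p)
    # identical groups give 0/0 -> nan from scipy; keep t=0 only if means equal
    same_mean = np.isclose(A.mean(axis=0), B.mean(axis=0))
    zerovar = degenerate & same_mean
    t = np.where(zerovar, 0.0, t)
    p = np.where(zerovar, 1.0, p)

    iu, ju = np.triu_indices(n, k=1)
    out = pd.DataFrame({"i": iu, "j": ju, "t": t, "p": p})
    if correction == "bh_fdr":
        q = np.full(len(out), np.nan)
        ok = np.isfinite(out["p"].to_numpy())
        if ok.any():
            q[ok] = multipletests(out["p"].to_numpy()[ok], method="fdr_bh")[1]
        out["q"] = q
    elif correction != "none":
        raise ValueError("correction must be 'none' or 'bh_fdr'")
    return out


# ---------------------------------------------------------------------------
# seed-based summaries


def seedmap(m: ConnectivityMatrix, seed_node: int) -> np.ndarray:
    """Connectivity of one seed node to every other node (own entry NaN)."""
    if not (0 <= seed_node < m.n_nodes):
        raise ValueError(f"seed node {seed_node} outside 0..{m.n_nodes - 1}")
    row = m.values[seed_node].astype(float).copy()
    row[seed_node] = np.nan
    return row


@dataclass
class SeedTargetResult:
    """2 x 2 (seed x target set) repeated-measures interaction test."""

    cell_means: np.ndarray  # 2x2 group means, seeds on rows, target sets on cols
    subject_cells: pd.DataFrame  # per-subject cell values
    interaction_stat: float  # F
    dfs: tuple[int, int]
    p: float


def seed_target_specificity(
    matrices: list[ConnectivityMatrix],
    seed_a: int,
    seed_b: int,
    targets_a: set[int] | list[int],
    targets_b: set[int] | list[int],
) -> SeedTargetResult:
    """Seed-target interaction: does each seed couple preferentially with its
    own target set?

    Per subject, four cell values (mean z from each seed to each target set,
    both seeds excluded from the targets); the seed x target-set interaction
    is tested with a classical 2 x 2 repeated-measures decomposition, which
    for a 2 x 2 within-subject design reduces to a one-sample t test on the
    per-subject interaction contrast.
    """
    ta = set(int(t) for t in targets_a)
    tb = set(int(t) for t in targets_b)
    if seed_a in ta or seed_b in tb:
        raise ValueError("a seed may not belong to its own target set")
    # identical target sets are allowed (the interaction is then trivially 0);
    # partial overlap would make the cells incomparable
    if ta != tb and (ta & tb):
        raise ValueError("target sets must be disjoint (or identical)")
    if len(matrices) < 3:
        raise ValueError("need >= 3 subjects")

    exclude = {seed_a, seed_b}
    ta_idx = sorted(ta - exclude)
    tb_idx = sorted(tb - exclude)
    if not ta_idx or not tb_idx:
        raise ValueError("target sets empty after excluding seeds")

    rows = []
    for m in matrices:
        cells = {
            ("A", "A"): float(np.mean(m.values[seed_a, ta_idx])),
            ("A", "B"): float(np.mean(m.values[seed_a, tb_idx])),
            ("B", "A"): float(np.mean(m.values[seed_b, ta_idx])),
            ("B", "B"): float(np.mean(m.values[seed_b, tb_idx])),
        }
        rows.append(cells)
    table = pd.DataFrame(
        {
            "seedA_targetsA": [r[("A", "A")] for r in rows],
            "seedA_targetsB": [r[("A", "B")] for r in rows],
            "seedB_targetsA": [r[("B", "A")] for r in rows],
            "seedB_targetsB": [r[("B", "B")] for r in rows],
        }
    )
    contrast = (
        table["seedA_targetsA"]
        - table["seedA_targetsB"]
        - table["seedB_targetsA"]
        + table["seedB_targetsB"]
    ).to_numpy()
    n = len(contrast)
    sd = contrast.std(ddof=1)
    if sd == 0:
        f_val, p_val = 0.0, 1.0
    else:
        t_val = contrast.mean() / (sd / np.sqrt(n))
        f_val = float(t_val**2)
        p_val = float(stats.f.sf(f_val, 1, n - 1))
    cell_means = np.array(
        [
            [table["seedA_targetsA"].mean(), table["seedA_targetsB"].mean()],
            [table["seedB_targetsA"].mean(), table["seedB_targetsB"].mean()],
        ]
    )
    return SeedTargetResult(
        cell_means=cell_means,
        subject_cells=table,
        interaction_stat=f_val,
        dfs=(1, n - 1),
        p=p_val,
    )
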