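"""Synthetic parcellations and cohorts with planted modular correlation structure.

The generator plants everything the downstream analysis is supposed to find:
block-modular correlations (stronger within- than between-system), a
distance-dependent decay of coupling, an age-dependent rise of between-system
coupling (dedifferentiation), additive per-site offsets, and longitudinal
repeats.  Ground-truth parameters are returned alongside the data so recovery
tests can compare fitted quantities against what was planted.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .networks import SubjectTimeseries

logger = logging.getLogger(__name__)

UNASSIGNED = -1

#: diagonal-loading amounts tried, in order, when repairing a non-PD covariance
_LOADING_GRID = tuple(10.0 ** k for k in range(-8, -1))


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of a synthetic cohort.

    Off-diagonal target correlations are
    ``base * exp(-distance / distance_decay_scale) + site offset`` where
    ``base`` is ``within_r`` for same-system pairs and
    ``between_r_base + between_r_age_slope * age_norm`` otherwise, with age
    normalized to [0, 1] over the design's age range.
    """

    n_nodes: int = 40
    n_systems: int = 4
    frames_per_scan: int = 200
    within_r: float = 0.55
    between_r_base: float = 0.15
    between_r_age_slope: float = 0.10
    distance_decay_scale: float = math.inf
    site_shift: float = 0.0
    sites: tuple[str, ...] = ("siteA",)
    ages: tuple[float, ...] = tuple(float(a) for a in range(3, 21))
    sessions_per_subject: int = 1
    session_age_step: float = 3.0
    species: str = "mouse"
    species_preset: str = "mouse-like"
    spatial_scale: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ages:
            raise ValueError("ages must be nonempty")
        if self.sessions_per_subject < 1:
            raise ValueError("sessions_per_subject must be >= 1")
        if not (0.0 < self.within_r < 1.0):
            raise ValueError("within_r must lie in (0, 1)")
        if not (0.0 <= self.between_r_base < self.within_r):
            raise ValueError("between_r_base must lie in [0, within_r)")
        max_between = self.between_r_base + self.between_r_age_slope * max(
            self.normalize_age(a) for a in self.realized_ages()
        )
        if self.within_r <= max_between:
            raise ValueError(
                "within_r must exceed the between-system correlation at the "
                f"oldest age ({max_between:.3f}); blocks must stay dominant"
            )

    # -- age bookkeeping -------------------------------------------------
    def age_range(self) -> tuple[float, float]:
        return min(self.ages), max(self.ages)

    def normalize_age(self, age: float) -> float:
        """Map a native-unit age onto [0, 1] over the design's stated range.

        Longitudinal follow-up sessions may extend slightly past the maximum
        baseline age; those map above 1 by the same affine rule.
        """
        lo, hi = self.age_range()
        if hi == lo:
            return 0.0
        return (age - lo) / (hi - lo)

    def realized_ages(self) -> list[float]:
        """All scan ages implied by baseline ages plus session follow-ups."""
        return [
            a + k * self.session_age_step
            for a in self.ages
            for k in range(self.sessions_per_subject)
        ]

    def site_offsets(self) -> dict[str, float]:
        """Additive correlation offset per site; the first site is reference."""
        return {s: (0.0 if i == 0 else self.site_shift) for i, s in enumerate(self.sites)}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ages"] = list(self.ages)
        d["sites"] = list(self.sites)
        return d


def mouse_like(**overrides) -> SyntheticDesign:
    """Mouse-like preset: compact brain, strong distance decay, shallow
    dedifferentiation slope, ages in months over 3-20 mo adulthood."""
    params: dict = dict(
        n_nodes=40,
        n_systems=4,
        within_r=0.55,
        between_r_base=0.15,
        between_r_age_slope=0.10,
        distance_decay_scale=6.0,
        spatial_scale=4.0,
        ages=tuple(float(a) for a in range(3, 21)),
        session_age_step=3.0,
        species="mouse",
        species_preset="mouse-like",
    )
    params.update(overrides)
    return SyntheticDesign(**params)


def human_like(**overrides) -> SyntheticDesign:
    """Human-like preset: large brain, weak distance decay relative to its
    extent, steeper dedifferentiation slope, ages in years over 18-88 y."""
    params: dict = dict(
        n_nodes=40,
        n_systems=4,
        within_r=0.45,
        between_r_base=0.18,
        between_r_age_slope=0.16,
        distance_decay_scale=200.0,
        spatial_scale=30.0,
        ages=tuple(float(a) for a in range(18, 89, 2)),
        session_age_step=2.0,
        species="human",
        species_preset="human-like",
    )
    params.update(overrides)
    return SyntheticDesign(**params)


# ---------------------------------------------------------------------------
# parcellation


def generate_parcellation(design: SyntheticDesign) -> pd.DataFrame:
    """Generate a mirrored synthetic parcellation as a node table.

    Systems are spatially contiguous clusters: system centers sit on a circle
    of radius ``spatial_scale`` in the (y, z) plane, slightly lateral of the
    midline, and each left-hemisphere node is jittered around its system
    center and mirrored to the right hemisphere (x -> -x).

    Returns a DataFrame with columns node_id, name, hemisphere, x, y, z,
    system.
    """
    n, k = design.n_nodes, design.n_systems
    if k < 2:
        raise ValueError("n_systems must be >= 2 (segregation is undefined with one system)")
    if n % 2 != 0:
        raise ValueError("n_nodes must be even for hemispheric mirroring")
    if n < 2 * k:
        raise ValueError("n_nodes must be >= 2 * n_systems")

    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0x9A7C]))
    n_half = n // 2
    # near-equal split of left-hemisphere nodes over systems
    left_counts = np.full(k, n_half // k, dtype=int)
    left_counts[: n_half % k] += 1

    s = design.spatial_scale
    angles = 2.0 * math.pi * np.arange(k) / k
    centers = np.column_stack(
        [np.full(k, 0.35 * s), s * np.cos(angles), s * np.sin(angles)]
    )

    rows = []
    node_id = 0
    for sys_idx in range(k):
        for j in range(left_counts[sys_idx]):
            jitter = rng.normal(scale=0.15 * s, size=3)
            x, y, z = centers[sys_idx] + jitter
            x = abs(x)  # keep the left cluster strictly lateral
            label = f"sys{sys_idx + 1}"
            rows.append((node_id, f"{label}_L_{j:02d}", "L", x, y, z, label))
            rows.append((node_id + 1, f"{label}_R_{j:02d}", "R", -x, y, z, label))
            node_id += 2
    nodes = pd.DataFrame(
        rows, columns=["node_id", "name", "hemisphere", "x", "y", "z", "system"]
    )
    return nodes.sort_values("node_id", ignore_index=True)


def node_centroids(nodes: pd.DataFrame) -> np.ndarray:
    return nodes[["x", "y", "z"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# population covariance


def build_population_covariance(
    nodes: pd.DataFrame,
    design: SyntheticDesign,
    age: float,
    site: str | None = None,
) -> np.ndarray:
    """Target node-by-node correlation matrix for one (age, site) condition.

    ``age`` is normalized age in [0, 1].  Positive definiteness is repaired,
    if needed, by the smallest diagonal loading from a fixed grid; the amount
    used is logged.
    """
    if nodes["system"].isna().any() or (nodes["system"] == "").any():
        raise ValueError("all nodes must carry a system label")
    systems = nodes["system"].to_numpy()
    same_system = systems[:, None] == systems[None, :]

    xyz = node_centroids(nodes)
    dist = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)

    between_r = design.between_r_base + design.between_r_age_slope * age
    base = np.where(same_system, design.within_r, between_r)
    if math.isfinite(design.distance_decay_scale):
        base = base * np.exp(-dist / design.distance_decay_scale)

    offset = 0.0
    if site is not None:
        offsets = design.site_offsets()
        if site not in offsets:
            raise ValueError(f"unknown site {site!r}; design sites are {design.sites}")
        offset = offsets[site]

    cov = np.clip(base + offset, -0.99, 0.99)
    np.fill_diagonal(cov, 1.0)
    cov = (cov + cov.T) / 2.0
    return _ensure_positive_definite(cov)


def _is_positive_definite(m: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(m)
        return True
    except np.linalg.LinAlgError:
        return False


def _ensure_positive_definite(cov: np.ndarray) -> np.ndarray:
    if _is_positive_definite(cov):
        return cov
    for lam in _LOADING_GRID:
        repaired = (cov + lam * np.eye(cov.shape[0])) / (1.0 + lam)
        if _is_positive_definite(repaired):
            logger.info("covariance repaired with diagonal loading %.0e", lam)
            return repaired
    raise ValueError(
        "covariance not positive definite even after maximum diagonal loading "
        f"({_LOADING_GRID[-1]:.0e})"
    )


# ---------------------------------------------------------------------------
# timeseries


def simulate_subject_timeseries(
    covariance: np.ndarray,
    n_frames: int,
    seed: int | np.random.SeedSequence,
    scan_id: str = "scan",
    subject_id: str = "subject",
    meta: Mapping | None = None,
) -> SubjectTimeseries:
    """Draw a node x frame timeseries from a zero-mean multivariate normal."""
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    cov = np.asarray(covariance, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if not np.allclose(cov, cov.T):
        raise ValueError("covariance must be symmetric")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be positive definite") from exc
    if n_frames < 3:
        logger.warning(
            "n_frames=%d: sample correlations are rank-deficient (entries +/-1)",
            n_frames,
        )
    rng = np.random.default_rng(seed)
    data = chol @ rng.standard_normal((cov.shape[0], n_frames))
    return SubjectTimeseries(
        scan_id=scan_id,
        subject_id=subject_id,
        data=data,
        keep_mask=np.ones(n_frames, dtype=bool),
        meta=dict(meta or {}),
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class Cohort:
    """A generated cohort: parcellation, scans, metadata, and planted truth."""

    nodes: pd.DataFrame
    timeseries: list[SubjectTimeseries]
    table: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def __iter__(self):
        # (nodes, timeseries, table) unpacking for pipeline convenience
        return iter((self.nodes, self.timeseries, self.table))


def generate_cohort(design: SyntheticDesign) -> Cohort:
    """Generate one scan per subject x session, with planted structure.

    One subject per entry of ``design.ages``; subjects with more than one
    session age forward by ``session_age_step`` per follow-up (longitudinal).
    Sex alternates across subjects (a null covariate: nothing is planted on
    it) and sites rotate round-robin.
    """
    nodes = generate_parcellation(design)
    n_subjects = len(design.ages)
    n_scans = n_subjects * design.sessions_per_subject
    seed_seq = np.random.SeedSequence([design.seed, 0xC047])
    scan_seeds = seed_seq.generate_state(n_scans, dtype=np.uint32)

    cov_cache: dict[tuple[float, str], np.ndarray] = {}
    timeseries: list[SubjectTimeseries] = []
    rows = []
    scan_idx = 0
    for subj_idx, baseline_age in enumerate(design.ages):
        subject_id = f"{design.species}-{subj_idx:03d}"
        sex = "F" if subj_idx % 2 == 0 else "M"
        # rotate sites in blocks of two so site is not collinear with sex
        site = design.sites[(subj_idx // 2) % len(design.sites)]
        for session in range(design.sessions_per_subject):
            age = baseline_age + session * design.session_age_step
            key = (age, site)
            if key not in cov_cache:
                cov_cache[key] = build_population_covariance(
                    nodes, design, design.normalize_age(age), site
                )
            scan_id = f"{subject_id}_ses-{session + 1:02d}"
            meta = {
                "species": design.species,
                "age": age,
                "age_units": "months" if design.species == "mouse" else "years",
                "sex": sex,
                "site": site,
                "session": session + 1,
            }
            ts = simulate_subject_timeseries(
                cov_cache[key],
                design.frames_per_scan,
                int(scan_seeds[scan_idx]),
                scan_id=scan_id,
                subject_id=subject_id,
                meta=meta,
            )
            timeseries.append(ts)
            rows.append(
                dict(
                    scan_id=scan_id,
                    subject_id=subject_id,
                    species=design.species,
                    age=age,
                    sex=sex,
                    site=site,
                    session=session + 1,
                )
            )
            scan_idx += 1

    table = pd.DataFrame(rows)
    ages = sorted(set(design.realized_ages()))
    truth = {
        "design": design.to_dict(),
        "planted_segregation_by_age": {
            str(a): planted_segregation(nodes, design, a) for a in ages
        },
        "implied_age_slope": implied_age_slope(
            design, table["age"].to_numpy(), n_frames=design.frames_per_scan
        ),
        "implied_age_slope_population": implied_age_slope(design, table["age"].to_numpy()),
    }
    return Cohort(nodes=nodes, timeseries=timeseries, table=table, truth=truth)


# ---------------------------------------------------------------------------
# planted (closed-form) quantities


def planted_segregation(
    nodes: pd.DataFrame,
    design: SyntheticDesign,
    age: float,
    site: str | None = None,
) -> float:
    """Population system segregation implied by the design at a native age.

    Computed directly from the target covariance: Fisher z of the planted
    correlations, negatives zeroed, averaged over within- vs between-system
    node pairs under the planted labels.
    """
    cov = build_population_covariance(nodes, design, design.normalize_age(age), site)
    z = np.arctanh(np.clip(cov, -0.999999, 0.999999))
    np.fill_diagonal(z, 0.0)
    z = np.maximum(z, 0.0)
    systems = nodes["system"].to_numpy()
    same = systems[:, None] == systems[None, :]
    iu = np.triu_indices(len(nodes), k=1)
    within = z[iu][same[iu]]
    between = z[iu][~same[iu]]
    zw, zb = within.mean(), between.mean()
    return float((zw - zb) / zw)


def expected_measured_segregation(
    nodes: pd.DataFrame,
    design: SyntheticDesign,
    age: float,
    site: str | None = None,
    n_frames: int | None = None,
) -> float:
    """Expected segregation of a scan measured with ``n_frames`` frames.

    At finite frame counts the sample Fisher z of an edge is approximately
    normal around the planted value with standard deviation 1/sqrt(t - 3);
    zeroing negatives therefore inflates near-zero edges by the expectation of
    a censored normal, E[max(z, 0)] = mu * Phi(mu/sigma) + sigma * phi(mu/sigma).
    This closed form gives the estimand a linear model fitted on measured
    per-scan segregation actually targets.  With ``n_frames=None`` (or large)
    it reduces to :func:`planted_segregation`.
    """
    if n_frames is None:
        return planted_segregation(nodes, design, age, site)
    from scipy.stats import norm

    cov = build_population_covariance(nodes, design, design.normalize_age(age), site)
    mu = np.arctanh(np.clip(cov, -0.999999, 0.999999))
    sigma = 1.0 / math.sqrt(n_frames - 3)
    zeroed = mu * norm.cdf(mu / sigma) + sigma * norm.pdf(mu / sigma)
    systems = nodes["system"].to_numpy()
    same = systems[:, None] == systems[None, :]
    iu = np.triu_indices(len(nodes), k=1)
    zw = zeroed[iu][same[iu]].mean()
    zb = zeroed[iu][~same[iu]].mean()
    return float((zw - zb) / zw)


def implied_age_slope(
    design: SyntheticDesign,
    ages: Sequence[float],
    n_frames: int | None = None,
) -> float:
    """Generator-implied linear age slope of segregation over given scan ages.

    The estimand of a linear age model: the population least-squares slope of
    expected segregation regressed on age over the cohort's age distribution.
    With ``n_frames`` set, expectations account for finite-frame measurement
    (see :func:`expected_measured_segregation`).
    """
    nodes = generate_parcellation(design)
    ages = np.asarray(ages, dtype=float)
    seg = np.array(
        [expected_measured_segregation(nodes, design, a, n_frames=n_frames) for a in ages]
    )
    a = ages - ages.mean()
    denom = float(a @ a)
    if denom == 0.0:
        return float("nan")  # slope undefined with a single distinct age
    return float(a @ (seg - seg.mean()) / denom)


# ---------------------------------------------------------------------------
# on-disk representation


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort as tab-delimited text plus a ground-truth JSON sidecar."""
    from . import io as sio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sio.write_node_table(cohort.nodes, out / "nodes.tsv")
    sio.write_cohort_table(cohort.table, out / "cohort.tsv")
    ts_dir = out / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for ts in cohort.timeseries:
        sio.write_timeseries(ts, ts_dir / f"{ts.scan_id}.tsv")
    (out / "ground_truth.json").write_text(json.dumps(cohort.truth, indent=2))
    return out
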