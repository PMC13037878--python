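"""End-to-end orchestration: simulate -> networks -> harmonize -> communities
-> segregation -> distance -> trajectory, driven by a YAML config.

Each stage reads only files produced by earlier stages and writes its own
outputs under the run directory, so deleting later-stage outputs and re-running
reproduces them.  All randomness derives from the global seed by stable
hashing of stage names; deterministic stages are byte-identical across reruns
with the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from . import synth
from .communities import consensus_partition, default_densities, density_sweep
from .distance import classify_between_edges, distance_stratified_summary
from .harmonize import CovBat, edges_to_matrices, matrices_to_edges
from .networks import (
    ConnectivityMatrix,
    ScanRejected,
    censor_and_equate,
    connectivity_matrix,
    group_average,
)
from .segregation import system_segregation, within_between_means
from .stats import AgeMapping, cross_species_model, fit_age_trajectory

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "paths": {"data_dir": "data", "out_dir": "results"},
    "network": {
        "target_frames": None,  # default: min kept frames across scans
        "equate_method": "truncate",
        "densities": None,  # default: 0.005..0.20 step 0.005
        "reference_density": 0.07,
        "min_size": 4,
        "method": "map_equation",
        "n_restarts": 20,
        "negatives": "zero",
        "young_max_age": None,  # default: min age + 10% of range
    },
    "harmonization": {
        "enabled": True,
        "mode": "covbat",
        "pc_variance": 0.90,
        "empirical_bayes": True,
    },
    "age_mapping": {
        "mouse_anchor_young": 3.0,
        "human_anchor_young": 18.0,
        "mouse_anchor_old": 20.0,
        "human_anchor_old": 70.0,
    },
    "seed": 0,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file over the documented defaults."""

    def merge(base: dict, upd: dict) -> dict:
        out = dict(base)
        for k, v in (upd or {}).items():
            out[k] = merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
        return out

    config = DEFAULT_CONFIG
    if path is not None:
        config = merge(config, yaml.safe_load(Path(path).read_text()) or {})
    return merge(config, overrides or {})


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (zlib.crc32(stage.encode()) ^ int(global_seed)) % (2**31 - 1)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: dict, design: synth.SyntheticDesign | None = None) -> Path:
    """Generate a synthetic cohort into the configured data directory."""
    if design is None:
        sim = config.get("simulate", {})
        preset = sim.get("preset", "mouse-like")
        factory = synth.mouse_like if preset == "mouse-like" else synth.human_like
        overrides = dict(sim.get("overrides", {}))
        for key in ("ages", "sites"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        overrides.setdefault("seed", stage_seed(config["seed"], "simulate"))
        design = factory(**overrides)
    cohort = synth.generate_cohort(design)
    return synth.write_cohort(cohort, config["paths"]["data_dir"])


def load_inputs(config: dict):
    data_dir = Path(config["paths"]["data_dir"])
    nodes = sio.read_node_table(data_dir / "nodes.tsv")
    table = sio.read_cohort_table(data_dir / "cohort.tsv")
    timeseries = [
        sio.read_timeseries(data_dir / "timeseries" / f"{scan_id}.tsv")
        for scan_id in table["scan_id"]
    ]
    return nodes, table, timeseries


def stage_networks(config: dict) -> Path:
    """Frame-equated Fisher-z matrices per scan, plus the YA group average."""
    net = config["network"]
    nodes, table, timeseries = load_inputs(config)
    out = Path(config["paths"]["out_dir"])
    mat_dir = out / "matrices"
    mat_dir.mkdir(parents=True, exist_ok=True)

    target = net["target_frames"] or min(ts.n_kept for ts in timeseries)
    seed = stage_seed(config["seed"], "networks")
    kept_rows, matrices = [], {}
    for ts, (_, row) in zip(timeseries, table.iterrows()):
        try:
            eq = censor_and_equate(ts, target, method=net["equate_method"], seed=seed)
            m = connectivity_matrix(eq)
        except ScanRejected as exc:
            logger.warning("dropping scan: %s", exc)
            continue
        matrices[ts.scan_id] = m
        kept_rows.append(row)
        sio.write_dense_matrix(m, mat_dir / f"{ts.scan_id}.tsv")
    if not matrices:
        raise RuntimeError("stage networks: every scan was rejected")
    kept = pd.DataFrame(kept_rows).reset_index(drop=True)
    sio.write_cohort_table(kept, out / "cohort_kept.tsv")

    ya_mask = _young_mask(kept, net.get("young_max_age"))
    ya = group_average([matrices[s] for s in kept.loc[ya_mask, "scan_id"]])
    sio.write_dense_matrix(ya, out / "group_avg_ya.tsv")
    return out


def _young_mask(table: pd.DataFrame, young_max_age: float | None) -> np.ndarray:
    ages = table["age"].to_numpy(dtype=float)
    if young_max_age is None:
        young_max_age = ages.min() + 0.10 * (ages.max() - ages.min())
    mask = ages <= young_max_age
    if not mask.any():
        mask = ages == ages.min()
    return mask


def stage_harmonize(config: dict) -> Path:
    """CovBat-harmonize per-scan matrices across sites (batch = site)."""
    out = Path(config["paths"]["out_dir"])
    kept = sio.read_cohort_table(out / "cohort_kept.tsv")
    matrices = [
        sio.read_dense_matrix(out / "matrices" / f"{s}.tsv") for s in kept["scan_id"]
    ]
    har = config["harmonization"]
    harm_dir = out / "matrices_harmonized"
    harm_dir.mkdir(parents=True, exist_ok=True)
    n_sites = kept["site"].nunique()
    if not har["enabled"] or n_sites < 2:
        if har["enabled"] and n_sites < 2:
            logger.info("single site: harmonization is a no-op")
        for scan_id, m in zip(kept["scan_id"], matrices):
            sio.write_dense_matrix(m, harm_dir / f"{scan_id}.tsv")
        sio.write_json({"harmonized": False, "n_sites": int(n_sites)}, out / "harmonization.json")
        return out

    edges = matrices_to_edges(matrices)
    covariates = np.column_stack(
        [
            kept["age"].to_numpy(dtype=float),
            kept["sex"].astype(str).str.upper().map({"F": -0.5, "M": 0.5}).to_numpy(),
        ]
    )
    model = CovBat(
        mode=har["mode"],
        pc_variance=har["pc_variance"],
        empirical_bayes=har["empirical_bayes"],
    )
    harmonized = model.fit_transform(edges, batch=kept["site"].to_numpy(), covariates=covariates)
    n = matrices[0].n_nodes
    for scan_id, row in zip(kept["scan_id"], harmonized):
        m = edges_to_matrices(row[None, :], n)[0]
        sio.write_dense_matrix(m, harm_dir / f"{scan_id}.tsv")
    summary = {
        "harmonized": True,
        "mode": har["mode"],
        "pc_variance": har["pc_variance"],
        "empirical_bayes": har["empirical_bayes"],
        "batches": model.batches_,
        "protected_covariates": ["age", "sex"],
    }
    if har["mode"] == "covbat":
        summary["n_components"] = int(model.n_components_)
    sio.write_json(summary, out / "harmonization.json")

    net = config["network"]
    ya_mask = _young_mask(kept, net.get("young_max_age"))
    harm_mats = [
        sio.read_dense_matrix(harm_dir / f"{s}.tsv") for s in kept.loc[ya_mask, "scan_id"]
    ]
    sio.write_dense_matrix(group_average(harm_mats), out / "group_avg_ya.tsv")
    return out


def _matrix_dir(out: Path) -> Path:
    harm = out / "matrices_harmonized"
    return harm if harm.exists() else out / "matrices"


def stage_communities(config: dict) -> Path:
    """Density sweep plus consensus labels on the YA group-average matrix."""
    net = config["network"]
    out = Path(config["paths"]["out_dir"])
    ya = sio.read_dense_matrix(out / "group_avg_ya.tsv")
    densities = net["densities"] or default_densities()
    seed = stage_seed(config["seed"], "communities")
    sweep = density_sweep(
        ya, densities, seed=seed, method=net["method"], n_restarts=net["n_restarts"]
    )
    part_dir = out / "partitions"
    part_dir.mkdir(parents=True, exist_ok=True)
    index = []
    for p in sweep:
        fname = f"density_{p.density:.3f}.tsv"
        sio.write_partition(p, part_dir / fname)
        index.append(
            {
                "density": p.density,
                "file": fname,
                "n_communities": p.n_communities,
                "quality": p.quality,
            }
        )
    consensus = consensus_partition(
        sweep, ya, min_size=net["min_size"], reference_density=net["reference_density"]
    )
    sio.write_partition(consensus, part_dir / "consensus.tsv")
    sio.write_json(
        {
            "method": net["method"],
            "reference_density": net["reference_density"],
            "min_size": net["min_size"],
            "densities": index,
            "consensus_n_communities": consensus.n_communities,
        },
        part_dir / "index.json",
    )
    return out


def stage_segregate(config: dict) -> Path:
    """Per-scan segregation and within/between means under consensus labels."""
    out = Path(config["paths"]["out_dir"])
    kept = sio.read_cohort_table(out / "cohort_kept.tsv")
    partition = sio.read_partition(out / "partitions" / "consensus.tsv")
    negatives = config["network"]["negatives"]
    mdir = _matrix_dir(out)
    seg, zw, zb = [], [], []
    for scan_id in kept["scan_id"]:
        m = sio.read_dense_matrix(mdir / f"{scan_id}.tsv")
        w, b = within_between_means(m, partition, negatives=negatives)
        seg.append(system_segregation(m, partition, negatives=negatives))
        zw.append(w)
        zb.append(b)
    kept["segregation"] = seg
    kept["mean_within_z"] = zw
    kept["mean_between_z"] = zb
    sio.write_cohort_table(kept, out / "cohort_metrics.tsv")
    return out


def stage_distance(config: dict) -> Path:
    """Short/long-range classification of between-system edges + summaries."""
    out = Path(config["paths"]["out_dir"])
    nodes = sio.read_node_table(Path(config["paths"]["data_dir"]) / "nodes.tsv")
    partition = sio.read_partition(out / "partitions" / "consensus.tsv")
    dc = classify_between_edges(nodes, partition)
    dc.edges.to_csv(out / "distance_classification.tsv", sep="\t", index=False, float_format="%.6f")
    ya = sio.read_dense_matrix(out / "group_avg_ya.tsv")
    summary = distance_stratified_summary(ya, dc)
    summary.update({"threshold_mm": dc.threshold, "max_distance_mm": dc.max_distance})
    sio.write_json(summary, out / "distance_summary.json")
    return out


def stage_trajectory(config: dict) -> Path:
    """Mixed-model age trajectory of segregation (and companion means)."""
    out = Path(config["paths"]["out_dir"])
    table = sio.read_cohort_table(out / "cohort_metrics.tsv")
    results = {
        response: fit_age_trajectory(table, response=response)
        for response in ("segregation", "mean_within_z", "mean_between_z")
    }
    sio.write_json(results, out / "trajectory.json")
    return out


def run_cross_species(
    mouse_metrics: str | Path,
    human_metrics: str | Path,
    config: dict,
    out_path: str | Path,
) -> dict:
    """Cross-species interaction model from two cohort metric tables."""
    mapping = AgeMapping(**config["age_mapping"])
    mouse = sio.read_cohort_table(mouse_metrics)
    human = sio.read_cohort_table(human_metrics)
    result = cross_species_model(mouse, human, mapping=mapping)
    sio.write_json(result, out_path)
    return result


STAGES = {
    "networks": stage_networks,
    "harmonize": stage_harmonize,
    "communities": stage_communities,
    "segregate": stage_segregate,
    "distance": stage_distance,
    "trajectory": stage_trajectory,
}


def run_pipeline(config: dict, simulate: bool = False) -> Path:
    """Run every stage in order and write provenance; returns the out dir."""
    out = Path(config["paths"]["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    if simulate:
        stage_simulate(config)
    for name, fn in STAGES.items():
        logger.info("stage %s", name)
        try:
            fn(config)
        except Exception as exc:
            raise RuntimeError(f"pipeline halted at stage {name!r}: {exc}") from exc
    from . import __version__

    sio.write_json(
        {
            "config": config,
            "config_hash": _config_hash(config),
            "seed": config["seed"],
            "version": __version__,
        },
        out / "provenance.json",
    )
    return out
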