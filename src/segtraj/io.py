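"""Delimited-text readers and writers for every on-disk artifact.

Everything is plain tab-delimited text or JSON: node and cohort tables with a
header row, one nodes x frames matrix file per scan, dense matrices with
node-labeled columns, 3-column sparse edge lists for thresholded matrices, and
2-column partition files (unassigned nodes as -1).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .communities import Partition
from .networks import ConnectivityMatrix, SubjectTimeseries

_FLOAT_FMT = "%.10g"

NODE_COLUMNS = ["node_id", "name", "hemisphere", "x", "y", "z", "system"]


def write_node_table(nodes: pd.DataFrame, path: str | Path) -> None:
    nodes[NODE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_node_table(path: str | Path) -> pd.DataFrame:
    nodes = pd.read_csv(path, sep="\t")
    missing = set(NODE_COLUMNS[:-1]) - set(nodes.columns)
    if missing:
        raise ValueError(f"node table lacks column(s) {sorted(missing)}")
    if "system" not in nodes.columns:
        nodes["system"] = ""
    return nodes


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_timeseries(ts: SubjectTimeseries, path: str | Path) -> None:
    header = json.dumps(
        {"scan_id": ts.scan_id, "subject_id": ts.subject_id, "meta": ts.meta}
    )
    np.savetxt(path, ts.kept_data(), fmt=_FLOAT_FMT, delimiter="\t", header=header)


def read_timeseries(path: str | Path) -> SubjectTimeseries:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    info = {"scan_id": path.stem, "subject_id": path.stem, "meta": {}}
    if first.startswith("#"):
        try:
            info.update(json.loads(first[1:].strip()))
        except json.JSONDecodeError:
            pass
    data = np.loadtxt(path, delimiter="\t")
    return SubjectTimeseries(
        scan_id=info["scan_id"],
        subject_id=info["subject_id"],
        data=np.atleast_2d(data),
        keep_mask=np.ones(np.atleast_2d(data).shape[1], dtype=bool),
        meta=info.get("meta", {}),
    )


def write_dense_matrix(m: ConnectivityMatrix, path: str | Path) -> None:
    cols = [f"n{i}" for i in range(m.n_nodes)]
    pd.DataFrame(m.values, columns=cols).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_dense_matrix(path: str | Path, meta: dict | None = None) -> ConnectivityMatrix:
    values = pd.read_csv(path, sep="\t").to_numpy(dtype=float)
    return ConnectivityMatrix(values=values, meta=meta or {})


def write_sparse_edges(m: ConnectivityMatrix, path: str | Path) -> None:
    iu, ju = np.triu_indices(m.n_nodes, k=1)
    w = m.values[iu, ju]
    keep = w != 0
    df = pd.DataFrame({"i": iu[keep], "j": ju[keep], "z": w[keep]})
    with open(path, "w") as fh:
        fh.write(f"# n_nodes={m.n_nodes}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_sparse_edges(path: str | Path) -> ConnectivityMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# n_nodes="):
        raise ValueError("sparse edge list must start with a '# n_nodes=' line")
    n = int(first.split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    values = np.zeros((n, n))
    values[df["i"].to_numpy(), df["j"].to_numpy()] = df["z"].to_numpy()
    values += values.T
    return ConnectivityMatrix(values=values)


def write_partition(p: Partition, path: str | Path) -> None:
    df = pd.DataFrame({"node_id": np.arange(p.n_nodes), "community_label": p.labels})
    with open(path, "w") as fh:
        fh.write(
            f"# density={p.density:.6g} method={p.method} quality={p.quality:.10g} "
            f"seed={p.seed}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_partition(path: str | Path) -> Partition:
    with open(path) as fh:
        first = fh.readline().strip()
    meta = dict(
        item.split("=", 1) for item in first.lstrip("# ").split() if "=" in item
    )
    df = pd.read_csv(path, sep="\t", comment="#")
    return Partition(
        labels=df["community_label"].to_numpy(dtype=int),
        density=float(meta.get("density", np.nan)),
        quality=float(meta.get("quality", np.nan)),
        method=meta.get("method", "unknown"),
        seed=int(meta.get("seed", 0)),
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
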