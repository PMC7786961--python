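"""Plain-text readers and writers for every pipeline artifact.

All formats are tab-delimited text so intermediate results interoperate
with spreadsheet tools and R: time series as frames x ROIs with a label
header, matrices square with a label header (plus a long-format variant),
partitions and tables as TSV, configs as flat key-value files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .communities import Partition
from .scrub import SubjectTimeSeries


def write_timeseries(path: str | Path, ts: SubjectTimeSeries, labels: list[str]) -> None:
    df = pd.DataFrame(ts.data, columns=labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_timeseries(
    path: str | Path, subject_id: str, tr_seconds: float,
    fd: np.ndarray | None = None, dvars: np.ndarray | None = None,
) -> SubjectTimeSeries:
    df = pd.read_csv(path, sep="\t")
    n = len(df)
    z = np.zeros(n)
    return SubjectTimeSeries(
        subject_id=subject_id, data=df.to_numpy(float), tr_seconds=tr_seconds,
        fd=z if fd is None else fd, dvars=z if dvars is None else dvars,
    )


def write_motion(path: str | Path, fd: np.ndarray, dvars: np.ndarray) -> None:
    pd.DataFrame({"fd_mm": fd, "dvars_pct": dvars}).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_motion(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return df["fd_mm"].to_numpy(float), df["dvars_pct"].to_numpy(float)


def write_matrix(path: str | Path, mat: np.ndarray, labels: list[str]) -> None:
    pd.DataFrame(mat, columns=labels).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(float), list(df.columns)


def write_matrix_long(path: str | Path, mat: np.ndarray) -> None:
    """Long-format upper triangle: node_i, node_j, weight."""
    iu, ju = np.triu_indices(mat.shape[0], k=1)
    pd.DataFrame({"node_i": iu, "node_j": ju, "weight": mat[iu, ju]}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_partition(path: str | Path, part: Partition, labels: list[str]) -> None:
    pd.DataFrame({
        "node_id": np.arange(part.n_nodes),
        "label": labels,
        "community": part.labels,
    }).to_csv(path, sep="\t", index=False)


def read_partition(path: str | Path, level: str = "group", gamma: float = np.nan) -> Partition:
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("node_id")
    return Partition(labels=df["community"].to_numpy(int), level=level, gamma=gamma)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_config(path: str | Path, params: dict) -> None:
    """Flat key=value file (one pair per line)."""
    with open(path, "w") as fh:
        for k, v in params.items():
            fh.write(f"{k}={v}\n")


def read_config(path: str | Path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            k, _, v = line.partition("=")
            out[k.strip()] = v.strip()
    return out
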