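"""Plain-text I/O: dense matrix TSV, long-format trajectories, edge lists."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .netsim import TrajectoryEnsemble


def node_names(n: int) -> list[str]:
    return [f"G{i + 1}" for i in range(n)]


def write_matrix_tsv(path: str | Path, M: np.ndarray, names: list[str] | None = None) -> None:
    """Dense matrix as TSV; rows are target nodes i, columns source nodes j."""
    M = np.asarray(M)
    names = names or node_names(M.shape[0])
    pd.DataFrame(M, index=names, columns=names).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got {df.shape}")
    return df.to_numpy(dtype=float)


def write_edge_list(path: str | Path, adjacency: np.ndarray, names: list[str] | None = None) -> None:
    """DREAM5-style 3-column edge list (source, target, 1); A[i, j] is arc j -> i."""
    A = np.asarray(adjacency)
    names = names or node_names(A.shape[0])
    rows = [
        (names[j], names[i], 1)
        for i, j in zip(*np.nonzero(A))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_edge_list(path: str | Path, names: list[str]) -> np.ndarray:
    """Edge list back into an adjacency with A[i, j] = arc j -> i."""
    idx = {name: k for k, name in enumerate(names)}
    n = len(names)
    A = np.zeros((n, n), dtype=int)
    df = pd.read_csv(path, sep="\t", header=None)
    for src, dst in zip(df[0], df[1]):
        A[idx[str(dst)], idx[str(src)]] = 1
    return A


def write_ensemble_tsv(path: str | Path, ens: TrajectoryEnsemble) -> None:
    """Long-format TSV: ensemble_id, perturbed_param, time, node, value."""
    names = node_names(ens.n)
    frames = []

    def block(ens_id: str, param: int, traj: np.ndarray) -> pd.DataFrame:
        T, n = traj.shape
        return pd.DataFrame(
            {
                "ensemble_id": ens_id,
                "perturbed_param": param,
                "time": np.repeat(ens.times, n),
                "node": np.tile(names, T),
                "value": traj.ravel(),
            }
        )

    frames.append(block("baseline", -1, ens.baseline))
    for k, _ in ens.design:
        frames.append(block(f"pert{k}", k, ens.perturbed[k]))
    if ens.null_run is not None:
        frames.append(block("null", -1, ens.null_run))
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_ensemble_tsv(path: str | Path, design: list[tuple[int, float]], noise_sigma: float = 0.0) -> TrajectoryEnsemble:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    times = np.sort(df["time"].unique())
    names = sorted(df["node"].unique(), key=lambda s: int(s[1:]))

    def pivot(sub: pd.DataFrame) -> np.ndarray:
        return (
            sub.pivot(index="time", columns="node", values="value")[names]
            .sort_index()
            .to_numpy(dtype=float)
        )

    baseline = pivot(df[df.ensemble_id == "baseline"])
    perturbed = [pivot(df[df.ensemble_id == f"pert{k}"]) for k, _ in design]
    null_df = df[df.ensemble_id == "null"]
    null_run = pivot(null_df) if len(null_df) else None
    return TrajectoryEnsemble(
        times=times,
        baseline=baseline,
        perturbed=perturbed,
        design=design,
        noise_sigma=noise_sigma,
        null_run=null_run,
    )
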