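"""Trajectory serialization, run manifests, frame rendering, 3D validation.

Snapshots are plain tabular text (one row per circle) so that any run can be
replayed, re-classified, or plotted without rerunning the simulation.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ModelParams
from .state import Embryo, Lineage

__all__ = ["snapshot_frame", "write_trajectory", "read_trajectory",
           "embryo_from_frame", "RunManifest", "render_frames",
           "run_3d_validation", "LINEAGE_COLORS"]

#: Paper color code: TE blue, undetermined white, EPI green, PrE red.
LINEAGE_COLORS = {
    Lineage.UNDETERMINED_ICM: "#f2f2f2",
    Lineage.TE: "#3a7bbf",
    Lineage.EPI: "#3fa34d",
    Lineage.PRE: "#d1433f",
}


def snapshot_frame(embryo: Embryo) -> pd.DataFrame:
    """One row per living circle: id, coordinates, lineage, polarity, ids."""
    n = embryo.n
    cols = {"id": np.arange(n)}
    axes = "xyz"[: embryo.dim]
    for k, ax in enumerate(axes):
        cols[ax] = embryo.positions[:, k]
    cols["lineage"] = [Lineage(int(v)).name for v in embryo.lineages]
    for k, ax in enumerate(axes):
        cols[f"pol_{ax}"] = embryo.polarities[:, k]
    cols["alive"] = np.ones(n, dtype=bool)
    cols["te_pair_id"] = embryo.pair[:n]
    cols["stage"] = np.full(n, embryo.t)
    return pd.DataFrame(cols)


def write_trajectory(snapshots, path) -> list[Path]:
    """Write snapshots (Embryos or DataFrames) as numbered CSV files."""
    snapshots = list(snapshots)
    if not snapshots:
        raise ValueError("empty trajectory")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = []
    for k, snap in enumerate(snapshots):
        frame = snap if isinstance(snap, pd.DataFrame) else snapshot_frame(snap)
        f = path / f"snapshot_{k:05d}.csv"
        frame.to_csv(f, index=False)
        out.append(f)
    return out


def read_trajectory(path) -> list[pd.DataFrame]:
    files = sorted(Path(path).glob("snapshot_*.csv"))
    if not files:
        raise FileNotFoundError(f"no snapshots under {path}")
    return [pd.read_csv(f) for f in files]


def embryo_from_frame(frame: pd.DataFrame,
                      params: ModelParams | None = None) -> Embryo:
    """Rebuild an Embryo (positions/lineages/polarities) from a snapshot."""
    params = params if params is not None else ModelParams()
    dim = 3 if "z" in frame.columns else 2
    embryo = Embryo(params, dim=dim)
    axes = "xyz"[:dim]
    for _, row in frame.iterrows():
        lng = Lineage[row["lineage"]]
        pos = [row[a] for a in axes]
        pol = [row[f"pol_{a}"] for a in axes] if lng == Lineage.TE else None
        embryo.add_cell(pos, lng, polarity=pol, pair_id=int(row["te_pair_id"]))
    embryo.t = float(frame["stage"].iloc[0]) if len(frame) else 0.0
    embryo.rule1_done = bool((embryo.lineages != int(Lineage.UNDETERMINED_ICM)).any())
    return embryo


@dataclass
class RunManifest:
    """Everything needed to regenerate a run exactly."""

    experiment: str
    master_seed: int
    n_replicates: int
    params: dict
    rule_config: dict
    code_version: str = ""
    replicate_seeds: list = field(default_factory=list)
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))
    outputs: list = field(default_factory=list)

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))
        return path

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def render_frames(trajectory, path, dpi: int = 80) -> list[Path]:
    """Render 2D snapshots as PNG frames in the paper's color code."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frames = list(trajectory)
    if not frames:
        raise ValueError("empty trajectory")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = []
    for k, frame in enumerate(frames):
        if not isinstance(frame, pd.DataFrame):
            frame = snapshot_frame(frame)
        fig, ax = plt.subplots(figsize=(6, 6))
        for _, row in frame.iterrows():
            color = LINEAGE_COLORS[Lineage[row["lineage"]]]
            ax.add_patch(plt.Circle((row["x"], row["y"]), 1.0, color=color,
                                    alpha=0.8, ec="0.4", lw=0.4))
            if row["lineage"] == "TE":
                ax.arrow(row["x"], row["y"], 1.3 * row["pol_x"],
                         1.3 * row["pol_y"], head_width=0.3, color="k", lw=0.4)
        ax.set_xlim(frame["x"].min() - 3, frame["x"].max() + 3)
        ax.set_ylim(frame["y"].min() - 3, frame["y"].max() + 3)
        ax.set_aspect("equal")
        ax.set_title(f"t = {frame['stage'].iloc[0]:.2f}")
        f = path / f"frame_{k:05d}.png"
        fig.savefig(f, dpi=dpi)
        plt.close(fig)
        out.append(f)
    return out


def run_3d_validation(n_replicates: int = 1, seed: int = 0,
                      params: ModelParams | None = None) -> dict:
    """Minimal 3D mode: the same rule pipeline on spheres.

    Positions and polarities are 3-vectors, TE pairs interact through the
    halfway-point true-nearest-neighbor graph, daughters are placed at the
    center of the three nearest neighbors, and the endpoint is assessed
    qualitatively (connected TE shell enclosing the ICM, plus an interior
    void).  Returns per-replicate diagnostics.
    """
    from .experiments import ExperimentSpec, run_replicate
    from .params import StageSchedule

    params = params if params is not None else ModelParams()
    # polarity fires one cleavage round later than in 2D: a 16-cell ball has
    # almost no interior, a 32-cell ball has the ~1/4 inner fraction that
    # gives a workable ICM
    schedule = StageSchedule(stage_unit=params.stage_unit, rule1_cell_count=32)
    spec = ExperimentSpec(name="wild_type_3d", n_replicates=n_replicates,
                          seed=seed, params=params, schedule=schedule)
    results = []
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    for child in children:
        last = {}
        run_replicate(spec, child, record=lambda e: last.update(embryo=e),
                      dim=3)
        results.append(shell_diagnostics_3d(last["embryo"]))
    return {"replicates": results,
            "all_shells_intact": all(r["shell_intact"] for r in results)}


def shell_diagnostics_3d(embryo: Embryo) -> dict:
    """Qualitative 3D endpoint check: TE shell connectivity and enclosure,
    and the largest empty sphere inside (the blastocoel)."""
    from scipy.spatial import cKDTree

    from .state import biological_counts

    pos = embryo.positions
    lin = embryo.lineages
    te = pos[lin == int(Lineage.TE)]
    icm = pos[lin != int(Lineage.TE)]
    counts, _ = biological_counts(embryo)
    out = {"counts": counts, "shell_intact": False, "cavity_clearance": 0.0}
    if len(te) < 4:
        return out
    # shell connectivity at the TE contact range
    tree = cKDTree(te)
    pairs = tree.query_pairs(r=embryo.params.te_te_cutoff * 1.3)
    parent = list(range(len(te)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in pairs:
        parent[find(i)] = find(j)
    connected = len({find(i) for i in range(len(te))}) == 1
    center = te.mean(axis=0)
    r_te = np.linalg.norm(te - center, axis=1)
    enclosed = (len(icm) == 0
                or np.linalg.norm(icm - center, axis=1).max() < r_te.max() + 1.0)
    out["shell_intact"] = bool(connected and enclosed)
    # largest clearance among probe points inside the shell
    all_tree = cKDTree(pos)
    rng = np.random.default_rng(0)
    probes = center + rng.uniform(-1, 1, size=(4096, 3)) * r_te.mean() * 0.8
    d, _ = all_tree.query(probes)
    out["cavity_clearance"] = float(d.max() - 1.0)
    return out
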