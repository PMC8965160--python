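"""Trajectory and artifact I/O.

Trajectory sets are stored as one ``.npz`` array file per trajectory plus a
``manifest.json`` recording feature names, units, frame time, seed and
scenario; a plain-CSV representation (one row per frame, header = feature
names) is supported for both reading and writing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import FeatureTrajectory

__all__ = [
    "save_trajectories",
    "load_trajectories",
    "trajectory_to_csv",
    "trajectory_from_csv",
]

MANIFEST_NAME = "manifest.json"


def save_trajectories(
    trajs: Sequence[FeatureTrajectory],
    directory: str | Path,
    fmt: str = "npz",
    units: dict[str, str] | None = None,
    extra_meta: dict | None = None,
) -> Path:
    """Write trajectories plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt not in ("npz", "csv"):
        raise ValueError("fmt must be 'npz' or 'csv'")
    entries = []
    feature_names = list(trajs[0].feature_names)
    for k, t in enumerate(trajs):
        if list(t.feature_names) != feature_names:
            raise ValueError("inconsistent feature sets across trajectories")
        fname = f"traj_{k:05d}.{fmt}"
        if fmt == "npz":
            arrays = {"X": t.X}
            if t.hidden_states is not None:
                arrays["hidden_states"] = t.hidden_states
            np.savez_compressed(directory / fname, **arrays)
        else:
            trajectory_to_csv(t, directory / fname)
        entries.append(
            {"file": fname, "trajectory_id": t.trajectory_id, "n_frames": len(t)}
        )
    manifest = {
        "feature_names": feature_names,
        "units": units or {},
        "frame_dt_ns": trajs[0].frame_dt,
        "format": fmt,
        "trajectories": entries,
    }
    manifest.update(extra_meta or {})
    path = directory / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_trajectories(path: str | Path) -> list[FeatureTrajectory]:
    """Load a trajectory set from a manifest file, a directory containing
    one, or a directory of bare CSV files."""
    path = Path(path)
    if path.is_dir():
        manifest_path = path / MANIFEST_NAME
        if not manifest_path.exists():
            csvs = sorted(path.glob("*.csv"))
            if not csvs:
                raise FileNotFoundError(f"no manifest or CSV trajectories in {path}")
            trajs = [trajectory_from_csv(p) for p in csvs]
            _check_consistent(trajs)
            return trajs
        path = manifest_path
    if not path.exists():
        raise FileNotFoundError(path)
    manifest = json.loads(path.read_text())
    directory = path.parent
    feature_names = manifest["feature_names"]
    frame_dt = float(manifest.get("frame_dt_ns", 1.0))
    trajs = []
    for entry in manifest["trajectories"]:
        f = directory / entry["file"]
        if f.suffix == ".npz":
            with np.load(f) as data:
                X = data["X"]
                hidden = data["hidden_states"] if "hidden_states" in data else None
        elif f.suffix == ".csv":
            t = trajectory_from_csv(f, frame_dt=frame_dt)
            if list(t.feature_names) != list(feature_names):
                raise ValueError(
                    f"{f.name}: feature columns {t.feature_names} do not match "
                    f"manifest {feature_names}"
                )
            X, hidden = t.X, t.hidden_states
        else:
            raise ValueError(f"unsupported trajectory format: {f.suffix}")
        trajs.append(
            FeatureTrajectory(
                trajectory_id=entry.get("trajectory_id", f.stem),
                frame_dt=frame_dt,
                X=X,
                feature_names=list(feature_names),
                hidden_states=hidden,
            )
        )
    if not trajs:
        raise ValueError(f"manifest {path} lists no trajectories")
    return trajs


def _check_consistent(trajs: list[FeatureTrajectory]) -> None:
    names = trajs[0].feature_names
    for t in trajs[1:]:
        if t.feature_names != names:
            raise ValueError(
                f"trajectory {t.trajectory_id!r} has feature set {t.feature_names}, "
                f"expected {names}"
            )


HIDDEN_COL = "_hidden_state"


def trajectory_to_csv(traj: FeatureTrajectory, path: str | Path) -> None:
    df = pd.DataFrame(traj.X, columns=traj.feature_names)
    if traj.hidden_states is not None:
        df[HIDDEN_COL] = traj.hidden_states
    df.to_csv(path, index=False)


def trajectory_from_csv(
    path: str | Path, frame_dt: float = 1.0, trajectory_id: str | None = None
) -> FeatureTrajectory:
    path = Path(path)
    df = pd.read_csv(path)
    hidden = None
    if HIDDEN_COL in df.columns:
        hidden = df.pop(HIDDEN_COL).to_numpy(dtype=int)
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValueError(f"{path.name}: non-numeric columns {bad}")
    return FeatureTrajectory(
        trajectory_id=trajectory_id or path.stem,
        frame_dt=frame_dt,
        X=df.to_numpy(dtype=float),
        feature_names=list(df.columns),
        hidden_states=hidden,
    )
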