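"""File I/O: frame directories, trajectory CSVs, aspiration CSVs, cohorts.

Videos are stored as zero-padded PNG frame directories
(``frame_000001.png`` ...) with a JSON sidecar (``ground_truth.json``)
carrying the arena calibration, frame rate and, for synthetic videos, the
ground-truth trajectory. Tabular data are plain CSVs with header rows.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .chorion import AspirationRecording
from .synth import ArenaSpec, GroundTruthTrajectory
from .track import Trajectory

__all__ = [
    "write_frames",
    "read_frames",
    "read_sidecar",
    "trajectory_to_csv",
    "trajectory_from_csv",
    "write_aspiration_csv",
    "read_aspiration_csv",
    "cohort_to_csv",
    "cohort_from_csv",
]

SIDECAR_NAME = "ground_truth.json"


def write_frames(
    frames: np.ndarray,
    outdir: str | Path,
    arena: ArenaSpec,
    fps: float = 25.0,
    traj: GroundTruthTrajectory | None = None,
    view: str = "top",
) -> Path:
    """Write a frame stack as PNGs plus a JSON sidecar; returns the directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames, start=1):
        iio.imwrite(outdir / f"frame_{i:06d}.png", frame)
    meta: dict = {
        "arena": dataclasses.asdict(arena),
        "fps": fps,
        "view": view,
        "n_frames": int(len(frames)),
    }
    if traj is not None:
        meta["ground_truth"] = {
            "times": traj.times.tolist(),
            "positions": traj.positions.tolist(),
            "state_sequence": traj.state_sequence.astype(int).tolist(),
            "seed": traj.seed,
        }
    (outdir / SIDECAR_NAME).write_text(json.dumps(meta))
    return outdir


def read_frames(indir: str | Path) -> tuple[np.ndarray, dict | None]:
    """Read a PNG frame directory (sorted by name) and its sidecar, if any."""
    indir = Path(indir)
    paths = sorted(indir.glob("frame_*.png"))
    if not paths:
        paths = sorted(
            p for p in indir.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
    if not paths:
        raise FileNotFoundError(f"no frames found in {indir}")
    frames = np.stack([iio.imread(p) for p in paths])
    meta = read_sidecar(indir)
    return frames, meta


def read_sidecar(indir: str | Path) -> dict | None:
    path = Path(indir) / SIDECAR_NAME
    if not path.exists():
        return None
    meta = json.loads(path.read_text())
    if "ground_truth" in meta:
        gt = meta["ground_truth"]
        meta["ground_truth"] = GroundTruthTrajectory(
            times=np.asarray(gt["times"], dtype=float),
            positions=np.asarray(gt["positions"], dtype=float),
            state_sequence=np.asarray(gt["state_sequence"], dtype=bool),
            seed=int(gt["seed"]),
        )
    if "arena" in meta:
        meta["arena"] = ArenaSpec(**meta["arena"])
    return meta


def trajectory_to_csv(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    cols = {"frame": np.arange(len(traj.times)), "time_s": traj.times}
    names = ["x_mm", "y_mm", "z_mm"][: traj.positions.shape[1]]
    for i, name in enumerate(names):
        cols[name] = traj.positions[:, i]
    cols["detected"] = traj.detected.astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


def trajectory_from_csv(path: str | Path, calibration: float = 1.0) -> Trajectory:
    df = pd.read_csv(path)
    names = [c for c in ("x_mm", "y_mm", "z_mm") if c in df.columns]
    return Trajectory(
        times=df["time_s"].to_numpy(dtype=float),
        positions=df[names].to_numpy(dtype=float),
        detected=df["detected"].to_numpy().astype(bool)
        if "detected" in df.columns
        else np.ones(len(df), dtype=bool),
        calibration=calibration,
    )


def write_aspiration_csv(
    rec: AspirationRecording, pl_path: str | Path, force_path: str | Path
) -> None:
    pd.DataFrame({"pressure_pa": rec.pressures, "length_m": rec.lengths}).to_csv(
        pl_path, index=False
    )
    pd.DataFrame({"time_s": rec.force_times, "force_au": rec.forces}).to_csv(
        force_path, index=False
    )


def read_aspiration_csv(
    pl_path: str | Path, force_path: str | Path, pipette_radius: float
) -> AspirationRecording:
    pl = pd.read_csv(pl_path)
    ft = pd.read_csv(force_path)
    return AspirationRecording(
        pressures=pl["pressure_pa"].to_numpy(dtype=float),
        lengths=pl["length_m"].to_numpy(dtype=float),
        force_times=ft["time_s"].to_numpy(dtype=float),
        forces=ft["force_au"].to_numpy(dtype=float),
        pipette_radius=pipette_radius,
    )


def cohort_to_csv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def cohort_from_csv(path: str | Path) -> pd.DataFrame:
    from .devtox import validate_cohort_table

    return validate_cohort_table(pd.read_csv(path))
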