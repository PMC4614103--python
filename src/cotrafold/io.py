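"""Trajectory persistence and run configuration.

Trajectories are stored as XTC (compressed single-precision coordinates
with per-frame times) next to a Cα PDB topology sidecar, so any standard
trajectory viewer can open them.  Engine coordinates are Å; XTC stores nm.

Run configuration is a flat YAML namespace (``engine.dt``,
``release.interval``, ``tunnel.radius``, ``model.bond_k``, ...).  Every run
writes its fully-resolved configuration next to its outputs, so any output
file is reproducible from the persisted config and seeds alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml
from mdtraj.formats import XTCTrajectoryFile

from .go_engine import GoModelParams
from .release_protocol import ReleaseSchedule, TunnelGeometry
from .structures import Trajectory

__all__ = [
    "TruncatedTrajectoryError",
    "write_trajectory",
    "read_trajectory",
    "RunConfig",
]

_NM_PER_ANGSTROM = 0.1


class TruncatedTrajectoryError(IOError):
    """A trajectory file ended mid-frame; ``n_good`` frames are readable."""

    def __init__(self, path, n_good: int):
        self.n_good = n_good
        super().__init__(
            f"{path}: truncated after frame {n_good} "
            f"({n_good} frames are recoverable with read_trajectory(..., "
            f"max_frames={n_good}))"
        )


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    """Write frames + times as XTC (single precision, nm)."""
    with XTCTrajectoryFile(str(path), "w") as fh:
        fh.write(
            xyz=(traj.xyz * _NM_PER_ANGSTROM).astype(np.float32),
            time=traj.times.astype(np.float32),
            step=np.arange(len(traj)),
        )


def read_trajectory(
    path: str | Path,
    stride: int = 1,
    max_frames: int | None = None,
) -> Trajectory:
    """Read an XTC trajectory back into Å, frame by frame.

    ``stride`` keeps every stride-th stored frame (times preserved).  A
    corrupt or truncated tail raises :class:`TruncatedTrajectoryError`
    naming the number of intact leading frames; pass that count as
    ``max_frames`` to recover the readable prefix.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frames, times = [], []
    n_good = 0
    with XTCTrajectoryFile(str(path), "r") as fh:
        while max_frames is None or n_good < max_frames:
            try:
                xyz, t, _, _ = fh.read(1)
            except Exception:
                raise TruncatedTrajectoryError(path, n_good) from None
            if xyz.shape[0] == 0:
                break
            if n_good % stride == 0:
                frames.append(xyz[0] / _NM_PER_ANGSTROM)
                times.append(float(t[0]))
            n_good += 1
    if not frames:
        raise IOError(f"{path}: no frames")
    return Trajectory(np.array(frames), np.array(times), metadata={"path": str(path)})


@dataclass
class RunConfig:
    """Fully-resolved configuration of a co-release simulation campaign.

    Defaults are the package's calibrated study conditions for the
    synthetic 35-residue bundle: sub-folding-temperature Langevin dynamics
    (T = 0.45 ε/k_B against a folding temperature of ≈0.6), light friction
    (0.25 τ⁻¹, which folds roughly an order of magnitude faster than the
    overdamped regime), a release interval of 5 τ per residue and a bulk
    phase long enough for most seeds to fold.
    """

    out_dir: str = "runs/corelease"
    seeds: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])

    # engine.*
    dt: float = 0.0005
    temperature: float = 0.45
    friction: float = 0.25
    bulk_steps: int = 1_650_000
    stride: int = 10_000

    # release.* / tunnel.*
    release_interval: float = 5.0  # reduced time per residue; None/0 = free folding
    tunnel_radius: float = 7.5
    tunnel_wall_k: float = 10.0
    tunnel_exit_plane_x: float = 0.0

    # model.*
    model: GoModelParams = field(default_factory=GoModelParams)

    # structure.*: synthetic bundle by default; optional user PDB
    pdb_path: str | None = None
    pdb_chain: str | None = None
    packing_distance: float = 9.5

    # analysis.*
    analysis_temperature_K: float = 300.0
    fel_bin_width: float = 0.1
    folded_threshold: float = 2.0
    segment_threshold: float = 2.0
    fpt_cap: float | None = None  # default: total simulated time per seed

    def schedule(self, n_residues: int) -> ReleaseSchedule | None:
        if not self.release_interval:
            return None
        return ReleaseSchedule(interval=self.release_interval, n_residues=n_residues)

    def tunnel(self) -> TunnelGeometry:
        return TunnelGeometry(
            radius=self.tunnel_radius,
            wall_k=self.tunnel_wall_k,
            exit_plane_x=self.tunnel_exit_plane_x,
        )

    # -- flat YAML namespace ------------------------------------------------

    _FLAT_MAP = {
        "engine.dt": "dt",
        "engine.temperature": "temperature",
        "engine.friction": "friction",
        "engine.bulk_steps": "bulk_steps",
        "engine.stride": "stride",
        "release.interval": "release_interval",
        "tunnel.radius": "tunnel_radius",
        "tunnel.wall_k": "tunnel_wall_k",
        "tunnel.exit_plane_x": "tunnel_exit_plane_x",
        "structure.pdb_path": "pdb_path",
        "structure.pdb_chain": "pdb_chain",
        "structure.packing_distance": "packing_distance",
        "analysis.temperature_K": "analysis_temperature_K",
        "analysis.fel_bin_width": "fel_bin_width",
        "analysis.folded_threshold": "folded_threshold",
        "analysis.segment_threshold": "segment_threshold",
        "analysis.fpt_cap": "fpt_cap",
        "out_dir": "out_dir",
        "seeds": "seeds",
    }

    def to_yaml(self, path: str | Path) -> None:
        flat: dict = {}
        for key, attr in self._FLAT_MAP.items():
            flat[key] = getattr(self, attr)
        for f in fields(GoModelParams):
            flat[f"model.{f.name}"] = getattr(self.model, f.name)
        with open(path, "w") as fh:
            yaml.safe_dump(flat, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            flat = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        model_kwargs: dict = {}
        model_fields = {f.name for f in fields(GoModelParams)}
        for key, value in flat.items():
            if key.startswith("model."):
                name = key[len("model."):]
                if name not in model_fields:
                    raise KeyError(f"unknown model parameter {key!r}")
                model_kwargs[name] = value
            elif key in cls._FLAT_MAP:
                kwargs[cls._FLAT_MAP[key]] = value
            else:
                raise KeyError(f"unknown config key {key!r}")
        kwargs["model"] = GoModelParams(**model_kwargs)
        return cls(**kwargs)
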