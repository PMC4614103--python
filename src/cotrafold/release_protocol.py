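"""Sequential residue release from a cylindrical tunnel confinement.

The co-releasing protocol models translation termination and extraction of
a nascent chain from the ribosomal exit tunnel: residues leave the tunnel
one at a time, N-terminus first, at a fixed interval τ per residue.  While a
residue is still "in the tunnel" it feels a soft harmonic wall confining it
radially to a cylinder of radius R_c about the tunnel axis and axially
behind the tunnel mouth; a released residue feels no tunnel interaction at
all (nascent-chain–ribosome interactions beyond confinement are not
modelled).

The confined set changes stepwise at multiples of τ: during the first
interval residue 1 is free and residues 2..L are confined, during the
second interval residues 1–2 are free, and so on, so a chain of L residues
is completely released at t = L·τ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from .structures import Conformation

__all__ = [
    "TunnelGeometry",
    "ReleaseSchedule",
    "confined_residues",
    "total_release_time",
    "tunnel_wall_energy",
]


@dataclass(frozen=True)
class TunnelGeometry:
    """Cylindrical confinement geometry.

    The axis is fixed along +x (the initial conformation is aligned along
    the x axis); ``radius`` is the cylinder radius R_c in Å, ``wall_k`` the
    harmonic wall stiffness in ε/Å², and ``exit_plane_x`` the x coordinate
    of the tunnel mouth: a one-sided axial wall keeps confined residues at
    x ≤ exit_plane_x.
    """

    radius: float = 7.5
    wall_k: float = 10.0
    exit_plane_x: float = 0.0
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("tunnel radius must be positive")
        if self.wall_k < 0:
            raise ValueError("wall stiffness must be non-negative")
        ax = np.asarray(self.axis, dtype=float)
        if not np.allclose(ax, (1.0, 0.0, 0.0)):
            raise NotImplementedError("only the +x tunnel axis is supported")


@dataclass(frozen=True)
class ReleaseSchedule:
    """Stepwise N-terminus-first release: one residue per ``interval``.

    ``interval`` is the time τ spent per residue (reduced units in the
    engine; the protocol itself is unit-agnostic, e.g. 2 ns per residue in
    a physical description).
    """

    interval: float
    n_residues: int

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("release interval must be positive")
        if self.n_residues < 1:
            raise ValueError("need at least one residue")


def confined_residues(schedule: ReleaseSchedule, t: float) -> frozenset[int]:
    """Set of residues still confined in the tunnel at time t.

    The number of released residues is k = min(L, floor(t/τ) + 1): residues
    1..k are free, residues k+1..L confined.  Empty from t = L·τ onward.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    k = min(schedule.n_residues, math.floor(t / schedule.interval) + 1)
    return frozenset(range(k + 1, schedule.n_residues + 1))


def n_confined(schedule: ReleaseSchedule, t: float) -> int:
    """Number of confined residues at time t (the confined set is always a
    contiguous C-terminal block, so the count determines the set)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    k = min(schedule.n_residues, math.floor(t / schedule.interval) + 1)
    return schedule.n_residues - k


def total_release_time(schedule: ReleaseSchedule) -> float:
    """Time at which the chain is completely released: L·τ."""
    return schedule.n_residues * schedule.interval


def tunnel_wall_energy(
    conformation: Conformation | np.ndarray,
    confined: frozenset[int] | set[int],
    tunnel: TunnelGeometry,
) -> tuple[float, np.ndarray]:
    """Soft-wall confinement energy and per-residue forces.

    For each confined residue at radial distance ρ = sqrt(y² + z²) from the
    tunnel axis, the radial wall contributes wall_k/2 · max(0, ρ − R_c)²;
    a one-sided axial wall contributes wall_k/2 · max(0, x − exit_plane_x)².
    Returned forces are the exact negative gradient, shaped like the input
    coordinates; unconfined residues get zero force.
    """
    coords = (
        conformation.coords
        if isinstance(conformation, Conformation)
        else np.asarray(conformation, dtype=float)
    )
    n = coords.shape[0]
    forces = np.zeros_like(coords)
    if not confined:
        return 0.0, forces
    idx = np.array(sorted(confined), dtype=int) - 1
    if idx.min() < 0 or idx.max() >= n:
        raise ValueError("confined set references residues outside the chain")
    k = tunnel.wall_k
    energy = 0.0

    yz = coords[idx, 1:]
    rho = np.sqrt((yz**2).sum(axis=1))
    over = np.maximum(0.0, rho - tunnel.radius)
    energy += 0.5 * k * float((over**2).sum())
    # radial force: -k * (rho - R_c) * unit radial vector (only where over>0)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(rho[:, None] > 0, yz / rho[:, None], 0.0)
    forces[idx, 1:] -= k * over[:, None] * unit

    x_over = np.maximum(0.0, coords[idx, 0] - tunnel.exit_plane_x)
    energy += 0.5 * k * float((x_over**2).sum())
    forces[idx, 0] -= k * x_over
    return energy, forces
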