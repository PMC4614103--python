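"""Coarse-grained Cα structure-based (Gō-type) Langevin dynamics engine.

One bead per residue, unit mass, reduced units: energies in units of the
native-contact well depth ε, lengths in Å, temperature in ε/k_B, time in
τ = sqrt(m·Å²/ε).  The potential is the standard structure-based form:

* harmonic bonds          V = k_b (r − r₀)²
* harmonic pseudo-angles  V = k_a (θ − θ₀)²
* 1–3 cosine dihedrals    V = k₁[1 − cos(φ − φ₀)] + k₃[1 − cos 3(φ − φ₀)]
* native contacts (12-10) V = ε[5(σ/r)¹² − 6(σ/r)¹⁰], σ the native distance
* non-native repulsion    V = ε(σ_rep/r)¹²  for |i−j| > 3 non-contact pairs
* tunnel wall             soft harmonic cylinder + axial wall on confined
                          residues (see :mod:`cotrafold.release_protocol`)

Attractive interactions exist only between native-contact pairs, so the
global energy minimum is the native structure and folding is funnelled
toward it.  Dynamics are Langevin, discretised with the BAOAB splitting,
which gives accurate configurational sampling at comparatively large time
steps.  Engine time is reduced units throughout and is never mapped to
physical nanoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .release_protocol import ReleaseSchedule, TunnelGeometry, tunnel_wall_energy
from .structures import Conformation, NativeStructure, Trajectory

__all__ = [
    "GoModelParams",
    "GoModel",
    "EngineState",
    "build_go_model",
    "potential_energy",
    "forces",
    "step_langevin",
    "initial_state",
    "validate_timestep",
]


@dataclass(frozen=True)
class GoModelParams:
    """Tunable model parameters (reduced units).

    Defaults are common structure-based-model choices: stiff bonds, softer
    angles, weak dihedrals, unit contact well depth, a 4 Å excluded-volume
    diameter.
    """

    bond_k: float = 100.0       # ε/Å²
    angle_k: float = 20.0       # ε/rad²
    dihedral_k1: float = 1.0    # ε
    dihedral_k3: float = 0.5    # ε
    contact_eps: float = 1.0    # ε
    repulsive_sigma: float = 4.0  # Å
    repulsive_eps: float = 1.0  # ε


@dataclass(frozen=True)
class GoModel:
    """Precomputed force-field arrays for one native structure.

    All index arrays are 0-based.  ``contact_pairs`` is identical to the
    native structure's contact set.
    """

    native: NativeStructure
    params: GoModelParams
    bond_r0: np.ndarray        # (n-1,)
    angle_theta0: np.ndarray   # (n-2,)
    dihedral_phi0: np.ndarray  # (n-3,)
    contact_i: np.ndarray
    contact_j: np.ndarray
    contact_sigma: np.ndarray  # native pair distances, Å
    rep_i: np.ndarray
    rep_j: np.ndarray

    @property
    def n_residues(self) -> int:
        return self.native.n_residues

    @property
    def contact_pairs(self) -> frozenset[tuple[int, int]]:
        return frozenset(
            (int(i) + 1, int(j) + 1) for i, j in zip(self.contact_i, self.contact_j)
        )


@dataclass
class EngineState:
    """Mutable integrator state: positions/velocities (Å, Å/τ), time, RNG.

    ``seed`` plus the number of previous ``step_langevin`` calls fully
    determine the noise stream, so identical seeds and inputs reproduce
    trajectories bit for bit.
    """

    positions: np.ndarray
    velocities: np.ndarray
    time: float = 0.0
    seed: int = 0
    n_calls: int = 0


def build_go_model(
    native: NativeStructure, params: GoModelParams | None = None
) -> GoModel:
    """Construct the Gō model whose global minimum is the native structure.

    Every bonded term evaluates to zero at the native geometry and every
    native-contact term sits at its −ε minimum at the native pair distance.

    Raises ``ValueError`` if any native bond length falls outside
    [2.5, 5.0] Å (a malformed Cα trace).
    """
    if params is None:
        params = GoModelParams()
    x = native.coords
    n = x.shape[0]
    if n < 5:
        raise ValueError("need at least 5 residues")

    bond_r0 = np.linalg.norm(np.diff(x, axis=0), axis=1)
    bad = (bond_r0 < 2.5) | (bond_r0 > 5.0)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            f"native bond {i + 1}-{i + 2} length {bond_r0[i]:.2f} Å outside "
            "[2.5, 5.0] Å: malformed Cα trace"
        )

    angle_theta0 = np.array([_angle(x[i], x[i + 1], x[i + 2]) for i in range(n - 2)])
    dihedral_phi0 = np.array(
        [_dihedral(x[i], x[i + 1], x[i + 2], x[i + 3]) for i in range(n - 3)]
    )

    pairs = sorted(native.native_contacts)
    ci = np.array([p[0] - 1 for p in pairs], dtype=np.int64)
    cj = np.array([p[1] - 1 for p in pairs], dtype=np.int64)
    sig = np.linalg.norm(x[ci] - x[cj], axis=1)

    # all |i-j| > 3 pairs that are not native contacts are purely repulsive
    ii, jj = np.triu_indices(n, k=4)
    contact_set = set(zip(ci.tolist(), cj.tolist()))
    keep = np.array([(a, b) not in contact_set for a, b in zip(ii, jj)])
    return GoModel(
        native=native,
        params=params,
        bond_r0=bond_r0,
        angle_theta0=angle_theta0,
        dihedral_phi0=dihedral_phi0,
        contact_i=ci,
        contact_j=cj,
        contact_sigma=sig,
        rep_i=ii[keep].astype(np.int64),
        rep_j=jj[keep].astype(np.int64),
    )


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u = a - b
    v = c - b
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cos, -1.0, 1.0)))


def _dihedral(p0, p1, p2, p3) -> float:
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    m = np.cross(b1, b2)
    n = np.cross(b2, b3)
    sin = np.dot(np.cross(m, n), b2) / np.linalg.norm(b2)
    cos = np.dot(m, n)
    return float(np.arctan2(sin, cos))


# ---------------------------------------------------------------------------
# Numba force kernel


@njit(fastmath=False)
def _forces_kernel(
    pos,
    bond_k,
    bond_r0,
    angle_k,
    theta0,
    k1,
    k3,
    phi0,
    ci,
    cj,
    sigma,
    eps,
    ri,
    rj,
    rep_sigma,
    rep_eps,
    first_confined,
    wall_k,
    tunnel_r,
    exit_x,
):
    """Total potential energy and forces.

    ``first_confined`` is the 0-based index of the first tunnel-confined
    residue (the confined set is the C-terminal block); pass n for no
    confinement.
    """
    n = pos.shape[0]
    f = np.zeros((n, 3))
    energy = 0.0

    # bonds: V = k_b (r - r0)^2
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[i]
        energy += bond_k * dr * dr
        g = 2.0 * bond_k * dr / r
        f[i, 0] += g * dx
        f[i, 1] += g * dy
        f[i, 2] += g * dz
        f[i + 1, 0] -= g * dx
        f[i + 1, 1] -= g * dy
        f[i + 1, 2] -= g * dz

    # angles: V = k_a (theta - theta0)^2
    for i in range(n - 2):
        ux = pos[i, 0] - pos[i + 1, 0]
        uy = pos[i, 1] - pos[i + 1, 1]
        uz = pos[i, 2] - pos[i + 1, 2]
        vx = pos[i + 2, 0] - pos[i + 1, 0]
        vy = pos[i + 2, 1] - pos[i + 1, 1]
        vz = pos[i + 2, 2] - pos[i + 1, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        cos = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if cos > 1.0:
            cos = 1.0
        elif cos < -1.0:
            cos = -1.0
        theta = np.arccos(cos)
        dth = theta - theta0[i]
        energy += angle_k * dth * dth
        sin = np.sqrt(1.0 - cos * cos)
        if sin < 1e-8:
            sin = 1e-8
        dvdth = 2.0 * angle_k * dth
        # dtheta/dp0 = (cos*u_hat - v_hat) / (|u| sin)
        c0 = dvdth / (nu * sin)
        g0x = -c0 * (cos * ux / nu - vx / nv)
        g0y = -c0 * (cos * uy / nu - vy / nv)
        g0z = -c0 * (cos * uz / nu - vz / nv)
        c2 = dvdth / (nv * sin)
        g2x = -c2 * (cos * vx / nv - ux / nu)
        g2y = -c2 * (cos * vy / nv - uy / nu)
        g2z = -c2 * (cos * vz / nv - uz / nu)
        f[i, 0] += g0x
        f[i, 1] += g0y
        f[i, 2] += g0z
        f[i + 2, 0] += g2x
        f[i + 2, 1] += g2y
        f[i + 2, 2] += g2z
        f[i + 1, 0] -= g0x + g2x
        f[i + 1, 1] -= g0y + g2y
        f[i + 1, 2] -= g0z + g2z

    # dihedrals: V = k1[1 - cos(phi - phi0)] + k3[1 - cos 3(phi - phi0)]
    for i in range(n - 3):
        b1x = pos[i + 1, 0] - pos[i, 0]
        b1y = pos[i + 1, 1] - pos[i, 1]
        b1z = pos[i + 1, 2] - pos[i, 2]
        b2x = pos[i + 2, 0] - pos[i + 1, 0]
        b2y = pos[i + 2, 1] - pos[i + 1, 1]
        b2z = pos[i + 2, 2] - pos[i + 1, 2]
        b3x = pos[i + 3, 0] - pos[i + 2, 0]
        b3y = pos[i + 3, 1] - pos[i + 2, 1]
        b3z = pos[i + 3, 2] - pos[i + 2, 2]
        mx = b1y * b2z - b1z * b2y
        my = b1z * b2x - b1x * b2z
        mz = b1x * b2y - b1y * b2x
        nx = b2y * b3z - b2z * b3y
        ny = b2z * b3x - b2x * b3z
        nz = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        cxx = my * nz - mz * ny
        cxy = mz * nx - mx * nz
        cxz = mx * ny - my * nx
        sinphi = (cxx * b2x + cxy * b2y + cxz * b2z) / nb2
        cosphi = mx * nx + my * ny + mz * nz
        phi = np.arctan2(sinphi, cosphi)
        dphi = phi - phi0[i]
        energy += k1 * (1.0 - np.cos(dphi)) + k3 * (1.0 - np.cos(3.0 * dphi))
        dvdphi = k1 * np.sin(dphi) + 3.0 * k3 * np.sin(3.0 * dphi)
        # near three-atom collinearity the torsion force diverges; skip the
        # (ill-defined) force there rather than inject unbounded kicks
        m2 = mx * mx + my * my + mz * mz
        n2 = nx * nx + ny * ny + nz * nz
        if m2 < 1e-6 or n2 < 1e-6:
            continue
        # force on first and last atom (standard torsion gradient)
        ca = dvdphi * nb2 / m2
        fix = ca * mx
        fiy = ca * my
        fiz = ca * mz
        cb = -dvdphi * nb2 / n2
        flx = cb * nx
        fly = cb * ny
        flz = cb * nz
        p = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        q = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        sx = p * fix - q * flx
        sy = p * fiy - q * fly
        sz = p * fiz - q * flz
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[i + 1, 0] += -fix - sx
        f[i + 1, 1] += -fiy - sy
        f[i + 1, 2] += -fiz - sz
        f[i + 2, 0] += sx - flx
        f[i + 2, 1] += sy - fly
        f[i + 2, 2] += sz - flz
        f[i + 3, 0] += flx
        f[i + 3, 1] += fly
        f[i + 3, 2] += flz

    # native contacts: 12-10 well
    for c in range(ci.shape[0]):
        a = ci[c]
        b = cj[c]
        dx = pos[a, 0] - pos[b, 0]
        dy = pos[a, 1] - pos[b, 1]
        dz = pos[a, 2] - pos[b, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        s2 = (sigma[c] * sigma[c]) / r2
        s10 = s2 * s2 * s2 * s2 * s2
        s12 = s10 * s2
        energy += eps * (5.0 * s12 - 6.0 * s10)
        # -dV/dr / r
        g = 60.0 * eps * (s12 - s10) / r2
        f[a, 0] += g * dx
        f[a, 1] += g * dy
        f[a, 2] += g * dz
        f[b, 0] -= g * dx
        f[b, 1] -= g * dy
        f[b, 2] -= g * dz

    # non-native repulsion: (sigma_rep / r)^12
    rs2 = rep_sigma * rep_sigma
    for c in range(ri.shape[0]):
        a = ri[c]
        b = rj[c]
        dx = pos[a, 0] - pos[b, 0]
        dy = pos[a, 1] - pos[b, 1]
        dz = pos[a, 2] - pos[b, 2]
        r2 = dx * dx + dy * dy + dz * dz
        s2 = rs2 / r2
        s12 = s2 * s2 * s2 * s2 * s2 * s2
        energy += rep_eps * s12
        g = 12.0 * rep_eps * s12 / r2
        f[a, 0] += g * dx
        f[a, 1] += g * dy
        f[a, 2] += g * dz
        f[b, 0] -= g * dx
        f[b, 1] -= g * dy
        f[b, 2] -= g * dz

    # tunnel wall on the confined C-terminal block
    if wall_k > 0.0:
        for a in range(first_confined, n):
            rho = np.sqrt(pos[a, 1] * pos[a, 1] + pos[a, 2] * pos[a, 2])
            over = rho - tunnel_r
            if over > 0.0 and rho > 0.0:
                energy += 0.5 * wall_k * over * over
                g = wall_k * over / rho
                f[a, 1] -= g * pos[a, 1]
                f[a, 2] -= g * pos[a, 2]
            xo = pos[a, 0] - exit_x
            if xo > 0.0:
                energy += 0.5 * wall_k * xo * xo
                f[a, 0] -= wall_k * xo

    return energy, f


@njit(fastmath=False)
def _baoab_kernel(
    pos,
    vel,
    t0,
    n_steps,
    dt,
    kT,
    friction,
    seed,
    stride,
    out_xyz,
    out_t,
    bond_k,
    bond_r0,
    angle_k,
    theta0,
    k1,
    k3,
    phi0,
    ci,
    cj,
    sigma,
    eps,
    ri,
    rj,
    rep_sigma,
    rep_eps,
    release_tau,
    wall_k,
    tunnel_r,
    exit_x,
):
    """BAOAB Langevin loop with the stepwise release schedule evaluated at
    every step.  Returns (final_time, n_frames_written, error_step) where
    error_step is -1 on success."""
    np.random.seed(seed)
    n = pos.shape[0]
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT)
    t = t0

    if release_tau > 0.0:
        fc = min(n, int(np.floor(t / release_tau)) + 1)
    else:
        fc = n
    e, f = _forces_kernel(
        pos, bond_k, bond_r0, angle_k, theta0, k1, k3, phi0,
        ci, cj, sigma, eps, ri, rj, rep_sigma, rep_eps,
        fc, wall_k, tunnel_r, exit_x,
    )
    n_out = 0
    for step in range(n_steps):
        # B
        for a in range(n):
            vel[a, 0] += 0.5 * dt * f[a, 0]
            vel[a, 1] += 0.5 * dt * f[a, 1]
            vel[a, 2] += 0.5 * dt * f[a, 2]
        # A
        for a in range(n):
            pos[a, 0] += 0.5 * dt * vel[a, 0]
            pos[a, 1] += 0.5 * dt * vel[a, 1]
            pos[a, 2] += 0.5 * dt * vel[a, 2]
        # O
        for a in range(n):
            vel[a, 0] = c1 * vel[a, 0] + c2 * np.random.standard_normal()
            vel[a, 1] = c1 * vel[a, 1] + c2 * np.random.standard_normal()
            vel[a, 2] = c1 * vel[a, 2] + c2 * np.random.standard_normal()
        # A
        for a in range(n):
            pos[a, 0] += 0.5 * dt * vel[a, 0]
            pos[a, 1] += 0.5 * dt * vel[a, 1]
            pos[a, 2] += 0.5 * dt * vel[a, 2]
        t = t0 + (step + 1) * dt
        # confined set re-queried from the schedule at every step
        if release_tau > 0.0:
            fc = min(n, int(np.floor(t / release_tau)) + 1)
        else:
            fc = n
        e, f = _forces_kernel(
            pos, bond_k, bond_r0, angle_k, theta0, k1, k3, phi0,
            ci, cj, sigma, eps, ri, rj, rep_sigma, rep_eps,
            fc, wall_k, tunnel_r, exit_x,
        )
        if not np.isfinite(e):
            return t, n_out, step
        # B
        for a in range(n):
            vel[a, 0] += 0.5 * dt * f[a, 0]
            vel[a, 1] += 0.5 * dt * f[a, 1]
            vel[a, 2] += 0.5 * dt * f[a, 2]
        if (step + 1) % stride == 0:
            for a in range(n):
                out_xyz[n_out, a, 0] = pos[a, 0]
                out_xyz[n_out, a, 1] = pos[a, 1]
                out_xyz[n_out, a, 2] = pos[a, 2]
            out_t[n_out] = t
            n_out += 1
    return t, n_out, -1


# ---------------------------------------------------------------------------
# Public wrappers


def _kernel_args(model: GoModel, tunnel: TunnelGeometry | None):
    p = model.params
    if tunnel is None:
        wall_k, radius, exit_x = 0.0, 1.0, 0.0
    else:
        wall_k, radius, exit_x = tunnel.wall_k, tunnel.radius, tunnel.exit_plane_x
    return (
        p.bond_k, model.bond_r0, p.angle_k, model.angle_theta0,
        p.dihedral_k1, p.dihedral_k3, model.dihedral_phi0,
        model.contact_i, model.contact_j, model.contact_sigma, p.contact_eps,
        model.rep_i, model.rep_j, p.repulsive_sigma, p.repulsive_eps,
        wall_k, radius, exit_x,
    )


def potential_energy(
    model: GoModel,
    conformation: Conformation | np.ndarray,
    confined: frozenset[int] | set[int] | None = None,
    tunnel: TunnelGeometry | None = None,
) -> float:
    """Total potential energy in ε (bonded + contacts + repulsion + wall).

    The tunnel wall term applies only to the residues in ``confined`` and
    contributes exactly zero for an empty confined set.
    """
    e, _ = forces(model, conformation, confined, tunnel)
    return e


def forces(
    model: GoModel,
    conformation: Conformation | np.ndarray,
    confined: frozenset[int] | set[int] | None = None,
    tunnel: TunnelGeometry | None = None,
) -> tuple[float, np.ndarray]:
    """Energy (ε) and forces (ε/Å) for an arbitrary confined residue set."""
    pos = (
        conformation.coords
        if isinstance(conformation, Conformation)
        else np.asarray(conformation, dtype=float)
    )
    pos = np.ascontiguousarray(pos, dtype=np.float64)
    args = _kernel_args(model, None)
    e, f = _forces_kernel(pos, *args[:-3], model.n_residues, *args[-3:])
    if confined and tunnel is not None:
        ew, fw = tunnel_wall_energy(pos, confined, tunnel)
        e += ew
        f += fw
    return float(e), f


def initial_state(
    conformation: Conformation | np.ndarray,
    seed: int,
    temperature: float = 0.0,
) -> EngineState:
    """Engine state with Maxwell–Boltzmann velocities at ``temperature``."""
    pos = (
        conformation.coords
        if isinstance(conformation, Conformation)
        else np.asarray(conformation, dtype=float)
    )
    rng = np.random.default_rng(seed)
    vel = rng.standard_normal(pos.shape) * np.sqrt(max(temperature, 0.0))
    t = conformation.time if isinstance(conformation, Conformation) else 0.0
    return EngineState(
        positions=np.array(pos, dtype=np.float64),
        velocities=vel,
        time=float(t),
        seed=int(seed),
    )


class EngineBlowupError(RuntimeError):
    """Raised when the integrator produces a non-finite energy."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"non-finite energy at step {step}; reduce dt")


def step_langevin(
    model: GoModel,
    state: EngineState,
    n_steps: int,
    dt: float = 0.0005,
    temperature: float = 1.0,
    friction: float = 1.0,
    schedule: ReleaseSchedule | None = None,
    tunnel: TunnelGeometry | None = None,
    stride: int = 10_000,
) -> Trajectory:
    """Advance the state by ``n_steps`` BAOAB Langevin steps in place.

    Frames are recorded every ``stride`` steps and returned as a
    :class:`Trajectory`.  With a ``schedule`` + ``tunnel``, the confined set
    is recomputed from the schedule at every step, so residues are released
    mid-run exactly at multiples of the release interval.  The noise stream
    is a pure function of ``state.seed`` and the number of prior calls on
    the state: rerunning an identical setup is bit-identical.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    pos = state.positions
    vel = state.velocities
    n_frames = n_steps // stride
    out_xyz = np.empty((n_frames, model.n_residues, 3))
    out_t = np.empty(n_frames)
    release_tau = schedule.interval if schedule is not None else 0.0
    if schedule is not None and tunnel is None:
        raise ValueError("a release schedule requires a tunnel geometry")
    if tunnel is None:
        wall_k, radius, exit_x = 0.0, 1.0, 0.0
    else:
        wall_k, radius, exit_x = tunnel.wall_k, tunnel.radius, tunnel.exit_plane_x
    call_seed = (state.seed * 1_000_003 + state.n_calls * 7919 + 12345) % (2**31 - 1)
    p = model.params
    t_end, n_out, err = _baoab_kernel(
        pos, vel, state.time, n_steps, dt, temperature, friction,
        call_seed, stride, out_xyz, out_t,
        p.bond_k, model.bond_r0, p.angle_k, model.angle_theta0,
        p.dihedral_k1, p.dihedral_k3, model.dihedral_phi0,
        model.contact_i, model.contact_j, model.contact_sigma, p.contact_eps,
        model.rep_i, model.rep_j, p.repulsive_sigma, p.repulsive_eps,
        release_tau, wall_k, radius, exit_x,
    )
    state.n_calls += 1
    state.time = float(t_end)
    if err >= 0:
        raise EngineBlowupError(err)
    return Trajectory(
        out_xyz[:n_out],
        out_t[:n_out],
        metadata={
            "seed": state.seed,
            "dt": dt,
            "temperature": temperature,
            "friction": friction,
            "release_interval": release_tau if schedule is not None else None,
            "stride": stride,
        },
    )


def validate_timestep(
    model: GoModel,
    conformation: Conformation | np.ndarray,
    dt: float,
    n_check: int = 1000,
) -> None:
    """Check integrator stability: a short zero-temperature run from the
    given conformation must not diverge.  Raises ``EngineBlowupError`` or
    ``ValueError`` if the energy grows by more than 10 ε."""
    state = initial_state(conformation, seed=0, temperature=0.0)
    e0 = potential_energy(model, state.positions)
    step_langevin(
        model, state, n_steps=n_check, dt=dt, temperature=0.0,
        friction=1.0, stride=n_check,
    )
    e1 = potential_energy(model, state.positions)
    if not np.isfinite(e1) or e1 > e0 + 10.0:
        raise ValueError(f"dt={dt} unstable: energy rose from {e0:.2f} to {e1:.2f} ε")
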