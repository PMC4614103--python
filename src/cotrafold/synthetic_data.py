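"""Synthetic inputs: idealized helix bundles, post-tunnel states, scripted series.

Everything the pipeline needs can be generated here without downloads.  The
default product is an idealized 35-residue three-helix bundle that stands
in for a villin-headpiece-like fold: three ideal α-helices (rise 1.5
Å/residue, radius 2.3 Å, 100°/residue) packed antiparallel (up–down–up)
with short loop linkers, plus an N-/C-segment decomposition that overlaps
on the middle helix.  All generators are pure functions of their arguments
and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .analysis import OrderParameterSeries
from .structures import Conformation, NativeStructure

__all__ = [
    "BundleSpec",
    "make_helix_bundle",
    "make_extended_with_helices",
    "make_scripted_series",
    "perturb_native",
]

HELIX_RISE = 1.5  # Å per residue
HELIX_RADIUS = 2.3  # Å
HELIX_TWIST = np.deg2rad(100.0)  # per residue
CA_CA = 3.8  # Å, ideal consecutive Cα distance in loops


@dataclass(frozen=True)
class BundleSpec:
    """Geometry of the synthetic helix bundle.

    Defaults give a 35-residue three-helix bundle (11 + 3 + 7 + 3 + 11)
    with helix axes packed ``packing_distance`` Å apart in an up–down–up
    topology.
    """

    helix_lengths: tuple[int, ...] = (11, 7, 11)
    linker_lengths: tuple[int, ...] = (3, 3)
    packing_distance: float = 9.5

    def __post_init__(self) -> None:
        if len(self.linker_lengths) != len(self.helix_lengths) - 1:
            raise ValueError("need one linker between each pair of helices")
        if any(h < 4 for h in self.helix_lengths):
            raise ValueError("helix lengths must be >= 4 residues")
        if any(l < 1 for l in self.linker_lengths):
            raise ValueError("linker lengths must be >= 1 residue")

    @property
    def n_helices(self) -> int:
        return len(self.helix_lengths)

    @property
    def n_residues(self) -> int:
        return sum(self.helix_lengths) + sum(self.linker_lengths)

    def helix_spans(self) -> list[tuple[int, int]]:
        """1-based inclusive residue ranges of the helices."""
        spans = []
        start = 1
        for k, h in enumerate(self.helix_lengths):
            spans.append((start, start + h - 1))
            start += h
            if k < len(self.linker_lengths):
                start += self.linker_lengths[k]
        return spans


def _ideal_helix(
    n: int, axis_xy: np.ndarray, z_start: float, direction: float, phi0: float
) -> np.ndarray:
    """Ideal α-helix Cα trace around a vertical axis at ``axis_xy``."""
    k = np.arange(n)
    phi = phi0 + HELIX_TWIST * k
    x = axis_xy[0] + HELIX_RADIUS * np.cos(phi)
    y = axis_xy[1] + HELIX_RADIUS * np.sin(phi)
    z = z_start + direction * HELIX_RISE * k
    return np.column_stack([x, y, z])


def _arc_linker(a: np.ndarray, b: np.ndarray, n_pts: int, bulge: np.ndarray) -> np.ndarray:
    """``n_pts`` points on a circular arc from a to b with consecutive
    spacing exactly CA_CA (including the a- and b-junction bonds).

    The arc lies in the plane spanned by the chord and ``bulge`` and bends
    toward ``bulge``.  Requires |b - a| < (n_pts + 1) · CA_CA.
    """
    chord = b - a
    g = float(np.linalg.norm(chord))
    m = n_pts + 1  # number of equal sub-chords
    if g >= m * CA_CA:
        raise ValueError("linker too short to span the gap at ideal Cα spacing")
    e1 = chord / g
    u = bulge - np.dot(bulge, e1) * e1
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        u = np.array([0.0, 0.0, 1.0]) - e1[2] * e1
        nu = np.linalg.norm(u)
    u = u / nu

    def f(theta: float) -> float:
        return np.sin(theta / 2) / np.sin(theta / (2 * m)) - g / CA_CA

    theta = brentq(f, 1e-9, 2 * np.pi - 1e-9)
    rho = CA_CA / (2 * np.sin(theta / (2 * m)))
    mid = 0.5 * (a + b)
    center = mid - u * rho * np.cos(theta / 2)
    normal = np.cross(e1, u)
    a_rel = a - center
    for sign in (1.0, -1.0):
        end = Rotation.from_rotvec(sign * theta * normal).apply(a_rel) + center
        if np.linalg.norm(end - b) < 1e-6:
            ks = np.arange(1, n_pts + 1)
            rots = Rotation.from_rotvec(
                np.outer(sign * theta * ks / m, normal)
            )
            return rots.apply(a_rel) + center
    raise RuntimeError("arc construction failed to reach the far junction")


def make_helix_bundle(spec: BundleSpec | None = None, seed: int = 0) -> NativeStructure:
    """Build an idealized antiparallel helix-bundle native structure.

    Helix axes are placed on a regular polygon of side ``packing_distance``
    (a triangle for three helices), alternating up/down, with arc-shaped
    linkers keeping every consecutive Cα distance at the ideal 3.8 Å.
    Segments are auto-defined: ``N`` spans helices 1–2, ``C`` spans helices
    2–len, overlapping on the middle helix, and ``global`` excludes the two
    terminal residues.  The geometry is deterministic; ``seed`` is accepted
    for API uniformity.

    Raises ``ValueError`` if the resulting structure has fewer than 10
    long-range native contacts (pack the helices tighter).
    """
    if spec is None:
        spec = BundleSpec()
    d = spec.packing_distance
    nh = spec.n_helices
    # axis positions: regular polygon of side d (line for 2, triangle for 3, ...)
    if nh == 1:
        axis_xy = [np.zeros(2)]
    else:
        r_poly = d / (2 * np.sin(np.pi / nh)) if nh > 2 else d / 2
        ang = 2 * np.pi * np.arange(nh) / nh
        axis_xy = [r_poly * np.array([np.cos(a), np.sin(a)]) for a in ang]
        axis_xy = [p - axis_xy[0] for p in axis_xy]

    pieces: list[np.ndarray] = []
    prev_end: np.ndarray | None = None
    centroid = np.mean(axis_xy, axis=0)
    for k, h_len in enumerate(spec.helix_lengths):
        direction = 1.0 if k % 2 == 0 else -1.0
        if k == 0:
            phi0 = 0.0
            z_start = 0.0
        else:
            # start residue faces the previous helix's end point; same height
            to_prev = prev_end[:2] - axis_xy[k]
            phi0 = float(np.arctan2(to_prev[1], to_prev[0]))
            z_start = prev_end[2]
        helix = _ideal_helix(h_len, axis_xy[k], z_start, direction, phi0)
        if k > 0:
            bulge = 0.5 * (prev_end[:2] + helix[0, :2]) - centroid
            bulge3 = np.array([bulge[0], bulge[1], 0.0])
            if np.linalg.norm(bulge3) < 1e-9:
                bulge3 = np.array([0.0, 0.0, 1.0])
            try:
                linker = _arc_linker(
                    prev_end, helix[0], spec.linker_lengths[k - 1], bulge3
                )
            except ValueError as err:
                raise ValueError(
                    f"{err}; use a tighter packing_distance or longer linkers"
                ) from None
            pieces.append(linker)
        pieces.append(helix)
        prev_end = helix[-1]
    coords = np.vstack(pieces)
    n = coords.shape[0]

    spans = spec.helix_spans()
    segments = {
        "global": (2, n - 1),
        "N": (spans[0][0], spans[1][1]),
        "C": (spans[1][0], spans[-1][1]),
    }
    native = NativeStructure.from_coords(
        coords, segments=segments, helices=tuple(spans)
    )
    if len(native.native_contacts) < 10:
        raise ValueError(
            f"only {len(native.native_contacts)} native contacts; "
            "use a tighter packing_distance"
        )
    return native


def _align_to_minus_x(span_coords: np.ndarray) -> np.ndarray:
    """Rigidly rotate a helix span so its first→last axis points along −x."""
    x = span_coords - span_coords.mean(axis=0)
    # principal axis, oriented from first to last residue
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, span_coords[-1] - span_coords[0]) < 0:
        axis = -axis
    target = np.array([-1.0, 0.0, 0.0])
    v = np.cross(axis, target)
    s = np.linalg.norm(v)
    c = float(np.dot(axis, target))
    if s < 1e-12:
        rot = Rotation.identity() if c > 0 else Rotation.from_rotvec([0, 0, np.pi])
    else:
        rot = Rotation.from_rotvec(v / s * np.arctan2(s, c))
    return rot.apply(x)


def make_extended_with_helices(
    native: NativeStructure,
    tunnel_radius: float = 7.5,
    mouth_x: float = 0.0,
    seed: int = 0,
) -> Conformation:
    """Post-tunnel starting state: native helices formed, chain extended.

    Each helical span keeps its exact native local geometry (rigidly
    rotated so its axis runs along −x); linker residues are laid out on
    straight segments at their native bond lengths.  Residue 1 sits at the
    tunnel mouth (x = ``mouth_x``) and the chain extends toward −x, deeper
    into the tunnel, so the whole chain fits inside a cylinder of radius
    ``tunnel_radius`` and has no tertiary (inter-helix) contacts.

    Raises ``ValueError`` if the native structure carries no helix
    annotations or the result violates the radius constraint.
    """
    if native.helices is None:
        raise ValueError("native structure has no helix annotations")
    bonds = np.linalg.norm(np.diff(native.coords, axis=0), axis=1)
    n = native.n_residues
    coords = np.full((n, 3), np.nan)

    cursor = np.array([mouth_x, 0.0, 0.0])
    prev_end_idx: int | None = None
    for lo, hi in native.helices:
        span = _align_to_minus_x(native.coords[lo - 1 : hi])
        if prev_end_idx is None:
            span = span - span[0] + cursor
        else:
            # straight linker from previous helix end to this helix start,
            # each bond at its native length (collinear points)
            a = coords[prev_end_idx]
            gap_bonds = bonds[prev_end_idx : lo - 1]
            d_total = float(gap_bonds.sum())
            span = span - span[0]
            # put the helix start on the tunnel axis, displaced along -x
            dyz = np.linalg.norm(a[1:])
            dx = np.sqrt(max(d_total**2 - dyz**2, (0.5 * d_total) ** 2))
            b = np.array([a[0] - dx, 0.0, 0.0])
            direction = (b - a) / np.linalg.norm(b - a)
            perp = np.array([0.0, 1.0, 0.0]) - direction[1] * direction
            perp /= np.linalg.norm(perp)
            acc = 0.0
            for m, blen in enumerate(gap_bonds[:-1]):
                acc += blen
                # small alternating transverse offset: a perfectly straight
                # linker would sit on the torsion-term singularity
                zig = 0.4 * (1 if m % 2 == 0 else -1)
                coords[prev_end_idx + 1 + m] = a + direction * acc + perp * zig
            span = span + b
        coords[lo - 1 : hi] = span
        prev_end_idx = hi - 1
    if np.any(np.isnan(coords)):
        raise RuntimeError("chain layout incomplete (non-terminal linker?)")
    radial = np.sqrt(coords[:, 1] ** 2 + coords[:, 2] ** 2)
    if radial.max() > tunnel_radius:
        raise ValueError(
            f"extended chain radial extent {radial.max():.2f} Å exceeds "
            f"tunnel radius {tunnel_radius:.2f} Å"
        )
    return Conformation(coords, time=0.0)


#: Default global-RMSD centre (Å) attached to 2-tuple basin centres.
_DEFAULT_GLOBAL = {"F": 1.0, "I_on": 4.0, "I_off": 4.0, "U": 8.0}


def make_scripted_series(
    state_sequence: Sequence[tuple[str, float]],
    basin_centers: Mapping[str, tuple[float, ...]],
    noise_sd: float,
    seed: int,
    dt_frame: float = 1.0,
) -> OrderParameterSeries:
    """Order-parameter series with known state occupancies, for testing.

    ``state_sequence`` is a list of (label, dwell_time); each dwell emits
    round(dwell/dt_frame) frames whose (RMSD_N, RMSD_C) are the state's
    basin centre plus Gaussian noise truncated at zero.  Basin centres may
    be (rmsd_N, rmsd_C) or (rmsd_N, rmsd_C, rmsd_global); 2-tuples get a
    label-dependent default global RMSD.  The returned series carries the
    generating labels in its ``state`` field (ground truth for recovery
    tests); Q_nat/Q_non are filled with a smooth monotone proxy of the
    global RMSD.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows_n, rows_c, rows_g, labels = [], [], [], []
    for label, dwell in state_sequence:
        if dwell <= 0:
            raise ValueError("dwell times must be positive")
        centre = basin_centers[label]
        if len(centre) == 2:
            cn, cc = centre
            cg = _DEFAULT_GLOBAL[label]
        else:
            cn, cc, cg = centre
        if min(cn, cc, cg) < 0:
            raise ValueError("basin centres must be non-negative")
        n_frames = int(round(dwell / dt_frame))
        for _ in range(n_frames):
            rows_n.append(max(0.0, cn + rng.normal(0.0, noise_sd) if noise_sd else cn))
            rows_c.append(max(0.0, cc + rng.normal(0.0, noise_sd) if noise_sd else cc))
            rows_g.append(max(0.0, cg + rng.normal(0.0, noise_sd) if noise_sd else cg))
            labels.append(label)
    n = len(labels)
    if n == 0:
        raise ValueError("state sequence produced no frames")
    times = (np.arange(n) + 1) * dt_frame
    rg = np.array(rows_g)
    q_nat = np.clip(1.0 - rg / 10.0, 0.0, 1.0)
    q_non = np.full(n, 0.05)
    return OrderParameterSeries(
        times=times,
        rmsd_global=rg,
        rmsd_N=np.array(rows_n),
        rmsd_C=np.array(rows_c),
        q_nat=q_nat,
        q_non=q_non,
        state=np.array(labels, dtype="<U5"),
    )


def perturb_native(native: NativeStructure, sd: float, seed: int) -> Conformation:
    """Native coordinates plus i.i.d. Gaussian displacement (``sd`` per
    coordinate, Å)."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    return Conformation(native.coords + rng.normal(0.0, sd, native.coords.shape))
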