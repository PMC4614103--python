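"""Cα structure representation, PDB I/O, superposition RMSD and native contacts.

The package works exclusively with Cα traces.  A :class:`NativeStructure` is
the reference (native) conformation together with its residue numbering,
named segment definitions and the set of long-range native contacts; a
:class:`Conformation` is a single snapshot of the same chain, and a
:class:`Trajectory` is a time-ordered stack of snapshots.

Distances are in Å throughout.  Residue numbering is 1-based and contiguous
after reading a structure; original author numbering is retained as metadata
only, because all segment and contact definitions in this package use chain
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

__all__ = [
    "NativeStructure",
    "Conformation",
    "Trajectory",
    "read_ca_structure",
    "write_ca_structure",
    "superpose_rmsd",
    "extract_native_contacts",
    "hp35_segments",
]

#: Default geometric rule for a long-range native contact:
#: Cα–Cα distance strictly below 7 Å ...
CONTACT_CUTOFF = 7.0
#: ... and sequence separation strictly larger than 3 residues.
CONTACT_MIN_SEPARATION = 3


def hp35_segments() -> dict[str, tuple[int, int]]:
    """Segment conventions for a 35-residue villin-headpiece-like chain.

    Global RMSD excludes the flexible terminal residues (2–34); the
    N-segment spans helices I–II (3–21) and the C-segment helices II–III
    (15–33).  The middle helix belongs to both segments, so a chain with
    both segments folded is globally native.
    """
    return {"global": (2, 34), "N": (3, 21), "C": (15, 33)}


@dataclass(frozen=True)
class NativeStructure:
    """Reference Cα structure with segments and native contacts."""

    coords: np.ndarray
    segments: Mapping[str, tuple[int, int]]
    native_contacts: frozenset[tuple[int, int]]
    author_numbering: tuple[int, ...] | None = None
    helices: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("native coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        n = coords.shape[0]
        for name, (lo, hi) in self.segments.items():
            if not (1 <= lo <= hi <= n):
                raise ValueError(
                    f"segment {name!r} range ({lo}, {hi}) outside [1, {n}]"
                )
        for i, j in self.native_contacts:
            if not (1 <= i < j <= n):
                raise ValueError(f"contact ({i}, {j}) out of range")
            if j - i <= CONTACT_MIN_SEPARATION:
                raise ValueError(f"contact ({i}, {j}) violates |i-j| > 3")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    @property
    def residue_ids(self) -> np.ndarray:
        """1-based contiguous residue numbering."""
        return np.arange(1, self.n_residues + 1)

    @classmethod
    def from_coords(
        cls,
        coords: np.ndarray,
        segments: Mapping[str, tuple[int, int]] | None = None,
        author_numbering: tuple[int, ...] | None = None,
        helices: tuple[tuple[int, int], ...] | None = None,
        cutoff: float = CONTACT_CUTOFF,
        min_separation: int = CONTACT_MIN_SEPARATION,
    ) -> "NativeStructure":
        """Build a native structure, extracting contacts with the default rule."""
        coords = np.asarray(coords, dtype=float)
        n = coords.shape[0]
        if segments is None:
            segments = {"global": (1, n)}
        contacts = _contacts_from_coords(coords, cutoff, min_separation)
        return cls(
            coords=coords,
            segments=dict(segments),
            native_contacts=contacts,
            author_numbering=author_numbering,
            helices=helices,
        )

    def segment_slice(self, name: str) -> slice:
        lo, hi = self.segments[name]
        return slice(lo - 1, hi)


@dataclass(frozen=True)
class Conformation:
    """A single Cα snapshot with its simulation time (engine time units)."""

    coords: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("conformation coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]


class Trajectory:
    """Time-ordered stack of Cα frames.

    Stored internally as an ``(n_frames, n_residues, 3)`` array plus a time
    vector; iteration yields :class:`Conformation` objects.
    """

    def __init__(
        self,
        xyz: np.ndarray,
        times: np.ndarray,
        metadata: dict | None = None,
    ) -> None:
        xyz = np.asarray(xyz, dtype=float)
        times = np.asarray(times, dtype=float)
        if xyz.ndim != 3 or xyz.shape[2] != 3:
            raise ValueError("xyz must be (n_frames, n_residues, 3)")
        if times.shape != (xyz.shape[0],):
            raise ValueError("times must have one entry per frame")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.xyz = xyz
        self.times = times
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return self.xyz.shape[0]

    def __getitem__(self, i: int) -> Conformation:
        return Conformation(self.xyz[i], time=float(self.times[i]))

    def __iter__(self) -> Iterator[Conformation]:
        for i in range(len(self)):
            yield self[i]

    @property
    def n_residues(self) -> int:
        return self.xyz.shape[1]

    @classmethod
    def from_frames(
        cls, frames: list[Conformation], metadata: dict | None = None
    ) -> "Trajectory":
        xyz = np.stack([f.coords for f in frames])
        times = np.array([f.time for f in frames])
        return cls(xyz, times, metadata)


# ---------------------------------------------------------------------------
# PDB I/O


def read_ca_structure(
    path: str | Path,
    chain: str | None = None,
    segments: Mapping[str, tuple[int, int]] | None = None,
) -> NativeStructure:
    """Read a Cα trace from a PDB file.

    One Cα per residue, in residue order.  Alternate locations are resolved
    to the highest-occupancy conformer.  Residues are renumbered 1..n
    (original author numbering kept as metadata).

    Parameters
    ----------
    path:
        PDB file path.
    chain:
        Chain identifier; defaults to the first chain in the file.
    segments:
        Optional named 1-based inclusive residue ranges; defaults to a
        single ``global`` segment spanning the whole chain.

    Raises
    ------
    ValueError
        If any residue in the chain lacks a Cα atom (the residue is named
        in the message), or the chain has fewer than 5 residues.
    """
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    atoms = atoms[~atoms.hetero]
    if chain is None:
        chain = atoms.chain_id[0]
    atoms = atoms[atoms.chain_id == chain]
    if atoms.array_length() == 0:
        raise ValueError(f"chain {chain!r} not found or empty")

    author_ids: list[int] = []
    coords: list[np.ndarray] = []
    res_starts = bst.get_residue_starts(atoms)
    for k, start in enumerate(res_starts):
        stop = res_starts[k + 1] if k + 1 < len(res_starts) else atoms.array_length()
        residue = atoms[start:stop]
        ca = residue[residue.atom_name == "CA"]
        if ca.array_length() == 0:
            raise ValueError(
                f"residue {residue.res_name[0]} {residue.res_id[0]} "
                f"(chain {chain}) has no CA atom"
            )
        coords.append(ca.coord[0])
        author_ids.append(int(residue.res_id[0]))
    if len(coords) < 5:
        raise ValueError(f"chain {chain!r} has fewer than 5 residues with CA")
    return NativeStructure.from_coords(
        np.array(coords),
        segments=segments,
        author_numbering=tuple(author_ids),
    )


def write_ca_structure(
    structure: NativeStructure | Conformation, path: str | Path
) -> None:
    """Write a Cα trace as fixed-width PDB ATOM records (one CA per residue).

    Raises ``ValueError`` on non-finite coordinates before any bytes are
    written.
    """
    coords = np.asarray(structure.coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("refusing to write non-finite coordinates")
    n = coords.shape[0]
    atoms = bst.AtomArray(n)
    atoms.coord = coords
    atoms.chain_id[:] = "A"
    atoms.res_id[:] = np.arange(1, n + 1)
    atoms.res_name[:] = "ALA"
    atoms.atom_name[:] = "CA"
    atoms.element[:] = "C"
    atoms.hetero[:] = False
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Superposition and contacts


def _range_coords(coords: np.ndarray, residue_range: tuple[int, int]) -> np.ndarray:
    lo, hi = residue_range
    if not (1 <= lo <= hi <= coords.shape[0]):
        raise ValueError(f"residue range ({lo}, {hi}) invalid for {coords.shape[0]} residues")
    return coords[lo - 1 : hi]


def superpose_rmsd(
    mobile: Conformation | np.ndarray,
    reference: NativeStructure | np.ndarray,
    residue_range: tuple[int, int] | None = None,
) -> float:
    """Minimum Cα RMSD over all proper rigid-body transforms (Kabsch).

    Both point sets are restricted to ``residue_range`` (1-based inclusive;
    default: all residues), centred, and optimally rotated.  Reflections are
    excluded: the rotation is always proper, as in standard trajectory
    analysis tools.

    Raises
    ------
    ValueError
        Fewer than 3 residues in the range, or degenerate (collinear)
        coordinates in either set.
    """
    mob = mobile.coords if isinstance(mobile, Conformation) else np.asarray(mobile, float)
    ref = reference.coords if isinstance(reference, NativeStructure) else np.asarray(reference, float)
    if mob.shape != ref.shape:
        raise ValueError("mobile and reference must have the same residue count")
    if residue_range is not None:
        mob = _range_coords(mob, residue_range)
        ref = _range_coords(ref, residue_range)
    n = mob.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 residues")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    for pts, label in ((mob_c, "mobile"), (ref_c, "reference")):
        if np.linalg.matrix_rank(pts, tol=1e-9) < 2:
            raise ValueError(f"{label} coordinates are collinear (degenerate)")
    # Rotation.align_vectors solves the orthogonal Procrustes problem with a
    # proper rotation (Kabsch with determinant correction).  The RMSD is
    # recomputed from the rotated coordinates: the rssd returned by scipy
    # loses ~1e-7 absolute precision to cancellation near zero.
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    d = ref_c - rot.apply(mob_c)
    return float(np.sqrt((d**2).sum() / n))


def _contacts_from_coords(
    coords: np.ndarray, cutoff: float, min_separation: int
) -> frozenset[tuple[int, int]]:
    n = coords.shape[0]
    d = cdist(coords, coords)
    i_idx, j_idx = np.triu_indices(n, k=1)
    mask = ((j_idx - i_idx) > min_separation) & (d[i_idx, j_idx] < cutoff)
    return frozenset(
        (int(i) + 1, int(j) + 1) for i, j in zip(i_idx[mask], j_idx[mask])
    )


def extract_native_contacts(
    native: NativeStructure | np.ndarray,
    cutoff: float = CONTACT_CUTOFF,
    min_separation: int = CONTACT_MIN_SEPARATION,
) -> frozenset[tuple[int, int]]:
    """All unordered residue pairs (i, j) with |i-j| > min_separation and
    Cα–Cα distance strictly below ``cutoff`` (defaults: 7 Å, 3 residues).

    Pairs are 1-based with i < j.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    if min_separation < 0:
        raise ValueError("min_separation must be non-negative")
    coords = native.coords if isinstance(native, NativeStructure) else np.asarray(native, float)
    return _contacts_from_coords(coords, cutoff, min_separation)
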