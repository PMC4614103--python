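"""Trajectory analysis: order parameters, landscapes and passage times.

The analysis stack mirrors standard practice for folding trajectories of a
small three-helix bundle:

* per-frame Cα RMSDs to the native structure — the whole chain excluding
  the flexible terminal residues, plus two overlapping segments (N-segment,
  helices I–II; C-segment, helices II–III), each with its own independent
  superposition;
* long-range contact ratios Q_nat (native contacts formed / all native
  contacts) and Q_non (non-native contacts formed / all native contacts),
  both using the geometric contact rule (Cα–Cα < 7 Å, |i−j| > 3);
* a 2-D free-energy landscape over (RMSD_N, RMSD_C), F = −RT·ln(N/N_T) in
  kcal/mol with 0.1 Å × 0.1 Å bins, pooled over trajectories;
* a four-state classification per frame: folded (F), on-pathway
  intermediate (I_on, C-segment native first), off-pathway intermediate
  (I_off, N-segment native), unfolded (U);
* mean first passage time to the folded state with non-folding
  trajectories censored at a cap, exactly as the censored-mean convention
  prints it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .structures import (
    CONTACT_CUTOFF,
    CONTACT_MIN_SEPARATION,
    Conformation,
    NativeStructure,
    Trajectory,
    extract_native_contacts,
    superpose_rmsd,
)

__all__ = [
    "GAS_CONSTANT_KCAL",
    "OrderParameterSeries",
    "FreeEnergyLandscape",
    "FptResult",
    "StateThresholds",
    "compute_order_parameters",
    "contact_ratios",
    "free_energy_landscape",
    "classify_state",
    "first_passage_times",
    "per_residue_contact_profile",
    "block_average",
]

#: Gas constant in kcal/(mol·K).
GAS_CONSTANT_KCAL = 1.987204e-3

STATE_LABELS = ("U", "I_on", "I_off", "F")


@dataclass(frozen=True)
class StateThresholds:
    """RMSD thresholds (Å) for the four-state classification.

    ``folded`` is the global folded criterion (RMSD < 2 Å).  ``segment`` is
    the per-segment folded criterion used to tell the intermediates apart;
    basin boundaries on a landscape are a visual convention, so this
    package uses the same 2 Å rule for segments by default (configurable).
    """

    folded: float = 2.0
    segment: float = 2.0


def classify_state(
    rmsd_N: float,
    rmsd_C: float,
    rmsd_global: float,
    thresholds: StateThresholds | None = None,
) -> str:
    """Label a frame as ``F``, ``I_on``, ``I_off`` or ``U``.

    F: global RMSD strictly below the folded threshold.  Otherwise I_on if
    the C-segment is native while the N-segment is not (the productive
    route folds the C-segment first), I_off for the mirror case (the
    misfolded intermediate forms the N-segment), else U.  All comparisons
    are strict on the folded side, so a frame exactly at a threshold is
    not folded.
    """
    t = thresholds or StateThresholds()
    if min(rmsd_N, rmsd_C, rmsd_global) < 0:
        raise ValueError("RMSDs must be non-negative")
    if rmsd_global < t.folded:
        return "F"
    if rmsd_C < t.segment <= rmsd_N:
        return "I_on"
    if rmsd_N < t.segment <= rmsd_C:
        return "I_off"
    return "U"


@dataclass
class OrderParameterSeries:
    """Per-frame order parameters for one trajectory."""

    times: np.ndarray
    rmsd_global: np.ndarray
    rmsd_N: np.ndarray
    rmsd_C: np.ndarray
    q_nat: np.ndarray
    q_non: np.ndarray
    state: np.ndarray  # dtype '<U5' labels

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("rmsd_global", "rmsd_N", "rmsd_C", "q_nat", "q_non", "state"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if np.any(self.q_nat < -1e-12) or np.any(self.q_nat > 1 + 1e-12):
            raise ValueError("q_nat must lie in [0, 1]")
        if np.any(self.q_non < -1e-12):
            raise ValueError("q_non must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "rmsd_global": self.rmsd_global,
                "rmsd_N": self.rmsd_N,
                "rmsd_C": self.rmsd_C,
                "q_nat": self.q_nat,
                "q_non": self.q_non,
                "state": self.state,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "OrderParameterSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(
            times=df["time"].to_numpy(float),
            rmsd_global=df["rmsd_global"].to_numpy(float),
            rmsd_N=df["rmsd_N"].to_numpy(float),
            rmsd_C=df["rmsd_C"].to_numpy(float),
            q_nat=df["q_nat"].to_numpy(float),
            q_non=df["q_non"].to_numpy(float),
            state=df["state"].to_numpy(str),
        )


def contact_ratios(
    conformation: Conformation | np.ndarray,
    native: NativeStructure,
    cutoff: float = CONTACT_CUTOFF,
    min_separation: int = CONTACT_MIN_SEPARATION,
) -> tuple[float, float]:
    """Long-range native and non-native contact ratios of a snapshot.

    The snapshot contact set C uses the same geometric rule as the native
    set S.  Q_nat = |C ∩ S| / |S| and Q_non = |C \\ S| / |S|; the
    denominator is the native contact count in both, so Q_non may exceed 1
    for highly collapsed non-native conformations.
    """
    s_nat = native.native_contacts
    if not s_nat:
        raise ValueError("native contact set is empty")
    coords = (
        conformation.coords
        if isinstance(conformation, Conformation)
        else np.asarray(conformation, float)
    )
    snap = extract_native_contacts(coords, cutoff=cutoff, min_separation=min_separation)
    n_nat = len(snap & s_nat)
    n_non = len(snap - s_nat)
    return n_nat / len(s_nat), n_non / len(s_nat)


def compute_order_parameters(
    traj: Trajectory | Sequence[Conformation],
    native: NativeStructure,
    thresholds: StateThresholds | None = None,
) -> OrderParameterSeries:
    """Order parameters for every frame of a trajectory.

    Requires the native structure to define ``global``, ``N`` and ``C``
    segments.  Each RMSD uses its own independent superposition over its
    own residue range, matching the per-selection convention of standard
    trajectory tools.
    """
    frames = list(traj) if not isinstance(traj, Trajectory) else traj
    if len(frames) == 0:
        raise ValueError("trajectory is empty")
    for key in ("global", "N", "C"):
        if key not in native.segments:
            raise ValueError(f"native structure lacks segment {key!r}")
    n = len(frames)
    times = np.empty(n)
    rg = np.empty(n)
    rn = np.empty(n)
    rc = np.empty(n)
    qn = np.empty(n)
    qx = np.empty(n)
    st = np.empty(n, dtype="<U5")
    for k in range(n):
        frame = frames[k]
        if frame.coords.shape[0] != native.n_residues:
            raise ValueError("frame residue count does not match native structure")
        times[k] = frame.time
        rg[k] = superpose_rmsd(frame.coords, native, native.segments["global"])
        rn[k] = superpose_rmsd(frame.coords, native, native.segments["N"])
        rc[k] = superpose_rmsd(frame.coords, native, native.segments["C"])
        qn[k], qx[k] = contact_ratios(frame.coords, native)
        st[k] = classify_state(rn[k], rc[k], rg[k], thresholds)
    return OrderParameterSeries(times, rg, rn, rc, qn, qx, st)


# ---------------------------------------------------------------------------
# Free-energy landscape


@dataclass
class FreeEnergyLandscape:
    """2-D binned free-energy surface over (RMSD_N, RMSD_C).

    ``free_energy`` is defined only where ``counts > 0`` (see ``mask``);
    empty bins carry NaN rather than an infinite sentinel.
    """

    bin_edges_x: np.ndarray
    bin_edges_y: np.ndarray
    counts: np.ndarray
    free_energy: np.ndarray
    mask: np.ndarray  # True where the bin is empty
    temperature: float
    gas_constant: float = GAS_CONSTANT_KCAL

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def minimum_bin(self) -> tuple[int, int]:
        """Indices of the bin with the lowest free energy (= modal bin)."""
        fe = np.where(self.mask, np.inf, self.free_energy)
        return tuple(np.unravel_index(np.argmin(fe), fe.shape))

    def to_tsv(self, path, edges_path=None) -> None:
        """Dense TSV matrix of free energies (NaN for empty bins); bin
        edges written to an optional sidecar."""
        np.savetxt(path, self.free_energy, delimiter="\t", fmt="%.6f")
        if edges_path is not None:
            with open(edges_path, "w") as fh:
                fh.write("# bin edges, Å (x = RMSD_N rows, y = RMSD_C columns)\n")
                fh.write("x\t" + "\t".join(f"{e:.4f}" for e in self.bin_edges_x) + "\n")
                fh.write("y\t" + "\t".join(f"{e:.4f}" for e in self.bin_edges_y) + "\n")


def free_energy_landscape(
    series_list: Iterable[OrderParameterSeries],
    temperature: float = 300.0,
    bin_width: float = 0.1,
) -> FreeEnergyLandscape:
    """Pooled 2-D free-energy landscape over (RMSD_N, RMSD_C).

    Frames from all trajectories are pooled into one histogram with
    half-open square bins [lo, hi) of ``bin_width`` Å anchored at 0, and
    F_bin = −R·T·ln(N_bin / N_T) in kcal/mol.  The modal bin therefore
    attains the minimum free energy, and Σ_bins N = N_T exactly.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    series_list = list(series_list)
    xs = np.concatenate([s.rmsd_N for s in series_list])
    ys = np.concatenate([s.rmsd_C for s in series_list])
    if xs.size == 0:
        raise ValueError("no frames to bin")
    ix = np.floor(xs / bin_width).astype(int)
    iy = np.floor(ys / bin_width).astype(int)
    nx = int(ix.max()) + 1
    ny = int(iy.max()) + 1
    counts = np.zeros((nx, ny), dtype=np.int64)
    np.add.at(counts, (ix, iy), 1)
    n_total = counts.sum()
    mask = counts == 0
    with np.errstate(divide="ignore"):
        fe = np.where(
            mask, np.nan, -GAS_CONSTANT_KCAL * temperature * np.log(counts / n_total)
        )
    edges_x = np.arange(nx + 1) * bin_width
    edges_y = np.arange(ny + 1) * bin_width
    return FreeEnergyLandscape(
        bin_edges_x=edges_x,
        bin_edges_y=edges_y,
        counts=counts,
        free_energy=fe,
        mask=mask,
        temperature=temperature,
    )


# ---------------------------------------------------------------------------
# First passage times


@dataclass
class FptResult:
    """Per-trajectory first passage times with right-censoring at a cap.

    A trajectory that never crosses the folded threshold is censored: its
    passage time is recorded as the cap itself, and the mean is the plain
    arithmetic mean over all trajectories (the censored-mean convention;
    it biases the estimate low when censoring is heavy).
    """

    fpt: np.ndarray
    censored: np.ndarray
    cap: float

    def __post_init__(self) -> None:
        if np.any(self.fpt > self.cap + 1e-12):
            raise ValueError("passage times must not exceed the cap")

    @property
    def mfpt(self) -> float:
        return float(np.mean(self.fpt))

    def kaplan_meier_mean(self) -> float:
        """Restricted mean survival time up to the cap via the product-limit
        estimator — an alternative to the cap-substitution mean.  With all
        observed events distinct it reduces to the same arithmetic mean, and
        it diverges from it only under tied censoring structure."""
        order = np.argsort(self.fpt)
        t_sorted = self.fpt[order]
        d_sorted = ~self.censored[order]
        n = len(t_sorted)
        at_risk = n
        surv = 1.0
        mean = 0.0
        prev_t = 0.0
        for t, event in zip(t_sorted, d_sorted):
            mean += surv * (t - prev_t)
            prev_t = t
            if event:
                surv *= 1.0 - 1.0 / at_risk
            at_risk -= 1
        mean += surv * (self.cap - prev_t)
        return float(mean)


def first_passage_times(
    series_list: Iterable[OrderParameterSeries],
    folded_threshold: float = 2.0,
    cap: float = 3.0,
) -> FptResult:
    """First passage time to the folded state per trajectory, censored mean.

    FPT is the time of the first frame with global RMSD strictly below
    ``folded_threshold``; trajectories that never cross are censored at
    ``cap``.  ``series_list`` may also contain pre-computed passage times
    (floats), which is convenient when only the printed times of published
    runs are available; a float above the cap is treated as censored.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    fpts: list[float] = []
    censored: list[bool] = []
    for item in series_list:
        if isinstance(item, (int, float)):
            t = float(item)
            if t >= cap:
                fpts.append(cap)
                censored.append(True)
            else:
                fpts.append(t)
                censored.append(False)
            continue
        if len(item) == 0:
            raise ValueError("empty order-parameter series")
        below = item.rmsd_global < folded_threshold
        if np.any(below):
            t = float(item.times[np.argmax(below)])
            if t >= cap:
                fpts.append(cap)
                censored.append(True)
            else:
                fpts.append(t)
                censored.append(False)
        else:
            fpts.append(cap)
            censored.append(True)
    if not fpts:
        raise ValueError("no trajectories given")
    return FptResult(np.array(fpts), np.array(censored), cap)


# ---------------------------------------------------------------------------
# Per-residue contacts and averaging


def per_residue_contact_profile(
    conformation: Conformation | np.ndarray,
    native: NativeStructure,
) -> np.ndarray:
    """Fraction of each residue's native contacts formed in a snapshot.

    Entry i−1 is the fraction of native contacts involving residue i that
    are present in the snapshot (same geometric rule).  Residues with no
    native contacts are flagged with NaN.  Useful for spotting linker
    regions whose contacts only form partially.
    """
    s_nat = native.native_contacts
    if not s_nat:
        raise ValueError("native contact set is empty")
    coords = (
        conformation.coords
        if isinstance(conformation, Conformation)
        else np.asarray(conformation, float)
    )
    snap = extract_native_contacts(coords)
    formed = snap & s_nat
    n = native.n_residues
    total = np.zeros(n)
    hit = np.zeros(n)
    for i, j in s_nat:
        total[i - 1] += 1
        total[j - 1] += 1
    for i, j in formed:
        hit[i - 1] += 1
        hit[j - 1] += 1
    with np.errstate(invalid="ignore"):
        return np.where(total > 0, hit / np.maximum(total, 1), np.nan)


def block_average(
    times: np.ndarray, values: np.ndarray, window: float
) -> tuple[np.ndarray, np.ndarray]:
    """Average ``values`` in consecutive time blocks of width ``window``.

    Returns block-centre times and block means; blocks without frames are
    dropped.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    idx = np.floor(np.asarray(times) / window).astype(int)
    out_t, out_v = [], []
    for b in np.unique(idx):
        sel = idx == b
        out_t.append((b + 0.5) * window)
        out_v.append(float(np.mean(np.asarray(values)[sel])))
    return np.array(out_t), np.array(out_v)
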