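"""Trajectory analytics: superposition, RMSD, RMSF, DCCM, H-bond occupancy.

Operates on a plain in-memory frame array (F x N x 3, Angstrom) with per-atom
masses and residue assignments. Readers cover multi-model PDB (via
MDAnalysis) and a whitespace xyz-per-frame table. Inputs are assumed imaged:
no periodic-boundary handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "Trajectory",
    "CorrelationMatrix",
    "read_pdb",
    "read_xyz_table",
    "superpose",
    "rmsd_series",
    "rmsf",
    "dccm",
    "hbond_occupancy",
]


@dataclass(frozen=True)
class Trajectory:
    """F frames of N atoms with masses (amu) and residue assignments."""

    frames: np.ndarray          # (F, N, 3)
    masses: np.ndarray          # (N,)
    residue_of: np.ndarray      # (N,) integer residue ids
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        object.__setattr__(self, "residue_of", np.asarray(self.residue_of, dtype=int))
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, N, 3)")
        n = self.frames.shape[1]
        if self.masses.shape != (n,) or np.any(self.masses <= 0):
            raise ValueError("masses must be positive, one per atom")
        if self.residue_of.shape != (n,):
            raise ValueError("residue_of must give one residue id per atom")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @classmethod
    def from_frames(cls, frames, masses=None, residue_of=None, labels=()) -> "Trajectory":
        frames = np.asarray(frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        n = frames.shape[1]
        if masses is None:
            masses = np.ones(n)
        if residue_of is None:
            residue_of = np.arange(n)
        return cls(frames, masses, residue_of, tuple(labels))


@dataclass(frozen=True)
class CorrelationMatrix:
    """Normalized displacement cross-correlations, entries in [-1, 1].

    ``undefined`` marks atoms whose displacement variance is zero; their
    rows/columns are NaN (reported missing, never silently 0).
    """

    matrix: np.ndarray
    undefined: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> Trajectory:
    """Read a (multi-model) PDB file into a Trajectory.

    Masses come from the reader's element inference; atoms it cannot assign
    fall back to 1 amu with a warning. Residue numbering is preserved.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # mass-guessing chatter
        u = mda.Universe(str(path))
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
        masses = np.asarray(u.atoms.masses, dtype=float).copy()
    bad = ~(masses > 0)
    if bad.any():
        warnings.warn(f"{bad.sum()} atom(s) without inferable mass; using 1 amu")
        masses[bad] = 1.0
    labels = tuple(f"{n}" for n in u.atoms.names)
    return Trajectory(frames, masses, np.asarray(u.atoms.resids, dtype=int), labels)


def read_xyz_table(path: str | Path, masses=None, residue_of=None) -> Trajectory:
    """Read a whitespace table with columns frame, atom, x, y, z.

    Frames must contain the same atoms in the same order. Masses default to
    1 amu and residues to one per atom unless provided.
    """
    df = pd.read_csv(
        path, sep=r"\s+", comment="#",
        names=["frame", "atom", "x", "y", "z"], header=None,
    )
    if df.iloc[0].astype(str).str.match(r"^[A-Za-z]").drop(["atom"]).any():
        df = df.iloc[1:].reset_index(drop=True)  # tolerate a header row
    df = df.astype({"frame": int, "x": float, "y": float, "z": float})
    n_per = df.groupby("frame").size()
    if n_per.nunique() != 1:
        raise ValueError("all frames must contain the same number of atoms")
    n_atoms = int(n_per.iloc[0])
    frames = df[["x", "y", "z"]].to_numpy().reshape(-1, n_atoms, 3)
    labels = tuple(str(a) for a in df["atom"].iloc[:n_atoms])
    return Trajectory.from_frames(frames, masses, residue_of, labels)


# ---------------------------------------------------------------------------
# Superposition and deviation metrics
# ---------------------------------------------------------------------------

def _selection_indices(traj: Trajectory, selection) -> np.ndarray:
    idx = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    return idx


def superpose(traj: Trajectory, ref: np.ndarray, selection=None) -> Trajectory:
    """Rigid-body align every frame onto ``ref`` (least squares on selection).

    The optimal rotation is the standard Kabsch/quaternion solution; the
    selection needs at least 3 non-collinear atoms for it to be unique.
    """
    idx = _selection_indices(traj, selection)
    ref = np.asarray(ref, dtype=float)
    if ref.shape != (traj.n_atoms, 3):
        raise ValueError("ref must match the trajectory's atom count")
    ref_sel = ref[idx]
    if idx.size < 3 or _collinear(ref_sel):
        raise ValueError("need at least 3 non-collinear selected atoms")
    ref_centroid = ref_sel.mean(axis=0)

    aligned = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        mob_sel = traj.frames[f][idx]
        mob_centroid = mob_sel.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_sel - ref_centroid, mob_sel - mob_centroid)
        aligned[f] = rot.apply(traj.frames[f] - mob_centroid) + ref_centroid
    return replace(traj, frames=aligned)


def _collinear(points: np.ndarray, tol: float = 1e-10) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s.size < 2 or s[1] <= tol * max(s[0], 1.0)


def rmsd_series(
    traj: Trajectory,
    ref: np.ndarray,
    selection=None,
    mass_weighted: bool = True,
    align: bool = False,
) -> np.ndarray:
    """Per-frame (mass-weighted) RMSD to a reference structure, Angstrom.

    RMSD(t) = sqrt( sum_i m_i |r_i(t) - r'_i|^2 / sum_i m_i ) over the
    selection; with ``mass_weighted=False`` all weights are 1.
    """
    idx = _selection_indices(traj, selection)
    ref = np.asarray(ref, dtype=float)
    if ref.shape != (traj.n_atoms, 3):
        raise ValueError("ref must match the trajectory's atom count")
    if align:
        traj = superpose(traj, ref, selection=idx)
    w = traj.masses[idx] if mass_weighted else np.ones(idx.size)
    d2 = ((traj.frames[:, idx] - ref[idx]) ** 2).sum(axis=2)
    return np.sqrt((d2 * w).sum(axis=1) / w.sum())


def rmsf(traj: Trajectory, level: str = "atom", reference: np.ndarray | None = None):
    """Positional fluctuations, Angstrom.

    Atom level: sqrt of the time-mean squared displacement of each atom from
    its time-mean position (or from ``reference`` when given). Residue
    level: the mass-weighted average of the atomic values over each
    residue's atoms, returned as a dict {residue_id: value}.
    """
    mean = traj.frames.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    atom_vals = np.sqrt(((traj.frames - mean) ** 2).sum(axis=2).mean(axis=0))
    if level == "atom":
        return atom_vals
    if level != "residue":
        raise ValueError(f"level must be 'atom' or 'residue', got {level!r}")
    out: dict[int, float] = {}
    for res in np.unique(traj.residue_of):
        sel = traj.residue_of == res
        m = traj.masses[sel]
        out[int(res)] = float((atom_vals[sel] * m).sum() / m.sum())
    return out


def dccm(traj: Trajectory, selection=None, presuperposed: bool = True) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix of atomic displacements.

    C_ij = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>) with dr the displacement
    from the time-mean position (3-D scalar products). The trajectory should
    be superposed first to remove global motion; pass
    ``presuperposed=False`` to have that done here against the mean of the
    first frame. Zero-variance atoms give NaN rows/columns and are listed
    in ``undefined``.
    """
    idx = _selection_indices(traj, selection)
    if not presuperposed:
        traj = superpose(traj, traj.frames[0], selection=idx)
    disp = traj.frames[:, idx] - traj.frames[:, idx].mean(axis=0)
    cov = np.einsum("fik,fjk->ij", disp, disp) / traj.n_frames
    var = np.diag(cov).copy()
    undefined = tuple(int(i) for i in np.nonzero(var <= 0)[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.where(var > 0, var, np.nan))
        c = cov / denom[:, None] / denom[None, :]
    keep = var > 0
    c[np.ix_(keep, keep)] = np.clip(c[np.ix_(keep, keep)], -1.0, 1.0)
    np.fill_diagonal(c, np.where(keep, 1.0, np.nan))
    return CorrelationMatrix(c, undefined)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def hbond_occupancy(
    traj: Trajectory,
    donors,
    acceptors,
    distance_cutoff: float = 3.5,
    angle_min: float = 120.0,
    angle_max: float = 180.0,
    distance_mode: str = "donor-acceptor",
):
    """Geometric hydrogen-bond statistics over a trajectory.

    A frame counts a bond for donor pair (D, H) and acceptor A when the
    distance (D...A by default, H...A with ``distance_mode='hydrogen-
    acceptor'``) is < ``distance_cutoff`` Angstrom and the D-H...A angle is
    strictly between ``angle_min`` and ``angle_max`` degrees (a perfectly
    linear 180 deg geometry is excluded by the strict upper bound).

    Returns ``(per_pair, total)``: occupancy (fraction of frames) per
    (D, H, A) triple, and the mean bond count per frame. Geometrically
    degenerate pairs (coincident atoms) are skipped with a warning.
    """
    if distance_mode not in ("donor-acceptor", "hydrogen-acceptor"):
        raise ValueError(f"unknown distance_mode {distance_mode!r}")
    donors = [(int(d), int(h)) for d, h in donors]
    acceptors = [int(a) for a in acceptors]
    per_pair: dict[tuple[int, int, int], float] = {}
    f = traj.frames
    for d, h in donors:
        for a in acceptors:
            if a in (d, h):
                continue
            dist_pair = (d, a) if distance_mode == "donor-acceptor" else (h, a)
            dist = np.linalg.norm(f[:, dist_pair[0]] - f[:, dist_pair[1]], axis=1)
            v1 = f[:, d] - f[:, h]
            v2 = f[:, a] - f[:, h]
            n1 = np.linalg.norm(v1, axis=1)
            n2 = np.linalg.norm(v2, axis=1)
            degenerate = (n1 <= 0) | (n2 <= 0)
            if degenerate.any():
                warnings.warn(
                    f"skipping pair D={d},H={h},A={a}: coincident atoms make "
                    "the angle undefined"
                )
                continue
            cosang = np.clip((v1 * v2).sum(axis=1) / (n1 * n2), -1.0, 1.0)
            ang = np.degrees(np.arccos(cosang))
            hit = (dist < distance_cutoff) & (ang > angle_min) & (ang < angle_max)
            per_pair[(d, h, a)] = float(hit.mean())
    total = float(sum(per_pair.values()))
    return per_pair, total
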