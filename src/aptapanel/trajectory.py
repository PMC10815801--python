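"""MD trajectory post-processing: superposition RMSD, GROMOS conformational
clustering, and hydrogen-bond occupancy.

A :class:`Trajectory` is an ordered stack of coordinate frames (N atoms x 3,
in Angstrom) with atom labels and replicate boundaries (independent
simulation repeats concatenated along the frame axis).  All operations are
mass-unweighted and use every supplied atom.

* :func:`kabsch_superpose` computes the optimal rigid (proper-rotation)
  superposition of one coordinate set onto another and the resulting RMSD.
* :func:`gromos_cluster` implements the greedy neighbor-counting clustering
  of conformations on the pairwise superposed-RMSD matrix: the frame with
  the most unassigned neighbors within the cutoff becomes the next cluster's
  centroid, that frame and its neighbors are removed, and the procedure
  repeats until all frames are assigned.
* :func:`hbond_occupancy` scores donor-hydrogen-acceptor triples with a
  geometric criterion (donor-acceptor distance and D-H...A angle at the
  hydrogen) and reports the percentage of frames satisfying each, flagging
  those above an occupancy floor (20% by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "ClusterResult",
    "HBondSpec",
    "kabsch_superpose",
    "rmsd_series",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "hbond_occupancy",
]

DEFAULT_HBOND_DISTANCE = 3.5  # donor-acceptor, Angstrom
DEFAULT_HBOND_ANGLE = 135.0  # D-H...A at the hydrogen, degrees


@dataclass
class Trajectory:
    """Ordered coordinate frames with atom labels and replicate boundaries.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom.  ``labels`` is
    one string per atom (conventionally ``name:residue``), identical across
    frames.  ``replicate_boundaries`` holds the strictly increasing start
    index of each replicate after the first; an empty tuple means a single
    replicate.  ``frame_spacing_ns`` is metadata only.
    """

    coords: np.ndarray
    labels: tuple[str, ...]
    replicate_boundaries: tuple[int, ...] = ()
    frame_spacing_ns: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.coords.shape[1]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.coords.shape[1]} atoms"
            )
        b = tuple(int(i) for i in self.replicate_boundaries)
        if any(x >= y for x, y in zip(b, b[1:])) or any(
            not 0 < i < self.n_frames for i in b
        ):
            raise ValueError("replicate boundaries must be strictly increasing "
                             "interior frame indices")
        self.replicate_boundaries = b

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_boundaries) + 1

    def replicate_slices(self) -> list[slice]:
        edges = (0, *self.replicate_boundaries, self.n_frames)
        return [slice(a, b) for a, b in zip(edges, edges[1:])]

    def atom_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown atom label {label!r}") from None


def kabsch_superpose(
    P: np.ndarray, Q: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``Q`` onto ``P`` (Kabsch algorithm).

    Returns ``(rotation, translation, rmsd)`` such that
    ``Q @ rotation.T + translation`` minimises the RMSD to ``P`` over all
    proper rotations and translations (reflections excluded).  Requires at
    least 3 non-collinear atoms in each set.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must both have shape (n_atoms, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms for superposition")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    if _collinear(Pc) or _collinear(Qc):
        raise ValueError("degenerate (collinear) coordinates")
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = P.mean(axis=0) - Q.mean(axis=0) @ R.T
    diff = Qc @ R.T - Pc
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return R, t, rmsd


def _collinear(centered: np.ndarray, tol: float = 1e-10) -> bool:
    s = np.linalg.svd(centered, compute_uv=False)
    return bool((s[1:] < tol * max(s[0], 1.0)).all())


def superposed_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    return kabsch_superpose(P, Q)[2]


def rmsd_series(traj: Trajectory, reference: int = 0) -> pd.DataFrame:
    """Per-frame RMSD (after superposition) to a reference frame.

    Returns a table with frame index, replicate index, time (ns) and RMSD.
    """
    if not 0 <= reference < traj.n_frames:
        raise IndexError(f"reference frame {reference} out of range")
    ref = traj.coords[reference]
    values = np.array([superposed_rmsd(ref, frame) for frame in traj.coords])
    replicate = np.zeros(traj.n_frames, dtype=int)
    for i, sl in enumerate(traj.replicate_slices()):
        replicate[sl] = i
    return pd.DataFrame(
        {
            "frame": np.arange(traj.n_frames),
            "replicate": replicate,
            "time_ns": np.arange(traj.n_frames) * traj.frame_spacing_ns,
            "rmsd": values,
        }
    )


def pairwise_rmsd_matrix(traj: Trajectory) -> np.ndarray:
    """Symmetric matrix of pairwise superposed RMSDs (per-pair fitting)."""
    n = traj.n_frames
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = superposed_rmsd(traj.coords[i], traj.coords[j])
    return m


@dataclass
class ClusterResult:
    """Frame-to-cluster assignment with representative (centroid) frames.

    Clusters are numbered 0, 1, ... in extraction order, which for the
    GROMOS algorithm is descending size order (largest first, ties by
    extraction sequence); ``centroids[k]`` is the representative frame of
    cluster ``k`` and ``sizes[k]`` its member count.
    """

    assignment: np.ndarray
    centroids: tuple[int, ...]
    sizes: tuple[int, ...]

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def members(self, k: int) -> np.ndarray:
        return np.nonzero(self.assignment == k)[0]


def gromos_cluster(
    traj: Trajectory, cutoff: float = 2.5, rmsd_matrix: np.ndarray | None = None
) -> ClusterResult:
    """GROMOS conformational clustering at an RMSD ``cutoff`` (Angstrom).

    Repeatedly: among unassigned frames, the frame with the most unassigned
    neighbors within the cutoff (ties broken by lowest frame index) becomes
    the next cluster's centroid, and it and those neighbors are removed.
    Cluster indices are then relabelled in descending size order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    m = pairwise_rmsd_matrix(traj) if rmsd_matrix is None else np.asarray(rmsd_matrix)
    n = traj.n_frames
    within = (m <= cutoff)
    unassigned = np.ones(n, dtype=bool)
    raw: list[tuple[int, np.ndarray]] = []
    while unassigned.any():
        candidates = np.nonzero(unassigned)[0]
        neighbor_counts = within[np.ix_(candidates, candidates)].sum(axis=1)
        centroid = int(candidates[int(np.argmax(neighbor_counts))])  # argmax: lowest index on ties
        members = candidates[within[centroid, candidates]]
        raw.append((centroid, members))
        unassigned[members] = False
    order = sorted(range(len(raw)), key=lambda i: (-len(raw[i][1]), i))
    assignment = np.full(n, -1, dtype=int)
    centroids, sizes = [], []
    for new_k, i in enumerate(order):
        centroid, members = raw[i]
        assignment[members] = new_k
        centroids.append(centroid)
        sizes.append(len(members))
    return ClusterResult(assignment=assignment, centroids=tuple(centroids), sizes=tuple(sizes))


@dataclass(frozen=True)
class HBondSpec:
    """A donor-hydrogen-acceptor triple with its geometric criterion."""

    donor: str
    hydrogen: str
    acceptor: str
    distance_cutoff: float = DEFAULT_HBOND_DISTANCE
    angle_cutoff: float = DEFAULT_HBOND_ANGLE

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.angle_cutoff <= 180:
            raise ValueError("angle cutoff must be in (0, 180]")

    @property
    def label(self) -> str:
        return f"{self.donor}-{self.hydrogen}...{self.acceptor}"


def _dha_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Donor-hydrogen-acceptor angle at the hydrogen, in degrees."""
    v1 = d - h
    v2 = a - h
    cosang = (v1 * v2).sum(axis=-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def hbond_occupancy(
    traj: Trajectory,
    specs: Sequence[HBondSpec],
    min_occupancy_pct: float = 20.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Occupancy percentage per hydrogen-bond spec, pooled across replicates.

    A frame satisfies a spec when the donor-acceptor distance is at most the
    distance cutoff AND the D-H...A angle is at least the angle cutoff.
    Returns ``(table, report)``: the full table with pooled and per-replicate
    occupancies, and the report restricted to specs whose pooled occupancy
    exceeds ``min_occupancy_pct``, sorted descending.
    """
    rows = []
    slices = traj.replicate_slices()
    for spec in specs:
        di = traj.atom_index(spec.donor)
        hi = traj.atom_index(spec.hydrogen)
        ai = traj.atom_index(spec.acceptor)
        d = traj.coords[:, di]
        h = traj.coords[:, hi]
        a = traj.coords[:, ai]
        dist = np.linalg.norm(a - d, axis=-1)
        ang = _dha_angle(d, h, a)
        sat = (dist <= spec.distance_cutoff) & (ang >= spec.angle_cutoff)
        row = {
            "hbond": spec.label,
            "donor": spec.donor,
            "hydrogen": spec.hydrogen,
            "acceptor": spec.acceptor,
            "distance_cutoff": spec.distance_cutoff,
            "angle_cutoff": spec.angle_cutoff,
            "n_frames": traj.n_frames,
            "occupancy_pct": 100.0 * sat.sum() / traj.n_frames,
        }
        for i, sl in enumerate(slices):
            nrep = sl.stop - sl.start
            row[f"occupancy_pct_rep{i}"] = 100.0 * sat[sl].sum() / nrep
        rows.append(row)
    table = pd.DataFrame(rows)
    report = (
        table[table["occupancy_pct"] > min_occupancy_pct]
        .sort_values("occupancy_pct", ascending=False, ignore_index=True)
        if len(table)
        else table
    )
    return table, report
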