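"""Trajectory file I/O: multi-model PDB and plain whitespace frame tables.

Two interchangeable on-disk forms for :class:`~aptapanel.trajectory.Trajectory`:

* multi-model PDB (one ``MODEL``/``ENDMDL`` block per frame), via biotite —
  atom labels map to ``name:res_id``;
* a plain whitespace-delimited text table with columns
  ``frame  atom_label  x  y  z``, convenient for hand-built fixtures.

Replicate boundaries and frame spacing are not stored in either format and
are supplied by the caller on read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .trajectory import Trajectory

__all__ = ["write_pdb", "read_pdb", "write_frames_table", "read_frames_table"]


def _split_label(label: str) -> tuple[str, int]:
    name, _, res = label.partition(":")
    try:
        return name, int(res)
    except ValueError:
        return name, 1


def write_pdb(traj: Trajectory, path) -> None:
    """Write all frames as MODEL/ENDMDL blocks of a PDB file."""
    n_atoms = traj.n_atoms
    template = struc.AtomArray(n_atoms)
    names, res_ids = zip(*(_split_label(l) for l in traj.labels))
    template.atom_name = np.array(names, dtype="U6")
    template.res_id = np.array(res_ids, dtype=int)
    template.res_name = np.full(n_atoms, "UNK", dtype="U5")
    template.chain_id = np.full(n_atoms, "A", dtype="U4")
    template.element = np.array([n[0] if n else "C" for n in names], dtype="U2")
    stack = struc.from_template(template, traj.coords)
    f = pdb.PDBFile()
    pdb.set_structure(f, stack)
    f.write(str(path))


def read_pdb(
    path, replicate_boundaries: tuple[int, ...] = (), frame_spacing_ns: float = 1.0
) -> Trajectory:
    """Read a multi-model PDB file into a Trajectory."""
    f = pdb.PDBFile.read(str(path))
    stack = pdb.get_structure(f)
    if isinstance(stack, struc.AtomArray):  # single model
        coords = stack.coord[np.newaxis]
        names, res_ids = stack.atom_name, stack.res_id
    else:
        coords = stack.coord
        names, res_ids = stack.atom_name, stack.res_id
    labels = tuple(f"{n}:{r}" for n, r in zip(names, res_ids))
    return Trajectory(
        coords=np.asarray(coords, float),
        labels=labels,
        replicate_boundaries=replicate_boundaries,
        frame_spacing_ns=frame_spacing_ns,
    )


def write_frames_table(traj: Trajectory, path) -> None:
    """Write frames as a plain text table: frame, atom_label, x, y, z."""
    with open(path, "w") as handle:
        handle.write("frame atom x y z\n")
        for t in range(traj.n_frames):
            for a, label in enumerate(traj.labels):
                x, y, z = traj.coords[t, a]
                handle.write(f"{t} {label} {x:.6f} {y:.6f} {z:.6f}\n")


def read_frames_table(
    path, replicate_boundaries: tuple[int, ...] = (), frame_spacing_ns: float = 1.0
) -> Trajectory:
    """Read a whitespace-delimited frame table into a Trajectory."""
    df = pd.read_csv(path, sep=r"\s+")
    required = {"frame", "atom", "x", "y", "z"}
    if not required <= set(df.columns):
        raise ValueError(f"frames table lacks columns {sorted(required - set(df.columns))}")
    frames = sorted(df["frame"].unique())
    labels = tuple(df.loc[df["frame"] == frames[0], "atom"])
    coords = np.empty((len(frames), len(labels), 3))
    for i, t in enumerate(frames):
        sub = df[df["frame"] == t]
        if tuple(sub["atom"]) != labels:
            raise ValueError(f"frame {t}: atom labels or order differ from frame {frames[0]}")
        coords[i] = sub[["x", "y", "z"]].to_numpy(float)
    return Trajectory(
        coords=coords,
        labels=labels,
        replicate_boundaries=replicate_boundaries,
        frame_spacing_ns=frame_spacing_ns,
    )
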