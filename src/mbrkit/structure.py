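"""Atomic structures, trajectories, atom selections and coordinate file I/O.

A :class:`Frame` is a flat, array-backed snapshot of atoms (element, atom
name, residue id/name, chain, Cartesian coordinates in Angstrom) with an
optional timestamp; a :class:`Trajectory` is an ordered list of frames.
PDB reading/writing (including multi-model MODEL/ENDMDL trajectories) is
delegated to biotite; the minimalist XYZ trajectory format is handled
directly.

Selections use a small textual grammar of ``and``-joined clauses::

    element P
    name CA and resid 436-488
    chain A and resname CDL
    not resname ACY

Each clause is ``<key> <values>`` where values are comma-separated tokens
and ``resid`` accepts ``start-end`` ranges.  ``all`` matches every atom.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence, Union

import numpy as np

from .constants import ATOMIC_MASSES
from .errors import InputError

Selection = Union[str, Callable[["Frame"], np.ndarray], np.ndarray, None]


@dataclass
class Frame:
    """One snapshot of atomic coordinates.

    All per-atom fields are numpy arrays of equal length; ``coords`` has
    shape ``(n_atoms, 3)`` in Angstrom.
    """

    elements: np.ndarray
    atom_names: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chains: np.ndarray
    coords: np.ndarray
    time_ps: float = 0.0

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype="U4")
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype="U4")
        self.chains = np.asarray(self.chains, dtype="U2")
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        n = len(self.elements)
        for arr in (self.atom_names, self.res_ids, self.res_names, self.chains):
            if len(arr) != n:
                raise InputError("per-atom arrays must have equal length")
        if self.coords.shape != (n, 3):
            raise InputError(f"coords must have shape ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def masses(self) -> np.ndarray:
        """Per-atom standard atomic masses (Da)."""
        try:
            return np.array([ATOMIC_MASSES[e] for e in self.elements])
        except KeyError as exc:
            raise InputError(f"no mass for element {exc.args[0]!r}") from None

    def subset(self, mask: np.ndarray) -> "Frame":
        mask = np.asarray(mask)
        return Frame(
            self.elements[mask],
            self.atom_names[mask],
            self.res_ids[mask],
            self.res_names[mask],
            self.chains[mask],
            self.coords[mask],
            self.time_ps,
        )

    def select(self, selection: Selection) -> np.ndarray:
        """Boolean atom mask for a selection expression, callable or mask."""
        if selection is None:
            return np.ones(self.n_atoms, dtype=bool)
        if callable(selection):
            mask = np.asarray(selection(self))
        elif isinstance(selection, str):
            mask = _eval_selection(self, selection)
        else:
            mask = np.asarray(selection)
        if mask.dtype != bool or mask.shape != (self.n_atoms,):
            raise InputError("selection must produce a boolean per-atom mask")
        return mask

    def atoms(self, selection: Selection) -> "Frame":
        """Subset frame containing only the selected atoms."""
        return self.subset(self.select(selection))

    def com(self, selection: Selection = None) -> np.ndarray:
        """Mass-weighted center of mass (Angstrom) of the selected atoms."""
        sub = self.atoms(selection)
        if sub.n_atoms == 0:
            raise InputError("empty selection for center of mass")
        m = sub.masses()
        return (sub.coords * m[:, None]).sum(axis=0) / m.sum()

    def translated(self, shift) -> "Frame":
        return replace(self, coords=self.coords + np.asarray(shift, dtype=float))

    def rotated(self, rotation, center=None) -> "Frame":
        """Frame rotated by a 3x3 matrix about ``center`` (default origin)."""
        rotation = np.asarray(rotation, dtype=float)
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        return replace(self, coords=(self.coords - c) @ rotation.T + c)


def concat_frames(frames: Sequence[Frame], time_ps: float | None = None) -> Frame:
    """Concatenate atoms of several frames into one (e.g. protein + membrane)."""
    if not frames:
        raise InputError("no frames to concatenate")
    return Frame(
        np.concatenate([f.elements for f in frames]),
        np.concatenate([f.atom_names for f in frames]),
        np.concatenate([f.res_ids for f in frames]),
        np.concatenate([f.res_names for f in frames]),
        np.concatenate([f.chains for f in frames]),
        np.vstack([f.coords for f in frames]),
        frames[0].time_ps if time_ps is None else time_ps,
    )


@dataclass
class Trajectory:
    """Ordered, time-stamped frames plus optional per-frame ground-truth labels."""

    frames: list[Frame] = field(default_factory=list)
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def times_ps(self) -> np.ndarray:
        return np.array([f.time_ps for f in self.frames])


# --------------------------------------------------------------------------
# selection grammar


def _eval_selection(frame: Frame, expr: str) -> np.ndarray:
    mask = np.ones(frame.n_atoms, dtype=bool)
    for clause in expr.split(" and "):
        tokens = clause.strip().split()
        if not tokens:
            raise InputError("empty selection clause")
        negate = False
        if tokens[0] == "not":
            negate = True
            tokens = tokens[1:]
        if tokens == ["all"]:
            part = np.ones(frame.n_atoms, dtype=bool)
        else:
            if len(tokens) < 2:
                raise InputError(f"cannot parse selection clause {clause!r}")
            key, values = tokens[0], " ".join(tokens[1:])
            part = _eval_clause(frame, key, values)
        mask &= ~part if negate else part
    return mask


def _eval_clause(frame: Frame, key: str, values: str) -> np.ndarray:
    items = [v for v in values.replace(",", " ").split() if v]
    if key == "resid":
        mask = np.zeros(frame.n_atoms, dtype=bool)
        for item in items:
            m = re.fullmatch(r"(-?\d+)-(-?\d+)", item)
            if m:
                lo_i, hi_i = int(m.group(1)), int(m.group(2))
                mask |= (frame.res_ids >= lo_i) & (frame.res_ids <= hi_i)
            else:
                mask |= frame.res_ids == int(item)
        return mask
    fields = {
        "element": frame.elements,
        "name": frame.atom_names,
        "resname": frame.res_names,
        "chain": frame.chains,
    }
    if key not in fields:
        raise InputError(f"unknown selection key {key!r}")
    return np.isin(fields[key], items)


def resid_range(lo: int, hi: int) -> str:
    """Selection expression for an inclusive residue-id interval."""
    return f"resid {lo}-{hi}"


# --------------------------------------------------------------------------
# file I/O


def _to_atom_array(frame: Frame):
    import biotite.structure as struc

    arr = struc.AtomArray(frame.n_atoms)
    arr.coord = frame.coords.astype(np.float32)
    arr.element = frame.elements
    arr.atom_name = frame.atom_names
    arr.res_id = frame.res_ids
    arr.res_name = frame.res_names
    arr.chain_id = frame.chains
    arr.hetero = np.zeros(frame.n_atoms, dtype=bool)
    return arr


def _from_atom_array(arr, time_ps: float = 0.0) -> Frame:
    return Frame(
        np.asarray(arr.element, dtype="U4"),
        np.asarray(arr.atom_name, dtype="U6"),
        np.asarray(arr.res_id, dtype=int),
        np.asarray(arr.res_name, dtype="U4"),
        np.asarray(arr.chain_id, dtype="U2"),
        np.asarray(arr.coord, dtype=float),
        time_ps,
    )


def write_pdb(path, frames: Union[Frame, Iterable[Frame]]) -> None:
    """Write a frame (single model) or trajectory (MODEL/ENDMDL) as PDB."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(frames, Frame):
        frames = [frames]
    arrays = [_to_atom_array(f) for f in frames]
    pdb = PDBFile()
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        pdb.set_structure(struc.stack(arrays))
    pdb.write(str(path))


def read_pdb(path, dt_ps: float = 0.0, times_ps: Sequence[float] | None = None) -> Trajectory:
    """Read a PDB file; multi-model files become multi-frame trajectories.

    PDB carries no time information, so frame times are assigned as
    ``i * dt_ps`` unless explicit ``times_ps`` are given.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    obj = pdb.get_structure(model=None)
    if isinstance(obj, struc.AtomArray):
        models = [obj]
    else:
        models = [obj[i] for i in range(obj.stack_depth())]
    if times_ps is None:
        times_ps = [i * dt_ps for i in range(len(models))]
    frames = [_from_atom_array(m, t) for m, t in zip(models, times_ps)]
    return Trajectory(frames)


def write_xyz(path, frames: Union[Frame, Iterable[Frame]]) -> None:
    """Write frames in plain XYZ; the comment line records ``time_ps``."""
    if isinstance(frames, Frame):
        frames = [frames]
    with open(path, "w") as fh:
        for f in frames:
            fh.write(f"{f.n_atoms}\n")
            fh.write(f"time_ps={f.time_ps:.6g}\n")
            for e, (x, y, z) in zip(f.elements, f.coords):
                fh.write(f"{e} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> Trajectory:
    """Read an XYZ trajectory written by :func:`write_xyz`.

    Atom metadata beyond the element is not representable in XYZ; residue
    ids are assigned sequentially and names default to ``UNK``.
    """
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i].strip())
        comment = lines[i + 1]
        time_ps = 0.0
        if "time_ps=" in comment:
            time_ps = float(comment.split("time_ps=")[1].split()[0])
        elems, coords = [], []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            elems.append(parts[0])
            coords.append([float(p) for p in parts[1:4]])
        frames.append(
            Frame(
                np.array(elems),
                np.array(elems),
                np.arange(1, n + 1),
                np.full(n, "UNK"),
                np.full(n, "A"),
                np.array(coords),
                time_ps,
            )
        )
        i += 2 + n
    return Trajectory(frames)
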