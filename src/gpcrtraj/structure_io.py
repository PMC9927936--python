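"""Molecular ensemble I/O and atom selection.

The one required on-disk trajectory format is the multi-model PDB dialect
(``MODEL``/``ENDMDL`` per snapshot over a fixed topology).  Parsing and
serialisation are delegated to :mod:`biotite`; this module wraps them in a
small, explicit :class:`Trajectory` contract so that every downstream
analysis stage is insulated from file-format details.

Conventions
-----------
* Residue numbering follows the file (author numbering, 1-based).
* Internal atom indices are 0-based and never appear in reports.
* Alternate locations: altloc "A" or blank is kept, others are dropped.
* Insertion codes are rejected with an error rather than silently folded
  into the residue id.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

WATER_RESNAMES = frozenset({"HOH", "TIP3", "SOL", "WAT"})

__all__ = [
    "WATER_RESNAMES",
    "PDBFormatError",
    "AtomRecord",
    "Frame",
    "Trajectory",
    "AtomIndexSet",
    "read_pdb_models",
    "write_pdb_models",
    "select_atoms",
    "concat_trajectories",
]


class PDBFormatError(ValueError):
    """Raised for unparseable or internally inconsistent PDB input."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the (frame-independent) topology.

    ``residue_id`` is the author numbering exactly as written in the file.
    """

    serial: int
    atom_name: str
    residue_name: str
    residue_id: int
    chain_id: str
    element: str
    hetero: bool = False

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_RESNAMES

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity of the atom within a model: (chain, residue, name)."""
        return (self.chain_id, self.residue_id, self.atom_name)


@dataclass
class Frame:
    """Coordinates (Å) for one snapshot, ordered as the topology."""

    coordinates: np.ndarray  # (n_atoms, 3)
    box: np.ndarray | None = None  # optional (3,) box lengths, Å

    def validate(self, n_atoms: int) -> None:
        if self.coordinates.shape != (n_atoms, 3):
            raise ValueError(
                f"frame has {self.coordinates.shape[0]} atoms, topology has {n_atoms}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("frame contains non-finite coordinates")


class Trajectory:
    """An ordered stack of frames over a fixed atom topology.

    Coordinates are held as a single ``(n_frames, n_atoms, 3)`` float array;
    :meth:`frame` exposes individual snapshots as :class:`Frame` views.
    ``frame_interval_ns`` carries the saving interval so that
    ``n_frames * frame_interval_ns`` is the sampled duration.
    """

    def __init__(
        self,
        topology: Sequence[AtomRecord],
        coords: np.ndarray,
        frame_interval_ns: float = 1.0,
        source_label: str = "",
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if coords.shape[1] != len(topology):
            raise ValueError("coordinate count does not match topology atom count")
        if not np.all(np.isfinite(coords)):
            raise ValueError("trajectory contains non-finite coordinates")
        if frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be positive")
        self.topology: list[AtomRecord] = list(topology)
        self.coords = coords
        self.frame_interval_ns = float(frame_interval_ns)
        self.source_label = source_label
        self._check_topology()

    def _check_topology(self) -> None:
        serials = [a.serial for a in self.topology]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serial in topology")
        keys = [a.key for a in self.topology]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue, atom_name) in topology")

    # -- basic properties -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def duration_ns(self) -> float:
        return self.n_frames * self.frame_interval_ns

    def frame(self, i: int) -> Frame:
        return Frame(coordinates=self.coords[i])

    def iter_frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def with_coords(self, coords: np.ndarray, source_label: str | None = None) -> "Trajectory":
        """A new trajectory over the same topology with replaced coordinates."""
        return Trajectory(
            self.topology,
            coords,
            frame_interval_ns=self.frame_interval_ns,
            source_label=self.source_label if source_label is None else source_label,
        )


@dataclass(frozen=True)
class AtomIndexSet:
    """Strictly increasing 0-based topology positions."""

    indices: tuple[int, ...]

    def __post_init__(self):
        idx = self.indices
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("indices must be strictly increasing")
        if idx and idx[0] < 0:
            raise ValueError("indices must be non-negative")

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


# ---------------------------------------------------------------------------
# PDB reading / writing (biotite-backed)
# ---------------------------------------------------------------------------

_KEPT_ALTLOCS = {"", " ", ".", "A"}


def _model_to_records_coords(atoms) -> tuple[list[AtomRecord], np.ndarray]:
    """Convert one biotite AtomArray to (topology records, coords)."""
    bad_ins = [str(c) for c in np.unique(atoms.ins_code) if str(c).strip()]
    if bad_ins:
        raise PDBFormatError(
            f"insertion codes are not supported (found {sorted(bad_ins)})"
        )
    keep = np.array([str(a) in _KEPT_ALTLOCS for a in atoms.altloc_id], dtype=bool)
    atoms = atoms[keep]
    records = [
        AtomRecord(
            serial=int(atoms.atom_id[i]),
            atom_name=str(atoms.atom_name[i]),
            residue_name=str(atoms.res_name[i]),
            residue_id=int(atoms.res_id[i]),
            chain_id=str(atoms.chain_id[i]),
            element=str(atoms.element[i]),
            hetero=bool(atoms.hetero[i]),
        )
        for i in range(atoms.array_length())
    ]
    return records, np.array(atoms.coord, dtype=float)


def read_pdb_models(path: str | Path) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    The first model defines the topology; every later model must present the
    same atoms in the same order.  A file without ``MODEL`` records is read
    as a single implicit model.
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise PDBFormatError(f"no models in {path}")
    pdb_file = pdb.PDBFile.read(_io.StringIO(text))
    try:
        n_models = pdb_file.get_model_count()
    except Exception as exc:  # pragma: no cover - biotite internals
        raise PDBFormatError(f"no models in {path}: {exc}") from exc
    if n_models == 0:
        raise PDBFormatError(f"no models in {path}")

    topology: list[AtomRecord] | None = None
    ref_keys: list[tuple] | None = None
    frames: list[np.ndarray] = []
    for m in range(1, n_models + 1):
        atoms = pdb_file.get_structure(
            model=m, altloc="all", extra_fields=["atom_id"]
        )
        records, coords = _model_to_records_coords(atoms)
        keys = [(r.key, r.residue_name, r.element) for r in records]
        if topology is None:
            topology, ref_keys = records, keys
        elif keys != ref_keys:
            raise PDBFormatError(
                f"inconsistent topology in model {m} of {path.name}"
            )
        frames.append(coords)

    traj = Trajectory(topology, np.stack(frames), source_label=str(path))
    return traj


def write_pdb_models(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a standard multi-model PDB file.

    One ``MODEL``/``ENDMDL`` block per frame; coordinates are emitted at the
    PDB precision of 3 decimals, so a round trip preserves them to 1e-3 Å.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    if not np.all(np.isfinite(traj.coords)):
        raise ValueError("refusing to write non-finite coordinates")

    n = traj.n_atoms
    arr = struc.AtomArray(n)
    arr.chain_id = np.array([a.chain_id for a in traj.topology])
    arr.res_id = np.array([a.residue_id for a in traj.topology])
    arr.res_name = np.array([a.residue_name for a in traj.topology])
    arr.atom_name = np.array([a.atom_name for a in traj.topology])
    arr.element = np.array([a.element for a in traj.topology])
    arr.hetero = np.array([a.hetero for a in traj.topology])
    stack = struc.AtomArrayStack(traj.n_frames, n)
    for cat in arr.get_annotation_categories():
        stack.set_annotation(cat, arr.get_annotation(cat))
    stack.coord = np.asarray(traj.coords, dtype=np.float32)

    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def select_atoms(
    traj: Trajectory,
    chain: str | None = None,
    residue_id: int | Iterable[int] | None = None,
    atom_name: str | None = None,
    water_only: bool | None = None,
    element: str | None = None,
) -> AtomIndexSet:
    """Deterministic conjunctive filter over the topology.

    Selection depends only on the topology, never on frame content.  An
    empty result is valid.
    """
    if residue_id is None:
        res_ids = None
    elif isinstance(residue_id, (int, np.integer)):
        res_ids = {int(residue_id)}
    else:
        res_ids = {int(r) for r in residue_id}

    picked = []
    for i, rec in enumerate(traj.topology):
        if chain is not None and rec.chain_id != chain:
            continue
        if res_ids is not None and rec.residue_id not in res_ids:
            continue
        if atom_name is not None and rec.atom_name != atom_name:
            continue
        if water_only and not rec.is_water:
            continue
        if element is not None and rec.element != element:
            continue
        picked.append(i)
    return AtomIndexSet(tuple(picked))


def concat_trajectories(trajs: Sequence[Trajectory], source_label: str = "") -> Trajectory:
    """Concatenate frame stacks of topologically identical trajectories.

    Used to pool independent runs of one system before histogramming.
    """
    if not trajs:
        raise ValueError("nothing to concatenate")
    first = trajs[0]
    ref = [(a.key, a.residue_name, a.element) for a in first.topology]
    for k, t in enumerate(trajs[1:], start=2):
        if [(a.key, a.residue_name, a.element) for a in t.topology] != ref:
            raise ValueError(f"trajectory {k} has a different topology")
        if t.frame_interval_ns != first.frame_interval_ns:
            raise ValueError(f"trajectory {k} has a different frame interval")
    coords = np.concatenate([t.coords for t in trajs], axis=0)
    label = source_label or "+".join(t.source_label for t in trajs)
    return Trajectory(first.topology, coords, first.frame_interval_ns, label)
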