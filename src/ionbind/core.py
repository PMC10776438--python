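"""Domain types and file I/O shared by all analysis stages.

Unit conventions
----------------
Lengths are in Å throughout.  Raw frame times are stored in ps (the unit
MD engines dump); binding times and other kinetic quantities are reported
in ns, with the conversion applied only at the reporting boundary.
Coordinates are Cartesian and are never wrapped on read; periodic-image
handling (minimum-image convention) is the responsibility of the
consuming analysis and is exposed as a flag wherever distances are
computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "BACKBONE_NAMES",
    "ParseError",
    "Topology",
    "Trajectory",
    "IonSelection",
    "SiteDefinition",
    "read_structure",
    "read_trajectory",
    "write_trajectory",
    "write_report",
    "min_image",
    "pair_distances",
]

#: Three-letter codes treated as protein residues when selecting the
#: "protein side" of ion-protein distances.
AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL HID HIE HIP CYX ASH GLH LYN".split()
)

#: Atom names constituting the protein backbone.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


class ParseError(ValueError):
    """Raised when a structure or trajectory file cannot be parsed."""


def _infer_element(name: str, element_field: str) -> str:
    """Element symbol from the PDB element column, else from the atom name.

    The fallback strips leading digits (``1HG1`` -> hydrogen) and takes the
    first letter, which is the conventional tolerance for PDB dialects that
    leave columns 77-78 blank.
    """
    element_field = element_field.strip()
    if element_field:
        return element_field.capitalize()
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ParseError(f"cannot infer element from atom name {name!r}")
    return stripped[0].upper()


@dataclass(frozen=True)
class Topology:
    """Static atom/residue tables for a molecular system.

    Atoms are stored as parallel arrays ordered as in the source file.
    ``residue_index`` indexes into the residue table (positional, 0-based),
    so cross-references are total by construction.
    """

    atom_ids: np.ndarray          # (n_atoms,) int
    names: np.ndarray             # (n_atoms,) str
    elements: np.ndarray          # (n_atoms,) str
    residue_indices: np.ndarray   # (n_atoms,) int, into residue table
    residue_names: np.ndarray     # (n_residues,) str, 3-letter codes
    chains: np.ndarray            # (n_residues,) str

    def __post_init__(self) -> None:
        n = len(self.atom_ids)
        for arr in (self.names, self.elements, self.residue_indices):
            if len(arr) != n:
                raise ValueError("atom arrays must have equal length")
        if len(self.residue_names) != len(self.chains):
            raise ValueError("residue arrays must have equal length")
        if n and len(np.unique(self.atom_ids)) != n:
            raise ValueError("atom_ids must be unique")
        if n and (
            self.residue_indices.min() < 0
            or self.residue_indices.max() >= len(self.residue_names)
        ):
            raise ValueError("dangling residue_index in topology")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    @property
    def is_heavy(self) -> np.ndarray:
        """Heavy-atom flags; an atom is heavy iff its element is not hydrogen."""
        return np.asarray(self.elements) != "H"

    def protein_mask(self) -> np.ndarray:
        """Atoms belonging to amino-acid residues."""
        res_is_protein = np.isin(np.asarray(self.residue_names), list(AMINO_ACIDS))
        return res_is_protein[self.residue_indices]

    def backbone_mask(self) -> np.ndarray:
        return self.protein_mask() & np.isin(np.asarray(self.names), list(BACKBONE_NAMES))

    def heavy_protein_indices(self) -> np.ndarray:
        """Positional indices of protein heavy atoms."""
        return np.flatnonzero(self.is_heavy & self.protein_mask())

    def atom_positions_of_residues(self, residue_indices: Iterable[int]) -> np.ndarray:
        """Positional indices of heavy atoms of the given residues."""
        residues = np.asarray(list(residue_indices))
        mask = np.isin(self.residue_indices, residues) & self.is_heavy
        return np.flatnonzero(mask)

    def index_of_atom_id(self, atom_id: int) -> int:
        hits = np.flatnonzero(self.atom_ids == atom_id)
        if len(hits) != 1:
            raise KeyError(f"atom id {atom_id} not found in topology")
        return int(hits[0])


@dataclass
class Trajectory:
    """Topology plus per-frame coordinates, times (ps) and periodic boxes (Å)."""

    topology: Topology
    times: np.ndarray            # (n_frames,) ps
    coords: np.ndarray           # (n_frames, n_atoms, 3) Å
    boxes: np.ndarray | None = None  # (n_frames, 3) Å or None (no PBC)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] != len(self.times):
            raise ValueError("frame count mismatch between times and coords")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coords have {self.coords.shape[1]} atoms per frame, "
                f"topology has {self.topology.n_atoms}"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if self.boxes is not None:
            self.boxes = np.asarray(self.boxes, dtype=float)
            if self.boxes.shape != (len(self.times), 3):
                raise ValueError("boxes must have shape (n_frames, 3)")
            if np.any(self.boxes <= 0):
                raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def uniform_dt(self, rtol: float = 1e-6) -> float:
        """Frame spacing in ps; raises if the sampling is not uniform."""
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames to determine dt")
        diffs = np.diff(self.times)
        dt = diffs[0]
        if not np.allclose(diffs, dt, rtol=rtol, atol=1e-9):
            raise ValueError("trajectory is not uniformly sampled; resample upstream")
        return float(dt)


@dataclass(frozen=True)
class IonSelection:
    """A one- or two-atom ion (e.g. Cl- or the two oxygens of superoxide)."""

    label: str
    atom_ids: tuple[int, ...]
    charge: float = -1.0

    def __post_init__(self) -> None:
        if not 1 <= len(self.atom_ids) <= 2:
            raise ValueError("an ion selection has 1 or 2 atoms")

    def atom_indices(self, topology: Topology) -> np.ndarray:
        return np.array([topology.index_of_atom_id(a) for a in self.atom_ids])


@dataclass(frozen=True)
class SiteDefinition:
    """A binding site defined by its anchoring residues.

    ``bound_cutoff`` is the ion-to-site-residue heavy-atom distance below
    which the ion counts as bound to the site (3 Å by default).
    """

    name: str
    residues: tuple[int, ...]
    bound_cutoff: float = 3.0

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("site must reference at least one residue")
        if self.bound_cutoff <= 0:
            raise ValueError("bound_cutoff must be positive")

    def validate(self, topology: Topology) -> None:
        for r in self.residues:
            if not 0 <= r < topology.n_residues:
                raise ValueError(f"site {self.name!r}: residue {r} not in topology")


# ---------------------------------------------------------------------------
# Periodic distances
# ---------------------------------------------------------------------------

def min_image(displacements: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Valid for orthorhombic boxes; ``box`` broadcasts against the last axis.
    """
    box = np.asarray(box, dtype=float)
    return displacements - box * np.round(displacements / box)


def pair_distances(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | None = None
) -> np.ndarray:
    """Distances between point sets a (n,3) and b (m,3) -> (n, m)."""
    disp = np.asarray(a)[:, None, :] - np.asarray(b)[None, :, :]
    if box is not None:
        disp = min_image(disp, box)
    return np.linalg.norm(disp, axis=-1)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_structure(path: str | Path) -> tuple[Topology, np.ndarray]:
    """Read a PDB file into a Topology plus single-frame coordinates.

    Every ATOM/HETATM record becomes one atom; the residue table is built
    from the (chain, resSeq, resName) triple in file order.  Malformed
    records raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    atom_ids: list[int] = []
    names: list[str] = []
    elements: list[str] = []
    residx: list[int] = []
    res_names: list[str] = []
    chains: list[str] = []
    res_keys: dict[tuple, int] = {}
    coords: list[list[float]] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path.name}, line {lineno}: truncated {rec} record")
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                res_name = line[17:20].strip()
                chain = line[21].strip()
                res_seq = line[22:26].strip()
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except ValueError as exc:
                raise ParseError(f"{path.name}, line {lineno}: {exc}") from exc
            element = _infer_element(name, line[76:78] if len(line) >= 78 else "")
            key = (chain, res_seq, res_name)
            if key not in res_keys:
                res_keys[key] = len(res_names)
                res_names.append(res_name)
                chains.append(chain)
            atom_ids.append(serial)
            names.append(name)
            elements.append(element)
            residx.append(res_keys[key])
            coords.append(xyz)
    if not atom_ids:
        raise ParseError(f"{path.name}: no ATOM/HETATM records found")
    topology = Topology(
        atom_ids=np.array(atom_ids),
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        residue_indices=np.array(residx),
        residue_names=np.array(res_names, dtype=object),
        chains=np.array(chains, dtype=object),
    )
    return topology, np.array(coords, dtype=float)


_TRAJ_COLUMNS = ["frame", "time_ps", "atom_id", "x", "y", "z"]
_BOX_ATOM_ID = -1  # sentinel atom_id for per-frame box rows


def read_trajectory(path: str | Path, topology: Topology) -> Trajectory:
    """Read the native tabular (CSV) trajectory format.

    One row per atom per frame with columns ``frame, time_ps, atom_id, x, y,
    z``; rows with ``atom_id == -1`` carry the box lengths of that frame in
    the x/y/z columns.  The atom count is validated per frame and times must
    be strictly increasing.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"trajectory file missing columns: {sorted(missing)}")

    box_rows = df[df["atom_id"] == _BOX_ATOM_ID]
    atom_rows = df[df["atom_id"] != _BOX_ATOM_ID]

    frames = np.sort(atom_rows["frame"].unique())
    n_atoms = topology.n_atoms
    id_to_pos = {int(a): i for i, a in enumerate(topology.atom_ids)}

    times = np.empty(len(frames))
    coords = np.empty((len(frames), n_atoms, 3))
    boxes = None
    if len(box_rows):
        boxes = np.empty((len(frames), 3))

    grouped = atom_rows.groupby("frame", sort=True)
    box_grouped = box_rows.groupby("frame", sort=True) if len(box_rows) else None
    for i, (frame, sub) in enumerate(grouped):
        if len(sub) != n_atoms:
            raise ParseError(
                f"frame {frame}: expected {n_atoms} atoms, found {len(sub)}"
            )
        times[i] = sub["time_ps"].iloc[0]
        pos = np.array([id_to_pos[int(a)] for a in sub["atom_id"]])
        coords[i, pos, :] = sub[["x", "y", "z"]].to_numpy()
        if boxes is not None:
            if box_grouped is None or frame not in box_rows["frame"].values:
                raise ParseError(f"frame {frame}: missing box row")
            brow = box_rows[box_rows["frame"] == frame].iloc[0]
            boxes[i] = [brow["x"], brow["y"], brow["z"]]
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ParseError("frame times are not strictly increasing")
    return Trajectory(topology=topology, times=times, coords=coords, boxes=boxes)


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write a Trajectory in the native tabular format (lossless round-trip)."""
    path = Path(path)
    records = []
    for i in range(traj.n_frames):
        if traj.boxes is not None:
            bx, by, bz = traj.boxes[i]
            records.append((i, traj.times[i], _BOX_ATOM_ID, bx, by, bz))
        for j, aid in enumerate(traj.topology.atom_ids):
            x, y, z = traj.coords[i, j]
            records.append((i, traj.times[i], int(aid), x, y, z))
    df = pd.DataFrame.from_records(records, columns=_TRAJ_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def write_report(
    results, path: str | Path, format: str = "csv", float_digits: int = 6
) -> Path:
    """Serialise a stage output to CSV or JSON with deterministic ordering.

    CSV floats are written with ``float_digits`` significant digits (6 by
    default); JSON is written at full precision so nested records
    round-trip losslessly.
    """
    path = Path(path)
    if format == "csv":
        if isinstance(results, pd.DataFrame):
            df = results
        elif isinstance(results, Mapping):
            df = pd.DataFrame([results])
        else:
            df = pd.DataFrame(list(results))
        df.to_csv(path, index=False, float_format=f"%.{float_digits}g")
    elif format == "json":
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            raise TypeError(f"not JSON serialisable: {type(o)}")

        if isinstance(results, pd.DataFrame):
            payload = results.to_dict(orient="records")
        else:
            payload = results
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=default)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path
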