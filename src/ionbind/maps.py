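"""Rigid-body alignment, RMSD/RMSF and voxelised ion-occupancy maps.

Occupancy semantics: with a single selected ion (or in ``probability``
mode) a voxel's value is the fraction of frames in which at least one
ion reference point lies inside it — at 1 Å³ voxels the probability of
finding an ion in that cube in a random frame.  ``mean_count`` mode
stores the mean per-frame ion count instead, which conserves the number
of in-bounds ions when summed over the grid.

For two-atom ions the reference point defaults to the bond midpoint.
Hotspots are 26-connected components of voxels above an iso-level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .core import IonSelection, Topology, Trajectory

__all__ = [
    "OccupancyGrid",
    "Hotspot",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_per_residue",
    "occupancy_grid",
    "extract_hotspots",
    "write_dx",
    "read_dx",
    "hotspots_to_pdb",
]


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation 3x3 proper, translation 3-vector, rmsd) such that
    ``mobile @ R.T + t`` best matches ``reference`` over the selection.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is not None:
        mobile_sel = mobile[selection]
        reference_sel = reference[selection]
    else:
        mobile_sel, reference_sel = mobile, reference
    if mobile_sel.shape != reference_sel.shape:
        raise ValueError("selections must have equal atom counts")
    n = len(mobile_sel)
    if n < 3:
        raise ValueError("need at least 3 atoms for superposition")
    mob_c = mobile_sel - mobile_sel.mean(axis=0)
    ref_c = reference_sel - reference_sel.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) selection")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = reference_sel.mean(axis=0) - mobile_sel.mean(axis=0) @ R.T
    rmsd = float(rssd / math.sqrt(n))
    return R, t, rmsd


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    selection: np.ndarray | str = "backbone",
) -> np.ndarray:
    """Per-frame superposed RMSD of the selection relative to ``reference``.

    ``selection`` may be ``"backbone"``, ``"heavy"`` or an array of
    positional atom indices.
    """
    sel = _resolve_selection(traj.topology, selection)
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        _, _, out[i] = kabsch_superpose(traj.coords[i], reference, sel)
    return out


def _resolve_selection(top: Topology, selection) -> np.ndarray:
    if isinstance(selection, str):
        if selection == "backbone":
            sel = np.flatnonzero(top.backbone_mask())
        elif selection == "heavy":
            sel = np.flatnonzero(top.is_heavy & top.protein_mask())
        else:
            raise ValueError(f"unknown selection {selection!r}")
        if len(sel) == 0:
            raise ValueError(f"selection {selection!r} matches no atoms")
        return sel
    return np.asarray(selection)


def rmsf_per_residue(
    traj: Trajectory, selection: np.ndarray | str = "heavy"
) -> pd.DataFrame:
    """Root-mean-square fluctuation about the time-average structure.

    Assumes the trajectory is already aligned.  Per atom the RMSF is the
    root-mean-square deviation from its average position; per residue, the
    mean over member atoms.  Columns: residue_index, residue_name, rmsf.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = _resolve_selection(traj.topology, selection)
    pos = traj.coords[:, sel, :]
    mean_pos = pos.mean(axis=0)
    rmsf_atom = np.sqrt(np.mean(np.sum((pos - mean_pos) ** 2, axis=2), axis=0))
    res_idx = traj.topology.residue_indices[sel]
    df = pd.DataFrame({"residue_index": res_idx, "rmsf": rmsf_atom})
    per_res = df.groupby("residue_index", as_index=False)["rmsf"].mean()
    per_res["residue_name"] = [
        str(traj.topology.residue_names[i]) for i in per_res["residue_index"]
    ]
    return per_res[["residue_index", "residue_name", "rmsf"]]


# ---------------------------------------------------------------------------
# Occupancy grids
# ---------------------------------------------------------------------------

@dataclass
class OccupancyGrid:
    """3-D voxel histogram of ion occupancy over an aligned trajectory."""

    origin: np.ndarray        # (3,) Å, corner of voxel (0,0,0)
    voxel_size: float         # Å
    values: np.ndarray        # (nx, ny, nz)
    mode: str = "probability"
    n_frames: int = 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Cartesian centres of voxels given integer index triples (k, 3)."""
        return self.origin + (np.asarray(indices) + 0.5) * self.voxel_size


def ion_reference_points(
    traj: Trajectory, ions: Sequence[IonSelection], per_atom: bool = False
) -> np.ndarray:
    """(n_frames, n_points, 3) reference points; midpoint for 2-atom ions."""
    pts = []
    for ion in ions:
        idx = ion.atom_indices(traj.topology)
        if per_atom or len(idx) == 1:
            for j in idx:
                pts.append(traj.coords[:, j, :])
        else:
            pts.append(traj.coords[:, idx, :].mean(axis=1))
    return np.stack(pts, axis=1)


def occupancy_grid(
    traj: Trajectory,
    ions: Sequence[IonSelection],
    voxel_size: float = 1.0,
    mode: str = "probability",
    margin: float = 2.0,
    per_atom: bool = False,
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
) -> OccupancyGrid:
    """Voxelised occupancy of ion reference points over the trajectory.

    Grid bounds auto-fit the data plus ``margin`` unless ``origin`` and
    ``shape`` are given.  ``probability`` mode: fraction of frames with at
    least one ion in the voxel; ``mean_count`` mode: mean per-frame count.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if mode not in ("probability", "mean_count"):
        raise ValueError(f"unknown mode {mode!r}")
    points = ion_reference_points(traj, ions, per_atom=per_atom)  # (F, P, 3)
    n_frames, n_points, _ = points.shape
    flat = points.reshape(-1, 3)
    if origin is None:
        origin = np.floor((flat.min(axis=0) - margin) / voxel_size) * voxel_size
    origin = np.asarray(origin, dtype=float)
    if shape is None:
        upper = flat.max(axis=0) + margin
        shape = tuple(
            int(math.ceil((upper[k] - origin[k]) / voxel_size)) for k in range(3)
        )

    idx = np.floor((flat - origin) / voxel_size).astype(np.int64)
    in_bounds = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    lin = np.ravel_multi_index(tuple(idx[in_bounds].T), shape)
    frame_of = np.repeat(np.arange(n_frames), n_points)[in_bounds]

    n_vox = int(np.prod(shape))
    if mode == "mean_count":
        counts = np.bincount(lin, minlength=n_vox).astype(float)
        values = counts / n_frames
    else:
        # Count each (frame, voxel) pair once.
        pair = frame_of.astype(np.int64) * n_vox + lin
        uniq = np.unique(pair)
        counts = np.bincount((uniq % n_vox).astype(np.int64), minlength=n_vox).astype(float)
        values = counts / n_frames
    return OccupancyGrid(
        origin=origin,
        voxel_size=voxel_size,
        values=values.reshape(shape),
        mode=mode,
        n_frames=n_frames,
    )


# ---------------------------------------------------------------------------
# Hotspots
# ---------------------------------------------------------------------------

@dataclass
class Hotspot:
    """A 26-connected component of voxels at or above an iso-level."""

    voxel_indices: np.ndarray  # (k, 3)
    centroid: np.ndarray       # (3,) Å, occupancy-weighted
    peak_value: float
    total_occupancy: float
    nearby_residues: tuple[str, ...] = ()


def extract_hotspots(
    grid: OccupancyGrid,
    iso_level: float,
    topology: Topology | None = None,
    coords: np.ndarray | None = None,
    residue_radius: float = 4.0,
) -> list[Hotspot]:
    """Connected components of voxels >= iso_level, sorted by peak value.

    If a structure is supplied, residues with a heavy atom within
    ``residue_radius`` of a hotspot centroid are annotated.
    """
    if iso_level <= 0:
        raise ValueError("iso_level must be positive")
    mask = grid.values >= iso_level
    structure = np.ones((3, 3, 3), dtype=int)  # 26-connectivity
    labels, n_comp = ndimage.label(mask, structure=structure)
    hotspots = []
    for comp in range(1, n_comp + 1):
        vox = np.argwhere(labels == comp)
        vals = grid.values[tuple(vox.T)]
        centers = grid.voxel_centers(vox)
        centroid = np.average(centers, axis=0, weights=vals)
        nearby: tuple[str, ...] = ()
        if topology is not None and coords is not None:
            heavy = np.flatnonzero(topology.is_heavy)
            d = np.linalg.norm(coords[heavy] - centroid, axis=1)
            res = sorted(
                {
                    f"{topology.residue_names[topology.residue_indices[a]]}{topology.residue_indices[a]}"
                    for a in heavy[d <= residue_radius]
                }
            )
            nearby = tuple(res)
        hotspots.append(
            Hotspot(
                voxel_indices=vox,
                centroid=centroid,
                peak_value=float(vals.max()),
                total_occupancy=float(vals.sum()),
                nearby_residues=nearby,
            )
        )
    hotspots.sort(key=lambda h: h.peak_value, reverse=True)
    return hotspots


# ---------------------------------------------------------------------------
# OpenDX I/O and PDB export
# ---------------------------------------------------------------------------

def write_dx(grid: OccupancyGrid, path: str | Path) -> Path:
    """Write the grid as an OpenDX scalar field (VMD-loadable)."""
    path = Path(path)
    nx, ny, nz = grid.shape
    d = grid.voxel_size
    # DX grid positions are voxel centres.
    ox, oy, oz = grid.origin + 0.5 * d
    vals = grid.values.ravel(order="C")
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {d:.6f} 0 0\n")
        fh.write(f"delta 0 {d:.6f} 0\n")
        fh.write(f"delta 0 0 {d:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {vals.size} data follows\n"
        )
        for i in range(0, vals.size, 3):
            fh.write(" ".join(f"{v:.10g}" for v in vals[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')
    return path


def read_dx(path: str | Path) -> OccupancyGrid:
    """Read an OpenDX scalar field written by :func:`write_dx`."""
    counts = None
    origin = None
    deltas = []
    data: list[float] = []
    n_items = 0
    with open(path) as fh:
        for line in fh:
            toks = line.split()
            if not toks:
                continue
            if toks[:4] == ["object", "1", "class", "gridpositions"]:
                counts = tuple(int(x) for x in toks[-3:])
            elif toks[0] == "origin":
                origin = np.array([float(x) for x in toks[1:4]])
            elif toks[0] == "delta":
                deltas.append([float(x) for x in toks[1:4]])
            elif toks[:4] == ["object", "3", "class", "array"]:
                n_items = int(toks[toks.index("items") + 1])
            elif toks[0] not in ("attribute", "object", "component") and n_items:
                data.extend(float(x) for x in toks)
    if counts is None or origin is None or len(data) != n_items:
        raise ValueError(f"malformed DX file {path}")
    d = deltas[0][0]
    values = np.array(data).reshape(counts, order="C")
    return OccupancyGrid(
        origin=origin - 0.5 * d, voxel_size=d, values=values, mode="probability"
    )


def hotspots_to_pdb(hotspots: Sequence[Hotspot], path: str | Path) -> Path:
    """Write hotspot centroids as HETATM pseudo-atoms for visual inspection."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, h in enumerate(hotspots, start=1):
            x, y, z = h.centroid
            fh.write(
                f"HETATM{i:5d}  XE  HOT A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{h.peak_value:6.2f}          Xe\n"
            )
        fh.write("END\n")
    return path


def hotspots_to_dataframe(hotspots: Sequence[Hotspot]) -> pd.DataFrame:
    rows = []
    for i, h in enumerate(hotspots, start=1):
        rows.append(
            {
                "hotspot": i,
                "x": h.centroid[0],
                "y": h.centroid[1],
                "z": h.centroid[2],
                "peak": h.peak_value,
                "n_voxels": len(h.voxel_indices),
                "residues": ";".join(h.nearby_residues),
            }
        )
    return pd.DataFrame(rows)
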