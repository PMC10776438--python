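"""Ion-state-resolved radial distribution functions and solvation shells.

Frames are first classified by the ion's distance to the protein: bound
(d <= 3 Å), bulk (d >= 10 Å) or intermediate (excluded from both RDFs).
The RDF uses the standard pair-distribution estimator — distance
histogram normalised by the spherical shell volume 4 pi r^2 dr and a
reference density — with the cumulative water count n(r) accumulated
directly from the histogram, so n(r_max) equals the mean number of
waters within r_max exactly.  Shell boundaries are local minima of the
(optionally smoothed) g(r) between successive maxima; per-shell water
counts and the bound-vs-bulk "shed water" differences follow from n(r)
evaluated at those boundaries.

Water reference point is the oxygen position; for a two-atom ion,
distances are taken from whichever ion atom is closer to each water.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import min_image

__all__ = [
    "BOUND",
    "BULK",
    "INTERMEDIATE",
    "RDFProfile",
    "classify_ion_state",
    "rdf",
    "shell_boundaries",
    "shell_water_counts",
    "shed_waters",
]

BOUND, INTERMEDIATE, BULK = 0, 1, 2
_STATE_NAMES = {BOUND: "bound", INTERMEDIATE: "intermediate", BULK: "bulk"}


@dataclass
class RDFProfile:
    """Radial distribution of water around an ion, with cumulative counts."""

    bin_centers: np.ndarray   # Å
    g: np.ndarray             # dimensionless
    n_cumulative: np.ndarray  # mean waters within r (upper bin edge)
    state: str = "all"        # bound | bulk | all
    reference_density: float = 0.0  # Å^-3
    n_frames: int = 0

    def __post_init__(self) -> None:
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")
        if np.any(np.diff(self.n_cumulative) < -1e-9):
            raise ValueError("cumulative count must be non-decreasing")

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    def n_at(self, r: float) -> float:
        """Cumulative water count at radius r (linear interpolation)."""
        edges = self.bin_centers + 0.5 * self.bin_width
        return float(np.interp(r, edges, self.n_cumulative))


def classify_ion_state(
    d_min: np.ndarray, bound_cutoff: float = 3.0, bulk_cutoff: float = 10.0
) -> np.ndarray:
    """Per-frame ion state: BOUND (d<=3 Å), BULK (d>=10 Å) or INTERMEDIATE."""
    d = np.asarray(d_min, dtype=float)
    out = np.full(d.shape, INTERMEDIATE, dtype=np.int64)
    out[d <= bound_cutoff] = BOUND
    out[d >= bulk_cutoff] = BULK
    return out


def rdf(
    ion_positions: np.ndarray,
    water_positions: np.ndarray | Sequence[np.ndarray],
    frame_mask: np.ndarray | None = None,
    bin_width: float = 0.05,
    r_max: float = 10.0,
    box: np.ndarray | None = None,
    reference_density: float | None = None,
    state: str = "all",
) -> RDFProfile:
    """Pair-distribution estimator of water around an ion.

    Parameters
    ----------
    ion_positions
        (F, 3) single-atom positions or (F, k, 3) for a k-atom ion (the
        closest ion atom per water is used).
    water_positions
        (F, W, 3) array, or a length-F sequence of (W_f, 3) arrays.
    frame_mask
        Boolean mask selecting the frames to pool (e.g. bound frames).
    reference_density
        Bulk number density for normalisation; measured from the data
        (waters per frame / box volume, or within the r_max sphere when no
        box is given) if omitted.
    """
    if bin_width <= 0 or r_max <= 0:
        raise ValueError("bin_width and r_max must be positive")
    F = len(ion_positions)
    if frame_mask is None:
        frame_mask = np.ones(F, dtype=bool)
    frames = np.flatnonzero(frame_mask)
    if len(frames) == 0:
        raise ValueError("empty frame mask: no frames in the requested state")

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    total_waters = 0
    for fi in frames:
        waters = np.asarray(water_positions[fi], dtype=float)
        if waters.size == 0:
            raise ValueError(f"frame {fi}: no water positions")
        total_waters += len(waters)
        ion = np.asarray(ion_positions[fi], dtype=float)
        ion = ion.reshape(-1, 3)
        disp = waters[None, :, :] - ion[:, None, :]
        if box is not None:
            disp = min_image(disp, np.asarray(box))
        d = np.linalg.norm(disp, axis=-1).min(axis=0)  # closest ion atom
        h, _ = np.histogram(d, bins=edges)
        counts += h

    n_frames = len(frames)
    mean_counts = counts / n_frames
    n_cum = np.cumsum(mean_counts)

    if reference_density is None:
        if box is not None:
            vol = float(np.prod(np.asarray(box, dtype=float).reshape(-1, 3)[0]))
        else:
            vol = 4.0 / 3.0 * math.pi * r_max**3
        reference_density = (total_waters / n_frames) / vol
    if reference_density <= 0:
        raise ValueError("reference density must be positive")

    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 * math.pi * centers**2 * bin_width
    g = mean_counts / (shell_vol * reference_density)
    return RDFProfile(
        bin_centers=centers,
        g=g,
        n_cumulative=n_cum,
        state=state,
        reference_density=float(reference_density),
        n_frames=n_frames,
    )


def shell_boundaries(
    profile: RDFProfile, n_shells: int, smooth_window: int = 5
) -> np.ndarray:
    """Radii of the first ``n_shells`` solvation-shell boundaries.

    Boundaries are local minima of the (moving-average smoothed) g(r)
    occurring after the first maximum; ``smooth_window`` of 1 disables
    smoothing.  Raises if fewer minima than requested are found.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd positive integer")
    g = profile.g
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        g = np.convolve(g, kernel, mode="same")

    maxima, _ = find_peaks(g)
    minima, _ = find_peaks(-g)
    if len(maxima) == 0:
        raise ValueError("monotone g(r): found 0 maxima, cannot place boundaries")
    # A boundary is a local minimum occurring after the first peak.
    bounds = [int(i) for i in minima if i > maxima[0]]
    if len(bounds) < n_shells:
        raise ValueError(
            f"found only {len(bounds)} shell boundaries, {n_shells} requested"
        )
    return profile.bin_centers[np.array(bounds[:n_shells])]


def shed_waters(n_bulk: float, n_bound: float) -> float:
    """Waters shed upon binding, reported at one decimal place."""
    return round(n_bulk - n_bound, 1)


def shell_water_counts(
    bound_profile: RDFProfile,
    bulk_profile: RDFProfile,
    boundaries: Sequence[float],
) -> pd.DataFrame:
    """Per-shell water counts for bound and bulk states, and their difference.

    The same boundaries are applied to both profiles; shell k spans
    (boundary[k-1], boundary[k]] with the first shell starting at 0.
    Columns: shell, r_shell, n_bulk, n_bound, shed (1 d.p.).
    """
    boundaries = np.asarray(boundaries, dtype=float)
    if np.any(np.diff(boundaries) <= 0):
        raise ValueError("boundaries must be strictly increasing")
    for prof in (bound_profile, bulk_profile):
        r_hi = prof.bin_centers[-1] + 0.5 * prof.bin_width
        if boundaries.max() > r_hi + 1e-9:
            raise ValueError("boundary outside profile range")
    rows = []
    prev = 0.0
    for k, b in enumerate(boundaries, start=1):
        n_bulk = bulk_profile.n_at(b) - (bulk_profile.n_at(prev) if prev else 0.0)
        n_bound = bound_profile.n_at(b) - (bound_profile.n_at(prev) if prev else 0.0)
        rows.append(
            {
                "shell": k,
                "r_shell": float(b),
                "n_bulk": n_bulk,
                "n_bound": n_bound,
                "shed": shed_waters(n_bulk, n_bound),
            }
        )
        prev = float(b)
    return pd.DataFrame(rows)
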