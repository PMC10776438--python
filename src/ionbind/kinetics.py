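"""Detection and characterisation of ion-protein binding events.

A binding event is a maximal run of consecutive frames in which the
ion-to-nearest-protein-heavy-atom distance stays below a cutoff (4 Å by
default), kept only if it spans at least a minimum duration (two frame
intervals by default).  The duration convention is

    t_b = n_frames_in_run * dt,

so a minimal two-frame event at 0.2 ns sampling has t_b = 0.4 ns; this is
the convention under which reported event counts and binding-time
summaries are internally consistent.

Also provided: survival (bound-fraction) curves and their bi-exponential
fits, per-residue binding statistics, site assignment, escape-termination
rules, hit rates, geometric hydrogen-bond detection and the Pearson
correlation used to relate binding times to rotational correlation times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import IonSelection, SiteDefinition, Trajectory, pair_distances

__all__ = [
    "DistanceSeries",
    "BindingEvent",
    "SurvivalCurve",
    "BiexpFit",
    "min_distance_series",
    "distance_density",
    "detect_binding_events",
    "assign_site",
    "residue_binding_stats",
    "binding_time_summary",
    "group_durations_by_site",
    "mean_binding_time",
    "bound_fraction_curve",
    "fit_biexponential",
    "hit_rate",
    "escape_termination",
    "detect_hydrogen_bonds",
    "pearson_correlation",
]


@dataclass
class DistanceSeries:
    """Per-frame minimum ion-protein heavy-atom distance.

    For a two-atom ion the distance is taken from whichever ion atom is
    closest.  ``nearest_residue`` holds the residue index of the closest
    protein heavy atom per frame.
    """

    times_ns: np.ndarray
    d_min: np.ndarray
    nearest_residue: np.ndarray
    ion_label: str = "ion"

    def __post_init__(self) -> None:
        if not (len(self.times_ns) == len(self.d_min) == len(self.nearest_residue)):
            raise ValueError("series arrays must have equal length")
        if np.any(self.d_min < 0):
            raise ValueError("distances must be non-negative")

    def uniform_dt(self) -> float:
        if len(self.times_ns) < 2:
            raise ValueError("need at least 2 frames")
        diffs = np.diff(self.times_ns)
        if not np.allclose(diffs, diffs[0], rtol=1e-6, atol=1e-12):
            raise ValueError("series is not uniformly sampled; resample upstream")
        return float(diffs[0])


@dataclass
class BindingEvent:
    """One contiguous ion-protein contact interval."""

    ion_id: str
    start_index: int  # first frame of the run (inclusive)
    end_index: int    # last frame of the run (inclusive)
    t_start: float    # ns
    t_end: float      # ns, t_start + t_b
    t_b: float        # ns, duration (n_frames * dt convention)
    residues_contacted: frozenset = frozenset()
    site: str | None = None

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if not math.isclose(self.t_b, self.t_end - self.t_start, rel_tol=1e-9):
            raise ValueError("t_b must equal t_end - t_start")

    @property
    def n_frames(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass
class SurvivalCurve:
    """Fraction of initially bound configurations still bound at lag t."""

    times: np.ndarray  # ns, starts at 0
    fraction: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.times[0] != 0 or not math.isclose(self.fraction[0], 1.0):
            raise ValueError("survival curve must start at f(0) = 1")
        if np.any(np.diff(self.fraction) > 1e-12):
            raise ValueError("survival curve must be non-increasing")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class BiexpFit:
    """f(t) = a_fast exp(-t/tau_fast) + a_slow exp(-t/tau_slow), a_fast+a_slow=1."""

    a_fast: float
    tau_fast: float  # ns
    a_slow: float
    tau_slow: float  # ns
    residual: float

    def __post_init__(self) -> None:
        if not math.isclose(self.a_fast + self.a_slow, 1.0, abs_tol=1e-9):
            raise ValueError("amplitudes must sum to 1")
        if min(self.a_fast, self.a_slow) < -1e-12:
            raise ValueError("amplitudes must be non-negative")
        if not 0 < self.tau_fast <= self.tau_slow:
            raise ValueError("need 0 < tau_fast <= tau_slow")

    @property
    def slow_fraction(self) -> float:
        """Fractional contribution of the slow component (amplitude weight)."""
        return self.a_slow

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a_fast * np.exp(-t / self.tau_fast) + self.a_slow * np.exp(
            -t / self.tau_slow
        )


# ---------------------------------------------------------------------------
# Distance series
# ---------------------------------------------------------------------------

def min_distance_series(
    traj: Trajectory,
    ion: IonSelection,
    protein_atoms: np.ndarray | None = None,
    use_min_image: bool | None = None,
    chunk: int = 4096,
) -> DistanceSeries:
    """Per-frame minimum distance between ion atoms and protein heavy atoms.

    Hydrogens are excluded from the protein side.  ``use_min_image``
    defaults to on when the trajectory carries a box.  ``protein_atoms``
    (positional indices) overrides the default selection of heavy atoms in
    amino-acid residues.
    """
    top = traj.topology
    ion_idx = ion.atom_indices(top)
    if protein_atoms is None:
        protein_atoms = top.heavy_protein_indices()
        protein_atoms = protein_atoms[~np.isin(protein_atoms, ion_idx)]
    protein_atoms = np.asarray(protein_atoms)
    if len(protein_atoms) == 0:
        raise ValueError("no protein heavy atoms available for distance calculation")
    if use_min_image is None:
        use_min_image = traj.boxes is not None

    n = traj.n_frames
    d_min = np.empty(n)
    nearest = np.empty(n, dtype=np.int64)
    res_of_protein_atom = top.residue_indices[protein_atoms]

    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        ipos = traj.coords[lo:hi][:, ion_idx, :]      # (f, k, 3)
        ppos = traj.coords[lo:hi][:, protein_atoms, :]  # (f, m, 3)
        disp = ipos[:, :, None, :] - ppos[:, None, :, :]
        if use_min_image and traj.boxes is not None:
            box = traj.boxes[lo:hi][:, None, None, :]
            disp = disp - box * np.round(disp / box)
        d = np.linalg.norm(disp, axis=-1)  # (f, k, m)
        d_flat = d.reshape(hi - lo, -1)
        arg = d_flat.argmin(axis=1)
        d_min[lo:hi] = d_flat[np.arange(hi - lo), arg]
        nearest[lo:hi] = res_of_protein_atom[arg % len(protein_atoms)]

    return DistanceSeries(
        times_ns=traj.times / 1000.0,
        d_min=d_min,
        nearest_residue=nearest,
        ion_label=ion.label,
    )


def distance_density(
    series: DistanceSeries,
    bin_width: float = 0.05,
    contact_cutoff: float = 2.75,
    r_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Normalised histogram of minimum distances plus a contact probability.

    Returns (bin_centers, density, p_contact) where the density integrates
    to 1 and p_contact is the fraction of frames with d_min <= cutoff.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(series.d_min) == 0:
        raise ValueError("empty distance series")
    if r_max is None:
        r_max = float(series.d_min.max()) + bin_width
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    density, edges = np.histogram(series.d_min, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p_contact = float(np.mean(series.d_min <= contact_cutoff))
    return centers, density, p_contact


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def _runs_below_cutoff(below: np.ndarray, gap: int) -> list[tuple[int, int]]:
    """Maximal runs of True, merging runs separated by <= gap False frames."""
    padded = np.concatenate([[False], below, [False]])
    d = np.diff(padded.astype(int))
    starts = list(np.flatnonzero(d == 1))
    ends = list(np.flatnonzero(d == -1) - 1)  # inclusive
    if gap > 0 and len(starts) > 1:
        merged = [(starts[0], ends[0])]
        for s, e in zip(starts[1:], ends[1:]):
            ps, pe = merged[-1]
            if s - pe - 1 <= gap:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        return merged
    return list(zip(starts, ends))


def detect_binding_events(
    series: DistanceSeries,
    cutoff: float = 4.0,
    min_duration: float | None = None,
    gap: int = 0,
) -> list[BindingEvent]:
    """Maximal runs of frames with d_min < cutoff, shorter runs dropped.

    ``min_duration`` is in ns and defaults to two frame intervals (the
    two-consecutive-frames rule: 0.4 ns at 0.2 ns sampling).  ``gap``
    tolerates that many frames above the cutoff inside an event (0 =
    strict, a single excursion ends the event).
    """
    dt = series.uniform_dt()
    if min_duration is None:
        min_duration = 2.0 * dt
    below = series.d_min < cutoff
    events: list[BindingEvent] = []
    for start, end in _runs_below_cutoff(below, gap):
        n_run = end - start + 1
        t_b = n_run * dt
        if t_b < min_duration - 1e-12:
            continue
        in_run = np.arange(start, end + 1)
        contacted = frozenset(
            int(r) for r in series.nearest_residue[in_run][below[in_run]]
        )
        t_start = float(series.times_ns[start])
        events.append(
            BindingEvent(
                ion_id=series.ion_label,
                start_index=int(start),
                end_index=int(end),
                t_start=t_start,
                t_end=t_start + t_b,
                t_b=t_b,
                residues_contacted=contacted,
            )
        )
    return events


def assign_site(
    event: BindingEvent,
    traj: Trajectory,
    ion: IonSelection,
    sites: Sequence[SiteDefinition],
    use_min_image: bool | None = None,
) -> str | None:
    """Assign an event to the site most often within its bound cutoff.

    The winning site is the one whose defining residues' heavy atoms come
    within ``bound_cutoff`` of the ion for the largest number of event
    frames; ties break towards the smaller mean distance; None if no site
    is ever within its cutoff.
    """
    top = traj.topology
    ion_idx = ion.atom_indices(top)
    if use_min_image is None:
        use_min_image = traj.boxes is not None
    frames = np.arange(event.start_index, event.end_index + 1)
    best: tuple[int, float, str] | None = None  # (count, mean_d, name)
    for site in sites:
        site_atoms = top.atom_positions_of_residues(site.residues)
        if len(site_atoms) == 0:
            continue
        ipos = traj.coords[frames][:, ion_idx, :]
        spos = traj.coords[frames][:, site_atoms, :]
        disp = ipos[:, :, None, :] - spos[:, None, :, :]
        if use_min_image and traj.boxes is not None:
            box = traj.boxes[frames][:, None, None, :]
            disp = disp - box * np.round(disp / box)
        d = np.linalg.norm(disp, axis=-1).reshape(len(frames), -1).min(axis=1)
        count = int(np.sum(d <= site.bound_cutoff))
        mean_d = float(d.mean())
        if count > 0:
            cand = (count, mean_d, site.name)
            if (
                best is None
                or cand[0] > best[0]
                or (cand[0] == best[0] and cand[1] < best[1])
            ):
                best = cand
    return None if best is None else best[2]


def residue_binding_stats(
    events: Sequence[BindingEvent],
    series: DistanceSeries,
    topology,
) -> dict[str, float]:
    """Fraction of binding events per residue type (3-letter code).

    Each event's binding partner is its modal nearest residue over the
    event frames; fractions over events sum to 1.
    """
    if not events:
        return {}
    counts: dict[str, int] = {}
    for ev in events:
        res_idx = series.nearest_residue[ev.start_index : ev.end_index + 1]
        vals, cnts = np.unique(res_idx, return_counts=True)
        modal = int(vals[np.argmax(cnts)])
        name = str(topology.residue_names[modal])
        counts[name] = counts.get(name, 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in sorted(counts.items())}


# ---------------------------------------------------------------------------
# Summaries and fits
# ---------------------------------------------------------------------------

def group_durations_by_site(events: Iterable[BindingEvent]) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {}
    for ev in events:
        out.setdefault(ev.site if ev.site is not None else "unassigned", []).append(
            ev.t_b
        )
    return out


def binding_time_summary(
    durations_by_site: Mapping[str, Sequence[float]] | Iterable[BindingEvent],
    thresholds: Sequence[float] = (1.0, 10.0, 100.0),
) -> pd.DataFrame:
    """Per-site and aggregate counts of events exceeding duration thresholds.

    One row per site plus an ``all`` row.  ``pct_ge_X`` columns are the
    percentage of that site's events (aggregate row: of the grand total)
    with t_b >= X ns, rounded to one decimal; ``share_pct`` is the site's
    share of all events.
    """
    if not isinstance(durations_by_site, Mapping):
        durations_by_site = group_durations_by_site(durations_by_site)
    rows = []
    grand_total = sum(len(v) for v in durations_by_site.values())
    agg_counts = [0] * len(thresholds)
    for site in durations_by_site:
        tb = np.asarray(list(durations_by_site[site]), dtype=float)
        row: dict = {"site": site, "total": len(tb)}
        row["share_pct"] = (
            round(100.0 * len(tb) / grand_total, 1) if grand_total else 0.0
        )
        for j, thr in enumerate(thresholds):
            c = int(np.sum(tb >= thr))
            agg_counts[j] += c
            row[f"n_ge_{thr:g}ns"] = c
            row[f"pct_ge_{thr:g}ns"] = round(100.0 * c / len(tb), 1) if len(tb) else 0.0
        rows.append(row)
    agg: dict = {"site": "all", "total": grand_total, "share_pct": 100.0 if grand_total else 0.0}
    for j, thr in enumerate(thresholds):
        agg[f"n_ge_{thr:g}ns"] = agg_counts[j]
        agg[f"pct_ge_{thr:g}ns"] = (
            round(100.0 * agg_counts[j] / grand_total, 1) if grand_total else 0.0
        )
    rows.append(agg)
    return pd.DataFrame(rows)


def mean_binding_time(events: Iterable[BindingEvent] | Sequence[float]) -> float:
    """Arithmetic mean of t_b (ns): the MLE of the inverse decay rate of an
    exponential binding-time distribution."""
    tb = [ev.t_b if isinstance(ev, BindingEvent) else float(ev) for ev in events]
    if not tb:
        raise ValueError("no binding events")
    return float(np.mean(tb))


def bound_fraction_curve(events: Iterable[BindingEvent] | Sequence[float]) -> SurvivalCurve:
    """Empirical survival curve f(t) = #{t_b >= t} / N on the distinct-t_b grid."""
    tb = np.asarray(
        [ev.t_b if isinstance(ev, BindingEvent) else float(ev) for ev in events]
    )
    if len(tb) == 0:
        raise ValueError("no binding events")
    grid = np.unique(tb)
    times = np.concatenate([[0.0], grid])
    frac = np.array([np.mean(tb >= t) for t in times])
    return SurvivalCurve(times=times, fraction=frac)


def _biexp_model(t, a, tau_f, tau_s):
    return a * np.exp(-t / tau_f) + (1.0 - a) * np.exp(-t / tau_s)


def fit_biexponential(curve: SurvivalCurve) -> BiexpFit:
    """Constrained nonlinear least-squares bi-exponential fit of f(t).

    Deterministic multi-start over decade-spaced (tau_fast, tau_slow)
    pairs bracketing the data's time range; the best residual wins, ties
    broken towards the smaller tau_slow.
    """
    t = curve.times
    f = curve.fraction
    if len(np.unique(t)) < 6:
        raise ValueError("need at least 6 distinct time points for a biexp fit")
    t_pos = t[t > 0]
    lo = max(t_pos.min() / 10.0, 1e-6)
    hi = t.max() * 10.0
    decades = 10.0 ** np.arange(math.floor(math.log10(lo)), math.ceil(math.log10(hi)) + 1)

    best: tuple[float, float, tuple[float, float, float]] | None = None
    for i, tf0 in enumerate(decades):
        for ts0 in decades[i:]:
            for a0 in (0.3, 0.7, 0.95):
                try:
                    res = optimize.least_squares(
                        lambda p: _biexp_model(t, *p) - f,
                        x0=[a0, tf0, ts0],
                        bounds=([0.0, 1e-9, 1e-9], [1.0, np.inf, np.inf]),
                        method="trf",
                    )
                except ValueError:
                    continue
                if not res.success:
                    continue
                a, tau_f, tau_s = res.x
                if tau_f > tau_s:  # canonical ordering
                    a, tau_f, tau_s = 1.0 - a, tau_s, tau_f
                cost = float(res.cost)
                cand = (cost, tau_s, (a, tau_f, tau_s))
                if best is None or cand[0] < best[0] - 1e-15 or (
                    math.isclose(cand[0], best[0], rel_tol=1e-9, abs_tol=1e-15)
                    and cand[1] < best[1]
                ):
                    best = cand
    if best is None:
        raise RuntimeError("bi-exponential fit failed to converge from any start")
    cost, _, (a, tau_f, tau_s) = best
    return BiexpFit(
        a_fast=float(a),
        tau_fast=float(tau_f),
        a_slow=float(1.0 - a),
        tau_slow=float(tau_s),
        residual=math.sqrt(2.0 * cost),
    )


def hit_rate(n_events: int, total_time: float) -> float:
    """Binding events per ns of simulation time."""
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    return n_events / total_time


# ---------------------------------------------------------------------------
# Escape termination
# ---------------------------------------------------------------------------

def escape_termination(
    traj: Trajectory,
    ion: IonSelection,
    sites: Sequence[SiteDefinition],
    mode: str = "site_local",
    site: str | None = None,
    site_local_cutoff: float = 3.0,
    far_field_cutoff: float = 10.0,
    use_min_image: bool | None = None,
) -> int:
    """Frame index at which an escape criterion first triggers.

    ``site_local``: first frame with the ion more than ``site_local_cutoff``
    from the designated site's residues.  ``far_field``: first frame more
    than ``far_field_cutoff`` from every site's residues.  Returns
    ``traj.n_frames`` if never triggered.
    """
    if not sites:
        raise ValueError("need at least one site")
    if mode not in ("site_local", "far_field"):
        raise ValueError(f"unknown mode {mode!r}")
    top = traj.topology
    ion_idx = ion.atom_indices(top)
    if use_min_image is None:
        use_min_image = traj.boxes is not None

    def site_dist(s: SiteDefinition) -> np.ndarray:
        atoms = top.atom_positions_of_residues(s.residues)
        ipos = traj.coords[:, ion_idx, :]
        spos = traj.coords[:, atoms, :]
        disp = ipos[:, :, None, :] - spos[:, None, :, :]
        if use_min_image and traj.boxes is not None:
            box = traj.boxes[:, None, None, :]
            disp = disp - box * np.round(disp / box)
        return np.linalg.norm(disp, axis=-1).reshape(traj.n_frames, -1).min(axis=1)

    if mode == "site_local":
        chosen = sites[0] if site is None else next(s for s in sites if s.name == site)
        escaped = site_dist(chosen) > site_local_cutoff
    else:
        d_all = np.stack([site_dist(s) for s in sites], axis=1)
        escaped = (d_all > far_field_cutoff).all(axis=1)
    hits = np.flatnonzero(escaped)
    return int(hits[0]) if len(hits) else traj.n_frames


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def detect_hydrogen_bonds(
    traj: Trajectory,
    ion: IonSelection,
    donor_atom_ids: Sequence[int],
    distance_cutoff: float = 3.5,
    angle_min_deg: float = 120.0,
    h_bond_length: float = 1.25,
) -> list[list[dict]]:
    """Geometric donor-H...acceptor contacts per frame.

    Criterion: donor-acceptor distance <= ``distance_cutoff`` and
    donor-H...acceptor angle (at the hydrogen) >= ``angle_min_deg``.
    Hydrogens attached to a donor are those of the donor's residue within
    ``h_bond_length`` in the first frame; a donor with none raises.
    """
    top = traj.topology
    acc_idx = ion.atom_indices(top)
    donors = []
    for aid in donor_atom_ids:
        d_idx = top.index_of_atom_id(aid)
        same_res = np.flatnonzero(
            (top.residue_indices == top.residue_indices[d_idx])
            & (np.asarray(top.elements) == "H")
        )
        if len(same_res):
            dist0 = np.linalg.norm(
                traj.coords[0, same_res, :] - traj.coords[0, d_idx, :], axis=1
            )
            attached = same_res[dist0 <= h_bond_length]
        else:
            attached = np.empty(0, dtype=int)
        if len(attached) == 0:
            raise ValueError(
                f"donor atom {aid} ({top.names[d_idx]}) has no attached hydrogen"
            )
        donors.append((d_idx, attached))

    contacts_per_frame: list[list[dict]] = []
    cos_max = math.cos(math.radians(angle_min_deg))  # angle >= min <=> cos <= cos_max
    for fi in range(traj.n_frames):
        frame_contacts: list[dict] = []
        for d_idx, h_indices in donors:
            dpos = traj.coords[fi, d_idx]
            for a_idx in acc_idx:
                apos = traj.coords[fi, a_idx]
                if np.linalg.norm(apos - dpos) > distance_cutoff:
                    continue
                for h_idx in h_indices:
                    hpos = traj.coords[fi, h_idx]
                    v1 = dpos - hpos
                    v2 = apos - hpos
                    cosang = float(
                        np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    )
                    if cosang <= cos_max:
                        frame_contacts.append(
                            {
                                "donor": int(top.atom_ids[d_idx]),
                                "hydrogen": int(top.atom_ids[h_idx]),
                                "acceptor": int(top.atom_ids[a_idx]),
                                "distance": float(np.linalg.norm(apos - dpos)),
                                "angle_deg": float(
                                    math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                                ),
                            }
                        )
        contacts_per_frame.append(frame_contacts)
    return contacts_per_frame


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation between binding times and tau_2 values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("inputs must have nonzero variance")
    return float(stats.pearsonr(x, y).statistic)
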