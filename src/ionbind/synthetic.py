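"""Synthetic trajectory and point-set generators with known ground truth.

The generators emulate the statistical structure the downstream analyses
assume — ions that stochastically bind and unbind at labelled protein
sites with exponential residence times, rotational Brownian motion of a
bond vector with a prescribed correlation time, and pseudo-water point
clouds with a prescribed radial shell structure — so that every stage is
testable against a latent truth without MD data.

All generators are deterministic given (spec, seed).  The binding
generator expands one global seed into per-ion substreams with
:class:`numpy.random.SeedSequence` spawn keys, so adding ions does not
perturb the streams of existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import SiteDefinition, Topology, Trajectory

__all__ = [
    "SiteKineticsSpec",
    "BindingKineticsSpec",
    "RotationalDiffusionSpec",
    "SolvationShellSpec",
    "ShellSpec",
    "simulate_markov_binding",
    "latent_residence_times",
    "simulate_rotational_diffusion",
    "generate_solvation_points",
    "generate_decoy_protein",
]

#: Exclusion radius (Å) around site centres for free-ion placement.
FREE_EXCLUSION_RADIUS = 6.0

FREE = -1  # latent-state code for an unbound ion


@dataclass(frozen=True)
class SiteKineticsSpec:
    """One binding site of the two-state (free <-> bound) kinetics model."""

    site_id: str
    center: tuple[float, float, float]
    k_on: float  # ns^-1, free -> this site
    k_off: float  # ns^-1, this site -> free
    jitter_sigma: float = 0.5  # Å, isotropic positional jitter when bound

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("rates must be non-negative")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")


@dataclass(frozen=True)
class BindingKineticsSpec:
    """Conditions of a synthetic binding/unbinding simulation.

    Defaults mirror the coarse-sampled bulk-diffusion condition: frames
    every 0.2 ns, bound-state jitter 0.5 Å.  ``duration`` and ``dt`` are in
    ns.
    """

    sites: tuple[SiteKineticsSpec, ...]
    box: tuple[float, float, float]
    n_ions: int
    duration: float  # ns
    dt: float = 0.2  # ns
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least dt")
        if self.n_ions < 1:
            raise ValueError("need at least one ion")
        if any(b <= 0 for b in self.box):
            raise ValueError("box lengths must be positive")
        k_on_total = sum(s.k_on for s in self.sites)
        k_off_max = max((s.k_off for s in self.sites), default=0.0)
        if k_on_total * self.dt > 1 or k_off_max * self.dt > 1:
            raise ValueError(
                "total per-step transition probability exceeds 1; use a smaller dt"
            )

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration / self.dt)) + 1


def _sample_run_lengths(rng: np.random.Generator, p: float, need: int) -> np.ndarray:
    """Geometric (first-success) run lengths; p may be 0 (never leaves)."""
    if p <= 0:
        return np.full(need, np.iinfo(np.int64).max, dtype=np.int64)
    return rng.geometric(p, size=need)


def _simulate_states_one_ion(
    spec: BindingKineticsSpec, rng: np.random.Generator
) -> np.ndarray:
    """Per-frame latent state of one ion: FREE or site index.

    Equivalent to a per-step Bernoulli chain with transition probability
    1 - exp(-k dt) per step, realised by sampling alternating geometric
    run lengths.
    """
    n = spec.n_frames
    k_on = np.array([s.k_on for s in spec.sites])
    k_on_total = k_on.sum()
    p_bind = 1.0 - math.exp(-k_on_total * spec.dt) if k_on_total > 0 else 0.0
    states = np.empty(n, dtype=np.int64)
    pos = 0
    state = FREE  # all ions start free
    while pos < n:
        if state == FREE:
            run = int(_sample_run_lengths(rng, p_bind, 1)[0]) if p_bind > 0 else n - pos
            run = min(run, n - pos)
            states[pos : pos + run] = FREE
            pos += run
            if pos < n:
                state = int(rng.choice(len(spec.sites), p=k_on / k_on_total))
        else:
            p_off = 1.0 - math.exp(-spec.sites[state].k_off * spec.dt)
            run = int(_sample_run_lengths(rng, p_off, 1)[0]) if p_off > 0 else n - pos
            run = min(run, n - pos)
            states[pos : pos + run] = state
            pos += run
            state = FREE
    return states


def _place_ion(
    spec: BindingKineticsSpec, states: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Coordinates for one ion given its latent state series.

    Bound frames: site centre + isotropic Gaussian jitter.  Free frames:
    i.i.d. uniform in the box, rejection-sampled outside spheres of radius
    ``FREE_EXCLUSION_RADIUS`` around every site centre.
    """
    n = len(states)
    box = np.asarray(spec.box)
    centers = np.array([s.center for s in spec.sites]) if spec.sites else np.empty((0, 3))
    coords = np.empty((n, 3))

    free_mask = states == FREE
    n_free = int(free_mask.sum())
    if n_free:
        placed = np.empty((n_free, 3))
        todo = np.arange(n_free)
        while len(todo):
            cand = rng.uniform(0.0, 1.0, size=(len(todo), 3)) * box
            if len(centers):
                d = np.linalg.norm(cand[:, None, :] - centers[None, :, :], axis=-1)
                ok = (d > FREE_EXCLUSION_RADIUS).all(axis=1)
            else:
                ok = np.ones(len(todo), dtype=bool)
            placed[todo[ok]] = cand[ok]
            todo = todo[~ok]
        coords[free_mask] = placed

    for j, site in enumerate(spec.sites):
        m = states == j
        if m.any():
            jitter = rng.normal(0.0, site.jitter_sigma, size=(int(m.sum()), 3))
            coords[m] = np.asarray(site.center) + jitter
    return coords


def simulate_markov_binding(
    spec: BindingKineticsSpec,
    protein: tuple[Topology, np.ndarray] | None = None,
    ion_label: str = "SOX",
    two_atom_ions: bool = False,
    bond_length: float = 1.33,
) -> tuple[Trajectory, np.ndarray]:
    """Simulate ions hopping between free diffusion and binding sites.

    Each ion is an independent two-state (free <-> each site) Markov chain
    discretised at ``spec.dt``; residence times are geometric with per-step
    leaving probability 1 - exp(-k_off dt), i.e. exponential with mean
    1/k_off in the continuum limit.  Reproducible under a fixed seed.

    Parameters
    ----------
    protein
        Optional (topology, coords) of a static scaffold (e.g. from
        :func:`generate_decoy_protein`) prepended to the trajectory so
        distance-based detection has a protein side.
    two_atom_ions
        If true, each ion gets two atoms separated by ``bond_length`` along
        a random (per-frame) orientation, mimicking the O-O bond.

    Returns
    -------
    trajectory, states
        ``states`` has shape (n_frames, n_ions) with -1 for free and the
        site index otherwise.
    """
    n_frames = spec.n_frames
    states = np.empty((n_frames, spec.n_ions), dtype=np.int64)
    ion_coords = []
    for i in range(spec.n_ions):
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(i,)))
        s = _simulate_states_one_ion(spec, rng)
        states[:, i] = s
        ion_coords.append(_place_ion(spec, s, rng))

    # Assemble topology: protein atoms first, then ion atoms.
    atoms_per_ion = 2 if two_atom_ions else 1
    if protein is not None:
        ptop, pcoords = protein
        base_atoms = ptop.n_atoms
        base_res = ptop.n_residues
        atom_ids = list(ptop.atom_ids)
        names = list(ptop.names)
        elements = list(ptop.elements)
        residx = list(ptop.residue_indices)
        res_names = list(ptop.residue_names)
        chains = list(ptop.chains)
    else:
        base_atoms = base_res = 0
        atom_ids, names, elements, residx, res_names, chains = [], [], [], [], [], []
        pcoords = np.empty((0, 3))

    next_id = (max(atom_ids) + 1) if atom_ids else 1
    for i in range(spec.n_ions):
        res_names.append(ion_label)
        chains.append("I")
        for a in range(atoms_per_ion):
            atom_ids.append(next_id)
            next_id += 1
            names.append(f"O{a + 1}" if two_atom_ions else "ION")
            elements.append("O" if two_atom_ions else "Cl")
            residx.append(base_res + i)

    topology = Topology(
        atom_ids=np.array(atom_ids),
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        residue_indices=np.array(residx),
        residue_names=np.array(res_names, dtype=object),
        chains=np.array(chains, dtype=object),
    )

    n_atoms = base_atoms + spec.n_ions * atoms_per_ion
    coords = np.empty((n_frames, n_atoms, 3))
    if base_atoms:
        coords[:, :base_atoms, :] = pcoords[None, :, :]
    orient_rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(spec.n_ions,))
    )
    for i in range(spec.n_ions):
        start = base_atoms + i * atoms_per_ion
        if two_atom_ions:
            u = orient_rng.normal(size=(n_frames, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            half = 0.5 * bond_length * u
            coords[:, start, :] = ion_coords[i] + half
            coords[:, start + 1, :] = ion_coords[i] - half
        else:
            coords[:, start, :] = ion_coords[i]

    times_ps = np.arange(n_frames) * spec.dt * 1000.0
    boxes = np.tile(np.asarray(spec.box, dtype=float), (n_frames, 1))
    traj = Trajectory(topology=topology, times=times_ps, coords=coords, boxes=boxes)
    return traj, states


def latent_residence_times(states: np.ndarray, dt: float) -> np.ndarray:
    """Complete bound-run durations (ns) from a latent state series.

    Runs truncated by the start or end of the series are excluded.  The
    duration convention is n_frames_in_run * dt, matching the event
    detector.
    """
    states = np.atleast_2d(states.T).T  # (n_frames, n_ions)
    out = []
    for i in range(states.shape[1]):
        s = states[:, i]
        bound = s != FREE
        padded = np.concatenate([[False], bound, [False]])
        d = np.diff(padded.astype(int))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)  # exclusive
        for a, b in zip(starts, ends):
            if a == 0 or b == len(s):
                continue  # truncated by the observation window
            out.append((b - a) * dt)
    return np.array(out)


# ---------------------------------------------------------------------------
# Rotational Brownian motion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RotationalDiffusionSpec:
    """Isotropic rotational Brownian motion of a unit bond vector.

    Ground truth: the second-rank orientational correlation decays as
    exp(-6 D_r t), i.e. tau_2 = 1 / (6 D_r).
    """

    D_r: float  # rad^2 / ps
    dt: float  # ps
    n_steps: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D_r < 0:
            raise ValueError("D_r must be non-negative")
        if self.dt <= 0 or self.n_steps < 1:
            raise ValueError("dt must be positive and n_steps >= 1")
        if self.D_r * self.dt >= 0.01:
            raise ValueError(
                "D_r * dt too large for the small-angle step (need < 0.01 rad^2); "
                "use a smaller dt"
            )

    @property
    def tau2(self) -> float:
        """Ground-truth correlation time in ps (inf if D_r == 0)."""
        return math.inf if self.D_r == 0 else 1.0 / (6.0 * self.D_r)


def simulate_rotational_diffusion(spec: RotationalDiffusionSpec) -> np.ndarray:
    """Unit-vector time series (n_steps + 1, 3) under rotational diffusion.

    Each step applies a Gaussian rotation vector in the tangent plane of
    the current orientation, with variance 2 D_r dt per transverse
    component (total angular variance 4 D_r dt) — the standard isotropic
    discretisation for which <P2(u(0)·u(t))> = exp(-6 D_r t).  |u| = 1 is
    re-normalised every step and holds to 1e-12.
    """
    n = spec.n_steps
    out = np.empty((n + 1, 3))
    out[0] = (0.0, 0.0, 1.0)
    if spec.D_r == 0:
        out[:] = out[0]
        return out

    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(2.0 * spec.D_r * spec.dt)
    xi = rng.normal(0.0, sigma, size=(n, 2))
    # Plain-float inner loop: the recursion is inherently sequential and
    # scalar math is markedly faster than per-step numpy ops.
    xs = xi[:, 0].tolist()
    ys = xi[:, 1].tolist()
    ux, uy, uz = 0.0, 0.0, 1.0
    sqrt = math.sqrt
    cos, sin = math.cos, math.sin
    for k in range(n):
        # Orthonormal tangent basis (e1, e2) at u.
        if abs(uz) < 0.9:
            ax, ay, az = 0.0, 0.0, 1.0
        else:
            ax, ay, az = 1.0, 0.0, 0.0
        e1x = ay * uz - az * uy
        e1y = az * ux - ax * uz
        e1z = ax * uy - ay * ux
        inv = 1.0 / sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
        e1x *= inv
        e1y *= inv
        e1z *= inv
        e2x = uy * e1z - uz * e1y
        e2y = uz * e1x - ux * e1z
        e2z = ux * e1y - uy * e1x
        a, b = xs[k], ys[k]
        theta = sqrt(a * a + b * b)
        if theta > 0.0:
            # Rotate u by angle theta about the unit tangent axis
            # (a e1 + b e2)/theta; since the axis is perpendicular to u,
            # Rodrigues reduces to u' = u cos(theta) + (axis x u) sin(theta).
            wx = (a * e1x + b * e2x) / theta
            wy = (a * e1y + b * e2y) / theta
            wz = (a * e1z + b * e2z) / theta
            cx = wy * uz - wz * uy
            cy = wz * ux - wx * uz
            cz = wx * uy - wy * ux
            c, s = cos(theta), sin(theta)
            ux = ux * c + cx * s
            uy = uy * c + cy * s
            uz = uz * c + cz * s
            inv = 1.0 / sqrt(ux * ux + uy * uy + uz * uz)
            ux *= inv
            uy *= inv
            uz *= inv
        out[k + 1] = (ux, uy, uz)
    return out


# ---------------------------------------------------------------------------
# Solvation point sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShellSpec:
    """One solvation shell: n_waters points at radius r0 +/- width."""

    r0: float
    width: float
    n_waters: int

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.width < 0 or self.n_waters < 0:
            raise ValueError("invalid shell parameters")


@dataclass(frozen=True)
class SolvationShellSpec:
    """Pseudo-water point cloud around an ion at the origin.

    Bulk points come from a homogeneous Poisson process of intensity
    ``bulk_density`` within 1.5 Å < r <= r_max; each shell adds
    ``n_waters`` points at Gaussian-jittered radius, uniform directions.
    """

    bulk_density: float  # Å^-3
    shells: tuple[ShellSpec, ...]
    r_max: float
    seed: int = 0
    r_core: float = 1.5  # excluded-volume core radius

    def __post_init__(self) -> None:
        if self.bulk_density < 0:
            raise ValueError("bulk_density must be non-negative")
        radii = [s.r0 for s in self.shells]
        if radii != sorted(radii):
            raise ValueError("shells must be sorted by r0")
        if self.shells and self.r_max <= max(radii):
            raise ValueError("r_max must exceed the outermost shell radius")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")


def _uniform_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_solvation_points(spec: SolvationShellSpec) -> np.ndarray:
    """Pseudo-water oxygen positions (n, 3) around an ion at the origin."""
    rng = np.random.default_rng(spec.seed)
    points = []

    if spec.bulk_density > 0:
        vol = 4.0 / 3.0 * math.pi * (spec.r_max**3 - spec.r_core**3)
        n_bulk = rng.poisson(spec.bulk_density * vol)
        if n_bulk:
            u = rng.uniform(size=n_bulk)
            r = (spec.r_core**3 + u * (spec.r_max**3 - spec.r_core**3)) ** (1.0 / 3.0)
            points.append(_uniform_directions(rng, n_bulk) * r[:, None])

    for shell in spec.shells:
        if shell.n_waters:
            r = rng.normal(shell.r0, shell.width, size=shell.n_waters)
            r = np.abs(r)  # reflect the (negligible) negative tail
            points.append(_uniform_directions(rng, shell.n_waters) * r[:, None])

    if not points:
        return np.empty((0, 3))
    return np.concatenate(points, axis=0)


# ---------------------------------------------------------------------------
# Decoy protein
# ---------------------------------------------------------------------------

_DECOY_RESNAMES = ["ALA", "GLY", "SER", "THR", "LEU", "VAL", "ASP", "GLU"]


def generate_decoy_protein(
    n_residues: int,
    charged_site_residues: list[int] | tuple[int, ...] = (),
    seed: int = 0,
    radius: float = 10.0,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[Topology, np.ndarray, list[SiteDefinition]]:
    """Pseudo-protein of single-atom residues on a sphere surface.

    Residues listed in ``charged_site_residues`` are labelled ARG and each
    becomes the anchor of a :class:`SiteDefinition` (3 Å bound cutoff).
    Deterministic given the seed.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    for r in charged_site_residues:
        if not 0 <= r < n_residues:
            raise ValueError(f"site residue index {r} out of range")
    rng = np.random.default_rng(seed)
    coords = _uniform_directions(rng, n_residues) * radius + np.asarray(center)

    res_names = []
    site_set = set(charged_site_residues)
    for i in range(n_residues):
        if i in site_set:
            res_names.append("ARG")
        else:
            res_names.append(_DECOY_RESNAMES[i % len(_DECOY_RESNAMES)])

    topology = Topology(
        atom_ids=np.arange(1, n_residues + 1),
        names=np.array(["CA"] * n_residues, dtype=object),
        elements=np.array(["C"] * n_residues, dtype=object),
        residue_indices=np.arange(n_residues),
        residue_names=np.array(res_names, dtype=object),
        chains=np.array(["A"] * n_residues, dtype=object),
    )
    sites = [
        SiteDefinition(name=f"site_{k + 1}", residues=(r,))
        for k, r in enumerate(charged_site_residues)
    ]
    return topology, coords, sites
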