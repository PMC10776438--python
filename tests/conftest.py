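"""Shared fixtures: toy structures and session-scoped synthetic systems.

The expensive simulations (Markov binding with ~2500 events, 10^6-step
rotational diffusion) are generated once per session and shared across
the unit and acceptance tests that validate parameter recovery.
"""

import numpy as np
import pytest

from ionbind.core import IonSelection, Topology
from ionbind.synthetic import (
    BindingKineticsSpec,
    RotationalDiffusionSpec,
    SiteKineticsSpec,
    generate_decoy_protein,
    simulate_markov_binding,
    simulate_rotational_diffusion,
)

TOY_PDB = """\
ATOM      1  N   ALA A   1      20.000  20.000  20.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      21.400  20.000  20.000  1.00  0.00           C
ATOM      3  HA  ALA A   1      21.800  21.000  20.000  1.00  0.00           H
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


def make_topology(n_atoms, elements=None, res_names=("ALA",), residue_of=None):
    """Small hand-built topology; defaults to all atoms in one residue."""
    if elements is None:
        elements = ["C"] * n_atoms
    if residue_of is None:
        residue_of = [0] * n_atoms
    return Topology(
        atom_ids=np.arange(1, n_atoms + 1),
        names=np.array([f"A{i}" for i in range(n_atoms)], dtype=object),
        elements=np.array(elements, dtype=object),
        residue_indices=np.array(residue_of),
        residue_names=np.array(list(res_names), dtype=object),
        chains=np.array(["A"] * len(res_names), dtype=object),
    )


# ---------------------------------------------------------------------------
# Session-scoped synthetic systems
# ---------------------------------------------------------------------------

MARKOV_SEED = 11
MARKOV_K_OFF = 1.0  # ns^-1


@pytest.fixture(scope="session")
def markov_system():
    """Single-site binding system at fine (0.005 ns) sampling, ~2500 events.

    The decoy scaffold sits entirely within 1.5 Å of the site centre so
    the 4 Å contact criterion cleanly separates bound from free frames
    (free placements are excluded within 6 Å of the site).
    """
    top, coords, sites = generate_decoy_protein(
        8, [0], seed=3, radius=1.5, center=(20.0, 20.0, 20.0)
    )
    spec = BindingKineticsSpec(
        sites=(
            SiteKineticsSpec(
                "site_1", (20.0, 20.0, 20.0), k_on=1.0, k_off=MARKOV_K_OFF
            ),
        ),
        box=(40.0, 40.0, 40.0),
        n_ions=8,
        duration=600.0,
        dt=0.005,
        seed=MARKOV_SEED,
    )
    traj, states = simulate_markov_binding(spec, protein=(top, coords))
    return spec, traj, states, sites


@pytest.fixture(scope="session")
def markov_ions(markov_system):
    spec, traj, _, _ = markov_system
    n_protein = traj.topology.n_atoms - spec.n_ions
    return [
        IonSelection(
            label=f"ion_{i}", atom_ids=(int(traj.topology.atom_ids[n_protein + i]),)
        )
        for i in range(spec.n_ions)
    ]


ROT_TAU2 = 100.0  # ps, ground truth


@pytest.fixture(scope="session")
def rotational_series():
    """10^6-step rotational Brownian motion with tau_2 = 100 ps."""
    spec = RotationalDiffusionSpec(
        D_r=1.0 / (6.0 * ROT_TAU2), dt=1.0, n_steps=1_000_000, seed=7
    )
    return spec, simulate_rotational_diffusion(spec)
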