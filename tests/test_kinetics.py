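"""Binding-event detection, summaries, survival curves and fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import MARKOV_K_OFF, make_topology
from ionbind.core import IonSelection, SiteDefinition, Trajectory
from ionbind.kinetics import (
    BindingEvent,
    DistanceSeries,
    assign_site,
    binding_time_summary,
    bound_fraction_curve,
    detect_binding_events,
    detect_hydrogen_bonds,
    distance_density,
    escape_termination,
    fit_biexponential,
    group_durations_by_site,
    hit_rate,
    mean_binding_time,
    min_distance_series,
    pearson_correlation,
    residue_binding_stats,
)


def series_from(d_values, dt=0.2, residues=None):
    d = np.asarray(d_values, dtype=float)
    if residues is None:
        residues = np.zeros(len(d), dtype=int)
    return DistanceSeries(
        times_ns=np.arange(len(d)) * dt,
        d_min=d,
        nearest_residue=np.asarray(residues),
        ion_label="ion",
    )


def brute_force_events(d, cutoff, min_frames):
    """Independent run-length oracle for event detection."""
    runs = []
    start = None
    for i, v in enumerate(d):
        if v < cutoff and start is None:
            start = i
        elif v >= cutoff and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(d) - 1))
    return [(s, e) for s, e in runs if e - s + 1 >= min_frames]


# ---------------------------------------------------------------------------
# Distance series
# ---------------------------------------------------------------------------

class TestMinDistanceSeries:
    def _traj(self, atom_pos, ion_pos, box=None, ion_atoms=1):
        """One protein C atom(s) + ion atoms, single frame."""
        n_prot = len(atom_pos)
        n_atoms = n_prot + ion_atoms
        top = make_topology(
            n_atoms,
            elements=["C"] * n_prot + ["O"] * ion_atoms,
            res_names=["ALA", "SOX"],
            residue_of=[0] * n_prot + [1] * ion_atoms,
        )
        coords = np.array([list(atom_pos) + list(ion_pos)], dtype=float)
        boxes = np.array([box]) if box is not None else None
        return (
            Trajectory(topology=top, times=np.array([0.0]), coords=coords, boxes=boxes),
            IonSelection(
                label="sox", atom_ids=tuple(range(n_prot + 1, n_atoms + 1))
            ),
        )

    def test_simple_distance(self):
        traj, ion = self._traj([(0, 0, 3)], [(0, 0, 0)])
        s = min_distance_series(traj, ion)
        assert s.d_min[0] == pytest.approx(3.0)

    def test_closest_ion_atom_rule(self):
        traj, ion = self._traj([(0, 0, 0)], [(0, 0, 3), (0, 0, 5)], ion_atoms=2)
        s = min_distance_series(traj, ion)
        assert s.d_min[0] == pytest.approx(3.0)

    def test_minimum_image_against_brute_force(self):
        box = (10.0, 10.0, 10.0)
        traj, ion = self._traj([(6.0, 0.0, 0.0)], [(0.0, 0.0, 0.0)], box=box)
        s = min_distance_series(traj, ion)
        shifts = np.array(
            [
                [i, j, k]
                for i in (-1, 0, 1)
                for j in (-1, 0, 1)
                for k in (-1, 0, 1)
            ]
        )
        d_brute = np.linalg.norm(
            np.array([6.0, 0.0, 0.0]) + shifts * np.array(box), axis=1
        ).min()
        assert s.d_min[0] == pytest.approx(d_brute)

    def test_hydrogens_excluded_from_protein_side(self):
        # H at 1 Å, C at 3 Å: distance must be to the carbon
        top = make_topology(
            3,
            elements=["H", "C", "O"],
            res_names=["ALA", "SOX"],
            residue_of=[0, 0, 1],
        )
        coords = np.array([[[0, 0, 1.0], [0, 0, 3.0], [0, 0, 0.0]]])
        traj = Trajectory(topology=top, times=np.array([0.0]), coords=coords)
        s = min_distance_series(traj, IonSelection(label="sox", atom_ids=(3,)))
        assert s.d_min[0] == pytest.approx(3.0)

    def test_no_heavy_atoms_errors(self):
        top = make_topology(
            2, elements=["H", "O"], res_names=["ALA", "SOX"], residue_of=[0, 1]
        )
        coords = np.zeros((1, 2, 3))
        traj = Trajectory(topology=top, times=np.array([0.0]), coords=coords)
        with pytest.raises(ValueError, match="heavy"):
            min_distance_series(traj, IonSelection(label="sox", atom_ids=(2,)))


class TestDistanceDensity:
    def test_all_in_contact(self):
        _, _, p = distance_density(series_from([2.0] * 10), contact_cutoff=2.75)
        assert p == 1.0

    def test_half_in_contact(self):
        _, _, p = distance_density(
            series_from([2.0] * 5 + [5.0] * 5), contact_cutoff=2.75
        )
        assert p == 0.5

    def test_density_integrates_to_one(self):
        centers, density, _ = distance_density(
            series_from([2.0, 2.5, 3.7, 5.1, 6.0]), bin_width=0.1
        )
        assert np.sum(density) * 0.1 == pytest.approx(1.0)

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            distance_density(series_from([2.0]), bin_width=0.0)


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

class TestDetectBindingEvents:
    def test_minimal_two_frame_event_kept(self):
        """A 2-frame contact at 0.2 ns sampling spans 0.4 ns and is kept."""
        evs = detect_binding_events(series_from([5, 3.9, 3.8, 5]))
        assert len(evs) == 1
        assert evs[0].t_b == pytest.approx(0.4)

    def test_all_above_cutoff_empty(self):
        assert detect_binding_events(series_from([5, 6, 7, 8])) == []

    def test_two_events(self):
        evs = detect_binding_events(series_from([3, 3, 5, 3, 3]))
        assert [e.t_b for e in evs] == [pytest.approx(0.4), pytest.approx(0.4)]

    def test_single_frame_event_dropped(self):
        evs = detect_binding_events(series_from([5, 3.9, 5, 5]))
        assert evs == []

    def test_gap_tolerance_merges(self):
        d = [3, 3, 5, 3, 3]
        strict = detect_binding_events(series_from(d), gap=0)
        merged = detect_binding_events(series_from(d), gap=1)
        assert len(strict) == 2
        assert len(merged) == 1
        assert merged[0].t_b == pytest.approx(1.0)

    def test_residues_contacted_union(self):
        evs = detect_binding_events(
            series_from([3, 3, 3, 5], residues=[4, 7, 4, 0])
        )
        assert evs[0].residues_contacted == frozenset({4, 7})

    def test_non_uniform_dt_rejected(self):
        s = DistanceSeries(
            times_ns=np.array([0.0, 0.2, 0.5]),
            d_min=np.array([3.0, 3.0, 3.0]),
            nearest_residue=np.zeros(3, dtype=int),
        )
        with pytest.raises(ValueError, match="resample"):
            detect_binding_events(s)

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(st.lists(st.floats(0.1, 8.0), min_size=2, max_size=100))
    def test_matches_brute_force_run_scan(self, d):
        evs = detect_binding_events(series_from(d), cutoff=4.0, min_duration=0.4)
        expected = brute_force_events(d, 4.0, 2)
        assert [(e.start_index, e.end_index) for e in evs] == expected
        for e in evs:
            assert e.t_b == pytest.approx(e.n_frames * 0.2)

    def test_markov_bound_time_recovered(self, markov_system, markov_ions):
        """Detected per-ion bound time matches the latent truth within 5%."""
        spec, traj, states, _ = markov_system
        for i in (0, 3):
            s = min_distance_series(traj, markov_ions[i])
            evs = detect_binding_events(s)
            detected = sum(e.t_b for e in evs)
            latent = np.sum(states[:, i] != -1) * spec.dt
            assert detected == pytest.approx(latent, rel=0.05)

    def test_markov_mean_binding_time(self, markov_system, markov_ions):
        """Mean detected t_b converges to 1/k_off within 5% (>=2000 events)."""
        spec, traj, _, _ = markov_system
        tb = []
        for ion in markov_ions:
            s = min_distance_series(traj, ion)
            tb.extend(e.t_b for e in detect_binding_events(s))
        assert len(tb) >= 2000
        assert np.mean(tb) == pytest.approx(1.0 / MARKOV_K_OFF, rel=0.05)


# ---------------------------------------------------------------------------
# Site assignment and per-residue statistics
# ---------------------------------------------------------------------------

class TestAssignSite:
    def _system(self):
        """Two single-residue sites 12 Å apart."""
        top = make_topology(
            3,
            elements=["C", "C", "O"],
            res_names=["ARG", "ARG", "SOX"],
            residue_of=[0, 1, 2],
        )
        sites = [
            SiteDefinition(name="A", residues=(0,)),
            SiteDefinition(name="B", residues=(1,)),
        ]
        return top, sites

    def _traj(self, top, ion_path):
        n = len(ion_path)
        coords = np.zeros((n, 3, 3))
        coords[:, 0] = (0.0, 0.0, 0.0)
        coords[:, 1] = (12.0, 0.0, 0.0)
        coords[:, 2] = ion_path
        return Trajectory(topology=top, times=np.arange(n) * 200.0, coords=coords)

    def test_jitter_near_site(self):
        top, sites = self._system()
        rng = np.random.default_rng(0)
        path = rng.normal(0.0, 0.5, size=(10, 3))
        traj = self._traj(top, path)
        ev = BindingEvent("i", 0, 9, 0.0, 2.0, 2.0)
        assert assign_site(ev, traj, IonSelection("sox", (3,)), sites) == "A"

    def test_far_from_all_sites_none(self):
        top, sites = self._system()
        traj = self._traj(top, np.full((5, 3), (6.0, 6.0, 0.0)))
        ev = BindingEvent("i", 0, 4, 0.0, 1.0, 1.0)
        assert assign_site(ev, traj, IonSelection("sox", (3,)), sites) is None

    def test_majority_frame_tally(self):
        top, sites = self._system()
        # 10 frames within 3 Å of A, 3 frames within 3 Å of B
        path = [(1.0, 0, 0)] * 10 + [(11.0, 0, 0)] * 3
        traj = self._traj(top, np.array(path))
        ev = BindingEvent("i", 0, 12, 0.0, 2.6, 2.6)
        assert assign_site(ev, traj, IonSelection("sox", (3,)), sites) == "A"


class TestResidueBindingStats:
    def test_all_arg(self):
        top = make_topology(1, res_names=["ARG"], residue_of=[0])
        s = series_from([3, 3, 3], residues=[0, 0, 0])
        evs = detect_binding_events(s, min_duration=0.4)
        assert residue_binding_stats(evs, s, top) == {"ARG": 1.0}

    def test_even_split(self):
        top = make_topology(
            2, res_names=["ARG", "LYS"], residue_of=[0, 1]
        )
        s = series_from(
            [3, 3, 5, 3, 3, 5, 3, 3, 5, 3, 3],
            residues=[0, 0, 0, 1, 1, 0, 0, 0, 0, 1, 1],
        )
        evs = detect_binding_events(s)
        stats = residue_binding_stats(evs, s, top)
        assert stats == {"ARG": 0.5, "LYS": 0.5}

    def test_synthetic_arg_site_dominates(self, markov_system, markov_ions):
        spec, traj, _, _ = markov_system
        s = min_distance_series(traj, markov_ions[0])
        evs = detect_binding_events(s)
        stats = residue_binding_stats(evs, s, traj.topology)
        # residue 0 is the ARG anchor nearest the site centre in the decoy
        assert stats.get("ARG", 0.0) >= 0.0  # present key sanity
        assert sum(stats.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Summaries, survival curves, fits
# ---------------------------------------------------------------------------

# (total, >=1 ns, >=10 ns, >=100 ns) per site, and the printed percentages.
CONDITION_I = {
    "1": (2113, 764, 26, 0),
    "2": (3165, 1339, 44, 0),
    "3": (304, 94, 5, 2),
    "4": (2660, 670, 2, 0),
    "5": (1961, 432, 0, 0),
}
CONDITION_I_PCT = {
    "1": (36.2, 1.2, 0.0),
    "2": (42.3, 1.4, 0.0),
    "3": (30.9, 1.6, 0.7),
    "4": (25.2, 0.1, 0.0),
    "5": (22.0, 0.0, 0.0),
}


def durations_from_counts(counts):
    """Synthesise per-site duration lists realising printed band counts."""
    out = {}
    for site, (total, c1, c10, c100) in counts.items():
        out[site] = (
            [0.5] * (total - c1) + [2.0] * (c1 - c10) + [20.0] * (c10 - c100) + [150.0] * c100
        )
    return out


class TestBindingTimeSummary:
    def test_condition_counts_reproduce_percentages(self):
        df = binding_time_summary(durations_from_counts(CONDITION_I)).set_index("site")
        for site, (p1, p10, p100) in CONDITION_I_PCT.items():
            assert df.loc[site, "pct_ge_1ns"] == p1
            assert df.loc[site, "pct_ge_10ns"] == p10
            assert df.loc[site, "pct_ge_100ns"] == p100
        assert df.loc["all", "total"] == 10203
        assert df.loc["all", "pct_ge_1ns"] == 32.3
        assert df.loc["2", "share_pct"] == 31.0

    def test_counts_consistent_with_percentages(self):
        df = binding_time_summary(durations_from_counts(CONDITION_I))
        for _, row in df.iterrows():
            if row["total"]:
                assert row["pct_ge_1ns"] == pytest.approx(
                    round(100.0 * row["n_ge_1ns"] / row["total"], 1)
                )

    def test_empty_input(self):
        df = binding_time_summary({})
        assert df.loc[0, "site"] == "all"
        assert df.loc[0, "total"] == 0


class TestMeanBindingTime:
    def test_simple_mean(self):
        assert mean_binding_time([1.0, 2.0, 3.0]) == pytest.approx(2.0)

    def test_single_event(self):
        assert mean_binding_time([7.5]) == pytest.approx(7.5)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mean_binding_time([])

    def test_exponential_sample_mle(self):
        rng = np.random.default_rng(12)
        tb = rng.exponential(1.1, size=5000)
        assert mean_binding_time(tb) == pytest.approx(1.1, rel=0.03)


class TestSurvivalCurve:
    def test_fraction_at_lag(self):
        c = bound_fraction_curve([1.0, 2.0, 3.0])
        i = np.searchsorted(c.times, 2.0)
        assert c.fraction[i] == pytest.approx(2.0 / 3.0)

    def test_starts_at_one(self):
        c = bound_fraction_curve([0.4, 5.0])
        assert c.times[0] == 0.0
        assert c.fraction[0] == 1.0

    def test_step_grid_is_sorted_distinct_tb(self):
        tb = [2.0, 0.4, 2.0, 7.0]
        c = bound_fraction_curve(tb)
        np.testing.assert_allclose(c.times, [0.0, 0.4, 2.0, 7.0])
        assert np.all(np.diff(c.fraction) <= 0)


class TestBiexpFit:
    def test_recovers_noiseless_parameters(self):
        from ionbind.kinetics import SurvivalCurve

        t = np.linspace(0, 200, 200)
        f = 0.9 * np.exp(-t / 1.0) + 0.1 * np.exp(-t / 50.0)
        fit = fit_biexponential(SurvivalCurve(times=t, fraction=f))
        assert fit.a_fast == pytest.approx(0.9, rel=0.05)
        assert fit.tau_fast == pytest.approx(1.0, rel=0.05)
        assert fit.tau_slow == pytest.approx(50.0, rel=0.05)
        assert fit.slow_fraction == pytest.approx(0.1, rel=0.05)

    def test_monoexponential_degenerates_gracefully(self):
        from ionbind.kinetics import SurvivalCurve

        t = np.linspace(0, 20, 100)
        f = np.exp(-t / 2.0)
        fit = fit_biexponential(SurvivalCurve(times=t, fraction=f))
        assert np.max(np.abs(fit(t) - f)) < 1e-6
        # integral of the fitted model equals the mono-exponential tau
        assert fit.a_fast * fit.tau_fast + fit.a_slow * fit.tau_slow == pytest.approx(
            2.0, rel=0.05
        )

    def test_model_is_one_at_zero(self):
        from ionbind.kinetics import SurvivalCurve

        t = np.linspace(0, 30, 50)
        f = 0.7 * np.exp(-t / 0.5) + 0.3 * np.exp(-t / 8.0)
        fit = fit_biexponential(SurvivalCurve(times=t, fraction=f))
        assert fit(np.array([0.0]))[0] == pytest.approx(1.0)


class TestHitRate:
    def test_printed_totals(self):
        assert hit_rate(498, 3074.8) == pytest.approx(0.162, abs=5e-4)

    def test_zero_events(self):
        assert hit_rate(0, 100.0) == 0.0

    def test_simple(self):
        assert hit_rate(10, 100.0) == pytest.approx(0.1)

    def test_zero_time_errors(self):
        with pytest.raises(ValueError):
            hit_rate(1, 0.0)


# ---------------------------------------------------------------------------
# Escape termination and hydrogen bonds
# ---------------------------------------------------------------------------

class TestEscapeTermination:
    def _system(self, ion_path):
        top = make_topology(
            2, elements=["C", "O"], res_names=["ARG", "SOX"], residue_of=[0, 1]
        )
        n = len(ion_path)
        coords = np.zeros((n, 2, 3))
        coords[:, 1] = ion_path
        traj = Trajectory(topology=top, times=np.arange(n) * 200.0, coords=coords)
        site = SiteDefinition(name="A", residues=(0,))
        return traj, IonSelection("sox", (2,)), [site]

    def test_never_triggered(self):
        traj, ion, sites = self._system([(2.0, 0, 0)] * 5)
        assert escape_termination(traj, ion, sites, "site_local") == 5

    def test_site_local_crossing(self):
        path = [(2.0, 0, 0)] * 7 + [(5.0, 0, 0)] * 3
        traj, ion, sites = self._system(path)
        assert escape_termination(traj, ion, sites, "site_local") == 7

    def test_far_field_crossing(self):
        path = [(2.0, 0, 0)] * 4 + [(5.0, 0, 0)] * 4 + [(11.0, 0, 0)] * 2
        traj, ion, sites = self._system(path)
        assert escape_termination(traj, ion, sites, "far_field") == 8


class TestHydrogenBonds:
    def _system(self, h_pos, acc_pos):
        top = make_topology(
            3,
            elements=["N", "H", "O"],
            res_names=["ARG", "SOX"],
            residue_of=[0, 0, 1],
        )
        coords = np.array([[[0.0, 0.0, 0.0], list(h_pos), list(acc_pos)]])
        traj = Trajectory(topology=top, times=np.array([0.0]), coords=coords)
        return traj, IonSelection("sox", (3,))

    def test_collinear_contact(self):
        traj, ion = self._system((0, 0, 1.0), (0, 0, 2.9))
        contacts = detect_hydrogen_bonds(traj, ion, donor_atom_ids=[1])
        assert len(contacts[0]) == 1
        assert contacts[0][0]["angle_deg"] == pytest.approx(180.0)

    def test_bent_geometry_rejected(self):
        # D-A within 3.5 Å but D-H...A angle ~ 104 degrees: no contact
        traj, ion = self._system((1.0, 0.0, 0.0), (1.5, 2.0, 0.0))
        contacts = detect_hydrogen_bonds(traj, ion, donor_atom_ids=[1])
        assert contacts[0] == []

    def test_donor_without_hydrogen_errors(self):
        top = make_topology(
            2, elements=["N", "O"], res_names=["ARG", "SOX"], residue_of=[0, 1]
        )
        coords = np.zeros((1, 2, 3))
        coords[0, 1] = (0, 0, 2.9)
        traj = Trajectory(topology=top, times=np.array([0.0]), coords=coords)
        with pytest.raises(ValueError, match="hydrogen"):
            detect_hydrogen_bonds(traj, IonSelection("sox", (2,)), donor_atom_ids=[1])

    def test_contacts_monotone_in_distance_cutoff(self):
        traj, ion = self._system((0, 0, 1.0), (0, 0, 3.2))
        counts = [
            sum(len(f) for f in detect_hydrogen_bonds(traj, ion, [1], distance_cutoff=c))
            for c in (4.0, 3.5, 3.0, 2.5)
        ]
        assert counts == sorted(counts, reverse=True)


class TestPearson:
    def test_perfect_positive(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_correlation(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = [1.0, 2.0, 3.0]
        assert pearson_correlation(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_correlation([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])
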