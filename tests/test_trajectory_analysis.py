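"""Trajectory observables: RMSF, DCC, contacts, ion occupancy, angle series."""

import math

import numpy as np
import pytest

from complexlens import (
    ContactParams,
    DomainDefinition,
    Structure,
    Trajectory,
    angle_timeseries,
    contact_frequency,
    dynamic_cross_correlation,
    ion_occupancy,
    mean_angle_difference,
    resolve_selection,
    rmsf,
)
from complexlens.synthetic import (
    SyntheticSpec,
    make_gaussian_trajectory,
    make_ion_trajectory,
    make_ternary_toy,
)

from conftest import chain_of_cas


def traj_of(coords_per_frame, topology=None):
    frames = np.asarray(coords_per_frame, dtype=float)
    top = topology or Structure(chain_of_cas("A", frames[0]))
    return Trajectory(topology=top, frames=frames)


def sel_all(traj):
    return resolve_selection(traj.topology, {"chains": traj.topology.chains})


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        frames = [[[0, 0, 0], [3, 0, 0]]] * 4
        traj = traj_of(frames)
        profile = rmsf(traj)
        np.testing.assert_allclose(profile.rmsf, 0.0, atol=1e-12)

    def test_closed_form_three_frame_case(self):
        d = 0.7
        frames = [[[0, 0, 0]], [[d, 0, 0]], [[-d, 0, 0]]]
        traj = traj_of(frames)
        profile = rmsf(traj, superpose=False)
        assert profile.rmsf[0] == pytest.approx(d * math.sqrt(2.0 / 3.0))

    def test_gaussian_fixture_matches_generator_expectation(self):
        spec = SyntheticSpec(seed=7, n_frames=2000, per_atom_sigma=[0.3, 0.5, 0.8, 1.2] * 3)
        traj, truth = make_gaussian_trajectory(spec)
        profile = rmsf(traj, superpose=False)
        np.testing.assert_allclose(profile.rmsf, truth["expected_rmsf"], rtol=0.05)

    def test_invariant_under_global_rigid_transform_with_superposition(self):
        spec = SyntheticSpec(seed=8, n_frames=50, per_atom_sigma=[0.4] * 8)
        traj, _ = make_gaussian_trajectory(spec)
        base = rmsf(traj, superpose=True)
        t = math.radians(40.0)
        rot = np.array(
            [[math.cos(t), -math.sin(t), 0], [math.sin(t), math.cos(t), 0], [0, 0, 1]]
        )
        frames = traj.frames @ rot.T + np.array([10.0, -4.0, 2.0])
        moved = Trajectory(topology=traj.topology, frames=frames)
        np.testing.assert_allclose(rmsf(moved, superpose=True).rmsf, base.rmsf, atol=1e-8)

    def test_single_frame_rejected(self):
        traj = traj_of([[[0, 0, 0]]])
        with pytest.raises(ValueError, match="2 frames"):
            rmsf(traj)


class TestDcc:
    def test_identical_displacements_give_plus_one(self):
        base = np.array([[0, 0, 0], [10, 0, 0]], dtype=float)
        disp = [[0, 0, 0], [1, 1, 0], [-1, 0.5, 0], [0.5, -1, 0]]
        frames = [base + np.array([d, d]) for d in map(np.asarray, disp)]
        traj = traj_of(frames)
        mat = dynamic_cross_correlation(traj, superpose=False).matrix
        assert mat[0, 1] == pytest.approx(1.0)

    def test_opposite_displacements_give_minus_one(self):
        base = np.array([[0, 0, 0], [10, 0, 0]], dtype=float)
        disp = [[0, 0, 0], [1, 1, 0], [-1, 0.5, 0], [0.5, -1, 0]]
        frames = [
            np.array([base[0] + d, base[1] - d]) for d in map(np.asarray, disp)
        ]
        traj = traj_of(frames)
        mat = dynamic_cross_correlation(traj, superpose=False).matrix
        assert mat[0, 1] == pytest.approx(-1.0)

    def test_imposed_correlation_recovered(self):
        spec = SyntheticSpec(
            seed=11, n_frames=5000, per_atom_sigma=[0.5] * 6,
            pair_correlations={(0, 1): 0.5, (2, 3): -0.8},
        )
        traj, truth = make_gaussian_trajectory(spec)
        mat = dynamic_cross_correlation(traj, superpose=False).matrix
        assert mat[0, 1] == pytest.approx(0.5, abs=0.05)
        assert mat[2, 3] == pytest.approx(-0.8, abs=0.05)
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat), 1.0)
        assert np.all(mat >= -1.0) and np.all(mat <= 1.0)

    def test_zero_variance_atom_zeroed_with_warning(self):
        spec = SyntheticSpec(seed=5, n_frames=100, per_atom_sigma=[0.5, 0.0, 0.5])
        traj, truth = make_gaussian_trajectory(spec)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            mat = dynamic_cross_correlation(traj, superpose=False).matrix
        assert mat[1, 1] == 1.0
        assert np.all(mat[1, [0, 2]] == 0.0) and np.all(mat[[0, 2], 1] == 0.0)

    def test_atom_permutation_permutes_matrix(self):
        spec = SyntheticSpec(
            seed=13, n_frames=400, per_atom_sigma=[0.3, 0.6, 0.9, 0.4],
            pair_correlations={(0, 2): 0.6},
        )
        traj, _ = make_gaussian_trajectory(spec)
        mat = dynamic_cross_correlation(traj, superpose=False).matrix
        perm = [2, 0, 3, 1]
        atoms = [traj.topology.atoms[i] for i in perm]
        ptraj = Trajectory(topology=Structure(atoms), frames=traj.frames[:, perm])
        pmat = dynamic_cross_correlation(ptraj, superpose=False).matrix
        np.testing.assert_allclose(pmat, mat[np.ix_(perm, perm)], atol=1e-12)


class TestContactFrequency:
    def two_group_traj(self, distances):
        """One residue per chain; per-frame separation along x."""
        top = Structure(
            chain_of_cas("A", [[0, 0, 0]]) + chain_of_cas("B", [[1, 0, 0]], start_resseq=2)
        )
        frames = [[[0, 0, 0], [d, 0, 0]] for d in distances]
        return Trajectory(topology=top, frames=np.asarray(frames, float))

    def groups(self, traj):
        return (
            resolve_selection(traj.topology, "chain A"),
            resolve_selection(traj.topology, "chain B"),
        )

    def test_always_within_cutoff(self):
        traj = self.two_group_traj([5.0] * 6)
        ga, gb = self.groups(traj)
        cmap = contact_frequency(traj, ga, gb)
        assert list(cmap.fractions.values()) == [1.0]

    def test_never_within_cutoff(self):
        traj = self.two_group_traj([50.0] * 6)
        ga, gb = self.groups(traj)
        assert list(contact_frequency(traj, ga, gb).fractions.values()) == [0.0]

    def test_partial_occupancy_counted_exactly(self):
        distances = [5, 5, 50, 50, 5, 50, 50, 5, 50, 50]
        traj = self.two_group_traj(distances)
        ga, gb = self.groups(traj)
        cmap = contact_frequency(traj, ga, gb)
        assert list(cmap.fractions.values()) == [0.4]
        assert cmap.pairs_above(0.3) == 1
        assert cmap.pairs_above(0.5) == 0

    def test_fraction_monotone_in_cutoff(self):
        distances = [2.0, 6.0, 9.0, 12.0, 20.0]
        traj = self.two_group_traj(distances)
        ga, gb = self.groups(traj)
        previous = 0.0
        for cutoff in (1.0, 3.0, 7.0, 10.0, 15.0, 25.0):
            frac = list(
                contact_frequency(traj, ga, gb, ContactParams(cutoff=cutoff)).fractions.values()
            )[0]
            assert frac >= previous
            previous = frac

    def test_residue_com_mode(self):
        traj = self.two_group_traj([5.0, 15.0])
        ga, gb = self.groups(traj)
        cmap = contact_frequency(
            traj, ga, gb, ContactParams(cutoff=10.0, distance_mode="residue-COM")
        )
        assert list(cmap.fractions.values()) == [0.5]


class TestIonOccupancy:
    def test_scripted_counts_match_exactly(self):
        spec = SyntheticSpec(seed=3, n_frames=10, ion_script={2: [0, 3, 5], 4: list(range(10))})
        traj, truth = make_ion_trajectory(spec)
        occ = ion_occupancy(
            traj,
            resolve_selection(traj.topology, "chain A"),
            resolve_selection(traj.topology, "ions"),
        )
        got = {key[1]: pct for key, pct in zip(occ.residues, occ.percent_frames)}
        assert got[2] == 30.0
        assert got[4] == 100.0
        assert got[1] == 0.0

    def test_distant_ion_never_counts(self):
        spec = SyntheticSpec(seed=3, n_frames=8, ion_script={})
        traj, _ = make_ion_trajectory(spec)
        occ = ion_occupancy(
            traj,
            resolve_selection(traj.topology, "chain A"),
            resolve_selection(traj.topology, "ions"),
        )
        assert np.all(occ.percent_frames == 0.0)

    def test_two_ions_alternating_give_full_occupancy(self):
        spec = SyntheticSpec(seed=3, n_frames=10, n_ions=2, ion_script={3: list(range(10))})
        traj, _ = make_ion_trajectory(spec)
        occ = ion_occupancy(
            traj,
            resolve_selection(traj.topology, "chain A"),
            resolve_selection(traj.topology, "ions"),
        )
        got = {key[1]: pct for key, pct in zip(occ.residues, occ.percent_frames)}
        assert got[3] == 100.0
        # both ions actually take part in the script (round-robin placement)
        n_prot = sum(1 for a in traj.topology.atoms if not a.is_ion)
        ion_rows = traj.frames[:, n_prot:]
        moved = [(ion_rows[:, k] != ion_rows[0, k]).any() for k in range(2)]
        assert all(moved)

    def test_matches_brute_force_distance_scan(self):
        spec = SyntheticSpec(
            seed=21, n_frames=20, n_ions=3,
            ion_script={1: [0, 1, 2], 3: [4, 9, 14, 19], 5: list(range(0, 20, 2))},
        )
        traj, truth = make_ion_trajectory(spec)
        res_sel = resolve_selection(traj.topology, "chain A")
        ion_sel = resolve_selection(traj.topology, "ions")
        occ = ion_occupancy(traj, res_sel, ion_sel, cutoff=1.0)

        # brute-force oracle: per-frame all-pairs scan
        top = traj.topology
        by_res = top.atoms_by_residue(res_sel.resolved_indices)
        masses = top.masses
        expected = {}
        for key, idx in by_res.items():
            idx = np.array(idx)
            hits = 0
            for f in range(traj.frame_count):
                com = (traj.frames[f, idx] * masses[idx, None]).sum(0) / masses[idx].sum()
                dmin = min(
                    np.linalg.norm(traj.frames[f, i] - com) for i in ion_sel.resolved_indices
                )
                hits += dmin <= 1.0
            expected[key] = 100.0 * hits / traj.frame_count
        for key, pct in zip(occ.residues, occ.percent_frames):
            assert pct == expected[key]

    def test_empty_ion_selection_rejected(self):
        traj = traj_of([[[0, 0, 0]], [[0, 0, 0]]])
        sel = sel_all(traj)
        from complexlens.structure_io import Selection, SelectionError

        with pytest.raises(SelectionError, match="ion"):
            ion_occupancy(traj, sel, Selection("ions", ()), cutoff=1.0)


class TestAngleSeries:
    def domains(self, top):
        return [
            DomainDefinition(c, resolve_selection(top, {"chains": [c]}))
            for c in ("R", "L", "B")
        ]

    @staticmethod
    def oscillating_trajectory(mean_deg, amplitude_deg, n_frames, seed=0):
        """SD1 chain swung around the ligand vertex: angle scripted per frame."""
        st = make_ternary_toy(SyntheticSpec(seed=seed, geometry_angle_deg=mean_deg))
        b_idx = [i for i, a in enumerate(st.atoms) if a.chain_id == "B"]
        frames = np.repeat(st.coords[None], n_frames, axis=0)
        phases = np.linspace(0, 2 * math.pi, n_frames, endpoint=False)
        for f, ph in enumerate(phases):
            delta = amplitude_deg * math.sin(ph)
            t = math.radians(delta)
            rot = np.array(
                [[math.cos(t), -math.sin(t), 0], [math.sin(t), math.cos(t), 0], [0, 0, 1]]
            )
            frames[f, b_idx] = st.coords[b_idx] @ rot.T
        return Trajectory(topology=st, frames=frames), mean_deg

    def test_static_trajectory_constant_series(self):
        st = make_ternary_toy(SyntheticSpec(seed=2, geometry_angle_deg=120.0))
        traj = Trajectory(topology=st, frames=np.repeat(st.coords[None], 5, axis=0))
        d1, lig, sd1 = self.domains(st)
        series = angle_timeseries(traj, d1, lig, sd1)
        np.testing.assert_allclose(series.angles_deg, 120.0, atol=1e-9)
        assert series.range_deg == pytest.approx(0.0, abs=1e-9)
        assert series.histogram_counts.sum() == 5

    def test_oscillation_mean_and_range(self):
        traj, mean_deg = self.oscillating_trajectory(100.0, 5.0, 360)
        d1, lig, sd1 = self.domains(traj.topology)
        series = angle_timeseries(traj, d1, lig, sd1)
        assert series.mean_deg == pytest.approx(100.0, abs=0.5)
        assert series.range_deg == pytest.approx(10.0, abs=0.5)

    def test_mean_difference_between_two_series(self):
        traj_a, _ = self.oscillating_trajectory(100.0, 5.0, 360, seed=1)
        traj_b, _ = self.oscillating_trajectory(112.6, 5.0, 360, seed=1)
        d1a, liga, sd1a = self.domains(traj_a.topology)
        series_a = angle_timeseries(traj_a, d1a, liga, sd1a)
        d1b, ligb, sd1b = self.domains(traj_b.topology)
        series_b = angle_timeseries(traj_b, d1b, ligb, sd1b)
        assert mean_angle_difference(series_a, series_b) == pytest.approx(12.6, abs=0.5)
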