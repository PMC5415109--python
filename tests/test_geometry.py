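from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lysodimer as ld
from lysodimer.geometry import minimum_image_displacement, pairwise_min_distance
from lysodimer.structures import AtomRecord

from _oracles import brute_min_distance, brute_water_count


def _atom(serial, name, resname, resid, pos, chain="A", element=None):
    return AtomRecord(
        serial=serial, atom_name=name, residue_name=resname, residue_id=resid,
        chain_id=chain, element=element or name[0], position=np.asarray(pos, float),
    )


def _static_traj(atoms, n_frames=1, box=None, frame_interval=5.0):
    coords = np.array([a.position for a in atoms])
    frames = np.repeat(coords[None], n_frames, axis=0)
    return ld.Trajectory(atom_table=atoms, frames=frames, box=box,
                         frame_interval=frame_interval)


class TestPairDistances:
    def test_fixed_atoms_constant_series(self):
        atoms = [_atom(1, "OD1", "ASP", 1, (0, 0, 0)), _atom(2, "OH", "TYR", 2, (3, 0, 0))]
        traj = _static_traj(atoms, n_frames=4)
        a = ld.Selection(indices=(0,))
        b = ld.Selection(indices=(1,))
        series = ld.pair_distance_series(traj, a, b)
        assert np.allclose(series.distance, 3.0)

    def test_guard_pair_minimum_over_cross_product(self):
        # R62 {NE, NH1, NH2} x D49 {OD1, OD2}: NH1-OD1 = 2.8 is the closest
        atoms = [
            _atom(1, "NE", "ARG", 62, (0, 0, 0)),
            _atom(2, "NH1", "ARG", 62, (0, 4, 0)),
            _atom(3, "NH2", "ARG", 62, (0, 8, 0)),
            _atom(4, "OD1", "ASP", 49, (2.8, 4, 0)),
            _atom(5, "OD2", "ASP", 49, (3.4, 8, 0)),
        ]
        traj = _static_traj(atoms)
        sel_r = ld.sidechain_contact_selection(traj, "A", 62, "N")
        sel_d = ld.sidechain_contact_selection(traj, "A", 49, "O")
        assert len(sel_r) == 3 and len(sel_d) == 2
        series = ld.pair_distance_series(traj, sel_r, sel_d)
        oracle = brute_min_distance(traj.frames[0][sel_r.as_array()],
                                    traj.frames[0][sel_d.as_array()])
        assert series.distance[0] == pytest.approx(2.8, abs=1e-9)
        assert series.distance[0] == pytest.approx(oracle, abs=1e-12)

    def test_minimum_image_across_box_edge(self):
        atoms = [_atom(1, "CA", "GLY", 1, (0.5, 0, 0)), _atom(2, "CA", "GLY", 2, (19.5, 0, 0))]
        traj = _static_traj(atoms, box=np.array([20.0, 20.0, 20.0]))
        series = ld.pair_distance_series(
            traj, ld.Selection(indices=(0,)), ld.Selection(indices=(1,))
        )
        assert series.distance[0] == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_matches_brute_force_and_minimum_image_bound(self, seed):
        rng = np.random.default_rng(seed)
        box = np.array([15.0, 18.0, 12.0])
        A = rng.uniform(0, 30, (4, 3))
        B = rng.uniform(0, 30, (3, 3))
        assert pairwise_min_distance(A, B, box) == pytest.approx(
            brute_min_distance(A, B, box), abs=1e-9
        )
        # minimum image can only shorten a displacement
        d = A[0] - B[0]
        assert np.linalg.norm(minimum_image_displacement(d, box)) <= np.linalg.norm(d) + 1e-12

    def test_empty_group_rejected(self):
        atoms = [_atom(1, "CA", "GLY", 1, (0, 0, 0))]
        traj = _static_traj(atoms)
        with pytest.raises(ld.EmptySelectionError):
            ld.pair_distance_series(traj, ld.Selection(indices=()), ld.Selection(indices=(0,)))


class TestHydration:
    def _watery_traj(self, n_frames=1):
        atoms = [_atom(1, "SG", "CYS", 65, (0, 0, 0), element="S")]
        positions = [(2.5, 0, 0), (0, 2.5, 0), (0, 0, 2.5), (5.5, 0, 0), (0, 5.5, 0)]
        for i, p in enumerate(positions):
            atoms.append(_atom(2 + i, "O", "HOH", 200 + i, p, chain="W", element="O"))
        return _static_traj(atoms, n_frames=n_frames)

    def test_crafted_counts_at_two_radii(self):
        traj = self._watery_traj()
        center = ld.select(traj, ("atom", "A", 65, "SG"))
        assert ld.count_pocket_waters(traj, center, 3.0) == (3.0, 0.0)
        assert ld.count_pocket_waters(traj, center, 6.0) == (5.0, 0.0)

    def test_counts_match_brute_force_every_frame(self, hl):
        spec = ld.MockTrajectorySpec(reference=hl, n_frames=30, water_target=4.0, seed=11)
        traj, _ = ld.generate_mock_trajectory(spec)
        center = ld.select(traj, ("atom", "A", 65, "SG"))
        waters = ld.select(traj, "waters").as_array()
        for radius in (3.0, 6.0):
            mean, _ = ld.count_pocket_waters(traj, center, radius)
            oracle = np.mean([
                brute_water_count(traj.frames[f], waters, center.indices[0], radius)
                for f in range(traj.n_frames)
            ])
            assert mean == pytest.approx(oracle, abs=1e-12)

    def test_dry_system_warns_and_returns_zero(self, hl):
        traj = _static_traj(list(hl.atoms))
        center = ld.select(traj, ("atom", "A", 65, "SG"))
        with pytest.warns(UserWarning, match="no water"):
            assert ld.count_pocket_waters(traj, center, 6.0) == (0.0, 0.0)

    def test_scan_sorts_radii_and_counts_monotone(self):
        traj = self._watery_traj(n_frames=3)
        center = ld.select(traj, ("atom", "A", 65, "SG"))
        profile = ld.hydration_shell_scan(traj, center, radii=(6.0, 3.0, 5.0, 4.0))
        assert np.array_equal(profile.radii, [3.0, 4.0, 5.0, 6.0])
        assert np.all(np.diff(profile.mean_count) >= 0)

    def test_poisson_pocket_recovered(self, hl):
        target = 6.0
        spec = ld.MockTrajectorySpec(reference=hl, n_frames=400, water_target=target, seed=5)
        traj, truth = ld.generate_mock_trajectory(spec)
        center = ld.select(traj, ("atom", *tuple(truth["water"]["center"])))
        profile = ld.hydration_shell_scan(traj, center, radii=(3.0, 4.0, 5.0, 6.0))
        mean6, sd6 = profile.mean_count[-1], profile.sd_count[-1]
        assert abs(mean6 - target) <= 3 * sd6 / np.sqrt(traj.n_frames) + 1e-9


class TestRingCentroids:
    def test_hexagon_centroid_separation(self):
        theta = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        ring = 1.4 * np.column_stack([np.cos(theta), np.sin(theta), np.zeros(6)])
        names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        atoms = [_atom(i + 1, n, "TYR", 1, ring[i]) for i, n in enumerate(names)]
        atoms += [_atom(7 + i, n, "TYR", 2, ring[i] + [0, 0, 5.0]) for i, n in enumerate(names)]
        traj = _static_traj(atoms)
        series = ld.ring_centroid_distance_series(traj, ("A", 1), ("A", 2))
        assert series.distance[0] == pytest.approx(5.0, abs=1e-9)

    def test_his_ring_centroid_is_plain_mean(self, rng):
        names = ("CG", "ND1", "CD2", "CE1", "NE2")
        pos = rng.normal(size=(5, 3))
        atoms = [_atom(i + 1, n, "HIS", 1, pos[i]) for i, n in enumerate(names)]
        atoms += [_atom(6 + i, n, "HIS", 2, pos[i] + 2.0) for i, n in enumerate(names)]
        traj = _static_traj(atoms)
        series = ld.ring_centroid_distance_series(traj, ("A", 1), ("A", 2))
        assert series.distance[0] == pytest.approx(np.linalg.norm([2.0] * 3), abs=1e-9)

    def test_identical_residue_zero(self):
        theta = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        ring = 1.4 * np.column_stack([np.cos(theta), np.sin(theta), np.zeros(6)])
        names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        atoms = [_atom(i + 1, n, "PHE", 1, ring[i]) for i, n in enumerate(names)]
        traj = _static_traj(atoms)
        series = ld.ring_centroid_distance_series(traj, ("A", 1), ("A", 1))
        assert series.distance[0] == 0.0

    def test_missing_ring_atom_named(self):
        atoms = [_atom(1, "CG", "HIS", 1, (0, 0, 0))]
        traj = _static_traj(atoms)
        with pytest.raises(ld.EmptySelectionError, match="ND1"):
            ld.ring_centroid_distance_series(traj, ("A", 1), ("A", 1))


class TestCenterOfMass:
    def test_two_equal_mass_atoms(self):
        atoms = [_atom(1, "CA", "GLY", 1, (0, 0, 0), chain="A"),
                 _atom(2, "CA", "GLY", 1, (8, 0, 0), chain="B")]
        series = ld.com_separation_series(_static_traj(atoms), "A", "B")
        assert series.distance[0] == pytest.approx(8.0, abs=1e-12)

    def test_mass_weighting_matches_hand_calculation(self):
        # chain A: C at 0 and O at 1 along x -> COM at 16/28.01 = 0.5712
        atoms = [
            _atom(1, "C", "GLY", 1, (0, 0, 0), chain="A", element="C"),
            _atom(2, "O", "GLY", 1, (1, 0, 0), chain="A", element="O"),
            _atom(3, "CA", "GLY", 1, (10, 0, 0), chain="B", element="C"),
        ]
        series = ld.com_separation_series(_static_traj(atoms), "A", "B")
        com_a = 15.999 / (12.011 + 15.999)
        assert series.distance[0] == pytest.approx(10 - com_a, abs=1e-9)

    def test_joint_translation_leaves_series_constant(self, rng):
        atoms = [_atom(1, "CA", "GLY", 1, (0, 0, 0), chain="A"),
                 _atom(2, "CA", "GLY", 1, (6, 0, 0), chain="B")]
        coords = np.array([a.position for a in atoms])
        shifts = rng.normal(size=(5, 1, 3))
        frames = coords[None] + shifts  # both chains move together
        traj = ld.Trajectory(atom_table=atoms, frames=frames, frame_interval=5.0)
        series = ld.com_separation_series(traj, "A", "B")
        assert np.allclose(series.distance, 6.0, atol=1e-9)

    def test_unknown_element_rejected(self):
        atoms = [_atom(1, "XX", "UNK", 1, (0, 0, 0), chain="A", element="XX"),
                 _atom(2, "CA", "GLY", 1, (5, 0, 0), chain="B")]
        from lysodimer.geometry import UnknownElementError
        with pytest.raises(UnknownElementError):
            ld.com_separation_series(_static_traj(atoms), "A", "B")


class TestDimerStability:
    def _series(self, values, dt_ns=1.0):
        values = np.asarray(values, float)
        return ld.DistanceSeries(time=np.arange(len(values)) * dt_ns, distance=values)

    def test_constant_series_is_stable(self):
        report = ld.classify_dimer_stability(self._series([30.0] * 50), (0, 10))
        assert report.verdict == "stable"
        assert report.dissociation_time is None

    def test_sustained_step_dissociates_at_step_time(self):
        d = [30.0] * 20 + [42.0] * 30
        report = ld.classify_dimer_stability(self._series(d), (0, 20))
        assert report.verdict == "dissociated"
        assert report.dissociation_time == pytest.approx(20.0)

    def test_transient_spike_is_not_dissociation(self):
        d = [30.0] * 20 + [41.0] + [30.0] * 29
        report = ld.classify_dimer_stability(self._series(d), (0, 20))
        assert report.verdict == "stable"

    def test_verdict_invariant_to_time_rescaling(self):
        d = [30.0] * 20 + [45.0] * 30
        r1 = ld.classify_dimer_stability(self._series(d, dt_ns=1.0), (0, 20))
        r2 = ld.classify_dimer_stability(self._series(d, dt_ns=0.1), (0, 20))
        assert r1.verdict == r2.verdict == "dissociated"
        assert r2.dissociation_time == pytest.approx(r1.dissociation_time * 0.1)

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            ld.classify_dimer_stability(self._series([30.0] * 10), (5, 5))


class TestOpeningHistogram:
    def test_degenerate_samples(self):
        summary = ld.opening_histogram(np.array([10.0, 10.0, 10.0]))
        assert summary.mean == 10.0 and summary.sd == 0.0
        assert len(summary.counts) == 1 and summary.counts[0] == 3

    def test_gaussian_moments_recovered(self):
        rng = np.random.default_rng(99)
        draws = rng.normal(18.3, 1.0, 10_000)
        summary = ld.opening_histogram(draws)
        assert summary.mean == pytest.approx(18.3, abs=0.05)
        assert summary.sd == pytest.approx(1.0, abs=0.05)
        assert summary.gaussian_fit_ok
        assert int(np.sum(summary.counts)) == summary.n

    def test_bimodal_mixture_flagged(self):
        rng = np.random.default_rng(7)
        draws = np.concatenate([rng.normal(14, 0.1, 5000), rng.normal(23, 0.1, 5000)])
        summary = ld.opening_histogram(draws)
        assert not summary.gaussian_fit_ok
        assert "poor Gaussian fit" in summary.note

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ld.opening_histogram(np.array([1.0]))


class TestClassifyUnfolded:
    @pytest.mark.parametrize(
        "mean,expected",
        [
            (14.0, "folded"),  # wild type at room temperature
            (18.3, "folded"),  # variant at room temperature, below threshold
            (23.5, "unfolded"),  # variant at high temperature
            (20.0, "folded"),  # boundary: strictly greater than required
        ],
    )
    def test_threshold_rule(self, mean, expected):
        assert ld.classify_unfolded(mean) == expected
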