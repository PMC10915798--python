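"""Contact series, survival probabilities and ionic bridges."""

import numpy as np
import pytest

from ionbridge.core_model import SelectionGroup, Trajectory, minimum_image_distance
from ionbridge.kinetics import (
    ContactSeries,
    bridge_anchor_residues,
    bridge_lifetimes,
    build_contact_series,
    detect_bridges,
    survival_probability,
)

BOX = 10.0


def _traj(frames, dt=100.0):
    frames = np.asarray(frames, dtype=float)
    return Trajectory(times=np.arange(len(frames)) * dt, coordinates=frames)


def _series(occ, dt=100.0):
    occ = np.atleast_2d(np.asarray(occ, dtype=bool))
    return ContactSeries(
        entities=[(f"ion{i}", "prot") for i in range(occ.shape[0])],
        occupancy=occ,
        frame_spacing=dt,
    )


class TestBuildContactSeries:
    def _protein(self):
        return SelectionGroup("prot", frozenset({0}), "protein_A")

    def test_permanent_contact(self):
        frames = [[[1.0, 1.0, 1.0], [1.3, 1.0, 1.0]]] * 4
        series = build_contact_series(_traj(frames), {"a": [1]}, self._protein(), BOX)
        assert series.occupancy.all()

    def test_never_in_contact(self):
        frames = [[[1.0, 1.0, 1.0], [1.5, 1.0, 1.0]]] * 4
        series = build_contact_series(_traj(frames), {"a": [1]}, self._protein(), BOX)
        assert not series.occupancy.any()

    def test_three_ion_brute_force(self):
        rng = np.random.default_rng(2)
        frames = rng.uniform(0, 2, size=(6, 5, 3))  # atoms 0-1 protein, 2-4 ions
        protein = SelectionGroup("prot", frozenset({0, 1}), "protein_A")
        ions = {"i2": [2], "i3": [3], "i4": [4]}
        series = build_contact_series(_traj(frames), ions, protein, BOX, cutoff=0.4)
        for c, ion_atom in enumerate([2, 3, 4]):
            for f in range(6):
                oracle = any(
                    minimum_image_distance(frames[f, ion_atom], frames[f, p], BOX) <= 0.4
                    for p in (0, 1)
                )
                assert series.occupancy[c, f] == oracle

    def test_ion_residue_granularity(self):
        frames = [[[1.0, 1.0, 1.0], [5.0, 5.0, 5.0], [1.2, 1.0, 1.0]]]
        protein = SelectionGroup("prot", frozenset({0, 1}), "protein_A")
        series = build_contact_series(
            _traj(frames),
            {"ion": [2]},
            protein,
            BOX,
            granularity="ion-residue",
            residue_atoms={1: [0], 2: [1]},
        )
        assert series.occupancy[0, 0]  # residue 1 in contact
        assert not series.occupancy[1, 0]  # residue 2 far away

    def test_empty_ions_rejected(self):
        with pytest.raises(ValueError, match="ion"):
            build_contact_series(_traj(np.zeros((1, 2, 3))), {}, self._protein(), BOX)


class TestSurvivalProbability:
    def test_s0_is_one(self):
        rng = np.random.default_rng(1)
        series = _series(rng.random((5, 40)) < 0.5)
        curve = survival_probability(series, max_lag_ps=1000.0)
        assert curve.S[0] == 1.0

    def test_permanent_channel(self):
        series = _series(np.ones(30, dtype=bool))
        curve = survival_probability(series, max_lag_ps=1000.0)
        np.testing.assert_allclose(curve.S, 1.0)

    def test_nonincreasing(self):
        rng = np.random.default_rng(7)
        series = _series(rng.random((20, 60)) < 0.6)
        curve = survival_probability(series, max_lag_ps=3000.0)
        finite = curve.S[np.isfinite(curve.S)]
        assert all(a >= b - 1e-12 for a, b in zip(finite, finite[1:]))

    def test_known_hand_case(self):
        # occupied frames 0,1,2,4; at lag 1 the valid origins are frames
        # 0,1,2 (frame 4 has no room) and only 0 and 1 survive
        series = _series([True, True, True, False, True])
        curve = survival_probability(series, max_lag_ps=100.0)
        assert curve.S[1] == pytest.approx(2.0 / 3.0)

    def test_gap_tolerance_upper_bounds_strict(self):
        rng = np.random.default_rng(3)
        series = _series(rng.random((10, 50)) < 0.5)
        strict = survival_probability(series, 2000.0, gap_tolerance=0)
        lenient = survival_probability(series, 2000.0, gap_tolerance=10**6)
        assert np.all(lenient.S >= strict.S - 1e-12)

    def test_gap_tolerance_bridges_single_gap(self):
        series = _series([True, False, True])
        strict = survival_probability(series, 200.0, gap_tolerance=0)
        lenient = survival_probability(series, 200.0, gap_tolerance=1)
        assert strict.S[2] == 0.0
        assert lenient.S[2] == 1.0  # one origin valid at lag 2; gap forgiven

    def test_no_occupied_origins(self):
        series = _series(np.zeros(10, dtype=bool))
        with pytest.raises(ValueError, match="occupied"):
            survival_probability(series, 500.0)

    def test_max_lag_bounds(self):
        series = _series(np.ones(5, dtype=bool))
        with pytest.raises(ValueError, match="lag"):
            survival_probability(series, 1e6)


class TestDetectBridges:
    def _proteins(self):
        a = SelectionGroup("A", frozenset({0}), "protein_A")
        b = SelectionGroup("B", frozenset({1}), "protein_B")
        return a, b

    def test_bridge_present(self):
        a, b = self._proteins()
        frame = np.array([[1.0, 1.0, 1.0], [1.6, 1.0, 1.0], [1.3, 1.0, 1.0]])
        assert detect_bridges(frame, {"ion": [2]}, a, b, BOX) == {"ion"}

    def test_one_sided_contact_is_no_bridge(self):
        a, b = self._proteins()
        frame = np.array([[1.0, 1.0, 1.0], [1.8, 1.0, 1.0], [1.3, 1.0, 1.0]])
        # 0.3 from A but 0.5 from B
        assert detect_bridges(frame, {"ion": [2]}, a, b, BOX) == set()

    def test_symmetry_and_brute_force(self):
        rng = np.random.default_rng(13)
        wall_a = rng.uniform([0.5, 0, 0], [0.7, 2, 2], size=(5, 3))
        wall_b = rng.uniform([1.1, 0, 0], [1.3, 2, 2], size=(5, 3))
        ions = rng.uniform([0.4, 0, 0], [1.4, 2, 2], size=(10, 3))
        frame = np.vstack([wall_a, wall_b, ions])
        a = SelectionGroup("A", frozenset(range(5)), "protein_A")
        b = SelectionGroup("B", frozenset(range(5, 10)), "protein_B")
        molecules = {f"ion{k}": [10 + k] for k in range(10)}
        found = detect_bridges(frame, molecules, a, b, BOX)
        oracle = set()
        for k in range(10):
            da = min(minimum_image_distance(frame[10 + k], frame[i], BOX) for i in range(5))
            db = min(minimum_image_distance(frame[10 + k], frame[j], BOX) for j in range(5, 10))
            if da < 0.4 and db < 0.4:
                oracle.add(f"ion{k}")
        assert found == oracle
        assert detect_bridges(frame, molecules, b, a, BOX) == found

    def test_overlapping_proteins_rejected(self):
        a = SelectionGroup("A", frozenset({0}), "protein_A")
        b = SelectionGroup("B", frozenset({0}), "protein_B")
        with pytest.raises(ValueError, match="disjoint"):
            detect_bridges(np.zeros((2, 3)), {"i": [1]}, a, b, BOX)


def _bridge_setup(ion_track):
    """Two 1-bead proteins 0.7 nm apart; the ion follows ``ion_track``."""
    pos_a, pos_b = np.array([4.65, 5.0, 5.0]), np.array([5.35, 5.0, 5.0])
    frames = []
    for spot in ion_track:
        frames.append([pos_a, pos_b, np.asarray(spot, dtype=float)])
    traj = _traj(np.asarray(frames), dt=100.0)  # 0.1 ns spacing
    a = SelectionGroup("A", frozenset({0}), "protein_A")
    b = SelectionGroup("B", frozenset({1}), "protein_B")
    residue_of_atom = {0: 1, 1: 2}
    return traj, a, b, residue_of_atom


MID = [5.0, 5.0, 5.0]
FAR = [1.0, 1.0, 1.0]


class TestBridgeLifetimes:
    def test_ten_frame_bridge_duration(self):
        traj, a, b, roa = _bridge_setup([MID] * 10)
        records, _ = bridge_lifetimes(
            traj, {"ion": [2]}, a, b, roa, BOX, max_lag_ps=400.0
        )
        assert len(records) == 1
        assert records[0].duration_ps(traj.frame_spacing) == pytest.approx(1000.0)  # 1 ns

    def test_never_bridging(self):
        traj, a, b, roa = _bridge_setup([FAR] * 6)
        records, curve = bridge_lifetimes(
            traj, {"ion": [2]}, a, b, roa, BOX, max_lag_ps=200.0
        )
        assert records == []
        assert curve is None

    def test_no_record_for_absent_ion_with_other_bridging(self):
        traj, a, b, roa = _bridge_setup([MID] * 6)
        # add a second, never-bridging ion
        coords = np.concatenate(
            [traj.coordinates, np.tile(np.array(FAR), (6, 1, 1))], axis=1
        )
        traj2 = _traj(coords, dt=100.0)
        records, _ = bridge_lifetimes(
            traj2, {"near": [2], "far": [3]}, a, b, roa, BOX, max_lag_ps=200.0
        )
        assert {r.ion_id for r in records} == {"near"}

    def test_gap_tolerance_merges_records(self):
        track = [MID] * 3 + [FAR] + [MID] * 3
        traj, a, b, roa = _bridge_setup(track)
        strict, _ = bridge_lifetimes(traj, {"ion": [2]}, a, b, roa, BOX, max_lag_ps=300.0)
        merged, _ = bridge_lifetimes(
            traj, {"ion": [2]}, a, b, roa, BOX, gap_tolerance=1, max_lag_ps=300.0
        )
        assert len(strict) == 2
        assert len(merged) == 1
        assert merged[0].n_frames == 7

    def test_record_distance_invariant(self):
        traj, a, b, roa = _bridge_setup([MID] * 5)
        records, _ = bridge_lifetimes(traj, {"ion": [2]}, a, b, roa, BOX, max_lag_ps=200.0)
        record = records[0]
        assert np.all(record.d_min_A < 0.4)
        assert np.all(record.d_min_B < 0.4)


class TestBridgeAnchors:
    def _two_residue_setup(self):
        # protein A: ARG (res 1) and LYS (res 2); protein B: LYS (res 3)
        frames = np.array(
            [
                [
                    [4.7, 5.0, 5.0],  # atom 0, res 1 (ARG)
                    [4.7, 6.0, 5.0],  # atom 1, res 2 (LYS) - farther from ion
                    [5.3, 5.0, 5.0],  # atom 2, res 3 on B
                    [5.0, 5.0, 5.0],  # atom 3, ion
                ]
            ]
        )
        traj = _traj(frames)
        a = SelectionGroup("A", frozenset({0, 1}), "protein_A")
        b = SelectionGroup("B", frozenset({2}), "protein_B")
        roa = {0: 1, 1: 2, 2: 3}
        return traj, a, b, roa

    def test_nearest_residues(self):
        traj, a, b, roa = self._two_residue_setup()
        records, _ = bridge_lifetimes(traj, {"ion": [3]}, a, b, roa, BOX, max_lag_ps=0.0)
        assert bridge_anchor_residues(records[0], 0) == (1, 3)

    def test_tie_break_lower_residue(self):
        frames = np.array(
            [
                [
                    [4.7, 5.0, 5.0],  # res 2 listed first in atom order
                    [4.7, 5.0, 5.0],  # res 1 at identical position
                    [5.3, 5.0, 5.0],  # res 3 on B
                    [5.0, 5.0, 5.0],  # ion
                ]
            ]
        )
        traj = _traj(frames)
        a = SelectionGroup("A", frozenset({0, 1}), "protein_A")
        b = SelectionGroup("B", frozenset({2}), "protein_B")
        roa = {0: 2, 1: 1, 2: 3}
        records, _ = bridge_lifetimes(traj, {"ion": [3]}, a, b, roa, BOX, max_lag_ps=0.0)
        assert bridge_anchor_residues(records[0], 0) == (1, 3)

    def test_frame_outside_record(self):
        traj, a, b, roa = self._two_residue_setup()
        records, _ = bridge_lifetimes(traj, {"ion": [3]}, a, b, roa, BOX, max_lag_ps=0.0)
        with pytest.raises(ValueError, match="outside"):
            bridge_anchor_residues(records[0], 5)

    def test_random_frame_vs_brute_force(self):
        rng = np.random.default_rng(21)
        n_a, n_b = 6, 6
        coords_a = rng.uniform(4.4, 4.9, size=(n_a, 3))
        coords_b = rng.uniform(5.1, 5.6, size=(n_b, 3))
        ion = np.array([[5.0, 5.0, 5.0]])
        frames = np.concatenate([coords_a, coords_b, ion])[None, :, :]
        traj = _traj(frames)
        a = SelectionGroup("A", frozenset(range(n_a)), "protein_A")
        b = SelectionGroup("B", frozenset(range(n_a, n_a + n_b)), "protein_B")
        roa = {i: i + 1 for i in range(n_a + n_b)}  # one residue per atom
        records, _ = bridge_lifetimes(
            traj, {"ion": [n_a + n_b]}, a, b, roa, BOX, cutoff=2.0, max_lag_ps=0.0
        )
        res_a, res_b = bridge_anchor_residues(records[0], 0)
        oracle_a = min(
            range(n_a),
            key=lambda i: minimum_image_distance(frames[0, n_a + n_b], frames[0, i], BOX),
        )
        oracle_b = min(
            range(n_a, n_a + n_b),
            key=lambda j: minimum_image_distance(frames[0, n_a + n_b], frames[0, j], BOX),
        )
        assert res_a == oracle_a + 1
        assert res_b == oracle_b + 1


class TestTelegraphRecovery:
    def test_exponential_survival(self, telegraph_survival):
        _, curve = telegraph_survival
        # memoryless off-process: -d ln S / dt == k_off
        s = curve.at(500.0)
        assert s == pytest.approx(np.exp(-1.0), abs=0.01)

    def test_rate_recovery(self, telegraph_survival):
        _, curve = telegraph_survival
        mask = (curve.lags > 0) & np.isfinite(curve.S) & (curve.S > 0)
        slope = np.polyfit(curve.lags[mask] / 1000.0, np.log(curve.S[mask]), 1)[0]
        assert -slope == pytest.approx(2.0, rel=0.05)
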