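"""Surface rdfs, contact counting and the adsorption index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionbridge.adsorption import (
    average_contacts,
    bai_distribution,
    compute_bai,
    count_contacts,
    cumulative_count,
    surface_rdf,
)
from ionbridge.core_model import SelectionGroup, Trajectory, minimum_image_distance
from ionbridge.structure_metrics import SasaResult
from ionbridge.adsorption import species_average_bai

BOX = 12.0


def _traj(frames):
    frames = np.asarray(frames, dtype=float)
    return Trajectory(times=np.arange(len(frames), dtype=float), coordinates=frames)


def _group(name, ids, role="buffer_state"):
    return SelectionGroup(name, frozenset(ids), role)


class TestSurfaceRdf:
    def test_single_pair_density(self):
        # target 0.35 nm from the single reference atom -> bin [0.3, 0.4)
        coords = [[[6.0, 6.0, 6.0], [6.35, 6.0, 6.0]]]
        profile = surface_rdf(
            _traj(coords),
            _group("ref", {0}, "protein_A"),
            _group("tgt", {1}),
            BOX,
            bin_width=0.1,
            r_max=1.0,
            skip=0,
        )
        expected = np.zeros(10)
        expected[3] = 10.0  # 1 count / (1 frame * 0.1 nm)
        np.testing.assert_allclose(profile.density, expected)

    def test_conservation(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, BOX, size=(4, 6, 3))
        profile = surface_rdf(
            _traj(coords),
            _group("ref", {0}, "protein_A"),
            _group("tgt", {1, 2, 3, 4, 5}),
            BOX,
            bin_width=0.05,
            r_max=BOX,  # generous range catches every target atom
            skip=0,
        )
        assert profile.total_count() == pytest.approx(5.0)

    def test_binned_by_nearer_reference(self):
        # target at 0.25 from the nearer of two reference atoms
        coords = [[[6.0, 6.0, 6.0], [7.0, 6.0, 6.0], [6.75, 6.0, 6.0]]]
        profile = surface_rdf(
            _traj(coords),
            _group("ref", {0, 1}, "protein_A"),
            _group("tgt", {2}),
            BOX,
            bin_width=0.1,
            r_max=1.0,
            skip=0,
        )
        occupied = np.flatnonzero(profile.density)
        assert list(occupied) == [2]  # bin [0.2, 0.3), not [0.7, 0.8)

    def test_skip_bounds(self):
        coords = np.zeros((2, 2, 3))
        coords[:, 1, 0] = 1.0
        with pytest.raises(ValueError, match="skip"):
            surface_rdf(
                _traj(coords),
                _group("ref", {0}, "protein_A"),
                _group("tgt", {1}),
                BOX,
                skip=2,
            )


class TestCumulativeCount:
    @pytest.fixture()
    def toy_profile(self):
        rng = np.random.default_rng(5)
        self_coords = rng.uniform(0, BOX, size=(3, 8, 3))
        ref = _group("ref", {0}, "protein_A")
        tgt = _group("tgt", set(range(1, 8)))
        profile = surface_rdf(
            _traj(self_coords), ref, tgt, BOX, bin_width=0.1, r_max=BOX, skip=0
        )
        return profile, self_coords

    def test_zero_at_origin(self, toy_profile):
        profile, _ = toy_profile
        assert cumulative_count(profile, 0.0) == 0.0

    def test_total_at_r_max(self, toy_profile):
        profile, _ = toy_profile
        assert cumulative_count(profile, profile.r_max) == pytest.approx(7.0)

    def test_against_direct_counting(self, toy_profile):
        profile, coords = toy_profile
        r = 4.0
        # oracle: per-frame count of targets whose distance to the single
        # reference atom is inside [0, r), averaged over frames
        per_frame = []
        for frame in coords:
            d = [minimum_image_distance(frame[0], frame[j], BOX) for j in range(1, 8)]
            per_frame.append(sum(1 for x in d if x < r))
        assert cumulative_count(profile, r) == pytest.approx(np.mean(per_frame))

    def test_out_of_range(self, toy_profile):
        profile, _ = toy_profile
        with pytest.raises(ValueError, match="outside"):
            cumulative_count(profile, profile.r_max + 1.0)

    def test_nondecreasing(self, toy_profile):
        profile, _ = toy_profile
        values = [cumulative_count(profile, r) for r in np.linspace(0, profile.r_max, 40)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))


class TestCountContacts:
    def test_pair_inside_cutoff(self):
        frame = np.array([[1.0, 1.0, 1.0], [1.39, 1.0, 1.0]])
        counts = count_contacts(frame, {1: np.array([0])}, np.array([1]), BOX)
        assert counts == {1: 1}

    def test_pair_outside_cutoff(self):
        frame = np.array([[1.0, 1.0, 1.0], [1.41, 1.0, 1.0]])
        counts = count_contacts(frame, {1: np.array([0])}, np.array([1]), BOX)
        assert counts == {1: 0}

    def test_against_double_loop(self):
        rng = np.random.default_rng(9)
        protein = rng.uniform(0, 3, size=(20, 3))
        buffer_atoms = rng.uniform(0, 3, size=(15, 3))
        frame = np.vstack([protein, buffer_atoms])
        residue_atoms = {1: np.arange(10), 2: np.arange(10, 20)}
        counts = count_contacts(frame, residue_atoms, np.arange(20, 35), box_length=6.0)
        oracle = {1: 0, 2: 0}
        for res, atoms in residue_atoms.items():
            for i in atoms:
                for j in range(20, 35):
                    if minimum_image_distance(frame[i], frame[j], 6.0) <= 0.4:
                        oracle[res] += 1
        assert counts == oracle


class TestAverageContacts:
    def test_constant(self):
        counts = np.full((10, 4), 3)
        np.testing.assert_allclose(average_contacts([counts]), 3.0)

    def test_two_trajectories(self):
        a = np.full((5, 1), 2)
        b = np.full((9, 1), 4)
        assert average_contacts([a, b])[0] == pytest.approx(3.0)

    def test_ragged_against_hand_computation(self):
        a = np.array([[1, 0], [3, 2], [5, 4]])  # means (3, 2)
        b = np.array([[0, 8]])  # means (0, 8)
        np.testing.assert_allclose(average_contacts([a, b]), [1.5, 5.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_contacts([])


def _bai_table(n_avg, states=None):
    n = len(n_avg)
    return pd.DataFrame(
        {
            "residue_index": np.arange(1, n + 1),
            "residue_name": ["LYS"] * n,
            "state": states if states is not None else ["S"] * n,
            "n_avg": n_avg,
        }
    )


class TestComputeBai:
    def test_maximum_is_zero(self):
        result = compute_bai(_bai_table([5.0, 2.0]))
        assert result.table["bai"].iloc[0] == 0.0

    def test_derived_values(self):
        result = compute_bai(_bai_table([12.0, 6.0, 3.0]))
        np.testing.assert_allclose(
            result.table["bai"], [0.0, np.log(2.0), np.log(4.0)], atol=1e-9
        )
        assert result.n_max == 12.0

    def test_zero_contact_sentinel(self):
        result = compute_bai(_bai_table([4.0, 0.0]))
        assert np.isinf(result.table["bai"].iloc[1])
        assert bool(result.zero_contact_flags.iloc[1])
        assert len(result.finite()) == 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            compute_bai(_bai_table([0.0, 0.0]))

    def test_n_max_shared_across_states(self):
        table = _bai_table([10.0, 5.0], states=["minus1", "minus2"])
        result = compute_bai(table)
        # the weaker state is referenced to the global maximum
        assert result.table["bai"].iloc[1] == pytest.approx(np.log(2.0))

    @settings(deadline=None, max_examples=30)
    @given(scale=st.floats(0.1, 100.0))
    def test_scale_invariance(self, scale):
        base = compute_bai(_bai_table([8.0, 4.0, 1.0]))
        scaled = compute_bai(_bai_table([8.0 * scale, 4.0 * scale, 1.0 * scale]))
        np.testing.assert_allclose(scaled.table["bai"], base.table["bai"], atol=1e-9)


def _sasa(areas):
    return SasaResult(
        per_residue_area=dict(areas),
        residue_names={k: "LYS" for k in areas},
        probe_radius=0.14,
        n_points=960,
    )


class TestSpeciesAverageBai:
    def test_uniform_species(self):
        table = pd.DataFrame(
            {
                "residue_index": [1, 2],
                "residue_name": ["LYS", "LYS"],
                "state": ["S", "S"],
                "n_avg": [1.0, 1.0],
            }
        )
        bai = compute_bai(table)
        bai.table["bai"] = [2.0, 2.0]  # hand-set indices for the averaging rule
        out = species_average_bai(bai, _sasa({1: 0.5, 2: 0.7}))
        assert out["mean_bai"].iloc[0] == pytest.approx(2.0)

    def test_buried_residue_excluded(self):
        table = pd.DataFrame(
            {
                "residue_index": [1, 2],
                "residue_name": ["LYS", "LYS"],
                "state": ["S", "S"],
                "n_avg": [4.0, 2.0],
            }
        )
        bai = compute_bai(table)
        out = species_average_bai(bai, _sasa({1: 0.5, 2: 0.0}))
        assert out["mean_bai"].iloc[0] == pytest.approx(0.0)  # only residue 1 counts

    def test_six_residue_hand_average(self):
        table = pd.DataFrame(
            {
                "residue_index": [1, 2, 3, 4, 5, 6],
                "residue_name": ["LYS", "LYS", "ARG", "ARG", "ASP", "ASP"],
                "state": ["S"] * 6,
                "n_avg": [10.0, 5.0, 10.0, 2.0, 1.0, 0.0],
            }
        )
        bai = compute_bai(table)
        sasa = _sasa({1: 1.0, 2: 1.0, 3: 1.0, 4: 0.0, 5: 1.0, 6: 1.0})
        out = species_average_bai(bai, sasa).set_index("residue_name")["mean_bai"]
        assert out["LYS"] == pytest.approx((0.0 + np.log(2.0)) / 2)
        assert out["ARG"] == pytest.approx(0.0)  # residue 4 buried
        assert out["ASP"] == pytest.approx(np.log(10.0))  # residue 6 infinite

    def test_missing_sasa_rejected(self):
        bai = compute_bai(_bai_table([1.0, 2.0]))
        with pytest.raises(ValueError, match="SASA"):
            species_average_bai(bai, _sasa({1: 0.5}))


class TestBaiDistribution:
    def test_single_value(self):
        bai = compute_bai(_bai_table([3.0]))
        edges, p = bai_distribution(bai, bin_width=0.5)
        assert np.sum(p > 0) == 1
        assert p.max() == pytest.approx(1.0 / 0.5)

    def test_normalization(self):
        rng = np.random.default_rng(4)
        bai = compute_bai(_bai_table(rng.uniform(0.5, 20, size=100)))
        edges, p = bai_distribution(bai, bin_width=0.25)
        assert np.sum(p) * 0.25 == pytest.approx(1.0)

    def test_against_hand_binning(self):
        rng = np.random.default_rng(6)
        n_avg = rng.uniform(1.0, 50.0, size=100)
        bai = compute_bai(_bai_table(n_avg))
        bw = 0.5
        edges, p = bai_distribution(bai, bin_width=bw)
        values = -np.log(n_avg / n_avg.max())
        oracle = np.zeros(len(edges) - 1)
        for v in values:
            oracle[min(int(v / bw), len(oracle) - 1)] += 1
        # hand-binned counts: left-closed bins
        hand = np.zeros(len(oracle))
        for v in values:
            hand[int(v // bw) if v < edges[-1] else len(hand) - 1] += 1
        np.testing.assert_allclose(p, hand / (len(values) * bw))


class TestRdfDegeneratesToPairRdf:
    def test_single_reference_atom(self):
        # with one reference atom the nearest-atom distance is the pair distance
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, BOX, size=(2, 5, 3))
        profile = surface_rdf(
            _traj(coords),
            _group("ref", {0}, "protein_A"),
            _group("tgt", {1, 2, 3, 4}),
            BOX,
            bin_width=0.05,
            r_max=BOX,
            skip=0,
        )
        pair_distances = [
            minimum_image_distance(frame[0], frame[j], BOX)
            for frame in coords
            for j in range(1, 5)
        ]
        hand, _ = np.histogram(pair_distances, bins=profile.bin_edges)
        np.testing.assert_allclose(profile.density, hand / (2 * 0.05))
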