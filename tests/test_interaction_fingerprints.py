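import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ligdyn.errors import AnnotationError, SelectionError
from ligdyn.interaction_fingerprints import (
    DetectorConfig,
    contact_class_map,
    detect_all_frame,
    detect_hbonds_frame,
    detect_hydrophobic_frame,
    detect_pi_stacking_frame,
    detect_salt_bridges_frame,
    fingerprint_trajectory,
    hbond_distance_table,
)
from ligdyn.structure_model import Atom, MolecularFrameSeries
from ligdyn.synthetic_data import (
    PlantedInteraction,
    plant_interaction_snapshot,
    plant_interaction_trajectory,
)

from conftest import dense_contact_interactions, sparse_contact_interactions


def planted(*interactions):
    return plant_interaction_snapshot(None, list(interactions))


class TestHBondDetector:
    @pytest.mark.parametrize("h_a,d_a", [(2.96, 3.94), (1.79, 2.72), (2.33, 3.22),
                                         (2.03, 2.97), (2.52, 3.49)])
    def test_planted_geometries_detected(self, h_a, d_a):
        side = "protein" if h_a > 2.6 else "ligand"
        snap = planted(PlantedInteraction(type="hbond", geometry={"h_a": h_a, "d_a": d_a},
                                          donor_side=side))
        events = detect_hbonds_frame(snap)
        assert len(events) == 1
        assert events[0].geometry["h_a"] == pytest.approx(h_a, abs=0.01)
        assert events[0].geometry["d_a"] == pytest.approx(d_a, abs=0.01)

    def test_h_a_beyond_threshold_not_detected(self):
        snap = planted(PlantedInteraction(type="hbond", geometry={"h_a": 3.5, "d_a": 3.9}))
        assert detect_hbonds_frame(snap) == []

    def test_d_a_beyond_threshold_not_detected(self):
        snap = planted(PlantedInteraction(type="hbond", geometry={"h_a": 3.3, "d_a": 4.2}))
        assert detect_hbonds_frame(snap) == []

    def test_unannotated_series_rejected(self, toy_complex):
        bare = toy_complex.copy()
        bare.annotated = False
        with pytest.raises(AnnotationError):
            detect_hbonds_frame(bare)


class TestSaltBridgeDetector:
    @pytest.mark.parametrize("dist,found", [(4.19, True), (5.26, True), (6.0, False)])
    def test_distance_thresholds(self, dist, found):
        snap = planted(PlantedInteraction(type="salt_bridge", geometry={"min_distance": dist}))
        events = detect_salt_bridges_frame(snap)
        assert (len(events) == 1) is found
        if found:
            assert events[0].geometry["min_distance"] == pytest.approx(dist, abs=0.01)


class TestPiStackingDetector:
    def test_parallel_rings_at_printed_geometry(self):
        snap = planted(PlantedInteraction(
            type="pi_stacking", geometry={"centroid_distance": 5.37, "offset": 0.63}))
        events = detect_pi_stacking_frame(snap)
        assert len(events) == 1
        assert events[0].geometry["centroid_distance"] == pytest.approx(5.37, abs=0.01)
        assert events[0].geometry["offset"] == pytest.approx(0.63, abs=0.01)

    def test_centroid_beyond_threshold(self):
        snap = planted(PlantedInteraction(
            type="pi_stacking", geometry={"centroid_distance": 7.0, "offset": 0.5}))
        assert detect_pi_stacking_frame(snap) == []

    def test_large_lateral_offset_rejected(self):
        # centroid 5.0 A with 3.0 A lateral offset: within centroid cutoff
        # but beyond the offset rule
        snap = planted(PlantedInteraction(
            type="pi_stacking", geometry={"centroid_distance": 5.0, "offset": 3.0}))
        assert detect_pi_stacking_frame(snap) == []


class TestHydrophobicDetector:
    @pytest.mark.parametrize("dist,found", [(4.0, True), (5.0, False)])
    def test_distance_thresholds(self, dist, found):
        snap = planted(PlantedInteraction(type="hydrophobic", geometry={"distance": dist}))
        assert (len(detect_hydrophobic_frame(snap)) == 1) is found

    def test_planted_pocket_residue_set(self):
        snap = planted(
            PlantedInteraction(type="hydrophobic", geometry={"distance": 3.8},
                               residue_name="TRP", residue_seq=115),
            PlantedInteraction(type="hydrophobic", geometry={"distance": 4.4},
                               residue_name="ILE", residue_seq=110),
        )
        events = detect_hydrophobic_frame(snap)
        assert {e.protein_residue for e in events} == {"TRP115", "ILE110"}


class TestSnapshotContactSets:
    def test_dense_complex_counts(self, dense_snapshot):
        assert len(detect_hbonds_frame(dense_snapshot)) == 3
        assert len(detect_salt_bridges_frame(dense_snapshot)) == 2
        assert len(detect_pi_stacking_frame(dense_snapshot)) == 1

    def test_sparse_complex_counts(self, sparse_snapshot):
        assert len(detect_hbonds_frame(sparse_snapshot)) == 2
        assert detect_salt_bridges_frame(sparse_snapshot) == []
        assert detect_pi_stacking_frame(sparse_snapshot) == []

    def test_every_event_geometry_satisfies_thresholds(self, dense_snapshot, sparse_snapshot):
        cfg = DetectorConfig()
        for snap in (dense_snapshot, sparse_snapshot):
            for e in detect_all_frame(snap, 0, cfg):
                g = e.geometry
                if e.type == "hbond":
                    assert g["h_a"] <= cfg.hbond_h_a_max
                    assert g["d_a"] <= cfg.hbond_d_a_max
                    assert g["dha_angle"] >= cfg.hbond_dha_min
                elif e.type == "salt_bridge":
                    assert g["min_distance"] <= cfg.salt_bridge_max
                elif e.type == "pi_stacking":
                    assert g["centroid_distance"] <= cfg.pi_centroid_max
                    assert g["offset"] <= cfg.pi_offset_max
                    assert g["normal_angle"] <= cfg.pi_planarity_max
                else:
                    assert g["min_distance"] <= cfg.hydrophobic_max

    @pytest.mark.parametrize("seed", range(3))
    def test_detectors_invariant_under_rigid_transform(self, dense_snapshot, seed):
        moved = dense_snapshot.copy()
        rot = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        shift = np.random.default_rng(seed).uniform(-40, 40, 3)
        moved.frames = moved.frames @ rot.T + shift
        base = detect_all_frame(dense_snapshot)
        after = detect_all_frame(moved)
        assert [(e.type, e.protein_residue) for e in base] == \
               [(e.type, e.protein_residue) for e in after]
        for e1, e2 in zip(base, after):
            for k, v in e1.geometry.items():
                assert e2.geometry[k] == pytest.approx(v, abs=1e-5)


class TestFingerprintTrajectory:
    def test_always_present_persistence_one(self):
        traj = plant_interaction_trajectory(
            None,
            [PlantedInteraction(type="hbond", geometry={"h_a": 2.0, "d_a": 2.9},
                                occupancy=1.0)],
            n_frames=6,
        )
        fp = fingerprint_trajectory(traj)
        assert fp.persistence[("GLY1", "hbond")] == 1.0

    def test_alternating_occupancy_half(self):
        traj = plant_interaction_trajectory(
            None,
            [PlantedInteraction(type="hbond", geometry={"h_a": 2.0, "d_a": 2.9},
                                occupancy=0.5)],
            n_frames=10,
        )
        fp = fingerprint_trajectory(traj)
        assert fp.persistence[("GLY1", "hbond")] == 0.5
        assert fp.matrix[:, 0].tolist() == [False, True] * 5

    def test_empty_interface_empty_matrix(self):
        # toy complex ligand sits ~6 A from the backbone: no contacts
        from ligdyn.synthetic_data import LigandSpec, make_toy_complex
        series = make_toy_complex(12, LigandSpec(n_rings=0, n_donors=0, n_acceptors=1,
                                                 n_apolar=0), seed=2)
        fp = fingerprint_trajectory(series)
        assert fp.keys == []
        assert fp.matrix.shape == (1, 0)

    def test_single_frame_equals_union_of_detectors(self, dense_snapshot):
        fp = fingerprint_trajectory(dense_snapshot)
        direct = detect_all_frame(dense_snapshot)
        assert set(fp.keys) == {(e.protein_residue, e.type) for e in direct}
        assert fp.matrix.all()

    def test_column_truecount_ratio_is_persistence(self):
        traj = plant_interaction_trajectory(
            None,
            [PlantedInteraction(type="salt_bridge", geometry={"min_distance": 4.0},
                                occupancy=0.7)],
            n_frames=10,
        )
        fp = fingerprint_trajectory(traj)
        for k, key in enumerate(fp.keys):
            assert fp.persistence[key] == fp.matrix[:, k].sum() / fp.n_frames


def two_atom_series(frame_dists):
    atoms = [
        Atom(serial=1, name="N", element="N", residue_index=1, residue_name="GLY",
             chain_id="A", coords=np.zeros(3), mass=14.007),
        Atom(serial=2, name="O1", element="O", residue_index=386, residue_name="LIG",
             chain_id="A", coords=np.array([3.0, 0, 0]), mass=15.999, is_ligand=True),
    ]
    frames = np.array([[[0, 0, 0], [d, 0, 0]] for d in frame_dists], float)
    return MolecularFrameSeries(
        atoms=atoms, frames=frames, frame_times=np.arange(len(frame_dists), dtype=float),
        ligand_mask=np.array([False, True]),
    )


class TestHBondDistanceTable:
    def test_constant_three_angstrom(self):
        series = two_atom_series([3.0, 3.0, 3.0])
        stats = hbond_distance_table(series, [("GLY1", "N", "LIG386", "O1")])
        assert stats[0].mean_distance_nm == pytest.approx(0.30, abs=1e-12)

    def test_alternating_three_five(self):
        series = two_atom_series([3.0, 5.0, 3.0, 5.0])
        stats = hbond_distance_table(series, [("GLY1", "N", "LIG386", "O1")])
        assert stats[0].mean_distance_nm == pytest.approx(0.40, abs=1e-12)

    def test_drifting_pair_matches_brute_force(self, rng):
        dists = rng.uniform(2.5, 11.0, 25)
        series = two_atom_series(dists.tolist())
        stats = hbond_distance_table(series, [("GLY1", "N", "LIG386", "O1")])
        assert stats[0].mean_distance_nm == pytest.approx(sum(dists) / len(dists) / 10, rel=1e-12)

    def test_unresolvable_pair_named(self):
        series = two_atom_series([3.0])
        with pytest.raises(SelectionError, match="GLY2.N"):
            hbond_distance_table(series, [("GLY2", "N", "LIG386", "O1")])


class TestContactClassMap:
    def test_green_yellow_none_bands(self):
        snap = planted(
            PlantedInteraction(type="hydrophobic", geometry={"distance": 3.9},
                               residue_name="ALA", residue_seq=1),
            PlantedInteraction(type="hydrophobic", geometry={"distance": 4.2},
                               residue_name="ALA", residue_seq=2),
            PlantedInteraction(type="hydrophobic", geometry={"distance": 8.0},
                               residue_name="ALA", residue_seq=3),
        )
        cmap = contact_class_map(snap)
        assert cmap["ALA1"] == "green"
        assert cmap["ALA2"] == "yellow"
        assert cmap["ALA3"] == "none"

    def test_requires_ligand(self):
        from ligdyn.synthetic_data import make_toy_complex
        series = make_toy_complex(8, ligand_spec=None, seed=0)
        with pytest.raises(SelectionError):
            contact_class_map(series)
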