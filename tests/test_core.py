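"""Core data model: geometry, leaflets, directive vectors, file I/O."""

import numpy as np
import pytest
from helpers import constructed_trajectory

import memprops as mp
from memprops.annotations import default_annotation, load_annotation, save_annotation
from memprops.core import UPPER, LOWER


class TestMinimumImage:
    @pytest.mark.parametrize(
        "delta,expected",
        [
            ((5.9, 0, 0), (-0.1, 0, 0)),
            ((0, 0, 0), (0, 0, 0)),
            ((-3.0, 0, 0), (-3.0, 0, 0)),  # half-open convention keeps -L/2
            ((3.0, 0, 0), (-3.0, 0, 0)),  # +L/2 maps onto -L/2
        ],
    )
    def test_wrap_cases(self, delta, expected):
        box = np.array([6.0, 6.0, 6.0])
        np.testing.assert_allclose(mp.minimum_image(delta, box), expected, atol=1e-12)

    def test_components_in_half_open_interval(self, rng):
        box = np.array([3.0, 5.0, 7.0])
        deltas = rng.uniform(-30, 30, size=(1000, 3))
        wrapped = mp.minimum_image(deltas, box)
        assert np.all(wrapped >= -box / 2)
        assert np.all(wrapped < box / 2)

    def test_invalid_box(self):
        with pytest.raises(ValueError):
            mp.minimum_image([1.0, 0, 0], [0.0, 6, 6])


class TestDirectiveVector:
    def test_all_trans_upper_chain_points_down(self):
        traj = constructed_trajectory(
            [{"leaflet": UPPER, "tilt_deg": 0.0, "xy": (1.0, 1.0)},
             {"leaflet": LOWER, "tilt_deg": 0.0, "xy": (2.0, 2.0)}]
        )
        v = mp.directive_vector(traj.frames[0], 0, "chain")
        np.testing.assert_allclose(v, [0, 0, -1], atol=1e-9)

    def test_tilted_chain_angle(self):
        traj = constructed_trajectory(
            [{"leaflet": UPPER, "tilt_deg": 30.0, "xy": (1.0, 1.0)},
             {"leaflet": LOWER, "tilt_deg": 0.0, "xy": (2.0, 2.0)}]
        )
        v = mp.directive_vector(traj.frames[0], 0, "chain")
        angle = np.degrees(np.arccos(np.dot(v, [0, 0, -1])))
        assert angle == pytest.approx(30.0, abs=1e-6)

    def test_unit_norm_for_all_chains(self, small_bilayer):
        traj, _ = small_bilayer
        vecs, *_ = mp.directive_vectors(traj.frames[0])
        np.testing.assert_allclose(np.linalg.norm(vecs, axis=1), 1.0, atol=1e-9)

    def test_second_terminal_carbon_convention(self):
        spec = mp.default_annotation()["C16S"]
        assert spec.directive_endpoints["chain"] == ("C1", "C15")

    def test_coincident_endpoints_error(self):
        traj = constructed_trajectory(
            [{"leaflet": UPPER, "tilt_deg": 0.0, "xy": (1.0, 1.0)},
             {"leaflet": LOWER, "tilt_deg": 0.0, "xy": (2.0, 2.0)}]
        )
        frame = traj.frames[0]
        mol = frame.topology.molecules[0]
        frame.coords[mol.index_of("C11")] = frame.coords[mol.index_of("C1")]
        with pytest.raises(ValueError, match="coincident"):
            mp.directive_vector(frame, 0, "chain")


class TestLeaflets:
    def test_symmetric_split(self, small_bilayer):
        traj, truth = small_bilayer
        la = mp.assign_leaflets(traj.frames[0])
        assert la.n_upper == la.n_lower == 16
        np.testing.assert_array_equal(la.labels, np.asarray(truth.leaflet_labels))

    def test_invariant_under_z_translation(self, small_bilayer):
        traj, _ = small_bilayer
        frame = traj.frames[0]
        shifted = mp.BilayerFrame(
            time=frame.time,
            box=frame.box,
            coords=frame.coords + [0, 0, 1.7],
            topology=frame.topology,
        )
        la0 = mp.assign_leaflets(frame)
        la1 = mp.assign_leaflets(shifted)
        np.testing.assert_array_equal(la0.labels, la1.labels)

    def test_tie_goes_upper(self):
        # three identical molecules collapsed to z = +2, -2 and 0: the
        # amphiphile center of mass is exactly 0, so the third head is
        # an exact tie and must label upper
        traj = constructed_trajectory(
            [{"leaflet": UPPER, "tilt_deg": 0.0, "xy": (1.0, 1.0)},
             {"leaflet": LOWER, "tilt_deg": 0.0, "xy": (2.0, 2.0)},
             {"leaflet": UPPER, "tilt_deg": 0.0, "xy": (3.0, 3.0)}]
        )
        frame = traj.frames[0]
        for mol, z in zip(frame.topology.molecules, (2.0, -2.0, 0.0)):
            idx = np.array(sorted(mol.atom_index.values()))
            frame.coords[idx] = [1.0, 1.0, z]
        la = mp.assign_leaflets(frame)
        assert abs(la.bilayer_center_z) < 1e-12
        assert la.labels[2] == UPPER

    def test_monolayer_warns(self):
        traj = constructed_trajectory(
            [{"leaflet": UPPER, "tilt_deg": 0.0, "xy": (1.0, 1.0)},
             {"leaflet": UPPER, "tilt_deg": 0.0, "xy": (2.0, 2.0)}]
        )
        with pytest.warns(UserWarning, match="monolayer"):
            mp.assign_leaflets(traj.frames[0])


class TestTrajectoryIO:
    def test_gro_xtc_round_trip(self, small_bilayer, tmp_path):
        traj, _ = small_bilayer
        gro = tmp_path / "system.gro"
        xtc = tmp_path / "traj.xtc"
        mp.write_trajectory(traj, gro, xtc)
        back = mp.read_trajectory(gro, xtc, temperature=traj.temperature)
        assert back.n_frames == traj.n_frames
        assert len(back.topology.amphiphiles) == 32
        assert len(back.topology.waters) == 160
        np.testing.assert_allclose(
            back.frames[0].coords, traj.frames[0].coords, atol=2e-3
        )
        np.testing.assert_allclose(
            back.frames[-1].coords, traj.frames[-1].coords, atol=2e-3
        )

    def test_fully_hydrated_pc_system_counts(self, tmp_path, rng):
        # a 128-DPPC bilayer solvated with 3464 waters reads back with
        # the correct molecule census
        from helpers import build_topology

        ann = default_annotation()
        specs = [ann["DPPC"]] * 128 + [ann["TIP3"]] * 3464
        top = build_topology(specs)
        coords = rng.uniform(0.2, 6.2, size=(top.n_atoms, 3))
        frame = mp.BilayerFrame(0.0, np.array([6.5, 6.5, 7.0]), coords, top)
        traj = mp.Trajectory(topology=top, frames=[frame])
        gro = tmp_path / "dppc.gro"
        mp.write_trajectory(traj, gro)
        back = mp.read_trajectory(gro, annotation=ann)
        assert len(back.topology.amphiphiles) == 128
        assert len(back.topology.waters) == 3464

    def test_unknown_residue_is_hard_error(self, small_bilayer, tmp_path):
        traj, _ = small_bilayer
        gro = tmp_path / "system.gro"
        mp.write_trajectory(traj, gro)
        annotation = {k: v for k, v in default_annotation().items() if k != "SYN"}
        with pytest.raises(ValueError, match="SYN"):
            mp.read_trajectory(gro, annotation=annotation)

    def test_single_frame_has_no_dt(self, small_bilayer, tmp_path):
        traj, _ = small_bilayer
        gro = tmp_path / "single.gro"
        mp.write_trajectory(traj, gro)
        back = mp.read_trajectory(gro)
        assert back.n_frames == 1
        assert back.dt is None

    def test_empty_trajectory_rejected(self, small_bilayer):
        with pytest.raises(ValueError, match="empty"):
            mp.Trajectory(topology=small_bilayer[0].topology, frames=[])


class TestAnnotations:
    def test_default_covers_paper_species(self):
        ann = default_annotation()
        for name in ("DPPC", "DSPC", "C16TMA", "C16S", "TIP3", "SOL", "SYN"):
            assert name in ann

    def test_charge_sums_match_formal_charge(self):
        ann = default_annotation()
        assert ann["C12TMA"].formal_charge == 1.0
        assert ann["C12S"].formal_charge == -1.0
        assert ann["DPPC"].formal_charge == 0.0
        # validation is active: a broken spec raises
        broken = ann["SYN"].to_dict()
        broken["charges"]["N"] = 0.5
        with pytest.raises(ValueError, match="charges sum"):
            mp.MoleculeSpec.from_dict(broken)

    def test_pc_directive_starts_at_carbonyl(self):
        spec = default_annotation()["DPPC"]
        assert spec.directive_endpoints["sn2"] == ("C21", "C215")
        assert spec.directive_endpoints["sn1"] == ("C31", "C315")

    def test_yaml_round_trip(self, tmp_path):
        ann = default_annotation()
        path = tmp_path / "ann.yml"
        save_annotation(ann, path)
        back = load_annotation(path)
        assert set(back) == set(ann)
        assert back["SYN"].chain_defs == ann["SYN"].chain_defs
        assert back["SYN"].charges == ann["SYN"].charges
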