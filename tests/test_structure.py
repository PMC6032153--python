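"""Structural metrics: areas, profiles, thickness, tilt, |SCD|, gauche, RDF."""

import numpy as np
import pytest
from helpers import WATER_SPEC, build_topology, constructed_trajectory

import memprops as mp
from memprops.core import BilayerFrame, Trajectory, UPPER, LOWER
from memprops.structure import ZProfile, thickness
from memprops.synth import tilt_density_moments


class TestMolecularArea:
    def test_fixed_box_exact(self):
        traj = constructed_trajectory(
            [{"leaflet": UPPER, "tilt_deg": 0.0, "xy": (1, 1)},
             {"leaflet": LOWER, "tilt_deg": 0.0, "xy": (2, 2)}],
            box=(6.4, 6.4, 8.0),
            n_frames=3,
        )
        area = mp.molecular_area(traj, 64)
        assert area.mean == pytest.approx(0.640, abs=1e-12)
        assert area.sd == 0.0

    def test_recovers_generator_mean(self, small_bilayer):
        traj, truth = small_bilayer
        area = mp.molecular_area(traj, 16)
        sem = area.sd / np.sqrt(area.n)
        assert abs(area.mean - truth.a0_true) < 2 * area.sd
        assert abs(area.mean - truth.a0_true) < 6 * sem

    def test_single_frame_warns(self):
        traj = constructed_trajectory(
            [{"leaflet": UPPER, "tilt_deg": 0.0, "xy": (1, 1)},
             {"leaflet": LOWER, "tilt_deg": 0.0, "xy": (2, 2)}]
        )
        with pytest.warns(UserWarning, match="single frame"):
            area = mp.molecular_area(traj, 2)
        assert area.sd == 0.0

    def test_invalid_nmol(self, small_bilayer):
        with pytest.raises(ValueError):
            mp.molecular_area(small_bilayer[0], 0)


class TestDensityProfile:
    def test_uniform_points_flat(self, rng):
        # ideal-gas waters fill the box: the profile is flat within noise
        n = 3000
        top = build_topology([WATER_SPEC] * n)
        coords = np.zeros((top.n_atoms, 3))
        box = np.array([4.0, 4.0, 6.0])
        pos = rng.uniform(0, 1, size=(n, 3)) * box
        for mol, p in zip(top.molecules, pos):
            for j, a in enumerate(mol.spec.atoms):
                coords[mol.atom_index[a]] = p + [0, 0, 0.0001 * j]
        frames = [BilayerFrame(0.0, box, coords, top)]
        traj = Trajectory(topology=top, frames=frames)
        prof = mp.density_profile(traj, "SOL:OW", bin_width=0.5)
        inner = prof.values[(np.abs(prof.centers) < 2.5)]
        expected = n / (box[0] * box[1] * box[2])
        assert np.all(np.abs(inner - expected) < 5 * np.sqrt(expected / (0.5 * 16)))

    def test_head_sheets_give_two_peaks(self, small_bilayer):
        traj, truth = small_bilayer
        prof = mp.density_profile(traj, "cation_center", bin_width=0.1)
        half = truth.thickness_true / 2
        centers = prof.centers
        upper_peak = centers[np.argmax(np.where(centers > 0, prof.values, 0))]
        lower_peak = centers[np.argmax(np.where(centers < 0, prof.values, 0))]
        assert upper_peak == pytest.approx(half, abs=0.1)
        assert lower_peak == pytest.approx(-half, abs=0.1)

    def test_number_integral_conserves_count(self, small_bilayer):
        traj, _ = small_bilayer
        prof = mp.density_profile(traj, "cation_center", bin_width=0.1)
        assert prof.integral() == pytest.approx(32, rel=0.005)

    def test_neutral_system_charge_integral_zero(self, small_bilayer):
        traj, _ = small_bilayer
        prof = mp.density_profile(traj, "SYN", weighting="charge", bin_width=0.1)
        assert abs(prof.integral()) < 1e-6

    def test_empty_selection_error(self, small_bilayer):
        with pytest.raises(ValueError):
            mp.density_profile(small_bilayer[0], "TIP3:OH2")


class TestThickness:
    def test_sheets_at_two_nm_give_four(self):
        edges = np.arange(-3.0, 3.01, 0.1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        up = np.exp(-0.5 * ((centers - 2.0) / 0.1) ** 2)
        lo = np.exp(-0.5 * ((centers + 2.0) / 0.1) ** 2)
        pu = ZProfile(edges, up, "head")
        pl = ZProfile(edges, lo, "head")
        assert thickness(pu, pl) == pytest.approx(4.0, abs=1e-6)

    def test_generator_separation_recovered(self, small_bilayer):
        traj, truth = small_bilayer
        h = mp.bilayer_thickness(traj, bin_width=0.1)
        assert abs(h - truth.thickness_true) <= 0.1

    def test_single_leaflet_error(self):
        traj = constructed_trajectory(
            [{"leaflet": UPPER, "tilt_deg": 0.0, "xy": (1, 1)},
             {"leaflet": UPPER, "tilt_deg": 0.0, "xy": (2, 2)}]
        )
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                mp.bilayer_thickness(traj)

    def test_shift_aligns_reference_peak_to_zero(self):
        from memprops.structure import shift_profile

        edges = np.arange(-3.0, 3.01, 0.1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ref = ZProfile(edges, np.exp(-0.5 * ((centers - 1.2) / 0.1) ** 2), "head")
        prof = ZProfile(edges, np.exp(-0.5 * (centers / 0.3) ** 2), "water")
        shifted = shift_profile(prof, ref)
        # the reference peak position becomes the new origin
        assert shifted.bin_edges[0] == pytest.approx(edges[0] - 1.2, abs=0.01)
        np.testing.assert_array_equal(shifted.values, prof.values)

    def test_ambiguous_peak_error(self):
        edges = np.arange(-3.0, 3.01, 0.1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        vals = np.zeros_like(centers)
        vals[5] = 1.0
        vals[40] = 0.999  # second maximum within 1%, far away
        prof = ZProfile(edges, vals, "head")
        with pytest.raises(ValueError, match="ambiguous"):
            thickness(prof, prof)


class TestTiltAngles:
    def test_constructed_thirty_degrees(self):
        chains = [
            {"leaflet": UPPER, "tilt_deg": 30.0, "azimuth_deg": a, "xy": (1 + a / 100, 1)}
            for a in (0.0, 90.0, 215.0)
        ] + [{"leaflet": LOWER, "tilt_deg": 30.0, "azimuth_deg": 10.0, "xy": (2, 2)}]
        traj = constructed_trajectory(chains)
        samples = mp.tilt_angles(traj)
        np.testing.assert_allclose(samples.degrees(), 30.0, atol=1e-6)

    def test_vertical_chains_zero(self):
        traj = constructed_trajectory(
            [{"leaflet": UPPER, "tilt_deg": 0.0, "xy": (1, 1)},
             {"leaflet": LOWER, "tilt_deg": 0.0, "xy": (2, 2)}]
        )
        samples = mp.tilt_angles(traj)
        np.testing.assert_allclose(samples.degrees(), 0.0, atol=1e-6)

    def test_generator_mean_matches_quadrature(self, small_bilayer):
        traj, truth = small_bilayer
        samples = mp.tilt_angles(traj)
        mean, _ = tilt_density_moments(truth.chi_tilt_true, truth.theta0_true)
        assert abs(np.degrees(samples.angles.mean() - mean)) < 0.5


class TestDeuteriumOrder:
    def test_all_trans_vertical_half(self):
        traj = constructed_trajectory(
            [{"leaflet": UPPER, "tilt_deg": 0.0, "xy": (1, 1)},
             {"leaflet": LOWER, "tilt_deg": 0.0, "xy": (2, 2)}]
        )
        prof = mp.deuterium_order(traj)
        np.testing.assert_allclose(prof.scd["chain"], 0.5, atol=1e-9)

    def test_magic_angle_zero(self):
        # place every C-H at the magic angle to the normal
        traj = constructed_trajectory(
            [{"leaflet": UPPER, "tilt_deg": 0.0, "xy": (1, 1)},
             {"leaflet": LOWER, "tilt_deg": 0.0, "xy": (2, 2)}]
        )
        frame = traj.frames[0]
        top = frame.topology
        magic = np.arccos(1.0 / np.sqrt(3.0))
        direction = np.array([np.sin(magic), 0.0, np.cos(magic)]) * 0.109
        for mol in top.amphiphiles:
            for cname, hnames in mol.spec.chain_hydrogens.items():
                c = frame.coords[mol.index_of(cname)]
                for h in hnames:
                    frame.coords[mol.index_of(h)] = c + direction
        prof = mp.deuterium_order(traj)
        np.testing.assert_allclose(prof.scd["chain"], 0.0, atol=1e-9)

    def test_isotropic_ch_vectors_vanish(self, rng):
        traj = constructed_trajectory(
            [{"leaflet": UPPER, "tilt_deg": 0.0, "xy": (1, 1), "seed": s}
             for s in range(30)]
            + [{"leaflet": LOWER, "tilt_deg": 0.0, "xy": (2, 2)}],
            n_frames=1,
        )
        # replicate the frame with freshly randomized C-H orientations
        top = traj.topology
        base = traj.frames[0].coords
        frames = []
        for f in range(1400):
            coords = base.copy()
            for mol in top.amphiphiles:
                for cname, hnames in mol.spec.chain_hydrogens.items():
                    c = coords[mol.index_of(cname)]
                    for h in hnames:
                        u = rng.normal(size=3)
                        coords[mol.index_of(h)] = c + 0.109 * u / np.linalg.norm(u)
            frames.append(BilayerFrame(f * 10.0, traj.frames[0].box, coords, top))
        iso = Trajectory(topology=top, frames=frames, dt=10.0)
        prof = mp.deuterium_order(iso)
        # about 1e6 C-H samples per carbon position in total
        assert np.nanmax(prof.scd["chain"]) < 0.01

    def test_bounds_invariant(self, small_bilayer):
        prof = mp.deuterium_order(small_bilayer[0])
        vals = prof.scd["chain"]
        assert np.all(vals[np.isfinite(vals)] <= 0.5 + 1e-12)


class TestGaucheProfile:
    def test_all_trans_zero(self):
        traj = constructed_trajectory(
            [{"leaflet": UPPER, "tilt_deg": 10.0, "xy": (1, 1)},
             {"leaflet": LOWER, "tilt_deg": 10.0, "xy": (2, 2)}]
        )
        prof = mp.gauche_profile(traj)
        np.testing.assert_array_equal(prof.gauche["chain"], 0.0)

    def test_forced_mask_counts(self):
        mask = np.zeros(9, bool)
        mask[[0, 3]] = True
        traj = constructed_trajectory(
            [{"leaflet": UPPER, "tilt_deg": 0.0, "xy": (1, 1), "gauche_mask": mask},
             {"leaflet": LOWER, "tilt_deg": 0.0, "xy": (2, 2), "gauche_mask": mask}]
        )
        prof = mp.gauche_profile(traj)
        np.testing.assert_array_equal(prof.gauche["chain"], mask.astype(float))
        assert prof.gauche["chain"].mean() == pytest.approx(2.0 / 9.0)

    def test_sixty_degree_dihedral_is_gauche(self):
        # +/-60 deg sits inside the open (-120, 120) gauche window
        mask = np.ones(9, bool)
        traj = constructed_trajectory(
            [{"leaflet": UPPER, "tilt_deg": 0.0, "xy": (1, 1), "gauche_mask": mask},
             {"leaflet": LOWER, "tilt_deg": 0.0, "xy": (2, 2), "gauche_mask": mask}]
        )
        prof = mp.gauche_profile(traj)
        np.testing.assert_array_equal(prof.gauche["chain"], 1.0)

    def test_bernoulli_recovery(self):
        traj, truth = mp.gen_bilayer(
            n_per_leaflet=50, n_frames=100, seed=77, gauche_p=0.2, n_waters=0, n_shell=0
        )
        prof = mp.gauche_profile(traj)
        np.testing.assert_allclose(prof.gauche["chain"], 0.2, atol=0.015)


class TestRdf2D:
    def _grid_traj(self, positions, n_frames=1, box=(10.0, 10.0, 8.0), jitter=None, seed=0):
        rng = np.random.default_rng(seed)
        chains = []
        for x, y in positions:
            chains.append({"leaflet": UPPER, "tilt_deg": 0.0, "xy": (x, y)})
            chains.append({"leaflet": LOWER, "tilt_deg": 0.0, "xy": (x, y)})
        traj = constructed_trajectory(chains, box=box)
        if n_frames > 1:
            top = traj.topology
            base = traj.frames[0].coords
            frames = []
            for f in range(n_frames):
                coords = base.copy()
                if jitter == "uniform":
                    for mol in top.amphiphiles:
                        idx = np.array(sorted(mol.atom_index.values()))
                        xy = rng.uniform(0, box[0], size=2)
                        coords[idx, 0] = coords[idx, 0] - coords[idx, 0].mean() + xy[0]
                        coords[idx, 1] = coords[idx, 1] - coords[idx, 1].mean() + xy[1]
                frames.append(BilayerFrame(f * 10.0, np.asarray(box), coords, top))
            traj = Trajectory(topology=top, frames=frames, dt=10.0)
        return traj

    def test_poisson_points_give_unity(self):
        pts = [(0.0, 0.0)] * 80
        traj = self._grid_traj(pts, n_frames=80, jitter="uniform", seed=5)
        r, g = mp.rdf_2d(traj, "cation_center", "cation_center", r_max=3.0, bin_width=0.1)
        sel = r > 0.5
        assert np.all(np.abs(g[sel] - 1.0) < 0.05)

    def test_hexagonal_lattice_first_peak(self):
        a = 1.0
        pts = []
        for i in range(6):
            for j in range(6):
                pts.append(((i + 0.5 * (j % 2)) * a + 1.0, j * a * np.sqrt(3) / 2 + 1.0))
        traj = self._grid_traj(pts, box=(6.0 * a, 6.0 * np.sqrt(3) / 2 * a, 8.0))
        r, g = mp.rdf_2d(traj, "cation_center", "cation_center", r_max=1.4, bin_width=0.05)
        first = r[np.argmax(g * (r > 0.5))]
        assert first == pytest.approx(a, abs=0.05)

    def test_rmax_validation_and_empty_selection(self, small_bilayer):
        traj, _ = small_bilayer
        with pytest.raises(ValueError, match="r_max"):
            mp.rdf_2d(traj, "cation_center", "cation_center", r_max=50.0)
        with pytest.raises(ValueError):
            mp.rdf_2d(traj, "cation_center", "TIP3:OH2", r_max=1.0)
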