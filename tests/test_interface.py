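"""Interfacial analyses: H-bonds, orientation, potential, correlations."""

import numpy as np
import pytest
from helpers import constructed_trajectory

import memprops as mp
from memprops.core import UPPER, LOWER
from memprops.interface import (
    fit_biexponential,
    p2_autocorrelation,
    survival_correlation,
)
from memprops.structure import ZProfile
from memprops.synth import SHEET_PHI_V, gen_rotating_vectors, gen_shell_occupancy


def _two_chain_layout():
    return [
        {"leaflet": UPPER, "tilt_deg": 0.0, "xy": (1.0, 1.0)},
        {"leaflet": LOWER, "tilt_deg": 0.0, "xy": (2.0, 2.0)},
    ]


class TestHydrogenBonds:
    def _water_at(self, traj, distance, toward_s=True):
        """A water whose O sits `distance` from the upper S, one H collinear."""
        frame = traj.frames[0]
        mol = frame.topology.molecules[0]
        s_pos = frame.coords[mol.index_of("S")]
        o = s_pos + np.array([0.0, 0.0, distance])
        if toward_s:
            return {"o": o, "aim": s_pos - o}  # O-H...S collinear
        return {"o": o, "dipole": (0, 0, 1.0)}  # both H's point away

    def test_bond_inside_both_cutoffs(self):
        base = constructed_trajectory(_two_chain_layout())
        water = self._water_at(base, 0.28)
        traj = constructed_trajectory(_two_chain_layout(), waters=[water])
        counts = mp.hydrogen_bonds(traj)
        assert counts.mean == pytest.approx(1.0 / 2.0)  # one bond over two amphiphiles

    def test_distance_cutoff_excludes(self):
        base = constructed_trajectory(_two_chain_layout())
        water = self._water_at(base, 0.40)
        traj = constructed_trajectory(_two_chain_layout(), waters=[water])
        assert mp.hydrogen_bonds(traj).mean == 0.0

    def test_angle_cutoff_excludes(self):
        base = constructed_trajectory(_two_chain_layout())
        water = self._water_at(base, 0.28, toward_s=False)  # H's point away
        traj = constructed_trajectory(_two_chain_layout(), waters=[water])
        assert mp.hydrogen_bonds(traj).mean == 0.0

    def test_k_bonded_waters_per_lipid(self):
        base = constructed_trajectory(_two_chain_layout())
        frame = base.frames[0]
        waters = []
        for mol in frame.topology.molecules[:2]:
            s_pos = frame.coords[mol.index_of("S")]
            for k in range(3):
                off = np.array([0.25 * np.cos(2 * np.pi * k / 3),
                                0.25 * np.sin(2 * np.pi * k / 3), 0.12])
                o = s_pos + off
                waters.append({"o": o, "aim": s_pos - o})
        traj = constructed_trajectory(_two_chain_layout(), waters=waters)
        counts = mp.hydrogen_bonds(traj)
        assert counts.mean == pytest.approx(3.0)

    def test_no_donors_or_acceptors_error(self, small_bilayer):
        traj, _ = small_bilayer
        stripped = constructed_trajectory(_two_chain_layout())
        for m in stripped.topology.amphiphiles:
            m.spec.head_atoms["hbond_acceptors"] = []
        with pytest.raises(ValueError, match="neither donors nor acceptors"):
            mp.hydrogen_bonds(stripped)


class TestWaterOrientation:
    def test_outward_dipoles_peak_at_zero(self):
        waters = [{"o": (1.0, 1.0, 6.5), "dipole": (0, 0, 1.0)},
                  {"o": (2.0, 2.0, 1.5), "dipole": (0, 0, -1.0)}]
        traj = constructed_trajectory(_two_chain_layout(), waters=waters)
        omap = mp.water_orientation(traj)
        occupied = omap.prob.sum(axis=1) > 0
        modes = [omap.alpha_edges[np.argmax(row)] for row in omap.prob[occupied]]
        assert all(m < 5.0 for m in modes)

    def test_rows_normalized(self, small_bilayer):
        omap = mp.water_orientation(small_bilayer[0])
        sums = omap.prob.sum(axis=1)
        occupied = sums > 0
        np.testing.assert_allclose(sums[occupied], 1.0, atol=1e-12)

    def test_isotropic_dipoles_average_to_zero(self, rng):
        n = 40_000
        waters = []
        for _ in range(n):
            d = rng.normal(size=3)
            waters.append({"o": rng.uniform(1, 5, size=3), "dipole": d / np.linalg.norm(d)})
        traj = constructed_trajectory(_two_chain_layout(), waters=waters)
        omap = mp.water_orientation(traj, bin_width_z=2.0, bin_width_alpha=1.0)
        centers = 0.5 * (omap.alpha_edges[:-1] + omap.alpha_edges[1:])
        occupied = omap.prob.sum(axis=1) > 0
        mean_cos = (omap.prob[occupied] * np.cos(np.radians(centers))).sum(axis=1)
        assert np.all(np.abs(mean_cos) < 0.01)


class TestElectrostaticPotential:
    def _profile(self, rho, edges, area=25.0):
        return ZProfile(bin_edges=edges, values=rho, species="all",
                        weighting="charge", area=area)

    def test_zero_density_zero_potential(self):
        edges = np.arange(-3.0, 3.001, 0.01)
        z, phi = mp.electrostatic_potential(self._profile(np.zeros(len(edges) - 1), edges))
        np.testing.assert_allclose(phi, 0.0, atol=1e-15)

    def test_parallel_plate_capacitor(self):
        # +/- Gaussian sheets (sigma_s = 0.5 e/nm^2, separation 1 nm)
        # both above the center, like one leaflet's charge double layer:
        # the potential drop across the pair is sigma*d/eps0
        edges = np.arange(-3.0, 3.0001, 0.005)
        centers = 0.5 * (edges[:-1] + edges[1:])
        sig_s, d, w = 0.5, 1.0, 0.02
        rho = sig_s / (w * np.sqrt(2 * np.pi)) * (
            np.exp(-0.5 * ((centers - 1.0) / w) ** 2)
            - np.exp(-0.5 * ((centers - 1.0 - d) / w) ** 2)
        )
        z, phi = mp.electrostatic_potential(self._profile(rho, edges))
        delta = abs(np.interp(2.7, z, phi) - np.interp(0.0, z, phi))
        expected = sig_s * d * SHEET_PHI_V
        assert delta == pytest.approx(expected, rel=0.005)

    def test_mirror_symmetric_density_gives_even_potential(self):
        edges = np.arange(-3.0, 3.0001, 0.01)
        centers = 0.5 * (edges[:-1] + edges[1:])
        rho = np.cos(centers) * np.exp(-centers**2)  # even, near-neutral
        rho -= rho.mean()  # enforce exact neutrality
        z, phi = mp.electrostatic_potential(self._profile(rho, edges))
        phi_neg = np.interp(-z, z, phi)
        np.testing.assert_allclose(phi, phi_neg, atol=1e-3 * np.abs(phi).max())

    def test_net_charge_rejected(self):
        edges = np.arange(-1.0, 1.001, 0.01)
        rho = np.full(len(edges) - 1, 0.05)
        with pytest.raises(ValueError, match="net box charge"):
            mp.electrostatic_potential(self._profile(rho, edges))

    def test_mirror_symmetric_bilayer_edges_agree(self):
        # exactly mirrored leaflets: the charge density is even in z,
        # so the potential at the two box edges must coincide
        traj = constructed_trajectory(
            [{"leaflet": UPPER, "tilt_deg": 15.0, "azimuth_deg": 30.0, "xy": (1.0, 1.0)},
             {"leaflet": LOWER, "tilt_deg": 15.0, "azimuth_deg": 30.0, "xy": (1.0, 1.0)},
             {"leaflet": UPPER, "tilt_deg": 0.0, "azimuth_deg": 0.0, "xy": (3.0, 3.0)},
             {"leaflet": LOWER, "tilt_deg": 0.0, "azimuth_deg": 0.0, "xy": (3.0, 3.0)}]
        )
        top = traj.topology
        frame = traj.frames[0]
        edges = np.arange(-4.0, 4.0001, 0.05)
        zrel = frame.coords[:, 2] - frame.box[2] / 2.0  # exact mirror plane
        hist, _ = np.histogram(zrel, bins=edges, weights=top.charges)
        area = frame.box[0] * frame.box[1]
        prof = self._profile(hist / (0.05 * area), edges, area=area)
        z, phi = mp.electrostatic_potential(prof)
        assert abs(phi[0] - phi[-1]) < 1e-3  # volts: edges agree within 1 mV


class TestSurvivalCorrelation:
    def test_starts_at_one(self):
        occ = gen_shell_occupancy(50.0, 500, 50, 10.0, seed=1)
        lags, r = survival_correlation(occ, 10.0)
        assert r[0] == 1.0

    @pytest.mark.parametrize("tau,dt", [(10.0, 2.0), (50.0, 10.0), (200.0, 40.0)])
    def test_recovery_across_taus(self, tau, dt):
        occ = gen_shell_occupancy(tau, 2048, 600, dt, seed=5, n_shell=256)
        lags, r = survival_correlation(occ, dt, max_lag=200)
        fit, t = fit_biexponential(lags, r)
        assert t == pytest.approx(tau, rel=0.10)

    def test_residence_time_on_bilayer(self, small_bilayer):
        traj, truth = small_bilayer
        series = mp.residence_time(traj)
        assert series.values[0] == 1.0
        assert series.tau == pytest.approx(truth.tau_res_true, rel=0.10)

    def test_never_leaving_waters_error(self):
        waters = [{"o": (1.0, 1.0, 6.0), "dipole": (0, 0, 1.0)}]
        traj = constructed_trajectory(_two_chain_layout(), waters=waters, n_frames=120)
        frame0 = traj.frames[0]
        mol = frame0.topology.molecules[0]
        s_pos = frame0.coords[mol.index_of("S")]
        for f in traj.frames:  # pin the water inside the shell forever
            w = f.topology.waters[0]
            shift = s_pos + [0, 0, 0.3] - f.coords[w.index_of("OW")]
            for a in w.spec.atoms:
                f.coords[w.index_of(a)] += shift
        with pytest.raises(ValueError, match="diverges"):
            mp.residence_time(traj)


class TestRotationalRelaxation:
    def test_static_vectors_unity(self):
        v = np.tile(np.array([[0.0, 0.0, 1.0]]), (50, 20, 1))
        lags, c = p2_autocorrelation(v, 1.0)
        np.testing.assert_allclose(c, 1.0, atol=1e-12)

    def test_ninety_degree_flips_alternate(self):
        v = np.zeros((40, 5, 3))
        v[0::2, :, 2] = 1.0
        v[1::2, :, 0] = 1.0
        lags, c = p2_autocorrelation(v, 1.0, max_lag=6)
        np.testing.assert_allclose(c[0::2], 1.0, atol=1e-12)
        np.testing.assert_allclose(c[1::2], -0.5, atol=1e-12)

    @pytest.mark.parametrize("tau", [10.0, 50.0, 200.0])
    def test_isotropic_diffusion_tau(self, tau):
        dr = 1.0 / (6.0 * tau)
        dt = tau / 10.0
        v = gen_rotating_vectors(dr, 400, 1200, dt, seed=int(tau))
        lags, c = p2_autocorrelation(v, dt, max_lag=500)
        fit, t = fit_biexponential(lags, c)
        assert t == pytest.approx(tau, rel=0.10)

    def test_water_dipole_tau_on_bilayer(self, small_bilayer):
        traj, truth = small_bilayer
        series = mp.rotational_relaxation(traj, vector="water_dipole")
        assert series.values[0] == pytest.approx(1.0, abs=1e-9)
        assert series.tau == pytest.approx(truth.tau_rot_true, rel=0.15)

    def test_single_exponential_reduces(self):
        t = np.arange(0, 200.0, 2.0)
        y = np.exp(-t / 40.0)
        fit, tau = fit_biexponential(t, y)
        assert tau == pytest.approx(40.0, rel=1e-3)
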