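"""Bilayer-water interfacial properties.

Hydrogen-bond counts between water and the hydrophilic groups
(geometric criterion: donor-acceptor distance <= 0.35 nm and
H-donor-acceptor angle <= 30 deg), water-dipole orientation maps along
the bilayer normal, the membrane electrostatic potential from double
integration of the charge density, the interfacial water residence
time from the intermittent shell survival correlation, and rotational
relaxation times from second-Legendre autocorrelation functions, both
integrated through bi-exponential fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .core import Trajectory, minimum_image
from .structure import ZProfile

log = logging.getLogger("memprops")

E_CHARGE = 1.602176634e-19  # C
EPS0 = 8.8541878128e-12  # F/m
# double integral of rho[e/nm^3] over z[nm]^2, divided by eps0, in volts
_PHI_FACTOR = E_CHARGE * 1e27 * 1e-18 / EPS0

__all__ = [
    "CorrelationSeries",
    "OrientationMap",
    "hydrogen_bonds",
    "water_orientation",
    "electrostatic_potential",
    "residence_time",
    "rotational_relaxation",
    "survival_correlation",
    "p2_autocorrelation",
    "fit_biexponential",
]


@dataclass
class CorrelationSeries:
    """A normalized correlation function with its bi-exponential fit."""

    lags: np.ndarray  # ps
    values: np.ndarray
    fit: dict | None = None  # {A0, tau0, A1, tau1}
    tau: float | None = None  # ps, analytic integral of the fit
    integral: float | None = None  # trapezoidal integral of the data
    warnings: list = field(default_factory=list)


@dataclass
class OrientationMap:
    """Normalized P(alpha | z): water dipole angle vs transverse position."""

    z_edges: np.ndarray  # nm
    alpha_edges: np.ndarray  # deg
    prob: np.ndarray  # (n_z, n_alpha), each occupied z-row sums to 1
    counts: np.ndarray | None = None

    def mode_alpha(self, z_value: float) -> float:
        """Most probable dipole angle (deg) in the slab containing z."""
        i = int(np.clip(np.searchsorted(self.z_edges, z_value) - 1, 0, len(self.prob) - 1))
        centers = 0.5 * (self.alpha_edges[:-1] + self.alpha_edges[1:])
        return float(centers[np.argmax(self.prob[i])])


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _wrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.mod(coords, box)


def hydrogen_bonds(
    traj: Trajectory,
    distance_cutoff: float = 0.35,
    angle_cutoff: float = np.radians(30.0),
) -> "MeanSDTuple":
    """Mean water-headgroup hydrogen bonds per amphiphile, +/- sd over frames.

    Donors and acceptors come from the MoleculeSpec head-atom roles:
    water donates through its hydrogens to the head-group acceptors,
    and head-group donors (if any) donate to the water oxygen.  A bond
    requires donor-acceptor distance <= ``distance_cutoff`` (nm) and an
    H-donor-acceptor angle <= ``angle_cutoff``.
    """
    top = traj.topology
    n_amph = len(top.amphiphiles)
    if n_amph == 0:
        raise ValueError("no amphiphiles in topology")

    def _role_atoms(molecules, role):
        donors, hydrogens = [], []
        for m in molecules:
            for name in m.spec.head_atoms.get(role, []) or []:
                hs = m.spec.donor_hydrogens.get(name, []) if role == "hbond_donors" else []
                donors.append(m.index_of(name))
                hydrogens.append([m.index_of(h) for h in hs])
        return np.asarray(donors, dtype=int), hydrogens

    amph_acc, _ = _role_atoms(top.amphiphiles, "hbond_acceptors")
    amph_don, amph_don_h = _role_atoms(top.amphiphiles, "hbond_donors")
    wat_don, wat_don_h = _role_atoms(top.waters, "hbond_donors")
    wat_acc, _ = _role_atoms(top.waters, "hbond_acceptors")
    if amph_acc.size == 0 and amph_don.size == 0:
        raise ValueError("head groups declare neither donors nor acceptors")

    def _count(frame, don_idx, don_h, acc_idx):
        if don_idx.size == 0 or acc_idx.size == 0:
            return 0
        box = frame.box
        tree = cKDTree(_wrap(frame.coords[acc_idx], box), boxsize=box)
        pairs = tree.query_ball_point(
            _wrap(frame.coords[don_idx], box), r=distance_cutoff
        )
        n = 0
        for di, acc_list in enumerate(pairs):
            if not acc_list:
                continue
            d_pos = frame.coords[don_idx[di]]
            h_pos = frame.coords[don_h[di]] if don_h[di] else None
            if h_pos is None:
                continue
            dh = minimum_image(h_pos - d_pos, box)  # (n_h, 3)
            dh_u = dh / np.linalg.norm(dh, axis=-1, keepdims=True)
            for ai in acc_list:
                da = minimum_image(frame.coords[acc_idx[ai]] - d_pos, box)
                dist = np.linalg.norm(da)
                if dist < 1e-9:
                    continue
                cosang = dh_u @ (da / dist)
                if np.any(np.arccos(np.clip(cosang, -1, 1)) <= angle_cutoff):
                    n += 1
        return n

    per_frame = np.empty(traj.n_frames)
    for fi, frame in enumerate(traj.frames):
        n = _count(frame, wat_don, wat_don_h, amph_acc)
        n += _count(frame, amph_don, amph_don_h, wat_acc)
        per_frame[fi] = n / n_amph
    return MeanSDTuple(float(per_frame.mean()), float(per_frame.std()), per_frame)


@dataclass
class MeanSDTuple:
    mean: float
    sd: float
    series: np.ndarray


# ---------------------------------------------------------------------------
# water orientation
# ---------------------------------------------------------------------------

def water_orientation(
    traj: Trajectory,
    bin_width_z: float = 0.2,
    bin_width_alpha: float = 5.0,
) -> OrientationMap:
    """Map of the water dipole angle alpha vs transverse position z.

    alpha is the angle between the water electric dipole (sum of q_i
    r_i, origin-independent for a neutral molecule) and the
    leaflet-signed outward normal (+z above the bilayer center, -z
    below); the histogram is normalized per z-slab.
    """
    top = traj.topology
    waters = top.waters
    if not waters:
        raise ValueError("no waters in topology")
    idx = np.array([[m.atom_index[a] for a in m.spec.atoms] for m in waters])  # (W, n_at)
    q = np.array([[m.spec.charges[a] for a in m.spec.atoms] for m in waters])
    if np.allclose(q, 0):
        raise ValueError("water model carries no charges: dipole undefined")
    zmax = max(f.box[2] for f in traj.frames) / 2.0
    n_z = int(np.ceil(2 * zmax / bin_width_z))
    z_edges = (np.arange(n_z + 1) - n_z / 2.0) * bin_width_z
    a_edges = np.arange(0.0, 180.0 + bin_width_alpha, bin_width_alpha)
    counts = np.zeros((n_z, len(a_edges) - 1))
    for frame in traj.frames:
        pos = frame.coords[idx]  # (W, n_at, 3)
        o = pos[:, :1, :]
        mu = np.sum(q[..., None] * (pos - o), axis=1)
        mu_norm = np.linalg.norm(mu, axis=-1)
        if np.any(mu_norm < 1e-12):
            raise ValueError("zero water dipole encountered")
        zc = frame.com_z()
        z = pos[:, 0, 2] - zc
        outward = np.where(z >= 0, 1.0, -1.0)
        cosa = np.clip(mu[:, 2] * outward / mu_norm, -1.0, 1.0)
        alpha = np.degrees(np.arccos(cosa))
        h, _, _ = np.histogram2d(z, alpha, bins=(z_edges, a_edges))
        counts += h
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(row > 0, counts / row, 0.0)
    return OrientationMap(z_edges=z_edges, alpha_edges=a_edges, prob=prob, counts=counts)


# ---------------------------------------------------------------------------
# electrostatic potential
# ---------------------------------------------------------------------------

def electrostatic_potential(charge_profile: ZProfile) -> tuple[np.ndarray, np.ndarray]:
    """Electrostatic potential phi(z) in volts from the charge density.

    Double integration of rho(z) (e/nm^3) outward from the bilayer
    center with phi(0) = 0:
    ``phi(z) = -(1/eps0) int_0^z dz' int_0^z' rho(z'') dz''``.
    Requires a net-neutral box (|Q| <= 1e-3 e).  Returns ``(z, phi)``.
    """
    if charge_profile.weighting != "charge":
        raise ValueError("electrostatic potential needs a charge-weighted profile")
    z = charge_profile.centers
    rho = charge_profile.values
    total = charge_profile.integral()
    if abs(total) > 1e-3:
        raise ValueError(f"net box charge {total:.3g} e: potential ill-defined")

    def _cum_from_zero(y):
        c = np.concatenate([[0.0], np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(z))])
        at0 = np.interp(0.0, z, c)
        return c - at0

    field_int = _cum_from_zero(rho)  # int_0^z rho
    phi_raw = _cum_from_zero(field_int)  # int_0^z int_0^z' rho
    phi = -_PHI_FACTOR * phi_raw
    return z, phi


# ---------------------------------------------------------------------------
# time correlation functions
# ---------------------------------------------------------------------------

def _weighted_autocorr(series: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """sum_t0 w[t0] * sum_i series[t0, i] * series[t0+t, i] via FFT."""
    f, m = series.shape
    n = 1 << int(np.ceil(np.log2(2 * f)))
    sw = series * weights[:, None]
    fa = np.fft.rfft(sw, n=n, axis=0)
    fb = np.fft.rfft(series, n=n, axis=0)
    corr = np.fft.irfft(np.conj(fa) * fb, n=n, axis=0)[:f]
    return corr.sum(axis=1)


def survival_correlation(occupancy: np.ndarray, dt: float, max_lag: int | None = None):
    """Intermittent survival correlation R(t) from a shell-occupancy matrix.

    ``R(t) = < (1/N0) sum_i P_i(t) >`` over time origins, with P_i = 1
    when water i is in the shell at both the origin and origin + t
    (absences between the endpoints allowed).  Origins with an empty
    shell are skipped.  R(0) = 1 exactly.
    """
    occ = np.asarray(occupancy, dtype=float)
    f = occ.shape[0]
    if max_lag is None:
        max_lag = f - 1
    n0 = occ.sum(axis=1)
    valid = n0 > 0
    if not np.any(valid):
        raise ValueError("shell is empty at every origin")
    w = np.where(valid, 1.0 / np.where(valid, n0, 1.0), 0.0)
    num = _weighted_autocorr(occ, w)
    n_origins = np.concatenate(
        [[valid.sum()], [valid[: f - t].sum() for t in range(1, max_lag + 1)]]
    ).astype(float)
    # numerator must also count only valid origins; w is zero there already,
    # so divide by the number of valid origins per lag
    denom = np.array([w[: f - t].astype(bool).sum() for t in range(0, max_lag + 1)], dtype=float)
    denom[denom == 0] = np.nan
    r = num[: max_lag + 1] / denom
    r[0] = 1.0  # P_i(0) = 1 by definition for every shell water
    lags = np.arange(max_lag + 1) * dt
    good = np.isfinite(r)
    return lags[good], r[good]


def p2_autocorrelation(vectors: np.ndarray, dt: float, max_lag: int | None = None):
    """C(t) = <P2(u(t0) . u(t0+t))> for unit-vector series (F, M, 3).

    Uses the tensor-product expansion of (u.v)^2 so the average is a
    sum of component autocorrelations, evaluated by FFT.
    """
    v = np.asarray(vectors, dtype=float)
    f, m, _ = v.shape
    if max_lag is None:
        max_lag = f - 1
    prods = np.stack(
        [
            v[..., 0] * v[..., 0],
            v[..., 1] * v[..., 1],
            v[..., 2] * v[..., 2],
            np.sqrt(2.0) * v[..., 0] * v[..., 1],
            np.sqrt(2.0) * v[..., 0] * v[..., 2],
            np.sqrt(2.0) * v[..., 1] * v[..., 2],
        ],
        axis=-1,
    )  # (F, M, 6)
    n = 1 << int(np.ceil(np.log2(2 * f)))
    fa = np.fft.rfft(prods, n=n, axis=0)
    corr = np.fft.irfft(np.abs(fa) ** 2, n=n, axis=0)[: max_lag + 1]
    total = corr.sum(axis=(1, 2))
    n_origins = (f - np.arange(max_lag + 1)) * m
    cos2 = total / n_origins
    c = 1.5 * cos2 - 0.5
    c[0] = 1.0  # theta(t0, t0) = 0 by definition, so P2 = 1 exactly
    lags = np.arange(max_lag + 1) * dt
    return lags, c


def fit_biexponential(lags: np.ndarray, values: np.ndarray):
    """Fit A0 exp(-t/tau0) + A1 exp(-t/tau1) with A0 + A1 = C(0).

    Nonlinear least squares with non-negative amplitudes and
    tau0 <= tau1, initialized from a two-segment log-linear fit.
    Returns ``(fit_dict, tau)`` with ``tau = A0 tau0 + A1 tau1`` (the
    analytic integral), or ``(None, None)`` when the fit fails.
    """
    t = np.asarray(lags, dtype=float)
    y = np.asarray(values, dtype=float)
    y0 = y[0]
    # fit only the resolvable head of the decay: once the signal falls
    # below a few percent of C(0) the tail is sampling noise
    pos = y > max(0.02 * abs(y0), 1e-12)
    if not pos[0]:
        return None, None
    stop = int(np.argmin(pos)) if not pos.all() else len(y)
    t_fit, y_fit = t[:stop], y[:stop]
    if len(t_fit) < 3:
        return None, None
    span = t_fit[-1] - t_fit[0]
    # init: log-linear on early and late halves
    half = max(len(t_fit) // 2, 2)

    def _slope(tt, yy):
        with np.errstate(divide="ignore"):
            ly = np.log(np.maximum(yy, 1e-300))
        a = np.polyfit(tt, ly, 1)
        return -1.0 / a[0] if a[0] < 0 else None

    tau_fast = _slope(t_fit[1: half + 1], y_fit[1: half + 1]) or (t_fit[-1] / 4 + 1e-9)
    tau_slow = _slope(t_fit[half:], y_fit[half:]) or tau_fast * 4
    tau_fast = max(tau_fast, 1e-6)
    tau_slow = max(tau_slow, tau_fast)

    def model(tt, frac, tau0, dtau):
        return y0 * (frac * np.exp(-tt / tau0) + (1 - frac) * np.exp(-tt / (tau0 + dtau)))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # time constants slower than ~5x the fitted span are not
            # resolvable and would inflate the analytic integral
            tau_cap = 5.0 * max(span, t[1] - t[0])
            popt, _ = curve_fit(
                model,
                t_fit,
                y_fit,
                p0=[0.7, min(tau_fast, tau_cap), np.clip(tau_slow - tau_fast, 1e-6, tau_cap / 2)],
                bounds=([0.0, 1e-9, 0.0], [1.0, tau_cap, tau_cap]),
                maxfev=20000,
            )
    except (RuntimeError, ValueError):
        return None, None
    frac, tau0, dtau = popt
    a0 = y0 * frac
    a1 = y0 * (1 - frac)
    tau1 = tau0 + dtau
    fit = {"A0": float(a0), "tau0": float(tau0), "A1": float(a1), "tau1": float(tau1)}
    tau = a0 * tau0 + a1 * tau1
    return fit, float(tau)


def _series_from_fit(lags, values, label: str) -> CorrelationSeries:
    fit, tau = fit_biexponential(lags, values)
    integral = float(np.trapezoid(values, lags))
    series = CorrelationSeries(
        lags=lags, values=values, fit=fit, tau=tau, integral=integral
    )
    if fit is None:
        series.warnings.append(
            f"{label}: bi-exponential fit failed; reporting the trapezoidal integral"
        )
        series.tau = None
        warnings.warn(series.warnings[-1], stacklevel=3)
    return series


def residence_time(
    traj: Trajectory,
    shell: float = 0.45,
    reference: str = "anion_center",
    max_lag: int | None = None,
) -> CorrelationSeries:
    """Interfacial water residence time from the shell survival correlation.

    A water counts as interfacial when its oxygen is within ``shell``
    (nm, default the first solvation shell 0.45) of any reference atom
    (phosphorus for PC, sulfur for IPA: the ``anion_center`` role).
    R(t) uses the intermittent definition and is fitted bi-exponentially;
    tau = A0 tau0 + A1 tau1.
    """
    top = traj.topology
    waters = top.waters
    if not waters:
        raise ValueError("no waters in topology")
    if traj.n_frames < 100:
        warnings.warn("fewer than 100 frames: residence statistics will be poor", stacklevel=2)
    if traj.dt is None:
        raise ValueError("residence time needs a multi-frame trajectory with dt")
    ref_idx = top.select_atoms(reference)
    if ref_idx.size == 0:
        raise ValueError(f"no reference atoms for selector {reference!r}")
    o_idx = np.array([m.atom_index[m.spec.atoms[0]] for m in waters])
    occ = np.zeros((traj.n_frames, len(waters)), dtype=bool)
    for fi, frame in enumerate(traj.frames):
        box = frame.box
        tree = cKDTree(_wrap(frame.coords[ref_idx], box), boxsize=box)
        d, _ = tree.query(_wrap(frame.coords[o_idx], box), k=1)
        occ[fi] = d <= shell
    if occ.all():
        raise ValueError("waters never leave the shell: residence time diverges")
    lags, r = survival_correlation(occ, traj.dt, max_lag=max_lag)
    return _series_from_fit(lags, r, "residence")


def rotational_relaxation(
    traj: Trajectory,
    vector: str = "water_dipole",
    max_lag: int | None = None,
) -> CorrelationSeries:
    """Rotational relaxation time of a molecular vector.

    ``vector`` is ``water_dipole``, ``directive`` (all chain directive
    vectors) or ``PN`` (anion-center to cation-center head vector).
    C(t) is the second-Legendre autocorrelation averaged over origins
    and molecules, fitted bi-exponentially; tau_relax = A0' tau0' +
    A1' tau1'.
    """
    if traj.dt is None:
        raise ValueError("rotational relaxation needs a multi-frame trajectory with dt")
    top = traj.topology
    if vector == "water_dipole":
        waters = top.waters
        if not waters:
            raise ValueError("no waters in topology")
        idx = np.array([[m.atom_index[a] for a in m.spec.atoms] for m in waters])
        q = np.array([[m.spec.charges[a] for a in m.spec.atoms] for m in waters])
        vecs = np.empty((traj.n_frames, len(waters), 3))
        for fi, frame in enumerate(traj.frames):
            pos = frame.coords[idx]
            mu = np.sum(q[..., None] * (pos - pos[:, :1, :]), axis=1)
            vecs[fi] = mu / np.linalg.norm(mu, axis=-1, keepdims=True)
    elif vector == "directive":
        from .core import directive_vectors

        first, *_ = directive_vectors(traj.frames[0])
        vecs = np.empty((traj.n_frames, first.shape[0], 3))
        for fi, frame in enumerate(traj.frames):
            vecs[fi] = directive_vectors(frame)[0]
    elif vector == "PN":
        cat = top.head_index("cation_center")
        an = top.head_index("anion_center")
        vecs = np.empty((traj.n_frames, len(cat), 3))
        for fi, frame in enumerate(traj.frames):
            d = minimum_image(frame.coords[cat] - frame.coords[an], frame.box)
            vecs[fi] = d / np.linalg.norm(d, axis=-1, keepdims=True)
    else:
        raise ValueError(f"unknown vector selector {vector!r}")
    lags, c = p2_autocorrelation(vecs, traj.dt, max_lag=max_lag)
    return _series_from_fit(lags, c, "rotation")
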