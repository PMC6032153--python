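"""Synthetic bilayer trajectories with known ground truth.

Every estimator in this package is verified by parameter recovery: the
generators here draw data from models whose parameters (area
compressibility, tilt/splay stiffness, gauche fractions, order
parameters, residence and rotational times, two-state melting
thermodynamics, charge-sheet geometry) are recorded in a
:class:`GroundTruth` sidecar, and the analysis modules must recover
them within stated tolerances.

The default bilayer emulates a gel-like (S phase) membrane: 64
molecules per leaflet, all-trans tilted chains with a sin-Jacobian
Boltzmann tilt distribution, Gaussian lateral-area fluctuations, +/-
charge sheets in each head region, and a hydrating water slab with
Markovian first-shell exchange and rotational dipole diffusion.  All
generators are reproducible: the same seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .annotations import MoleculeSpec, synthetic_amphiphile_spec, _water_spec
from .core import BilayerFrame, Molecule, Topology, Trajectory, UPPER, LOWER
from .mechanics import AngleSamples, _weighted_quadratic

log = logging.getLogger("memprops")

KB_J = 1.380649e-23  # J/K
KB_KJ_MOL = 8.314462618e-3  # kJ/mol/K
E_CHARGE = 1.602176634e-19  # C
EPS0 = 8.8541878128e-12  # F/m
# potential of a charge double sheet: sigma[e/nm^2] * d[nm] * this = volts
SHEET_PHI_V = E_CHARGE * 1e9 / EPS0

_CC_BOND = 0.153  # nm
_CH_BOND = 0.109  # nm
_TETRA = np.arccos(-1.0 / 3.0)  # ideal tetrahedral angle

__all__ = [
    "GroundTruth",
    "gen_area_series",
    "gen_angle_samples",
    "gen_chain",
    "gen_bilayer",
    "gen_enthalpy_replicas",
    "gen_shell_occupancy",
    "gen_rotating_vectors",
    "tilt_density_moments",
    "analytic_splay_modulus",
]


@dataclass
class GroundTruth:
    """True parameter values embedded in every generated dataset."""

    ka_true: float | None = None  # mN/m
    a0_true: float | None = None  # nm^2
    chi_tilt_true: float | None = None  # kBT/rad^2
    theta0_true: float | None = None  # rad
    chi_splay_true: dict | None = None  # per pair type, kBT/rad^2
    gauche_fraction_true: list | None = None  # per dihedral position
    scd_true: list | None = None  # per carbon, signed
    tau_res_true: float | None = None  # ps
    dr_true: float | None = None  # rad^2/ps
    tau_rot_true: float | None = None  # ps, = 1/(6 Dr)
    two_state: dict | None = None  # {deltaH kJ/mol, Tm K}
    sheet_charge: dict | None = None  # {sigma e/nm^2, separation nm, delta_phi V}
    leaflet_labels: list | None = None  # per molecule, +1 upper / -1 lower
    thickness_true: float | None = None  # nm (head-sheet separation)
    tilt_mean_true: float | None = None  # rad
    temperature: float | None = None  # K
    surface_alpha_true: float | None = None  # rad, oriented shell waters
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("ka_true", "chi_tilt_true", "tau_res_true", "dr_true"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.gauche_fraction_true is not None:
            g = np.asarray(self.gauche_fraction_true, dtype=float)
            if np.any((g < 0) | (g > 1)):
                raise ValueError("gauche fractions must lie in [0, 1]")
        if self.scd_true is not None:
            s = np.asarray(self.scd_true, dtype=float)
            if np.any(np.abs(s) > 0.5 + 1e-12):
                raise ValueError("|SCD| cannot exceed 0.5")

    def to_json(self, path) -> None:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            return v

        with open(path, "w") as fh:
            json.dump({k: _clean(v) for k, v in dataclasses.asdict(self).items()}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# area fluctuations
# ---------------------------------------------------------------------------

def gen_area_series(
    ka_true: float,
    a0: float,
    n_molecules: int,
    temperature: float,
    n_frames: int,
    seed: int = 0,
):
    """i.i.d. Gaussian molecular-area series consistent with a target KA.

    The linear-response relation fixes the variance:
    ``Var(Amol) = kB T A0 / (N KA)`` with KA in mN/m, areas in nm^2.
    Returns ``(areas, GroundTruth)``.
    """
    if ka_true <= 0:
        raise ValueError("ka_true must be positive")
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    ka_j_nm2 = ka_true * 1e-21  # mN/m -> J/nm^2
    var = KB_J * temperature * a0 / (n_molecules * ka_j_nm2)
    rng = np.random.default_rng(seed)
    areas = rng.normal(a0, np.sqrt(var), size=n_frames)
    truth = GroundTruth(
        ka_true=ka_true, a0_true=a0, temperature=temperature, seed=seed,
        extras={"var_area_nm4": var, "n_molecules": n_molecules},
    )
    return areas, truth


# ---------------------------------------------------------------------------
# tilt/splay angle sampling and analytic moments
# ---------------------------------------------------------------------------

def _tilt_density(theta, chi, theta0, jacobian=True):
    """Unnormalized P(theta) on [0, pi]."""
    w = np.exp(-0.5 * chi * (theta - theta0) ** 2)
    return np.sin(theta) * w if jacobian else w


def gen_angle_samples(
    chi: float,
    theta0: float,
    n: int,
    seed: int = 0,
    jacobian: bool = True,
    temperature: float | None = None,
) -> AngleSamples:
    """Draw angles from ``P(theta) ~ sin(theta) exp(-chi/2 (theta-theta0)^2)``.

    Exact rejection sampling on [0, pi] with a uniform proposal under a
    grid-evaluated envelope (the density is bounded and smooth, so the
    envelope is its maximum times a small safety factor).  With
    ``jacobian=False`` the sin factor is dropped (truncated Gaussian).
    """
    if chi < 0:
        raise ValueError("chi must be non-negative")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, np.pi, 4096)
    env = _tilt_density(grid, chi, theta0, jacobian).max() * 1.0001
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(int((n - filled) * 1.8) + 64, 256)
        cand = rng.uniform(0.0, np.pi, size=m)
        keep = rng.uniform(0.0, env, size=m) < _tilt_density(cand, chi, theta0, jacobian)
        take = min(int(keep.sum()), n - filled)
        out[filled: filled + take] = cand[keep][:take]
        filled += take
    return AngleSamples(out, temperature=temperature, kind="tilt")


def _legendre_table(x: np.ndarray, l_max: int) -> np.ndarray:
    """P_l(x) for l = 0..l_max by upward recurrence; shape (l_max+1, len(x))."""
    out = np.empty((l_max + 1, len(x)))
    out[0] = 1.0
    if l_max >= 1:
        out[1] = x
    for l in range(2, l_max + 1):
        out[l] = ((2 * l - 1) * x * out[l - 1] - (l - 1) * out[l - 2]) / l
    return out


def tilt_density_moments(
    chi: float,
    theta0: float,
    l_max: int = 0,
    jacobian: bool = True,
    window: tuple[float, float] | None = None,
):
    """Numeric moments of the tilt density: mean angle and <P_l(cos theta)>.

    ``window`` restricts the density to [lo, hi] (renormalized), used
    for gated ensembles.  Returns ``(mean_theta, [<P_0>, ...,
    <P_l_max>])`` by quadrature on a fine grid (independent of any
    sampling).
    """
    theta = np.linspace(0.0, np.pi, 20001)
    p = _tilt_density(theta, chi, theta0, jacobian)
    if window is not None:
        p = np.where((theta >= window[0]) & (theta <= window[1]), p, 0.0)
    norm = np.trapezoid(p, theta)
    mean = np.trapezoid(theta * p, theta) / norm
    pl = _legendre_table(np.cos(theta), max(l_max, 1))
    moments = [float(np.trapezoid(pl[l] * p, theta) / norm) for l in range(l_max + 1)]
    return float(mean), moments


def analytic_splay_modulus(
    chi: float,
    theta0: float,
    fit_max: float = np.radians(40.0),
    l_max: int = 200,
    gate_sigma: float | None = None,
) -> float:
    """Splay stiffness implied by an i.i.d. axially symmetric tilt field.

    For two independent directors drawn from the tilt density with
    uniform azimuths, the density of their mutual angle gamma follows
    from the Legendre expansion ``f(cos g) = sum_l (2l+1)/2 <P_l>_1
    <P_l>_2 P_l(cos g)``.  With ``gate_sigma`` set, the pair ensemble
    is conditioned the way the splay collector gates pairs - at least
    one member's tilt within the density mode +/- gate_sigma - via the
    exact mixture of (gated, free) and (gated, gated) pair densities.
    The quadratic coefficient of ``-ln f(cos g)`` over (0, fit_max],
    weighted like the histogram estimator, defines the analytic
    chi_ij.  Purely numeric - no sampling, no shared code path with
    the estimator.
    """
    _, free = tilt_density_moments(chi, theta0, l_max=l_max)
    free = np.asarray(free)
    g = np.linspace(1e-4, fit_max, 2000)
    pl_g = _legendre_table(np.cos(g), l_max)
    weights_l = (2 * np.arange(l_max + 1) + 1) / 2.0
    if gate_sigma is None:
        f = (weights_l * free * free) @ pl_g
    else:
        # condition on "at least one member gated" via the complement:
        # f_union = [f_free,free - (1-q)^2 f_out,out] / (1 - (1-q)^2)
        theta = np.linspace(0.0, np.pi, 20001)
        dens = _tilt_density(theta, chi, theta0, True)
        mode = theta[int(np.argmax(dens))]
        lo, hi = max(mode - gate_sigma, 0.0), min(mode + gate_sigma, np.pi)
        inside = (theta >= lo) & (theta <= hi)
        q = np.trapezoid(np.where(inside, dens, 0.0), theta) / np.trapezoid(dens, theta)
        p_out = np.where(inside, 0.0, dens)
        norm_out = np.trapezoid(p_out, theta)
        pl_t = _legendre_table(np.cos(theta), l_max)
        outside = np.array(
            [np.trapezoid(pl_t[l] * p_out, theta) / norm_out for l in range(l_max + 1)]
        )
        f_ff = (weights_l * free * free) @ pl_g
        f_oo = (weights_l * outside * outside) @ pl_g
        f = (f_ff - (1 - q) ** 2 * f_oo) / (1.0 - (1 - q) ** 2)
    f = np.maximum(f, 1e-300)
    big_f = -np.log(f)
    big_f -= big_f.min()
    fit_weights = f * np.sin(g)  # counts-like weighting of the estimator's fit
    coef, _ = _weighted_quadratic(g, big_f, fit_weights, constrained=True)
    return float(2.0 * coef[-1])


# ---------------------------------------------------------------------------
# alkyl chain construction (internal-coordinate build)
# ---------------------------------------------------------------------------

def _nerf(a, b, c, bond, angle, dihedral):
    """Place the next atom from three predecessors and internal coordinates.

    Vectorized over leading dimensions; ``dihedral`` may be an array.
    """
    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    d = np.stack(
        [
            -bond * np.cos(angle) * np.ones_like(dihedral),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ],
        axis=-1,
    )
    return c + d[..., :1] * bc + d[..., 1:2] * m + d[..., 2:3] * n


def _build_chains(dihedrals: np.ndarray) -> np.ndarray:
    """Build (B, n, 3) all-carbon chains from (B, n-3) dihedral arrays (rad).

    The canonical chain runs along +z with ideal tetrahedral backbone
    angles; virtual neighbors beyond both termini are appended
    internally for hydrogen placement (returned array has n+2 rows:
    [virtual0, C1..Cn, virtualN]).
    """
    b, n_dih = dihedrals.shape
    n = n_dih + 3
    half = 0.5 * (np.pi - _TETRA)
    pos = np.zeros((b, n + 2, 3))
    # rows 1..n are C1..Cn
    pos[:, 1] = 0.0
    pos[:, 2] = [_CC_BOND * np.sin(half), 0.0, _CC_BOND * np.cos(half)]
    pos[:, 3] = pos[:, 2] + [-_CC_BOND * np.sin(half), 0.0, _CC_BOND * np.cos(half)]
    for k in range(n_dih):
        pos[:, 4 + k] = _nerf(
            pos[:, 1 + k], pos[:, 2 + k], pos[:, 3 + k], _CC_BOND, _TETRA, dihedrals[:, k]
        )
    trans = np.full((b,), np.pi)
    pos[:, 0] = _nerf(pos[:, 3], pos[:, 2], pos[:, 1], _CC_BOND, _TETRA, trans)
    pos[:, n + 1] = _nerf(pos[:, n - 2], pos[:, n - 1], pos[:, n], _CC_BOND, _TETRA, trans)
    return pos


def _place_hydrogens(chain_ext: np.ndarray) -> np.ndarray:
    """Two tetrahedral hydrogens per carbon from the extended chain.

    ``chain_ext`` is (B, n+2, 3) including the virtual terminus
    neighbors; every carbon (including termini) gets the methylene-style
    pair so an all-trans chain has every C-H exactly perpendicular to
    the chain axis.  Returns (B, n, 2, 3).
    """
    c = chain_ext[:, 1:-1]
    prev = chain_ext[:, :-2]
    nxt = chain_ext[:, 2:]
    e1 = prev - c
    e1 /= np.linalg.norm(e1, axis=-1, keepdims=True)
    e2 = nxt - c
    e2 /= np.linalg.norm(e2, axis=-1, keepdims=True)
    u = -(e1 + e2)
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    w = np.cross(e1, e2)
    w /= np.linalg.norm(w, axis=-1, keepdims=True)
    alpha, beta = 1.0 / np.sqrt(3.0), np.sqrt(2.0 / 3.0)
    h1 = c + _CH_BOND * (alpha * u + beta * w)
    h2 = c + _CH_BOND * (alpha * u - beta * w)
    return np.stack([h1, h2], axis=2)


def _align_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrices taking unit vectors a onto unit vectors b (batched)."""
    v = np.cross(a, b)
    c = np.sum(a * b, axis=-1)
    s2 = np.sum(v * v, axis=-1)
    eye = np.broadcast_to(np.eye(3), (*a.shape[:-1], 3, 3)).copy()
    ok = s2 > 1e-18
    vx = np.zeros((*a.shape[:-1], 3, 3))
    vx[..., 0, 1], vx[..., 0, 2] = -v[..., 2], v[..., 1]
    vx[..., 1, 0], vx[..., 1, 2] = v[..., 2], -v[..., 0]
    vx[..., 2, 0], vx[..., 2, 1] = -v[..., 1], v[..., 0]
    fac = np.where(ok, (1.0 - c) / np.where(ok, s2, 1.0), 0.0)
    rot = eye + vx + fac[..., None, None] * (vx @ vx)
    # anti-parallel: rotate 180 degrees about any perpendicular axis
    anti = (~ok) & (c < 0)
    if np.any(anti):
        idx = np.argwhere(anti)
        for i in idx:
            aa = a[tuple(i)]
            perp = np.cross(aa, [1.0, 0.0, 0.0])
            if np.linalg.norm(perp) < 1e-9:
                perp = np.cross(aa, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            rot[tuple(i)] = Rotation.from_rotvec(np.pi * perp).as_matrix()
    return rot


def _batch_chains(
    n_carbons: int,
    gauche_mask: np.ndarray,
    tilt: np.ndarray,
    azimuth: np.ndarray,
    spin: np.ndarray,
    gauche_sign: np.ndarray,
    leaflet: np.ndarray,
):
    """Oriented chains + hydrogens for a batch of molecules.

    tilt is measured from the leaflet-signed normal (-z for the upper
    leaflet), so chains point toward the bilayer center.  Returns
    ``(carbons (B,n,3), hydrogens (B,n,2,3))`` with C1 at the origin.
    """
    b = len(tilt)
    dihedrals = np.where(gauche_mask, gauche_sign * np.radians(60.0), np.pi)
    ext = _build_chains(dihedrals)
    carbons = ext[:, 1:-1]
    axis = carbons[:, n_carbons - 2] - carbons[:, 0]
    axis /= np.linalg.norm(axis, axis=-1, keepdims=True)
    # spin about the chain axis, then align the axis to the target direction
    spin_rot = Rotation.from_rotvec(axis * spin[:, None]).as_matrix()
    sign = np.where(leaflet == UPPER, -1.0, 1.0)
    target = np.stack(
        [
            np.sin(tilt) * np.cos(azimuth),
            np.sin(tilt) * np.sin(azimuth),
            sign * np.cos(tilt),
        ],
        axis=-1,
    )
    align = _align_rotation(axis, target)
    rot = align @ spin_rot
    origin = ext[:, 1:2]
    ext_rot = np.einsum("bij,bkj->bki", rot, ext - origin)
    carbons = ext_rot[:, 1:-1]
    hydrogens = _place_hydrogens(ext_rot)
    return carbons, hydrogens


def gen_chain(
    n_carbons: int,
    gauche_mask=None,
    tilt: float = 0.0,
    seed: int = 0,
    leaflet: int = UPPER,
    azimuth: float | None = None,
):
    """One amphiphile chain with ideal-geometry hydrogens.

    Dihedrals are 180 deg (trans) where the mask is False and +/-60 deg
    (gauche, random sign) where True; the chain axis is tilted by
    ``tilt`` radians from the leaflet-signed bilayer normal.  Returns
    ``(carbons (n,3), hydrogens (n,2,3))`` in nm with C1 at the origin.
    """
    if n_carbons < 4:
        raise ValueError("chains need at least 4 carbons")
    if gauche_mask is None:
        gauche_mask = np.zeros(n_carbons - 3, dtype=bool)
    gauche_mask = np.asarray(gauche_mask, dtype=bool)
    if gauche_mask.shape != (n_carbons - 3,):
        raise ValueError(
            f"gauche mask must have length n_carbons-3 = {n_carbons - 3}, got {gauche_mask.shape}"
        )
    rng = np.random.default_rng(seed)
    az = rng.uniform(0, 2 * np.pi) if azimuth is None else azimuth
    signs = rng.choice([-1.0, 1.0], size=(1, n_carbons - 3))
    carbons, hydrogens = _batch_chains(
        n_carbons,
        gauche_mask[None, :],
        np.array([tilt]),
        np.array([az]),
        np.array([0.0]),
        signs,
        np.array([leaflet]),
    )
    return carbons[0], hydrogens[0]


# ---------------------------------------------------------------------------
# water dynamics helpers
# ---------------------------------------------------------------------------

def gen_shell_occupancy(
    tau: float,
    n_waters: int,
    n_frames: int,
    dt: float,
    seed: int = 0,
    n_shell: int | None = None,
    recycle_delay_factor: float = 6.0,
) -> np.ndarray:
    """Boolean shell-occupancy matrix (frames x waters), Markov escape.

    Occupied waters leave with per-frame probability
    ``1 - exp(-dt/tau)``, so the survival correlation from any origin
    is exactly ``exp(-t/tau)`` on the frame grid for lags shorter than
    the re-entry delay.  With ``n_shell`` unset every water starts in
    the shell and never returns (pure death process); with ``n_shell``
    set the shell population is held stationary by re-admitting waters
    that have been out for at least ``recycle_delay_factor * tau`` -
    long enough that re-entries cannot contaminate the usable lag
    range.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = np.random.default_rng(seed)
    p = 1.0 - np.exp(-dt / tau)
    occ = np.zeros((n_frames, n_waters), dtype=bool)
    if n_shell is None:
        alive = np.ones(n_waters, dtype=bool)
        occ[0] = True
        for f in range(1, n_frames):
            alive &= rng.random(n_waters) >= p
            occ[f] = alive
        return occ
    if n_shell > n_waters:
        raise ValueError("n_shell cannot exceed n_waters")
    delay = int(np.ceil(recycle_delay_factor * tau / dt))
    in_shell = np.zeros(n_waters, dtype=bool)
    in_shell[:n_shell] = True
    t_left = np.full(n_waters, -10 * delay)
    occ[0] = in_shell
    for f in range(1, n_frames):
        esc = in_shell & (rng.random(n_waters) < p)
        in_shell[esc] = False
        t_left[esc] = f
        deficit = n_shell - int(in_shell.sum())
        if deficit > 0:
            eligible = np.flatnonzero(~in_shell & (t_left <= f - delay))
            in_shell[eligible[:deficit]] = True
        occ[f] = in_shell
    return occ


def gen_rotating_vectors(
    dr: float,
    n_vectors: int,
    n_frames: int,
    dt: float,
    seed: int = 0,
) -> np.ndarray:
    """Unit vectors under isotropic rotational diffusion Dr (rad^2/ps).

    The second-Legendre autocorrelation of the output decays as
    ``exp(-6 Dr t)``.  Returns an (n_frames, n_vectors, 3) array.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_vectors, 3))
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    out = np.empty((n_frames, n_vectors, 3))
    out[0] = v
    sigma = np.sqrt(2.0 * dr * dt)
    for f in range(1, n_frames):
        rot = Rotation.from_rotvec(rng.normal(scale=sigma, size=(n_vectors, 3)))
        v = rot.apply(v)
        out[f] = v
    return out


# ---------------------------------------------------------------------------
# full bilayer generator
# ---------------------------------------------------------------------------

# TIP3-style rigid water in its body frame: O at origin, dipole along +z
_W_OH = 0.09572
_W_HALF = np.radians(104.52 / 2.0)
_WATER_BODY = np.array(
    [
        [0.0, 0.0, 0.0],
        [_W_OH * np.sin(_W_HALF), 0.0, _W_OH * np.cos(_W_HALF)],
        [-_W_OH * np.sin(_W_HALF), 0.0, _W_OH * np.cos(_W_HALF)],
    ]
)


def gen_bilayer(
    n_per_leaflet: int = 64,
    n_frames: int = 500,
    seed: int = 0,
    *,
    n_carbons: int = 12,
    ka_true: float = 1200.0,  # mN/m (gel-like)
    a0: float = 0.45,  # nm^2 per molecule
    temperature: float = 288.0,  # K
    chi_tilt: float = 30.0,  # kBT/rad^2
    theta0: float = np.radians(20.0),
    gauche_p: float = 0.0,
    head_sep: float = 3.8,  # nm between the two cation-center sheets
    charge_sep: float = 0.2,  # nm between + and - sheets within a leaflet
    z_noise: float = 0.03,  # nm rigid per-molecule z jitter
    n_waters: int = 512,
    n_shell: int = 64,
    tau_res: float = 50.0,  # ps
    dr: float = 0.002,  # rad^2/ps
    surface_alpha: float | None = None,  # rad; oriented shell waters if set
    dt: float = 10.0,  # ps
    spec: MoleculeSpec | None = None,
    water_spec: MoleculeSpec | None = None,
):
    """Generate a synthetic two-leaflet trajectory plus its ground truth.

    Geometry: amphiphiles on a jittered grid in each leaflet, head
    cation centers (+1 e) on sheets at +/- head_sep/2, anion centers
    (-1 e) ``charge_sep`` below them, all-trans (or Bernoulli-gauche)
    chains pointing inward with tilts drawn from the sin-Jacobian
    Boltzmann density.  The lateral box follows Gaussian area
    fluctuations set by ``ka_true``.  Waters form a first shell (within
    0.45 nm of the anion centers) exchanging with the bulk by a Markov
    escape process of mean residence ``tau_res``; re-entry is delayed
    by at least 6 tau_res so the survival correlation stays a clean
    exponential over the usable lag range.  Water dipoles undergo
    isotropic rotational diffusion ``dr``.

    Returns ``(Trajectory, GroundTruth)``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    if spec is None:
        spec = synthetic_amphiphile_spec(n_carbons)
    if water_spec is None:
        water_spec = _water_spec("SOL", "OW", ("HW1", "HW2"))
    if n_shell > n_waters:
        raise ValueError("n_shell cannot exceed n_waters")
    rng = np.random.default_rng(seed)
    n_mol = 2 * n_per_leaflet

    # --- lateral geometry -------------------------------------------------
    areas, _ = gen_area_series(
        ka_true, a0, n_per_leaflet, temperature, n_frames, seed=int(rng.integers(2**31))
    )
    grid = int(np.ceil(np.sqrt(n_per_leaflet)))
    if a0 * n_per_leaflet / grid**2 < 0.2:
        raise ValueError("requested area per molecule too small for overlap-free packing")
    cells = np.stack(np.meshgrid(np.arange(grid), np.arange(grid), indexing="ij"), axis=-1)
    cells = cells.reshape(-1, 2)[:n_per_leaflet]
    frac = np.concatenate([cells, cells], axis=0).astype(float)  # upper then lower
    frac += 0.5 + rng.uniform(-0.15, 0.15, size=frac.shape)
    frac /= grid
    lz = head_sep + 4.0

    leaflet = np.concatenate(
        [np.full(n_per_leaflet, UPPER), np.full(n_per_leaflet, LOWER)]
    )
    sign = np.where(leaflet == UPPER, 1.0, -1.0)

    # --- per-molecule per-frame chain parameters -------------------------
    tilt_seed = int(rng.integers(2**31))
    tilts = gen_angle_samples(chi_tilt, theta0, n_frames * n_mol, seed=tilt_seed).angles
    tilts = tilts.reshape(n_frames, n_mol)
    azimuths = rng.uniform(0, 2 * np.pi, size=(n_frames, n_mol))
    spins = rng.uniform(0, 2 * np.pi, size=(n_frames, n_mol))
    n_dih = n_carbons - 3
    gauche_mask = rng.random(size=(n_frames, n_mol, n_dih)) < gauche_p
    gauche_sign = rng.choice([-1.0, 1.0], size=(n_frames, n_mol, n_dih))
    z_jitter = rng.normal(scale=z_noise, size=(n_frames, n_mol))

    # --- water bookkeeping ------------------------------------------------
    p_esc = 1.0 - np.exp(-dt / tau_res)
    delay_frames = int(np.ceil(6.0 * tau_res / dt))
    in_shell = np.zeros(n_waters, dtype=bool)
    in_shell[:n_shell] = True
    t_left = np.full(n_waters, -10 * delay_frames)  # long ago -> immediately eligible
    anchor = np.full(n_waters, -1)
    offsets = np.zeros((n_waters, 3))
    bulk_frac_xy = rng.uniform(0, 1, size=(n_waters, 2))
    bulk_z = np.empty(n_waters)

    anion_sheet = sign * (head_sep / 2.0 - charge_sep)
    bulk_lo = head_sep / 2.0 + 0.6
    bulk_hi = lz / 2.0 - 0.3

    def _draw_bulk_z(k):
        s = rng.choice([-1.0, 1.0], size=k)
        return s * rng.uniform(bulk_lo, bulk_hi, size=k)

    bulk_z[:] = _draw_bulk_z(n_waters)

    def _draw_offsets(k, side_sign):
        # anchored offsets: radial 0.26-0.42 nm, biased outward in z
        u = rng.normal(size=(k, 3))
        u[:, 2] = np.abs(u[:, 2]) * side_sign
        u /= np.linalg.norm(u, axis=-1, keepdims=True)
        r = rng.uniform(0.26, 0.42, size=(k, 1))
        return u * r

    init_anchor = rng.integers(0, n_mol, size=n_shell)
    anchor[:n_shell] = init_anchor
    offsets[:n_shell] = _draw_offsets(n_shell, sign[init_anchor])

    # water orientations evolve by rotational diffusion
    quat = (
        Rotation.random(n_waters, random_state=np.random.RandomState(seed + 17))
        if n_waters
        else None
    )
    sigma_rot = np.sqrt(2.0 * dr * dt)

    # --- topology ---------------------------------------------------------
    molecules: list[Molecule] = []
    idx = 0
    for i in range(n_mol):
        amap = {}
        for name in spec.atoms:
            amap[name] = idx
            idx += 1
        molecules.append(Molecule(i, spec, amap))
    water_atom0 = idx
    for j in range(n_waters):
        amap = {}
        for name in water_spec.atoms:
            amap[name] = idx
            idx += 1
        molecules.append(Molecule(n_mol + j, water_spec, amap))
    top = Topology(molecules, n_atoms=idx)

    n_idx = top.name_index(spec.name, spec.head_atoms["cation_center"])
    s_idx = top.name_index(spec.name, spec.head_atoms["anion_center"])
    c_idx = np.stack([top.name_index(spec.name, c) for c in spec.chain_defs["chain"]], axis=1)
    h_idx = np.stack(
        [
            np.stack([top.name_index(spec.name, h) for h in spec.chain_hydrogens[c]], axis=1)
            for c in spec.chain_defs["chain"]
        ],
        axis=1,
    )  # (n_mol, n_carbons, 2)

    frames: list[BilayerFrame] = []
    center = lz / 2.0
    z_head = sign * (head_sep / 2.0)
    z_anion = anion_sheet
    z_c1 = sign * (head_sep / 2.0 - charge_sep - 0.15)

    for f in range(n_frames):
        lbox = np.sqrt(max(areas[f], 0.05) * n_per_leaflet)
        box = np.array([lbox, lbox, lz])
        coords = np.zeros((idx, 3))
        xy = frac * lbox

        carbons, hydrogens = _batch_chains(
            n_carbons,
            gauche_mask[f],
            tilts[f],
            azimuths[f],
            spins[f],
            gauche_sign[f],
            leaflet,
        )
        zj = z_jitter[f]
        base = np.stack([xy[:, 0], xy[:, 1], z_c1 + zj], axis=-1)
        coords[c_idx.ravel()] = (carbons + base[:, None, :]).reshape(-1, 3)
        coords[h_idx.reshape(-1)] = (hydrogens + base[:, None, None, :]).reshape(-1, 3)
        coords[n_idx] = np.stack([xy[:, 0], xy[:, 1], z_head + zj], axis=-1)
        coords[s_idx] = np.stack([xy[:, 0], xy[:, 1], z_anion + zj], axis=-1)

        # --- waters -------------------------------------------------------
        if f > 0 and n_waters:
            # escapes
            esc = in_shell & (rng.random(n_waters) < p_esc)
            if np.any(esc):
                in_shell[esc] = False
                t_left[esc] = f
                k = int(esc.sum())
                bulk_frac_xy[esc] = rng.uniform(0, 1, size=(k, 2))
                bulk_z[esc] = _draw_bulk_z(k)
            # delayed re-entry to keep the shell population stationary
            deficit = n_shell - int(in_shell.sum())
            if deficit > 0:
                eligible = np.flatnonzero(~in_shell & (t_left <= f - delay_frames))
                if eligible.size:
                    take = eligible[:deficit]
                    in_shell[take] = True
                    a = rng.integers(0, n_mol, size=take.size)
                    anchor[take] = a
                    offsets[take] = _draw_offsets(take.size, sign[a])
            # rotational diffusion step for all waters
            step = Rotation.from_rotvec(rng.normal(scale=sigma_rot, size=(n_waters, 3)))
            quat = step * quat

        if n_waters:
            o_pos = np.empty((n_waters, 3))
            sh = in_shell
            if np.any(sh):
                o_pos[sh] = coords[s_idx[anchor[sh]]] + offsets[sh]
            bk = ~sh
            o_pos[bk, 0] = bulk_frac_xy[bk, 0] * lbox
            o_pos[bk, 1] = bulk_frac_xy[bk, 1] * lbox
            o_pos[bk, 2] = bulk_z[bk]
            mats = quat.as_matrix()
            if surface_alpha is not None and np.any(sh):
                # oriented surface waters: dipole at surface_alpha from the
                # outward normal, independent of the diffusive field
                k = int(sh.sum())
                side = np.sign(o_pos[sh, 2] + 1e-12)
                psi = rng.uniform(0, 2 * np.pi, size=k)
                jitterang = rng.normal(scale=np.radians(3.0), size=k)
                mats_sh = np.empty((k, 3, 3))
                for w, (sd, ps, ja) in enumerate(zip(side, psi, jitterang)):
                    tiltm = Rotation.from_euler(
                        "zyz", [ps, surface_alpha + ja, 0.0]
                    ).as_matrix()
                    flip = np.eye(3) if sd > 0 else Rotation.from_euler("x", np.pi).as_matrix()
                    mats_sh[w] = flip @ tiltm
                mats[sh] = mats_sh
            watoms = o_pos[:, None, :] + np.einsum("wij,aj->wai", mats, _WATER_BODY)
            coords[water_atom0:] = watoms.reshape(-1, 3)

        coords[:, 2] += center
        frames.append(BilayerFrame(time=f * dt, box=box, coords=coords, topology=top))

    traj = Trajectory(topology=top, frames=frames, dt=dt if n_frames > 1 else None,
                      temperature=temperature)

    # --- ground truth -----------------------------------------------------
    tilt_mean, moments = tilt_density_moments(chi_tilt, theta0, l_max=2)
    scd = None
    if gauche_p == 0.0:
        scd = [-0.5 * moments[2]] * n_carbons
    sigma_sheet = 1.0 / a0  # one +1/-1 pair per molecule per mean area
    truth = GroundTruth(
        ka_true=ka_true,
        a0_true=a0,
        chi_tilt_true=chi_tilt,
        theta0_true=theta0,
        chi_splay_true=(
            # the l_max=200 Legendre expansion resolves tilt densities
            # wider than ~0.05 rad; stiffer fields get no analytic value
            {
                "chain-chain": analytic_splay_modulus(
                    chi_tilt, theta0, gate_sigma=np.radians(5.0)
                )
            }
            if chi_tilt <= 400.0
            else None
        ),
        gauche_fraction_true=[gauche_p] * n_dih,
        scd_true=scd,
        tau_res_true=tau_res,
        dr_true=dr,
        tau_rot_true=1.0 / (6.0 * dr),
        sheet_charge={
            "sigma_e_per_nm2": sigma_sheet,
            "separation_nm": charge_sep,
            "delta_phi_V": sigma_sheet * charge_sep * SHEET_PHI_V,
        },
        leaflet_labels=leaflet.tolist(),
        thickness_true=head_sep,
        tilt_mean_true=tilt_mean,
        temperature=temperature,
        surface_alpha_true=surface_alpha,
        seed=seed,
        extras={"n_per_leaflet": n_per_leaflet, "n_waters": n_waters, "n_shell": n_shell,
                "n_carbons": n_carbons, "dt_ps": dt},
    )
    return traj, truth


# ---------------------------------------------------------------------------
# two-state enthalpy replicas
# ---------------------------------------------------------------------------

def gen_enthalpy_replicas(
    delta_h: float,
    tm: float,
    temps,
    n_samples: int,
    seed: int = 0,
    base_sigma: float = 10.0,
):
    """Two-state enthalpy series per temperature.

    State occupancy follows the Boltzmann factor
    ``exp(-deltaH (1/T - 1/Tm) / kB)`` (normalized two-state model);
    the sampled enthalpy is ``state * deltaH`` plus Gaussian base noise
    of width ``base_sigma`` (kJ/mol).  Returns
    ``(list[(T, H_samples)], GroundTruth)``.
    """
    temps = np.asarray(temps, dtype=float)
    if np.any(np.diff(temps) <= 0):
        raise ValueError("temperatures must be sorted ascending and unique")
    rng = np.random.default_rng(seed)
    out = []
    for t in temps:
        if delta_h == 0.0:
            p1 = 0.5
        else:
            logit = -delta_h * (1.0 / t - 1.0 / tm) / KB_KJ_MOL
            p1 = 1.0 / (1.0 + np.exp(-logit))
        state = rng.random(n_samples) < p1
        h = state * delta_h + rng.normal(scale=base_sigma, size=n_samples)
        out.append((float(t), h))
    truth = GroundTruth(
        two_state={"deltaH_kJ_mol": delta_h, "Tm_K": tm, "base_sigma": base_sigma},
        seed=seed,
    )
    return out, truth
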