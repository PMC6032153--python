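"""Fluctuation-based mechanical moduli of bilayers.

Three moduli are implemented:

* the area compressibility modulus ``KA = kB T <Amol> / (N Var(Amol))``
  from lateral-area fluctuations (linear response);
* the molecular tilt modulus ``chi``, the curvature of the tilt-angle
  potential of mean force ``F(theta) = -ln[P(theta)/sin(theta)]``
  obtained by Jacobian-corrected Boltzmann inversion and a weighted
  quadratic fit about the PMF minimum;
* pairwise splay moduli ``chi_ij`` (quadratic PMF of the angle between
  two directive vectors, fit constrained through zero) combined into an
  effective bending rigidity by a pair-count-weighted harmonic mean,
  ``1/KC_eff = sum(phi_ij/chi_ij) / sum(phi_ij)``.

PMFs are expressed in kBT; conversions to mN/m (for KA) happen at the
reporting layer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Trajectory, assign_leaflets, directive_vectors, minimum_image, UPPER

log = logging.getLogger("memprops")

KB_J = 1.380649e-23  # J/K
# 1 kBT/nm^2 in mN/m at temperature T:  kB[J/K]*T * 1e18 [1/m^2] * 1e3 [mN/N]
_KBT_PER_NM2_TO_MN_PER_M = KB_J * 1e21

__all__ = [
    "AngleSamples",
    "ModulusResult",
    "PMFTable",
    "area_compressibility",
    "boltzmann_invert",
    "tilt_modulus",
    "tilt_modulus_from_samples",
    "splay_pairs",
    "splay_modulus",
    "effective_bending_rigidity",
]


@dataclass
class AngleSamples:
    """Angle samples (radians, in [0, pi]) with their context."""

    angles: np.ndarray
    temperature: float | None = None
    kind: str = "tilt"  # tilt | splay | orientation
    labels: np.ndarray | None = None  # per-sample molecule/pair type
    frame_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.size and (
            self.angles.min() < -1e-9 or self.angles.max() > np.pi + 1e-9
        ):
            raise ValueError("angles must lie in [0, pi] radians")

    @property
    def n(self) -> int:
        return self.angles.size

    def degrees(self) -> np.ndarray:
        return np.degrees(self.angles)


@dataclass
class ModulusResult:
    """A fitted modulus with fit window, quality metrics and uncertainty."""

    value: float
    unit: str
    theta0: float | None = None
    f0: float | None = None
    fit_window: tuple[float, float] | None = None
    r_squared: float | None = None
    stderr: float | None = None
    n_samples: int = 0
    extras: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


@dataclass
class PMFTable:
    """Boltzmann-inverted free-energy profile F(theta) in kBT."""

    theta: np.ndarray  # bin centers, rad (nonempty bins only)
    f: np.ndarray  # kBT, shifted so min(F) = 0
    counts: np.ndarray
    bin_width: float
    n_samples: int


# ---------------------------------------------------------------------------
# area compressibility (linear response)
# ---------------------------------------------------------------------------

def area_compressibility(
    area_series: np.ndarray,
    n_molecules: int,
    temperature: float,
    n_blocks: int = 20,
    n_boot: int = 200,
    seed: int = 0,
) -> ModulusResult:
    """KA from the per-frame molecular-area series (plain sample variance).

    Reports the modulus in mN/m with the kBT/nm^2 value in ``extras``;
    the standard error comes from a block bootstrap over frames
    (contiguous blocks, resampled with replacement).
    """
    a = np.asarray(area_series, dtype=float)
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    if a.size < 2:
        raise ValueError("need at least two frames of areas")
    if a.size < 1000:
        warnings.warn(f"only {a.size} frames; KA estimate may be noisy", stacklevel=2)
    var = float(np.var(a))
    mean = float(np.mean(a))
    if var <= 1e-24 * mean**2:  # numerically zero fluctuations
        raise ValueError("zero area variance: KA undefined")

    def _ka_kbt(series: np.ndarray) -> float:
        return np.mean(series) / (n_molecules * np.var(series))

    ka_kbt = _ka_kbt(a)  # kBT / nm^2
    to_mn = _KBT_PER_NM2_TO_MN_PER_M * temperature
    rng = np.random.default_rng(seed)
    blocks = np.array_split(a, n_blocks)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, len(blocks), size=len(blocks))
        boot[b] = _ka_kbt(np.concatenate([blocks[i] for i in pick]))
    stderr = float(np.std(boot)) * to_mn
    return ModulusResult(
        value=ka_kbt * to_mn,
        unit="mN/m",
        stderr=stderr,
        n_samples=a.size,
        extras={
            "KA_kBT_per_nm2": ka_kbt,
            "mean_area_nm2": mean,
            "var_area_nm4": var,
            "temperature_K": temperature,
        },
    )


# ---------------------------------------------------------------------------
# Boltzmann inversion and quadratic fits
# ---------------------------------------------------------------------------

def boltzmann_invert(samples: AngleSamples, bin_width: float = np.radians(1.0)) -> PMFTable:
    """F(theta) = -ln[P(theta)/sin(theta)] per bin, in kBT.

    P is the normalized histogram of the samples on [0, pi]; empty bins
    are excluded (and logged); F is shifted so its minimum is zero.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    a = samples.angles
    if a.size < 1e4:
        warnings.warn(f"only {a.size} angle samples; PMF may be noisy", stacklevel=2)
    n_bins = max(int(np.ceil(np.pi / bin_width)), 1)
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts, _ = np.histogram(a, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nonempty = counts > 0
    n_empty_inside = int(np.sum(~nonempty[np.argmax(nonempty): len(nonempty) - np.argmax(nonempty[::-1])]))
    if n_empty_inside:
        log.debug("excluded %d empty bins inside the sampled range", n_empty_inside)
    if np.sum(nonempty) < 5:
        raise ValueError("fewer than 5 nonempty bins: narrow the bin width or add samples")
    p = counts[nonempty] / (a.size * bin_width)
    f = -np.log(p / np.sin(centers[nonempty]))
    f -= f.min()
    return PMFTable(
        theta=centers[nonempty],
        f=f,
        counts=counts[nonempty].astype(float),
        bin_width=bin_width,
        n_samples=a.size,
    )


def _weighted_quadratic(theta, f, w, constrained: bool):
    """Weighted LSQ fit of F = c0 + c1*theta + c2*theta^2 (c1=0 if constrained)."""
    if constrained:
        x = np.column_stack([np.ones_like(theta), theta**2])
    else:
        x = np.column_stack([np.ones_like(theta), theta, theta**2])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(x * sw[:, None], f * sw, rcond=None)
    pred = x @ coef
    ss_res = np.sum(w * (f - pred) ** 2)
    fbar = np.average(f, weights=w)
    ss_tot = np.sum(w * (f - fbar) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return coef, r2


def tilt_modulus(
    pmf: PMFTable,
    fit_window: float = np.radians(15.0),
    constrained: bool = False,
) -> ModulusResult:
    """Quadratic fit of the tilt PMF about its minimum.

    Fits ``F(theta) = F(theta0) + (chi/2)(theta - theta0)^2`` by
    weighted least squares (weights proportional to bin counts) over
    ``theta0 +/- fit_window``; returns chi (kBT/rad^2) and theta0.
    """
    imin = int(np.argmin(pmf.f))
    if imin == 0 or imin == len(pmf.f) - 1:
        raise ValueError("PMF minimum at the edge of its support: cannot fit tilt modulus")
    t0 = pmf.theta[imin]
    sel = np.abs(pmf.theta - t0) <= fit_window
    theta, f, w = pmf.theta[sel], pmf.f[sel], pmf.counts[sel]
    if len(theta) < 3:
        raise ValueError("too few PMF bins inside the fit window")
    coef, r2 = _weighted_quadratic(theta, f, w, constrained=False)
    c0, c1, c2 = coef
    chi = 2.0 * c2
    result = ModulusResult(
        value=chi,
        unit="kBT/rad^2",
        fit_window=(float(t0 - fit_window), float(t0 + fit_window)),
        r_squared=float(r2),
        n_samples=pmf.n_samples,
    )
    if chi <= 0 or abs(chi) < 1e-10:
        result.warnings.append("non-positive or near-zero curvature: flat PMF")
        result.theta0 = float(t0)
        result.f0 = float(f.min())
        return result
    theta0 = -c1 / (2.0 * c2)
    result.theta0 = float(theta0)
    result.f0 = float(c0 - c1**2 / (4.0 * c2))
    return result


def _adaptive_window(pmf: PMFTable, fit_window: float) -> float:
    """Widen the fit window when the PMF is too shallow to resolve.

    A quadratic rise below ~1 kBT inside the window carries little
    curvature information; the window is widened (once) so the
    expected rise reaches 1 kBT, capped at 45 degrees.
    """
    try:
        probe = tilt_modulus(pmf, fit_window)
    except ValueError:
        return fit_window
    chi = probe.value
    if chi > 0 and 0.5 * chi * fit_window**2 < 1.0:
        return float(min(np.sqrt(2.0 / chi), np.radians(45.0)))
    return fit_window


def tilt_modulus_from_samples(
    samples: AngleSamples,
    bin_width: float = np.radians(1.0),
    fit_window: float = np.radians(15.0),
    n_boot: int = 20,
    seed: int = 0,
    adaptive: bool = True,
) -> ModulusResult:
    """Invert + fit in one step, with a bootstrap standard error.

    With ``adaptive`` (default) the fit window is widened once when the
    PMF is too shallow for the default window to resolve its
    curvature.  Resampling is by frame blocks when frame ids are
    present, otherwise by plain bootstrap over samples.
    """
    pmf = boltzmann_invert(samples, bin_width)
    if adaptive:
        fit_window = _adaptive_window(pmf, fit_window)
    result = tilt_modulus(pmf, fit_window)
    rng = np.random.default_rng(seed)
    a = samples.angles
    vals = []
    if samples.frame_ids is not None:
        frames = np.unique(samples.frame_ids)
        blocks = np.array_split(frames, min(20, len(frames)))
        order = np.argsort(samples.frame_ids, kind="stable")
        sorted_fids = samples.frame_ids[order]
        for _ in range(n_boot):
            pick = rng.integers(0, len(blocks), size=len(blocks))
            chosen = np.concatenate([blocks[i] for i in pick])
            mask_idx = np.searchsorted(sorted_fids, chosen)
            sub = []
            for fr in chosen:
                lo = np.searchsorted(sorted_fids, fr, side="left")
                hi = np.searchsorted(sorted_fids, fr, side="right")
                sub.append(a[order[lo:hi]])
            sub = np.concatenate(sub) if sub else a
            try:
                vals.append(
                    tilt_modulus(boltzmann_invert(AngleSamples(sub), bin_width), fit_window).value
                )
            except ValueError:
                continue
    else:
        for _ in range(n_boot):
            sub = a[rng.integers(0, a.size, size=a.size)]
            try:
                vals.append(
                    tilt_modulus(boltzmann_invert(AngleSamples(sub), bin_width), fit_window).value
                )
            except ValueError:
                continue
    if vals:
        result.stderr = float(np.std(vals))
    return result


# ---------------------------------------------------------------------------
# splay and effective bending rigidity
# ---------------------------------------------------------------------------

def _pair_type(label_i: str, label_j: str) -> str:
    return "-".join(sorted((str(label_i), str(label_j))))


def splay_pairs(
    traj: Trajectory,
    theta_most_probable: float,
    sigma: float = np.radians(5.0),
    cutoff: float = 1.0,
    include_intra: bool = True,
):
    """Collect gated splay angles between neighboring directive vectors.

    For every same-leaflet chain pair with head-head lateral distance
    below ``cutoff`` (nm, measured between chain-start atoms) and at
    least one member's tilt inside ``theta_most_probable +/- sigma``,
    the angle between the two directive vectors is recorded.  Pair
    types enumerate chain-label combinations.

    Returns ``(samples_by_type, counts_by_type)``.
    """
    angles: dict[str, list] = {}
    frames_of: dict[str, list] = {}
    for fi, frame in enumerate(traj.frames):
        vecs, molids, labels, start_idx = directive_vectors(frame)
        leaf = assign_leaflets(frame)
        leaflet_of = dict(zip(leaf.molids.tolist(), leaf.labels.tolist()))
        chain_leaf = np.array([leaflet_of[m] for m in molids])
        # leaflet-signed tilt of every chain
        ref = np.where(chain_leaf == UPPER, -1.0, 1.0)
        tilt = np.arccos(np.clip(vecs[:, 2] * ref, -1.0, 1.0))
        gate = np.abs(tilt - theta_most_probable) <= sigma
        xy = frame.coords[start_idx, :2]
        box = frame.box
        for leaflet in (UPPER, -UPPER):
            idx = np.flatnonzero(chain_leaf == leaflet)
            if idx.size < 2:
                continue
            sub_xy = xy[idx]
            d = sub_xy[:, None, :] - sub_xy[None, :, :]
            d = minimum_image(
                np.concatenate([d, np.zeros((*d.shape[:2], 1))], axis=-1), box
            )[..., :2]
            dist = np.linalg.norm(d, axis=-1)
            ii, jj = np.triu_indices(idx.size, k=1)
            near = dist[ii, jj] < cutoff
            ok = near & (gate[idx[ii]] | gate[idx[jj]])
            if not include_intra:
                ok &= molids[idx[ii]] != molids[idx[jj]]
            gi, gj = idx[ii[ok]], idx[jj[ok]]
            cosang = np.clip(np.sum(vecs[gi] * vecs[gj], axis=1), -1.0, 1.0)
            ang = np.arccos(cosang)
            for a, li, lj in zip(ang, labels[gi], labels[gj]):
                key = _pair_type(li, lj)
                angles.setdefault(key, []).append(a)
                frames_of.setdefault(key, []).append(fi)
    if not angles:
        raise ValueError("no qualifying splay pairs (check cutoff and tilt gate)")
    samples = {
        key: AngleSamples(
            np.asarray(vals),
            temperature=traj.temperature,
            kind="splay",
            frame_ids=np.asarray(frames_of[key]),
        )
        for key, vals in angles.items()
    }
    counts = {key: s.n for key, s in samples.items()}
    return samples, counts


def splay_modulus(
    samples: AngleSamples,
    bin_width: float = np.radians(1.0),
    fit_max: float = np.radians(40.0),
    constrained: bool = True,
) -> ModulusResult:
    """Splay modulus chi_ij from Jacobian-corrected inversion of P(theta_ij).

    The default fit is the printed quadratic form through zero,
    ``F = F0 + (chi_ij/2) theta^2`` over (0, fit_max]; an unconstrained
    quadratic (with a linear term) is available for sensitivity checks.
    """
    pmf = boltzmann_invert(samples, bin_width)
    sel = (pmf.theta > 0) & (pmf.theta <= fit_max)
    theta, f, w = pmf.theta[sel], pmf.f[sel], pmf.counts[sel]
    if len(theta) < (2 if constrained else 3):
        raise ValueError("too few PMF bins inside the splay fit window")
    coef, r2 = _weighted_quadratic(theta, f, w, constrained=constrained)
    chi = 2.0 * coef[-1]
    res = ModulusResult(
        value=float(chi),
        unit="kBT/rad^2",
        f0=float(coef[0]),
        fit_window=(0.0, float(fit_max)),
        r_squared=float(r2),
        n_samples=samples.n,
    )
    if chi <= 1e-10:
        res.warnings.append("near-zero splay curvature: flat PMF")
    return res


def effective_bending_rigidity(
    chi_ij: dict[str, float | ModulusResult], phi_ij: dict[str, int]
) -> ModulusResult:
    """Count-weighted harmonic mean of the splay moduli.

    ``1/KC_eff = sum_ij(phi_ij / chi_ij) / sum_ij(phi_ij)``; collapses
    to chi_ij for a single pair type and is bounded by min/max chi_ij.
    """
    if set(chi_ij) != set(phi_ij):
        raise ValueError("chi_ij and phi_ij must cover the same pair types")
    if not chi_ij:
        raise ValueError("no pair types")
    inv = 0.0
    total = 0
    for key, chi in chi_ij.items():
        val = chi.value if isinstance(chi, ModulusResult) else float(chi)
        if val <= 0:
            raise ValueError(f"non-positive splay modulus for pair type {key!r}")
        inv += phi_ij[key] / val
        total += phi_ij[key]
    if total <= 0:
        raise ValueError("no pairs counted")
    kc = total / inv
    return ModulusResult(
        value=float(kc),
        unit="kBT",
        n_samples=total,
        extras={"phi_ij": dict(phi_ij), "chi_ij": {
            k: (v.value if isinstance(v, ModulusResult) else float(v)) for k, v in chi_ij.items()
        }},
    )
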