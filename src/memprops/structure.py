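"""Structural packing metrics of bilayers.

Molecular area (lateral box area over molecules per leaflet), transverse
density profiles and the peak-to-peak bilayer thickness, alkyl tilt
angles against the leaflet-signed normal, the deuterium order parameter
|SCD| = |<(3 cos^2 theta_CH - 1)/2>|, per-dihedral gauche fractions
(dihedral inside the open interval (-120 deg, 120 deg)), and lateral
two-dimensional radial distribution functions of head-group species.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    Trajectory,
    assign_leaflets,
    directive_vectors,
    minimum_image,
    UPPER,
)
from .mechanics import AngleSamples

log = logging.getLogger("memprops")

__all__ = [
    "ZProfile",
    "OrderProfile",
    "MeanSD",
    "molecular_area",
    "density_profile",
    "thickness",
    "bilayer_thickness",
    "shift_profile",
    "tilt_angles",
    "deuterium_order",
    "gauche_profile",
    "rdf_2d",
]


@dataclass
class MeanSD:
    mean: float
    sd: float
    n: int
    series: np.ndarray | None = None

    def __str__(self) -> str:
        return f"{self.mean:.4g} +/- {self.sd:.2g} (n={self.n})"


@dataclass
class ZProfile:
    """A quantity binned along the bilayer normal, centered on the bilayer."""

    bin_edges: np.ndarray  # nm, uniform
    values: np.ndarray  # per-nm^3 density (number, amu or e weighting)
    species: str
    weighting: str = "number"
    area: float = 1.0  # mean lateral area, nm^2 (for integral checks)
    n_frames: int = 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def integral(self) -> float:
        """Total amount of the species: integral times the lateral area."""
        return float(np.sum(self.values) * self.bin_width * self.area)


@dataclass
class OrderProfile:
    """Per-carbon |SCD| and/or per-dihedral gauche fraction by chain type."""

    scd: dict[str, np.ndarray] = field(default_factory=dict)  # |SCD| in [0, 0.5]
    scd_signed: dict[str, np.ndarray] = field(default_factory=dict)
    gauche: dict[str, np.ndarray] = field(default_factory=dict)  # in [0, 1]
    carbons: dict[str, list] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def plateau_scd(self) -> float:
        """Mean |SCD| over the middle third of carbons, pooled over chains."""
        vals = []
        for prof in self.scd.values():
            p = np.asarray(prof, dtype=float)
            p = p[np.isfinite(p)]
            k = len(p)
            if k == 0:
                continue
            lo = k // 3
            hi = max(2 * k // 3, lo + 1)
            vals.append(p[lo:hi])
        if not vals:
            raise ValueError("no finite |SCD| values")
        return float(np.mean(np.concatenate(vals)))


# ---------------------------------------------------------------------------


def molecular_area(traj: Trajectory, n_molecules: int) -> MeanSD:
    """Mean and sd of the per-frame molecular area Amol = Lx*Ly / Nmol."""
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    per_frame = traj.areas() / n_molecules
    if per_frame.size == 1:
        warnings.warn("single frame: area sd is zero by construction", stacklevel=2)
    return MeanSD(float(per_frame.mean()), float(per_frame.std()), per_frame.size, per_frame)


def density_profile(
    traj: Trajectory,
    species: str,
    weighting: str = "number",
    bin_width: float = 0.1,
    leaflet: int | None = None,
) -> ZProfile:
    """Transverse density of a species, averaged over frames.

    z is measured relative to the per-frame amphiphile center of mass;
    values are normalized by bin volume so the number-weighted integral
    times the lateral area recovers the selection size.  ``leaflet``
    restricts amphiphile selections to one leaflet (+1 upper/-1 lower).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if weighting not in ("number", "mass", "charge"):
        raise ValueError("weighting must be number, mass or charge")
    top = traj.topology
    idx = top.select_atoms(species)
    if idx.size == 0:
        raise ValueError(f"selector {species!r} matches no atoms")
    if leaflet is not None:
        la = assign_leaflets(traj.frames[0])
        keep_mol = set(la.molids[la.labels == leaflet].tolist())
        idx = idx[np.isin(top.atom_molid[idx], list(keep_mol))]
        if idx.size == 0:
            raise ValueError("selection empty after leaflet restriction")
    if weighting == "number":
        w = np.ones(idx.size)
    elif weighting == "mass":
        w = top.masses[idx]
    else:
        w = top.charges[idx]
    zmax = max(f.box[2] for f in traj.frames) / 2.0
    n_bins = int(np.ceil(2 * zmax / bin_width))
    edges = (np.arange(n_bins + 1) - n_bins / 2.0) * bin_width
    hist = np.zeros(n_bins)
    area_sum = 0.0
    for frame in traj.frames:
        z = frame.coords[idx, 2] - frame.com_z()
        h, _ = np.histogram(z, bins=edges, weights=w)
        hist += h
        area_sum += frame.box[0] * frame.box[1]
    mean_area = area_sum / traj.n_frames
    values = hist / (traj.n_frames * bin_width * mean_area)
    return ZProfile(
        bin_edges=edges,
        values=values,
        species=species,
        weighting=weighting,
        area=mean_area,
        n_frames=traj.n_frames,
    )


def _refined_peak(profile: ZProfile) -> float:
    """Peak position refined by a quadratic through the 3 bins at the max."""
    v = profile.values
    if not np.any(v > 0):
        raise ValueError(f"profile {profile.species!r} is empty")
    i = int(np.argmax(v))
    near = np.flatnonzero(v >= 0.99 * v[i])
    if np.any(np.abs(near - i) > 3):
        raise ValueError(
            "ambiguous profile maximum (two bins within 1% of the max more than "
            "3 bins apart): narrow the bins"
        )
    z = profile.centers
    if i == 0 or i == len(v) - 1:
        return float(z[i])
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # flat or non-concave neighborhood: keep the bin center
        return float(z[i])
    return float(z[i] + 0.5 * (y0 - y2) / denom * profile.bin_width)


def thickness(upper: ZProfile, lower: ZProfile) -> float:
    """Bilayer thickness: distance between the two head-group peaks (nm)."""
    zu = _refined_peak(upper)
    zl = _refined_peak(lower)
    if zu <= zl:
        raise ValueError("upper head peak not above lower head peak")
    return zu - zl


def bilayer_thickness(
    traj: Trajectory, head_selector: str = "cation_center", bin_width: float = 0.1
) -> float:
    """Thickness from per-leaflet head-group density profiles."""
    la = assign_leaflets(traj.frames[0])
    if la.n_upper == 0 or la.n_lower == 0:
        raise ValueError("both leaflets required to measure thickness")
    up = density_profile(traj, head_selector, bin_width=bin_width, leaflet=UPPER)
    lo = density_profile(traj, head_selector, bin_width=bin_width, leaflet=-UPPER)
    return thickness(up, lo)


def shift_profile(profile: ZProfile, reference: ZProfile) -> ZProfile:
    """Shift a profile so the reference species' peak sits at z = 0.

    Post-processing alignment used to overlay systems of different
    thickness on a common head-group frame.
    """
    shift = _refined_peak(reference)
    return ZProfile(
        bin_edges=profile.bin_edges - shift,
        values=profile.values.copy(),
        species=profile.species,
        weighting=profile.weighting,
        area=profile.area,
        n_frames=profile.n_frames,
    )


# ---------------------------------------------------------------------------


def tilt_angles(traj: Trajectory) -> AngleSamples:
    """Chain tilt angles (radians) against the leaflet-signed normal.

    The upper leaflet is measured against -z and the lower against +z,
    so an inward-pointing chain has a small tilt.  Samples carry frame
    ids and chain labels.
    """
    angles, labels, fids = [], [], []
    for fi, frame in enumerate(traj.frames):
        vecs, molids, chain_labels, _ = directive_vectors(frame)
        la = assign_leaflets(frame)
        leaflet_of = dict(zip(la.molids.tolist(), la.labels.tolist()))
        ref = np.array([-1.0 if leaflet_of[m] == UPPER else 1.0 for m in molids])
        cosang = np.clip(vecs[:, 2] * ref, -1.0, 1.0)
        angles.append(np.arccos(cosang))
        labels.append(chain_labels)
        fids.append(np.full(len(molids), fi))
    return AngleSamples(
        np.concatenate(angles),
        temperature=traj.temperature,
        kind="tilt",
        labels=np.concatenate(labels),
        frame_ids=np.concatenate(fids),
    )


def deuterium_order(traj: Trajectory, species: str | None = None) -> OrderProfile:
    """Per-carbon deuterium order parameter |SCD| for each chain type.

    SCD = <(3 cos^2 theta_CH - 1)/2> over hydrogens, molecules and
    frames, with theta_CH the C-H angle to the bilayer normal (z).
    Carbons without attached hydrogens (carbonyls) are reported as NaN
    with a warning.
    """
    top = traj.topology
    specs = {}
    for m in top.amphiphiles:
        if species is None or m.spec.name == species:
            specs.setdefault(m.spec.name, m.spec)
    if not specs:
        raise ValueError(f"no amphiphiles match species {species!r}")
    result = OrderProfile()
    coords = np.stack([f.coords for f in traj.frames])  # (F, A, 3)
    for spec_name, spec in specs.items():
        for chain_label, carbons in spec.chain_defs.items():
            key = f"{spec_name}:{chain_label}" if len(specs) > 1 else chain_label
            scd_per_c = np.full(len(carbons), np.nan)
            for k, cname in enumerate(carbons):
                hnames = spec.chain_hydrogens.get(cname, [])
                if not hnames:
                    warnings.warn(
                        f"carbon {cname} of {spec_name} has no hydrogens (carbonyl): skipped",
                        stacklevel=2,
                    )
                    continue
                ci = top.name_index(spec_name, cname)
                vals = []
                for hname in hnames:
                    hi = top.name_index(spec_name, hname)
                    d = coords[:, hi, :] - coords[:, ci, :]
                    cos = d[..., 2] / np.linalg.norm(d, axis=-1)
                    vals.append(1.5 * cos**2 - 0.5)
                scd_per_c[k] = float(np.mean(np.concatenate([v.ravel() for v in vals])))
            result.scd_signed[key] = scd_per_c
            result.scd[key] = np.abs(scd_per_c)
            result.carbons[key] = list(carbons)
    result.metadata["n_frames"] = traj.n_frames
    return result


def _dihedral_angles(p0, p1, p2, p3):
    """Dihedral angles in radians in (-pi, pi], vectorized over leading dims."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1n)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.arctan2(y, x)


def gauche_profile(traj: Trajectory, species: str | None = None) -> OrderProfile:
    """Fraction of gauche conformers per dihedral position per chain type.

    A dihedral is gauche when its angle lies strictly inside
    (-120 deg, 120 deg); the boundary counts as trans (open interval).
    """
    top = traj.topology
    specs = {}
    for m in top.amphiphiles:
        if species is None or m.spec.name == species:
            specs.setdefault(m.spec.name, m.spec)
    if not specs:
        raise ValueError(f"no amphiphiles match species {species!r}")
    coords = np.stack([f.coords for f in traj.frames])
    limit = np.radians(120.0)
    result = OrderProfile()
    for spec_name, spec in specs.items():
        for chain_label, carbons in spec.chain_defs.items():
            if len(carbons) < 4:
                raise ValueError(f"chain {chain_label} of {spec_name} has fewer than 4 carbons")
            key = f"{spec_name}:{chain_label}" if len(specs) > 1 else chain_label
            cidx = np.stack([top.name_index(spec_name, c) for c in carbons], axis=1)
            pos = coords[:, cidx, :]  # (F, M, n_c, 3)
            phi = _dihedral_angles(
                pos[:, :, :-3], pos[:, :, 1:-2], pos[:, :, 2:-1], pos[:, :, 3:]
            )  # (F, M, n_dih)
            gauche = np.abs(phi) < limit - 1e-12
            result.gauche[key] = gauche.reshape(-1, gauche.shape[-1]).mean(axis=0)
            result.carbons.setdefault(key, list(carbons))
    result.metadata["n_frames"] = traj.n_frames
    return result


# ---------------------------------------------------------------------------


def rdf_2d(
    traj: Trajectory,
    species_a: str,
    species_b: str,
    r_max: float = 2.0,
    bin_width: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Lateral radial distribution function g(r) of same-leaflet pairs.

    Distances are (x, y) minimum-image separations within each leaflet;
    normalization uses the ideal 2D density of species_b in the leaflet
    plane, so uncorrelated points give g -> 1.  Returns ``(r, g)``.
    """
    top = traj.topology
    idx_a = top.select_atoms(species_a)
    idx_b = top.select_atoms(species_b)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("empty species selection for 2D RDF")
    same = species_a == species_b
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    r = 0.5 * (edges[:-1] + edges[1:])
    hist = np.zeros(len(r))
    norm = 0.0
    for frame in traj.frames:
        if r_max > min(frame.box[0], frame.box[1]) / 2.0:
            raise ValueError("r_max exceeds half the smallest lateral box edge")
        la = assign_leaflets(frame)
        mol_leaf = dict(zip(la.molids.tolist(), la.labels.tolist()))
        leaf_a = np.array([mol_leaf.get(m, 0) for m in top.atom_molid[idx_a]])
        leaf_b = np.array([mol_leaf.get(m, 0) for m in top.atom_molid[idx_b]])
        area = frame.box[0] * frame.box[1]
        for leaflet in (UPPER, -UPPER):
            ia = idx_a[leaf_a == leaflet]
            ib = idx_b[leaf_b == leaflet]
            if ia.size == 0 or ib.size == 0:
                continue
            d = frame.coords[ia, None, :2] - frame.coords[None, ib, :2]
            d3 = np.concatenate([d, np.zeros((*d.shape[:2], 1))], axis=-1)
            d3 = minimum_image(d3, frame.box)
            dist = np.linalg.norm(d3[..., :2], axis=-1)
            if same:
                mask = ~np.isclose(dist, 0.0)
                dist = dist[mask]
            h, _ = np.histogram(dist, bins=edges)
            hist += h
            rho_b = (ib.size - (1 if same else 0)) / area
            norm += ia.size * rho_b
    shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = hist / (norm * shell)
    return r, g
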