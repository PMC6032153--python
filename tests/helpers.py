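"""Construction helpers for hand-built fixtures (exact geometries)."""

from __future__ import annotations

import numpy as np

from memprops.annotations import MoleculeSpec, synthetic_amphiphile_spec, _water_spec
from memprops.core import BilayerFrame, Molecule, Topology, Trajectory, UPPER
from memprops.synth import gen_chain

WATER_SPEC = _water_spec("SOL", "OW", ("HW1", "HW2"))


def build_topology(mol_specs: list[MoleculeSpec]) -> Topology:
    """Topology from an ordered list of per-molecule specs."""
    molecules = []
    idx = 0
    for mid, spec in enumerate(mol_specs):
        amap = {}
        for name in spec.atoms:
            amap[name] = idx
            idx += 1
        molecules.append(Molecule(mid, spec, amap))
    return Topology(molecules, n_atoms=idx)


def constructed_trajectory(
    chains,
    waters=(),
    box=(6.0, 6.0, 8.0),
    n_carbons: int = 12,
    n_frames: int = 1,
    dt: float = 10.0,
    temperature: float = 300.0,
    head_z: float = 1.9,
) -> Trajectory:
    """Exact-geometry trajectory from chain placement dicts.

    Each chain dict: ``leaflet`` (+1/-1), ``tilt_deg``, optional
    ``azimuth_deg`` (default 0), ``xy`` (lateral position), optional
    ``gauche_mask``.  Waters are dicts with an ``o`` position and an
    orientation unit vector ``dipole`` (H's placed symmetrically about
    it).  The bilayer center sits at z = box_z/2.
    """
    spec = synthetic_amphiphile_spec(n_carbons)
    specs = [spec] * len(chains) + [WATER_SPEC] * len(waters)
    top = build_topology(specs)
    coords = np.zeros((top.n_atoms, 3))
    center = box[2] / 2.0
    for mol, ch in zip(top.molecules[: len(chains)], chains):
        s = 1.0 if ch["leaflet"] == UPPER else -1.0
        x, y = ch["xy"]
        carb, hyd = gen_chain(
            n_carbons,
            gauche_mask=ch.get("gauche_mask"),
            tilt=np.radians(ch["tilt_deg"]),
            seed=ch.get("seed", 0),
            leaflet=ch["leaflet"],
            azimuth=np.radians(ch.get("azimuth_deg", 0.0)),
        )
        base = np.array([x, y, center + s * (head_z - 0.35)])
        coords[mol.index_of("N")] = [x, y, center + s * head_z]
        coords[mol.index_of("S")] = [x, y, center + s * (head_z - 0.2)]
        for k, cname in enumerate(spec.chain_defs["chain"]):
            coords[mol.index_of(cname)] = carb[k] + base
            for j, hname in enumerate(spec.chain_hydrogens[cname]):
                coords[mol.index_of(hname)] = hyd[k, j] + base
    for mol, w in zip(top.molecules[len(chains):], waters):
        o = np.asarray(w["o"], dtype=float)
        bond = 0.09572
        if "h1" in w:  # explicit hydrogen positions
            h1 = np.asarray(w["h1"], dtype=float)
            h2 = np.asarray(w["h2"], dtype=float)
        elif "aim" in w:
            # one O-H bond collinear with the aim direction, the other
            # at the H-O-H angle from it
            u = np.asarray(w["aim"], dtype=float)
            u = u / np.linalg.norm(u)
            perp = np.cross(u, [1.0, 0.0, 0.0])
            if np.linalg.norm(perp) < 1e-8:
                perp = np.cross(u, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            hoh = np.radians(104.52)
            h1 = o + bond * u
            h2 = o + bond * (np.cos(hoh) * u + np.sin(hoh) * perp)
        else:
            d = np.asarray(w.get("dipole", (0.0, 0.0, 1.0)), dtype=float)
            d = d / np.linalg.norm(d)
            # H's symmetric about the dipole in a plane containing d
            perp = np.cross(d, [1.0, 0.0, 0.0])
            if np.linalg.norm(perp) < 1e-8:
                perp = np.cross(d, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            half = np.radians(104.52 / 2)
            h1 = o + bond * (np.cos(half) * d + np.sin(half) * perp)
            h2 = o + bond * (np.cos(half) * d - np.sin(half) * perp)
        coords[mol.index_of("OW")] = o
        coords[mol.index_of("HW1")] = h1
        coords[mol.index_of("HW2")] = h2
    frames = [
        BilayerFrame(time=i * dt, box=np.asarray(box, float), coords=coords.copy(), topology=top)
        for i in range(n_frames)
    ]
    return Trajectory(topology=top, frames=frames, dt=dt if n_frames > 1 else None,
                      temperature=temperature)
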