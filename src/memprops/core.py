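"""Core data model: annotated bilayer trajectories and shared geometry.

Coordinates are stored internally in nm (converted from the Å used by
the underlying MDAnalysis readers); boxes are orthorhombic edge lengths.
Angles are radians internally and degrees at user-facing interfaces.
The bilayer normal is the box z-axis, the convention of semi-isotropic
NPT membrane simulations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .annotations import MoleculeSpec, default_annotation

log = logging.getLogger("memprops")

__all__ = [
    "Topology",
    "BilayerFrame",
    "Trajectory",
    "LeafletAssignment",
    "read_trajectory",
    "write_trajectory",
    "assign_leaflets",
    "directive_vector",
    "directive_vectors",
    "minimum_image",
]

UPPER, LOWER = 1, -1


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement components into the half-open interval [-L/2, L/2).

    Orthorhombic boxes only.  Works on a single vector or an (..., 3)
    array of displacements.
    """
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    return delta - box * np.floor(delta / box + 0.5)


@dataclass
class Molecule:
    """One molecule instance: its spec and global atom indices."""

    molid: int
    spec: MoleculeSpec
    atom_index: dict[str, int]

    def index_of(self, atom_name: str) -> int:
        try:
            return self.atom_index[atom_name]
        except KeyError:
            raise KeyError(f"molecule {self.molid} ({self.spec.name}) has no atom {atom_name!r}")


class Topology:
    """Static structure shared by all frames of a trajectory."""

    def __init__(self, molecules: list[Molecule], n_atoms: int):
        self.molecules = molecules
        self.n_atoms = n_atoms
        self.atom_names = np.empty(n_atoms, dtype=object)
        self.atom_molid = np.full(n_atoms, -1, dtype=int)
        self.charges = np.zeros(n_atoms)
        self.masses = np.zeros(n_atoms)
        for mol in molecules:
            for name, i in mol.atom_index.items():
                self.atom_names[i] = name
                self.atom_molid[i] = mol.molid
                self.charges[i] = mol.spec.charges.get(name, 0.0)
                self.masses[i] = mol.spec.masses.get(name, 0.0)
        self._name_index_cache: dict[tuple[str, str], np.ndarray] = {}

    # ---- selections -------------------------------------------------
    def molecules_of(self, spec_name: str | None = None, kind: str | None = None) -> list[Molecule]:
        out = []
        for m in self.molecules:
            if spec_name is not None and m.spec.name != spec_name:
                continue
            if kind is not None and m.spec.kind != kind:
                continue
            out.append(m)
        return out

    @property
    def amphiphiles(self) -> list[Molecule]:
        return [m for m in self.molecules if not m.spec.is_water]

    @property
    def waters(self) -> list[Molecule]:
        return [m for m in self.molecules if m.spec.is_water]

    def name_index(self, spec_name: str, atom_name: str) -> np.ndarray:
        """Global index of one named atom for every molecule of a species."""
        key = (spec_name, atom_name)
        if key not in self._name_index_cache:
            idx = np.array(
                [m.index_of(atom_name) for m in self.molecules_of(spec_name)], dtype=int
            )
            self._name_index_cache[key] = idx
        return self._name_index_cache[key]

    def head_index(self, role: str = "cation_center") -> np.ndarray:
        """Head-center atom index per amphiphile (role with fallback)."""
        idx = []
        for m in self.amphiphiles:
            name = m.spec.head_atoms.get(role)
            if name is None:
                for alt in ("cation_center", "anion_center"):
                    name = m.spec.head_atoms.get(alt)
                    if name is not None:
                        break
            if name is None:
                raise ValueError(f"molecule {m.spec.name} has no head-center atom for {role!r}")
            idx.append(m.index_of(name))
        return np.asarray(idx, dtype=int)

    def select_atoms(self, selector: str) -> np.ndarray:
        """Resolve a string selector to global atom indices.

        Grammar: ``"water"`` (all water atoms), ``"<species>"`` (all
        atoms of that residue name), ``"<species>:<atom>"`` (one named
        atom per molecule), ``"cation_center"``/``"anion_center"`` (the
        head-center atoms of all amphiphiles).
        """
        if selector in ("cation_center", "anion_center"):
            idx = [
                m.index_of(m.spec.head_atoms[selector])
                for m in self.amphiphiles
                if m.spec.head_atoms.get(selector)
            ]
            return np.asarray(idx, dtype=int)
        if selector == "water":
            idx = [i for m in self.waters for i in m.atom_index.values()]
            return np.asarray(sorted(idx), dtype=int)
        if ":" in selector:
            spec_name, atom = selector.split(":", 1)
            return self.name_index(spec_name, atom)
        mols = self.molecules_of(selector)
        if not mols:
            raise ValueError(f"selector {selector!r} matches no molecules")
        idx = [i for m in mols for i in m.atom_index.values()]
        return np.asarray(sorted(idx), dtype=int)


@dataclass
class BilayerFrame:
    """One snapshot: coordinates (nm), orthorhombic box (nm), time (ps)."""

    time: float
    box: np.ndarray
    coords: np.ndarray
    topology: Topology

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in frame")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("frame requires three positive orthorhombic box edges")

    def com_z(self, atom_idx: np.ndarray | None = None) -> float:
        """Mass-weighted center along z (amphiphiles by default)."""
        top = self.topology
        if atom_idx is None:
            atom_idx = np.asarray(
                sorted(i for m in top.amphiphiles for i in m.atom_index.values()), dtype=int
            )
            if atom_idx.size == 0:  # no amphiphiles: center on everything
                atom_idx = np.arange(top.n_atoms)
        w = top.masses[atom_idx]
        if w.sum() <= 0:
            w = np.ones(len(atom_idx))
        return float(np.average(self.coords[atom_idx, 2], weights=w))


@dataclass
class Trajectory:
    """Ordered frames with shared topology, frame spacing and temperature."""

    topology: Topology
    frames: list[BilayerFrame]
    dt: float | None = None
    temperature: float | None = None

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("empty trajectory")
        times = np.array([f.time for f in self.frames])
        if len(times) > 1:
            if np.any(np.diff(times) <= 0):
                raise ValueError("frame times must be strictly increasing")
            steps = np.diff(times)
            if self.dt is None:
                self.dt = float(steps[0])
            if not np.allclose(steps, self.dt, rtol=1e-6, atol=1e-9):
                raise ValueError("non-uniform frame spacing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def areas(self) -> np.ndarray:
        """Per-frame lateral box area Lx*Ly in nm^2."""
        return np.array([f.box[0] * f.box[1] for f in self.frames])


@dataclass
class LeafletAssignment:
    """Per-amphiphile leaflet labels (+1 upper / -1 lower)."""

    labels: np.ndarray  # aligned with topology.amphiphiles order
    bilayer_center_z: float
    molids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_upper(self) -> int:
        return int(np.sum(self.labels == UPPER))

    @property
    def n_lower(self) -> int:
        return int(np.sum(self.labels == LOWER))


# ---------------------------------------------------------------------------
# trajectory ingestion / export
# ---------------------------------------------------------------------------

def _build_topology(resnames, atom_names, resids, annotation) -> Topology:
    unknown = sorted({rn for rn in resnames if rn not in annotation})
    if unknown:
        raise ValueError(
            "unknown residue names (no MoleculeSpec in annotation): " + ", ".join(unknown)
        )
    molecules: list[Molecule] = []
    current = None
    idx_map: dict[str, int] = {}
    molid = -1
    for i, (rid, rn, an) in enumerate(zip(resids, resnames, atom_names)):
        if current != (rid, rn):
            if idx_map:
                molecules.append(Molecule(molid, annotation[current[1]], idx_map))
            current = (rid, rn)
            molid += 1
            idx_map = {}
        spec = annotation[rn]
        if an not in spec.atoms:
            raise ValueError(f"atom {an!r} of residue {rn} not declared in its MoleculeSpec")
        idx_map[an] = i
    if idx_map:
        molecules.append(Molecule(molid, annotation[current[1]], idx_map))
    return Topology(molecules, n_atoms=len(atom_names))


def read_trajectory(
    coord_file,
    traj_file=None,
    annotation: dict[str, MoleculeSpec] | None = None,
    temperature: float | None = None,
) -> Trajectory:
    """Read a coordinate file (GRO/PDB) plus optional trajectory (XTC/TRR/DCD).

    Every residue name in the file must map to a :class:`MoleculeSpec`
    in the annotation (the shipped default is used when none is given);
    unknown residues are a hard error listing the offenders.
    """
    import MDAnalysis as mda

    if annotation is None:
        annotation = default_annotation()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(coord_file)) if traj_file is None else mda.Universe(
            str(coord_file), str(traj_file)
        )
    top = _build_topology(
        u.atoms.resnames, u.atoms.names, u.atoms.resids, annotation
    )
    frames: list[BilayerFrame] = []
    for ts in u.trajectory:
        if ts.dimensions is None or np.any(np.asarray(ts.dimensions[:3]) <= 0):
            raise ValueError("box missing or degenerate in trajectory frame")
        frames.append(
            BilayerFrame(
                time=float(ts.time),
                box=np.asarray(ts.dimensions[:3], dtype=float) / 10.0,
                coords=np.asarray(ts.positions, dtype=float) / 10.0,
                topology=top,
            )
        )
    if not frames:
        raise ValueError("empty trajectory")
    dt = None
    if len(frames) > 1:
        dt = frames[1].time - frames[0].time
    n_amph = len(top.amphiphiles)
    n_wat = len(top.waters)
    log.info("read %d frames: %d amphiphiles, %d waters", len(frames), n_amph, n_wat)
    return Trajectory(topology=top, frames=frames, dt=dt, temperature=temperature)


def write_trajectory(traj: Trajectory, coord_file, traj_file=None) -> None:
    """Write the first frame to GRO/PDB and, optionally, all frames to XTC/TRR."""
    import MDAnalysis as mda

    top = traj.topology
    n_res = len(top.molecules)
    u = mda.Universe.empty(
        n_atoms=top.n_atoms,
        n_residues=n_res,
        atom_resindex=top.atom_molid,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(n) for n in top.atom_names])
    u.add_TopologyAttr("resnames", [m.spec.name for m in top.molecules])
    u.add_TopologyAttr("resids", [m.molid + 1 for m in top.molecules])
    first = traj.frames[0]
    u.atoms.positions = first.coords * 10.0
    u.dimensions = [*(first.box * 10.0), 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(coord_file))
        if traj_file is not None:
            with mda.Writer(str(traj_file), n_atoms=top.n_atoms) as w:
                for fr in traj.frames:
                    u.atoms.positions = fr.coords * 10.0
                    u.dimensions = [*(fr.box * 10.0), 90.0, 90.0, 90.0]
                    u.trajectory.ts.time = fr.time
                    w.write(u.atoms)


# ---------------------------------------------------------------------------
# leaflets and directive vectors
# ---------------------------------------------------------------------------

def assign_leaflets(frame: BilayerFrame) -> LeafletAssignment:
    """Assign each amphiphile to the upper or lower leaflet.

    A molecule whose head-center z lies at or above the amphiphile
    center of mass goes to the upper leaflet (ties break upward for
    determinism).  Deterministic and invariant under global
    z-translation.
    """
    top = frame.topology
    amph = top.amphiphiles
    if len(amph) < 2:
        raise ValueError("leaflet assignment requires at least 2 amphiphiles")
    center = frame.com_z()
    head_idx = top.head_index()
    head_z = frame.coords[head_idx, 2]
    labels = np.where(head_z >= center, UPPER, LOWER)
    if np.all(labels == labels[0]):
        warnings.warn("all molecules on one side of the center: monolayer?", stacklevel=2)
    return LeafletAssignment(
        labels=labels,
        bilayer_center_z=center,
        molids=np.array([m.molid for m in amph], dtype=int),
    )


def directive_vector(frame: BilayerFrame, molid: int, chain) -> np.ndarray:
    """Unit directive vector of one chain (start -> end endpoint atoms).

    ``chain`` may be the chain label or an integer index into the
    molecule's chain list.  The displacement is minimum-image corrected.
    """
    mol = frame.topology.molecules[molid]
    labels = list(mol.spec.directive_endpoints)
    label = labels[chain] if isinstance(chain, int) else chain
    start, end = mol.spec.directive_endpoints[label]
    d = minimum_image(
        frame.coords[mol.index_of(end)] - frame.coords[mol.index_of(start)], frame.box
    )
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise ValueError(f"coincident directive endpoints for molecule {molid} chain {label!r}")
    return d / norm


def directive_vectors(frame: BilayerFrame):
    """All chain directive vectors of a frame, vectorized.

    Returns ``(vectors, molids, chain_labels, start_idx)`` where
    ``vectors`` is (n_chains, 3) unit vectors and ``start_idx`` the
    global atom index of each chain's start endpoint (used for lateral
    pair distances).
    """
    top = frame.topology
    starts, ends, molids, labels = [], [], [], []
    for m in top.amphiphiles:
        for label, (s, e) in m.spec.directive_endpoints.items():
            starts.append(m.index_of(s))
            ends.append(m.index_of(e))
            molids.append(m.molid)
            labels.append(label)
    starts = np.asarray(starts, dtype=int)
    ends = np.asarray(ends, dtype=int)
    d = minimum_image(frame.coords[ends] - frame.coords[starts], frame.box)
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("coincident directive endpoints")
    return d / norms[:, None], np.asarray(molids), np.asarray(labels, dtype=object), starts
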