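"""Molecule annotations: map residue/atom names to analysis roles.

Every analysis in this package is driven by a :class:`MoleculeSpec` that
declares, for one molecule type, which atoms form the alkyl chains, which
pair of atoms defines each chain's directive vector, where the charged
head-group centers sit, and the per-atom partial charges and masses.

A shipped default annotation covers the di-acyl phosphatidylcholines
DCnPC, the alkyltrimethylammonium (CnTMA) and alkylsulfate (CnS) ion-pair
amphiphile components for n = 12, 14, 16, 18, a TIP3-style 3-site water,
and the single-chain zwitterionic test amphiphile ("SYN") emitted by the
synthetic trajectory generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = [
    "MoleculeSpec",
    "default_annotation",
    "load_annotation",
    "save_annotation",
]

VALID_KINDS = ("PC", "IPA_cation", "IPA_anion", "water")

# standard atomic masses, amu
_MASS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06}


@dataclass
class MoleculeSpec:
    """Role annotation for one molecule type.

    Parameters
    ----------
    name
        Residue name as it appears in coordinate files.
    kind
        One of ``PC`` (zwitterionic amphiphile), ``IPA_cation``,
        ``IPA_anion`` or ``water``.
    atoms
        Canonical atom-name order for one molecule.
    chain_defs
        Ordered carbon atom names per chain, keyed by chain label
        (``sn1``/``sn2`` for PC, ``chain`` for single-tail components).
        The first entry may be a carbonyl carbon without hydrogens.
    directive_endpoints
        ``(start, end)`` atom names per chain defining the directive
        vector: carbonyl carbon to second-last carbon for PC chains,
        first alkyl carbon to second-terminal carbon for ionic
        amphiphiles.  Overridable per chain to change the convention.
    head_atoms
        Mapping with keys ``cation_center``, ``anion_center``,
        ``hbond_acceptors``, ``hbond_donors`` (atom names or None/lists).
    chain_hydrogens
        Hydrogen atom names attached to each chain carbon.
    donor_hydrogens
        Hydrogen atom names attached to each hydrogen-bond donor atom.
    charges, masses
        Per-atom partial charge (e) and mass (amu).
    formal_charge
        Expected total charge: 0 for PC and water, +1/-1 for IPA parts.
    """

    name: str
    kind: str
    atoms: list[str]
    chain_defs: dict[str, list[str]] = field(default_factory=dict)
    directive_endpoints: dict[str, tuple[str, str]] = field(default_factory=dict)
    head_atoms: dict = field(default_factory=dict)
    chain_hydrogens: dict[str, list[str]] = field(default_factory=dict)
    donor_hydrogens: dict[str, list[str]] = field(default_factory=dict)
    charges: dict[str, float] = field(default_factory=dict)
    masses: dict[str, float] = field(default_factory=dict)
    formal_charge: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown molecule kind {self.kind!r}; expected one of {VALID_KINDS}")
        atom_set = set(self.atoms)
        for label, carbons in self.chain_defs.items():
            missing = [c for c in carbons if c not in atom_set]
            if missing:
                raise ValueError(f"{self.name}: chain {label!r} references unknown atoms {missing}")
        for label, (start, end) in self.directive_endpoints.items():
            if label not in self.chain_defs:
                raise ValueError(f"{self.name}: directive endpoints for unknown chain {label!r}")
            chain = self.chain_defs[label]
            for atom in (start, end):
                if atom not in chain:
                    raise ValueError(
                        f"{self.name}: directive endpoint {atom!r} not in chain {label!r}"
                    )
        if self.charges:
            total = sum(self.charges.get(a, 0.0) for a in self.atoms)
            if abs(total - self.formal_charge) > 1e-6:
                raise ValueError(
                    f"{self.name}: charges sum to {total:.6f}, expected formal "
                    f"charge {self.formal_charge:+.1f}"
                )

    @property
    def is_water(self) -> bool:
        return self.kind == "water"

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "kind": self.kind,
            "atoms": list(self.atoms),
            "chain_defs": {k: list(v) for k, v in self.chain_defs.items()},
            "directive_endpoints": {k: list(v) for k, v in self.directive_endpoints.items()},
            "head_atoms": self.head_atoms,
            "chain_hydrogens": {k: list(v) for k, v in self.chain_hydrogens.items()},
            "donor_hydrogens": {k: list(v) for k, v in self.donor_hydrogens.items()},
            "charges": self.charges,
            "masses": self.masses,
            "formal_charge": self.formal_charge,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MoleculeSpec":
        d = dict(d)
        d["directive_endpoints"] = {
            k: tuple(v) for k, v in d.get("directive_endpoints", {}).items()
        }
        return cls(**d)


def _chain_atoms(prefix: str, n: int, first: int = 1) -> list[str]:
    return [f"{prefix}{i}" for i in range(first, n + 1)]


def _tail_spec(n_carbons: int, carbon_prefix: str = "C") -> tuple[list[str], dict, list[str]]:
    """Carbon + hydrogen names for one alkyl tail (2 H per carbon, 3 on the terminal)."""
    carbons = _chain_atoms(carbon_prefix, n_carbons)
    hydrogens: dict[str, list[str]] = {}
    flat_h: list[str] = []
    for i, c in enumerate(carbons, start=1):
        labels = ["A", "B"] if i < n_carbons else ["A", "B", "C"]
        hydrogens[c] = [f"H{i}{s}" for s in labels]
        flat_h.extend(hydrogens[c])
    return carbons, hydrogens, flat_h


def _pc_spec(name: str, n: int) -> MoleculeSpec:
    """Di-acyl PC with two identical n-carbon acyl chains.

    Chain atom naming follows the CHARMM convention: sn-2 carbons
    C21..C2{n} (C21 is the carbonyl) with hydrogens H{k}R/H{k}S, sn-1
    carbons C31..C3{n} with hydrogens H{k}X/H{k}Y.  The head keeps the
    analysis-relevant N and P plus the phosphate/ester oxygens.
    """
    head = ["N", "C13", "C14", "C15", "C12", "C11", "P", "O11", "O12", "O13", "O14"]
    atoms = list(head)
    chain_defs: dict[str, list[str]] = {}
    chain_h: dict[str, list[str]] = {}
    for label, prefix, hsuf in (("sn2", "C2", ("R", "S", "T")), ("sn1", "C3", ("X", "Y", "Z"))):
        carbons = [f"{prefix}{k}" for k in range(1, n + 1)]
        chain_defs[label] = carbons
        atoms.extend(carbons)
        for k, c in enumerate(carbons, start=1):
            if k == 1:  # carbonyl carbon, no hydrogens
                chain_h[c] = []
                continue
            suffixes = hsuf[:2] if k < n else hsuf
            hs = [f"H{prefix[-1]}{k}{s}" for s in suffixes]
            chain_h[c] = hs
            atoms.extend(hs)
    charges = {a: 0.0 for a in atoms}
    charges["N"] = 1.0
    charges["P"] = -1.0
    masses = {a: _MASS[a[0]] for a in atoms if a[0] in _MASS}
    return MoleculeSpec(
        name=name,
        kind="PC",
        atoms=atoms,
        chain_defs=chain_defs,
        directive_endpoints={
            "sn2": (f"C21", f"C2{n - 1}"),
            "sn1": (f"C31", f"C3{n - 1}"),
        },
        head_atoms={
            "cation_center": "N",
            "anion_center": "P",
            "hbond_acceptors": ["O11", "O12", "O13", "O14"],
            "hbond_donors": [],
        },
        chain_hydrogens=chain_h,
        charges=charges,
        masses=masses,
        formal_charge=0.0,
    )


def _tma_spec(name: str, n: int) -> MoleculeSpec:
    """Alkyltrimethylammonium cation with an n-carbon tail."""
    carbons, chain_h, flat_h = _tail_spec(n)
    atoms = ["N", "CM1", "CM2", "CM3"] + carbons + flat_h
    charges = {a: 0.0 for a in atoms}
    charges["N"] = 1.0
    masses = {a: _MASS[a[0]] for a in atoms}
    return MoleculeSpec(
        name=name,
        kind="IPA_cation",
        atoms=atoms,
        chain_defs={"chain": carbons},
        directive_endpoints={"chain": ("C1", f"C{n - 1}")},
        head_atoms={
            "cation_center": "N",
            "anion_center": None,
            "hbond_acceptors": [],
            "hbond_donors": [],
        },
        chain_hydrogens=chain_h,
        charges=charges,
        masses=masses,
        formal_charge=1.0,
    )


def _sulfate_spec(name: str, n: int) -> MoleculeSpec:
    """Alkylsulfate anion with an n-carbon tail."""
    carbons, chain_h, flat_h = _tail_spec(n)
    atoms = ["S", "O1", "O2", "O3", "O4"] + carbons + flat_h
    charges = {a: 0.0 for a in atoms}
    charges["S"] = -1.0
    masses = {a: _MASS[a[0]] for a in atoms}
    return MoleculeSpec(
        name=name,
        kind="IPA_anion",
        atoms=atoms,
        chain_defs={"chain": carbons},
        directive_endpoints={"chain": ("C1", f"C{n - 1}")},
        head_atoms={
            "cation_center": None,
            "anion_center": "S",
            "hbond_acceptors": ["O1", "O2", "O3"],
            "hbond_donors": [],
        },
        chain_hydrogens=chain_h,
        charges=charges,
        masses=masses,
        formal_charge=-1.0,
    )


def _water_spec(name: str, o_name: str, h_names: tuple[str, str]) -> MoleculeSpec:
    atoms = [o_name, *h_names]
    return MoleculeSpec(
        name=name,
        kind="water",
        atoms=atoms,
        head_atoms={
            "cation_center": None,
            "anion_center": None,
            "hbond_acceptors": [o_name],
            "hbond_donors": [o_name],
        },
        donor_hydrogens={o_name: list(h_names)},
        charges={o_name: -0.834, h_names[0]: 0.417, h_names[1]: 0.417},
        masses={o_name: _MASS["O"], h_names[0]: _MASS["H"], h_names[1]: _MASS["H"]},
        formal_charge=0.0,
    )


def synthetic_amphiphile_spec(n_carbons: int = 12, name: str = "SYN") -> MoleculeSpec:
    """Single-chain zwitterionic amphiphile used by the synthetic generator.

    Head: a +1 cation center ``N`` and a -1 anion center ``S`` (net
    neutral, mimicking the laterally paired charges of an IPA complex);
    tail: ``n_carbons`` methylene-style carbons, each carrying two
    hydrogens so the all-trans order parameter is analytic.
    """
    carbons = _chain_atoms("C", n_carbons)
    chain_h = {c: [f"H{i}A", f"H{i}B"] for i, c in enumerate(carbons, start=1)}
    flat_h = [h for c in carbons for h in chain_h[c]]
    atoms = ["N", "S"] + carbons + flat_h
    charges = {a: 0.0 for a in atoms}
    charges["N"] = 1.0
    charges["S"] = -1.0
    masses = {a: _MASS[a[0]] for a in atoms}
    return MoleculeSpec(
        name=name,
        kind="PC",
        atoms=atoms,
        chain_defs={"chain": carbons},
        directive_endpoints={"chain": ("C1", f"C{n_carbons - 1}")},
        head_atoms={
            "cation_center": "N",
            "anion_center": "S",
            "hbond_acceptors": ["S"],
            "hbond_donors": [],
        },
        chain_hydrogens=chain_h,
        charges=charges,
        masses=masses,
        formal_charge=0.0,
    )


def default_annotation(chain_lengths: tuple[int, ...] = (12, 14, 16, 18)) -> dict[str, MoleculeSpec]:
    """Shipped default annotation: DCnPC, CnTMA, CnS, waters and SYN."""
    pc_names = {12: "DLPC", 14: "DMPC", 16: "DPPC", 18: "DSPC"}
    specs: dict[str, MoleculeSpec] = {}
    for n in chain_lengths:
        pc = pc_names.get(n, f"PC{n}")
        specs[pc] = _pc_spec(pc, n)
        specs[f"C{n}TMA"] = _tma_spec(f"C{n}TMA", n)
        specs[f"C{n}S"] = _sulfate_spec(f"C{n}S", n)
    specs["TIP3"] = _water_spec("TIP3", "OH2", ("H1", "H2"))
    specs["SOL"] = _water_spec("SOL", "OW", ("HW1", "HW2"))
    specs["SYN"] = synthetic_amphiphile_spec()
    return specs


def load_annotation(path) -> dict[str, MoleculeSpec]:
    """Load an annotation config (YAML mapping of residue name to spec)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"annotation file {path} does not contain a mapping")
    return {name: MoleculeSpec.from_dict(d) for name, d in raw.items()}


def save_annotation(specs: dict[str, MoleculeSpec], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({name: s.to_dict() for name, s in specs.items()}, fh, sort_keys=False)
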