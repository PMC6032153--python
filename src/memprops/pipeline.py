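"""Pipeline orchestration: run every enabled analysis over one system.

A validated :class:`RunConfig` drives the stages in dependency order
(tilt analysis feeds the splay gating), writes tidy TSV artifacts, a
summary table and a JSON run manifest, and records seeds and the
config snapshot so any output is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import interface, mechanics, structure
from .annotations import default_annotation, load_annotation
from .core import Trajectory, assign_leaflets, read_trajectory
from .structure import OrderProfile

log = logging.getLogger("memprops")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "phase_heuristic"]

_DEFAULT_TOGGLES = {
    "area": True,
    "density": True,
    "thickness": True,
    "tilt": True,
    "order": True,
    "gauche": True,
    "rdf": False,
    "ka": True,
    "tilt_modulus": True,
    "splay": True,
    "hbonds": True,
    "orientation": True,
    "potential": True,
    "residence": True,
    "rotation": True,
}

_DEFAULT_PARAMS = {
    "bin_width_profile": 0.1,  # nm
    "bin_width_angle_deg": 1.0,
    "tilt_fit_window_deg": 15.0,
    "splay_fit_max_deg": 40.0,
    "splay_cutoff_nm": 1.0,
    "splay_sigma_deg": None,  # None -> from phase heuristic (5 S / 10 Ld)
    "hbond_distance_nm": 0.35,
    "hbond_angle_deg": 30.0,
    "shell_nm": 0.45,
    "residence_reference": "anion_center",
    "rotation_vector": "water_dipole",
    "head_selector": "cation_center",
    "rdf_species": ["cation_center", "anion_center"],
    "rdf_rmax_nm": 2.0,
    "n_molecules_per_leaflet": None,  # None -> from leaflet assignment
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    coordinates: str | None = None
    trajectory: str | None = None
    annotation: str | None = None
    temperature: float | None = None
    phase_label: str = "auto"  # Ld | S | ripple | auto
    toggles: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "memprops_run"

    def __post_init__(self) -> None:
        if self.phase_label not in ("Ld", "S", "ripple", "auto"):
            raise ValueError(f"invalid phase_label {self.phase_label!r}")
        bad = set(self.toggles) - set(_DEFAULT_TOGGLES)
        if bad:
            raise ValueError(f"unknown analysis toggles: {sorted(bad)}")
        bad = set(self.params) - set(_DEFAULT_PARAMS)
        if bad:
            raise ValueError(f"unknown parameters: {sorted(bad)}")
        self.toggles = {**_DEFAULT_TOGGLES, **self.toggles}
        self.params = {**_DEFAULT_PARAMS, **self.params}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    summary: dict
    phase: str | None
    artifacts: dict[str, str]
    failures: dict[str, str]
    truth_comparison: dict | None = None

    @property
    def ok(self) -> bool:
        return not self.failures


def phase_heuristic(order_profile: OrderProfile) -> str:
    """Ld/S phase label from the plateau |SCD| (threshold 0.2, ties -> S).

    Advisory only: the plateau is the mean |SCD| over the middle third
    of chain carbons; below 0.2 indicates a liquid-disordered (Ld)
    bilayer, at or above 0.2 an ordered gel (S) bilayer.
    """
    plateau = order_profile.plateau_scd()
    if abs(plateau - 0.2) < 1e-12:
        log.warning("plateau |SCD| exactly at the 0.2 threshold: borderline, labeling S")
    return "Ld" if plateau < 0.2 else "S"


def _write_tsv(path: Path, df: pd.DataFrame, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig, traj: Trajectory | None = None) -> PipelineResult:
    """Execute every enabled analysis stage over one trajectory.

    The trajectory may be passed directly (e.g. fresh from the
    synthetic generator) or read from the configured files.  Stage
    failures are recorded and downstream dependents skipped; all
    artifacts are written under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = config.toggles
    p = config.params
    summary: dict = {}
    artifacts: dict[str, str] = {}
    failures: dict[str, str] = {}
    if not any(t.values()):
        warnings.warn("all analysis toggles are off: nothing to do", stacklevel=2)

    if traj is None:
        if config.coordinates is None:
            raise ValueError("no trajectory given and no coordinate file configured")
        annotation = (
            load_annotation(config.annotation) if config.annotation else default_annotation()
        )
        traj = read_trajectory(
            config.coordinates, config.trajectory, annotation, config.temperature
        )
    if traj.temperature is None:
        traj.temperature = config.temperature
    temperature = traj.temperature

    def _stage(name, enabled, fn, *deps):
        if not enabled:
            return None
        for d in deps:
            if d in failures:
                failures[name] = f"skipped: dependency {d} failed"
                log.warning("stage %s skipped (dependency %s failed)", name, d)
                return None
        try:
            value = fn()
            log.info("stage %s done", name)
            return value
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            failures[name] = str(exc)
            log.error("stage %s failed: %s", name, exc)
            return None

    leaf = _stage("leaflets", True, lambda: assign_leaflets(traj.frames[0]))
    n_per_leaflet = p["n_molecules_per_leaflet"]
    if n_per_leaflet is None and leaf is not None:
        n_per_leaflet = max(leaf.n_upper, leaf.n_lower)

    # --- structure -------------------------------------------------------
    area = _stage(
        "area", t["area"], lambda: structure.molecular_area(traj, n_per_leaflet), "leaflets"
    )
    if area is not None:
        summary["Amol_nm2"] = area.mean
        summary["Amol_sd"] = area.sd

    def _profiles():
        profs = {}
        for sel in ("water", p["head_selector"], "anion_center"):
            try:
                profs[sel] = structure.density_profile(
                    traj, sel, bin_width=p["bin_width_profile"]
                )
            except ValueError as exc:
                log.warning("density profile %s skipped: %s", sel, exc)
        if not profs:
            raise ValueError("no density profiles computable")
        rows = []
        for sel, prof in profs.items():
            for z, v in zip(prof.centers, prof.values):
                rows.append({"z_nm": z, "density": v, "species": sel})
        _write_tsv(out / "density_profiles.tsv", pd.DataFrame(rows),
                   ["transverse density profiles, bilayer-centered"])
        artifacts["density_profiles"] = str(out / "density_profiles.tsv")
        return profs

    profiles = _stage("density", t["density"], _profiles)

    h = _stage(
        "thickness",
        t["thickness"],
        lambda: structure.bilayer_thickness(
            traj, p["head_selector"], bin_width=p["bin_width_profile"]
        ),
        "leaflets",
    )
    if h is not None:
        summary["thickness_nm"] = h

    tilt = _stage("tilt", t["tilt"], lambda: structure.tilt_angles(traj), "leaflets")
    if tilt is not None:
        summary["tilt_mean_deg"] = float(np.degrees(tilt.angles.mean()))
        summary["tilt_sd_deg"] = float(np.degrees(tilt.angles.std()))

    order = _stage("order", t["order"], lambda: structure.deuterium_order(traj))
    gauche = _stage("gauche", t["gauche"], lambda: structure.gauche_profile(traj))
    if order is not None or gauche is not None:
        rows = []
        if order is not None:
            for chain, vals in order.scd.items():
                for k, v in enumerate(vals, start=1):
                    rows.append({"chain": chain, "position": k, "metric": "abs_SCD",
                                 "value": v})
        if gauche is not None:
            for chain, vals in gauche.gauche.items():
                for k, v in enumerate(vals, start=1):
                    rows.append({"chain": chain, "position": k, "metric": "gauche_fraction",
                                 "value": v})
        _write_tsv(out / "chain_order.tsv", pd.DataFrame(rows),
                   ["per-carbon |SCD| and per-dihedral gauche fractions"])
        artifacts["chain_order"] = str(out / "chain_order.tsv")
    if gauche is not None:
        summary["gauche_mean"] = float(
            np.mean(np.concatenate([np.asarray(v) for v in gauche.gauche.values()]))
        )

    phase = config.phase_label
    if phase in ("auto",):
        if order is not None:
            try:
                phase = phase_heuristic(order)
                summary["abs_SCD_plateau"] = order.plateau_scd()
            except ValueError:
                phase = None
        else:
            phase = None
    summary["phase"] = phase

    if t["rdf"]:
        def _rdf():
            a, b = p["rdf_species"]
            r, g = structure.rdf_2d(traj, a, b, r_max=p["rdf_rmax_nm"])
            _write_tsv(out / "rdf2d.tsv", pd.DataFrame({"r_nm": r, "g": g}),
                       [f"lateral 2D RDF {a} vs {b}"])
            artifacts["rdf2d"] = str(out / "rdf2d.tsv")
            return True

        _stage("rdf", True, _rdf, "leaflets")

    # --- mechanics -------------------------------------------------------
    def _ka():
        areas = traj.areas() / n_per_leaflet
        return mechanics.area_compressibility(
            areas, n_per_leaflet, temperature, seed=config.seed
        )

    ka = _stage("ka", t["ka"], _ka, "leaflets")
    if ka is not None:
        summary["KA_mN_per_m"] = ka.value
        summary["KA_stderr"] = ka.stderr

    bw = np.radians(p["bin_width_angle_deg"])
    tilt_mod = _stage(
        "tilt_modulus",
        t["tilt_modulus"],
        lambda: mechanics.tilt_modulus_from_samples(
            tilt, bin_width=bw, fit_window=np.radians(p["tilt_fit_window_deg"]),
            seed=config.seed,
        ),
        "tilt",
    )
    if tilt_mod is not None:
        summary["chi_tilt_kBT_rad2"] = tilt_mod.value
        summary["chi_tilt_r2"] = tilt_mod.r_squared
        summary["theta0_deg"] = float(np.degrees(tilt_mod.theta0))

    def _splay():
        sigma = p["splay_sigma_deg"]
        if sigma is None:
            sigma = 5.0 if phase == "S" else 10.0
        pmf = mechanics.boltzmann_invert(tilt, bw)
        theta_mp = pmf.theta[int(np.argmax(pmf.counts))]  # most probable tilt, ties -> lower
        samples, counts = mechanics.splay_pairs(
            traj, theta_mp, sigma=np.radians(sigma), cutoff=p["splay_cutoff_nm"]
        )
        chis = {
            key: mechanics.splay_modulus(
                s, bin_width=bw, fit_max=np.radians(p["splay_fit_max_deg"])
            )
            for key, s in samples.items()
        }
        kc = mechanics.effective_bending_rigidity(chis, counts)
        return chis, counts, kc

    splay = _stage("splay", t["splay"], _splay, "tilt", "tilt_modulus")
    if splay is not None:
        chis, counts, kc = splay
        summary["KC_eff_kBT"] = kc.value
        for key, res in chis.items():
            summary[f"chi_splay[{key}]_kBT_rad2"] = res.value
        artifact = pd.DataFrame(
            [
                {"pair_type": key, "chi_kBT_rad2": res.value, "n_pairs": counts[key],
                 "r2": res.r_squared}
                for key, res in chis.items()
            ]
        )
        _write_tsv(out / "splay_moduli.tsv", artifact, [f"KC_eff = {kc.value:.4g} kBT"])
        artifacts["splay_moduli"] = str(out / "splay_moduli.tsv")

    # --- interface -------------------------------------------------------
    hb = _stage(
        "hbonds",
        t["hbonds"],
        lambda: interface.hydrogen_bonds(
            traj, p["hbond_distance_nm"], np.radians(p["hbond_angle_deg"])
        ),
    )
    if hb is not None:
        summary["NHbond"] = hb.mean
        summary["NHbond_sd"] = hb.sd

    def _orientation():
        omap = interface.water_orientation(traj)
        rows = []
        zc = 0.5 * (omap.z_edges[:-1] + omap.z_edges[1:])
        ac = 0.5 * (omap.alpha_edges[:-1] + omap.alpha_edges[1:])
        for i, z in enumerate(zc):
            for j, a in enumerate(ac):
                if omap.prob[i, j] > 0:
                    rows.append({"z_nm": z, "alpha_deg": a, "prob": omap.prob[i, j]})
        _write_tsv(out / "water_orientation.tsv", pd.DataFrame(rows),
                   ["P(alpha | z), normalized per z slab"])
        artifacts["water_orientation"] = str(out / "water_orientation.tsv")
        return omap

    _stage("orientation", t["orientation"], _orientation)

    def _potential():
        qprof = _charge_profile()
        z, phi = interface.electrostatic_potential(qprof)
        _write_tsv(out / "potential.tsv", pd.DataFrame({"z_nm": z, "phi_V": phi}),
                   ["electrostatic potential, phi(0)=0 at bilayer center"])
        artifacts["potential"] = str(out / "potential.tsv")
        return z, phi

    def _charge_profile():
        # full-system charge density (every atom, charge-weighted)
        top = traj.topology
        zmax = max(f.box[2] for f in traj.frames) / 2.0
        bwz = p["bin_width_profile"]
        n_bins = int(np.ceil(2 * zmax / bwz))
        edges = (np.arange(n_bins + 1) - n_bins / 2.0) * bwz
        hist = np.zeros(n_bins)
        area_sum = 0.0
        for frame in traj.frames:
            z = frame.coords[:, 2] - frame.com_z()
            hsub, _ = np.histogram(z, bins=edges, weights=top.charges)
            hist += hsub
            area_sum += frame.box[0] * frame.box[1]
        mean_area = area_sum / traj.n_frames
        return structure.ZProfile(
            bin_edges=edges,
            values=hist / (traj.n_frames * bwz * mean_area),
            species="all",
            weighting="charge",
            area=mean_area,
            n_frames=traj.n_frames,
        )

    pot = _stage("potential", t["potential"], _potential)
    if pot is not None:
        z, phi = pot
        summary["phi_center_minus_edge_V"] = float(np.interp(0.0, z, phi) - phi[-1])

    res = _stage(
        "residence",
        t["residence"],
        lambda: interface.residence_time(
            traj, shell=p["shell_nm"], reference=p["residence_reference"]
        ),
    )
    if res is not None:
        summary["tau_residence_ps"] = res.tau if res.tau is not None else res.integral
        _write_tsv(out / "residence.tsv",
                   pd.DataFrame({"t_ps": res.lags, "R": res.values}),
                   [f"fit: {res.fit}", f"tau = {res.tau}"])
        artifacts["residence"] = str(out / "residence.tsv")

    rot = _stage(
        "rotation",
        t["rotation"],
        lambda: interface.rotational_relaxation(traj, vector=p["rotation_vector"]),
    )
    if rot is not None:
        summary["tau_rotation_ps"] = rot.tau if rot.tau is not None else rot.integral
        _write_tsv(out / "rotation.tsv",
                   pd.DataFrame({"t_ps": rot.lags, "C": rot.values}),
                   [f"fit: {rot.fit}", f"tau_relax = {rot.tau}"])
        artifacts["rotation"] = str(out / "rotation.tsv")

    # --- summary + manifest ----------------------------------------------
    summary_df = pd.DataFrame([summary])
    _write_tsv(out / "summary.tsv", summary_df, ["memprops summary table"])
    artifacts["summary"] = str(out / "summary.tsv")
    manifest = {
        "config": config.snapshot(),
        "seed": config.seed,
        "n_frames": traj.n_frames,
        "temperature_K": temperature,
        "failures": failures,
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=float)
    artifacts["manifest"] = str(out / "manifest.json")
    return PipelineResult(
        summary=summary, phase=phase, artifacts=artifacts, failures=failures
    )
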