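"""Heat-capacity profiles and melting-temperature extraction.

Consumes per-replica enthalpy series (e.g. from replica-exchange
simulations; the sampling engine itself is out of scope) and computes
``Cp(Ti) = (<Hi^2> - <Hi>^2) / (kB Ti^2)`` per replica, then locates
the main transition temperature Tm at the refined Cp peak.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("memprops")

KB_KJ_MOL = 8.314462618e-3  # kJ/mol/K

__all__ = ["ReplicaEnthalpy", "CpProfile", "heat_capacity", "tm_from_profile",
           "load_replica_tsv"]


@dataclass
class ReplicaEnthalpy:
    """Enthalpy samples (kJ/mol) simulated at one temperature (K)."""

    temperature: float
    enthalpy: np.ndarray

    def __post_init__(self) -> None:
        self.enthalpy = np.asarray(self.enthalpy, dtype=float)
        if self.enthalpy.size < 2:
            raise ValueError("each replica needs at least 2 enthalpy samples")


@dataclass
class CpProfile:
    """Heat capacity vs temperature, with the located transition peak."""

    temperatures: np.ndarray  # K, ascending
    cp: np.ndarray  # kJ/mol/K
    tm: float | None = None
    peak_uncertainty: float | None = None

    def __post_init__(self) -> None:
        if np.any(self.cp < 0):
            raise ValueError("heat capacity cannot be negative")


def heat_capacity(replicas) -> CpProfile:
    """Cp per replica from enthalpy fluctuations (molar units, kJ/mol/K).

    Accepts ReplicaEnthalpy objects or plain ``(temperature, samples)``
    pairs; the output is sorted by temperature.  Cp is invariant to
    adding a constant to all enthalpies of a replica.
    """
    reps = [
        r if isinstance(r, ReplicaEnthalpy) else ReplicaEnthalpy(r[0], np.asarray(r[1]))
        for r in replicas
    ]
    if not reps:
        raise ValueError("no replicas given")
    temps = np.array([r.temperature for r in reps])
    if len(np.unique(temps)) != len(temps):
        raise ValueError("replica temperatures must be unique")
    for r in reps:
        if r.enthalpy.size < 100:
            warnings.warn(
                f"replica at {r.temperature} K has only {r.enthalpy.size} samples",
                stacklevel=2,
            )
    order = np.argsort(temps)
    cp = np.array([np.var(reps[i].enthalpy) / (KB_KJ_MOL * temps[i] ** 2) for i in order])
    return CpProfile(temperatures=temps[order], cp=cp)


def tm_from_profile(profile: CpProfile) -> CpProfile:
    """Locate Tm at the Cp maximum, refined by quadratic interpolation.

    Requires the peak to be bracketed by the temperature ladder (a peak
    at either edge is an error).  The uncertainty is half the local
    ladder spacing.  Returns the profile with ``tm`` populated.
    """
    t, cp = profile.temperatures, profile.cp
    if len(t) < 3:
        raise ValueError("need at least 3 temperatures to locate a peak")
    i = int(np.argmax(cp))
    if i == 0 or i == len(t) - 1:
        raise ValueError("Cp peak at the ladder edge: the ladder does not bracket Tm")
    y0, y1, y2 = cp[i - 1], cp[i], cp[i + 1]
    denom = y0 - 2 * y1 + y2
    tm = float(t[i]) if denom >= 0 else float(
        t[i] + 0.5 * (y0 - y2) / denom * 0.5 * (t[i + 1] - t[i - 1])
    )
    spacing = 0.5 * (t[i + 1] - t[i - 1])
    profile.tm = tm
    profile.peak_uncertainty = float(spacing / 2.0)
    return profile


def load_replica_tsv(manifest_path) -> list[ReplicaEnthalpy]:
    """Read a replica ladder: a TSV manifest of (temperature, series file).

    Each series file is two-column TSV (time, enthalpy kJ/mol); paths
    are resolved relative to the manifest.
    """
    import pathlib

    manifest_path = pathlib.Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    if not {"temperature", "file"} <= set(manifest.columns):
        raise ValueError("ladder manifest needs 'temperature' and 'file' columns")
    reps = []
    for _, row in manifest.iterrows():
        series = pd.read_csv(manifest_path.parent / row["file"], sep="\t")
        reps.append(ReplicaEnthalpy(float(row["temperature"]), series.iloc[:, 1].to_numpy()))
    return reps
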