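"""Group-group electrostatic interaction energies and persistence-energy
correlation.

Energies are direct (non-periodic, cutoff-free) Coulomb sums over partial
charges in units of the elementary charge,

    E = k_e * sum_{i in A, j in B} q_i q_j / r_ij,  k_e = 332.0636 kcal A / (mol e^2),

averaged over a trailing window of snapshots.  The analysis of interest is
the relationship between the electrostatic energy of residue pairs and the
persistence of the hydrogen bonds they form: when secondary structure is
lost at higher temperature, both the persistence and the (negative)
interaction energy relax towards zero, so the two are strongly
anti-correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import Trajectory

__all__ = [
    "COULOMB_KCAL",
    "EnergyRecord",
    "CorrelationResult",
    "group_coulomb_energy",
    "energy_window_mean",
    "persistence_energy_correlation",
]

#: Coulomb constant in kcal mol^-1 A e^-2 (CODATA-derived MD convention).
COULOMB_KCAL = 332.0636


@dataclass
class EnergyRecord:
    """Per-frame and window-averaged interaction energy between two groups."""

    group_a: str
    group_b: str
    per_frame: np.ndarray
    window_mean: float
    window_sd: float


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between matched descriptor vectors."""

    r: float
    r_squared: float
    n_points: int


def group_coulomb_energy(
    frame: np.ndarray,
    charges: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
) -> float:
    """Direct Coulomb interaction energy (kcal/mol) between two disjoint groups."""
    frame = np.asarray(frame, dtype=float)
    charges = np.asarray(charges, dtype=float)
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups overlap; self-interaction is excluded by contract")
    delta = frame[group_a][:, None, :] - frame[group_b][None, :, :]
    r = np.linalg.norm(delta, axis=2)
    if np.any(r < 1e-9):
        raise ZeroDivisionError("coincident atoms across groups: Coulomb singularity")
    qq = charges[group_a][:, None] * charges[group_b][None, :]
    return float(COULOMB_KCAL * np.sum(qq / r))


def energy_window_mean(
    traj: Trajectory,
    charges: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    window: int | None = None,
    label_a: str = "A",
    label_b: str = "B",
) -> EnergyRecord:
    """Interaction energy per frame over the trailing window, with mean and SD."""
    if window is None:
        window = traj.n_frames
    if window < 1 or window > traj.n_frames:
        raise ValueError(f"window {window} outside [1, {traj.n_frames}]")
    energies = np.array(
        [
            group_coulomb_energy(traj.coords[f], charges, group_a, group_b)
            for f in range(traj.n_frames - window, traj.n_frames)
        ]
    )
    return EnergyRecord(
        group_a=label_a,
        group_b=label_b,
        per_frame=energies,
        window_mean=float(energies.mean()),
        window_sd=float(energies.std(ddof=0)),
    )


def persistence_energy_correlation(
    persistences: np.ndarray,
    energies: np.ndarray,
) -> CorrelationResult:
    """Pearson r between matched persistence and window-mean energy points."""
    persistences = np.asarray(persistences, dtype=float)
    energies = np.asarray(energies, dtype=float)
    if persistences.shape != energies.shape or persistences.ndim != 1:
        raise ValueError("persistences and energies must be matched 1-D vectors")
    if persistences.size < 3:
        raise ValueError("correlation needs at least 3 matched points")
    if np.ptp(persistences) == 0 or np.ptp(energies) == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(stats.pearsonr(persistences, energies).statistic)
    return CorrelationResult(r=r, r_squared=r * r, n_points=int(persistences.size))
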