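"""Solvent-accessible surface area by the rolling-probe point-sampling method.

Shrake-Rupley scheme: each atom's sphere is expanded by the probe radius
(default 1.4 A, a water-sized probe) and covered with a deterministic
Fibonacci lattice of test points; the accessible fraction is the fraction of
points not buried inside any neighbour's expanded sphere.  Point placement
is deterministic so results are bit-stable across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ._elements import vdw_radius_of
from .io import Structure, Trajectory

__all__ = ["SasaProfile", "sasa", "sasa_series", "delta_sasa_per_residue", "atom_radii"]


@dataclass
class SasaProfile:
    """Per-atom and per-residue SASA (A^2) for one frame."""

    atom_sasa: np.ndarray
    residue_keys: list[tuple[str, int, str]]
    residue_sasa: np.ndarray
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.atom_sasa.sum())


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice of ``n`` points."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden-angle increment
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_radii(structure: Structure, indices: np.ndarray | None = None) -> np.ndarray:
    """Bondi van der Waals radii for the selected atoms."""
    atoms = structure.atoms
    if indices is None:
        indices = np.arange(len(atoms))
    return np.array([vdw_radius_of(atoms[i].element) for i in np.asarray(indices, dtype=int)])


def sasa_atoms(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom Shrake-Rupley SASA (A^2) for one coordinate set."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    if n_points < 60:
        raise ValueError("n_points must be at least 60 for a usable sphere sampling")
    if np.any(radii <= 0):
        raise ValueError("vdW radii must be positive")
    n = coords.shape[0]
    expanded = radii + probe
    sphere = fibonacci_sphere(n_points)
    # Pairwise distances once; neighbour lists per atom.
    d = cdist(coords, coords)
    if n > 1:
        off_diag = d[~np.eye(n, dtype=bool)]
        if np.any(off_diag < 1e-9):
            warnings.warn(
                "coincident atoms in SASA input; overlapping surfaces are double counted",
                stacklevel=2,
            )
    out = np.empty(n)
    for i in range(n):
        nbr = np.where((d[i] < expanded[i] + expanded) & (np.arange(n) != i))[0]
        pts = coords[i] + expanded[i] * sphere
        if nbr.size:
            # buried if strictly inside a neighbour's expanded sphere
            dist2 = np.sum((pts[:, None, :] - coords[nbr][None, :, :]) ** 2, axis=2)
            buried = np.any(dist2 < (expanded[nbr] ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return out


def sasa(
    frame: np.ndarray,
    structure: Structure,
    selection: np.ndarray | None = None,
    probe: float = 1.4,
    n_points: int = 960,
    radii: np.ndarray | None = None,
) -> SasaProfile:
    """SASA profile of one frame over ``selection`` (default: all atoms)."""
    if selection is None:
        selection = np.arange(structure.n_atoms)
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty SASA selection")
    if radii is None:
        radii = atom_radii(structure, selection)
    atom_vals = sasa_atoms(np.asarray(frame)[selection], radii, probe, n_points)
    keys: list[tuple[str, int, str]] = []
    sums: dict[tuple[str, int, str], float] = {}
    for val, i in zip(atom_vals, selection):
        a = structure.atoms[i]
        key = (a.chain, a.residue_number, a.residue_name)
        if key not in sums:
            sums[key] = 0.0
            keys.append(key)
        sums[key] += float(val)
    return SasaProfile(
        atom_sasa=atom_vals,
        residue_keys=keys,
        residue_sasa=np.array([sums[k] for k in keys]),
        probe_radius=probe,
        n_sphere_points=n_points,
    )


def sasa_series(
    traj: Trajectory,
    structure: Structure,
    selection: np.ndarray | None = None,
    probe: float = 1.4,
    n_points: int = 960,
    stride: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Total SASA per analysed frame.

    Returns ``(frame_indices, totals)``; ``stride`` subsamples frames for
    long trajectories.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if selection is None:
        selection = np.arange(structure.n_atoms)
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty SASA selection")
    radii = atom_radii(structure, selection)
    frames = np.arange(0, traj.n_frames, stride)
    totals = np.array(
        [
            sasa_atoms(traj.coords[f][selection], radii, probe, n_points).sum()
            for f in frames
        ]
    )
    return frames, totals


def delta_sasa_per_residue(
    traj: Trajectory,
    structure: Structure,
    times: np.ndarray,
    selection: np.ndarray | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[list[tuple[str, int, str]], np.ndarray]:
    """Per-residue SASA change relative to frame 0 at the requested frames.

    Returns ``(residue_keys, dsasa)`` with ``dsasa`` of shape
    ``(len(times), n_residues)``; dSASA_i(t) = SASA_i(t) - SASA_i(0).
    """
    times = np.asarray(times, dtype=int)
    if np.any((times < 0) | (times >= traj.n_frames)):
        raise IndexError("requested frame index out of range")
    base = sasa(traj.coords[0], structure, selection, probe, n_points)
    rows = []
    for t in times:
        prof = sasa(traj.coords[t], structure, selection, probe, n_points)
        rows.append(prof.residue_sasa - base.residue_sasa)
    return base.residue_keys, np.asarray(rows)
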