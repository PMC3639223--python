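"""Ion radial distribution functions and first-shell coordination counts.

Distances use the minimum-image convention in a cubic periodic box (edge per
frame).  g(r) is normalised by shell volume, per-frame partner number
density, the number of reference (group A) atoms, and the frame count, so a
uniform ideal-gas partner distribution gives g ~ 1 in the bulk.  The
coordination number integrates rho * g(r) * 4 pi r^2 dr up to a cutoff and
is therefore the average number of partners within that cutoff per reference
atom per frame.  The reference group here is typically the backbone amide
hydrogens and the partner group the halide anions, probing N-H...X- contact
(first peak near 2 A for F-, near 2.5 A for Cl-).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Trajectory

__all__ = ["RDFProfile", "rdf", "coordination_number", "contact_count_series"]


class PBCError(ValueError):
    """Periodic-boundary information missing or inconsistent."""


@dataclass
class RDFProfile:
    """Radial distribution function between two atom groups."""

    bin_centers: np.ndarray
    g: np.ndarray
    dr: float
    r_max: float
    partner_density: float
    n_pairs_observed: int
    n_reference_atoms: int
    n_frames: int


def _min_image_distances(a: np.ndarray, b: np.ndarray, box: float) -> np.ndarray:
    """All pairwise minimum-image distances between point sets a and b."""
    delta = a[:, None, :] - b[None, :, :]
    delta -= box * np.round(delta / box)
    return np.linalg.norm(delta, axis=2)


def rdf(
    traj: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
    dr: float = 0.1,
    r_max: float | None = None,
) -> RDFProfile:
    """Radial distribution function of group B partners around group A atoms."""
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("rdf groups must be non-empty")
    if traj.box_per_frame is None:
        raise PBCError("rdf requires a periodic box edge per frame")
    if dr <= 0:
        raise ValueError("dr must be positive")
    min_box = float(np.min(traj.box_per_frame))
    if r_max is None:
        r_max = min(10.0, min_box / 2.0)
    if r_max > min_box / 2.0 + 1e-9:
        raise ValueError(f"r_max {r_max} exceeds half the smallest box edge {min_box / 2.0}")
    n_bins = int(round(r_max / dr))
    edges = np.arange(n_bins + 1) * dr
    hist = np.zeros(n_bins)
    density_sum = 0.0
    n_pairs = 0
    for f in range(traj.n_frames):
        box = float(traj.box_per_frame[f])
        d = _min_image_distances(traj.coords[f][group_a], traj.coords[f][group_b], box)
        h, _ = np.histogram(d.ravel(), bins=edges)
        hist += h
        n_pairs += int((d.ravel() < r_max).sum())
        density_sum += group_b.size / box**3
    rho = density_sum / traj.n_frames
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 * np.pi * centers**2 * dr
    norm = traj.n_frames * group_a.size * rho * shell_vol
    g = hist / norm
    return RDFProfile(
        bin_centers=centers,
        g=g,
        dr=dr,
        r_max=r_max,
        partner_density=rho,
        n_pairs_observed=n_pairs,
        n_reference_atoms=int(group_a.size),
        n_frames=traj.n_frames,
    )


def coordination_number(profile: RDFProfile, r_cut: float) -> float:
    """Average number of partners within ``r_cut`` per reference atom.

    N(r_cut) = rho * sum over bins below the cutoff of g(r) 4 pi r^2 dr.
    """
    if r_cut > profile.r_max + 1e-9:
        raise ValueError("r_cut exceeds the profile's r_max")
    mask = profile.bin_centers <= r_cut
    shell_vol = 4.0 * np.pi * profile.bin_centers[mask] ** 2 * profile.dr
    return float(profile.partner_density * np.sum(profile.g[mask] * shell_vol))


def contact_count_series(
    traj: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
    r_cut: float,
) -> np.ndarray:
    """Per-frame count of A-B pairs within ``r_cut`` under minimum image."""
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("contact groups must be non-empty")
    if traj.box_per_frame is None:
        raise PBCError("contact counting requires a periodic box edge per frame")
    out = np.empty(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        box = float(traj.box_per_frame[f])
        d = _min_image_distances(traj.coords[f][group_a], traj.coords[f][group_b], box)
        out[f] = int((d < r_cut).sum())
    return out
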