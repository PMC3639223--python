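"""Rigid-body superposition and positional-disorder descriptors.

The conventions follow the usual trajectory-analysis protocol: every frame
is least-squares superposed (Kabsch) onto the first frame over a backbone
selection, fluctuations are measured about the window-mean structure, and
RMSF is converted to an isotropic crystallographic B-factor via

    B = (8 pi^2 / 3) <|dr|^2>

with the per-residue B averaged over non-hydrogen backbone atoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from ._elements import mass_of
from .io import Structure, Trajectory

__all__ = [
    "SuperpositionResult",
    "BFactorProfile",
    "B_FROM_MSF",
    "kabsch_superpose",
    "apply_superposition",
    "superpose_frames",
    "rmsd_series",
    "average_structure",
    "rmsf",
    "bfactor_from_rmsf",
    "radius_of_gyration",
    "rgyr_series",
    "average_bfactor",
]

#: Conversion constant between mean-square fluctuation and B-factor, 8 pi^2 / 3.
B_FROM_MSF = 8.0 * np.pi**2 / 3.0


class DegenerateSelectionError(ValueError):
    """Superposition selection has fewer than 3 non-collinear atoms."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rotation, translation and post-fit RMSD (A).

    The transform maps mobile coordinates onto the reference:
    ``x_fit = (x_mobile - mobile_centroid) @ rotation.T + ref_centroid``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    mobile_centroid: np.ndarray
    reference_centroid: np.ndarray


@dataclass
class BFactorProfile:
    """Per-residue isotropic B-factors (A^2) with the per-atom RMSF source."""

    residue_keys: list[tuple[str, int, str]]
    b_values: np.ndarray
    source_rmsf: np.ndarray
    atom_indices: np.ndarray

    def as_dict(self) -> dict[tuple[str, int, str], float]:
        return dict(zip(self.residue_keys, self.b_values))


def _check_selection(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateSelectionError("superposition needs at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateSelectionError("superposition selection is collinear")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation (Kabsch).

    ``selection`` restricts the fit (and the reported RMSD) to a congruent
    subset of atom indices in both coordinate sets.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference coordinate sets are not congruent")
    if selection is not None:
        selection = np.asarray(selection, dtype=int)
        if selection.size == 0:
            raise DegenerateSelectionError("empty superposition selection")
        mob_sel, ref_sel = mobile[selection], reference[selection]
    else:
        mob_sel, ref_sel = mobile, reference
    _check_selection(mob_sel)
    mob_c = mob_sel.mean(axis=0)
    ref_c = ref_sel.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref_sel - ref_c, mob_sel - mob_c)
    R = rot.as_matrix()
    rmsd = float(rssd) / np.sqrt(mob_sel.shape[0])
    translation = ref_c - R @ mob_c
    return SuperpositionResult(
        rotation=R,
        translation=translation,
        rmsd=rmsd,
        mobile_centroid=mob_c,
        reference_centroid=ref_c,
    )


def apply_superposition(coords: np.ndarray, fit: SuperpositionResult) -> np.ndarray:
    """Apply a fitted rigid transform to a full coordinate set."""
    return coords @ fit.rotation.T + fit.translation


def superpose_frames(
    coords: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Superpose every frame of ``coords`` onto ``reference`` over ``selection``."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        fit = kabsch_superpose(coords[f], reference, selection)
        out[f] = apply_superposition(coords[f], fit)
    return out


def rmsd_series(
    traj: Trajectory,
    reference: Structure | np.ndarray,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame backbone RMSD (A) to a reference after independent superposition."""
    ref = reference.positions if isinstance(reference, Structure) else np.asarray(reference)
    if isinstance(reference, Structure) and selection is None:
        selection = reference.backbone_indices()
    return np.array(
        [kabsch_superpose(traj.coords[f], ref, selection).rmsd for f in range(traj.n_frames)]
    )


def average_structure(
    traj: Trajectory,
    window: int | None = None,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Coordinate-wise mean over the trailing ``window`` frames.

    All window frames are first superposed onto the trajectory's first frame
    over ``selection`` (typically the backbone).
    """
    if window is None:
        window = traj.n_frames
    if window <= 0:
        raise ValueError("window must be a positive frame count")
    if window > traj.n_frames:
        raise ValueError(f"window {window} exceeds trajectory length {traj.n_frames}")
    fitted = superpose_frames(traj.coords[-window:], traj.coords[0], selection)
    return fitted.mean(axis=0)


def rmsf(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    window: int | None = None,
    superpose_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom RMSF (A) about the window-mean position.

    Frames in the trailing window are superposed onto the first trajectory
    frame (over ``superpose_selection``, defaulting to ``selection``) before
    fluctuations are measured.  RMSF_i = sqrt(<|r_i - <r_i>|^2>).
    """
    if window is None:
        window = traj.n_frames
    if window < 2:
        raise ValueError("rmsf needs a window of at least 2 frames")
    if window > traj.n_frames:
        raise ValueError(f"window {window} exceeds trajectory length {traj.n_frames}")
    fit_sel = superpose_selection if superpose_selection is not None else selection
    fitted = superpose_frames(traj.coords[-window:], traj.coords[0], fit_sel)
    if selection is not None:
        fitted = fitted[:, np.asarray(selection, dtype=int), :]
    mean = fitted.mean(axis=0)
    msf = np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0)
    return np.sqrt(msf)


def bfactor_from_rmsf(
    rmsf_values: np.ndarray,
    structure: Structure,
    atom_indices: np.ndarray,
) -> BFactorProfile:
    """Convert per-atom RMSF to per-residue B-factors.

    B_atom = (8 pi^2 / 3) RMSF^2; the residue value is the mean over that
    residue's non-hydrogen backbone atoms among ``atom_indices``.
    """
    rmsf_values = np.asarray(rmsf_values, dtype=float)
    atom_indices = np.asarray(atom_indices, dtype=int)
    if rmsf_values.shape != atom_indices.shape:
        raise ValueError("rmsf_values and atom_indices must be congruent")
    if np.any(rmsf_values < 0):
        raise ValueError("RMSF values must be non-negative")
    b_atom = B_FROM_MSF * rmsf_values**2
    keys: list[tuple[str, int, str]] = []
    values: list[float] = []
    per_res: dict[tuple[str, int, str], list[float]] = {}
    order: list[tuple[str, int, str]] = []
    for b, i in zip(b_atom, atom_indices):
        a = structure.atoms[i]
        if a.is_hydrogen or not a.is_backbone:
            continue
        key = (a.chain, a.residue_number, a.residue_name)
        if key not in per_res:
            per_res[key] = []
            order.append(key)
        per_res[key].append(b)
    for key in order:
        keys.append(key)
        values.append(float(np.mean(per_res[key])))
    return BFactorProfile(
        residue_keys=keys,
        b_values=np.asarray(values),
        source_rmsf=rmsf_values,
        atom_indices=atom_indices,
    )


def radius_of_gyration(frame: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted RMS distance from the centre of mass (A)."""
    frame = np.asarray(frame, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if frame.shape[0] < 1:
        raise ValueError("radius_of_gyration needs at least one atom")
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    com = np.average(frame, axis=0, weights=masses)
    sq = np.sum((frame - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def rgyr_series(traj: Trajectory, structure: Structure) -> np.ndarray:
    """Per-frame radius of gyration using standard atomic masses."""
    masses = np.array([mass_of(a.element) for a in structure.atoms])
    return np.array([radius_of_gyration(traj.coords[f], masses) for f in range(traj.n_frames)])


def average_bfactor(profile: BFactorProfile) -> float:
    """Unweighted mean residue B-factor (A^2)."""
    if len(profile.b_values) == 0:
        raise ValueError("empty B-factor profile")
    return float(np.mean(profile.b_values))
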