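"""Synthetic structures, trajectories, ion systems and condition panels with
fully planted ground truth.

The generator emulates the features the analysis pipeline measures, not
physical dynamics:

* an ideal poly-alanine backbone (N, H, CA, C, O per residue) built from
  standard internal coordinates, as an alpha-helix (every residue i >= 5
  donates an amide N-H to the carbonyl O of residue i-4 within the geometric
  hydrogen-bond criteria) or as a fully extended strand (no hydrogen bonds);
* trajectories in which each donor/acceptor pair follows a deterministic
  frame schedule -- the first k of n frames bonded (donor-acceptor distance
  2.9 A, zero angular deviation), the rest broken (4.2 A) -- so presence
  fractions are exact rational numbers, plus optional isotropic Gaussian
  jitter whose sigma is kept small against the 3.5 A cutoff guard band;
* cubic periodic ion boxes with uniform mobile anions/cations, an optional
  "sticky" fraction of anions pinned 2.0 A from amide hydrogens, and
  optional glycan-like blocker particles occluding those sites;
* a full temperature x salt x glycosylation condition panel whose
  persistent-bond counts follow planted linear effects exactly.

Determinism: identical seeds and parameters give identical output arrays.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .interactions import detect_hbonds_frame, hbond_persistence
from .io import AtomRecord, ConditionSpec, Structure, Topology, Trajectory, perceive_topology

__all__ = [
    "PlantedTruth",
    "PanelSpec",
    "IonSystem",
    "generate_peptide",
    "generate_trajectory",
    "generate_ion_system",
    "generate_condition_panel",
]

# Scheduled donor-acceptor distances (A): bonded well inside the 3.5 A
# cutoff, broken well outside, so jitter sigma <= SIGMA_EXACT_MAX cannot
# flip a scheduled state (> 7 sigma margins even for three jittered atoms).
BONDED_DA = 2.9
BROKEN_DA = 4.2
SIGMA_EXACT_MAX = 0.05


@dataclass
class PlantedTruth:
    """Exact ground truth planted into a synthetic data set."""

    hbond_schedule: dict[tuple[int, int], float] = field(default_factory=dict)
    noise_sigma_by_T: dict[float, float] = field(default_factory=dict)
    planted_slope_per_50K: float | None = None
    planted_glyco_delta: float | None = None
    sticky_ion_fraction: float | None = None
    seed: int = 0
    expected_persistent_counts: dict[str, int] = field(default_factory=dict)
    expected_average_counts: dict[str, float] = field(default_factory=dict)
    expected_glyco_mean_delta: float | None = None
    expected_glyco_sign_consistency: tuple[int, int] | None = None
    expected_salt_deltas: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        def _key(k):
            return "|".join(str(x) for x in k) if isinstance(k, tuple) else str(k)

        payload = {
            "hbond_schedule": {_key(k): v for k, v in self.hbond_schedule.items()},
            "noise_sigma_by_T": {str(k): v for k, v in self.noise_sigma_by_T.items()},
            "planted_slope_per_50K": self.planted_slope_per_50K,
            "planted_glyco_delta": self.planted_glyco_delta,
            "sticky_ion_fraction": self.sticky_ion_fraction,
            "seed": self.seed,
            "expected_persistent_counts": self.expected_persistent_counts,
            "expected_average_counts": self.expected_average_counts,
            "expected_glyco_mean_delta": self.expected_glyco_mean_delta,
            "expected_glyco_sign_consistency": list(self.expected_glyco_sign_consistency)
            if self.expected_glyco_sign_consistency
            else None,
            "expected_salt_deltas": self.expected_salt_deltas,
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Ideal peptide construction
# ---------------------------------------------------------------------------

# Standard backbone internal coordinates (A, degrees).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.01
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

_CONFORMATIONS = {
    "helix": (-57.0, -47.0),  # alpha-helix: i -> i-4 amide ladder
    "extended": (180.0, 180.0),  # fully extended: no intra-backbone bonds
}


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, dihedral: float
) -> np.ndarray:
    """Position atom D given A-B-C, |CD|, angle(B,C,D) and dihedral(A,B,C,D)."""
    ang, dih = math.radians(angle), math.radians(dihedral)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * (-math.cos(ang) * bc + math.sin(ang) * math.cos(dih) * m + math.sin(ang) * math.sin(dih) * n)
    return c + d


def generate_peptide(n_res: int, geometry: str = "helix") -> Structure:
    """Ideal poly-alanine backbone with explicit amide hydrogens.

    ``geometry`` selects the backbone dihedrals: ``"helix"`` produces the
    alpha-helical amide ladder (donors i >= 5 bonded to acceptors i-4),
    ``"extended"`` a fully extended strand with no internal hydrogen bonds.
    """
    if n_res < 4:
        raise ValueError("peptide needs at least 4 residues")
    try:
        phi, psi = _CONFORMATIONS[geometry]
    except KeyError:
        raise ValueError(f"unknown geometry {geometry!r}; use 'helix' or 'extended'") from None

    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = math.radians(_A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])]
    O: list[np.ndarray | None] = [None] * n_res
    H: list[np.ndarray | None] = [None] * n_res

    for i in range(1, n_res):
        N.append(_place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi))
        CA.append(_place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0))
        C.append(_place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi))
        O[i - 1] = _place_atom(N[i], CA[i - 1], C[i - 1], _B_C_O, _A_CA_C_O, 180.0)
        u1 = C[i - 1] - N[i]
        u2 = CA[i] - N[i]
        bis = -(u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2))
        H[i] = N[i] + _B_N_H * bis / np.linalg.norm(bis)
    # C-terminal carbonyl O (excluded from acceptors downstream).
    O[n_res - 1] = _place_atom(N[n_res - 1], CA[n_res - 1], C[n_res - 1], _B_C_O, _A_CA_C_O, 180.0)

    atoms: list[AtomRecord] = []
    serial = 1
    for i in range(n_res):
        per_res = [("N", "N", N[i])]
        if H[i] is not None:
            per_res.append(("H", "H", H[i]))
        per_res += [("CA", "C", CA[i]), ("C", "C", C[i]), ("O", "O", O[i])]
        for name, element, pos in per_res:
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=element,
                    residue_name="ALA",
                    residue_number=i + 1,
                    chain="A",
                    position=pos,
                    is_hydrogen=element == "H",
                    is_backbone=True,
                )
            )
            serial += 1
    return Structure(atoms=atoms)


# ---------------------------------------------------------------------------
# Scheduled trajectories
# ---------------------------------------------------------------------------


def _base_pairs(
    structure: Structure, topology: Topology
) -> dict[tuple[int, int], tuple[int, int, int]]:
    """Donor/acceptor residue-number pairs bonded in the ideal frame,
    mapped to their (N, H, O) atom indices."""
    events = detect_hbonds_frame(structure.positions, topology, structure)
    out = {}
    for ev in events:
        d_res = structure.atoms[ev.donor_n].residue_number
        a_res = structure.atoms[ev.acceptor_o].residue_number
        out[(d_res, a_res)] = (ev.donor_n, ev.hydrogen, ev.acceptor_o)
    return out


def generate_trajectory(
    structure: Structure,
    n_frames: int,
    noise_sigma: float = 0.0,
    schedule: dict[tuple[int, int], float] | None = None,
    seed: int = 0,
    frame_interval_ps: float = 20.0,
    verify: bool = True,
) -> tuple[Trajectory, PlantedTruth]:
    """Trajectory with per-pair hydrogen-bond schedules realised exactly.

    ``schedule`` maps (donor residue number, acceptor residue number) to a
    target presence fraction expressible as k/n_frames.  Scheduled pairs are
    bonded (acceptor O placed 2.9 A from the donor N along the N->H axis,
    zero angular deviation) in the first k frames and broken (4.2 A along
    the same axis) afterwards.  Base-frame pairs not in the schedule keep
    their ideal geometry and therefore persist in every frame.  Isotropic
    Gaussian jitter with per-coordinate ``noise_sigma`` is added to every
    atom; above ``SIGMA_EXACT_MAX`` the exactness guarantee is dropped and
    verification is skipped.

    In noise-free mode (and ``verify=True``) the planted table is re-derived
    by running the detector on the finished trajectory and must match the
    schedule exactly, else a ``RuntimeError`` flags the construction.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be positive")
    schedule = dict(schedule or {})
    topology, structure = perceive_topology(structure)
    pair_atoms = _base_pairs(structure, topology)
    for pair, frac in schedule.items():
        if pair not in pair_atoms:
            raise ValueError(f"scheduled pair {pair} is not bonded in the base frame")
        k = frac * n_frames
        if not (0.0 <= frac <= 1.0) or abs(k - round(k)) > 1e-9:
            raise ValueError(
                f"pair {pair}: fraction {frac} is not expressible as k/{n_frames}"
            )

    rng = np.random.default_rng(seed)
    base = structure.positions
    coords = np.repeat(base[None, :, :], n_frames, axis=0)

    for pair, (n_i, h_i, o_i) in pair_atoms.items():
        frac = schedule.get(pair)
        if frac is None:
            continue  # unscheduled base pair keeps ideal geometry (fraction 1)
        k = int(round(frac * n_frames))
        axis = base[h_i] - base[n_i]
        axis = axis / np.linalg.norm(axis)
        coords[:k, o_i] = base[n_i] + BONDED_DA * axis
        coords[k:, o_i] = base[n_i] + BROKEN_DA * axis

    if noise_sigma > 0:
        coords = coords + rng.normal(0.0, noise_sigma, size=coords.shape)

    traj = Trajectory(coords=coords, frame_interval_ps=frame_interval_ps)

    expected = {
        pair: schedule.get(pair, 1.0) for pair in pair_atoms if schedule.get(pair, 1.0) > 0
    }
    truth = PlantedTruth(
        hbond_schedule=expected,
        noise_sigma_by_T={},
        seed=seed,
    )

    if verify and noise_sigma <= SIGMA_EXACT_MAX:
        table = hbond_persistence(traj, topology, structure)
        measured = {}
        for (n_i, h_i, o_i), frac in table.fractions.items():
            d_res = structure.atoms[n_i].residue_number
            a_res = structure.atoms[o_i].residue_number
            measured[(d_res, a_res)] = frac
        if noise_sigma == 0.0 and measured != expected:
            extra = set(measured) - set(expected)
            missing = set(expected) - set(measured)
            bad = {
                p: (expected.get(p), measured.get(p))
                for p in set(expected) & set(measured)
                if not math.isclose(expected[p], measured[p])
            }
            raise RuntimeError(
                "planted schedule not realised exactly: "
                f"extra={sorted(extra)} missing={sorted(missing)} mismatched={bad}"
            )
    return traj, truth


# ---------------------------------------------------------------------------
# Ion systems
# ---------------------------------------------------------------------------


@dataclass
class IonSystem:
    """A peptide in a cubic periodic box with mobile monovalent ions."""

    structure: Structure
    traj: Trajectory
    charges: np.ndarray
    amide_h_indices: np.ndarray
    anion_indices: np.ndarray
    cation_indices: np.ndarray
    blocker_indices: np.ndarray
    planted_first_shell: float
    seed: int


def generate_ion_system(
    peptide: Structure,
    box_length: float,
    n_pairs: int,
    n_frames: int = 100,
    sticky_fraction: float = 0.0,
    sticky_distance: float = 2.0,
    shielded: bool = False,
    anion: str = "F",
    cation: str = "K",
    seed: int = 0,
    frame_interval_ps: float = 20.0,
) -> IonSystem:
    """Peptide centred in a cubic box with uniform ions and optional sticky sites.

    A ``sticky_fraction`` of the anions is pinned ``sticky_distance`` (2.0 A,
    the N-H...F- contact distance) beyond randomly chosen distinct amide
    hydrogens along the outward N->H axis for the whole trajectory; the
    remainder (and all cations) are redrawn uniformly in the box every frame.  With ``shielded`` set, neutral
    glycan-like blocker particles occupy the sticky positions instead and
    the would-be sticky anions are released to the bulk, emulating steric
    occlusion of anion-binding sites by surface carbohydrate.

    The planted first-shell coordination (average anions within the contact
    shell per amide H) is ``n_sticky / n_sites`` when unshielded, 0 when
    shielded, bulk background aside.
    """
    if not (0.0 <= sticky_fraction <= 1.0):
        raise ValueError("sticky_fraction must lie in [0, 1]")
    if box_length <= 0 or n_pairs < 0 or n_frames < 1:
        raise ValueError("box_length must be > 0, n_pairs >= 0, n_frames >= 1")

    topology, peptide = perceive_topology(peptide)
    sites = np.asarray(topology.amide_hydrogens, dtype=int)
    if sites.size == 0:
        raise ValueError("peptide has no amide hydrogens to serve as sticky sites")
    n_sticky = int(round(sticky_fraction * n_pairs))
    if n_sticky > sites.size:
        raise ValueError(f"{n_sticky} sticky anions exceed {sites.size} available sites")

    rng = np.random.default_rng(seed)
    # centre the peptide in the box
    base = peptide.positions
    shift = np.full(3, box_length / 2.0) - base.mean(axis=0)
    pep = base + shift

    chosen_sites = rng.choice(sites, size=n_sticky, replace=False) if n_sticky else np.array([], dtype=int)
    # sticky ions sit on the outward N->H axis, sticky_distance beyond the H
    # (the physical N-H...X- contact direction); this keeps each pinned ion in
    # the first shell of exactly one site.
    donor_of = {h: n for n, h in topology.donors}
    sticky_pos = np.empty((n_sticky, 3))
    for k, h in enumerate(chosen_sites):
        n = donor_of[int(h)]
        u = pep[h] - pep[n]
        u = u / np.linalg.norm(u)
        sticky_pos[k] = pep[h] + sticky_distance * u

    n_pep = pep.shape[0]
    n_blockers = n_sticky if shielded else 0
    atoms = list(peptide.atoms)
    serial = max(a.serial for a in atoms) + 1

    def _ion(name: str, element: str, resname: str, resnum: int, pos: np.ndarray) -> AtomRecord:
        nonlocal serial
        rec = AtomRecord(
            serial=serial,
            name=name,
            element=element,
            residue_name=resname,
            residue_number=resnum,
            chain="I",
            position=pos,
            is_hydrogen=False,
            is_backbone=False,
        )
        serial += 1
        return rec

    resnum = 1000
    anion_idx, cation_idx, blocker_idx = [], [], []
    for i in range(n_pairs):
        anion_idx.append(len(atoms))
        atoms.append(_ion(anion, anion, anion + "-", resnum + i, np.zeros(3)))
    for i in range(n_pairs):
        cation_idx.append(len(atoms))
        atoms.append(_ion(cation, cation, cation + "+", resnum + n_pairs + i, np.zeros(3)))
    for i in range(n_blockers):
        blocker_idx.append(len(atoms))
        atoms.append(_ion("C", "C", "NAG", resnum + 2 * n_pairs + i, sticky_pos[i]))

    anion_idx = np.asarray(anion_idx, dtype=int)
    cation_idx = np.asarray(cation_idx, dtype=int)
    blocker_idx = np.asarray(blocker_idx, dtype=int)

    coords = np.empty((n_frames, len(atoms), 3))
    coords[:, :n_pep] = pep[None, :, :]
    if n_blockers:
        coords[:, blocker_idx] = sticky_pos[None, :, :]
    for f in range(n_frames):
        an = rng.uniform(0.0, box_length, size=(n_pairs, 3))
        if n_sticky and not shielded:
            an[:n_sticky] = sticky_pos
        coords[f, anion_idx] = an
        coords[f, cation_idx] = rng.uniform(0.0, box_length, size=(n_pairs, 3))

    structure = Structure(atoms=atoms, box_length=box_length)
    charges = np.zeros(len(atoms))
    charges[anion_idx] = -1.0
    charges[cation_idx] = +1.0
    traj = Trajectory(
        coords=coords,
        frame_interval_ps=frame_interval_ps,
        box_per_frame=np.full(n_frames, float(box_length)),
    )
    planted = 0.0 if shielded else (n_sticky / sites.size)
    return IonSystem(
        structure=structure,
        traj=traj,
        charges=charges,
        amide_h_indices=sites,
        anion_indices=anion_idx,
        cation_indices=cation_idx,
        blocker_indices=blocker_idx,
        planted_first_shell=planted,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Condition panels
# ---------------------------------------------------------------------------


@dataclass
class PanelSpec:
    """Planted effect sizes and sampling layout for a full condition panel.

    Defaults mirror the study layout: 5 salt backgrounds x glycosylated /
    non-glycosylated x 3 temperatures = 30 conditions, 100 analysed frames
    at 20 ps.  Planted effects: 9 persistent bonds lost per 50 K; +5
    persistent bonds per glycosylation pairing except one adversarial
    pairing at -4 (paired mean +4.4, sign-consistent in 14 of 15); a KF
    deficit of -2 at 0.3 M and -6 at 1.2 M relative to NaCl; +3 persistent
    bonds for any ionic background over salt-free.
    """

    n_res: int = 180
    n_frames: int = 100
    frame_interval_ps: float = 20.0
    temperatures: tuple[float, ...] = (300.0, 350.0, 400.0)
    salt_conditions: tuple[tuple[str, float], ...] = (
        ("NONE", 0.0),
        ("NACL", 0.3),
        ("NACL", 1.2),
        ("KF", 0.3),
        ("KF", 1.2),
    )
    base_persistent: int = 155
    slope_per_50K: float = -9.0
    glyco_delta: int = 5
    adversarial_glyco: dict[tuple[str, float, float], int] = field(
        default_factory=lambda: {("NACL", 1.2, 350.0): -4}
    )
    ionic_bonus: int = 3
    kf_deficit: dict[float, int] = field(default_factory=lambda: {0.3: -2, 1.2: -6})
    on_fraction: float = 0.95
    noise_sigma_300K: float = 0.0
    seed: int = 0

    def planted_count(self, glyco: bool, salt: str, conc: float, T: float) -> int:
        c = self.base_persistent + self.slope_per_50K * (T - self.temperatures[0]) / 50.0
        if salt != "NONE":
            c += self.ionic_bonus
        if salt == "KF":
            c += self.kf_deficit.get(conc, 0)
        if glyco:
            # adversarial entries override the glycosylation delta outright
            c += self.adversarial_glyco.get((salt, conc, T), self.glyco_delta)
        if c < 0:
            raise ValueError(
                f"planted effects imply a negative count at ({glyco}, {salt}, {conc}, {T})"
            )
        return int(round(c))

    def condition_label(self, glyco: bool, salt: str, conc: float, T: float) -> str:
        tag = "NAG" if glyco else "noNAG"
        if salt == "NONE":
            ionic = "0P0M"
        else:
            ionic = f"{conc:.1f}M_{salt}".replace(".", "P")
        return f"{tag}_{ionic}_{T:.0f}K"


def generate_condition_panel(
    spec: PanelSpec | None = None,
) -> tuple[Structure, list[tuple[ConditionSpec, Trajectory]], PlantedTruth]:
    """Generate the full synthetic condition panel with exact planted counts.

    Returns the shared peptide structure, one (condition, trajectory) pair
    per panel cell, and the planted truth (expected persistent and average
    counts per condition plus the derived statistics the aggregation should
    recover exactly in noise-free mode).
    """
    spec = spec or PanelSpec()
    peptide = generate_peptide(spec.n_res, "helix")
    topology, peptide = perceive_topology(peptide)
    pair_atoms = _base_pairs(peptide, topology)
    ordered_pairs = sorted(pair_atoms)  # by donor residue number
    n_pairs_avail = len(ordered_pairs)

    truth = PlantedTruth(
        noise_sigma_by_T={
            T: spec.noise_sigma_300K * math.sqrt(T / 300.0) for T in spec.temperatures
        },
        planted_slope_per_50K=spec.slope_per_50K,
        planted_glyco_delta=float(spec.glyco_delta),
        seed=spec.seed,
    )

    out: list[tuple[ConditionSpec, Trajectory]] = []
    cell_index = 0
    for glyco in (True, False):
        for salt, conc in spec.salt_conditions:
            for T in spec.temperatures:
                count = spec.planted_count(glyco, salt, conc, T)
                if count > n_pairs_avail:
                    raise ValueError(
                        f"planted count {count} exceeds the {n_pairs_avail} "
                        f"realisable pairs; increase n_res"
                    )
                schedule: dict[tuple[int, int], float] = {}
                for j, pair in enumerate(ordered_pairs):
                    schedule[pair] = spec.on_fraction if j < count else 0.0
                label = spec.condition_label(glyco, salt, conc, T)
                sigma = truth.noise_sigma_by_T[T]
                traj, _ = generate_trajectory(
                    peptide,
                    spec.n_frames,
                    noise_sigma=sigma,
                    schedule=schedule,
                    seed=spec.seed + 7919 * cell_index,
                    frame_interval_ps=spec.frame_interval_ps,
                    verify=sigma == 0.0,
                )
                cond = ConditionSpec(
                    label=label,
                    temperature_K=T,
                    salt=salt,
                    concentration_M=conc,
                    glycosylated=glyco,
                )
                out.append((cond, traj))
                truth.expected_persistent_counts[label] = count
                truth.expected_average_counts[label] = count * spec.on_fraction
                cell_index += 1

    # Derived statistics the aggregation must recover.
    deltas = []
    for salt, conc in spec.salt_conditions:
        for T in spec.temperatures:
            deltas.append(spec.adversarial_glyco.get((salt, conc, T), spec.glyco_delta))
    truth.expected_glyco_mean_delta = float(np.mean(deltas))
    truth.expected_glyco_sign_consistency = (
        int(sum(1 for d in deltas if d > 0)),
        len(deltas),
    )
    for conc, deficit in spec.kf_deficit.items():
        truth.expected_salt_deltas[f"KF_minus_NACL_{conc}M"] = float(deficit)
    return peptide, out, truth


def write_panel(
    out_dir: str | Path,
    spec: PanelSpec | None = None,
    trajectory_format: str = "xyz",
) -> tuple[Path, Path, Path]:
    """Write a panel to disk: structure PDB, per-condition trajectories,
    manifest YAML and planted-truth JSON sidecar.

    Returns (structure_path, manifest_path, truth_path).
    """
    from .io import write_condition_manifest, write_structure, write_trajectory

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = spec or PanelSpec()
    peptide, panel, truth = generate_condition_panel(spec)
    structure_path = out_dir / "peptide.pdb"
    write_structure(peptide, structure_path)
    extra = {}
    for cond, traj in panel:
        traj_path = out_dir / f"{cond.label}.{trajectory_format}"
        write_trajectory(peptide, traj, traj_path, format=trajectory_format)
        extra[cond.label] = {
            "trajectory": traj_path.name,
            "structure": structure_path.name,
        }
    manifest_path = out_dir / "manifest.yaml"
    write_condition_manifest([c for c, _ in panel], manifest_path, extra=extra)
    truth_path = out_dir / "planted_truth.json"
    truth_path.write_text(truth.to_json())
    return structure_path, manifest_path, truth_path
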