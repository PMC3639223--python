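"""Structures, trajectories, chemical topology, and condition manifests.

PDB structures are parsed with Biopython's ``Bio.PDB``; multi-model
coordinate frames and XYZ trajectories use a light fixed-column fast path
(coordinates only, topology taken from the reference structure) so that
hundred-frame trajectories parse quickly.  Author residue numbering is
preserved everywhere; internal 0-based atom indices never appear in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from ._elements import element_from_name
from ._residues import (
    AMINO_ACIDS,
    BACKBONE_NAMES,
    BASIC_NITROGENS,
    CARBOXYLATE_OXYGENS,
    DEFAULT_GLYCAN_RESNAMES,
)

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "Topology",
    "ConditionSpec",
    "ParseError",
    "CongruenceError",
    "TopologyError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "perceive_topology",
    "read_condition_manifest",
    "write_condition_manifest",
]


class ParseError(ValueError):
    """Malformed or empty input file."""


class CongruenceError(ValueError):
    """Frames of a trajectory disagree in atom count or order."""


class TopologyError(ValueError):
    """Chemical perception cannot proceed (e.g. no hydrogens available)."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, residue membership, and position in Angstrom."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    position: np.ndarray
    is_hydrogen: bool = False
    is_backbone: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class Structure:
    """An ordered atom list with an optional cubic box edge (A)."""

    atoms: list[AtomRecord]
    box_length: float | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ParseError("structure contains no atoms")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ParseError("duplicate atom serial numbers in structure")
        if self.box_length is not None and self.box_length <= 0:
            raise ValueError("box_length must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def backbone_indices(self, include_hydrogens: bool = False) -> np.ndarray:
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if a.is_backbone and (include_hydrogens or not a.is_hydrogen)
        ]
        return np.array(idx, dtype=int)

    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if not a.is_hydrogen], dtype=int)

    def residues(self) -> list[tuple[tuple[str, int, str], list[int]]]:
        """Group atom indices by (chain, residue_number, residue_name), file order."""
        out: list[tuple[tuple[str, int, str], list[int]]] = []
        key = None
        for i, a in enumerate(self.atoms):
            k = (a.chain, a.residue_number, a.residue_name)
            if k != key:
                out.append((k, []))
                key = k
            out[-1][1].append(i)
        return out


@dataclass
class Trajectory:
    """Coordinate frames congruent with a Structure's atom list.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom;
    ``frame_interval_ps`` is the saving interval; ``box_per_frame`` is the
    cubic box edge per frame when periodic analyses apply.
    """

    coords: np.ndarray
    frame_interval_ps: float
    box_per_frame: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")
        if self.box_per_frame is not None:
            self.box_per_frame = np.asarray(self.box_per_frame, dtype=float)
            if self.box_per_frame.shape != (self.n_frames,):
                raise ValueError("box_per_frame must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ps


@dataclass
class Topology:
    """Donor/acceptor and charged-group bookkeeping derived from a Structure.

    Indices are 0-based positions into ``structure.atoms``.
    """

    donors: list[tuple[int, int]] = field(default_factory=list)  # (N, H)
    acceptors: list[int] = field(default_factory=list)  # carbonyl O
    carboxylate_groups: dict[tuple[str, int, str], list[int]] = field(default_factory=dict)
    basic_groups: dict[tuple[str, int, str], list[int]] = field(default_factory=dict)
    glycan_residues: list[tuple[str, int, str]] = field(default_factory=list)
    amide_hydrogens: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class ConditionSpec:
    """One simulated condition: temperature, salt, concentration, glycosylation."""

    label: str
    temperature_K: float
    salt: str = "NONE"
    concentration_M: float = 0.0
    glycosylated: bool = False
    n_ion_pairs: int = 0
    box_length: float | None = None

    def __post_init__(self) -> None:
        if self.salt not in ("NONE", "NACL", "KF"):
            raise ValueError(f"{self.label}: salt must be NONE, NACL or KF, got {self.salt!r}")
        if self.concentration_M < 0 or self.n_ion_pairs < 0:
            raise ValueError(f"{self.label}: concentration and ion pairs must be non-negative")
        if self.salt == "NONE" and (self.concentration_M != 0 or self.n_ion_pairs != 0):
            raise ValueError(
                f"{self.label}: salt NONE requires zero concentration and zero ion pairs"
            )
        if self.box_length is not None and self.box_length <= 0:
            raise ValueError(f"{self.label}: box_length must be positive")


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------


def _atoms_from_biopdb_model(model, first_serial: int = 1) -> list[AtomRecord]:
    records: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            resname = res.resname.strip()
            resnum = res.id[1]
            for atom in res:
                name = atom.get_name()
                element = (atom.element or "").strip()
                if not element:
                    element = element_from_name(atom.get_fullname() or name, resname)
                element = element.upper()
                is_h = element == "H"
                is_bb = (
                    resname in AMINO_ACIDS
                    and name in BACKBONE_NAMES
                    and name != "HA"  # alpha H is side-of-CA, not amide ladder
                )
                records.append(
                    AtomRecord(
                        serial=atom.serial_number or (first_serial + len(records)),
                        name=name,
                        element=element,
                        residue_name=resname,
                        residue_number=resnum,
                        chain=chain.id if chain.id.strip() else "A",
                        position=np.asarray(atom.coord, dtype=float),
                        is_hydrogen=is_h,
                        is_backbone=is_bb,
                    )
                )
    return records


def _read_cryst1(path: Path) -> float | None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                try:
                    a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
                except ValueError as exc:
                    raise ParseError(f"{path}: malformed CRYST1 record") from exc
                if math.isclose(a, b, rel_tol=1e-6) and math.isclose(a, c, rel_tol=1e-6):
                    return a
                return None  # non-cubic cells are ignored
    return None


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a structure file (PDB) into a :class:`Structure`.

    Atoms are returned in file order with author residue numbering.  A cubic
    CRYST1 cell, if present, populates ``box_length``.
    """
    path = Path(path)
    if format.lower() != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    try:
        bio = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise ParseError(f"{path}: {exc}") from exc
    models = list(bio)
    if not models:
        raise ParseError(f"{path}: no atoms found")
    atoms = _atoms_from_biopdb_model(models[0])
    if not atoms:
        raise ParseError(f"{path}: no atoms found")
    return Structure(atoms=atoms, box_length=_read_cryst1(path))


def _format_pdb_atom(a: AtomRecord, serial: int) -> str:
    record = "ATOM  " if a.residue_name in AMINO_ACIDS else "HETATM"
    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
    x, y, z = a.position
    return (
        f"{record}{serial:5d} {name:4s} {a.residue_name:<3s} {a.chain:1s}"
        f"{a.residue_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {a.element:>2s}"
    )


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as a single-model PDB file (3-decimal coordinates)."""
    path = Path(path)
    lines = []
    if structure.box_length is not None:
        L = structure.box_length
        lines.append(f"CRYST1{L:9.3f}{L:9.3f}{L:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1")
    for i, a in enumerate(structure.atoms, start=1):
        lines.append(_format_pdb_atom(a, i))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_trajectory(
    structure: Structure,
    traj: Trajectory,
    path: str | Path,
    format: str = "pdb",
) -> None:
    """Write trajectory frames as multi-model PDB or multi-frame XYZ."""
    path = Path(path)
    fmt = format.lower()
    if traj.n_atoms != structure.n_atoms:
        raise CongruenceError("trajectory and structure atom counts differ")
    if fmt == "pdb":
        chunks = []
        if structure.box_length is not None:
            L = structure.box_length
            chunks.append(
                f"CRYST1{L:9.3f}{L:9.3f}{L:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
            )
        for f in range(traj.n_frames):
            chunks.append(f"MODEL     {f + 1:4d}")
            for i, a in enumerate(structure.atoms):
                chunks.append(_format_pdb_atom(replace(a, position=traj.coords[f, i]), i + 1))
            chunks.append("ENDMDL")
        chunks.append("END")
        path.write_text("\n".join(chunks) + "\n")
    elif fmt == "xyz":
        with open(path, "w") as fh:
            for f in range(traj.n_frames):
                fh.write(f"{traj.n_atoms}\n")
                fh.write(f"frame {f} t_ps {f * traj.frame_interval_ps:.6g}\n")
                for a, (x, y, z) in zip(structure.atoms, traj.coords[f]):
                    fh.write(f"{a.element:<2s} {x:12.6f} {y:12.6f} {z:12.6f}\n")
    else:
        raise ValueError(f"unsupported trajectory format {format!r}")


def _read_pdb_frames(path: Path) -> np.ndarray:
    """Fast coordinate-only reader for multi-model PDB trajectories."""
    frames: list[list[list[float]]] = []
    current: list[list[float]] | None = None
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6]
            if tag == "MODEL ":
                saw_model = True
                current = []
            elif tag in ("ATOM  ", "HETATM"):
                if current is None:
                    current = []
                try:
                    current.append(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    )
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: malformed coordinate at line {lineno}"
                    ) from exc
            elif tag == "ENDMDL":
                if current is not None:
                    frames.append(current)
                    current = None
    if current:  # single-model file without MODEL/ENDMDL bookkeeping
        frames.append(current)
    if not frames or not frames[0]:
        raise ParseError(f"{path}: no coordinate frames found")
    n0 = len(frames[0])
    for f, fr in enumerate(frames):
        if len(fr) != n0:
            raise CongruenceError(
                f"{path}: frame {f} has {len(fr)} atoms, expected {n0}"
            )
    del saw_model
    return np.asarray(frames, dtype=float)


def _read_xyz_frames(path: Path) -> np.ndarray:
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}: expected atom count at line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise CongruenceError(f"{path}: frame {len(frames)} truncated")
        try:
            coords = np.array(
                [[float(v) for v in ln.split()[1:4]] for ln in block], dtype=float
            )
        except (ValueError, IndexError) as exc:
            raise ParseError(
                f"{path}: malformed XYZ record near line {i + 3}"
            ) from exc
        if coords.shape != (n, 3):
            raise ParseError(f"{path}: malformed XYZ frame {len(frames)}")
        frames.append(coords)
        i += 2 + n
        lineno = i
    del lineno
    if not frames:
        raise ParseError(f"{path}: no coordinate frames found")
    n0 = frames[0].shape[0]
    for f, fr in enumerate(frames):
        if fr.shape[0] != n0:
            raise CongruenceError(f"{path}: frame {f} has {fr.shape[0]} atoms, expected {n0}")
    return np.stack(frames)


def read_trajectory(
    path: str | Path,
    format: str | None = None,
    frame_interval_ps: float = 20.0,
    box_length: float | None = None,
) -> Trajectory:
    """Read a multi-model PDB or multi-frame XYZ file as a Trajectory.

    Every frame must have the same atom count and order as the first; a
    mismatch raises :class:`CongruenceError` naming the offending frame.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        coords = _read_pdb_frames(path)
        if box_length is None:
            box_length = _read_cryst1(path)
    elif fmt == "xyz":
        coords = _read_xyz_frames(path)
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    box = None
    if box_length is not None:
        box = np.full(coords.shape[0], float(box_length))
    return Trajectory(coords=coords, frame_interval_ps=frame_interval_ps, box_per_frame=box)


# ---------------------------------------------------------------------------
# Topology perception
# ---------------------------------------------------------------------------


def _construct_amide_h(
    n_pos: np.ndarray, prev_c_pos: np.ndarray, ca_pos: np.ndarray
) -> np.ndarray:
    """Planar amide hydrogen: in the C(prev)-N-CA plane, N-H = 1.01 A,
    bisecting the external angle at N."""
    u1 = prev_c_pos - n_pos
    u2 = ca_pos - n_pos
    u1 = u1 / np.linalg.norm(u1)
    u2 = u2 / np.linalg.norm(u2)
    d = -(u1 + u2)
    norm = np.linalg.norm(d)
    if norm < 1e-8:
        raise TopologyError("degenerate backbone geometry while constructing amide H")
    return n_pos + 1.01 * d / norm


def perceive_topology(
    structure: Structure,
    construct_missing_hydrogens: bool = False,
    glycan_resnames: Iterable[str] = DEFAULT_GLYCAN_RESNAMES,
) -> tuple[Topology, Structure]:
    """Derive donors, acceptors, charged groups and glycan residues.

    Donors are backbone amide N-H pairs; proline and each chain's N-terminal
    residue contribute none.  Acceptors are backbone carbonyl O atoms; the
    C-terminal residue of each chain (its carboxylate, including OXT) is
    excluded.  When the structure lacks amide hydrogens and
    ``construct_missing_hydrogens`` is set, hydrogens are placed with the
    standard planar-amide geometry and appended to a copy of the structure.

    Returns ``(topology, structure)``; the returned structure is the input
    unless hydrogens were constructed.
    """
    glycan_set = {g.upper() for g in glycan_resnames}
    atoms = list(structure.atoms)
    residues = structure.residues()

    # Identify amino-acid residues per chain, in order.
    chain_residues: dict[str, list[int]] = {}
    for ridx, ((chain, _, resname), _idxs) in enumerate(residues):
        if resname in AMINO_ACIDS:
            chain_residues.setdefault(chain, []).append(ridx)

    def atom_in(ridx: int, name: str) -> int | None:
        for i in residues[ridx][1]:
            if atoms[i].name == name:
                return i
        return None

    topo = Topology()
    new_atoms: list[AtomRecord] = []
    next_serial = max(a.serial for a in atoms) + 1

    for chain, rlist in chain_residues.items():
        for pos, ridx in enumerate(rlist):
            (ch, resnum, resname), idxs = residues[ridx]
            n_i = atom_in(ridx, "N")
            # Acceptors: backbone carbonyl O, C-terminal residue excluded.
            if pos < len(rlist) - 1:
                o_i = atom_in(ridx, "O")
                if o_i is not None:
                    topo.acceptors.append(o_i)
            # Donors: amide N-H, excluding proline and the chain N-terminus.
            if pos == 0 or resname == "PRO" or n_i is None:
                continue
            h_i = None
            for cand in ("H", "HN"):
                h_i = atom_in(ridx, cand)
                if h_i is not None:
                    break
            if h_i is None:
                if not construct_missing_hydrogens:
                    raise TopologyError(
                        f"residue {resname}{resnum} chain {chain} lacks an amide H; "
                        "enable construct_missing_hydrogens to place one"
                    )
                prev_ridx = rlist[pos - 1]
                prev_c = atom_in(prev_ridx, "C")
                ca_i = atom_in(ridx, "CA")
                if prev_c is None or ca_i is None:
                    raise TopologyError(
                        f"cannot construct amide H for {resname}{resnum}: missing C/CA"
                    )
                h_pos = _construct_amide_h(
                    atoms[n_i].position, atoms[prev_c].position, atoms[ca_i].position
                )
                rec = AtomRecord(
                    serial=next_serial,
                    name="H",
                    element="H",
                    residue_name=resname,
                    residue_number=resnum,
                    chain=chain,
                    position=h_pos,
                    is_hydrogen=True,
                    is_backbone=True,
                )
                next_serial += 1
                h_i = len(atoms) + len(new_atoms)
                new_atoms.append(rec)
            topo.donors.append((n_i, h_i))
            topo.amide_hydrogens.append(h_i)

    for ridx, ((chain, resnum, resname), idxs) in enumerate(residues):
        key = (chain, resnum, resname)
        if resname in CARBOXYLATE_OXYGENS:
            oxy = [i for i in idxs if atoms[i].name in CARBOXYLATE_OXYGENS[resname]]
            if len(oxy) == 2:
                topo.carboxylate_groups[key] = oxy
        if resname in BASIC_NITROGENS:
            nit = [i for i in idxs if atoms[i].name in BASIC_NITROGENS[resname]]
            if 1 <= len(nit) <= 3:
                topo.basic_groups[key] = nit
        if resname.upper() in glycan_set:
            topo.glycan_residues.append(key)

    out_structure = structure
    if new_atoms:
        out_structure = Structure(atoms=atoms + new_atoms, box_length=structure.box_length)
    for n_i, h_i in topo.donors:
        if not out_structure.atoms[h_i].is_hydrogen:
            raise TopologyError("internal error: donor hydrogen not flagged as hydrogen")
    return topo, out_structure


# ---------------------------------------------------------------------------
# Condition manifests
# ---------------------------------------------------------------------------

_CONDITION_FIELDS = {
    "label",
    "temperature_K",
    "salt",
    "concentration_M",
    "glycosylated",
    "n_ion_pairs",
    "box_length",
}


def read_condition_manifest(path: str | Path) -> list[ConditionSpec]:
    """Read a YAML condition manifest: a list of ConditionSpec mappings."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        return []
    if not isinstance(raw, list):
        raise ParseError(f"{path}: manifest must be a list of condition entries")
    specs: list[ConditionSpec] = []
    seen: set[str] = set()
    for i, entry in enumerate(raw):
        if not isinstance(entry, dict):
            raise ParseError(f"{path}: entry {i} is not a mapping")
        unknown = set(entry) - _CONDITION_FIELDS - {"trajectory", "structure"}
        if unknown:
            raise ParseError(f"{path}: entry {i} has unknown fields {sorted(unknown)}")
        kwargs = {k: v for k, v in entry.items() if k in _CONDITION_FIELDS}
        try:
            spec = ConditionSpec(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: entry {i}: {exc}") from exc
        if spec.label in seen:
            raise ParseError(f"{path}: duplicate condition label {spec.label!r}")
        seen.add(spec.label)
        specs.append(spec)
    return specs


def write_condition_manifest(
    specs: Sequence[ConditionSpec],
    path: str | Path,
    extra: dict[str, dict] | None = None,
) -> None:
    """Write specs to YAML; ``extra`` maps label -> additional per-entry keys
    (e.g. trajectory file names)."""
    entries = []
    for s in specs:
        d = {
            "label": s.label,
            "temperature_K": s.temperature_K,
            "salt": s.salt,
            "concentration_M": s.concentration_M,
            "glycosylated": s.glycosylated,
            "n_ion_pairs": s.n_ion_pairs,
        }
        if s.box_length is not None:
            d["box_length"] = s.box_length
        if extra and s.label in extra:
            d.update(extra[s.label])
        entries.append(d)
    Path(path).write_text(yaml.safe_dump(entries, sort_keys=False))
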