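"""Backbone hydrogen-bond and salt-bridge persistence statistics.

A donor-hydrogen-acceptor interaction counts as a hydrogen bond when the
donor-acceptor distance is strictly below 3.5 A and the angle between the
D->H and D->A vectors is strictly below 30 degrees (the angular deviation at
the donor, not the internal D-H-A angle).  Persistence is the fraction of
analysed frames in which the criteria hold; "persistent" means strictly more
than 50% of the window.  Salt bridges pass a 3.2 A atomwise pre-screen (any
carboxylate O to any basic side-chain N, in at least one frame) and are then
filtered on the carboxylate-O/basic-N centre-of-mass distance staying below
3.5 A for more than half of the frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._elements import mass_of
from .io import Structure, Topology, Trajectory

__all__ = [
    "HBondEvent",
    "PersistenceTable",
    "SaltBridgeRecord",
    "detect_hbonds_frame",
    "hbond_count_series",
    "average_hbond_count",
    "hbond_persistence",
    "persistent_count",
    "persistence_loss",
    "salt_bridge_candidates",
    "salt_bridge_persistence",
]

D_MAX_DEFAULT = 3.5  # A, donor-acceptor distance cutoff
A_MAX_DEFAULT = 30.0  # degrees, deviation between D->H and D->A
SB_PRESCREEN_DEFAULT = 3.2  # A, atomwise O-N pre-screen
SB_COM_DEFAULT = 3.5  # A, carboxylate-COM to basic-N-COM filter
PERSISTENCE_THRESHOLD_DEFAULT = 0.5


@dataclass(frozen=True)
class HBondEvent:
    """One detected hydrogen bond in one frame."""

    donor_n: int
    hydrogen: int
    acceptor_o: int
    distance_DA: float
    angle_deviation: float


@dataclass
class PersistenceTable:
    """Presence fraction per donor-acceptor pair over an analysis window.

    Keys are ``(donor_n, hydrogen, acceptor_o)`` atom-index triples; the
    ``pairs`` frame adds author residue numbering for reporting.  Pairs never
    present in the window are omitted, so the sum of fractions equals the
    average per-frame hydrogen-bond count exactly.
    """

    fractions: dict[tuple[int, int, int], float]
    n_frames_analyzed: int
    residue_info: dict[tuple[int, int, int], tuple[str, str]] = field(default_factory=dict)

    def total_fraction(self) -> float:
        return float(sum(self.fractions.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, frac in sorted(self.fractions.items()):
            donor_res, acceptor_res = self.residue_info.get(key, ("", ""))
            rows.append(
                {
                    "donor_res": donor_res,
                    "acceptor_res": acceptor_res,
                    "donor_n": key[0],
                    "donor_h": key[1],
                    "acceptor_o": key[2],
                    "fraction": frac,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["donor_res", "acceptor_res", "donor_n", "donor_h", "acceptor_o", "fraction"],
        )


@dataclass
class SaltBridgeRecord:
    """One acidic/basic residue pair through the two-stage filter."""

    acidic: tuple[str, int, str]
    basic: tuple[str, int, str]
    candidate: bool
    com_distance_series: np.ndarray
    persistence_fraction: float
    retained: bool


def _residue_label(structure: Structure, atom_index: int) -> str:
    a = structure.atoms[atom_index]
    return f"{a.residue_name}{a.residue_number}"


def detect_hbonds_frame(
    frame: np.ndarray,
    topology: Topology,
    structure: Structure | None = None,
    d_max: float = D_MAX_DEFAULT,
    a_max: float = A_MAX_DEFAULT,
) -> list[HBondEvent]:
    """All donor-acceptor pairs satisfying the geometric criteria in one frame.

    Strict inequalities at both cutoffs; donor and acceptor in the same
    residue are excluded (sequence-adjacent pairs are allowed).
    """
    frame = np.asarray(frame, dtype=float)
    if not topology.donors or not topology.acceptors:
        return []
    donors = np.asarray(topology.donors, dtype=int)  # (nd, 2)
    acceptors = np.asarray(topology.acceptors, dtype=int)  # (na,)
    d_pos = frame[donors[:, 0]]  # N
    h_pos = frame[donors[:, 1]]  # H
    a_pos = frame[acceptors]  # O

    da = a_pos[None, :, :] - d_pos[:, None, :]  # (nd, na, 3)
    dist = np.linalg.norm(da, axis=2)
    dh = h_pos - d_pos  # (nd, 3)
    dh_norm = np.linalg.norm(dh, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ikj->ik", dh, da) / (dh_norm[:, None] * dist)
    cosang = np.clip(cosang, -1.0, 1.0)
    angle = np.degrees(np.arccos(cosang))
    hits = (dist < d_max) & (angle < a_max)

    if structure is not None:
        # exclude within-residue donor/acceptor pairs
        d_num = np.array([structure.atoms[i].residue_number for i in donors[:, 0]])
        a_num = np.array([structure.atoms[i].residue_number for i in acceptors])
        d_ch = np.array([structure.atoms[i].chain for i in donors[:, 0]])
        a_ch = np.array([structure.atoms[i].chain for i in acceptors])
        same = (d_num[:, None] == a_num[None, :]) & (d_ch[:, None] == a_ch[None, :])
        hits &= ~same

    events = []
    for i, j in zip(*np.nonzero(hits)):
        events.append(
            HBondEvent(
                donor_n=int(donors[i, 0]),
                hydrogen=int(donors[i, 1]),
                acceptor_o=int(acceptors[j]),
                distance_DA=float(dist[i, j]),
                angle_deviation=float(angle[i, j]),
            )
        )
    return events


def _window_slice(n_frames: int, window: int | None) -> slice:
    if window is None:
        window = n_frames
    if window < 1:
        raise ValueError("window must cover at least one frame")
    if window > n_frames:
        raise ValueError(f"window {window} exceeds trajectory length {n_frames}")
    return slice(n_frames - window, n_frames)


def hbond_count_series(
    traj: Trajectory,
    topology: Topology,
    structure: Structure | None = None,
    window: int | None = None,
    d_max: float = D_MAX_DEFAULT,
    a_max: float = A_MAX_DEFAULT,
) -> np.ndarray:
    """Per-frame hydrogen-bond counts over the trailing window."""
    sl = _window_slice(traj.n_frames, window)
    return np.array(
        [
            len(detect_hbonds_frame(traj.coords[f], topology, structure, d_max, a_max))
            for f in range(sl.start, sl.stop)
        ]
    )


def average_hbond_count(
    traj: Trajectory,
    topology: Topology,
    structure: Structure | None = None,
    window: int | None = None,
    d_max: float = D_MAX_DEFAULT,
    a_max: float = A_MAX_DEFAULT,
) -> float:
    """Mean per-frame hydrogen-bond count over the trailing window."""
    return float(hbond_count_series(traj, topology, structure, window, d_max, a_max).mean())


def hbond_persistence(
    traj: Trajectory,
    topology: Topology,
    structure: Structure | None = None,
    window: int | None = None,
    d_max: float = D_MAX_DEFAULT,
    a_max: float = A_MAX_DEFAULT,
) -> PersistenceTable:
    """Presence fraction per donor-acceptor pair over the trailing window."""
    sl = _window_slice(traj.n_frames, window)
    n = sl.stop - sl.start
    counts: dict[tuple[int, int, int], int] = {}
    for f in range(sl.start, sl.stop):
        for ev in detect_hbonds_frame(traj.coords[f], topology, structure, d_max, a_max):
            key = (ev.donor_n, ev.hydrogen, ev.acceptor_o)
            counts[key] = counts.get(key, 0) + 1
    fractions = {k: c / n for k, c in counts.items()}
    info: dict[tuple[int, int, int], tuple[str, str]] = {}
    if structure is not None:
        for key in fractions:
            info[key] = (
                _residue_label(structure, key[0]),
                _residue_label(structure, key[2]),
            )
    return PersistenceTable(fractions=fractions, n_frames_analyzed=n, residue_info=info)


def persistent_count(
    table: PersistenceTable, threshold: float = PERSISTENCE_THRESHOLD_DEFAULT
) -> int:
    """Number of pairs whose presence fraction strictly exceeds the threshold."""
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must lie in [0, 1)")
    return int(sum(1 for f in table.fractions.values() if f > threshold))


def persistence_loss(
    table_a: PersistenceTable,
    table_b: PersistenceTable,
    threshold: float = PERSISTENCE_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Pairs persistent in A but not in B, with both fractions reported."""
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must lie in [0, 1)")
    rows = []
    for key, fa in sorted(table_a.fractions.items()):
        if fa > threshold:
            fb = table_b.fractions.get(key, 0.0)
            if not fb > threshold:
                donor_res, acceptor_res = table_a.residue_info.get(key, ("", ""))
                rows.append(
                    {
                        "donor_res": donor_res,
                        "acceptor_res": acceptor_res,
                        "donor_n": key[0],
                        "donor_h": key[1],
                        "acceptor_o": key[2],
                        "fraction_a": fa,
                        "fraction_b": fb,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "donor_res",
            "acceptor_res",
            "donor_n",
            "donor_h",
            "acceptor_o",
            "fraction_a",
            "fraction_b",
        ],
    )


def salt_bridge_candidates(
    traj: Trajectory,
    topology: Topology,
    window: int | None = None,
    d_pre: float = SB_PRESCREEN_DEFAULT,
) -> set[tuple[tuple[str, int, str], tuple[str, int, str]]]:
    """(acidic, basic) residue pairs with any O-N contact below ``d_pre``.

    The pre-screen passes if the minimum over frames and over carboxylate-O /
    basic-N atom pairs of the distance is strictly below the cutoff in at
    least one frame.
    """
    sl = _window_slice(traj.n_frames, window)
    out: set[tuple[tuple[str, int, str], tuple[str, int, str]]] = set()
    for acid_key, o_idx in topology.carboxylate_groups.items():
        for base_key, n_idx in topology.basic_groups.items():
            o = traj.coords[sl, :, :][:, o_idx, :]  # (nf, nO, 3)
            nn = traj.coords[sl, :, :][:, n_idx, :]  # (nf, nN, 3)
            d = np.linalg.norm(o[:, :, None, :] - nn[:, None, :, :], axis=3)
            if np.any(d < d_pre):
                out.add((acid_key, base_key))
    return out


def salt_bridge_persistence(
    traj: Trajectory,
    topology: Topology,
    candidates: set[tuple[tuple[str, int, str], tuple[str, int, str]]],
    structure: Structure,
    window: int | None = None,
    d_com: float = SB_COM_DEFAULT,
    threshold: float = PERSISTENCE_THRESHOLD_DEFAULT,
) -> list[SaltBridgeRecord]:
    """Centre-of-mass persistence filter over pre-screened candidates.

    Per candidate pair the mass-weighted COM of the carboxylate oxygens and
    of the basic side-chain nitrogens is computed per frame; the pair is
    retained iff the fraction of frames with COM distance strictly below
    ``d_com`` strictly exceeds ``threshold``.
    """
    sl = _window_slice(traj.n_frames, window)
    records = []
    for acid_key, base_key in sorted(candidates):
        o_idx = topology.carboxylate_groups[acid_key]
        n_idx = topology.basic_groups[base_key]
        o_mass = np.array([mass_of(structure.atoms[i].element) for i in o_idx])
        n_mass = np.array([mass_of(structure.atoms[i].element) for i in n_idx])
        o_com = np.average(traj.coords[sl][:, o_idx, :], axis=1, weights=o_mass)
        n_com = np.average(traj.coords[sl][:, n_idx, :], axis=1, weights=n_mass)
        series = np.linalg.norm(o_com - n_com, axis=1)
        frac = float(np.mean(series < d_com))
        records.append(
            SaltBridgeRecord(
                acidic=acid_key,
                basic=base_key,
                candidate=True,
                com_distance_series=series,
                persistence_fraction=frac,
                retained=frac > threshold,
            )
        )
    return records
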