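"""Per-trajectory descriptor bundles: the glue between the analysis stages
and the condition-level aggregation.

``analyze_trajectory`` runs every applicable stage on one trajectory and
returns (and optionally writes) a descriptor bundle; ``compare_bundles``
feeds the bundles into the response aggregation.  All persistence
statistics share one trailing analysis window, by default the frames
covering the last 2 ns at the declared frame interval (100 frames at
20 ps).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, interactions, ions, surface
from .io import ConditionSpec, Structure, Topology, Trajectory, perceive_topology
from .response import ResponseSummary, aggregate

__all__ = ["AnalysisConfig", "analyze_trajectory", "compare_bundles", "write_bundle"]

ANALYSIS_WINDOW_PS = 2000.0  # trailing stretch used for persistence statistics


@dataclass
class AnalysisConfig:
    """Cutoffs and sampling parameters for one analysis run.

    Defaults are the conventional criteria: 3.5 A donor-acceptor distance,
    30 degree angular deviation, >50% persistence, 3.2 A salt-bridge
    pre-screen, 3.5 A centre-of-mass filter, 1.4 A SASA probe.
    """

    window_frames: int | None = None  # None: frames covering the last 2 ns
    d_max: float = interactions.D_MAX_DEFAULT
    a_max: float = interactions.A_MAX_DEFAULT
    persistence_threshold: float = interactions.PERSISTENCE_THRESHOLD_DEFAULT
    sb_prescreen: float = interactions.SB_PRESCREEN_DEFAULT
    sb_com: float = interactions.SB_COM_DEFAULT
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    sasa_stride: int = 1
    rdf_dr: float = 0.1
    rdf_r_max: float | None = None
    contact_r_cut: float = 2.5

    def resolve_window(self, traj: Trajectory) -> int:
        if self.window_frames is not None:
            w = self.window_frames
        else:
            w = int(round(ANALYSIS_WINDOW_PS / traj.frame_interval_ps))
        w = max(2, min(w, traj.n_frames))
        return w


def analyze_trajectory(
    structure: Structure,
    traj: Trajectory,
    config: AnalysisConfig | None = None,
    topology: Topology | None = None,
) -> dict:
    """All per-trajectory descriptors as one bundle.

    The bundle dict holds scalars under the keys the aggregation expects
    (``average_hbond_count``, ``persistent_hbond_count``, ``average_bfactor``,
    ``mean_rgyr``, ``mean_sasa``) plus the underlying tables as DataFrames.
    """
    config = config or AnalysisConfig()
    if traj.n_atoms != structure.n_atoms:
        raise ValueError(
            f"trajectory has {traj.n_atoms} atoms but structure has {structure.n_atoms}"
        )
    if topology is None:
        topology, structure = perceive_topology(structure, construct_missing_hydrogens=True)
    window = config.resolve_window(traj)
    backbone = structure.backbone_indices()

    bundle: dict = {"window_frames": window}

    # Positional descriptors
    rmsd = geometry.rmsd_series(traj, structure, backbone)
    bundle["rmsd_series"] = pd.DataFrame(
        {"frame": np.arange(traj.n_frames), "time_ps": traj.times_ps(), "rmsd_A": rmsd}
    )
    bundle["mean_rmsd"] = float(rmsd[-window:].mean())

    rmsf = geometry.rmsf(traj, selection=backbone, window=window, superpose_selection=backbone)
    profile = geometry.bfactor_from_rmsf(rmsf, structure, backbone)
    bundle["bfactor_table"] = pd.DataFrame(
        {
            "chain": [k[0] for k in profile.residue_keys],
            "resnum": [k[1] for k in profile.residue_keys],
            "resname": [k[2] for k in profile.residue_keys],
            "B_A2": profile.b_values,
        }
    )
    bundle["average_bfactor"] = geometry.average_bfactor(profile)

    rgyr = geometry.rgyr_series(traj, structure)
    bundle["rgyr_series"] = pd.DataFrame(
        {"frame": np.arange(traj.n_frames), "time_ps": traj.times_ps(), "rgyr_A": rgyr}
    )
    bundle["mean_rgyr"] = float(rgyr[-window:].mean())

    # SASA over the protein part only
    protein = np.array(
        [i for i, a in enumerate(structure.atoms) if a.chain != "I"], dtype=int
    )
    frames, totals = surface.sasa_series(
        traj,
        structure,
        selection=protein,
        probe=config.probe_radius,
        n_points=config.n_sphere_points,
        stride=config.sasa_stride,
    )
    bundle["sasa_series"] = pd.DataFrame(
        {"frame": frames, "time_ps": frames * traj.frame_interval_ps, "total_sasa_A2": totals}
    )
    in_window = frames >= traj.n_frames - window
    bundle["mean_sasa"] = float(totals[in_window].mean()) if in_window.any() else float(totals.mean())

    # Hydrogen bonds
    table = interactions.hbond_persistence(
        traj, topology, structure, window, config.d_max, config.a_max
    )
    bundle["persistence_table"] = table
    bundle["average_hbond_count"] = table.total_fraction()
    bundle["persistent_hbond_count"] = interactions.persistent_count(
        table, config.persistence_threshold
    )

    # Salt bridges (only when acidic and basic side chains exist)
    if topology.carboxylate_groups and topology.basic_groups:
        candidates = interactions.salt_bridge_candidates(
            traj, topology, window, config.sb_prescreen
        )
        records = interactions.salt_bridge_persistence(
            traj, topology, candidates, structure, window, config.sb_com,
            config.persistence_threshold,
        )
        bundle["salt_bridges"] = pd.DataFrame(
            {
                "acid_res": [f"{r.acidic[2]}{r.acidic[1]}" for r in records],
                "base_res": [f"{r.basic[2]}{r.basic[1]}" for r in records],
                "persistence": [r.persistence_fraction for r in records],
                "mean_com_dist_A": [float(r.com_distance_series.mean()) for r in records],
                "retained": [r.retained for r in records],
            }
        )
        bundle["persistent_salt_bridges"] = int(sum(r.retained for r in records))

    # Amide-H / anion radial distribution (needs a box and anions)
    anion_idx = np.array(
        [i for i, a in enumerate(structure.atoms) if a.element in ("F", "CL")], dtype=int
    )
    if traj.box_per_frame is not None and anion_idx.size and topology.amide_hydrogens:
        prof = ions.rdf(
            traj,
            np.asarray(topology.amide_hydrogens),
            anion_idx,
            dr=config.rdf_dr,
            r_max=config.rdf_r_max,
        )
        bundle["rdf"] = pd.DataFrame({"r_A": prof.bin_centers, "g_r": prof.g})
        bundle["first_shell_coordination"] = ions.coordination_number(
            prof, config.contact_r_cut
        )
    return bundle


_SCALAR_KEYS = [
    "window_frames",
    "mean_rmsd",
    "average_bfactor",
    "mean_rgyr",
    "mean_sasa",
    "average_hbond_count",
    "persistent_hbond_count",
    "persistent_salt_bridges",
    "first_shell_coordination",
]

_TABLE_KEYS = {
    "rmsd_series": "rmsd.tsv",
    "bfactor_table": "bfactor.tsv",
    "rgyr_series": "rgyr.tsv",
    "sasa_series": "sasa.tsv",
    "salt_bridges": "salt_bridges.tsv",
    "rdf": "rdf.tsv",
}


def write_bundle(bundle: dict, out_dir: str | Path, config: AnalysisConfig | None = None) -> Path:
    """Write a descriptor bundle as TSV tables plus a machine-readable summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for key, fname in _TABLE_KEYS.items():
        if key in bundle:
            bundle[key].to_csv(out_dir / fname, sep="\t", index=False, float_format="%.6g")
    if "persistence_table" in bundle:
        bundle["persistence_table"].to_frame().to_csv(
            out_dir / "hbond_persistence.tsv", sep="\t", index=False, float_format="%.6g"
        )
    summary = {k: bundle[k] for k in _SCALAR_KEYS if k in bundle}
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    if config is not None:
        (out_dir / "run_config.json").write_text(json.dumps(asdict(config), indent=2))
    return out_dir / "summary.json"


def compare_bundles(
    results: dict[str, dict], manifest: list[ConditionSpec]
) -> ResponseSummary:
    """Aggregate per-condition descriptor bundles into the response summary."""
    return aggregate(results, manifest)
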