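"""Multi-condition response aggregation.

Each simulated condition (temperature, salt species, concentration,
glycosylation flag) yields a descriptor bundle; this module assembles the
per-condition table and the derived cross-condition statistics:

* temperature gradient of hydrogen-bond counts, as an ordinary least-squares
  slope over the 300/350/400 K grid scaled to "per 50 K" (loss is negative);
* glycosylation deltas, pairing glycosylated vs non-glycosylated conditions
  matched on (salt, concentration, temperature), with the number of pairs in
  which glycosylation gained bonds as a sign-consistency count;
* salt-type deltas (KF minus NaCl) matched on (glycosylation, concentration,
  temperature);
* the ionic-concentration bookkeeping that converts an ion-pair count and a
  cubic box edge into a molar background concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ConditionSpec

__all__ = [
    "AVOGADRO",
    "ResponseSummary",
    "aggregate",
    "temperature_gradient",
    "paired_delta",
    "ionic_concentration",
    "ionic_concentration_water_volume",
]

AVOGADRO = 6.02214076e23  # mol^-1
_A3_TO_L = 1e-27  # 1 cubic Angstrom in litres

DESCRIPTOR_COLUMNS = [
    "average_hbond_count",
    "persistent_hbond_count",
    "average_bfactor",
    "mean_rgyr",
    "mean_sasa",
]


@dataclass
class ResponseSummary:
    """Per-condition descriptor table plus derived cross-condition statistics."""

    table: pd.DataFrame
    hb_slope_per_50K: float | None = None
    hb_slope_families: list[tuple] = field(default_factory=list)
    avg_hb_slope_per_50K: float | None = None
    glyco_delta_persistent: float | None = None
    glyco_sign_consistency: tuple[int, int] | None = None
    glyco_pairs: list[tuple] = field(default_factory=list)
    salt_delta_persistent: float | None = None
    salt_pairs: list[tuple] = field(default_factory=list)

    def derived_dict(self) -> dict:
        return {
            "hb_slope_per_50K": self.hb_slope_per_50K,
            "avg_hb_slope_per_50K": self.avg_hb_slope_per_50K,
            "glyco_delta_persistent": self.glyco_delta_persistent,
            "glyco_sign_consistency": list(self.glyco_sign_consistency)
            if self.glyco_sign_consistency
            else None,
            "salt_delta_persistent": self.salt_delta_persistent,
            "n_glyco_pairs": len(self.glyco_pairs),
            "n_salt_pairs": len(self.salt_pairs),
            "n_slope_families": len(self.hb_slope_families),
        }


def ionic_concentration(n_pairs: int, box_length: float) -> float:
    """Background molarity of ``n_pairs`` ion pairs in a cubic cell (edge in A).

    c = n / (N_A * V) with the full cell volume in litres.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be non-negative")
    if box_length <= 0:
        raise ValueError("box_length must be positive")
    volume_l = box_length**3 * _A3_TO_L
    return n_pairs / (AVOGADRO * volume_l)


def ionic_concentration_water_volume(
    n_pairs: int, n_waters: int, water_molecular_volume_A3: float = 30.0
) -> float:
    """Molarity referred to the water volume only (configurable molecular volume)."""
    if n_pairs < 0 or n_waters <= 0:
        raise ValueError("n_pairs must be >= 0 and n_waters > 0")
    if water_molecular_volume_A3 <= 0:
        raise ValueError("water molecular volume must be positive")
    volume_l = n_waters * water_molecular_volume_A3 * _A3_TO_L
    return n_pairs / (AVOGADRO * volume_l)


def temperature_gradient(counts: dict[float, float], step: float = 50.0) -> float:
    """Least-squares slope of count vs temperature, scaled to the step.

    With counts at two temperatures this equals the finite difference scaled
    to the step; loss with rising temperature is negative.
    """
    if len(counts) < 2:
        raise ValueError("temperature gradient needs at least two temperatures")
    temps = np.array(sorted(counts))
    vals = np.array([counts[t] for t in temps], dtype=float)
    slope = np.polyfit(temps, vals, 1)[0]
    return float(slope * step)


def paired_delta(
    values_on: dict, values_off: dict
) -> tuple[float, int]:
    """Mean (on - off) over matched keys and the count of pairs with on > off."""
    if set(values_on) != set(values_off):
        missing = set(values_on) ^ set(values_off)
        raise ValueError(f"unmatched pairing keys: {sorted(missing, key=repr)}")
    if not values_on:
        raise ValueError("no pairs to compare")
    keys = sorted(values_on, key=repr)
    deltas = np.array([values_on[k] - values_off[k] for k in keys], dtype=float)
    return float(deltas.mean()), int((deltas > 0).sum())


def _family_slopes(
    table: pd.DataFrame, column: str, step: float = 50.0
) -> tuple[list[tuple], list[float]]:
    """OLS slope of ``column`` vs temperature within each
    (glycosylated, salt, concentration) family having >= 2 temperatures."""
    families, slopes = [], []
    for key, grp in table.groupby(["glycosylated", "salt", "concentration_M"]):
        if grp["temperature_K"].nunique() < 2:
            continue
        counts = dict(zip(grp["temperature_K"], grp[column]))
        families.append(key)
        slopes.append(temperature_gradient(counts, step))
    return families, slopes


def aggregate(
    results: dict[str, dict],
    manifest: list[ConditionSpec],
    temperature_step: float = 50.0,
) -> ResponseSummary:
    """Assemble the per-condition table and derived statistics.

    ``results`` maps condition labels to descriptor dicts holding at least
    ``persistent_hbond_count`` and ``average_hbond_count``.  Derived
    statistics are computed only over complete pairings/families and record
    which conditions contributed.
    """
    if not manifest:
        raise ValueError("empty condition manifest: nothing to aggregate")
    rows = []
    for spec in manifest:
        if spec.label not in results:
            raise KeyError(f"missing descriptor bundle for condition {spec.label!r}")
        bundle = results[spec.label]
        row = {
            "label": spec.label,
            "temperature_K": spec.temperature_K,
            "salt": spec.salt,
            "concentration_M": spec.concentration_M,
            "glycosylated": spec.glycosylated,
        }
        for col in DESCRIPTOR_COLUMNS:
            row[col] = bundle.get(col, np.nan)
        rows.append(row)
    extra = set(results) - {s.label for s in manifest}
    if extra:
        raise KeyError(f"descriptor bundles with no manifest entry: {sorted(extra)}")
    table = pd.DataFrame(rows).sort_values("label", kind="stable").reset_index(drop=True)

    summary = ResponseSummary(table=table)

    families, slopes = _family_slopes(table, "persistent_hbond_count", temperature_step)
    if slopes:
        summary.hb_slope_families = families
        summary.hb_slope_per_50K = float(np.mean(slopes))
    _, avg_slopes = _family_slopes(table, "average_hbond_count", temperature_step)
    if avg_slopes:
        summary.avg_hb_slope_per_50K = float(np.mean(avg_slopes))

    # Glycosylation deltas: pair on (salt, concentration, temperature).
    on, off = {}, {}
    for _, row in table.iterrows():
        key = (row["salt"], row["concentration_M"], row["temperature_K"])
        target = on if row["glycosylated"] else off
        target[key] = row["persistent_hbond_count"]
    common = set(on) & set(off)
    if common:
        on_c = {k: on[k] for k in common}
        off_c = {k: off[k] for k in common}
        mean_delta, consistent = paired_delta(on_c, off_c)
        summary.glyco_delta_persistent = mean_delta
        summary.glyco_sign_consistency = (consistent, len(common))
        summary.glyco_pairs = sorted(common, key=repr)

    # Salt-type deltas (KF vs NaCl): pair on (glycosylated, concentration, T).
    kf, nacl = {}, {}
    for _, row in table.iterrows():
        key = (row["glycosylated"], row["concentration_M"], row["temperature_K"])
        if row["salt"] == "KF":
            kf[key] = row["persistent_hbond_count"]
        elif row["salt"] == "NACL":
            nacl[key] = row["persistent_hbond_count"]
    common_salt = set(kf) & set(nacl)
    if common_salt:
        kf_c = {k: kf[k] for k in common_salt}
        nacl_c = {k: nacl[k] for k in common_salt}
        mean_delta, _ = paired_delta(kf_c, nacl_c)
        summary.salt_delta_persistent = mean_delta
        summary.salt_pairs = sorted(common_salt, key=repr)

    return summary
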