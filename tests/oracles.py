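"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use plain Python loops and elementary formulas, sharing
no code path with the package internals they verify.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_hbonds(frame, donors, acceptors, residue_of, d_max=3.5, a_max=30.0):
    """All-pairs loop over donor (N, H) pairs and acceptor O atoms."""
    found = set()
    for n_i, h_i in donors:
        for o_i in acceptors:
            if residue_of[n_i] == residue_of[o_i]:
                continue
            d = math.dist(frame[n_i], frame[o_i])
            if d >= d_max:
                continue
            v_dh = frame[h_i] - frame[n_i]
            v_da = frame[o_i] - frame[n_i]
            cosang = np.dot(v_dh, v_da) / (np.linalg.norm(v_dh) * np.linalg.norm(v_da))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if ang < a_max:
                found.add((n_i, h_i, o_i))
    return found


def brute_force_salt_bridges(
    coords, carboxylate_groups, basic_groups, masses, d_pre=3.2, d_com=3.5, threshold=0.5
):
    """Two-stage filter by explicit loops: atomwise pre-screen then COM filter."""
    candidates = set()
    n_frames = coords.shape[0]
    for acid, o_idx in carboxylate_groups.items():
        for base, n_idx in basic_groups.items():
            hit = False
            for f in range(n_frames):
                for o in o_idx:
                    for n in n_idx:
                        if math.dist(coords[f, o], coords[f, n]) < d_pre:
                            hit = True
            if hit:
                candidates.add((acid, base))
    retained = {}
    for acid, base in candidates:
        o_idx = carboxylate_groups[acid]
        n_idx = basic_groups[base]
        count = 0
        for f in range(n_frames):
            o_com = np.average(coords[f, o_idx], axis=0, weights=[masses[i] for i in o_idx])
            n_com = np.average(coords[f, n_idx], axis=0, weights=[masses[i] for i in n_idx])
            if math.dist(o_com, n_com) < d_com:
                count += 1
        frac = count / n_frames
        retained[(acid, base)] = (frac, frac > threshold)
    return candidates, retained


def numeric_min_rmsd(mobile, reference, n_starts=40, seed=0):
    """Minimum RMSD over rigid transforms by numeric optimisation over
    rotation vectors from many random starting orientations."""
    mobile = mobile - mobile.mean(axis=0)
    reference = reference - reference.mean(axis=0)
    n = mobile.shape[0]

    def loss(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return np.sum((mobile @ R.T - reference) ** 2)

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        rv0 = rng.normal(size=3) * np.pi
        res = minimize(loss, rv0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 5000})
        best = min(best, res.fun)
    return math.sqrt(best / n)


def direct_rgyr(points, masses):
    com = np.zeros(3)
    total = 0.0
    for p, m in zip(points, masses):
        com += m * np.asarray(p)
        total += m
    com /= total
    s = 0.0
    for p, m in zip(points, masses):
        s += m * float(np.sum((np.asarray(p) - com) ** 2))
    return math.sqrt(s / total)
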