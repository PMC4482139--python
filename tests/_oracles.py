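"""Independent brute-force oracles used by the test suite only.

These deliberately avoid the library's own code paths: the matcher oracle is
an exact bitmask dynamic program over all one-to-one pairings, the motif
oracle is a regex sliding window, and the superposition oracle is a generic
numerical minimiser over rotation vectors.
"""

from __future__ import annotations

import re
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_match(ref_peaks, qry_peaks, tol):
    """Exact maximum-cardinality, minimum-total-cost in-box matching.

    Returns (n_matched, total_cost).  Exponential-state DP over query-peak
    bitmasks; fine for lists of up to ~14 peaks.
    """
    n_q = len(qry_peaks)
    cand = []
    for rp in ref_peaks:
        row = []
        for j, qp in enumerate(qry_peaks):
            dh = abs(rp.h_shift - qp.h_shift)
            dn = abs(rp.n_shift - qp.n_shift)
            if dh <= tol.tol_h and dn <= tol.tol_n:
                row.append((j, float(np.hypot(dh, tol.n_weight * dn))))
        cand.append(tuple(row))
    cand = tuple(cand)

    @lru_cache(maxsize=None)
    def best(i: int, mask: int):
        if i == len(cand):
            return (0, 0.0)
        # option: leave ref peak i unmatched
        score = best(i + 1, mask)
        for j, cost in cand[i]:
            if mask & (1 << j):
                continue
            count, total = best(i + 1, mask | (1 << j))
            option = (count + 1, total + cost)
            if (-option[0], option[1]) < (-score[0], score[1]):
                score = option
        return score

    assert n_q <= 20, "bitmask oracle limited to small query lists"
    result = best(0, 0)
    best.cache_clear()
    return result


# regex per motif: pattern string and the phosphosite offset from match start
MOTIF_REGEX = {
    "mode2_1433": (r"R...[ST]..P", 4),
    "mode1_1433": (r"R..[ST].P", 3),
    "camk2": (r"R..[ST]", 3),
    "agc": (r"R...[ST]", 4),
    "gsk3": (r"[ST]...[ST]", 0),
}


def regex_motif_sites(residues: str, motif_name: str) -> set[int]:
    """1-based phosphosite positions of a motif via overlapping regex search."""
    pattern, offset = MOTIF_REGEX[motif_name]
    return {
        m.start() + offset + 1
        for m in re.finditer(f"(?=({pattern}))", residues)
    }


def numeric_best_rmsd(P: np.ndarray, Q: np.ndarray, n_starts: int = 8,
                      seed: int = 0) -> float:
    """Best RMSD over rigid motions found by a generic numerical minimiser."""
    rng = np.random.default_rng(seed)

    def objective(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        moved = P @ R.T + x[3:]
        return np.mean(np.sum((moved - Q) ** 2, axis=1))

    best = np.inf
    for _ in range(n_starts):
        x0 = np.concatenate([rng.uniform(-np.pi, np.pi, 3),
                             Q.mean(axis=0) - P.mean(axis=0)])
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        best = min(best, res.fun)
    return float(np.sqrt(best))
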