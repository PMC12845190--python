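"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: the rotation oracle
minimises RMSD numerically over a rotation-vector parameterisation instead
of using an SVD, and the window oracle enumerates every window with plain
Python.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def plain_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((np.asarray(a) - np.asarray(b)) ** 2, axis=1))))


def rotation_oracle_rmsd(mobile: np.ndarray, reference: np.ndarray,
                         n_starts: int = 24, seed: int = 0) -> float:
    """Minimum RMSD over all rigid transforms, found by multi-start numerical
    optimisation over rotation vectors (no SVD involved)."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)

    def cost(rotvec):
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        return plain_rmsd(mc @ rot.T, rc)

    rng = np.random.default_rng(seed)
    best = cost(np.zeros(3))
    starts = [np.zeros(3)] + [rng.uniform(-np.pi, np.pi, 3) for _ in range(n_starts)]
    for s in starts:
        res = minimize(cost, s, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, float(res.fun))
    return best


def window_diff_oracle(ids, a, b, window, min_abs_diff):
    """Enumerate every sliding window, flag it, and merge flagged windows into
    (start_id, end_id, direction, peak) tuples by plain scanning."""
    ids = list(ids)
    a = list(a)
    b = list(b)
    flags = []
    for s in range(len(ids) - window + 1):
        d = max(a[s:s + window]) - max(b[s:s + window])
        if abs(d) >= min_abs_diff:
            flags.append((s, "A-higher" if d > 0 else "B-higher", abs(d)))
    segments = []
    for s, direction, peak in flags:
        if (segments
                and segments[-1]["direction"] == direction
                and s <= segments[-1]["last"] + window - 1):
            segments[-1]["last"] = s
            segments[-1]["peak"] = max(segments[-1]["peak"], peak)
        else:
            segments.append({"first": s, "last": s, "direction": direction, "peak": peak})
    return [
        (ids[seg["first"]], ids[seg["last"]], seg["direction"], seg["peak"])
        for seg in segments
    ]
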