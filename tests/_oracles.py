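"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the superposition
oracle goes through the quaternion (Horn) eigenvalue method instead of the
SVD route, and the distance/count oracles are explicit Python loops.
"""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Least-squares superposition RMSD via the quaternion key matrix.

    Builds Horn's 4x4 matrix from the centered correlation matrix and reads
    the optimal (proper-rotation) superposition from its largest
    eigenvalue: rmsd^2 = (|P0|^2 + |Q0|^2 - 2 lambda_max) / n.
    """
    P0 = np.asarray(P, float) - np.mean(P, axis=0)
    Q0 = np.asarray(Q, float) - np.mean(Q, axis=0)
    n = P0.shape[0]
    S = P0.T @ Q0
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = float(np.linalg.eigvalsh(K)[-1])
    msd = (np.sum(P0**2) + np.sum(Q0**2) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def brute_min_distance(xyz_a, xyz_b, box=None) -> float:
    """Minimum cross-product distance by explicit loops."""
    best = np.inf
    for a in np.asarray(xyz_a, float):
        for b in np.asarray(xyz_b, float):
            d = a - b
            if box is not None:
                for k in range(3):
                    d[k] -= box[k] * round(d[k] / box[k])
            best = min(best, float(np.sqrt(np.sum(d**2))))
    return best


def brute_water_count(frame, water_indices, center_index, radius, box=None) -> int:
    """All-pairs water count by explicit loops."""
    c = frame[center_index]
    count = 0
    for w in water_indices:
        d = frame[w] - c
        if box is not None:
            for k in range(3):
                d[k] -= box[k] * round(d[k] / box[k])
        if float(np.sqrt(np.sum(d**2))) <= radius:
            count += 1
    return count
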