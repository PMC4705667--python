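"""Independent oracles used by the test suite.

These deliberately re-derive results through different algorithms than the
package (Horn's quaternion eigenvector method instead of Kabsch/SVD
alignment, covariance eigendecomposition instead of SVD plane fits, full
enumeration instead of scipy's rank-sum machinery, concordant-pair counting
instead of trapezoid ROC integration).
"""

from itertools import combinations

import numpy as np


def quaternion_superpose(P, Q):
    """Horn's closed-form absolute orientation: rotation+translation mapping
    point set P onto Q in the least-squares sense.

    Returns (R, t, rmsd) with Q ~ P @ R.T + t.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    A = (P - pc).T @ (Q - qc)
    Sxx, Sxy, Sxz = A[0]
    Syx, Syy, Syz = A[1]
    Szx, Szy, Szz = A[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    eigenvalues, eigenvectors = np.linalg.eigh(N)
    w, x, y, z = eigenvectors[:, np.argmax(eigenvalues)]
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1)))
    return R, t, float(rmsd)


def plane_deviation(points, query):
    """Distance of ``query`` from the least-squares plane of ``points``,
    via eigendecomposition of the covariance matrix."""
    points = np.asarray(points, dtype=float)
    centroid = points.mean(axis=0)
    cov = (points - centroid).T @ (points - centroid)
    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    normal = eigenvectors[:, np.argmin(eigenvalues)]
    return float(abs((np.asarray(query) - centroid) @ normal))


def exact_ranksum_p(a, b):
    """Two-sided exact rank-sum p-value by full enumeration of all
    C(m+n, m) assignments of the pooled (tie-free) values to group A."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    m, n = len(a), len(b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in a) - m * (m + 1) / 2
    mn = m * n
    stat_obs = min(u_obs, mn - u_obs)
    hits = total = 0
    for combo in combinations(range(m + n), m):
        u = sum(r + 1 for r in combo) - m * (m + 1) / 2
        if min(u, mn - u) <= stat_obs + 1e-12:
            hits += 1
        total += 1
    return hits / total


def pair_counting_auc(scores, labels):
    """AUC as the fraction of concordant (positive, negative) score pairs,
    counting ties as one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = len(pos) * len(neg)
    concordant = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(concordant) / total
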