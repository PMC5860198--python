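"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the package's optimised code paths:
the pseudo-inverse comes from numpy's SVD-based ``pinv``, double-force
responses are rebuilt from scratch per orientation pair (no superposition
shortcut), and aggregations are plain Python loops.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import null_space


def rms_distance(displacement: np.ndarray) -> float:
    per_res = displacement.reshape(-1, 3)
    return float(np.sqrt(np.mean(np.sum(per_res**2, axis=1))))


def rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal 3N×6 basis of infinitesimal rigid motions."""
    n = len(coords)
    centred = coords - coords.mean(axis=0)
    cols = []
    for ax in np.eye(3):
        cols.append(np.tile(ax, n))
        cols.append(np.cross(np.broadcast_to(ax, (n, 3)), centred).ravel())
    q, _ = np.linalg.qr(np.array(cols).T)
    return q


def constrained_solve(hessian: np.ndarray, force: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Minimise ½xᵀHx − Fᵀx over the subspace orthogonal to rigid motions."""
    rigid = rigid_body_basis(coords)
    q = null_space(rigid.T)  # 3N × (3N−6) complement basis
    y = np.linalg.solve(q.T @ hessian @ q, q.T @ force)
    return q @ y


def naive_pinv(hessian: np.ndarray) -> np.ndarray:
    return np.linalg.pinv(hessian, rcond=1e-8, hermitian=True)


def naive_force(n_nodes: int, site: int, orientation: np.ndarray, magnitude: float) -> np.ndarray:
    f = np.zeros(3 * n_nodes)
    f[3 * site:3 * site + 3] = magnitude * np.asarray(orientation)
    return f


def naive_pair_score(
    hessian: np.ndarray,
    i: int,
    j: int,
    orientations: np.ndarray,
    magnitude: float,
    scheme: str,
) -> float:
    """Max-then-mean rescuability, rebuilding every response from scratch."""
    hp = naive_pinv(hessian)
    n = hessian.shape[0] // 3
    row_maxima = []
    for oa in orientations:
        fi = naive_force(n, i, oa, magnitude)
        di = rms_distance(hp @ fi)
        best = -np.inf
        for ob in orientations:
            fj = naive_force(n, j, ob, magnitude)
            if scheme == "FR":
                dj = rms_distance(hp @ fj)
                fj = fj * (di / dj)
            dij = rms_distance(hp @ (fi + fj))
            best = max(best, (di - dij) / di)
        row_maxima.append(best)
    return float(np.mean(row_maxima))


def naive_scan(hessian, orientations, magnitude, scheme):
    n = hessian.shape[0] // 3
    s = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i != j:
                s[i, j] = naive_pair_score(hessian, i, j, orientations, magnitude, scheme)
    return s


def naive_compensatory_power(matrices: dict, degree) -> np.ndarray:
    """Per-residue loop over count / degree, min-max rescale, average."""
    n = len(degree)
    comps = []
    for s in matrices.values():
        ratios = []
        for j in range(n):
            count = sum(1 for i in range(n) if i != j and s[i, j] > 0)
            ratios.append(count / degree[j])
        lo, hi = min(ratios), max(ratios)
        if hi == lo:
            comps.append([0.0] * n)
        else:
            comps.append([(r - lo) / (hi - lo) for r in ratios])
    return np.array([sum(c[j] for c in comps) / len(comps) for j in range(n)])


def naive_optimal_threshold(scores, positives):
    """Exhaustive enumeration of all candidate strict cut points."""
    scores = np.asarray(scores, dtype=float)
    pos = set(positives)
    n = len(scores)
    best = None
    for t in sorted(set(scores.tolist())):
        tp = fp = fn = tn = 0
        for idx, v in enumerate(scores):
            predicted = v > t
            if predicted and idx in pos:
                tp += 1
            elif predicted:
                fp += 1
            elif idx in pos:
                fn += 1
            else:
                tn += 1
        sens = tp / (tp + fn)
        spec = tn / (tn + fp) if tn + fp else 1.0
        d = (1 - sens) ** 2 + (1 - spec) ** 2
        npred = tp + fp
        if best is None or d < best[0] or (d == best[0] and npred < best[2]):
            best = (d, t, npred)
    return best[1], best[0]
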