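"""Double force scanning (DFS) core.

For every ordered residue pair (i, j) a force at the first (pathogenic)
site i is combined with a force at the second (candidate rescue) site j,
and the rescuability index

    ρ_ij = (d(u, p_i) − d(u, p_ij)) / d(u, p_i)

measures how much the second force reduces the structural deformation
caused by the first alone (u is the native structure, p_i and p_ij the
singly and doubly perturbed structures).  ρ in (0, 1] flags a compensatory
effect; ρ = 1 is perfect cancellation.

The pair score S_ij maximises ρ over second-site force orientations and
averages the maxima over first-site orientations.  Scores over all pairs
form the rescuability matrices S^FF and S^FR (one per magnitude scheme),
which are aggregated per residue into the compensatory power P.

Within linear response the double-force displacement is the superposition
of the two single-force responses, so a full scan only needs the three
unit-force responses per site (columns of H⁺); the engine precomputes
these and reduces every pair to a small Gram-matrix update.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .enm import DEFAULT_ZERO_TOL, ElasticNetwork, pseudo_inverse
from .forces import ForceBasis

SCHEMES = ("FF", "FR")
DEFAULT_PERCENTILE = 0.28  # top fraction of residues classified as rescue sites


def structural_distance(displacement: np.ndarray) -> float:
    """RMS per-residue displacement magnitude of a 3N field, in Å.

    d = sqrt((1/N)·Σ_i ‖Δr_i‖²).  No rigid-body superposition is applied:
    pseudo-inverse responses are already orthogonal to the rigid subspace.
    """
    displacement = np.asarray(displacement, dtype=float)
    if displacement.size % 3:
        raise ValueError("displacement length must be divisible by 3")
    n = displacement.size // 3
    return float(np.linalg.norm(displacement) / np.sqrt(n))


def rescuability(d_i: float, d_ij: float, tol: float = 1e-12) -> float:
    """ρ = (d_i − d_ij)/d_i; bounded above by 1, unbounded below."""
    if d_i <= tol:
        raise ValueError(
            "first-site force produced no deformation (d_i ~ 0): "
            "network defect"
        )
    return (d_i - d_ij) / d_i


def score_from_rho_grid(rho: np.ndarray) -> float:
    """Aggregate a ρ grid (rows: F_i orientations, cols: F_j) into S_ij.

    Maximum over second-site orientations, then mean over first-site ones.
    """
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    return float(rho.max(axis=1).mean())


@dataclass
class RescuabilityMatrix:
    """N×N ordered pair scores for one scheme; diagonal masked as NaN."""

    scheme: str
    S: np.ndarray

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        self.S = np.asarray(self.S, dtype=float)

    def to_tsv(self, labels: list[str] | None = None) -> str:
        df = pd.DataFrame(self.S, index=labels, columns=labels)
        return df.to_csv(sep="\t", index=labels is not None, float_format="%.10g")


@dataclass
class CompensatoryProfile:
    """Per-residue aggregation of the rescuability matrices.

    For each scheme, ``counts[scheme][j]`` is the number of first sites i
    with S_ij > 0 (residues j can rescue), divided by the contact degree of
    j and min-max rescaled across residues into ``components[scheme]``.
    P is the mean of the per-scheme components.
    """

    counts: dict[str, np.ndarray]
    components: dict[str, np.ndarray]
    degree: np.ndarray
    P: np.ndarray

    @property
    def schemes(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def to_dataframe(self, structure=None) -> pd.DataFrame:
        cols: dict[str, object] = {}
        if structure is not None:
            cols["chain"] = [k.chain for k in structure.keys]
            cols["resnum"] = [k.resnum for k in structure.keys]
            cols["icode"] = [k.icode for k in structure.keys]
            cols["aa"] = list(structure.aa)
        cols["degree"] = self.degree
        for sch in self.counts:
            cols[f"count_{sch}"] = self.counts[sch]
        for sch in self.components:
            cols[f"component_{sch}"] = self.components[sch]
        cols["P"] = self.P
        return pd.DataFrame(cols)


class _ResponseTable:
    """Precomputed unit-magnitude responses per site and orientation."""

    def __init__(self, invH: np.ndarray, basis: ForceBasis):
        n3 = invH.shape[0]
        self.n_nodes = n3 // 3
        self.basis = basis
        o = basis.orientations.T  # (3, n_or)
        # resp[j] has one 3N response column per orientation of a unit force
        self.resp = [invH[:, 3 * j:3 * j + 3] @ o for j in range(self.n_nodes)]
        self.norms = np.array([np.linalg.norm(r, axis=0) for r in self.resp])

    def rho_grid(self, i: int, j: int, scheme: str) -> np.ndarray:
        """ρ over the (F_i orientation, F_j orientation) grid for pair (i, j).

        Uses ‖x + s·y‖² = ‖x‖² + 2s·x·y + s²‖y‖²; the 1/√N factor and the
        base force magnitude cancel in ρ.
        """
        ni = self.norms[i]  # (n_or,)
        nj = self.norms[j]
        if np.any(ni <= 1e-12) or np.any(nj <= 1e-12):
            raise ValueError(
                f"unit force at site {i if np.any(ni <= 1e-12) else j} "
                "produced no deformation: network defect"
            )
        cross = self.resp[i].T @ self.resp[j]  # (n_or, n_or)
        if scheme == "FF":
            s = 1.0
        elif scheme == "FR":
            s = ni[:, None] / nj[None, :]
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        nij_sq = ni[:, None] ** 2 + 2.0 * s * cross + (s * nj[None, :]) ** 2
        nij = np.sqrt(np.maximum(nij_sq, 0.0))
        return (ni[:, None] - nij) / ni[:, None]


def pair_score(
    invH: np.ndarray, i: int, j: int, basis: ForceBasis, scheme: str
) -> float:
    """S_ij for a single ordered pair (max over F_j, mean over F_i)."""
    if i == j:
        raise ValueError("self-pairs are excluded from the scan")
    table = _ResponseTable(invH, basis)
    return score_from_rho_grid(table.rho_grid(i, j, scheme))


def scan(
    net: ElasticNetwork,
    basis: ForceBasis | None = None,
    schemes: tuple[str, ...] = SCHEMES,
    invH: np.ndarray | None = None,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> dict[str, RescuabilityMatrix]:
    """Full DFS scan: one rescuability matrix per requested scheme.

    All ordered pairs i ≠ j are scored; the diagonal is NaN.
    """
    n = net.n_nodes
    if n < 3:
        raise ValueError("need at least 3 residues to scan")
    for sch in schemes:
        if sch not in SCHEMES:
            raise ValueError(f"unknown scheme {sch!r}")
    if basis is None:
        basis = ForceBasis()
    if invH is None:
        invH = pseudo_inverse(net, zero_tol)
    table = _ResponseTable(invH, basis)
    out: dict[str, RescuabilityMatrix] = {}
    for sch in schemes:
        S = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                S[i, j] = score_from_rho_grid(table.rho_grid(i, j, sch))
        out[sch] = RescuabilityMatrix(sch, S)
    return out


def compensatory_power(
    matrices: dict[str, RescuabilityMatrix], degree: np.ndarray
) -> CompensatoryProfile:
    """Aggregate rescuability matrices into the per-residue power P.

    For each scheme: count_j = |{i ≠ j : S_ij > 0}|, ratio_j =
    count_j / degree_j, then min-max rescaling of the ratios to [0, 1]
    across residues.  P is the mean of the scheme components.  A flat ratio
    vector (max == min) rescales to all zeros — it carries no signal.
    """
    if not matrices:
        raise ValueError("need at least one rescuability matrix")
    degree = np.asarray(degree)
    if np.any(degree == 0):
        bad = np.flatnonzero(degree == 0)
        raise ValueError(
            f"isolated nodes {bad.tolist()} (degree 0): increase r_c"
        )
    counts: dict[str, np.ndarray] = {}
    components: dict[str, np.ndarray] = {}
    for sch, mat in matrices.items():
        S = mat.S
        if S.shape[0] != degree.size:
            raise ValueError("matrix and degree sizes disagree")
        with np.errstate(invalid="ignore"):
            cnt = np.nansum(S > 0, axis=0).astype(int)  # column j: rescuer
        ratio = cnt / degree
        lo, hi = ratio.min(), ratio.max()
        if hi == lo:
            logger.warning(
                "scheme %s: flat rescued-count/degree profile; "
                "component set to zero for all residues", sch,
            )
            comp = np.zeros_like(ratio)
        else:
            comp = (ratio - lo) / (hi - lo)
        counts[sch] = cnt
        components[sch] = comp
    P = np.mean(list(components.values()), axis=0)
    return CompensatoryProfile(counts, components, degree.astype(int), P)


def prediction_threshold(P: np.ndarray, percentile: float = DEFAULT_PERCENTILE) -> float:
    """Strict P cutoff corresponding to the top ``percentile`` fraction."""
    if not 0 < percentile < 1:
        raise ValueError("percentile must be in (0, 1)")
    return float(np.quantile(np.asarray(P, dtype=float), 1.0 - percentile))

def classify_rescue_sites(
    P: np.ndarray, percentile: float = DEFAULT_PERCENTILE
) -> np.ndarray:
    """Indices of residues with P strictly above the top-fraction cutoff.

    Ties at the threshold are excluded (strict inequality), so a flat P
    profile predicts nothing.
    """
    thr = prediction_threshold(P, percentile)
    return np.flatnonzero(np.asarray(P, dtype=float) > thr)


def compensatory_motion(
    invH: np.ndarray, i: int, j: int, basis: ForceBasis, scheme: str
) -> np.ndarray:
    """Double-force displacement at the orientation pair maximising ρ.

    Ties resolve to the lowest (first-site, second-site) orientation index
    pair.  The returned 3N vector carries the basis magnitude.
    """
    if i == j:
        raise ValueError("self-pairs are excluded")
    table = _ResponseTable(invH, basis)
    rho = table.rho_grid(i, j, scheme)
    a, b = np.unravel_index(np.argmax(rho), rho.shape)
    s = 1.0 if scheme == "FF" else table.norms[i][a] / table.norms[j][b]
    disp = table.resp[i][:, a] + s * table.resp[j][:, b]
    return basis.magnitude * disp


def orientation_convergence(
    net: ElasticNetwork,
    ns: tuple[int, ...] = (6, 12, 24),
    schemes: tuple[str, ...] = SCHEMES,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> pd.DataFrame:
    """Drift of the rescuability matrices as the orientation set is refined.

    Runs the scan at each orientation count in ``ns`` and reports
    max |ΔS| over defined entries between consecutive counts, per scheme.
    """
    if len(ns) < 2:
        raise ValueError("need at least two orientation counts")
    invH = pseudo_inverse(net, zero_tol)
    results = {n: scan(net, ForceBasis(n), schemes, invH=invH) for n in ns}
    rows = []
    for n_from, n_to in zip(ns[:-1], ns[1:]):
        for sch in schemes:
            delta = np.abs(results[n_to][sch].S - results[n_from][sch].S)
            rows.append(
                {
                    "scheme": sch,
                    "n_from": n_from,
                    "n_to": n_to,
                    "max_abs_dS": float(np.nanmax(delta)),
                }
            )
    return pd.DataFrame(rows)
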