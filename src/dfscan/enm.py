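"""Anisotropic network model (ANM) and its linear-response operator.

Residues are nodes connected by Hookean springs whenever their Cα-Cα
distance is below a cutoff ``r_c``.  The 3N×3N hessian H of this network
governs harmonic fluctuations; the first-order displacement under an
external force F follows linear response theory, ΔR = H⁺F, with the
pseudo-inverse taken over the non-rigid modes.  A connected, non-planar
network has exactly six zero modes (rigid translations and rotations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial.distance import squareform, pdist

from .structures import CoarseGrainedStructure

DEFAULT_CUTOFF = 15.0  # Å, canonical ANM choice
DEFAULT_GAMMA = 1.0
DEFAULT_ZERO_TOL = 1e-6  # relative to the largest eigenvalue


@dataclass
class ElasticNetwork:
    structure: CoarseGrainedStructure
    r_c: float
    gamma: float
    hessian: np.ndarray  # (3N, 3N)
    degree: np.ndarray  # (N,) neighbours within r_c, self excluded

    _evals: np.ndarray | None = None
    _evecs: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.structure)

    def eigh(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (cached) eigendecomposition of the hessian, ascending."""
        if self._evals is None:
            self._evals, self._evecs = scipy.linalg.eigh(self.hessian)
        return self._evals, self._evecs


@dataclass
class ModeSpectrum:
    """Non-rigid normal modes, ascending by eigenvalue.

    ``eigenvectors`` has one orthonormal 3N mode per column.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero: int


def build_network(
    s: CoarseGrainedStructure,
    r_c: float = DEFAULT_CUTOFF,
    gamma: float = DEFAULT_GAMMA,
) -> ElasticNetwork:
    """Assemble the ANM hessian for structure ``s``.

    For a connected pair (i, j) the off-diagonal 3×3 block is
    −γ·ê_ij ê_ijᵀ with ê_ij the unit inter-node vector; diagonal blocks are
    minus the sum of the row's off-diagonal blocks, which makes each 3×3
    super-row sum vanish (translation invariance).
    """
    if len(s) < 2:
        raise ValueError("need at least 2 nodes")
    if r_c <= 0 or gamma <= 0:
        raise ValueError("r_c and gamma must be positive")
    coords = s.coords
    n = len(s)
    dmat = squareform(pdist(coords))
    close = dmat < 1e-6
    np.fill_diagonal(close, False)
    if close.any():
        i, j = np.argwhere(close)[0]
        raise ValueError(f"coincident nodes {i} and {j}: spring direction undefined")
    contact = dmat < r_c
    np.fill_diagonal(contact, False)
    degree = contact.sum(axis=1).astype(int)

    hessian = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in np.flatnonzero(contact[i]):
            if j <= i:
                continue
            e = (coords[j] - coords[i]) / dmat[i, j]
            block = -gamma * np.outer(e, e)
            hessian[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            hessian[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
            hessian[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
            hessian[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return ElasticNetwork(s, r_c, gamma, hessian, degree)


def _split_spectrum(
    net: ElasticNetwork, zero_tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    evals, evecs = net.eigh()
    lam_max = evals[-1]
    if lam_max <= 0:
        raise ValueError("hessian has no positive eigenvalues (empty network?)")
    near_zero = evals < zero_tol * lam_max
    n_zero = int(near_zero.sum())
    if n_zero > 6:
        raise ValueError(
            f"{n_zero} near-zero eigenvalues (expected 6): network is "
            "disconnected, planar or floppy — increase r_c"
        )
    if n_zero < 6:
        raise ValueError(
            f"{n_zero} near-zero eigenvalues (expected 6): hessian is "
            "numerically broken"
        )
    return evals, evecs, near_zero


def pseudo_inverse(net: ElasticNetwork, zero_tol: float = DEFAULT_ZERO_TOL) -> np.ndarray:
    """Moore-Penrose inverse of the hessian over the non-rigid subspace.

    H⁺ = Σ_{λ_k ≥ tol} λ_k⁻¹ v_k v_kᵀ.  Errors if the count of near-zero
    eigenvalues is not exactly 6 (signals a defective network).
    """
    evals, evecs, near_zero = _split_spectrum(net, zero_tol)
    keep = ~near_zero
    v = evecs[:, keep]
    return (v / evals[keep]) @ v.T


def normal_modes(
    net: ElasticNetwork, k: int, zero_tol: float = DEFAULT_ZERO_TOL
) -> ModeSpectrum:
    """First ``k`` non-rigid modes, ascending by eigenvalue."""
    n3 = 3 * net.n_nodes
    if not 1 <= k <= n3 - 6:
        raise ValueError(f"k must be in [1, {n3 - 6}], got {k}")
    evals, evecs, near_zero = _split_spectrum(net, zero_tol)
    keep = np.flatnonzero(~near_zero)[:k]
    return ModeSpectrum(evals[keep], evecs[:, keep], n_zero=int(near_zero.sum()))


def spectrum_to_tsv(spec: ModeSpectrum) -> str:
    """Mode table: index, eigenvalue, collectivity."""
    lines = ["mode\teigenvalue\tcollectivity"]
    for idx, (lam, v) in enumerate(zip(spec.eigenvalues, spec.eigenvectors.T), start=1):
        lines.append(f"{idx}\t{lam:.10g}\t{collectivity(v):.10g}")
    return "\n".join(lines) + "\n"


def collectivity(mode: np.ndarray) -> float:
    """Exponential-entropy collectivity κ ∈ (0, 1] of a displacement field.

    With per-residue squared displacements u_i² normalised to sum to one,
    κ = (1/N)·exp(−Σ u_i² ln u_i²): 1/N for a motion confined to a single
    residue, 1 for a perfectly uniform one.
    """
    mode = np.asarray(mode, dtype=float)
    if mode.size % 3:
        raise ValueError("mode length must be divisible by 3")
    u2 = (mode.reshape(-1, 3) ** 2).sum(axis=1)
    total = u2.sum()
    if total <= 0:
        raise ValueError("zero mode vector")
    u2 = u2 / total
    nz = u2[u2 > 0]
    entropy = -float(np.sum(nz * np.log(nz)))
    return float(np.exp(entropy) / len(u2))
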