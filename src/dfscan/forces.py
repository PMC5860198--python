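"""Force generation: uniform orientation sets and magnitude schemes.

Mutational perturbations are mimicked by external forces applied at single
residues.  Because the structural response depends on force orientation,
each site receives a deterministic set of unit vectors spread as uniformly
as possible over the sphere (spherical Fibonacci lattice).  Two magnitude
schemes exist: Fixed Force (FF), where both sites receive the same
magnitude, and Fixed RMSD (FR), where the second-site magnitude is rescaled
so that each force alone deforms the structure equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GOLDEN_RATIO = (1.0 + np.sqrt(5.0)) / 2.0

DEFAULT_N_ORIENTATIONS = 12
DEFAULT_MAGNITUDE = 1.0


def fibonacci_orientations(n: int) -> np.ndarray:
    """``n`` unit vectors on the spherical Fibonacci lattice, shape (n, 3).

    z-coordinates are uniformly spaced in (−1, 1); azimuths advance by the
    golden angle 2π/φ².  Deterministic and duplicate-free.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k = np.arange(n)
    z = (2 * k + 1) / n - 1.0
    phi = 2.0 * np.pi * k / GOLDEN_RATIO**2
    r = np.sqrt(1.0 - z**2)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    # construction places points exactly on the unit sphere
    return pts


@dataclass
class ForceBasis:
    """Per-site force set: orientations × a base magnitude."""

    n_orientations: int = DEFAULT_N_ORIENTATIONS
    magnitude: float = DEFAULT_MAGNITUDE
    orientations: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.orientations = fibonacci_orientations(self.n_orientations)


def orientations_to_tsv(orientations: np.ndarray) -> str:
    """Orientation set as TSV (index, x, y, z) for visual inspection."""
    lines = ["index\tx\ty\tz"]
    for idx, (x, y, z) in enumerate(orientations):
        lines.append(f"{idx}\t{x:.12g}\t{y:.12g}\t{z:.12g}")
    return "\n".join(lines) + "\n"


def assemble_force_vector(
    n_nodes: int, site: int, orientation: np.ndarray, magnitude: float
) -> np.ndarray:
    """3N force vector: zero everywhere except the site's 3 components."""
    if not 0 <= site < n_nodes:
        raise ValueError(f"site {site} out of range [0, {n_nodes})")
    f = np.zeros(3 * n_nodes)
    f[3 * site:3 * site + 3] = magnitude * np.asarray(orientation, dtype=float)
    return f


def fr_rescale(d_i_unit: float, d_j_unit: float, tol: float = 1e-12) -> float:
    """Fixed-RMSD magnitude multiplier for the second-site force.

    Scaling F_j by ``d_i_unit / d_j_unit`` makes the two single-force
    deformations equal, d(u, p_i) = d(u, p_j), exactly within linear
    response.
    """
    if d_j_unit <= tol:
        raise ValueError(
            "second-site unit force produced no deformation: force lies in "
            "the rigid null space, network is defective"
        )
    return d_i_unit / d_j_unit
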