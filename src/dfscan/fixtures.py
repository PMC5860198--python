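"""Deterministic synthetic Cα geometries and reference labels.

These structures exercise the whole pipeline without downloads: a regular
tetrahedron (smallest non-planar network), an ideal α-helix trace, a
jittered cubic lattice and a self-avoiding random globule.  Consecutive
node spacing mimics the real Cα-Cα virtual bond (~3.8 Å) so that the
default 15 Å cutoff yields realistic contact degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import ReferenceSiteSet
from .structures import CoarseGrainedStructure, ResidueKey

KINDS = ("tetrahedron", "helix", "lattice3d", "random_globule")

#: ideal α-helix Cα-trace parameters
HELIX_RISE = 1.5  # Å per residue
HELIX_TURN = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å

TETRAHEDRON_EDGE = 3.8  # Å

LATTICE_SPACING = 3.8  # Å
GLOBULE_MIN_DIST = 3.5  # Å


@dataclass
class FixtureSpec:
    kind: str
    n_residues: int = 4
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def _tetrahedron() -> np.ndarray:
    verts = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    return verts * (TETRAHEDRON_EDGE / (2.0 * np.sqrt(2.0)))


def _helix(n: int, rise: float, turn_deg: float, radius: float) -> np.ndarray:
    k = np.arange(n)
    theta = np.deg2rad(turn_deg) * k
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * k]
    )


def _lattice3d(n: int, spacing: float, jitter: float, rng: np.random.Generator) -> np.ndarray:
    m = int(np.ceil(n ** (1.0 / 3.0)))
    grid = np.array(
        [(x, y, z) for x in range(m) for y in range(m) for z in range(m)],
        dtype=float,
    )[:n]
    return grid * spacing + rng.uniform(-jitter, jitter, size=(n, 3))


def _random_globule(n: int, min_dist: float, rng: np.random.Generator) -> np.ndarray:
    # seeded rejection sampling inside a sphere sized for ~loose packing
    radius = min_dist * max(2.0, 0.8 * n ** (1.0 / 3.0) + 1.0)
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        cand = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(cand) > radius:
            continue
        if all(np.linalg.norm(cand - p) >= min_dist for p in pts):
            pts.append(cand)
        attempts += 1
        if attempts > 200_000:
            raise RuntimeError("globule sampling failed; too dense")
    return np.asarray(pts)


def make_structure(spec: FixtureSpec) -> CoarseGrainedStructure:
    """Generate the Cα structure for a fixture spec (bit-reproducible)."""
    n = spec.n_residues
    if spec.kind == "tetrahedron":
        coords = _tetrahedron()
        n = 4
    elif n < 4:
        raise ValueError("non-planar fixtures need n_residues >= 4")
    if spec.kind == "helix":
        coords = _helix(
            n,
            spec.params.get("rise", HELIX_RISE),
            spec.params.get("turn", HELIX_TURN),
            spec.params.get("radius", HELIX_RADIUS),
        )
    elif spec.kind == "lattice3d":
        rng = np.random.default_rng(spec.seed)
        coords = _lattice3d(
            n, spec.params.get("spacing", LATTICE_SPACING),
            spec.params.get("jitter", 0.5), rng,
        )
    elif spec.kind == "random_globule":
        rng = np.random.default_rng(spec.seed)
        coords = _random_globule(n, spec.params.get("min_dist", GLOBULE_MIN_DIST), rng)
    from scipy.spatial.distance import pdist

    if len(coords) > 1 and pdist(coords).min() < 1e-6:
        raise ValueError("fixture parameters produced coincident nodes")
    keys = [ResidueKey("A", i + 1, "") for i in range(len(coords))]
    aa = ["ALA"] * len(coords)
    heavy = [c.reshape(1, 3) for c in coords]
    return CoarseGrainedStructure(keys, aa, coords, heavy_coords=heavy)


def make_reference_labels(
    s: CoarseGrainedStructure, n_PS: int, n_RS: int, seed: int
) -> ReferenceSiteSet:
    """Seeded disjoint random PS/RS label sets for evaluation tests."""
    n = len(s)
    if n_PS + n_RS > n:
        raise ValueError("n_PS + n_RS exceeds the number of residues")
    rng = np.random.default_rng(seed)
    picks = rng.choice(n, size=n_PS + n_RS, replace=False)
    return ReferenceSiteSet(
        pathogenic=set(int(i) for i in picks[:n_PS]),
        rescue=set(int(i) for i in picks[n_PS:]),
        source="synthetic",
    )
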