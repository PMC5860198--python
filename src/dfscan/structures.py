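"""Cα coarse-grained structure handling.

A protein is reduced to one node per residue, located at the Cα atom.
Heavy-atom coordinates of each retained residue are kept alongside, because
residue-residue proximity (e.g. the 4 Å contact rule used in the rescue-site
proximity analysis) is only meaningful between heavy atoms, not between Cα
positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

#: 3-letter codes accepted as standard amino acids when gemmi tabulation is
#: inconclusive (synthetic fixtures use these directly).
_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class ResidueKey(NamedTuple):
    """Unique residue identifier: author numbering is kept verbatim."""

    chain: str
    resnum: int
    icode: str  # "" when absent


@dataclass
class CoarseGrainedStructure:
    """Ordered Cα nodes plus retained heavy-atom coordinates.

    Attributes
    ----------
    keys : list of ResidueKey
        (chain, residue number, insertion code) in file order.
    aa : list of str
        3-letter residue names.
    coords : (N, 3) ndarray
        Cα coordinates in Å.
    heavy_coords : list of (k, 3) ndarray or None
        Heavy-atom coordinates per residue; ``None`` means only the Cα is
        known and proximity falls back to Cα distances.
    n_skipped : int
        Residues in the selection that lacked a Cα record.
    """

    keys: list[ResidueKey]
    aa: list[str]
    coords: np.ndarray
    heavy_coords: list = field(default_factory=list)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if len(self.keys) != len(self.coords) or len(self.aa) != len(self.coords):
            raise ValueError("keys, aa and coords must have equal length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("duplicate (chain, resnum, icode) residue keys")
        if not self.heavy_coords:
            self.heavy_coords = [None] * len(self.keys)

    def __len__(self) -> int:
        return len(self.keys)

    @property
    def n_residues(self) -> int:
        return len(self.keys)

    def index_of(self, key: ResidueKey) -> int:
        return self.keys.index(key)

    def labels(self) -> list[str]:
        """Human-readable per-residue labels, e.g. ``A:42`` or ``A:42A``."""
        return [f"{k.chain}:{k.resnum}{k.icode}" for k in self.keys]

    # ------------------------------------------------------------------ I/O

    def to_tsv(self) -> str:
        rows = [
            (k.chain, k.resnum, k.icode, a, *map(float, c))
            for k, a, c in zip(self.keys, self.aa, self.coords)
        ]
        df = pd.DataFrame(rows, columns=["chain", "resnum", "icode", "aa", "x", "y", "z"])
        return df.to_csv(sep="\t", index=False)

    def to_pdb(self) -> str:
        """Minimal PDB text with one CA ATOM record per node."""
        lines = []
        for i, (k, aa, c) in enumerate(zip(self.keys, self.aa, self.coords), start=1):
            icode = k.icode if k.icode else " "
            lines.append(
                f"ATOM  {i:5d}  CA  {aa:<3s} {k.chain[:1]}{k.resnum:4d}{icode}"
                f"   {c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}  1.00  0.00           C"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"


def structure_from_tsv(text: str) -> CoarseGrainedStructure:
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t", keep_default_na=False,
                     dtype={"chain": str, "icode": str, "aa": str})
    keys = [ResidueKey(r.chain, int(r.resnum), str(r.icode)) for r in df.itertuples()]
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    return CoarseGrainedStructure(keys, list(df["aa"]), coords)


def _is_amino_acid(residue: gemmi.Residue) -> bool:
    if residue.het_flag != "A":
        return False
    info = gemmi.find_tabulated_residue(residue.name)
    if info is not None:
        return info.is_amino_acid()
    return residue.name in _AA3


def _pick_altloc(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties resolved by first occurrence in file."""
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ:
            best = a
    return best


def read_calpha_structure(
    pdb_text: str, chain: str | None = None, model: int = 1
) -> CoarseGrainedStructure:
    """Extract the Cα coarse-grained model from PDB-format text.

    Parameters
    ----------
    chain : str or None
        Chain identifier to select; ``None`` (or ``"ALL"``) keeps every chain.
    model : int
        MODEL number for multi-model (NMR-style) files; single-model files
        ignore the distinction.

    Heteroatoms, waters and nucleic acids are excluded.  Residues without a
    Cα record are skipped and counted in ``n_skipped``.  Alternate locations
    resolve to the highest-occupancy conformer (ties: first in file).
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no models in PDB input")
    sel_model = None
    for m in st:
        if m.num == model:
            sel_model = m
            break
    if sel_model is None:
        if model == 1 and len(st) == 1:
            sel_model = st[0]
        else:
            raise ValueError(
                f"model {model} not found (available: {[m.num for m in st]})"
            )
    if chain is not None and str(chain).upper() == "ALL":
        chain = None

    keys: list[ResidueKey] = []
    aas: list[str] = []
    coords: list[np.ndarray] = []
    heavy: list[np.ndarray] = []
    n_skipped = 0
    seen_chain = False
    for ch in sel_model:
        if chain is not None and ch.name != chain:
            continue
        seen_chain = True
        for res in ch:
            if not _is_amino_acid(res):
                continue
            ca_candidates = [a for a in res if a.name == "CA" and a.element.name == "C"]
            if not ca_candidates:
                n_skipped += 1
                logger.warning(
                    "residue %s %d%s has no CA atom; skipped",
                    res.name, res.seqid.num, res.seqid.icode.strip(),
                )
                continue
            ca = _pick_altloc(ca_candidates)
            # heavy atoms: one position per atom name, altloc-resolved
            by_name: dict[str, list[gemmi.Atom]] = {}
            for a in res:
                if a.element.name in ("H", "D"):
                    continue
                by_name.setdefault(a.name, []).append(a)
            hcoords = np.array(
                [[*(_pick_altloc(v).pos.tolist())] for v in by_name.values()],
                dtype=float,
            )
            keys.append(
                ResidueKey(ch.name, res.seqid.num, res.seqid.icode.strip())
            )
            aas.append(res.name)
            coords.append(np.array(ca.pos.tolist(), dtype=float))
            heavy.append(hcoords)
    if chain is not None and not seen_chain:
        raise ValueError(f"chain {chain!r} not present in model {model}")
    if not keys:
        raise ValueError(
            f"no Cα atoms in selection (chain={chain!r}, model={model})"
        )
    return CoarseGrainedStructure(
        keys, aas, np.asarray(coords), heavy_coords=heavy, n_skipped=n_skipped
    )


def min_heavy_atom_distance(
    s: CoarseGrainedStructure, i: int, j: int
) -> tuple[float, bool]:
    """Minimum heavy-atom distance between residues ``i`` and ``j`` in Å.

    Returns ``(distance, used_heavy)`` where ``used_heavy`` is False when one
    of the residues has no stored heavy atoms and the Cα-Cα distance was used
    instead.
    """
    if i == j:
        raise ValueError("self-distance is undefined")
    a = s.heavy_coords[i]
    b = s.heavy_coords[j]
    if a is None or b is None or len(a) == 0 or len(b) == 0:
        d = float(np.linalg.norm(s.coords[i] - s.coords[j]))
        return d, False
    return float(cdist(a, b).min()), True
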