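"""Evaluation of rescue-site predictions against reference site sets.

Covers confusion-matrix statistics and enrichment, the D-minimising
threshold search, the 4 Å proximity analysis of missed rescue sites,
pair-specific rescue sets, rescue-pocket classification, normal-mode
decomposition of compensatory motions (RMSIP), and extraction of divergent
positions from pairwise human/homologue alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .enm import ModeSpectrum
from .structures import CoarseGrainedStructure, ResidueKey, min_heavy_atom_distance

STANDARD_AA1 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ReferenceSiteSet:
    """Pathogenic (PS) and rescue (RS) residue labels for one structure.

    Sites are stored as node indices into the associated structure; the TSV
    dialect keys them by author residue numbering (chain, resnum, icode).
    A residue may carry both labels.
    """

    pathogenic: set = field(default_factory=set)
    rescue: set = field(default_factory=set)
    source: str = "experimental"

    def to_tsv(self, structure: CoarseGrainedStructure) -> str:
        rows = []
        for idx in sorted(self.pathogenic | self.rescue):
            k = structure.keys[idx]
            label = (
                "PS+RS"
                if idx in self.pathogenic and idx in self.rescue
                else ("PS" if idx in self.pathogenic else "RS")
            )
            rows.append((k.chain, k.resnum, k.icode, label, self.source))
        df = pd.DataFrame(rows, columns=["chain", "resnum", "icode", "label", "source"])
        return df.to_csv(sep="\t", index=False)


def read_reference_sites(
    text: str, structure: CoarseGrainedStructure
) -> tuple[ReferenceSiteSet, list[ResidueKey]]:
    """Parse a reference-site TSV; returns the set and unresolved keys."""
    df = pd.read_csv(StringIO(text), sep="\t", keep_default_na=False,
                     dtype={"chain": str, "icode": str, "label": str})
    key_to_idx = {k: i for i, k in enumerate(structure.keys)}
    ref = ReferenceSiteSet(source=str(df["source"].iloc[0]) if len(df) else "experimental")
    unresolved: list[ResidueKey] = []
    for r in df.itertuples():
        key = ResidueKey(str(r.chain), int(r.resnum), str(r.icode))
        idx = key_to_idx.get(key)
        if idx is None:
            unresolved.append(key)
            continue
        labels = str(r.label).split("+")
        if "PS" in labels:
            ref.pathogenic.add(idx)
        if "RS" in labels:
            ref.rescue.add(idx)
    return ref, unresolved


@dataclass
class ConfusionSummary:
    TP: int
    FP: int
    FN: int
    TN: int
    nres: int
    sensitivity: float
    specificity: float
    accuracy: float
    enrichment: float | None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def confusion_metrics(
    predicted: Iterable[int], positives: Iterable[int], nres: int
) -> ConfusionSummary:
    """Exact-match confusion statistics and rescue-site enrichment.

    Enrichment = P_DFS / P_random with P_DFS = TP/(TP+FP) the precision of
    the predictions and P_random = (TP+FN)/nres the base rate of reference
    rescue sites; ``None`` when no sites were predicted.
    """
    pred = set(predicted)
    pos = set(positives)
    if not pos:
        raise ValueError("empty reference set")
    tp = len(pred & pos)
    fp = len(pred - pos)
    fn = len(pos - pred)
    tn = nres - tp - fp - fn
    if tn < 0:
        raise ValueError("prediction/reference sets exceed nres")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp) if tn + fp else 1.0
    acc = (tp + tn) / nres
    enr = None
    if tp + fp:
        enr = (tp / (tp + fp)) / ((tp + fn) / nres)
    return ConfusionSummary(tp, fp, fn, tn, nres, sens, spec, acc, enr)


def discrimination_distance(sensitivity: float, specificity: float) -> float:
    """D = (1 − sens)² + (1 − spec)²: distance from the perfect classifier."""
    return (1.0 - sensitivity) ** 2 + (1.0 - specificity) ** 2


def optimal_threshold(
    scores: Sequence[float], positives: Iterable[int]
) -> tuple[float, float]:
    """Strict score threshold minimising D over observed score values.

    Every distinct score is tried as a candidate cutoff (predict score >
    threshold).  Ties in D resolve to the threshold admitting fewer
    predicted positives.  Returns (threshold, D_min).
    """
    scores = np.asarray(scores, dtype=float)
    pos = set(positives)
    n = scores.size
    if not pos or len(pos) == n:
        raise ValueError("need at least one positive and one negative")
    best: tuple[float, float, int] | None = None  # (D, threshold, n_pred)
    for t in np.unique(scores):
        pred = np.flatnonzero(scores > t)
        cm = confusion_metrics(pred, pos, n)
        d = discrimination_distance(cm.sensitivity, cm.specificity)
        cand = (d, float(t), pred.size)
        if best is None or d < best[0] or (d == best[0] and pred.size < best[2]):
            best = cand
    return best[1], best[0]


def proximity_rescue(
    predicted: Iterable[int],
    reference: ReferenceSiteSet,
    s: CoarseGrainedStructure,
    cutoff: float = 4.0,
) -> dict[int, str]:
    """Categorise each reference rescue site against the predictions.

    ``predicted``: exact match; ``contact``: within ``cutoff`` Å (minimum
    heavy-atom distance) of any predicted site; ``missed`` otherwise.
    """
    pred = set(predicted)
    out: dict[int, str] = {}
    for r in sorted(reference.rescue):
        if r in pred:
            out[r] = "predicted"
            continue
        in_contact = False
        for p in pred:
            d, _ = min_heavy_atom_distance(s, r, p)
            if d < cutoff:
                in_contact = True
                break
        out[r] = "contact" if in_contact else "missed"
    return out


def pair_specific_rescue(
    S_FF: np.ndarray | None,
    S_FR: np.ndarray | None,
    i: int,
    predicted: Iterable[int] | None = None,
) -> set:
    """Candidate rescue sites for pathogenic site ``i``.

    j qualifies when S_ij > 0 under either scheme; when ``predicted`` is
    given (the default analysis), the set is intersected with the globally
    classified rescue sites, so that only residues already called rescue
    sites are associated with specific pathogenic positions.
    """
    mats = [m for m in (S_FF, S_FR) if m is not None]
    if not mats:
        raise ValueError("need at least one rescuability matrix")
    n = mats[0].shape[0]
    hits = {
        j
        for j in range(n)
        if j != i and any(m[i, j] > 0 for m in mats)
    }
    if predicted is not None:
        hits &= set(predicted)
    return hits


@dataclass
class PocketDefinition:
    pocket_id: str
    members: set

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pocket {self.pocket_id!r} has no members")


def read_pockets(text: str, structure: CoarseGrainedStructure) -> list[PocketDefinition]:
    """Pockets TSV (pocket_id, chain, resnum[, icode]; one row per member)."""
    df = pd.read_csv(StringIO(text), sep="\t", keep_default_na=False,
                     dtype={"pocket_id": str, "chain": str})
    if "icode" not in df.columns:
        df["icode"] = ""
    key_to_idx = {k: i for i, k in enumerate(structure.keys)}
    groups: dict[str, set] = {}
    for r in df.itertuples():
        key = ResidueKey(str(r.chain), int(r.resnum), str(r.icode))
        if key not in key_to_idx:
            raise ValueError(f"pocket residue {key} not in structure")
        groups.setdefault(str(r.pocket_id), set()).add(key_to_idx[key])
    return [PocketDefinition(pid, m) for pid, m in groups.items()]


def pocket_classification(
    pockets: Sequence[PocketDefinition],
    rescue_sites: Iterable[int],
    threshold: float = 0.20,
) -> pd.DataFrame:
    """Classify pockets as rescue pockets and rank by rescue-site content.

    A pocket is a rescue pocket when at least ``threshold`` (inclusive) of
    its member residues are rescue sites.  Ranking is by pct_RS descending,
    ties stable by pocket_id.
    """
    rs = set(rescue_sites)
    rows = []
    for p in pockets:
        pct = len(p.members & rs) / len(p.members)
        rows.append(
            {
                "pocket_id": p.pocket_id,
                "n_members": len(p.members),
                "pct_RS": pct,
                "is_rescue_pocket": pct >= threshold,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["pct_RS", "pocket_id"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
    return df


def rmsip(motion: np.ndarray, modes: ModeSpectrum) -> tuple[float, np.ndarray]:
    """Root mean square inner product of a motion with a set of modes.

    The motion is unit-normalised; RMSIP = sqrt(Σ_k (v·m_k)²) over the k
    orthonormal modes.  Also returns the per-mode squared inner products.
    """
    v = np.asarray(motion, dtype=float)
    norm = np.linalg.norm(v)
    if norm <= 0:
        raise ValueError("zero motion vector")
    v = v / norm
    overlaps = modes.eigenvectors.T @ v
    per_mode = overlaps**2
    return float(np.sqrt(per_mode.sum())), per_mode


def divergent_positions(fasta_text: str) -> list[int]:
    """Divergent positions between two aligned sequences (human first).

    Reports 1-based ungapped positions in the first sequence where both
    columns hold standard amino acids that differ (case-insensitive).
    Columns containing a gap in either sequence are skipped.
    """
    records = list(SeqIO.parse(StringIO(fasta_text), "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 aligned sequences, got {len(records)}")
    a, b = (str(r.seq).upper() for r in records)
    if len(a) != len(b):
        raise ValueError("aligned sequences differ in length")
    out: list[int] = []
    pos = 0  # ungapped position in the human (first) sequence
    for ca, cb in zip(a, b):
        if ca != "-":
            pos += 1
        if ca in STANDARD_AA1 and cb in STANDARD_AA1 and ca != cb:
            out.append(pos)
    return out
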