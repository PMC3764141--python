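"""Sequence-guided rigid superposition of two RNA structures.

Residues are matched by global affine-gap alignment of the extracted
sequences; matched residues contribute a small backbone/glycosidic atom
set (P, C4', C1', N1/N9) to a closed-form least-squares fit (Kabsch, with
the reflection excluded).  Optional iterative pruning re-fits after
discarding pairs deviating beyond a cutoff, which emulates the pruned-core
protocol of interactive matchmaking tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import PairwiseAligner

from .config import DEFAULT_CONFIG, DetectionConfig
from .structure_model import GLYCOSIDIC_N, ResidueId, StructureModel, extract_sequence

__all__ = [
    "CorrespondenceSet",
    "SuperpositionResult",
    "match_residues",
    "superpose",
    "kabsch",
]

DEFAULT_ATOMS = ("P", "C4'", "C1'", "glyN")


@dataclass
class CorrespondenceSet:
    pairs: List[Tuple[ResidueId, ResidueId]]
    atom_selection: Tuple[str, ...] = DEFAULT_ATOMS

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_matched: int
    pruned: List[Tuple[ResidueId, ResidueId]] = field(default_factory=list)


def _selected_atoms(model: StructureModel, rid: ResidueId, selection) -> Optional[List[np.ndarray]]:
    nuc = model.get(rid)
    out = []
    for name in selection:
        if name == "glyN":
            name = GLYCOSIDIC_N.get(nuc.base, "N1")
        pos = nuc.atom_pos(name)
        if pos is None:
            if name == "P":       # P is absent at 5' termini; tolerated
                continue
            return None
        out.append(pos)
    return out if out else None


def match_residues(
    a: StructureModel,
    b: StructureModel,
    chain_a: str = "",
    chain_b: str = "",
    config: DetectionConfig = DEFAULT_CONFIG,
    atom_selection: Tuple[str, ...] = DEFAULT_ATOMS,
) -> CorrespondenceSet:
    """Pair residues of two models by global sequence alignment."""
    seq_a, map_a = extract_sequence(a, chain_a)
    seq_b, map_b = extract_sequence(b, chain_b)
    if not seq_a or not seq_b:
        raise ValueError("cannot match empty chains")
    al = PairwiseAligner()
    al.mode = "global"
    al.match_score = config.align_match
    al.mismatch_score = config.align_mismatch
    al.open_gap_score = config.align_open
    al.extend_gap_score = config.align_extend
    best = al.align(seq_a, seq_b)[0]
    pairs: List[Tuple[ResidueId, ResidueId]] = []
    for (s1, e1), (s2, e2) in zip(*best.aligned):
        for d in range(e1 - s1):
            ra, rb = map_a[s1 + d], map_b[s2 + d]
            pa = _selected_atoms(a, ra, atom_selection)
            pb = _selected_atoms(b, rb, atom_selection)
            if pa is None or pb is None or len(pa) != len(pb):
                continue
            pairs.append((ra, rb))
    if not pairs:
        raise ValueError("no alignable residues with complete atom selections")
    return CorrespondenceSet(pairs=pairs, atom_selection=atom_selection)


def kabsch(x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rotation/translation mapping x onto y (proper rotation
    enforced); returns (R, t, rmsd) with y ~ x @ R.T + t."""
    cx, cy = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - cx, y - cy
    H = x0.T @ y0
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cy - R @ cx
    diff = x0 @ R.T - y0
    rmsd = float(np.sqrt((diff ** 2).sum() / len(x)))
    return R, t, rmsd


def _residue_coords(
    c: CorrespondenceSet, a: StructureModel, b: StructureModel
) -> List[Tuple[np.ndarray, np.ndarray]]:
    coords = []
    for ra, rb in c.pairs:
        pa = _selected_atoms(a, ra, c.atom_selection)
        pb = _selected_atoms(b, rb, c.atom_selection)
        n = min(len(pa), len(pb))  # a missing 5' P shortens one side
        coords.append((np.array(pa[-n:]), np.array(pb[-n:])))
    return coords


def superpose(
    c: CorrespondenceSet,
    a: StructureModel,
    b: StructureModel,
    prune_cutoff: Optional[float] = DEFAULT_CONFIG.superpose_prune_cutoff,
) -> SuperpositionResult:
    """Closed-form rigid fit of b's matched atoms onto a's, optionally
    iterating discard-and-refit until the retained set is stable."""
    if len(c) < 3:
        raise ValueError("need at least 3 correspondences")
    coords = _residue_coords(c, a, b)
    active = list(range(len(coords)))
    pruned_idx: List[int] = []
    while True:
        x = np.vstack([coords[i][0] for i in active])
        y = np.vstack([coords[i][1] for i in active])
        R, t, rmsd = kabsch(x, y)
        if prune_cutoff is None:
            break
        deviations = []
        for i in active:
            xa, yb = coords[i]
            d = np.linalg.norm(xa @ R.T + t - yb, axis=1).mean()
            deviations.append((i, d))
        dev_of = dict(deviations)
        bad = sorted((i for i, d in deviations if d > prune_cutoff),
                     key=lambda i: -dev_of[i])
        if not bad or len(active) <= 3:
            break
        # worst-first, one pair per iteration: when an outlier skews the
        # whole fit, discarding it alone lets the refit pull the remaining
        # pairs back under the cutoff
        worst = bad[0]
        pruned_idx.append(worst)
        active = [i for i in active if i != worst]
    return SuperpositionResult(
        rotation=R,
        translation=t,
        rmsd=rmsd,
        n_matched=len(active),
        pruned=[c.pairs[i] for i in sorted(pruned_idx)],
    )
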