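"""Hydrogen-bond detection and Leontis-Westhof-style base-pair classification.

Pairs are classified by which edge of each base carries the hydrogen bonds
(Watson-Crick / Hoogsteen / Sugar) and by the glycosidic orientation
(cis / trans).  A contact is only accepted as a base pair when it has at
least two base-involving hydrogen bonds and the two base planes are within
the pairing planarity cutoff -- the survey's "at least two hydrogen bond
interactions per base pair" rule, with "planar" enforced strictly only at
the triple stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .config import DEFAULT_CONFIG, DetectionConfig
from .structure_model import (
    BaseFrame,
    Nucleotide,
    ResidueId,
    StructureModel,
    base_frames,
    plane_angle,
)

__all__ = [
    "HydrogenBond",
    "BasePair",
    "detect_hbonds",
    "classify_pair",
    "detect_base_pairs",
    "WC",
    "HOOGSTEEN",
    "SUGAR",
]

WC = "WatsonCrick"
HOOGSTEEN = "Hoogsteen"
SUGAR = "Sugar"

# donor atom -> antecedent heavy atoms (the N-H direction is inferred from
# the antecedents because detectors work on heavy atoms only)
BASE_DONORS: Dict[str, Dict[str, Tuple[str, ...]]] = {
    "A": {"N6": ("C6",)},
    "G": {"N1": ("C2", "C6"), "N2": ("C2",)},
    "C": {"N4": ("C4",)},
    "U": {"N3": ("C2", "C4")},
}
SUGAR_DONORS: Dict[str, Tuple[str, ...]] = {"O2'": ("C2'",)}

BASE_ACCEPTORS: Dict[str, Tuple[str, ...]] = {
    "A": ("N1", "N3", "N7"),
    "G": ("O6", "N3", "N7"),
    "C": ("O2", "N3"),
    "U": ("O2", "O4"),
}
SUGAR_ACCEPTORS: Tuple[str, ...] = ("O2'", "O4'")
PHOSPHATE_ACCEPTORS: Tuple[str, ...] = ("OP1", "OP2", "O5'", "O3'")

# atom -> edge membership (atoms shared by two edges carry half a vote each)
EDGE_ATOMS: Dict[str, Dict[str, Tuple[str, ...]]] = {
    "A": {WC: ("N1", "C2", "N6"), HOOGSTEEN: ("N7", "C8", "N6"), SUGAR: ("N3", "C2", "O2'")},
    "G": {WC: ("N1", "N2", "O6"), HOOGSTEEN: ("N7", "C8", "O6"), SUGAR: ("N3", "N2", "O2'")},
    "C": {WC: ("N3", "N4", "O2"), HOOGSTEEN: ("C5", "C6", "N4"), SUGAR: ("O2", "O2'")},
    "U": {WC: ("N3", "O4", "O2"), HOOGSTEEN: ("C5", "C6", "O4"), SUGAR: ("O2", "O2'")},
}

BASE_ATOM_NAMES: Dict[str, FrozenSet[str]] = {
    "A": frozenset("N9 C8 N7 C5 C6 N6 N1 C2 N3 C4".split()),
    "G": frozenset("N9 C8 N7 C5 C6 O6 N1 C2 N2 N3 C4".split()),
    "C": frozenset("N1 C2 O2 N3 C4 N4 C5 C6".split()),
    "U": frozenset("N1 C2 O2 N3 C4 O4 C5 C6".split()),
}


def atom_moiety(base: str, name: str) -> str:
    if name in BASE_ATOM_NAMES.get(base, frozenset()):
        return "base"
    if name in ("P", "OP1", "OP2", "OP3", "O5'", "O3'"):
        return "phosphate"
    if name.endswith("'"):
        return "sugar"
    return "other"


@dataclass(frozen=True)
class HydrogenBond:
    donor: Tuple[ResidueId, str]
    acceptor: Tuple[ResidueId, str]
    distance: float
    donor_moiety: str
    acceptor_moiety: str
    planarity_angle: Optional[float] = None

    @property
    def residues(self) -> FrozenSet[ResidueId]:
        return frozenset((self.donor[0], self.acceptor[0]))

    def atom_of(self, rid: ResidueId) -> str:
        if self.donor[0] == rid:
            return self.donor[1]
        if self.acceptor[0] == rid:
            return self.acceptor[1]
        raise KeyError(rid)

    def moiety_of(self, rid: ResidueId) -> str:
        if self.donor[0] == rid:
            return self.donor_moiety
        if self.acceptor[0] == rid:
            return self.acceptor_moiety
        raise KeyError(rid)

    def involves_o2prime(self) -> bool:
        return self.donor[1] == "O2'" or self.acceptor[1] == "O2'"


@dataclass
class BasePair:
    a: ResidueId
    b: ResidueId
    base_a: str
    base_b: str
    edge_a: str
    edge_b: str
    orientation: str  # 'cis' | 'trans'
    hbonds: List[HydrogenBond] = field(default_factory=list)
    canonical: bool = False
    wobble: bool = False
    planarity: float = 0.0

    @property
    def key(self) -> FrozenSet[ResidueId]:
        return frozenset((self.a, self.b))

    def partner(self, rid: ResidueId) -> ResidueId:
        if rid == self.a:
            return self.b
        if rid == self.b:
            return self.a
        raise KeyError(rid)

    def edge_of(self, rid: ResidueId) -> str:
        if rid == self.a:
            return self.edge_a
        if rid == self.b:
            return self.edge_b
        raise KeyError(rid)

    def base_of(self, rid: ResidueId) -> str:
        if rid == self.a:
            return self.base_a
        if rid == self.b:
            return self.base_b
        raise KeyError(rid)


def _donor_sites(n: Nucleotide) -> List[Tuple[str, Tuple[str, ...], str]]:
    sites: List[Tuple[str, Tuple[str, ...], str]] = []
    for name, ante in BASE_DONORS.get(n.base, {}).items():
        sites.append((name, ante, "base"))
    for name, ante in SUGAR_DONORS.items():
        sites.append((name, ante, "sugar"))
    return sites


def _acceptor_sites(n: Nucleotide) -> List[Tuple[str, str]]:
    sites = [(name, "base") for name in BASE_ACCEPTORS.get(n.base, ())]
    sites += [(name, "sugar") for name in SUGAR_ACCEPTORS]
    sites += [(name, "phosphate") for name in PHOSPHATE_ACCEPTORS]
    return sites


def detect_hbonds(
    m: StructureModel,
    config: DetectionConfig = DEFAULT_CONFIG,
    frames: Optional[Dict[ResidueId, BaseFrame]] = None,
) -> List[HydrogenBond]:
    """All donor-acceptor heavy-atom contacts between distinct residues.

    Criteria: distance within [min, max] cutoffs and angle at the donor
    (antecedent -> donor -> acceptor) at least ``hbond_min_angle`` for every
    antecedent present.  Output is sorted by residue ids then atom names.
    """
    if frames is None:
        frames = base_frames(m)

    donors: List[Tuple[ResidueId, str, np.ndarray, List[np.ndarray], str]] = []
    acceptors: List[Tuple[ResidueId, str, np.ndarray, str]] = []
    for n in m.nucleotides:
        for name, antecedents, moiety in _donor_sites(n):
            pos = n.atom_pos(name)
            if pos is None:
                continue
            ante = [n.atom_pos(a) for a in antecedents]
            donors.append((n.rid, name, pos, [p for p in ante if p is not None], moiety))
        for name, moiety in _acceptor_sites(n):
            pos = n.atom_pos(name)
            if pos is not None:
                acceptors.append((n.rid, name, pos, moiety))

    if not donors or not acceptors:
        return []
    dtree = cKDTree(np.array([d[2] for d in donors]))
    atree = cKDTree(np.array([a[2] for a in acceptors]))
    candidates = dtree.query_ball_tree(atree, r=config.hbond_max_distance)

    found: Dict[Tuple[ResidueId, str, ResidueId, str], HydrogenBond] = {}
    for di, alist in enumerate(candidates):
        drid, dname, dpos, dante, dmoiety = donors[di]
        for ai in alist:
            arid, aname, apos, amoiety = acceptors[ai]
            if arid == drid:
                continue
            dist = float(np.linalg.norm(apos - dpos))
            if dist < config.hbond_min_distance or dist > config.hbond_max_distance:
                continue
            if not _donor_angle_ok(dpos, dante, apos, config.hbond_min_angle):
                continue
            # an O2'-O2' contact is found from both directions; keep one
            fwd = (drid, dname, arid, aname)
            rev = (arid, aname, drid, dname)
            if rev in found:
                continue
            angle = None
            fa, fb = frames.get(drid), frames.get(arid)
            if fa is not None and fb is not None:
                angle = plane_angle(fa.normal, fb.normal)
            found[fwd] = HydrogenBond(
                donor=(drid, dname),
                acceptor=(arid, aname),
                distance=dist,
                donor_moiety=dmoiety,
                acceptor_moiety=amoiety,
                planarity_angle=angle,
            )
    return sorted(
        found.values(),
        key=lambda h: (h.donor[0], h.acceptor[0], h.donor[1], h.acceptor[1]),
    )


def _donor_angle_ok(
    dpos: np.ndarray, antecedents: List[np.ndarray], apos: np.ndarray, min_angle: float
) -> bool:
    if not antecedents:
        return True
    v_acc = apos - dpos
    na = np.linalg.norm(v_acc)
    if na < 1e-9:
        return False
    for ante in antecedents:
        v_ante = ante - dpos
        nn = np.linalg.norm(v_ante)
        if nn < 1e-9:
            continue
        cosang = float(np.clip(np.dot(v_ante, v_acc) / (nn * na), -1.0, 1.0))
        if math.degrees(math.acos(cosang)) < min_angle:
            return False
    return True


def _pairing_bonds(
    a: ResidueId, b: ResidueId, hbonds: List[HydrogenBond], config: DetectionConfig
) -> List[HydrogenBond]:
    """Bonds that count toward the two-bond pairing rule (base-base by
    default; base-sugar included when configured)."""
    out = []
    for h in hbonds:
        ma, mb = h.moiety_of(a), h.moiety_of(b)
        if ma == "base" and mb == "base":
            out.append(h)
        elif config.count_sugar_bonds_in_pairing and "base" in (ma, mb) and "sugar" in (ma, mb):
            out.append(h)
    return out


_EDGE_PRIORITY = {WC: 0, HOOGSTEEN: 1, SUGAR: 2}


def _edge_vote(base: str, atom_names: List[str]) -> str:
    votes = {WC: 0.0, HOOGSTEEN: 0.0, SUGAR: 0.0}
    table = EDGE_ATOMS.get(base, {})
    for name in atom_names:
        membership = [e for e, atoms in table.items() if name in atoms]
        for e in membership:
            votes[e] += 1.0 / len(membership)
    return max(votes, key=lambda e: (votes[e], -_EDGE_PRIORITY[e]))


def classify_pair(
    na: Nucleotide,
    nb: Nucleotide,
    hbonds: List[HydrogenBond],
    frames: Dict[ResidueId, BaseFrame],
    config: DetectionConfig = DEFAULT_CONFIG,
) -> Optional[BasePair]:
    """Classify one residue contact as a base pair, or reject it.

    Requires >=2 qualifying hydrogen bonds, both base frames, and base-plane
    angle within the (loose) pairing planarity cutoff.  The edge of each
    base is a majority vote over the edge membership of its bonded atoms;
    orientation is read from the glycosidic-bond vectors relative to the
    pairing axis.
    """
    if na.rid > nb.rid:
        na, nb = nb, na
    bonds = _pairing_bonds(na.rid, nb.rid, hbonds, config)
    if len(bonds) < config.pair_min_hbonds:
        return None
    fa, fb = frames.get(na.rid), frames.get(nb.rid)
    if fa is None or fb is None:
        return None
    angle = plane_angle(fa.normal, fb.normal)
    if angle > config.pair_planarity_max:
        return None

    edge_a = _edge_vote(na.base, [h.atom_of(na.rid) for h in bonds])
    edge_b = _edge_vote(nb.base, [h.atom_of(nb.rid) for h in bonds])
    orientation = _orientation(na, nb, fa, fb)

    bases = frozenset((na.base, nb.base))
    is_wc_wc_cis = edge_a == WC and edge_b == WC and orientation == "cis"
    canonical = is_wc_wc_cis and bases in (frozenset("GC"), frozenset("AU"))
    wobble = is_wc_wc_cis and bases == frozenset("GU")
    return BasePair(
        a=na.rid,
        b=nb.rid,
        base_a=na.base,
        base_b=nb.base,
        edge_a=edge_a,
        edge_b=edge_b,
        orientation=orientation,
        hbonds=sorted(hbonds, key=lambda h: (h.donor, h.acceptor)),
        canonical=canonical,
        wobble=wobble,
        planarity=angle,
    )


def _orientation(
    na: Nucleotide, nb: Nucleotide, fa: BaseFrame, fb: BaseFrame
) -> str:
    from .structure_model import GLYCOSIDIC_N

    axis = fb.origin - fa.origin
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        return "cis"
    axis = axis / norm
    sides = []
    for n, f in ((na, fa), (nb, fb)):
        c1 = n.atom_pos("C1'")
        gn = n.atom_pos(GLYCOSIDIC_N.get(n.base, "N1"))
        if c1 is None or gn is None:
            return "cis"
        v = c1 - gn
        w = v - np.dot(v, axis) * axis
        sides.append(w)
    return "cis" if float(np.dot(sides[0], sides[1])) >= 0 else "trans"


def detect_base_pairs(
    m: StructureModel,
    config: DetectionConfig = DEFAULT_CONFIG,
    hbonds: Optional[List[HydrogenBond]] = None,
    frames: Optional[Dict[ResidueId, BaseFrame]] = None,
) -> List[BasePair]:
    """All classified base pairs of a model, in deterministic order.

    A residue may participate in several pairs (base triples rely on this).
    """
    if frames is None:
        frames = base_frames(m)
    if hbonds is None:
        hbonds = detect_hbonds(m, config, frames)
    by_pair: Dict[FrozenSet[ResidueId], List[HydrogenBond]] = {}
    for h in hbonds:
        res = h.residues
        if len(res) == 2:
            by_pair.setdefault(res, []).append(h)
    pairs: List[BasePair] = []
    for res_pair in sorted(by_pair, key=lambda fs: tuple(sorted(fs))):
        ra, rb = sorted(res_pair)
        bp = classify_pair(m.get(ra), m.get(rb), by_pair[res_pair], frames, config)
        if bp is not None:
            pairs.append(bp)
    return pairs


def pairs_tsv(pairs: List[BasePair], structure_id: str) -> str:
    """Render pairs as a TSV block (one pair per row)."""
    header = "structure\tres_a\tres_b\tedge_a\tedge_b\torientation\tcanonical\twobble\tn_hbonds"
    rows = [header]
    for p in pairs:
        rows.append(
            "\t".join(
                [
                    structure_id,
                    _rid_str(p.a, p.base_a),
                    _rid_str(p.b, p.base_b),
                    p.edge_a,
                    p.edge_b,
                    p.orientation,
                    str(p.canonical),
                    str(p.wobble),
                    str(len(p.hbonds)),
                ]
            )
        )
    return "\n".join(rows) + "\n"


def _rid_str(rid: ResidueId, base: str) -> str:
    chain, num, icode = rid
    return f"{chain}:{base}{num}{icode}"
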