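"""Detectors for the seven tertiary motif classes of the survey.

Base triples are residue triples in which one base pairs with both others
(or all three pairwise), every pairing carrying at least two hydrogen
bonds, and all base planes mutually within the triple planarity cutoff --
the "planar interactions consisting of at least two hydrogen bond
interactions per base pair" rule.  A/G-minor motifs, ribose zippers,
pseudoknots, kissing loops, kink-turns and loop-receptor interactions are
found by direct geometric pattern matching over the hydrogen-bond list,
the pair list and the secondary-structure elements.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .config import DEFAULT_CONFIG, DetectionConfig
from .pairing import WC, BasePair, HydrogenBond
from .secondary_structure import SecondaryStructure
from .structure_model import BaseFrame, ResidueId, StructureModel, plane_angle

__all__ = [
    "BaseTriple",
    "BaseQuadruple",
    "AMinor",
    "RiboseZipper",
    "PseudoknotRecord",
    "KissingLoop",
    "KinkTurn",
    "LoopReceptor",
    "detect_triples",
    "detect_quadruples",
    "detect_a_minor",
    "detect_ribose_zipper",
    "detect_pseudoknots",
    "detect_kissing_loops",
    "detect_kink_turn",
    "detect_loop_receptor",
    "crossing",
]

_DISPLAY_ORDER = "AGCU"  # purines first, the order triples are named in


def display_composition(bases: Sequence[str]) -> str:
    return "".join(sorted(bases, key=_DISPLAY_ORDER.index))


@dataclass
class BaseTriple:
    residues: Tuple[ResidueId, ResidueId, ResidueId]
    bases: Tuple[str, str, str]
    pairings: List[BasePair]
    planarity: float          # max pairwise base-normal angle, degrees
    contains_wc: bool
    context: str = ""

    @property
    def key(self) -> FrozenSet[ResidueId]:
        return frozenset(self.residues)

    @property
    def composition(self) -> str:
        """Sorted composition label, purines first (e.g. "AGC")."""
        return display_composition(self.bases)


@dataclass
class BaseQuadruple:
    residues: Tuple[ResidueId, ...]
    bases: Tuple[str, ...]
    triples: List[BaseTriple]
    context: str = ""

    @property
    def key(self) -> FrozenSet[ResidueId]:
        return frozenset(self.residues)


@dataclass
class AMinor:
    donor: ResidueId
    donor_base: str                  # 'A' or 'G'
    receptor: BasePair
    type: str                        # '0' | 'I' | 'II'
    hbonds: List[HydrogenBond]
    variant: str = "A-minor"         # 'A-minor' | 'G-minor'
    receptor_label: str = ""         # 5'-residue of the receptor pair first
    receptor_label_flipped: str = ""
    context: str = ""

    @property
    def key(self) -> FrozenSet[ResidueId]:
        return frozenset((self.donor, self.receptor.a, self.receptor.b))


@dataclass
class RiboseZipper:
    strand1: Tuple[ResidueId, ResidueId]
    strand2: Tuple[ResidueId, ResidueId]
    hbonds: List[HydrogenBond]
    zclass: str                      # 'canonical' | 'pseudo-cis' | 'other-variant'
    context: str = ""

    @property
    def key(self) -> FrozenSet[ResidueId]:
        return frozenset(self.strand1 + self.strand2)


@dataclass
class PseudoknotRecord:
    group1: List[BasePair]           # crossing pairs outside the skeleton
    group2: List[BasePair]           # the skeleton pairs they cross
    htype: bool
    context: str = ""

    @property
    def key(self) -> FrozenSet[ResidueId]:
        return frozenset(r for p in self.group1 for r in (p.a, p.b))


@dataclass
class KissingLoop:
    loop_a: str
    loop_b: str
    pairs: List[BasePair]
    context: str = ""

    @property
    def key(self) -> FrozenSet[ResidueId]:
        return frozenset(r for p in self.pairs for r in (p.a, p.b))


@dataclass
class KinkTurn:
    c_stem: str
    nc_pairs: List[BasePair]
    bulge: List[ResidueId]
    ga_pairs: List[BasePair]
    axis_angle: float
    internal_a_minor: Optional[AMinor] = None
    context: str = ""

    @property
    def key(self) -> FrozenSet[ResidueId]:
        out = set(self.bulge)
        for p in self.ga_pairs:
            out.update((p.a, p.b))
        return frozenset(out)


@dataclass
class LoopReceptor:
    loop_label: str
    loop_residues: List[ResidueId]
    receptor_stem: str
    a_minors: List[AMinor]
    zipper: Optional[RiboseZipper] = None
    loop_size: int = 0
    context: str = ""

    @property
    def key(self) -> FrozenSet[ResidueId]:
        return frozenset(self.loop_residues)


# ---------------------------------------------------------------------------
# base triples and quadruples
# ---------------------------------------------------------------------------


def detect_triples(
    m: StructureModel,
    pairs: Sequence[BasePair],
    frames: Dict[ResidueId, BaseFrame],
    config: DetectionConfig = DEFAULT_CONFIG,
) -> List[BaseTriple]:
    """All planar base triples: a central residue paired to two partners,
    every pairing with >=2 hydrogen bonds, all base planes within the
    triple planarity cutoff."""
    by_res: Dict[ResidueId, List[BasePair]] = {}
    for p in pairs:
        by_res.setdefault(p.a, []).append(p)
        by_res.setdefault(p.b, []).append(p)

    seen: Set[FrozenSet[ResidueId]] = set()
    triples: List[BaseTriple] = []
    for center, plist in sorted(by_res.items()):
        if len(plist) < 2:
            continue
        for p1, p2 in itertools.combinations(plist, 2):
            a = p1.partner(center)
            b = p2.partner(center)
            if a == b:
                continue
            trio = frozenset((center, a, b))
            if trio in seen:
                continue
            fs = [frames.get(r) for r in (center, a, b)]
            if any(f is None for f in fs):
                continue
            ang = max(
                plane_angle(f1.normal, f2.normal)
                for f1, f2 in itertools.combinations(fs, 2)
            )
            if ang > config.triple_planarity_max:
                continue
            seen.add(trio)
            residues = tuple(sorted(trio))
            bases = tuple(m.get(r).base for r in residues)
            pairings = [p1, p2]
            third = _pair_between(pairs, a, b)
            if third is not None:
                pairings.append(third)
            triples.append(
                BaseTriple(
                    residues=residues,  # type: ignore[arg-type]
                    bases=bases,        # type: ignore[arg-type]
                    pairings=pairings,
                    planarity=ang,
                    contains_wc=any(p.canonical for p in pairings),
                )
            )
    triples.sort(key=lambda t: t.residues)
    return triples


def _pair_between(
    pairs: Sequence[BasePair], a: ResidueId, b: ResidueId
) -> Optional[BasePair]:
    key = frozenset((a, b))
    for p in pairs:
        if p.key == key:
            return p
    return None


def detect_quadruples(
    triples: Sequence[BaseTriple], pairs: Sequence[BasePair]
) -> List[BaseQuadruple]:
    """Merge triples that share a pairing into four-base records.

    The constituent triples stay reported -- the census counts triples."""
    quads: List[BaseQuadruple] = []
    seen: Set[FrozenSet[ResidueId]] = set()
    for t1, t2 in itertools.combinations(triples, 2):
        union = t1.key | t2.key
        if len(union) != 4:
            continue
        shared_pairs = {p.key for p in t1.pairings} & {p.key for p in t2.pairings}
        if not shared_pairs:
            continue
        if union in seen:
            continue
        seen.add(union)
        residues = tuple(sorted(union))
        base_of = {}
        for t in (t1, t2):
            for r, b in zip(t.residues, t.bases):
                base_of[r] = b
        quads.append(
            BaseQuadruple(
                residues=residues,
                bases=tuple(base_of[r] for r in residues),
                triples=[t1, t2],
            )
        )
    quads.sort(key=lambda q: q.residues)
    return quads


# ---------------------------------------------------------------------------
# A-minor / G-minor
# ---------------------------------------------------------------------------

_DOCK_ATOMS = {"N3", "O2'", "C2"}   # sugar-edge atoms of the docking purine


def _minor_groove_atoms(base: str) -> Set[str]:
    if base in ("A", "G"):
        out = {"N3", "O2'"}
        if base == "G":
            out.add("N2")
        return out
    return {"O2", "O2'"}


def detect_a_minor(
    m: StructureModel,
    pairs: Sequence[BasePair],
    hbonds: Sequence[HydrogenBond],
    config: DetectionConfig = DEFAULT_CONFIG,
    order: Optional[Sequence[ResidueId]] = None,
) -> List[AMinor]:
    """A/G-minor motifs: an adenosine or guanosine docking its sugar edge
    into the minor groove of a canonical pair with >=2 hydrogen bonds.

    One record per docking residue; when several canonical pairs receive
    bonds from the same residue the best-supported receptor is kept.
    """
    canonical = [p for p in pairs if p.canonical]
    if not canonical:
        return []
    paired_wc: Dict[ResidueId, Set[ResidueId]] = {}
    for p in canonical:
        paired_wc.setdefault(p.a, set()).add(p.b)
        paired_wc.setdefault(p.b, set()).add(p.a)

    member_of: Dict[ResidueId, List[BasePair]] = {}
    for p in canonical:
        member_of.setdefault(p.a, []).append(p)
        member_of.setdefault(p.b, []).append(p)

    candidates: Dict[Tuple[ResidueId, FrozenSet[ResidueId]], List[HydrogenBond]] = {}
    receptor_of: Dict[FrozenSet[ResidueId], BasePair] = {
        p.key: p for p in canonical
    }
    for h in hbonds:
        for r_end, o_end in ((h.donor, h.acceptor), (h.acceptor, h.donor)):
            rid, atom = r_end
            orid, oatom = o_end
            nuc = m.get(rid)
            if nuc.base not in ("A", "G") or atom not in _DOCK_ATOMS:
                continue
            onuc = m.get(orid)
            if oatom not in _minor_groove_atoms(onuc.base):
                continue
            if orid in paired_wc.get(rid, set()):
                continue
            for rec in member_of.get(orid, []):
                if rid in (rec.a, rec.b):
                    continue
                candidates.setdefault((rid, rec.key), []).append(h)

    best_per_donor: Dict[ResidueId, Tuple[BasePair, List[HydrogenBond]]] = {}
    for (rid, rkey), blist in candidates.items():
        uniq = list({(h.donor, h.acceptor): h for h in blist}.values())
        if len(uniq) < config.aminor_min_hbonds:
            continue
        rec = receptor_of[rkey]
        cur = best_per_donor.get(rid)
        score = (len(uniq), -min(h.distance for h in uniq))
        if cur is None or score > (len(cur[1]), -min(h.distance for h in cur[1])):
            best_per_donor[rid] = (rec, uniq)

    pos = {r: i for i, r in enumerate(order)} if order else {
        n.rid: i for i, n in enumerate(m.nucleotides)
    }
    out: List[AMinor] = []
    for rid in sorted(best_per_donor):
        rec, blist = best_per_donor[rid]
        r_atoms = set()
        touched: Set[ResidueId] = set()
        for h in blist:
            for r_end, o_end in ((h.donor, h.acceptor), (h.acceptor, h.donor)):
                if r_end[0] == rid and r_end[1] in _DOCK_ATOMS:
                    r_atoms.add(r_end[1])
                    touched.add(o_end[0])
        if r_atoms == {"O2'"}:
            mtype = "0"
        elif "O2'" in r_atoms and (r_atoms & {"N3", "C2"}) and len(touched) == 2:
            mtype = "I"
        else:
            mtype = "II"
        base = m.get(rid).base
        five, three = (rec.a, rec.b) if pos.get(rec.a, 0) < pos.get(rec.b, 0) else (rec.b, rec.a)
        label = m.get(five).base + m.get(three).base
        if not config.receptor_label_five_prime_first:
            label = label[::-1]
        out.append(
            AMinor(
                donor=rid,
                donor_base=base,
                receptor=rec,
                type=mtype,
                hbonds=sorted(blist, key=lambda h: (h.donor, h.acceptor)),
                variant="G-minor" if base == "G" else "A-minor",
                receptor_label=label,
                receptor_label_flipped=label[::-1],
            )
        )
    return out


# ---------------------------------------------------------------------------
# ribose zippers
# ---------------------------------------------------------------------------


def detect_ribose_zipper(
    m: StructureModel,
    hbonds: Sequence[HydrogenBond],
    config: DetectionConfig = DEFAULT_CONFIG,
) -> List[RiboseZipper]:
    """Two sequence-distant dinucleotide segments laced by >=2 cross-segment
    hydrogen bonds, each involving at least one O2'."""
    order = [n.rid for n in m.nucleotides]
    pos = {rid: i for i, rid in enumerate(order)}
    o2_bonds = [h for h in hbonds if h.involves_o2prime()]

    def consecutive(i: int) -> bool:
        # dinucleotide step by author numbering on one chain
        a, b = order[i], order[i + 1]
        return a[0] == b[0] and b[1] == a[1] + 1

    def separation(i: int, j: int) -> int:
        a, b = order[i], order[j]
        if a[0] != b[0]:
            return 10 ** 6  # different chains: always sequence-distant
        return abs(b[1] - a[1])

    def bonds_between(i: int, j: int) -> List[HydrogenBond]:
        s1 = {order[i], order[i + 1]}
        s2 = {order[j], order[j + 1]}
        return [
            h for h in o2_bonds
            if (h.donor[0] in s1 and h.acceptor[0] in s2)
            or (h.donor[0] in s2 and h.acceptor[0] in s1)
        ]

    # candidate segment starts: residues appearing in O2'-mediated bonds
    involved = sorted(
        {pos[r] for h in o2_bonds for r in (h.donor[0], h.acceptor[0])}
    )
    found: List[Tuple[int, int, List[HydrogenBond]]] = []
    for i in involved:
        for di in (-1, 0):
            si = i + di
            if si < 0 or si + 1 >= len(order) or not consecutive(si):
                continue
            for j in involved:
                for dj in (-1, 0):
                    sj = j + dj
                    if sj <= si or sj + 1 >= len(order) or not consecutive(sj):
                        continue
                    if separation(si, sj) <= config.zipper_min_separation - 1:
                        continue
                    bonds = bonds_between(si, sj)
                    if len(bonds) >= config.zipper_min_hbonds:
                        found.append((si, sj, bonds))

    found.sort(key=lambda t: (-len(t[2]), t[0], t[1]))
    used: Set[int] = set()
    out: List[RiboseZipper] = []
    for si, sj, bonds in found:
        segment = {si, si + 1, sj, sj + 1}
        if segment & used:
            continue
        used |= segment
        out.append(
            RiboseZipper(
                strand1=(order[si], order[si + 1]),
                strand2=(order[sj], order[sj + 1]),
                hbonds=sorted(bonds, key=lambda h: (h.donor, h.acceptor)),
                zclass=_zipper_class(m, bonds),
            )
        )
    out.sort(key=lambda z: (z.strand1, z.strand2))
    return out


def _zipper_class(m: StructureModel, bonds: Sequence[HydrogenBond]) -> str:
    has_o2_o2 = any(
        h.donor[1] == "O2'" and h.acceptor[1] == "O2'" for h in bonds
    )
    has_o2_base = any(
        (h.donor[1] == "O2'" and h.acceptor[1] in ("O2", "N3"))
        or (h.acceptor[1] == "O2'" and h.donor[1] in ("O2", "N3"))
        for h in bonds
    )
    if has_o2_o2 and has_o2_base:
        return "canonical"
    if has_o2_base and not has_o2_o2:
        return "pseudo-cis"
    return "other-variant"


# ---------------------------------------------------------------------------
# pseudoknots and kissing loops
# ---------------------------------------------------------------------------


def crossing(p: Tuple[int, int], q: Tuple[int, int]) -> bool:
    """True when index pairs (i,j) and (k,l) interleave: i < k < j < l."""
    (i, j), (k, l) = sorted(p), sorted(q)
    return (i < k < j < l) or (k < i < l < j)


def detect_pseudoknots(
    skeleton: Sequence[BasePair],
    remainder: Sequence[BasePair],
    order: Sequence[ResidueId],
    ss: Optional[SecondaryStructure] = None,
) -> List[PseudoknotRecord]:
    """Crossing canonical pair groups outside the nested skeleton."""
    pos = {rid: i for i, rid in enumerate(order)}

    def idx(p: BasePair) -> Optional[Tuple[int, int]]:
        if p.a in pos and p.b in pos:
            return tuple(sorted((pos[p.a], pos[p.b])))  # type: ignore[return-value]
        return None

    rem = [(p, idx(p)) for p in remainder if p.canonical or p.wobble]
    rem = [(p, ij) for p, ij in rem if ij is not None]
    skel = [(p, idx(p)) for p in skeleton]
    skel = [(p, ij) for p, ij in skel if ij is not None]

    crossing_of: List[Set[int]] = []
    keep: List[Tuple[BasePair, Tuple[int, int]]] = []
    for p, ij in rem:
        crossed = {k for k, (_q, kl) in enumerate(skel) if crossing(ij, kl)}
        if crossed:
            keep.append((p, ij))
            crossing_of.append(crossed)
    if not keep:
        return []

    # merge mutually non-crossing remainder pairs that cross common skeleton
    # pairs into one pseudoknot group
    parent = list(range(len(keep)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(range(len(keep)), 2):
        if crossing(keep[a][1], keep[b][1]):
            continue
        if crossing_of[a] & crossing_of[b]:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

    groups: Dict[int, List[int]] = {}
    for x in range(len(keep)):
        groups.setdefault(find(x), []).append(x)

    hairpin_ranges = []
    if ss is not None:
        for loop in ss.hairpin_loops():
            ids = [pos[r] for r in loop.residues if r in pos]
            if ids:
                hairpin_ranges.append((min(ids), max(ids)))

    out: List[PseudoknotRecord] = []
    for members in groups.values():
        g1 = [keep[x][0] for x in members]
        crossed_idx = set().union(*(crossing_of[x] for x in members))
        g2 = [skel[k][0] for k in sorted(crossed_idx)]
        htype = False
        for x in members:
            i, j = keep[x][1]
            for lo, hi in hairpin_ranges:
                if lo <= i <= hi or lo <= j <= hi:
                    htype = True
        out.append(PseudoknotRecord(group1=g1, group2=g2, htype=htype))
    out.sort(key=lambda r: min((p.a for p in r.group1)))
    return out


def detect_kissing_loops(
    ss: SecondaryStructure,
    pairs: Sequence[BasePair],
    config: DetectionConfig = DEFAULT_CONFIG,
) -> List[KissingLoop]:
    """>=2 canonical pairs joining residues of two distinct hairpin loops."""
    loop_of: Dict[ResidueId, str] = {}
    for loop in ss.hairpin_loops():
        for rid in loop.residues:
            loop_of[rid] = loop.label
    grouped: Dict[Tuple[str, str], List[BasePair]] = {}
    for p in pairs:
        if not p.canonical:
            continue
        la, lb = loop_of.get(p.a), loop_of.get(p.b)
        if la is None or lb is None or la == lb:
            continue
        key = tuple(sorted((la, lb)))
        grouped.setdefault(key, []).append(p)
    out = [
        KissingLoop(loop_a=k[0], loop_b=k[1],
                    pairs=sorted(v, key=lambda p: (p.a, p.b)))
        for k, v in grouped.items()
        if len(v) >= config.kissing_min_pairs
    ]
    out.sort(key=lambda k: (k.loop_a, k.loop_b))
    return out


# ---------------------------------------------------------------------------
# kink-turns
# ---------------------------------------------------------------------------


def _axis_through(points: np.ndarray) -> Optional[np.ndarray]:
    if len(points) < 2:
        return None
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[0]


def detect_kink_turn(
    m: StructureModel,
    ss: SecondaryStructure,
    pairs: Sequence[BasePair],
    a_minors: Sequence[AMinor] = (),
    config: DetectionConfig = DEFAULT_CONFIG,
) -> List[KinkTurn]:
    """Helix - short bulge - tandem-sheared-G.A helix with bent axes."""
    order = [n.rid for n in m.nucleotides]
    pos = {rid: i for i, rid in enumerate(order)}

    def is_sheared_ga(p: BasePair) -> bool:
        if frozenset((p.base_a, p.base_b)) != frozenset(("G", "A")):
            return False
        return {p.edge_a, p.edge_b} == {"Sugar", "Hoogsteen"}

    ga = [p for p in pairs if is_sheared_ga(p)]
    # tandem: adjacent on both strands
    tandems: List[Tuple[BasePair, BasePair]] = []
    for p, q in itertools.combinations(ga, 2):
        pa, pb = sorted((pos[p.a], pos[p.b]))
        qa, qb = sorted((pos[q.a], pos[q.b]))
        if abs(pa - qa) == 1 and abs(pb - qb) == 1:
            tandems.append((p, q) if pa < qa else (q, p))

    out: List[KinkTurn] = []
    seen: Set[FrozenSet[ResidueId]] = set()
    for p, q in tandems:
        nc_idx = sorted(
            {pos[r] for r in (p.a, p.b, q.a, q.b)}
        )
        nc_lo, nc_hi = nc_idx[0], nc_idx[-1]
        # neighbouring non-canonical pairs extend the NC stem
        nc_pairs = [p, q]
        for extra in pairs:
            if extra.key in (p.key, q.key) or extra.canonical:
                continue
            ia, ib = sorted((pos[extra.a], pos[extra.b]))
            if abs(ia - nc_lo) <= 1 and abs(ib - nc_hi) <= 1:
                nc_pairs.append(extra)
        for stem in ss.stems:
            stem_idx = sorted(pos[r] for r in stem.residues if r in pos)
            if not stem_idx:
                continue
            # bulge between the stem's inner end and the NC block, 5' side
            gap = [
                k for k in range(stem_idx[len(stem.pairs) - 1] + 1, nc_lo)
                if order[k] not in ss.element_of
                or ss.kind_of.get(order[k]) in ("junction", "bulge", "internal", "hairpin")
            ]
            inner5 = max(i for i in stem_idx if i < nc_lo) if any(i < nc_lo for i in stem_idx) else None
            if inner5 is None:
                continue
            bulge_idx = [k for k in range(inner5 + 1, nc_lo)]
            if not (config.kink_bulge_min <= len(bulge_idx) <= config.kink_bulge_max):
                continue
            if any(order[k] in {r for st in ss.stems for r in st.residues} for k in bulge_idx):
                continue
            c_pts = np.array(
                [m.get(r).atom_pos("C1'") for r in stem.residues
                 if m.get(r).atom_pos("C1'") is not None]
            )
            nc_res = sorted({r for pr in nc_pairs for r in (pr.a, pr.b)})
            n_pts = np.array(
                [m.get(r).atom_pos("C1'") for r in nc_res
                 if m.get(r).atom_pos("C1'") is not None]
            )
            ax1, ax2 = _axis_through(c_pts), _axis_through(n_pts)
            if ax1 is None or ax2 is None:
                continue
            ang = plane_angle(ax1, ax2)  # folded to [0, 90]
            axis_angle = ang if ang <= 90 else 180 - ang
            if axis_angle > config.kink_axis_max_angle:
                continue
            key = frozenset(
                list(stem.residues) + [order[k] for k in bulge_idx] + nc_res
            )
            if key in seen:
                continue
            seen.add(key)
            internal = None
            stem_res = set(stem.residues)
            for am in a_minors:
                if am.donor in set(nc_res) and {am.receptor.a, am.receptor.b} <= stem_res:
                    internal = am
                    break
            out.append(
                KinkTurn(
                    c_stem=stem.label,
                    nc_pairs=sorted(nc_pairs, key=lambda x: (x.a, x.b)),
                    bulge=[order[k] for k in bulge_idx],
                    ga_pairs=[p, q],
                    axis_angle=axis_angle,
                    internal_a_minor=internal,
                )
            )
    out.sort(key=lambda k: sorted(k.key))
    return out


# ---------------------------------------------------------------------------
# loop-receptor interactions
# ---------------------------------------------------------------------------


def detect_loop_receptor(
    ss: SecondaryStructure,
    a_minors: Sequence[AMinor],
    zippers: Sequence[RiboseZipper],
    config: DetectionConfig = DEFAULT_CONFIG,
) -> List[LoopReceptor]:
    """Tetra/penta hairpin loop docking a distal stem via an A-minor, with
    a ribose zipper attached when one of its strands lies in the loop."""
    stem_of_label: Dict[str, str] = {}
    stem_residues: Dict[str, Set[ResidueId]] = {}
    for stem in ss.stems:
        stem_residues[stem.label] = set(stem.residues)
    out: List[LoopReceptor] = []
    for loop in ss.hairpin_loops():
        size = len(loop.residues)
        if not (config.loop_receptor_min_size <= size <= config.loop_receptor_max_size):
            continue
        loop_set = set(loop.residues)
        docked: Dict[str, List[AMinor]] = {}
        for am in a_minors:
            if am.donor not in loop_set:
                continue
            rec_res = {am.receptor.a, am.receptor.b}
            for label, sres in stem_residues.items():
                if rec_res <= sres and label.rstrip("abcdefgh") != loop.stem_label:
                    docked.setdefault(label, []).append(am)
        for label, ams in sorted(docked.items()):
            zipper = None
            for z in zippers:
                s1, s2 = set(z.strand1), set(z.strand2)
                if (s1 <= loop_set and s2 & stem_residues[label]) or (
                    s2 <= loop_set and s1 & stem_residues[label]
                ):
                    zipper = z
                    break
            out.append(
                LoopReceptor(
                    loop_label=loop.label,
                    loop_residues=list(loop.residues),
                    receptor_stem=label,
                    a_minors=ams,
                    zipper=zipper,
                    loop_size=size,
                )
            )
    out.sort(key=lambda lr: (lr.loop_label, lr.receptor_stem))
    return out
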