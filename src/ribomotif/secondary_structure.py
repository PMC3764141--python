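"""Nested secondary-structure skeleton and P/L/J element labelling.

The skeleton is the maximum-cardinality non-crossing, one-pairing-per-
residue subset of the canonical (and wobble) pairs, computed per chain by
interval dynamic programming; the pairs excluded by the skeleton (crossing
remainder) are what the pseudoknot and kissing-loop detectors consume.
Elements are labelled the way riboswitch secondary structures are drawn:
stems P1..Pn in 5'-order (sub-stems separated by internal loops lettered
P2a/P2b), hairpin loops L(k) named after their stem, and junction runs
"Ji-j" between consecutive stems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

from .pairing import BasePair
from .structure_model import ResidueId, StructureModel

__all__ = [
    "Stem",
    "LoopElement",
    "JunctionElement",
    "SecondaryStructure",
    "nested_skeleton",
    "build_elements",
    "classify_context",
    "dot_bracket",
    "element_tsv",
]


@dataclass
class Stem:
    label: str
    pairs: List[BasePair]
    number: int          # stem group number (the k of Pk)

    @property
    def residues(self) -> List[ResidueId]:
        out = []
        for p in self.pairs:
            out.extend([p.a, p.b])
        return out


@dataclass
class LoopElement:
    label: str
    kind: str            # 'hairpin' | 'internal' | 'bulge'
    residues: List[ResidueId]
    stem_label: str = ""


@dataclass
class JunctionElement:
    label: str
    residues: List[ResidueId]
    flanking: Tuple[str, str] = ("", "")


@dataclass
class SecondaryStructure:
    stems: List[Stem]
    loops: List[LoopElement]
    junctions: List[JunctionElement]
    element_of: Dict[ResidueId, str] = field(default_factory=dict)
    kind_of: Dict[ResidueId, str] = field(default_factory=dict)

    def stem_by_label(self, label: str) -> Optional[Stem]:
        for s in self.stems:
            if s.label == label:
                return s
        return None

    def hairpin_loops(self) -> List[LoopElement]:
        return [l for l in self.loops if l.kind == "hairpin"]


def _pair_indices(
    pairs: Sequence[BasePair], order: Sequence[ResidueId]
) -> List[Tuple[int, int, int, BasePair]]:
    """(i, j, n_hbonds, pair) with i < j in residue order; pairs with a
    residue outside ``order`` are dropped (inter-chain pairs)."""
    pos = {rid: k for k, rid in enumerate(order)}
    out = []
    for p in pairs:
        if p.a in pos and p.b in pos:
            i, j = sorted((pos[p.a], pos[p.b]))
            out.append((i, j, len(p.hbonds), p))
    return out


def nested_skeleton(
    pairs: Sequence[BasePair], order: Sequence[ResidueId]
) -> Tuple[List[BasePair], List[BasePair]]:
    """Split pairs into a maximum non-crossing skeleton and the remainder.

    Ties in cardinality are broken toward the subset with more hydrogen
    bonds, then lexicographically by pair indices.
    """
    indexed = _pair_indices(pairs, order)
    by_close: Dict[int, List[Tuple[int, int, int, BasePair]]] = {}
    for i, j, nh, p in indexed:
        by_close.setdefault(j, []).append((i, j, nh, p))

    n = len(order)

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> Tuple[int, int, Tuple[Tuple[int, int], ...]]:
        # returns (count, hbond total, chosen (i,j) tuples sorted)
        if i >= j:
            return (0, 0, ())
        top = best(i, j - 1)
        for k, jj, nh, _p in by_close.get(j, []):
            if k < i:
                continue
            left = best(i, k - 1)
            inner = best(k + 1, j - 1)
            cand = (
                left[0] + inner[0] + 1,
                left[1] + inner[1] + nh,
                tuple(sorted(left[2] + inner[2] + ((k, j),))),
            )
            if (cand[0], cand[1], tuple(-x for xy in cand[2] for x in xy)) > (
                top[0], top[1], tuple(-x for xy in top[2] for x in xy)
            ):
                top = cand
        return top

    _, _, chosen = best(0, n - 1)
    best.cache_clear()
    chosen_set = set(chosen)
    lookup = {(i, j): p for i, j, _nh, p in indexed}
    skeleton = [lookup[ij] for ij in sorted(chosen_set)]
    skeleton_keys = {frozenset((p.a, p.b)) for p in skeleton}
    remainder = [p for p in pairs if frozenset((p.a, p.b)) not in skeleton_keys]
    return skeleton, remainder


def _helix_runs(pair_map: Dict[int, int]) -> List[List[Tuple[int, int]]]:
    """Maximal stacked runs (i,j),(i+1,j-1),... from an index pair map."""
    pairs = sorted((i, j) for i, j in pair_map.items() if i < j)
    runs: List[List[Tuple[int, int]]] = []
    used = set()
    for i, j in pairs:
        if (i, j) in used:
            continue
        run = [(i, j)]
        used.add((i, j))
        while pair_map.get(run[-1][0] + 1) == run[-1][1] - 1 and run[-1][1] - 1 > run[-1][0] + 1:
            nxt = (run[-1][0] + 1, run[-1][1] - 1)
            run.append(nxt)
            used.add(nxt)
        runs.append(run)
    return runs


def build_elements(
    skeleton: Sequence[BasePair],
    model: StructureModel,
    chain: Optional[str] = None,
) -> SecondaryStructure:
    """Label stems, loops and junctions from a non-crossing skeleton."""
    if chain is None:
        chains = model.chains()
        if len(chains) != 1:
            raise ValueError("specify a chain for multi-chain models")
        chain = chains[0]
    order = [n.rid for n in model.nucleotides if n.chain == chain]
    pos = {rid: k for k, rid in enumerate(order)}
    pair_map: Dict[int, int] = {}
    pair_obj: Dict[Tuple[int, int], BasePair] = {}
    for p in skeleton:
        if p.a in pos and p.b in pos:
            i, j = sorted((pos[p.a], pos[p.b]))
            pair_map[i] = j
            pair_map[j] = i
            pair_obj[(i, j)] = p

    helices = _helix_runs(pair_map)
    helices.sort(key=lambda run: run[0][0])

    # group helices separated only by internal loops / bulges into one stem
    groups: List[List[List[Tuple[int, int]]]] = []
    for h in helices:
        placed = False
        if groups:
            prev = groups[-1][-1]
            pi, pj = prev[-1]          # innermost pair of previous helix
            hi, hj = h[0]              # outermost pair of this helix
            if pi < hi and hj < pj:
                gap5 = range(pi + 1, hi)
                gap3 = range(hj + 1, pj)
                if all(k not in pair_map for k in gap5) and all(
                    k not in pair_map for k in gap3
                ):
                    groups[-1].append(h)
                    placed = True
        if not placed:
            groups.append([h])

    stems: List[Stem] = []
    loops: List[LoopElement] = []
    junctions: List[JunctionElement] = []
    element_of: Dict[ResidueId, str] = {}
    kind_of: Dict[ResidueId, str] = {}

    stem_number_of_index: Dict[int, int] = {}
    for gnum, group in enumerate(groups, start=1):
        letters = "abcdefgh"
        multi = len(group) > 1
        for hnum, run in enumerate(group):
            label = f"P{gnum}{letters[hnum]}" if multi else f"P{gnum}"
            stems.append(
                Stem(label=label, number=gnum,
                     pairs=[pair_obj[ij] for ij in run])
            )
            for i, j in run:
                element_of[order[i]] = label
                element_of[order[j]] = label
                kind_of[order[i]] = "helix"
                kind_of[order[j]] = "helix"
                stem_number_of_index[i] = gnum
                stem_number_of_index[j] = gnum
        # internal loops / bulges between consecutive helices of the group
        for h1, h2 in zip(group, group[1:]):
            pi, pj = h1[-1]
            hi, hj = h2[0]
            side5 = [order[k] for k in range(pi + 1, hi)]
            side3 = [order[k] for k in range(hj + 1, pj)]
            if side5 and side3:
                kind = "internal"
                residues = side5 + side3
            else:
                kind = "bulge"
                residues = side5 or side3
            stem_label = f"P{gnum}"
            loop = LoopElement(
                label=f"{stem_label}.{kind}{len(loops)+1}",
                kind=kind, residues=residues, stem_label=stem_label,
            )
            loops.append(loop)
            for rid in residues:
                element_of[rid] = loop.label
                kind_of[rid] = kind

    # hairpin loops: unpaired run enclosed by the innermost pair of a group
    for gnum, group in enumerate(groups, start=1):
        pi, pj = group[-1][-1]
        inner = [k for k in range(pi + 1, pj) if k not in pair_map]
        if inner and all(k not in pair_map for k in range(pi + 1, pj)):
            label = f"L{gnum}"
            residues = [order[k] for k in inner]
            loops.append(
                LoopElement(label=label, kind="hairpin", residues=residues,
                            stem_label=f"P{gnum}")
            )
            for rid in residues:
                element_of[rid] = label
                kind_of[rid] = "hairpin"

    # junction / exterior runs: whatever is still unassigned
    run: List[int] = []
    for k in range(len(order) + 1):
        unassigned = k < len(order) and order[k] not in element_of
        if unassigned:
            run.append(k)
            continue
        if run:
            before = stem_number_of_index.get(run[0] - 1, 0)
            after = stem_number_of_index.get(run[-1] + 1, 0)
            label = f"J{before}-{after}"
            residues = [order[i] for i in run]
            junctions.append(
                JunctionElement(label=label, residues=residues,
                                flanking=(f"P{before}", f"P{after}"))
            )
            for rid in residues:
                element_of[rid] = label
                kind_of[rid] = "junction"
            run = []

    return SecondaryStructure(
        stems=stems, loops=loops, junctions=junctions,
        element_of=element_of, kind_of=kind_of,
    )


_KIND_NOUN = {
    "helix": "Helix",
    "hairpin": "Hairpin loop",
    "internal": "Internal loop",
    "bulge": "Bulged-out residue",
    "junction": "Junction",
}


def classify_context(
    residues: Sequence[ResidueId], ss: SecondaryStructure
) -> str:
    """Render the multiset of elements touched by a motif as the survey's
    context strings, e.g. "Helix - junction interaction (P2b & J3-4)"."""
    elements: List[Tuple[str, str]] = []  # (kind, label) in first-touch order
    for rid in residues:
        label = ss.element_of.get(rid)
        if label is None:
            return "unassigned"
        kind = ss.kind_of[rid]
        if (kind, label) not in elements:
            elements.append((kind, label))

    kinds = [k for k, _ in elements]
    labels = [l for _, l in elements]

    def lab(sep: str = " & ") -> str:
        return sep.join(labels)

    unique_kinds = sorted(set(kinds))
    if unique_kinds == ["junction"]:
        if len(elements) == 1:
            return f"Interaction within junction ({labels[0]})"
        return f"Interaction between junctions ({lab()})"
    if unique_kinds == ["helix"]:
        if len(elements) == 1:
            return f"Helix - helix interaction ({labels[0]})"
        return f"Helix - helix interaction ({lab()})"
    if unique_kinds == ["hairpin"]:
        if len(elements) == 1:
            return f"Interaction within hairpin loop ({labels[0]})"
        return f"Hairpin loop - hairpin loop interaction ({lab()})"
    if set(kinds) == {"helix", "junction"}:
        return f"Helix - junction interaction ({lab()})"
    if set(kinds) == {"helix", "hairpin"}:
        return f"Helix - hairpin loop interaction ({lab()})"
    if set(kinds) == {"helix", "bulge"}:
        bulge = next(e for e in elements if e[0] == "bulge")
        own = bulge[1].split(".")[0]  # the stem the bulge belongs to
        helix_labels = [l for k, l in elements if k == "helix"]
        others = [l for l in helix_labels if not l.startswith(own)]
        shown = [own] + others if others else [own]
        return f"Bulged-out residue - helix interaction ({' & '.join(shown)})"
    if set(kinds) == {"junction", "helix", "hairpin"}:
        ordered = sorted(elements, key=lambda e: ("junction", "helix", "hairpin").index(e[0]))
        return (
            "Junction - helix - hairpin loop interaction ("
            + ", ".join(l for _, l in ordered)
            + ")"
        )
    nouns = " - ".join(_KIND_NOUN[k] for k, _ in elements)
    return f"{nouns} interaction ({lab(', ')})"


def element_tsv(ss: SecondaryStructure) -> str:
    """Residue -> element label/kind table (one row per residue)."""
    lines = ["chain\tnumber\ticode\telement\tkind"]
    for rid in sorted(ss.element_of):
        chain, num, icode = rid
        lines.append(
            f"{chain}\t{num}\t{icode}\t{ss.element_of[rid]}\t{ss.kind_of[rid]}"
        )
    return "\n".join(lines) + "\n"


def dot_bracket(
    ss_or_skeleton,
    order: Sequence[ResidueId],
    remainder: Sequence[BasePair] = (),
) -> str:
    """Dot-bracket string; crossing remainder pairs rendered in [], {}."""
    if isinstance(ss_or_skeleton, SecondaryStructure):
        skeleton = [p for s in ss_or_skeleton.stems for p in s.pairs]
    else:
        skeleton = list(ss_or_skeleton)
    pos = {rid: k for k, rid in enumerate(order)}
    chars = ["." for _ in order]
    for p in skeleton:
        if p.a in pos and p.b in pos:
            i, j = sorted((pos[p.a], pos[p.b]))
            chars[i], chars[j] = "(", ")"
    layers = [("[", "]"), ("{", "}"), ("<", ">")]
    placed: List[List[Tuple[int, int]]] = [[] for _ in layers]
    for p in remainder:
        if p.a not in pos or p.b not in pos:
            continue
        i, j = sorted((pos[p.a], pos[p.b]))
        for layer, bucket in enumerate(placed):
            if all(not (a < i < b < j or i < a < j < b) for a, b in bucket):
                bucket.append((i, j))
                chars[i], chars[j] = layers[layer]
                break
    return "".join(chars)
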