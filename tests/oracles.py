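"""Independent brute-force reference implementations used to cross-check
the production detectors.  These deliberately avoid the package's spatial
indexing and dynamic programming: plain loops over all combinations."""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from ribomotif.config import DetectionConfig
from ribomotif.pairing import (
    BASE_ACCEPTORS,
    BASE_DONORS,
    PHOSPHATE_ACCEPTORS,
    SUGAR_ACCEPTORS,
    SUGAR_DONORS,
)
from ribomotif.structure_model import StructureModel


def brute_force_hbond_pairs(
    m: StructureModel, config: DetectionConfig
) -> Set[frozenset]:
    """Residue pairs with >=1 donor-acceptor contact, by exhaustive scan."""
    out: Set[frozenset] = set()
    for na, nb in itertools.combinations(m.nucleotides, 2):
        if _any_bond(na, nb, config) or _any_bond(nb, na, config):
            out.add(frozenset((na.rid, nb.rid)))
    return out


def _any_bond(donor_nuc, acceptor_nuc, config) -> bool:
    donors = dict(BASE_DONORS.get(donor_nuc.base, {}))
    donors.update(SUGAR_DONORS)
    acceptors = list(BASE_ACCEPTORS.get(acceptor_nuc.base, ())) + list(
        SUGAR_ACCEPTORS
    ) + list(PHOSPHATE_ACCEPTORS)
    for dname, antecedents in donors.items():
        dpos = donor_nuc.atom_pos(dname)
        if dpos is None:
            continue
        for aname in acceptors:
            apos = acceptor_nuc.atom_pos(aname)
            if apos is None:
                continue
            dist = float(np.linalg.norm(apos - dpos))
            if not (config.hbond_min_distance <= dist <= config.hbond_max_distance):
                continue
            ok = True
            for ante in antecedents:
                ap = donor_nuc.atom_pos(ante)
                if ap is None:
                    continue
                v1, v2 = ap - dpos, apos - dpos
                cosang = float(
                    np.clip(
                        np.dot(v1, v2)
                        / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                        -1, 1,
                    )
                )
                if math.degrees(math.acos(cosang)) < config.hbond_min_angle:
                    ok = False
                    break
            if ok:
                return True
    return False


def brute_force_base_base_bonds(
    m: StructureModel, config: DetectionConfig
) -> Dict[frozenset, int]:
    """Count base-base donor-acceptor contacts per residue pair."""
    from ribomotif.pairing import BASE_ATOM_NAMES

    counts: Dict[frozenset, int] = {}
    for na, nb in itertools.combinations(m.nucleotides, 2):
        n = 0
        seen = set()
        for d, a in ((na, nb), (nb, na)):
            donors = BASE_DONORS.get(d.base, {})
            for dname, antecedents in donors.items():
                if dname not in BASE_ATOM_NAMES.get(d.base, set()):
                    continue
                dpos = d.atom_pos(dname)
                if dpos is None:
                    continue
                for aname in BASE_ACCEPTORS.get(a.base, ()):
                    apos = a.atom_pos(aname)
                    if apos is None:
                        continue
                    key = frozenset(((d.rid, dname), (a.rid, aname)))
                    if key in seen:
                        continue
                    dist = float(np.linalg.norm(apos - dpos))
                    if not (
                        config.hbond_min_distance
                        <= dist
                        <= config.hbond_max_distance
                    ):
                        continue
                    ok = True
                    for ante in antecedents:
                        ap = d.atom_pos(ante)
                        if ap is None:
                            continue
                        v1, v2 = ap - dpos, apos - dpos
                        cosang = float(
                            np.clip(
                                np.dot(v1, v2)
                                / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                                -1, 1,
                            )
                        )
                        if math.degrees(math.acos(cosang)) < config.hbond_min_angle:
                            ok = False
                            break
                    if ok:
                        seen.add(key)
                        n += 1
        if n:
            counts[frozenset((na.rid, nb.rid))] = n
    return counts


def max_noncrossing_subset(pairs: Sequence[Tuple[int, int]]) -> int:
    """Exhaustive maximum cardinality of a non-crossing, one-pairing-per-
    residue subset (feasible up to ~12 pairs)."""
    best = 0
    n = len(pairs)
    for mask in range(1 << n):
        chosen = [pairs[i] for i in range(n) if mask >> i & 1]
        used: Set[int] = set()
        ok = True
        for i, j in chosen:
            if i in used or j in used:
                ok = False
                break
            used.update((i, j))
        if ok:
            for (i, j), (k, l) in itertools.combinations(
                [tuple(sorted(p)) for p in chosen], 2
            ):
                if i < k < j < l or k < i < l < j:
                    ok = False
                    break
        if ok:
            best = max(best, len(chosen))
    return best


def brute_force_crossing(pairs: Sequence[Tuple[int, int]]) -> Set[frozenset]:
    """All interleaving pairs-of-pairs by the i<k<j<l definition."""
    out: Set[frozenset] = set()
    for p, q in itertools.combinations(pairs, 2):
        (i, j), (k, l) = sorted(p), sorted(q)
        if i < k < j < l or k < i < l < j:
            out.add(frozenset((p, q)))
    return out


def brute_force_triples(
    m: StructureModel,
    pair_keys: Set[frozenset],
    frames,
    config: DetectionConfig,
) -> Set[frozenset]:
    """All residue triples passing the triple filter, enumerated directly:
    one residue paired (by the accepted pair list) to both others, all base
    planes mutually within the cutoff."""
    from ribomotif.structure_model import plane_angle

    out: Set[frozenset] = set()
    rids = [n.rid for n in m.nucleotides]
    for trio in itertools.combinations(rids, 3):
        linked = False
        for center in trio:
            others = [r for r in trio if r != center]
            if all(frozenset((center, o)) in pair_keys for o in others):
                linked = True
        if not linked:
            continue
        fs = [frames.get(r) for r in trio]
        if any(f is None for f in fs):
            continue
        ang = max(
            plane_angle(f1.normal, f2.normal)
            for f1, f2 in itertools.combinations(fs, 2)
        )
        if ang <= config.triple_planarity_max:
            out.add(frozenset(trio))
    return out
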