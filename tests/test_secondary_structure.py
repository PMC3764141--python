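import itertools

import numpy as np
import pytest

from ribomotif.pairing import BasePair, HydrogenBond
from ribomotif.secondary_structure import (
    build_elements,
    classify_context,
    dot_bracket,
    nested_skeleton,
)
from ribomotif.structure_model import Nucleotide, StructureModel
from ribomotif.synthetic_data import ideal_base

from .oracles import max_noncrossing_subset


def _rid(i):
    return ("A", i, "")


def _fake_pair(i, j, n_hbonds=2, canonical=True):
    hb = HydrogenBond(
        donor=(_rid(i), "N1"), acceptor=(_rid(j), "N3"), distance=2.9,
        donor_moiety="base", acceptor_moiety="base",
    )
    return BasePair(
        a=_rid(i), b=_rid(j), base_a="G", base_b="C",
        edge_a="WatsonCrick", edge_b="WatsonCrick", orientation="cis",
        hbonds=[hb] * n_hbonds, canonical=canonical, wobble=False,
    )


def _fake_model(n):
    nucs = [
        Nucleotide(chain="A", number=i, icode="", raw_name="G", base="G",
                   atoms=ideal_base("G"))
        for i in range(1, n + 1)
    ]
    return StructureModel(id="fake", nucleotides=nucs)


def _order(n):
    return [_rid(i) for i in range(1, n + 1)]


def test_already_nested_pairs_all_kept():
    pairs = [_fake_pair(1, 10), _fake_pair(2, 9), _fake_pair(3, 8)]
    skel, rem = nested_skeleton(pairs, _order(10))
    assert len(skel) == 3 and rem == []


def test_crossing_pair_tie_resolved_by_hbond_count():
    rich = _fake_pair(6, 16, n_hbonds=3)
    poor = _fake_pair(2, 11, n_hbonds=2)
    skel, rem = nested_skeleton([poor, rich], _order(16))
    assert skel == [rich] and rem == [poor]


def test_crossing_pair_equal_hbonds_keeps_first():
    p1 = _fake_pair(2, 11)
    p2 = _fake_pair(6, 16)
    skel, rem = nested_skeleton([p1, p2], _order(16))
    assert len(skel) == 1 and skel[0].a == _rid(2)


@pytest.mark.parametrize("seed", range(6))
def test_skeleton_cardinality_matches_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    n = 14
    npairs = 10
    pairs = []
    seen = set()
    while len(pairs) < npairs:
        i, j = sorted(rng.choice(np.arange(1, n + 1), 2, replace=False))
        if (i, j) in seen:
            continue
        seen.add((int(i), int(j)))
        pairs.append(_fake_pair(int(i), int(j)))
    skel, _rem = nested_skeleton(pairs, _order(n))
    idx = [(p.a[1], p.b[1]) for p in pairs]
    assert len(skel) == max_noncrossing_subset(idx)


def test_skeleton_enforces_one_pairing_per_residue():
    pairs = [_fake_pair(1, 10), _fake_pair(1, 8), _fake_pair(2, 9)]
    skel, rem = nested_skeleton(pairs, _order(10))
    used = [r for p in skel for r in (p.a, p.b)]
    assert len(used) == len(set(used))


def test_single_hairpin_elements():
    # stem 1-4 / 12-9, loop 5-8
    pairs = [_fake_pair(i, 13 - i) for i in range(1, 5)]
    m = _fake_model(12)
    ss = build_elements(pairs, m)
    assert [s.label for s in ss.stems] == ["P1"]
    hairpins = ss.hairpin_loops()
    assert len(hairpins) == 1 and hairpins[0].label == "L1"
    assert ss.junctions == []
    assert set(ss.element_of) == set(_order(12))


def test_cloverleaf_junction_labels():
    # three hairpins on an open multiloop, unpaired linkers between stems
    pairs = []
    for start in (2, 14, 26):
        pairs += [_fake_pair(start + k, start + 9 - k) for k in range(3)]
    m = _fake_model(38)
    ss = build_elements(pairs, m)
    assert [s.label for s in ss.stems] == ["P1", "P2", "P3"]
    labels = [j.label for j in ss.junctions]
    assert "J1-2" in labels and "J2-3" in labels


def test_substem_lettering_with_internal_loop():
    # helix 1-3/20-18, internal loop, helix 6-8/15-13
    pairs = [_fake_pair(i, 21 - i) for i in range(1, 4)]
    pairs += [_fake_pair(i, 21 - i) for i in range(6, 9)]
    m = _fake_model(20)
    ss = build_elements(pairs, m)
    assert [s.label for s in ss.stems] == ["P1a", "P1b"]
    internal = [l for l in ss.loops if l.kind == "internal"]
    assert len(internal) == 1


def test_bulge_recorded_on_one_side():
    # helix 1-3/20-18, bulge at 4-5 (5' side only), helix 6-8/17-15
    pairs = [_fake_pair(i, 21 - i) for i in range(1, 4)]
    pairs += [_fake_pair(6, 17), _fake_pair(7, 16), _fake_pair(8, 15)]
    m = _fake_model(20)
    ss = build_elements(pairs, m)
    bulges = [l for l in ss.loops if l.kind == "bulge"]
    assert len(bulges) == 1
    assert [r[1] for r in bulges[0].residues] == [4, 5]


def test_stem_naming_invariant_to_pair_order():
    pairs = [_fake_pair(i, 13 - i) for i in range(1, 5)]
    m = _fake_model(12)
    labels1 = [s.label for s in build_elements(pairs, m).stems]
    labels2 = [s.label for s in build_elements(list(reversed(pairs)), m).stems]
    assert labels1 == labels2


def test_element_partition_covers_every_residue(scenes):
    for name in ("hairpin", "kissing", "kink_turn", "loop_receptor"):
        sc = scenes(name)
        ss = sc["ss"]
        chain_res = [r for r in sc["order"] if r[0] == sc["order"][0][0]]
        assert set(ss.element_of) == set(chain_res)


class TestContextStrings:
    def _ss(self):
        # stem1 1-3/20-18 with hairpin 8-12 ... build a two-stem layout
        pairs = [_fake_pair(i, 21 - i) for i in range(1, 4)]   # P1: 1-3/20-18
        pairs += [_fake_pair(i, 21 - i) for i in range(6, 9)]  # nested: P1b 6-8/15-13
        m = _fake_model(20)
        return build_elements(pairs, m)

    def test_within_one_stem(self):
        ss = self._ss()
        s = classify_context([_rid(1), _rid(2), _rid(20)], ss)
        assert s == "Helix - helix interaction (P1a)"

    def test_helix_hairpin(self):
        ss = self._ss()
        s = classify_context([_rid(6), _rid(10)], ss)
        assert s.startswith("Helix - hairpin loop interaction")

    def test_unassigned(self):
        ss = self._ss()
        assert classify_context([("B", 99, "")], ss) == "unassigned"

    def test_between_junctions(self):
        pairs = []
        for start in (2, 14, 26):
            pairs += [_fake_pair(start + k, start + 9 - k) for k in range(3)]
        ss = build_elements(pairs, _fake_model(38))
        s = classify_context([_rid(12), _rid(24)], ss)
        assert s == "Interaction between junctions (J1-2 & J2-3)"


def test_dot_bracket_layers():
    skel = [_fake_pair(1, 10), _fake_pair(2, 9)]
    rem = [_fake_pair(5, 15)]
    db = dot_bracket(skel, _order(16), rem)
    assert db.count("(") == 2 and db.count("[") == 1
    assert len(db) == 16
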