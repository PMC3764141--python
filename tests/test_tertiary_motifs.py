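import itertools

import numpy as np
import pytest

from ribomotif.config import DEFAULT_CONFIG
from ribomotif import tertiary_motifs as tm

from .oracles import brute_force_crossing, brute_force_triples


class TestTriples:
    def test_planted_triple_recovered(self, scenes):
        sc = scenes("triple")
        triples = tm.detect_triples(sc["model"], sc["pairs"], sc["frames"])
        assert len(triples) == 1
        t = triples[0]
        assert t.composition == "AGC"
        assert t.contains_wc
        assert t.planarity <= DEFAULT_CONFIG.triple_planarity_max

    def test_out_of_plane_base_rejected(self, scenes):
        sc = scenes("tilted_triple")
        triples = tm.detect_triples(sc["model"], sc["pairs"], sc["frames"])
        assert triples == []

    def test_helix_has_no_triples(self, scenes):
        sc = scenes("helix4")
        assert tm.detect_triples(sc["model"], sc["pairs"], sc["frames"]) == []

    def test_filter_soundness_recheck(self, scenes):
        """Every emitted triple re-passes both filter clauses."""
        from ribomotif.structure_model import plane_angle

        for name in ("triple", "kink_turn", "loop_receptor"):
            sc = scenes(name)
            for t in tm.detect_triples(sc["model"], sc["pairs"], sc["frames"]):
                for p in t.pairings:
                    base_bonds = [
                        h for h in p.hbonds
                        if h.donor_moiety == "base" and h.acceptor_moiety == "base"
                    ]
                    assert len(base_bonds) >= 2
                fs = [sc["frames"][r] for r in t.residues]
                ang = max(
                    plane_angle(f1.normal, f2.normal)
                    for f1, f2 in itertools.combinations(fs, 2)
                )
                assert ang <= DEFAULT_CONFIG.triple_planarity_max

    @pytest.mark.parametrize("name", ["triple", "tilted_triple", "helix4", "aminor_I"])
    def test_matches_brute_force_enumeration(self, scenes, name):
        sc = scenes(name)
        assert len(sc["model"]) <= 20
        got = {
            t.key
            for t in tm.detect_triples(sc["model"], sc["pairs"], sc["frames"])
        }
        pair_keys = {p.key for p in sc["pairs"]}
        expected = brute_force_triples(
            sc["model"], pair_keys, sc["frames"], DEFAULT_CONFIG
        )
        assert got == expected


class TestQuadruples:
    def test_shared_pairing_merges(self, scenes):
        sc = scenes("triple")
        triples = tm.detect_triples(sc["model"], sc["pairs"], sc["frames"])
        # synthesize a second triple sharing the central pairing
        t1 = triples[0]
        fake = tm.BaseTriple(
            residues=(t1.residues[1], t1.residues[2], ("A", 99, "")),
            bases=(t1.bases[1], t1.bases[2], "A"),
            pairings=[t1.pairings[0], t1.pairings[1]],
            planarity=0.0,
            contains_wc=True,
        )
        quads = tm.detect_quadruples([t1, fake], sc["pairs"])
        assert len(quads) == 1
        assert len(quads[0].residues) == 4

    def test_disjoint_triples_do_not_merge(self, scenes):
        sc = scenes("triple")
        t1 = tm.detect_triples(sc["model"], sc["pairs"], sc["frames"])[0]
        other = tm.BaseTriple(
            residues=(("B", 1, ""), ("B", 2, ""), ("B", 3, "")),
            bases=("A", "G", "C"),
            pairings=[],
            planarity=0.0,
            contains_wc=False,
        )
        assert tm.detect_quadruples([t1, other], sc["pairs"]) == []


class TestAMinor:
    @pytest.mark.parametrize(
        "scene_name,expected_type",
        [("aminor_I", "I"), ("aminor_II", "II"), ("aminor_0", "0")],
    )
    def test_planted_type_recovered(self, scenes, scene_name, expected_type):
        sc = scenes(scene_name)
        ams = tm.detect_a_minor(
            sc["model"], sc["pairs"], sc["hbonds"], order=sc["order"]
        )
        assert len(ams) == 1
        am = ams[0]
        assert am.type == expected_type
        assert am.variant == "A-minor"
        assert am.receptor.canonical
        assert am.donor == ("A", 41, "")

    def test_g_donor_is_g_minor(self, scenes):
        sc = scenes("gminor_I")
        ams = tm.detect_a_minor(
            sc["model"], sc["pairs"], sc["hbonds"], order=sc["order"]
        )
        assert len(ams) == 1
        assert ams[0].variant == "G-minor"

    def test_receptor_label_orientation(self, scenes):
        sc = scenes("aminor_I")
        am = tm.detect_a_minor(
            sc["model"], sc["pairs"], sc["hbonds"], order=sc["order"]
        )[0]
        assert am.receptor_label == "GC"
        assert am.receptor_label_flipped == "CG"

    def test_helix_alone_has_no_a_minor(self, scenes):
        sc = scenes("helix4")
        assert tm.detect_a_minor(
            sc["model"], sc["pairs"], sc["hbonds"], order=sc["order"]
        ) == []


class TestRiboseZipper:
    def test_canonical_zipper_recovered(self, scenes):
        sc = scenes("zipper")
        zs = tm.detect_ribose_zipper(sc["model"], sc["hbonds"])
        assert len(zs) == 1
        z = zs[0]
        assert z.zclass == "canonical"
        assert {r[1] for r in z.strand1} == {1, 2}
        assert {r[1] for r in z.strand2} == {11, 12}

    def test_single_cross_bond_not_reported(self, scenes):
        sc = scenes("zipper")
        thinned = [h for h in sc["hbonds"] if h.donor[0][1] != 1]
        assert tm.detect_ribose_zipper(sc["model"], thinned) == []


class TestPseudoknots:
    def test_planted_pseudoknot(self, scenes):
        sc = scenes("pseudoknot")
        recs = tm.detect_pseudoknots(
            sc["skeleton"], sc["remainder"], sc["order"], sc["ss"]
        )
        assert len(recs) == 1
        assert recs[0].htype
        assert len(recs[0].group1) == 2

    def test_nested_only_input_is_empty(self, scenes):
        sc = scenes("hairpin")
        assert tm.detect_pseudoknots(
            sc["skeleton"], sc["remainder"], sc["order"], sc["ss"]
        ) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_crossing_predicate_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pairs = []
        while len(pairs) < 12:
            i, j = sorted(rng.choice(np.arange(40), 2, replace=False))
            if i != j:
                pairs.append((int(i), int(j)))
        got = {
            frozenset((p, q))
            for p, q in itertools.combinations(pairs, 2)
            if tm.crossing(p, q)
        }
        assert got == brute_force_crossing(pairs)


class TestKissingLoops:
    def test_planted_kissing_loop(self, scenes):
        sc = scenes("kissing")
        kls = tm.detect_kissing_loops(sc["ss"], sc["pairs"])
        assert len(kls) == 1
        assert len(kls[0].pairs) == 3
        assert {kls[0].loop_a, kls[0].loop_b} == {"L1", "L2"}

    def test_single_interloop_pair_below_threshold(self, scenes):
        sc = scenes("kissing")
        # keep only one of the three kissing pairs
        loops = {r for l in sc["ss"].hairpin_loops() for r in l.residues}
        inter = [p for p in sc["pairs"] if p.a in loops and p.b in loops
                 and p.canonical]
        keep_one = [p for p in sc["pairs"] if p not in inter[1:]]
        kls = tm.detect_kissing_loops(sc["ss"], keep_one)
        assert kls == []


class TestKinkTurn:
    def test_straight_helix_is_not_a_kink_turn(self, scenes):
        sc = scenes("helix4")
        assert tm.detect_kink_turn(sc["model"], sc["ss"], sc["pairs"]) == []

    def test_planted_kink_turn(self, scenes):
        sc = scenes("kink_turn")
        kts = tm.detect_kink_turn(sc["model"], sc["ss"], sc["pairs"])
        assert len(kts) == 1
        kt = kts[0]
        assert len(kt.ga_pairs) == 2
        assert [r[1] for r in kt.bulge] == [4, 5, 6]
        assert kt.axis_angle <= DEFAULT_CONFIG.kink_axis_max_angle


class TestLoopReceptor:
    def test_planted_loop_receptor(self, scenes):
        sc = scenes("loop_receptor")
        ams = tm.detect_a_minor(
            sc["model"], sc["pairs"], sc["hbonds"], order=sc["order"]
        )
        zs = tm.detect_ribose_zipper(sc["model"], sc["hbonds"])
        lrs = tm.detect_loop_receptor(sc["ss"], ams, zs)
        assert len(lrs) == 1
        lr = lrs[0]
        assert lr.loop_size == 4
        assert lr.zipper is not None
        assert len(lr.a_minors) == 1

    def test_zipper_without_a_minor_is_not_enough(self, scenes):
        sc = scenes("loop_receptor")
        zs = tm.detect_ribose_zipper(sc["model"], sc["hbonds"])
        assert tm.detect_loop_receptor(sc["ss"], [], zs) == []


def test_motif_lists_are_duplicate_free(scenes):
    for name in ("triple", "aminor_I", "zipper", "kissing", "kink_turn"):
        sc = scenes(name)
        triples = tm.detect_triples(sc["model"], sc["pairs"], sc["frames"])
        keys = [t.key for t in triples]
        assert len(keys) == len(set(keys))
        ams = tm.detect_a_minor(
            sc["model"], sc["pairs"], sc["hbonds"], order=sc["order"]
        )
        donors = [a.donor for a in ams]
        assert len(donors) == len(set(donors))
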