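import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ribomotif.config import DEFAULT_CONFIG
from ribomotif.pairing import (
    classify_pair,
    detect_base_pairs,
    detect_hbonds,
)
from ribomotif.structure_model import (
    Atom,
    Nucleotide,
    StructureModel,
    base_frames,
)
from ribomotif.synthetic_data import GeometrySpec, build_motif, ideal_base, place_pair

from .oracles import brute_force_base_base_bonds, brute_force_hbond_pairs


def _model(nucs, sid="test"):
    return StructureModel(id=sid, nucleotides=list(nucs))


def _base_base(hbonds):
    return [
        h for h in hbonds
        if h.donor_moiety == "base" and h.acceptor_moiety == "base"
    ]


def test_gc_wc_has_exactly_three_base_bonds():
    g, c = place_pair("G", "C", "WC")
    hb = _base_base(detect_hbonds(_model([g, c])))
    atom_pairs = {frozenset((h.donor[1], h.acceptor[1])) for h in hb}
    assert atom_pairs == {
        frozenset(("O6", "N4")),
        frozenset(("N1", "N3")),
        frozenset(("N2", "O2")),
    }


def test_au_wc_has_exactly_two_base_bonds():
    a, u = place_pair("A", "U", "WC")
    hb = _base_base(detect_hbonds(_model([a, u])))
    atom_pairs = {frozenset((h.donor[1], h.acceptor[1])) for h in hb}
    assert atom_pairs == {frozenset(("N6", "O4")), frozenset(("N1", "N3"))}


def test_distant_bases_have_no_bonds():
    g = Nucleotide(chain="A", number=1, icode="", raw_name="G", base="G",
                   atoms=ideal_base("G"))
    far = [Atom(a.name, a.element, a.position + np.array([10.0, 0, 0]))
           for a in ideal_base("C")]
    c = Nucleotide(chain="A", number=2, icode="", raw_name="C", base="C",
                   atoms=far)
    assert detect_hbonds(_model([g, c])) == []


@pytest.mark.parametrize(
    "b1,b2,geometry,edges,canonical,wobble",
    [
        ("G", "C", "WC", ("WatsonCrick", "WatsonCrick"), True, False),
        ("A", "U", "WC", ("WatsonCrick", "WatsonCrick"), True, False),
        ("G", "U", "GU_wobble", ("WatsonCrick", "WatsonCrick"), False, True),
        ("G", "A", "sheared_GA", ("Sugar", "Hoogsteen"), False, False),
    ],
)
def test_classify_named_geometries(b1, b2, geometry, edges, canonical, wobble):
    n1, n2 = place_pair(b1, b2, geometry)
    m = _model([n1, n2])
    pairs = detect_base_pairs(m)
    assert len(pairs) == 1
    p = pairs[0]
    got = (p.edge_of(n1.rid), p.edge_of(n2.rid))
    assert got == edges
    assert p.canonical == canonical
    assert p.wobble == wobble
    if geometry == "WC":
        assert p.orientation == "cis"


def test_single_hbond_contact_is_not_a_pair():
    a, u = place_pair("A", "U", "WC")
    # removing U:O4 leaves only the N1-N3 bond
    u.atoms = [at for at in u.atoms if at.name != "O4"]
    m = _model([a, u])
    frames = base_frames(m)
    hb = detect_hbonds(m, DEFAULT_CONFIG, frames)
    pair = classify_pair(a, u, hb, frames)
    assert pair is None


def test_helix_has_one_canonical_pair_per_step(scenes):
    pairs = scenes("helix4")["pairs"]
    assert len(pairs) == 4
    assert all(p.canonical for p in pairs)


def test_triple_fixture_two_pairs_share_center(scenes):
    pairs = scenes("triple")["pairs"]
    assert len(pairs) == 2
    shared = set.intersection(*({p.a, p.b} for p in pairs))
    assert len(shared) == 1


def test_empty_model_yields_no_pairs():
    g = Nucleotide(chain="A", number=1, icode="", raw_name="G", base="G",
                   atoms=ideal_base("G"))
    assert detect_base_pairs(_model([g])) == []


def test_pair_set_invariant_under_residue_order_reversal(scenes):
    m = scenes("kissing")["model"]
    pairs1 = {p.key for p in detect_base_pairs(m)}
    reversed_model = StructureModel(
        id="rev", nucleotides=list(reversed([
            Nucleotide(chain=n.chain, number=n.number, icode=n.icode,
                       raw_name=n.raw_name, base=n.base, atoms=n.atoms)
            for n in m.nucleotides
        ]))
    )
    pairs2 = {p.key for p in detect_base_pairs(reversed_model)}
    assert pairs1 == pairs2


@pytest.mark.parametrize("seed", [0, 7])
def test_pairs_invariant_under_rigid_transform(scenes, seed):
    m = scenes("triple")["model"]
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-30, 30, 3)
    moved = StructureModel(
        id="moved",
        nucleotides=[
            Nucleotide(
                chain=n.chain, number=n.number, icode=n.icode,
                raw_name=n.raw_name, base=n.base,
                atoms=[Atom(a.name, a.element, R @ a.position + t)
                       for a in n.atoms],
            )
            for n in m.nucleotides
        ],
    )
    ref = {(p.key, p.edge_a, p.edge_b, p.orientation) for p in detect_base_pairs(m)}
    got = {(p.key, p.edge_a, p.edge_b, p.orientation)
           for p in detect_base_pairs(moved)}
    assert ref == got
    d_ref = {(h.donor, h.acceptor): round(h.distance, 6)
             for h in detect_hbonds(m)}
    d_got = {(h.donor, h.acceptor): round(h.distance, 6)
             for h in detect_hbonds(moved)}
    assert d_ref == d_got


@pytest.mark.parametrize("scene_name", ["triple", "helix4", "aminor_I", "zipper"])
def test_hbond_residue_pairs_match_brute_force(scenes, scene_name):
    """The KD-tree contact search finds the same bonded residue pairs as an
    exhaustive all-pairs scan with the same criteria."""
    sc = scenes(scene_name)
    m = sc["model"]
    assert len(m) <= 20
    got = {h.residues for h in sc["hbonds"]}
    expected = brute_force_hbond_pairs(m, DEFAULT_CONFIG)
    assert got == expected


@pytest.mark.parametrize("scene_name", ["triple", "helix4", "kink_turn"])
def test_pair_list_matches_brute_force_filter(scenes, scene_name):
    """Accepted pairs = residue pairs with >=2 base-base bonds and base
    planes within the pairing cutoff, checked by direct enumeration."""
    sc = scenes(scene_name)
    m, frames = sc["model"], sc["frames"]
    from ribomotif.structure_model import plane_angle

    counts = brute_force_base_base_bonds(m, DEFAULT_CONFIG)
    expected = set()
    for key, n in counts.items():
        if n < DEFAULT_CONFIG.pair_min_hbonds:
            continue
        ra, rb = sorted(key)
        fa, fb = frames.get(ra), frames.get(rb)
        if fa is None or fb is None:
            continue
        if plane_angle(fa.normal, fb.normal) <= DEFAULT_CONFIG.pair_planarity_max:
            expected.add(key)
    got = {p.key for p in sc["pairs"]}
    assert got == expected
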