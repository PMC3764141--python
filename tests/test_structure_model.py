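import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ribomotif.structure_model import (
    Atom,
    EmptyModelError,
    FrameUnavailableError,
    Nucleotide,
    StructureModel,
    compute_base_frame,
    extract_sequence,
    load_structure,
    standardize_base,
)
from ribomotif.synthetic_data import (
    GeometrySpec,
    build_motif,
    ideal_base,
    write_pdb,
)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("G", "G"), ("A", "A"), ("C", "C"), ("U", "U"),
        ("PSU", "U"), ("1MA", "A"), ("5MC", "C"), ("OMG", "G"),
        ("DT", "U"), ("XYZ", "UNKNOWN"), ("", "UNKNOWN"),
    ],
)
def test_standardize_base(raw, expected):
    assert standardize_base(raw) == expected


def _nuc(base, chain="A", number=1, atoms=None):
    return Nucleotide(
        chain=chain, number=number, icode="", raw_name=base, base=base,
        atoms=atoms if atoms is not None else ideal_base(base),
    )


def test_pdb_round_trip(tmp_path):
    m = build_motif(GeometrySpec(kind="hairpin"))
    p = tmp_path / "hairpin.pdb"
    write_pdb(m, p)
    m2 = load_structure(p, fmt="PDB")
    assert len(m2) == len(m)
    for n1, n2 in zip(m.nucleotides, m2.nucleotides):
        assert (n1.chain, n1.number, n1.base) == (n2.chain, n2.number, n2.base)
        for a1 in n1.atoms:
            a2 = n2.atom(a1.name)
            assert a2 is not None
            assert np.allclose(a1.position, a2.position, atol=1e-3)


def test_load_rejects_waters_only(tmp_path):
    p = tmp_path / "water.pdb"
    p.write_text(
        "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
        "END\n"
    )
    with pytest.raises(EmptyModelError):
        load_structure(p)


def test_load_missing_file():
    from ribomotif.structure_model import StructureParseError

    with pytest.raises(StructureParseError):
        load_structure("/nonexistent/file.pdb")


def test_base_frame_planar_template():
    n = _nuc("G")
    frame = compute_base_frame(n)
    from ribomotif.structure_model import RING_ATOMS

    for name in RING_ATOMS["G"]:
        d = abs(float(np.dot(n.atom_pos(name) - frame.origin, frame.normal)))
        assert d < 0.01
    # orthonormal right-handed frame
    assert np.allclose(np.dot(frame.x_axis, frame.normal), 0, atol=1e-6)
    assert np.allclose(np.cross(frame.normal, frame.x_axis), frame.y_axis, atol=1e-6)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_base_frame_rotation_equivariance(seed):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-20, 20, 3)
    n = _nuc("A")
    f0 = compute_base_frame(n)
    n2 = _nuc(
        "A",
        atoms=[Atom(a.name, a.element, R @ a.position + t) for a in n.atoms],
    )
    f2 = compute_base_frame(n2)
    assert np.allclose(f2.normal, R @ f0.normal, atol=1e-9)  # sign preserved too
    assert np.allclose(f2.origin, R @ f0.origin + t, atol=1e-9)


def test_base_frame_too_few_ring_atoms():
    n = _nuc("G")
    keep = {"N9", "C8", "N7", "C1'", "O2'"}
    n.atoms = [a for a in n.atoms if a.name in keep]
    with pytest.raises(FrameUnavailableError):
        compute_base_frame(n)


def test_extract_sequence_and_map():
    m = build_motif(GeometrySpec(kind="hairpin"))
    seq, rmap = extract_sequence(m, "A")
    assert len(seq) == len(rmap) == len(m)
    assert set(seq) <= set("ACGU")
    # empty chain id on single-chain model selects it
    seq2, _ = extract_sequence(m, "")
    assert seq2 == seq
    with pytest.raises(KeyError):
        extract_sequence(m, "Z")


def test_extract_sequence_stable_under_atom_permutation():
    m = build_motif(GeometrySpec(kind="helix", params={"n": 3}))
    seq1, map1 = extract_sequence(m, "A")
    shuffled = StructureModel(
        id="perm",
        nucleotides=[
            Nucleotide(
                chain=n.chain, number=n.number, icode=n.icode,
                raw_name=n.raw_name, base=n.base,
                atoms=list(reversed(n.atoms)),
            )
            for n in m.nucleotides
        ],
    )
    seq2, map2 = extract_sequence(shuffled, "A")
    assert seq1 == seq2 and map1 == map2
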