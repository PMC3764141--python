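import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ribomotif.structure_model import Atom, Nucleotide, StructureModel
from ribomotif.superposition import (
    CorrespondenceSet,
    kabsch,
    match_residues,
    superpose,
)
from ribomotif.synthetic_data import GeometrySpec, build_motif


def _transformed_copy(m, R, t, jitter=0.0, rng=None):
    nucs = []
    for n in m.nucleotides:
        atoms = []
        for a in n.atoms:
            pos = R @ a.position + t
            if jitter and rng is not None:
                pos = pos + rng.normal(0, jitter, 3)
            atoms.append(Atom(a.name, a.element, pos))
        nucs.append(
            Nucleotide(chain=n.chain, number=n.number, icode=n.icode,
                       raw_name=n.raw_name, base=n.base, atoms=atoms)
        )
    return StructureModel(id=m.id + "_copy", nucleotides=nucs)


@pytest.fixture(scope="module")
def helix():
    return build_motif(GeometrySpec(kind="helix", params={"n": 4}))


def test_self_match_covers_every_residue(helix):
    c = match_residues(helix, helix)
    assert len(c) == len(helix)


def test_match_with_missing_residues(helix):
    truncated = StructureModel(
        id="trunc", nucleotides=[
            Nucleotide(chain=n.chain, number=n.number, icode=n.icode,
                       raw_name=n.raw_name, base=n.base, atoms=n.atoms)
            for n in helix.nucleotides[:-2]
        ]
    )
    c = match_residues(helix, truncated)
    assert len(c) == len(helix) - 2


def test_self_superposition_is_identity(helix):
    c = match_residues(helix, helix)
    r = superpose(c, helix, helix)
    assert r.rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(r.rotation, np.eye(3), atol=1e-9)


@pytest.mark.parametrize("seed", [0, 3, 8])
def test_rigid_copy_recovers_zero_rmsd(helix, seed):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-50, 50, 3)
    moved = _transformed_copy(helix, R, t)
    c = match_residues(helix, moved)
    res = superpose(c, helix, moved)
    assert res.rmsd == pytest.approx(0.0, abs=1e-6)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)


def test_rmsd_invariant_under_pre_transform(helix):
    rng = np.random.default_rng(42)
    noisy = _transformed_copy(helix, np.eye(3), np.zeros(3), jitter=0.5, rng=rng)
    c = match_residues(helix, noisy)
    base = superpose(c, helix, noisy, prune_cutoff=None).rmsd
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-30, 30, 3)
    moved = _transformed_copy(noisy, R, t)
    c2 = match_residues(helix, moved)
    again = superpose(c2, helix, moved, prune_cutoff=None).rmsd
    assert again == pytest.approx(base, abs=1e-6)


def test_pruning_never_increases_rmsd(helix):
    rng = np.random.default_rng(7)
    noisy = _transformed_copy(helix, np.eye(3), np.zeros(3), jitter=0.4, rng=rng)
    # displace one residue far so pruning has something to discard
    outlier = noisy.nucleotides[0]
    outlier.atoms = [
        Atom(a.name, a.element, a.position + np.array([15.0, 0, 0]))
        for a in outlier.atoms
    ]
    c = match_residues(helix, noisy)
    free = superpose(c, helix, noisy, prune_cutoff=None)
    pruned = superpose(c, helix, noisy, prune_cutoff=2.0)
    assert pruned.rmsd <= free.rmsd
    assert pruned.n_matched < free.n_matched


def test_too_few_correspondences_rejected(helix):
    c = CorrespondenceSet(pairs=[(helix.nucleotides[0].rid,) * 2])
    with pytest.raises(ValueError):
        superpose(c, helix, helix)


@pytest.mark.parametrize("seed", range(4))
def test_kabsch_beats_random_rotations(seed):
    """Monte-Carlo lower bound: no random rotation fits 5-point clouds
    better than the closed-form solution."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 5, (5, 3))
    y = rng.normal(0, 5, (5, 3))
    _R, _t, best = kabsch(x, y)
    cx, cy = x.mean(0), y.mean(0)
    x0, y0 = x - cx, y - cy
    for _ in range(2000):
        R = Rotation.random(random_state=rng).as_matrix()
        rmsd = float(np.sqrt(((x0 @ R.T - y0) ** 2).sum() / len(x)))
        assert rmsd >= best - 1e-9
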