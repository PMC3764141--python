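"""Synthetic structures and alignments with known ground truth.

Every detector in the package is exercised against geometry built here:
idealized planar base templates (standard-reference-frame coordinates with
short sugar/phosphate stubs) are assembled into pairs, helices, triples,
A-minor docks, ribose zippers, kink-turns, kissing loops and pseudoknotted
topologies by constrained rigid placement -- a fragment is rotated and
translated until the named donor-acceptor distances sit at hydrogen-bond
range while avoiding steric clashes.  No energy model is involved: the
geometry only has to satisfy the detectors' published criteria, and the
closure property (the planted motif, and nothing else of its class, is
recovered) is the central test surface.

The module also packages the published base-triple census as a
machine-readable fixture (:func:`reference_triple_census`) and generates alignments
with planted per-column conservation (:func:`make_alignment`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .config import DEFAULT_CONFIG, DetectionConfig
from .structure_model import Atom, Nucleotide, StructureModel

__all__ = [
    "GeometrySpec",
    "CensusRecord",
    "ideal_base",
    "place_pair",
    "build_helix",
    "build_motif",
    "make_alignment",
    "reference_triple_census",
    "write_pdb",
    "write_fixture_set",
]

# ---------------------------------------------------------------------------
# idealized planar base templates (standard reference frame, z = 0)
# ---------------------------------------------------------------------------

_BASE_XY: Dict[str, Dict[str, Tuple[float, float]]] = {
    "A": {
        "N9": (-1.291, 4.498), "C8": (0.024, 4.897), "N7": (0.877, 3.902),
        "C5": (0.071, 2.771), "C6": (0.369, 1.398), "N6": (1.611, 0.909),
        "N1": (-0.668, 0.532), "C2": (-1.912, 1.023), "N3": (-2.320, 2.290),
        "C4": (-1.267, 3.124),
    },
    "G": {
        "N9": (-1.289, 4.551), "C8": (0.023, 4.962), "N7": (0.870, 3.969),
        "C5": (0.071, 2.833), "C6": (0.424, 1.460), "O6": (1.554, 0.955),
        "N1": (-0.700, 0.641), "C2": (-1.999, 1.087), "N2": (-2.949, 0.139),
        "N3": (-2.342, 2.364), "C4": (-1.265, 3.177),
    },
    "C": {
        "N1": (-1.285, 4.542), "C2": (-1.472, 3.158), "O2": (-2.628, 2.709),
        "N3": (-0.391, 2.344), "C4": (0.837, 2.868), "N4": (1.875, 2.027),
        "C5": (1.056, 4.275), "C6": (-0.023, 5.068),
    },
    "U": {
        "N1": (-1.284, 4.500), "C2": (-1.462, 3.131), "O2": (-2.563, 2.608),
        "N3": (-0.302, 2.397), "C4": (0.989, 2.884), "O4": (1.935, 2.094),
        "C5": (1.089, 4.311), "C6": (-0.024, 5.053),
    },
}


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _sugar_stubs() -> List[Tuple[str, np.ndarray]]:
    """C1'/C2'/O2'/C4'/P stub positions shared by all four templates.

    The ribose is not built realistically (backbone closure is out of
    scope); the stubs provide a glycosidic attachment point and an O2'
    whose position can carry sugar-mediated hydrogen bonds.
    """
    c1 = np.array([-2.477, 5.399, 0.000])
    out = _unit([-0.55, 0.83, 0.0])  # radially away from the base, toward the groove
    c2 = c1 + 1.53 * _unit(out + [0.0, 0.0, 0.45])
    # hydroxyl turned back toward the sugar edge: N3...O2' ~ 4.2 A as in an
    # anti nucleoside, with C2' well off the N3-O2' axis
    o2 = c2 + 1.42 * _unit([-0.75, -0.60, 0.28])
    c4 = c1 + 2.35 * _unit([-0.35, -0.85, 0.39])  # 5' side, clear of O2'
    p = c4 + 2.55 * _unit([-0.30, -0.80, 0.52])
    return [("C1'", c1), ("C2'", c2), ("O2'", o2), ("C4'", c4), ("P", p)]


_ELEMENT = {"N": "N", "C": "C", "O": "O", "P": "P"}


def _element_of(name: str) -> str:
    return _ELEMENT[name[0]]


def ideal_base(base: str) -> List[Atom]:
    """Heavy-atom template for one nucleotide: planar base + stubs."""
    if base not in _BASE_XY:
        raise ValueError(f"no template for base {base!r} (need A/C/G/U)")
    atoms = [
        Atom(name=n, element=_element_of(n), position=np.array([x, y, 0.0]))
        for n, (x, y) in _BASE_XY[base].items()
    ]
    atoms.extend(
        Atom(name=n, element=_element_of(n), position=p) for n, p in _sugar_stubs()
    )
    return atoms


def _transform_atoms(atoms: Sequence[Atom], R: np.ndarray, t: np.ndarray) -> List[Atom]:
    return [
        Atom(name=a.name, element=a.element, position=R @ a.position + t)
        for a in atoms
    ]


def _nucleotide(base: str, chain: str, number: int, atoms: Sequence[Atom]) -> Nucleotide:
    return Nucleotide(
        chain=chain, number=number, icode="", raw_name=base, base=base,
        atoms=list(atoms),
    )


# ---------------------------------------------------------------------------
# constrained rigid placement
# ---------------------------------------------------------------------------

_CLASH_DIST = 2.5
_HB_TARGET = 2.9


def _fit_fragment(
    mobile: np.ndarray,
    constraints: Sequence[Tuple[int, np.ndarray, float]],
    fixed_clash: np.ndarray,
    starts: Sequence[Tuple[np.ndarray, np.ndarray]],
    coplanar: Optional[Tuple[np.ndarray, np.ndarray, Sequence[int]]] = None,
    repel: Sequence[Tuple[int, np.ndarray, float]] = (),
    mobile_clash_idx: Optional[Sequence[int]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Rigidly place ``mobile`` points so each constraint (index, target,
    distance) is satisfied, clashes with ``fixed_clash`` are avoided and,
    optionally, selected points stay in a given plane (origin, normal).
    ``repel`` entries (index, point, min_distance) keep covalent neighbours
    of bonded atoms out of the way, which forces near-linear donor geometry.

    Returns the best (rotation matrix, translation); raises if no start
    converges to bond errors below 0.1 A.
    """
    clash_rows = (np.arange(len(mobile)) if mobile_clash_idx is None
                  else np.asarray(mobile_clash_idx, dtype=int))

    def residuals(params: np.ndarray) -> np.ndarray:
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        t = params[3:]
        pts = mobile @ R.T + t
        res = []
        for idx, target, dist in constraints:
            res.append(3.0 * (np.linalg.norm(pts[idx] - target) - dist))
        if len(fixed_clash):
            d = np.linalg.norm(
                pts[clash_rows][:, None, :] - fixed_clash[None, :, :], axis=2
            )
            res.extend(np.maximum(0.0, _CLASH_DIST - d).ravel())
        for idx, point, dmin in repel:
            d = float(np.linalg.norm(pts[idx] - point))
            res.append(2.0 * max(0.0, dmin - d))
        if coplanar is not None:
            origin, normal, idxs = coplanar
            for i in idxs:
                res.append(float(np.dot(pts[i] - origin, normal)))
        return np.asarray(res)

    # Stage 1: satisfy the bond constraints alone (smooth problem), then
    # spin converged poses about the axis through the two bonded atoms --
    # the internal degree of freedom that relieves clash/repel terms.
    def bond_residuals(params: np.ndarray) -> np.ndarray:
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        t = params[3:]
        pts = mobile @ R.T + t
        res = [
            3.0 * (np.linalg.norm(pts[idx] - target) - dist)
            for idx, target, dist in constraints
        ]
        if coplanar is not None:
            origin, normal, idxs = coplanar
            res.extend(float(np.dot(pts[i] - origin, normal)) for i in idxs)
        while len(res) < 6:  # lm needs >= as many residuals as parameters
            res.append(0.0)
        return np.asarray(res)

    expanded: List[Tuple[np.ndarray, np.ndarray]] = []
    if len(constraints) >= 2 and coplanar is None:
        expanded.extend(_constructive_seeds(mobile, constraints))
    for rotvec, trans in starts:
        sol = least_squares(bond_residuals, np.concatenate([rotvec, trans]),
                            method="lm", max_nfev=200)
        expanded.append((sol.x[:3], sol.x[3:]))

    # optimize the most promising seeds first; stop at the first clean fit
    expanded.sort(
        key=lambda rt: float(
            np.sum(residuals(np.concatenate([rt[0], rt[1]])) ** 2)
        )
    )
    best = None
    best_cost = np.inf
    for rotvec, trans in expanded[:80]:
        x0 = np.concatenate([rotvec, trans])
        sol = least_squares(residuals, x0, method="lm", max_nfev=400)
        R = Rotation.from_rotvec(sol.x[:3]).as_matrix()
        t = sol.x[3:]
        pts = mobile @ R.T + t
        bond_err = max(
            abs(np.linalg.norm(pts[i] - target) - dist)
            for i, target, dist in constraints
        )
        clash = 0.0
        if len(fixed_clash):
            d = np.linalg.norm(
                pts[clash_rows][:, None, :] - fixed_clash[None, :, :], axis=2
            )
            clash = float(np.maximum(0.0, _CLASH_DIST - 0.1 - d).max())
        repel_err = 0.0
        for idx, point, dmin in repel:
            d = float(np.linalg.norm(pts[idx] - point))
            repel_err = max(repel_err, max(0.0, dmin - 0.1 - d))
        cost = bond_err + 10.0 * clash + 2.0 * repel_err
        if bond_err < 0.1 and clash <= 0.0 and repel_err <= 0.05 and cost < best_cost:
            best, best_cost = (R, t), cost
            if cost < 0.02:
                break
    if best is None:
        raise ValueError("constrained placement failed to converge")
    return best


def _fib_sphere(n: int) -> np.ndarray:
    """n roughly uniform unit vectors (Fibonacci lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def _sphere_circle(c1, r1, c2, r2):
    """Intersection circle of two spheres: (center, radius, e1, e2) or None."""
    u = c2 - c1
    d = float(np.linalg.norm(u))
    if d < 1e-9 or d > r1 + r2 or d < abs(r1 - r2):
        return None
    u = u / d
    a = (r1 * r1 - r2 * r2 + d * d) / (2.0 * d)
    h2 = r1 * r1 - a * a
    if h2 < 0:
        return None
    center = c1 + a * u
    e1 = np.cross(u, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(u, [0.0, 1.0, 0.0])
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return center, math.sqrt(h2), e1, e2


def _two_point_transform(q1, q2, p1, p2, spin_deg):
    """Rigid transform mapping local points q1->p1, q2->p2 (up to spin about
    the p1-p2 axis, set by ``spin_deg``)."""
    vm = q2 - q1
    vt = p2 - p1
    nm, nt = np.linalg.norm(vm), np.linalg.norm(vt)
    if nm < 1e-9 or nt < 1e-9:
        return None
    R0, _ = Rotation.align_vectors(vt[None, :] / nt, vm[None, :] / nm)
    axis = vt / nt
    S = Rotation.from_rotvec(np.radians(spin_deg) * axis)
    R = (S * R0).as_matrix()
    t = p1 - R @ q1
    return Rotation.from_matrix(R).as_rotvec(), t


def _constructive_seeds(
    mobile: np.ndarray,
    constraints: Sequence[Tuple[int, np.ndarray, float]],
    n_dirs: int = 40,
    n_circle: int = 6,
    n_spin: int = 6,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Deterministic seed poses that satisfy the first two distance
    constraints exactly: the first bonded atom is swept over its constraint
    sphere, the second over the compatible circle, and the remaining spin
    degree of freedom is sampled uniformly."""
    (i1, t1, d1), (i2, t2, d2) = constraints[0], constraints[1]
    q1, q2 = mobile[i1], mobile[i2]
    L = float(np.linalg.norm(q2 - q1))
    seeds: List[Tuple[np.ndarray, np.ndarray]] = []
    if L < 1e-6:
        # both constraints pin the same atom: place it on the intersection
        # circle of the two spheres; point the fragment body away from the
        # midpoint of the two targets and sweep the remaining spin
        circ = _sphere_circle(t1, d1, t2, d2)
        if circ is None:
            return []
        center, radius, e1, e2 = circ
        mid = 0.5 * (t1 + t2)
        v_m = mobile.mean(axis=0) - q1
        rng = np.random.default_rng(1234)
        for j in range(12):
            ang = 2.0 * np.pi * j / 12
            p = center + radius * (math.cos(ang) * e1 + math.sin(ang) * e2)
            v_t = p - mid
            nt = np.linalg.norm(v_t)
            nm = np.linalg.norm(v_m)
            if nt < 1e-9 or nm < 1e-9:
                continue
            R0, _ = Rotation.align_vectors(v_t[None, :] / nt, v_m[None, :] / nm)
            axis = v_t / nt
            for s in range(8):
                S_rot = Rotation.from_rotvec(np.radians(45.0 * s) * axis)
                R = (S_rot * R0).as_matrix()
                seeds.append((Rotation.from_matrix(R).as_rotvec(), p - R @ q1))
            for _ in range(4):
                R = Rotation.random(random_state=rng)
                seeds.append((R.as_rotvec(), p - R.apply(q1)))
        return seeds
    for u in _fib_sphere(n_dirs):
        p1 = t1 + d1 * u
        circ = _sphere_circle(p1, L, t2, d2)
        if circ is None:
            continue
        center, radius, e1, e2 = circ
        for j in range(n_circle):
            ang = 2.0 * np.pi * j / n_circle
            p2 = center + radius * (math.cos(ang) * e1 + math.sin(ang) * e2)
            for s in range(n_spin):
                tr = _two_point_transform(q1, q2, p1, p2, 360.0 * s / n_spin)
                if tr is not None:
                    seeds.append(tr)
    return seeds


_REPEL_DIST = 3.85  # keeps donor/acceptor antecedents back => near-linear bonds


def _repel_dist(bond_len: float) -> float:
    """Antecedent-to-partner distance implying a donor angle comfortably
    above the 110-degree hydrogen-bond criterion (1.4 A antecedent bond)."""
    return math.sqrt(1.96 + bond_len * bond_len + 0.957 * bond_len) + 0.12


_CLASH_EXEMPT = {"P", "C4'", "C1'"}  # coarse stubs: excluded from steric screening


def _clash_idx(atoms: Sequence[Atom]) -> List[int]:
    return [i for i, a in enumerate(atoms) if a.name not in _CLASH_EXEMPT]


def _clash_positions(nucs: Sequence[Nucleotide]) -> np.ndarray:
    return np.array(
        [a.position for nuc in nucs for a in nuc.atoms if a.name not in _CLASH_EXEMPT]
    )


def _neighbors(atoms: Sequence[Atom], name: str) -> List[str]:
    """Covalently bonded heavy-atom neighbours, inferred from distances."""
    center = next(a.position for a in atoms if a.name == name)
    out = []
    for a in atoms:
        if a.name == name:
            continue
        d = float(np.linalg.norm(a.position - center))
        if d < 1.8:
            out.append(a.name)
    return out


def _is_donor_atom(base: str, atom: str) -> bool:
    from .pairing import BASE_DONORS

    return atom == "O2'" or atom in BASE_DONORS.get(base, {})


def _bond_repel_entries(
    mobile_atoms: Sequence[Atom],
    mobile_base: str,
    idx: Dict[str, int],
    mobile_atom: str,
    env_atoms: Sequence[Atom],
    env_base: str,
    env_pos_of,
    env_atom: str,
    dist: float,
) -> List[Tuple[int, np.ndarray, float]]:
    """Repel terms enforcing a >=110-degree angle at whichever side donates.

    Only the donor's antecedents constrain the hydrogen-bond geometry; the
    acceptor side is free.  When both sides could donate (O2'-O2'), one
    passing direction suffices, so only the mobile side is constrained.
    """
    rd = _repel_dist(dist)
    entries: List[Tuple[int, np.ndarray, float]] = []
    if _is_donor_atom(mobile_base, mobile_atom):
        for nb in _neighbors(mobile_atoms, mobile_atom):
            entries.append((idx[nb], env_pos_of(env_atom), rd))
    elif _is_donor_atom(env_base, env_atom):
        for nb in _neighbors(env_atoms, env_atom):
            entries.append((idx[mobile_atom], env_pos_of(nb), rd))
    return entries


def _pair_starts() -> List[Tuple[np.ndarray, np.ndarray]]:
    """Start poses covering both faces and a fan of in-plane rotations."""
    starts = []
    for flip in (True, False):
        for deg in range(0, 360, 45):
            rot = Rotation.from_euler("z", deg, degrees=True)
            if flip:
                rot = rot * Rotation.from_euler("x", 180, degrees=True)
            for off in (np.array([8.0, 0.0, 0.0]), np.array([0.0, -8.0, 0.0]),
                        np.array([-8.0, 0.0, 0.0])):
                starts.append((rot.as_rotvec(), off))
    return starts


# hydrogen-bond blueprints per named pair geometry: (atom_of_b1, atom_of_b2)
PAIR_GEOMETRIES: Dict[str, Dict[Tuple[str, str], List[Tuple[str, str]]]] = {
    "WC": {
        ("G", "C"): [("O6", "N4"), ("N1", "N3"), ("N2", "O2")],
        ("A", "U"): [("N6", "O4"), ("N1", "N3")],
    },
    "GU_wobble": {
        ("G", "U"): [("O6", "N3"), ("N1", "O2")],
    },
    "sheared_GA": {
        ("G", "A"): [("N3", "N6"), ("N2", "N7")],
    },
    # Hoogsteen face of A paired to WC face of U (as in U-A-U triples)
    "hoogsteen_AU": {
        ("A", "U"): [("N7", "N3"), ("N6", "O4")],
    },
    # the "amino-N3, N1-amino" A-to-G pairing of the common AGC triple
    "AG_amino": {
        ("A", "G"): [("N6", "N3"), ("N1", "N2")],
    },
}


def _pair_bonds(b1: str, b2: str, geometry: str) -> Tuple[List[Tuple[str, str]], bool]:
    """Bond list for (b1, b2); second value: whether the roles are swapped."""
    table = PAIR_GEOMETRIES.get(geometry)
    if table is None:
        raise ValueError(f"unknown pair geometry {geometry!r}")
    if (b1, b2) in table:
        return table[(b1, b2)], False
    if (b2, b1) in table:
        return [(y, x) for x, y in table[(b2, b1)]], True
    raise ValueError(f"geometry {geometry!r} undefined for bases {b1}-{b2}")


def place_pair(
    b1: str,
    b2: str,
    geometry: str = "WC",
    chain: str = "A",
    numbers: Tuple[int, int] = (1, 2),
) -> Tuple[Nucleotide, Nucleotide]:
    """Two nucleotides in the named pairing geometry.

    The first base sits in its standard frame (plane z = 0); the partner is
    rigidly fitted so the geometry's donor-acceptor distances land at
    hydrogen-bond range (about 2.9 A) in the same plane.
    """
    R, t = _fit_pair_cached(b1, b2, geometry)
    atoms1 = ideal_base(b1)
    atoms2 = ideal_base(b2)
    n1 = _nucleotide(b1, chain, numbers[0], atoms1)
    n2 = _nucleotide(b2, chain, numbers[1], _transform_atoms(atoms2, R, t))
    return n1, n2


@lru_cache(maxsize=None)
def _fit_pair_cached(b1: str, b2: str, geometry: str) -> Tuple[np.ndarray, np.ndarray]:
    bonds, _swapped = _pair_bonds(b1, b2, geometry)
    atoms1 = ideal_base(b1)
    atoms2 = ideal_base(b2)
    pos1 = {a.name: a.position for a in atoms1}
    mobile = np.array([a.position for a in atoms2])
    name_to_idx = {a.name: i for i, a in enumerate(atoms2)}
    constraints = [
        (name_to_idx[a2], pos1[a1], _HB_TARGET) for a1, a2 in bonds
    ]
    repel = []
    for a1, a2 in bonds:
        repel.extend(
            _bond_repel_entries(
                atoms2, b2, name_to_idx, a2,
                atoms1, b1, lambda name: pos1[name], a1, _HB_TARGET,
            )
        )
    ring2 = [name_to_idx[n] for n in _BASE_XY[b2]]
    R, t = _fit_fragment(
        mobile,
        constraints,
        fixed_clash=np.array(
            [a.position for a in atoms1 if a.name not in _CLASH_EXEMPT]
        ),
        starts=_pair_starts(),
        coplanar=(np.zeros(3), np.array([0.0, 0.0, 1.0]), ring2),
        repel=repel,
        mobile_clash_idx=_clash_idx(atoms2),
    )
    return R, t


# ---------------------------------------------------------------------------
# helices and topology builders
# ---------------------------------------------------------------------------

A_FORM_TWIST = 32.7   # degrees per step
A_FORM_RISE = 2.81    # Angstrom per step


def _helix_step(i: int) -> Tuple[np.ndarray, np.ndarray]:
    R = Rotation.from_euler("z", i * A_FORM_TWIST, degrees=True).as_matrix()
    t = np.array([0.0, 0.0, i * A_FORM_RISE])
    return R, t


def build_helix(
    pair_seq: Sequence[Tuple[str, str]],
    chain: str = "A",
    numbers5: Optional[Sequence[int]] = None,
    numbers3: Optional[Sequence[int]] = None,
    base_transform: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> List[Nucleotide]:
    """Stack Watson-Crick/wobble pairs into an idealized A-form helix.

    ``numbers5``/``numbers3`` give author numbers of the two strands (the
    3' strand pairs in reverse); defaults produce a nested numbering
    1..n / 2n..n+1.
    """
    n = len(pair_seq)
    if numbers5 is None:
        numbers5 = list(range(1, n + 1))
    if numbers3 is None:
        numbers3 = list(range(2 * n, n, -1))
    nucleotides: List[Nucleotide] = []
    for i, (b5, b3) in enumerate(pair_seq):
        geometry = "GU_wobble" if frozenset((b5, b3)) == frozenset("GU") else "WC"
        n5, n3 = place_pair(b5, b3, geometry, chain=chain,
                            numbers=(numbers5[i], numbers3[i]))
        R, t = _helix_step(i)
        if base_transform is not None:
            Rb, tb = base_transform
            n5 = _nucleotide(b5, chain, numbers5[i],
                             _transform_atoms(_transform_atoms(n5.atoms, R, t), Rb, tb))
            n3 = _nucleotide(b3, chain, numbers3[i],
                             _transform_atoms(_transform_atoms(n3.atoms, R, t), Rb, tb))
        else:
            n5 = _nucleotide(b5, chain, numbers5[i], _transform_atoms(n5.atoms, R, t))
            n3 = _nucleotide(b3, chain, numbers3[i], _transform_atoms(n3.atoms, R, t))
        nucleotides.extend([n5, n3])
    return nucleotides


def _scatter_bases(
    bases: Sequence[str],
    chain: str,
    numbers: Sequence[int],
    origin: np.ndarray,
    spacing: float = 8.0,
) -> List[Nucleotide]:
    """Unpaired residues placed on a line, far enough apart not to bond."""
    out = []
    for k, (b, num) in enumerate(zip(bases, numbers)):
        t = origin + np.array([k * spacing, 0.0, 0.0])
        out.append(_nucleotide(b, chain, num, _transform_atoms(ideal_base(b), np.eye(3), t)))
    return out


def _dock_third_base(
    base: str,
    bonds: Sequence[Tuple[str, Tuple[str, str], float]],
    env: List[Nucleotide],
    coplanar_with: Optional[np.ndarray] = None,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Fit one extra base against an existing fragment.

    ``bonds``: (atom_of_new_base, (partner_label, partner_atom), distance)
    where partner_label indexes ``env`` by position.
    """
    atoms = ideal_base(base)
    mobile = np.array([a.position for a in atoms])
    idx = {a.name: i for i, a in enumerate(atoms)}
    env_pos = {
        (k, a.name): a.position for k, nuc in enumerate(env) for a in nuc.atoms
    }
    constraints = [
        (idx[an], env_pos[(int(pl), pa)], d) for an, (pl, pa), d in bonds
    ]
    repel = []
    for an, (pl, pa), d in bonds:
        pl = int(pl)
        repel.extend(
            _bond_repel_entries(
                atoms, base, idx, an,
                env[pl].atoms, env[pl].base,
                lambda name, _pl=pl: env_pos[(_pl, name)], pa, d,
            )
        )
    fixed = _clash_positions(env)
    coplanar = None
    if coplanar_with is not None:
        ring = [idx[n] for n in _BASE_XY[base]]
        coplanar = (np.zeros(3), coplanar_with, ring)
    rng = np.random.default_rng(seed)
    starts = list(_pair_starts())
    for _ in range(40):
        starts.append(
            (Rotation.random(random_state=rng).as_rotvec(),
             rng.uniform(-10, 10, size=3))
        )
    return _fit_fragment(mobile, constraints, fixed, starts, coplanar,
                         repel=repel, mobile_clash_idx=_clash_idx(atoms))


# ---------------------------------------------------------------------------
# motif builders
# ---------------------------------------------------------------------------


@dataclass
class GeometrySpec:
    """Declarative description of a synthetic motif scene."""

    kind: str
    bases: Tuple[str, ...] = ()
    params: Dict[str, object] = field(default_factory=dict)
    seed: int = 0


def build_motif(spec: GeometrySpec) -> StructureModel:
    """Render a :class:`GeometrySpec` into a structure model.

    Deterministic for a fixed seed; the corresponding detector recovers
    exactly the planted motif (closure property, asserted by the tests).
    """
    builders = {
        "helix": _build_helix_model,
        "hairpin": _build_hairpin_model,
        "triple": _build_triple_model,
        "tilted_triple": _build_tilted_triple_model,
        "aminor": _build_aminor_model,
        "zipper": _build_zipper_model,
        "pseudoknot": _build_pseudoknot_model,
        "kissing": _build_kissing_model,
        "kink_turn": _build_kink_turn_model,
        "loop_receptor": _build_loop_receptor_model,
    }
    if spec.kind not in builders:
        raise ValueError(f"unknown motif kind {spec.kind!r}")
    return builders[spec.kind](spec)


def _default_pairs(n: int) -> List[Tuple[str, str]]:
    cycle = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")]
    return [cycle[i % 4] for i in range(n)]


def _build_helix_model(spec: GeometrySpec) -> StructureModel:
    n = int(spec.params.get("n", 4))
    pair_seq = spec.params.get("pair_seq") or _default_pairs(n)
    nts = build_helix(pair_seq)
    return StructureModel(id=f"helix{n}", nucleotides=nts)


def _build_hairpin_model(spec: GeometrySpec) -> StructureModel:
    n = int(spec.params.get("stem", 4))
    loop = str(spec.params.get("loop", "GAAA"))
    pair_seq = spec.params.get("pair_seq") or _default_pairs(n)
    total = 2 * n + len(loop)
    numbers5 = list(range(1, n + 1))
    numbers3 = list(range(total, total - n, -1))
    nts = build_helix(pair_seq, numbers5=numbers5, numbers3=numbers3)
    loop_numbers = list(range(n + 1, n + 1 + len(loop)))
    top = np.array([0.0, 12.0, (n + 2) * A_FORM_RISE])
    nts += _scatter_bases(list(loop), "A", loop_numbers, top)
    return StructureModel(id="hairpin", nucleotides=nts)


def _build_triple_model(spec: GeometrySpec) -> StructureModel:
    """A third base docked coplanar onto one base of a WC pair.

    Default: the common AGC arrangement -- A pairs G of a G-C pair through
    its N6/N1 (amino-N3, N1-amino), all three bases in one plane.
    """
    b_pair = spec.params.get("pair", ("G", "C"))
    third = spec.params.get("third", "A")
    n1, n2 = place_pair(b_pair[0], b_pair[1], "WC", numbers=(2, 3))
    bonds = spec.params.get(
        "bonds",
        [("N6", (0, "N3"), _HB_TARGET), ("N1", (0, "N2"), _HB_TARGET)],
    )
    R, t = _dock_third_base(
        third, bonds, [n1, n2],
        coplanar_with=np.array([0.0, 0.0, 1.0]), seed=spec.seed,
    )
    n3 = _nucleotide(third, "A", 1, _transform_atoms(ideal_base(third), R, t))
    return StructureModel(id="triple", nucleotides=[n3, n1, n2])


def _build_tilted_triple_model(spec: GeometrySpec) -> StructureModel:
    """The triple fixture with the third base rotated out of plane.

    The rotation axis runs through the docked base's bonded-edge midpoint,
    so the hydrogen-bond distances survive while planarity is destroyed --
    isolating the planarity clause of the triple filter.
    """
    angle = float(spec.params.get("angle", 60.0))
    m = _build_triple_model(spec)
    third = m.nucleotides[0]
    a1 = third.atom_pos("N6")
    a2 = third.atom_pos("N1")
    pivot = 0.5 * (a1 + a2)
    axis = _unit(a1 - a2)
    R = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
    rotated = [
        Atom(a.name, a.element, R @ (a.position - pivot) + pivot)
        for a in third.atoms
    ]
    nts = [_nucleotide(third.base, third.chain, third.number, rotated)]
    nts.extend(m.nucleotides[1:])
    return StructureModel(id="tilted_triple", nucleotides=nts)


def _build_aminor_model(spec: GeometrySpec) -> StructureModel:
    """Type-I/II A-minor (or G-minor): a base docking the minor groove of a
    canonical receptor pair, embedded at the end of a short helix."""
    donor_base = str(spec.params.get("donor", "A"))
    aminor_type = str(spec.params.get("type", "I"))
    receptor = tuple(spec.params.get("receptor", ("G", "C")))
    if "G" not in receptor:
        # the synthetic minor groove is laced through G:N2/N3 -- the only
        # minor-groove donor available on heavy-atom templates
        raise ValueError("synthetic A-minor receptors must contain a G")
    gi = receptor.index("G")       # index of the guanosine within the pair
    yi = 1 - gi                    # its partner
    # receptor helix: planted pair first (5' side), then two more steps
    pair_seq = [receptor, ("C", "G"), ("G", "C")]
    nts = build_helix(pair_seq, numbers5=[11, 12, 13], numbers3=[24, 23, 22])
    rec5, rec3 = nts[0], nts[1]  # the receptor pair
    if aminor_type == "I":
        # N3 and O2' of the docking base both engaged, contacts reaching
        # both receptor residues across the minor-groove edge (G:N2 donates
        # to the docked N3; the docked O2' donates to the partner's O2)
        bonds = [
            ("N3", (gi, "N2"), _HB_TARGET),
            ("O2'", (yi, "O2"), _HB_TARGET),
        ]
    elif aminor_type == "II":
        # N3 and O2' engaged but confined to the guanosine side only
        bonds = [
            ("O2'", (gi, "N3"), _HB_TARGET),
            ("N3", (gi, "N2"), _HB_TARGET),
        ]
    elif aminor_type == "0":
        # shallow dock: only the O2' touches the receptor, at the sugar rim
        # of one residue (as in the kink-turn internal interaction)
        bonds = [
            ("O2'", (yi, "O2'"), _HB_TARGET),
            ("O2'", (yi, "O2"), 3.3),
        ]
    else:
        raise ValueError(f"unsupported A-minor type {aminor_type!r}")
    R, t = _dock_third_base(donor_base, bonds, [rec5, rec3], seed=spec.seed)
    donor = _nucleotide(donor_base, "A", 41, _transform_atoms(ideal_base(donor_base), R, t))
    return StructureModel(id=f"aminor_{aminor_type}", nucleotides=nts + [donor])


def _build_zipper_model(spec: GeometrySpec) -> StructureModel:
    """Canonical ribose zipper: two antiparallel dinucleotide segments
    laced by O2'-O2' and O2'-base(O2/N3) hydrogen bonds."""
    s1 = spec.params.get("strand1", ("A", "A"))
    s2 = spec.params.get("strand2", ("C", "G"))
    # segment 1: two stacked residues (numbers 1, 2)
    seg1: List[Nucleotide] = []
    for i, b in enumerate(s1):
        R, t = _helix_step(i)
        seg1.append(_nucleotide(b, "A", 1 + i, _transform_atoms(ideal_base(b), R, t)))
    # segment 2 placed as rigid dinucleotide with cross O2' bonds
    seg2_atoms: List[Atom] = []
    counts = []
    for i, b in enumerate(s2):
        R, t = _helix_step(i)
        placed = _transform_atoms(ideal_base(b), R, t)
        counts.append(len(placed))
        seg2_atoms.extend(placed)
    mobile = np.array([a.position for a in seg2_atoms])
    idx_r1 = {a.name: i for i, a in enumerate(seg2_atoms[: counts[0]])}
    idx_r2 = {a.name: counts[0] + i for i, a in enumerate(seg2_atoms[counts[0]:])}
    env_pos = {(k, a.name): a.position for k, nuc in enumerate(seg1) for a in nuc.atoms}
    base_acc = "N3" if s2[0] in ("A", "G") else "O2"
    # the two defining bonds of a canonical zipper, antiparallel register:
    # O2'-O2' across one rung, O2'-base(O2/N3) across the other
    constraints = [
        (idx_r2["O2'"], env_pos[(0, "O2'")], _HB_TARGET),
        (idx_r1[base_acc], env_pos[(1, "O2'")], 3.0),
    ]
    repel = [
        # donor-side antecedents only: mobile O2' donates across one rung,
        # the fixed-side O2' donates into the mobile base across the other
        (idx_r2["C2'"], env_pos[(0, "O2'")], _repel_dist(_HB_TARGET)),
        (idx_r1[base_acc], env_pos[(1, "C2'")], _repel_dist(3.0)),
    ]
    fixed = _clash_positions(seg1)
    rng = np.random.default_rng(spec.seed)
    starts = list(_pair_starts())
    for _ in range(40):
        starts.append((Rotation.random(random_state=rng).as_rotvec(),
                       rng.uniform(-10, 10, size=3)))
    R, t = _fit_fragment(mobile, constraints, fixed, starts, repel=repel,
                         mobile_clash_idx=_clash_idx(seg2_atoms))
    placed2 = _transform_atoms(seg2_atoms, R, t)
    seg2 = [
        _nucleotide(s2[0], "A", 11, placed2[: counts[0]]),
        _nucleotide(s2[1], "A", 12, placed2[counts[0]:]),
    ]
    return StructureModel(id="zipper", nucleotides=seg1 + seg2)


def _build_pseudoknot_model(spec: GeometrySpec) -> StructureModel:
    """H-type pseudoknot topology: hairpin stem 1 plus a second helix that
    pairs hairpin-loop residues with the downstream single strand."""
    stem1 = build_helix(_default_pairs(3), numbers5=[1, 2, 3], numbers3=[12, 11, 10])
    far = (Rotation.from_euler("y", 90, degrees=True).as_matrix(),
           np.array([30.0, 0.0, 0.0]))
    stem2 = build_helix(
        [("G", "C"), ("C", "G")],
        numbers5=[5, 6],       # inside the hairpin loop (4..9)
        numbers3=[16, 15],     # downstream tail
        base_transform=far,
    )
    rest = _scatter_bases(["A", "A", "A", "A"], "A", [4, 7, 8, 9],
                          np.array([0.0, 25.0, 0.0]))
    tail = _scatter_bases(["A", "A"], "A", [13, 14], np.array([0.0, -25.0, 0.0]))
    return StructureModel(id="pseudoknot",
                          nucleotides=stem1 + stem2 + rest + tail)


def _build_kissing_model(spec: GeometrySpec) -> StructureModel:
    """Two hairpins whose loops are joined by three WC pairs."""
    npairs = int(spec.params.get("n_kissing", 3))
    # hairpin 1: stem 1-3 / 12-10, loop 4-9 ; hairpin 2: stem 15-17 / 26-24,
    # loop 18-23 ; kissing pairs between residues 5-7 and 20-22
    stem1 = build_helix(_default_pairs(3), numbers5=[1, 2, 3], numbers3=[12, 11, 10])
    off2 = (np.eye(3), np.array([60.0, 0.0, 0.0]))
    stem2 = build_helix(_default_pairs(3), numbers5=[15, 16, 17],
                        numbers3=[26, 25, 24], base_transform=off2)
    mid = (Rotation.from_euler("y", 90, degrees=True).as_matrix(),
           np.array([30.0, 0.0, 0.0]))
    kiss = build_helix(
        _default_pairs(npairs),
        numbers5=list(range(5, 5 + npairs)),
        numbers3=list(range(22, 22 - npairs, -1)),
        base_transform=mid,
    )
    spare = _scatter_bases(
        ["A", "A", "A", "A", "A", "A"], "A", [4, 8, 9, 13, 14, 18],
        np.array([0.0, 30.0, 0.0]),
    )
    spare += _scatter_bases(["A", "A"], "A", [19, 23], np.array([0.0, -30.0, 0.0]))
    return StructureModel(id="kissing", nucleotides=stem1 + stem2 + kiss + spare)


def _build_kink_turn_model(spec: GeometrySpec) -> StructureModel:
    """Canonical stem + trinucleotide bulge + tandem sheared G.A stem with
    bent axes."""
    bend = float(spec.params.get("bend", 120.0))
    c_stem = build_helix(
        [("C", "G"), ("G", "C"), ("C", "G")],
        numbers5=[1, 2, 3], numbers3=[20, 19, 18],
    )
    # NC stem: two sheared G.A pairs then one WC pair, on a bent axis
    Rb = Rotation.from_euler("y", bend, degrees=True).as_matrix()
    tb = np.array([14.0, 0.0, 8.0])
    nc_nts: List[Nucleotide] = []
    nc_spec = [("G", "A", "sheared_GA"), ("G", "A", "sheared_GA"), ("G", "C", "WC")]
    numbers5 = [7, 8, 9]
    numbers3 = [17, 16, 15]
    for i, (b5, b3, geom) in enumerate(nc_spec):
        n5, n3 = place_pair(b5, b3, geom, numbers=(numbers5[i], numbers3[i]))
        R, t = _helix_step(i)
        n5 = _nucleotide(b5, "A", numbers5[i],
                         _transform_atoms(_transform_atoms(n5.atoms, R, t), Rb, tb))
        n3 = _nucleotide(b3, "A", numbers3[i],
                         _transform_atoms(_transform_atoms(n3.atoms, R, t), Rb, tb))
        nc_nts.extend([n5, n3])
    bulge = _scatter_bases(["U", "A", "A"], "A", [4, 5, 6], np.array([0.0, 25.0, 4.0]))
    return StructureModel(id="kink_turn", nucleotides=c_stem + nc_nts + bulge)


def _build_loop_receptor_model(spec: GeometrySpec) -> StructureModel:
    """Tetraloop docking a receptor helix through a type-I A-minor plus a
    ribose zipper -- the classic loop-loop receptor composition."""
    # receptor helix: residues 11-14 / 31-28 (receptor pair = 11-31)
    pair_seq = [("G", "C"), ("C", "G"), ("G", "C"), ("A", "U")]
    rec = build_helix(pair_seq, numbers5=[11, 12, 13, 14], numbers3=[31, 30, 29, 28])
    rec5, rec3 = rec[0], rec[1]
    # loop's own stem, far away: residues 41-43 / 52-50; loop = 44-47
    far = (np.eye(3), np.array([-45.0, 0.0, 0.0]))
    loop_stem = build_helix(_default_pairs(3), numbers5=[41, 42, 43],
                            numbers3=[52, 51, 50], base_transform=far)
    # docking adenosine (loop residue 46): type-I A-minor into pair 11-31
    R, t = _dock_third_base(
        "A",
        [("N3", (0, "N2"), _HB_TARGET), ("O2'", (1, "O2"), _HB_TARGET)],
        [rec5, rec3],
        seed=spec.seed,
    )
    dock = _nucleotide("A", "A", 46, _transform_atoms(ideal_base("A"), R, t))
    # zipper strand: loop residues 44-45 against receptor strand 12-13
    strand_env = [rec[2], rec[4]]  # residues 12 and 13 (5' strand)
    seg_atoms: List[Atom] = []
    counts = []
    for i, b in enumerate(("A", "A")):
        Rh, th = _helix_step(i)
        placed = _transform_atoms(ideal_base(b), Rh, th)
        counts.append(len(placed))
        seg_atoms.extend(placed)
    mobile = np.array([a.position for a in seg_atoms])
    idx_r1 = {a.name: i for i, a in enumerate(seg_atoms[: counts[0]])}
    idx_r2 = {a.name: counts[0] + i for i, a in enumerate(seg_atoms[counts[0]:])}
    env_pos = {(k, a.name): a.position for k, nuc in enumerate(strand_env) for a in nuc.atoms}
    constraints = [
        (idx_r2["O2'"], env_pos[(0, "O2'")], _HB_TARGET),
        (idx_r1["N3"], env_pos[(1, "O2'")], 3.0),
    ]
    repel = [
        (idx_r2["C2'"], env_pos[(0, "O2'")], _repel_dist(_HB_TARGET)),
        (idx_r1["N3"], env_pos[(1, "C2'")], _repel_dist(3.0)),
    ]
    fixed = _clash_positions(rec + [dock])
    rng = np.random.default_rng(spec.seed + 1)
    starts = list(_pair_starts())
    for _ in range(40):
        starts.append((Rotation.random(random_state=rng).as_rotvec(),
                       rng.uniform(-12, 12, size=3)))
    Rz, tz = _fit_fragment(mobile, constraints, fixed, starts, repel=repel,
                           mobile_clash_idx=_clash_idx(seg_atoms))
    placed = _transform_atoms(seg_atoms, Rz, tz)
    zipper_nts = [
        _nucleotide("A", "A", 44, placed[: counts[0]]),
        _nucleotide("A", "A", 45, placed[counts[0]:]),
    ]
    closing = _scatter_bases(["A"], "A", [47], np.array([0.0, 40.0, 0.0]))
    return StructureModel(
        id="loop_receptor",
        nucleotides=rec + loop_stem + [dock] + zipper_nts + closing,
    )


# ---------------------------------------------------------------------------
# alignments with planted conservation
# ---------------------------------------------------------------------------

_RNA = "ACGU"


def make_alignment(
    nrows: int,
    ncols: int,
    conservation: Sequence[float],
    seed: int = 0,
) -> List[Tuple[str, str]]:
    """Alignment rows with an exact planted modal fraction per column.

    Per column the modal count is ``round(fraction * nrows)`` (half up);
    the remaining rows receive the other three bases as evenly as possible.
    Raises if a requested fraction cannot leave the modal base strictly
    modal.
    """
    if len(conservation) != ncols:
        raise ValueError("conservation vector length must equal ncols")
    rng = np.random.default_rng(seed)
    columns: List[List[str]] = []
    for j, frac in enumerate(conservation):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"column {j}: fraction {frac} outside [0, 1]")
        modal_count = int(math.floor(frac * nrows + 0.5))
        others = nrows - modal_count
        modal = _RNA[rng.integers(4)]
        rest = [b for b in _RNA if b != modal]
        share, extra = divmod(others, 3)
        counts = [share + (1 if k < extra else 0) for k in range(3)]
        if modal_count <= max(counts, default=0):
            raise ValueError(
                f"column {j}: fraction {frac} infeasible at {nrows} rows "
                "(modal base would not be strictly modal)"
            )
        col = [modal] * modal_count
        for b, c in zip(rest, counts):
            col += [b] * c
        rng.shuffle(col)
        columns.append(col)
    rows = [
        (f"seq{i+1}", "".join(columns[j][i] for j in range(ncols)))
        for i in range(nrows)
    ]
    return rows


def write_stockholm(rows: Sequence[Tuple[str, str]], path) -> None:
    lines = ["# STOCKHOLM 1.0", ""]
    width = max(len(name) for name, _ in rows) + 2
    for name, seq in rows:
        lines.append(f"{name.ljust(width)}{seq}")
    lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# the published base-triple census, as a packaged fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CensusRecord:
    pdb_id: str
    riboswitch_class: str
    residues: Tuple[str, ...]       # e.g. ("A23", "G46", "C53"), table order
    wc_pair: Tuple[str, ...]        # the bold-faced WC pair, or ()
    context: str

    @property
    def composition(self) -> str:
        return "".join(sorted((r[0] for r in self.residues), key="AGCU".index))

    @property
    def contains_wc(self) -> bool:
        return bool(self.wc_pair)


def reference_triple_census() -> List[CensusRecord]:
    """The 19-row base-triple census shipped with the package."""
    text = (
        resources.files("ribomotif").joinpath("data/base_triple_census.tsv").read_text()
    )
    records: List[CensusRecord] = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        pdb_id, rclass, residues, wc, context = line.rstrip("\n").split("\t")
        records.append(
            CensusRecord(
                pdb_id=pdb_id,
                riboswitch_class=rclass,
                residues=tuple(residues.split("-")),
                wc_pair=tuple(wc.split("-")) if wc else (),
                context=context,
            )
        )
    return records


# ---------------------------------------------------------------------------
# PDB writing and fixture emission
# ---------------------------------------------------------------------------


def write_pdb(model: StructureModel, path) -> None:
    """Minimal PDB writer so the loader is exercised end-to-end."""
    lines: List[str] = []
    serial = 1
    for n in model.nucleotides:
        for a in n.atoms:
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            x, y, z = a.position
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{n.raw_name:>3s} {n.chain:1s}"
                f"{n.number:4d}{n.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {a.element:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


STANDARD_SPECS: Dict[str, GeometrySpec] = {
    "helix4": GeometrySpec(kind="helix", params={"n": 4}),
    "hairpin": GeometrySpec(kind="hairpin"),
    "triple_agc": GeometrySpec(kind="triple"),
    "aminor_typeI": GeometrySpec(kind="aminor", params={"type": "I"}),
    "aminor_typeII": GeometrySpec(kind="aminor", params={"type": "II"}),
    "gminor_typeI": GeometrySpec(kind="aminor", params={"type": "I", "donor": "G"}),
    "zipper": GeometrySpec(kind="zipper"),
    "pseudoknot": GeometrySpec(kind="pseudoknot"),
    "kissing": GeometrySpec(kind="kissing"),
    "kink_turn": GeometrySpec(kind="kink_turn"),
    "loop_receptor": GeometrySpec(kind="loop_receptor"),
}


def write_fixture_set(outdir, seed: int = 0) -> List[Path]:
    """Emit the standard fixture scenes as PDB files plus one Stockholm
    alignment with a planted conservation vector."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    for name, spec in STANDARD_SPECS.items():
        model = build_motif(
            GeometrySpec(kind=spec.kind, bases=spec.bases,
                         params=dict(spec.params), seed=seed)
        )
        p = outdir / f"{name}.pdb"
        write_pdb(model, p)
        written.append(p)
    fractions = [1.0, 0.98, 0.95, 0.8, 0.6, 1.0, 0.4, 0.97]
    rows = make_alignment(20, len(fractions), fractions, seed=seed)
    ap = outdir / "alignment.sto"
    write_stockholm(rows, ap)
    written.append(ap)
    return written
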