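"""Uniform nucleotide model for RNA 3D structures.

Parses PDB / mmCIF files into a flat list of nucleotides (standardized base
codes, author numbering) and computes per-base reference frames used by all
planarity-dependent motif detectors.  Residue identity throughout the package
is the author triple ``(chain, number, icode)`` because published motif
descriptions cite author numbering (e.g. "A23-G46-C53").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Nucleotide",
    "StructureModel",
    "BaseFrame",
    "ResidueId",
    "load_structure",
    "standardize_base",
    "compute_base_frame",
    "extract_sequence",
    "FrameUnavailableError",
    "EmptyModelError",
    "StructureParseError",
]

ResidueId = Tuple[str, int, str]  # (chain, author number, insertion code)


class StructureParseError(ValueError):
    """Raised when a structure file cannot be read."""


class EmptyModelError(ValueError):
    """Raised when a structure contains no nucleic-acid residues."""


class FrameUnavailableError(ValueError):
    """Raised when too few ring atoms are present to fit a base plane."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom name must be non-empty")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class Nucleotide:
    chain: str
    number: int
    icode: str
    raw_name: str
    base: str  # 'A' | 'C' | 'G' | 'U' | 'UNKNOWN'
    atoms: List[Atom] = field(default_factory=list)
    is_modified: bool = False

    @property
    def rid(self) -> ResidueId:
        return (self.chain, self.number, self.icode)

    @property
    def label(self) -> str:
        """Human-readable id like 'A:G23'."""
        b = self.base if self.base != "UNKNOWN" else self.raw_name
        return f"{self.chain}:{b}{self.number}{self.icode.strip()}"

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_pos(self, name: str) -> Optional[np.ndarray]:
        a = self.atom(name)
        return None if a is None else a.position


@dataclass
class StructureModel:
    id: str
    nucleotides: List[Nucleotide]
    source_format: str = "PDB"
    hetero_atoms: List[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.nucleotides.sort(key=lambda n: (n.chain, n.number, n.icode))
        self._index: Dict[ResidueId, Nucleotide] = {}
        for n in self.nucleotides:
            if n.rid in self._index:
                raise ValueError(f"duplicate residue id {n.rid} in model {self.id}")
            self._index[n.rid] = n

    def __len__(self) -> int:
        return len(self.nucleotides)

    def get(self, rid: ResidueId) -> Nucleotide:
        return self._index[rid]

    def chains(self) -> List[str]:
        seen: List[str] = []
        for n in self.nucleotides:
            if n.chain not in seen:
                seen.append(n.chain)
        return seen


@dataclass
class BaseFrame:
    origin: np.ndarray
    normal: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray


# Parent mapping for modified ribonucleotides, transcribed from the PDB
# chemical-component dictionary (one_letter parent codes).  Deoxy residues
# map to the RNA parent so mixed entries still produce usable sequences.
MODIFIED_PARENT: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "DA": "A", "DC": "C", "DG": "G", "DT": "U", "DU": "U",
    "PSU": "U", "H2U": "U", "5MU": "U", "4SU": "U", "UR3": "U", "OMU": "U",
    "3MU": "U", "70U": "U", "5BU": "U", "DHU": "U",
    "1MA": "A", "2MA": "A", "MA6": "A", "6MA": "A", "RIA": "A", "OMA": "A",
    "A23": "A", "AET": "A", "12A": "A",
    "5MC": "C", "OMC": "C", "4OC": "C", "M4C": "C", "CCC": "C", "1SC": "C",
    "1MG": "G", "2MG": "G", "M2G": "G", "7MG": "G", "OMG": "G", "YG": "G",
    "G7M": "G", "QUO": "G", "GTP": "G", "GDP": "G", "23G": "G",
    "I": "G", "DI": "G",
}

PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

RING_ATOMS: Dict[str, Tuple[str, ...]] = {
    "A": PURINE_RING,
    "G": PURINE_RING,
    "C": PYRIMIDINE_RING,
    "U": PYRIMIDINE_RING,
}

GLYCOSIDIC_N: Dict[str, str] = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}


def standardize_base(raw_name: str) -> str:
    """Map a deposited residue name to its parent base code.

    Total function: unknown names return ``"UNKNOWN"``.
    """
    name = raw_name.strip().upper()
    return MODIFIED_PARENT.get(name, "UNKNOWN")


def _is_nucleic(resname: str) -> bool:
    if standardize_base(resname) != "UNKNOWN":
        return True
    info = gemmi.find_tabulated_residue(resname)
    return bool(info and info.is_nucleic_acid())


def load_structure(path, fmt: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    First model only; highest-occupancy alternate location kept; waters,
    ions, ligands and amino acids excluded from the nucleotide list but
    retained as ``hetero_atoms``.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    try:
        if fmt == "auto":
            st = gemmi.read_structure(str(path))
        elif fmt.upper() == "PDB":
            st = gemmi.read_pdb(str(path))
        elif fmt.lower() in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureParseError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from None

    source = "mmCIF" if str(path).lower().endswith((".cif", ".cif.gz", ".mmcif")) else "PDB"
    st.remove_empty_chains()
    if len(st) == 0:
        raise EmptyModelError(f"{path}: file contains no models")
    model = st[0]  # X-ray entries: single model; NMR: first model policy

    nucleotides: List[Nucleotide] = []
    hetero: List[Atom] = []
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            atoms = _collapse_altlocs(res)
            if not _is_nucleic(res.name):
                hetero.extend(atoms)
                continue
            base = standardize_base(res.name)
            nucleotides.append(
                Nucleotide(
                    chain=chain.name,
                    number=res.seqid.num,
                    icode=(res.seqid.icode or " ").strip() or "",
                    raw_name=res.name,
                    base=base,
                    atoms=atoms,
                    is_modified=res.name.strip().upper() not in ("A", "C", "G", "U"),
                )
            )
    if not nucleotides:
        raise EmptyModelError(f"{path}: no nucleic-acid residues found")
    sid = st.name.strip().lower() if st.name.strip() else path.stem
    return StructureModel(id=sid, nucleotides=nucleotides, source_format=source)


def _collapse_altlocs(res: "gemmi.Residue") -> List[Atom]:
    best: Dict[str, Tuple[float, Atom]] = {}
    order: List[str] = []
    for at in res:
        pos = np.array([at.pos.x, at.pos.y, at.pos.z])
        atom = Atom(name=at.name, element=at.element.name, position=pos)
        occ = at.occ if at.occ is not None else 1.0
        if at.name not in best:
            best[at.name] = (occ, atom)
            order.append(at.name)
        elif occ > best[at.name][0]:
            best[at.name] = (occ, atom)
    return [best[name][1] for name in order]


def compute_base_frame(n: Nucleotide) -> BaseFrame:
    """Least-squares base-plane frame.

    Origin is the ring-atom centroid; the normal is the smallest-variance
    direction of the ring atoms.  The normal's sign follows base chirality
    (cross product of two ring-bond vectors) so that sequential residues of
    one strand fall in the same hemisphere; the x-axis points from the
    origin toward the glycosidic nitrogen, projected into the plane.
    """
    if n.base not in RING_ATOMS:
        raise FrameUnavailableError(f"{n.label}: no ring template for base {n.base}")
    ring = [n.atom_pos(a) for a in RING_ATOMS[n.base]]
    pts = np.array([p for p in ring if p is not None])
    if len(pts) < 5:
        raise FrameUnavailableError(
            f"{n.label}: only {len(pts)} ring atoms present (need >=5)"
        )
    origin = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - origin)
    normal = vt[2]

    # chirality-based sign: deterministic and rigid-transform equivariant
    anchor = GLYCOSIDIC_N[n.base]
    neigh = ("C8", "C4") if n.base in ("A", "G") else ("C6", "C2")
    p0, p1, p2 = n.atom_pos(anchor), n.atom_pos(neigh[0]), n.atom_pos(neigh[1])
    if p0 is not None and p1 is not None and p2 is not None:
        ref = np.cross(p1 - p0, p2 - p0)
        if np.dot(normal, ref) < 0:
            normal = -normal
    normal = normal / np.linalg.norm(normal)

    gpos = n.atom_pos(anchor)
    xdir = (gpos - origin) if gpos is not None else (pts[0] - origin)
    xdir = xdir - np.dot(xdir, normal) * normal
    nx = np.linalg.norm(xdir)
    if nx < 1e-9:  # glycosidic N exactly at centroid: degenerate, pick any in-plane axis
        xdir = np.cross(normal, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(xdir) < 1e-9:
            xdir = np.cross(normal, np.array([0.0, 1.0, 0.0]))
        nx = np.linalg.norm(xdir)
    x_axis = xdir / nx
    y_axis = np.cross(normal, x_axis)
    return BaseFrame(origin=origin, normal=normal, x_axis=x_axis, y_axis=y_axis)


def base_frames(m: StructureModel) -> Dict[ResidueId, BaseFrame]:
    """Frames for every nucleotide that has one; others are silently absent
    (they are excluded from planarity-dependent detectors)."""
    frames: Dict[ResidueId, BaseFrame] = {}
    for n in m.nucleotides:
        try:
            frames[n.rid] = compute_base_frame(n)
        except FrameUnavailableError:
            continue
    return frames


def plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two base planes in degrees, folded to [0, 90]."""
    c = abs(float(np.clip(np.dot(n1, n2), -1.0, 1.0)))
    return math.degrees(math.acos(c))


def extract_sequence(
    m: StructureModel, chain: str = ""
) -> Tuple[str, List[ResidueId]]:
    """One-letter sequence of a chain plus index -> residue-id map.

    An empty ``chain`` on a single-chain model selects that chain.
    UNKNOWN bases are emitted as ``N``.
    """
    chains = m.chains()
    if chain == "":
        if len(chains) != 1:
            raise KeyError(
                f"model {m.id} has chains {chains}; specify one explicitly"
            )
        chain = chains[0]
    if chain not in chains:
        raise KeyError(f"chain {chain!r} not in model {m.id} (has {chains})")
    seq: List[str] = []
    rmap: List[ResidueId] = []
    for n in m.nucleotides:
        if n.chain != chain:
            continue
        seq.append(n.base if n.base in "ACGU" else "N")
        rmap.append(n.rid)
    return "".join(seq), rmap
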