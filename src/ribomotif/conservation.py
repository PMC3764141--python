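"""Alignment-column conservation profiling and motif conservation classes.

Columns of a Stockholm alignment are profiled for their modal base
frequency; a column counts as conserved when that frequency strictly
exceeds the threshold (default 0.95, the "more than 95% sequence
conservation" rule), with gaps counted in the denominator by default.
Structure sequences are mapped onto alignment columns by affine-gap
pairwise insertion against the closest existing row -- a deliberate,
documented substitution for covariance-model alignment.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import AlignIO
from Bio.Align import PairwiseAligner
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import DEFAULT_CONFIG, DetectionConfig
from .structure_model import ResidueId

__all__ = [
    "Alignment",
    "ColumnProfile",
    "MotifConservation",
    "read_stockholm",
    "write_stockholm",
    "column_profiles",
    "insert_sequence",
    "motif_conservation",
]

GAP_CHARS = set("-.")


@dataclass
class Alignment:
    rows: List[Tuple[str, str]]           # (id, gapped sequence), upper-case U
    ss_cons: Optional[str] = None
    insert_columns: List[int] = field(default_factory=list)

    @property
    def ncols(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def ungapped(self, idx: int) -> str:
        return "".join(c for c in self.rows[idx][1] if c not in GAP_CHARS)


def _normalize(seq: str) -> str:
    return seq.upper().replace("T", "U")


def read_stockholm(path) -> Alignment:
    """Read a Stockholm 1.0 alignment, keeping #=GC SS_cons if present."""
    try:
        aln = AlignIO.read(str(path), "stockholm")
    except ValueError as exc:
        raise ValueError(f"{path}: not a valid Stockholm file ({exc})") from None
    rows = [(rec.id, _normalize(str(rec.seq))) for rec in aln]
    ss = aln.column_annotations.get("secondary_structure")
    return Alignment(rows=rows, ss_cons=ss)


def write_stockholm(a: Alignment, path, conserved_mask: Optional[str] = None) -> None:
    """Write Stockholm, optionally adding a '#=GC conserved' mask line."""
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in a.rows]
    )
    if a.ss_cons is not None:
        msa.column_annotations["secondary_structure"] = a.ss_cons
    handle = io.StringIO()
    AlignIO.write(msa, handle, "stockholm")
    text = handle.getvalue()
    if conserved_mask is not None:
        lines = text.rstrip().splitlines()
        assert lines[-1] == "//"
        lines.insert(len(lines) - 1, f"#=GC conserved {conserved_mask}")
        text = "\n".join(lines) + "\n"
    Path(path).write_text(text)


@dataclass
class ColumnProfile:
    column: int                       # 0-based
    counts: Dict[str, int]            # over A,C,G,U,gap (+ ambiguity codes)
    modal_base: str
    modal_fraction: float
    conserved: bool


def column_profiles(
    a: Alignment, config: DetectionConfig = DEFAULT_CONFIG
) -> List[ColumnProfile]:
    """Per-column base counts and the strict >threshold conserved flag.

    Gaps count in the denominator unless ``config.gaps_in_denominator`` is
    off; ambiguity symbols are tallied but never modal.
    """
    if len(a.rows) < 2:
        raise ValueError("need at least two alignment rows to profile")
    out: List[ColumnProfile] = []
    nrows = len(a.rows)
    for j in range(a.ncols):
        col = [row[1][j] for row in a.rows]
        counts = Counter("-" if c in GAP_CHARS else c for c in col)
        acgu = {b: counts.get(b, 0) for b in "ACGU"}
        modal_base = max(acgu, key=lambda b: (acgu[b], -"ACGU".index(b)))
        denom = nrows if config.gaps_in_denominator else max(
            1, nrows - counts.get("-", 0)
        )
        frac = acgu[modal_base] / denom
        out.append(
            ColumnProfile(
                column=j,
                counts=dict(counts),
                modal_base=modal_base,
                modal_fraction=frac,
                conserved=frac > config.conservation_threshold,
            )
        )
    return out


def _aligner(config: DetectionConfig) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "global"
    al.match_score = config.align_match
    al.mismatch_score = config.align_mismatch
    al.open_gap_score = config.align_open
    al.extend_gap_score = config.align_extend
    return al


def _identity(a: str, b: str, aligner: PairwiseAligner) -> float:
    if not a or not b:
        return 0.0
    best = aligner.align(a, b)[0]
    matches = 0
    for (s1, e1), (s2, e2) in zip(*best.aligned):
        matches += sum(1 for x, y in zip(a[s1:e1], b[s2:e2]) if x == y)
    return matches / max(len(a), len(b))


def insert_sequence(
    a: Alignment,
    seq: str,
    seq_id: str = "query",
    residue_map_ids: Optional[Sequence[ResidueId]] = None,
    config: DetectionConfig = DEFAULT_CONFIG,
) -> Tuple[Alignment, int, Dict[ResidueId, int]]:
    """Insert an ungapped sequence into the alignment by pairwise
    alignment against its closest row, transferring that row's gap
    pattern; columns the new sequence needs beyond the existing ones are
    added and flagged as insert columns (excluded from conservation
    reporting).

    Returns (new alignment, new row index, residue-id -> column map);
    the map uses ``residue_map_ids`` (index-aligned with ``seq``) or
    synthesized ids ("", i+1, "") when not given.
    """
    if not a.rows:
        raise ValueError("cannot insert into an empty alignment")
    seq = _normalize(seq)
    if not seq:
        raise ValueError("empty query sequence")
    aligner = _aligner(config)
    identities = [_identity(seq, a.ungapped(i), aligner) for i in range(len(a.rows))]
    closest = max(range(len(a.rows)), key=lambda i: identities[i])
    template_gapped = a.rows[closest][1]
    template = a.ungapped(closest)

    best = aligner.align(seq, template)[0]
    # per-position pairing between query indices and template indices
    pair_q2t: Dict[int, int] = {}
    for (qs, qe), (ts, te) in zip(*best.aligned):
        for dq in range(qe - qs):
            pair_q2t[qs + dq] = ts + dq

    # template residue index -> its alignment column
    t_col: List[int] = [
        j for j, c in enumerate(template_gapped) if c not in GAP_CHARS
    ]

    # walk the query; aligned residues land in the template's column, runs
    # of unaligned residues become insert columns after the previous column
    placements: List[Tuple[int, Optional[int]]] = []  # (query idx, col or None)
    for qi in range(len(seq)):
        ti = pair_q2t.get(qi)
        placements.append((qi, t_col[ti] if ti is not None else None))

    # build new column layout: original columns plus inserted ones
    inserts: Dict[int, List[int]] = {}  # after-column -> list of query idx
    prev_col = -1
    for qi, col in placements:
        if col is None:
            inserts.setdefault(prev_col, []).append(qi)
        else:
            prev_col = col

    old_ncols = a.ncols
    layout: List[Tuple[str, int]] = []  # ('old', j) or ('ins', query idx)
    for qi in inserts.get(-1, []):
        layout.append(("ins", qi))
    for j in range(old_ncols):
        layout.append(("old", j))
        for qi in inserts.get(j, []):
            layout.append(("ins", qi))

    col_of_query: Dict[int, int] = {}
    for newj, (kind, ref) in enumerate(layout):
        if kind == "ins":
            col_of_query[ref] = newj
    for qi, col in placements:
        if col is not None:
            newj = next(
                k for k, (kind, ref) in enumerate(layout)
                if kind == "old" and ref == col
            )
            col_of_query[qi] = newj

    new_rows: List[Tuple[str, str]] = []
    for name, gapped in a.rows:
        chars = []
        for kind, ref in layout:
            chars.append(gapped[ref] if kind == "old" else "-")
        new_rows.append((name, "".join(chars)))
    qchars = ["-"] * len(layout)
    for qi, newj in col_of_query.items():
        qchars[newj] = seq[qi]
    new_rows.append((seq_id, "".join(qchars)))

    new_ss = None
    if a.ss_cons is not None:
        ss_chars = [
            a.ss_cons[ref] if kind == "old" else "." for kind, ref in layout
        ]
        new_ss = "".join(ss_chars)

    insert_cols = sorted(
        k for k, (kind, _ref) in enumerate(layout) if kind == "ins"
    )
    new_aln = Alignment(rows=new_rows, ss_cons=new_ss, insert_columns=insert_cols)

    ids = (
        list(residue_map_ids)
        if residue_map_ids is not None
        else [("", i + 1, "") for i in range(len(seq))]
    )
    if len(ids) != len(seq):
        raise ValueError("residue_map_ids length must match the sequence")
    rmap = {ids[qi]: col for qi, col in sorted(col_of_query.items())}
    return new_aln, len(new_rows) - 1, rmap


@dataclass
class MotifConservation:
    residues: List[ResidueId]
    columns: List[Optional[int]]
    fractions: List[Optional[float]]
    klass: str     # 'fully_conserved' | 'highly_conserved' | 'variable' | 'unassessed'


def motif_conservation(
    residues: Sequence[ResidueId],
    rmap: Dict[ResidueId, int],
    profiles: Sequence[ColumnProfile],
    structure_base: Optional[Dict[ResidueId, str]] = None,
    config: DetectionConfig = DEFAULT_CONFIG,
) -> MotifConservation:
    """Classify a motif's conservation from its residues' columns.

    fully_conserved: every column has modal fraction 1.0 and (when the
    structure's bases are supplied) the modal base matches the structure;
    highly_conserved: every column strictly above the threshold; else
    variable.  Unmapped residues make the motif 'unassessed'.
    """
    prof_by_col = {p.column: p for p in profiles}
    cols: List[Optional[int]] = []
    fracs: List[Optional[float]] = []
    klass = "fully_conserved"
    for rid in residues:
        col = rmap.get(rid)
        cols.append(col)
        if col is None or col not in prof_by_col:
            fracs.append(None)
            klass = "unassessed"
            continue
        p = prof_by_col[col]
        fracs.append(p.modal_fraction)
    if klass != "unassessed":
        def base_ok(rid: ResidueId, p: ColumnProfile) -> bool:
            return (
                structure_base is None
                or structure_base.get(rid) is None
                or structure_base[rid] == p.modal_base
            )

        col_profiles = [prof_by_col[c] for c in cols]  # type: ignore[index]
        if all(
            p.modal_fraction == 1.0 and base_ok(rid, p)
            for rid, p in zip(residues, col_profiles)
        ):
            klass = "fully_conserved"
        elif all(
            p.modal_fraction > config.conservation_threshold
            for p in col_profiles
        ):
            klass = "highly_conserved"
        else:
            klass = "variable"
    return MotifConservation(
        residues=list(residues), columns=cols, fractions=fracs, klass=klass
    )
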