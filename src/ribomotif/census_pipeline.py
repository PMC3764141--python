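"""End-to-end motif census: structures in, annotated motif lists and
summary statistics out.

Per structure the pipeline loads coordinates, detects hydrogen bonds and
base pairs, builds the nested secondary-structure skeleton, runs all seven
motif detectors, attaches Table-style context strings, and -- when an
alignment is supplied -- maps the chain sequence onto alignment columns
and classifies each motif's conservation.  ``summarize`` computes the
survey's count statistics (triple counts and compositions, A-minor type
and receptor shares, zipper counts, unique-interaction total with
most-specific-wins de-duplication).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .config import DEFAULT_CONFIG, DetectionConfig
from .conservation import (
    column_profiles,
    insert_sequence,
    motif_conservation,
    read_stockholm,
)
from .pairing import detect_base_pairs, detect_hbonds
from .secondary_structure import build_elements, classify_context, nested_skeleton
from .structure_model import StructureModel, base_frames, extract_sequence, load_structure
from .synthetic_data import CensusRecord
from . import tertiary_motifs as tm

logger = logging.getLogger("ribomotif")

__all__ = ["MotifRecord", "CensusReport", "annotate_structure", "run_census",
           "summarize", "summarize_table_records", "write_report"]

# most-specific-wins order for unique-interaction counting
SPECIFICITY = (
    "kink_turn",
    "loop_receptor",
    "kissing_loop",
    "pseudoknot",
    "ribose_zipper",
    "aminor",
    "base_quadruple",
    "base_triple",
)


@dataclass
class MotifRecord:
    structure_id: str
    motif_class: str
    residues: List[str]                   # 'chain:BaseNumber' labels
    residue_ids: List[Tuple]              # raw ResidueId tuples
    composition: str = ""
    contains_wc: bool = False
    subtype: str = ""                     # A-minor type / zipper class / ...
    receptor: str = ""
    context: str = ""
    conservation: str = ""


@dataclass
class CensusReport:
    records: List[MotifRecord] = field(default_factory=list)
    structures: List[str] = field(default_factory=list)
    failures: List[str] = field(default_factory=list)
    conservation_rows: List[Dict] = field(default_factory=list)

    @property
    def partial(self) -> bool:
        return bool(self.failures)


def _labels(m: StructureModel, rids) -> List[str]:
    return [m.get(r).label for r in rids]


def annotate_structure(
    m: StructureModel, config: DetectionConfig = DEFAULT_CONFIG
) -> Dict[str, list]:
    """Run the full detector stack on one loaded structure."""
    frames = base_frames(m)
    hbonds = detect_hbonds(m, config, frames)
    pairs = detect_base_pairs(m, config, hbonds, frames)
    cw = [p for p in pairs if p.canonical or p.wobble]

    order = [n.rid for n in m.nucleotides]
    # per chain skeleton and elements; single-chain models dominate
    skeleton, remainder = [], []
    ss_by_chain = {}
    for chain in m.chains():
        chain_order = [r for r in order if r[0] == chain]
        chain_pairs = [p for p in cw if p.a[0] == chain and p.b[0] == chain]
        sk, rem = nested_skeleton(chain_pairs, chain_order)
        skeleton.extend(sk)
        remainder.extend(rem)
        ss_by_chain[chain] = build_elements(sk, m, chain)
    remainder.extend(
        p for p in cw if p.a[0] != p.b[0]
    )
    main_chain = m.chains()[0]
    ss = ss_by_chain[main_chain]

    triples = tm.detect_triples(m, pairs, frames, config)
    quadruples = tm.detect_quadruples(triples, pairs)
    a_minors = tm.detect_a_minor(m, pairs, hbonds, config, order)
    zippers = tm.detect_ribose_zipper(m, hbonds, config)
    pseudoknots = tm.detect_pseudoknots(
        skeleton, remainder, order, ss
    )
    kissing = tm.detect_kissing_loops(ss, pairs, config)
    kinks = tm.detect_kink_turn(m, ss, pairs, a_minors, config)
    loop_receptors = tm.detect_loop_receptor(ss, a_minors, zippers, config)

    merged_elements = _merge_ss(ss_by_chain)
    for motif_list in (triples, quadruples, a_minors, zippers, pseudoknots,
                       kissing, kinks, loop_receptors):
        for motif in motif_list:
            motif.context = classify_context(sorted(motif.key), merged_elements)

    return {
        "frames": frames,
        "hbonds": hbonds,
        "pairs": pairs,
        "skeleton": skeleton,
        "remainder": remainder,
        "ss": ss,
        "ss_by_chain": ss_by_chain,
        "base_triple": triples,
        "base_quadruple": quadruples,
        "aminor": a_minors,
        "ribose_zipper": zippers,
        "pseudoknot": pseudoknots,
        "kissing_loop": kissing,
        "kink_turn": kinks,
        "loop_receptor": loop_receptors,
    }


def _merge_ss(ss_by_chain):
    from .secondary_structure import SecondaryStructure

    stems, loops, junctions = [], [], []
    element_of, kind_of = {}, {}
    for ss in ss_by_chain.values():
        stems.extend(ss.stems)
        loops.extend(ss.loops)
        junctions.extend(ss.junctions)
        element_of.update(ss.element_of)
        kind_of.update(ss.kind_of)
    return SecondaryStructure(
        stems=stems, loops=loops, junctions=junctions,
        element_of=element_of, kind_of=kind_of,
    )


def _to_records(m: StructureModel, ann: Dict[str, list]) -> List[MotifRecord]:
    records: List[MotifRecord] = []
    for t in ann["base_triple"]:
        records.append(
            MotifRecord(
                structure_id=m.id, motif_class="base_triple",
                residues=_labels(m, t.residues), residue_ids=list(t.residues),
                composition=t.composition, contains_wc=t.contains_wc,
                context=t.context,
            )
        )
    for q in ann["base_quadruple"]:
        records.append(
            MotifRecord(
                structure_id=m.id, motif_class="base_quadruple",
                residues=_labels(m, q.residues), residue_ids=list(q.residues),
                composition=tm.display_composition(q.bases), context=q.context,
            )
        )
    for am in ann["aminor"]:
        rids = sorted(am.key)
        records.append(
            MotifRecord(
                structure_id=m.id, motif_class="aminor",
                residues=_labels(m, rids), residue_ids=rids,
                subtype=am.type, receptor=am.receptor_label,
                composition=am.variant, context=am.context,
            )
        )
    for z in ann["ribose_zipper"]:
        rids = sorted(z.key)
        records.append(
            MotifRecord(
                structure_id=m.id, motif_class="ribose_zipper",
                residues=_labels(m, rids), residue_ids=rids,
                subtype=z.zclass, context=z.context,
            )
        )
    for pk in ann["pseudoknot"]:
        rids = sorted(pk.key)
        records.append(
            MotifRecord(
                structure_id=m.id, motif_class="pseudoknot",
                residues=_labels(m, rids), residue_ids=rids,
                subtype="H-type" if pk.htype else "other", context=pk.context,
            )
        )
    for kl in ann["kissing_loop"]:
        rids = sorted(kl.key)
        records.append(
            MotifRecord(
                structure_id=m.id, motif_class="kissing_loop",
                residues=_labels(m, rids), residue_ids=rids,
                subtype=f"{kl.loop_a}-{kl.loop_b}", context=kl.context,
            )
        )
    for kt in ann["kink_turn"]:
        rids = sorted(kt.key)
        records.append(
            MotifRecord(
                structure_id=m.id, motif_class="kink_turn",
                residues=_labels(m, rids), residue_ids=rids,
                subtype=kt.c_stem, context=kt.context,
            )
        )
    for lr in ann["loop_receptor"]:
        rids = sorted(lr.key)
        records.append(
            MotifRecord(
                structure_id=m.id, motif_class="loop_receptor",
                residues=_labels(m, rids), residue_ids=rids,
                subtype=f"size{lr.loop_size}", receptor=lr.receptor_stem,
                context=lr.context,
            )
        )
    return records


def run_census(
    structures: Sequence,
    alignments: Optional[Dict[str, str]] = None,
    config: DetectionConfig = DEFAULT_CONFIG,
) -> CensusReport:
    """Annotate a list of structure files and assemble the census.

    ``alignments`` maps a structure id (file stem) to a Stockholm path;
    failures on individual structures are logged and skipped.
    """
    if not structures:
        raise ValueError("no structures given")
    report = CensusReport()
    for path in structures:
        path = Path(path)
        try:
            m = load_structure(path)
            ann = annotate_structure(m, config)
            records = _to_records(m, ann)
            if alignments and (path.stem in alignments or m.id in alignments):
                apath = alignments.get(path.stem, alignments.get(m.id))
                _attach_conservation(m, records, apath, config, report)
            report.records.extend(records)
            report.structures.append(m.id)
            counts = {}
            for r in records:
                counts[r.motif_class] = counts.get(r.motif_class, 0) + 1
            logger.info("%s: %s", m.id, counts or "no motifs")
        except Exception as exc:  # noqa: BLE001 - per-structure isolation
            logger.warning("skipping %s: %s", path, exc)
            report.failures.append(str(path))
    return report


def _attach_conservation(m, records, alignment_path, config, report):
    aln = read_stockholm(alignment_path)
    chain = m.chains()[0]
    seq, rid_map = extract_sequence(m, chain)
    new_aln, _row, rmap = insert_sequence(
        aln, seq, seq_id=m.id, residue_map_ids=rid_map, config=config
    )
    profiles = [
        p for p in column_profiles(new_aln, config)
        if p.column not in set(new_aln.insert_columns)
    ]
    bases = {n.rid: n.base for n in m.nucleotides}
    for rec in records:
        mc = motif_conservation(rec.residue_ids, rmap, profiles, bases, config)
        rec.conservation = mc.klass
    n_cons = sum(p.conserved for p in profiles)
    report.conservation_rows.append(
        {"structure": m.id, "alignment": str(alignment_path),
         "n_columns": len(profiles), "n_conserved": n_cons}
    )


def _round_percent(part: int, whole: int) -> int:
    if whole == 0:
        return 0
    import math
    return int(math.floor(100.0 * part / whole + 0.5))


def summarize(report_or_records) -> Dict:
    """Count statistics over a census: triples and their compositions,
    A-minor type and receptor shares, zipper count, and the unique-
    interaction total after most-specific-wins de-duplication."""
    records = (
        report_or_records.records
        if isinstance(report_or_records, CensusReport)
        else list(report_or_records)
    )
    triples = [r for r in records if r.motif_class == "base_triple"]
    comp_counts: Dict[str, int] = {}
    for t in triples:
        comp_counts[t.composition] = comp_counts.get(t.composition, 0) + 1
    modal_comp = max(comp_counts, key=lambda c: (comp_counts[c], c), default="")

    aminors = [r for r in records if r.motif_class == "aminor"]
    type_counts: Dict[str, int] = {}
    receptor_counts: Dict[str, int] = {}
    for a in aminors:
        type_counts[a.subtype] = type_counts.get(a.subtype, 0) + 1
        if a.receptor:
            receptor_counts[a.receptor] = receptor_counts.get(a.receptor, 0) + 1

    class_counts: Dict[str, int] = {}
    for r in records:
        class_counts[r.motif_class] = class_counts.get(r.motif_class, 0) + 1

    unique = _unique_interactions(records)
    non_triples = [
        r for r in unique
        if r.motif_class not in ("base_triple", "base_quadruple")
    ]

    return {
        "n_records": len(records),
        "n_triples": len(triples),
        "n_wc_triples": sum(t.contains_wc for t in triples),
        "composition_counts": dict(sorted(comp_counts.items())),
        "modal_composition": modal_comp,
        "modal_composition_count": comp_counts.get(modal_comp, 0),
        "aminor_count": len(aminors),
        "aminor_type_counts": dict(sorted(type_counts.items())),
        "aminor_type_percent": {
            k: _round_percent(v, len(aminors))
            for k, v in sorted(type_counts.items())
        },
        "receptor_counts": dict(sorted(receptor_counts.items())),
        "receptor_percent": {
            k: _round_percent(v, len(aminors))
            for k, v in sorted(receptor_counts.items())
        },
        "zipper_count": class_counts.get("ribose_zipper", 0),
        "class_counts": dict(sorted(class_counts.items())),
        "total_unique_interactions": len(unique),
        "non_triple_interactions": len(non_triples),
    }


def _unique_interactions(records: Sequence[MotifRecord]) -> List[MotifRecord]:
    """Drop records whose residues are contained in a more specific motif
    (e.g. the kink-turn internal A-minor); quadruples never suppress their
    constituent triples."""
    rank = {c: i for i, c in enumerate(SPECIFICITY)}
    kept: List[MotifRecord] = []
    for r in sorted(records, key=lambda r: rank.get(r.motif_class, 99)):
        rset = set(r.residue_ids)
        suppressed = False
        for k in kept:
            if k.structure_id != r.structure_id:
                continue
            if k.motif_class == "base_quadruple" and r.motif_class == "base_triple":
                continue
            if rank.get(k.motif_class, 99) < rank.get(r.motif_class, 99) and rset <= set(
                k.residue_ids
            ):
                suppressed = True
                break
        if not suppressed:
            kept.append(r)
    return kept


def summarize_table_records(census: Sequence[CensusRecord]) -> Dict:
    """Summarize a packaged base-triple census (the printed-table fixture)."""
    records = [
        MotifRecord(
            structure_id=c.pdb_id,
            motif_class="base_triple",
            residues=list(c.residues),
            residue_ids=[(c.pdb_id, i, r) for i, r in enumerate(c.residues)],
            composition=tm.display_composition([r[0] for r in c.residues]),
            contains_wc=c.contains_wc,
            context=c.context,
        )
        for c in census
    ]
    return summarize(records)


_CENSUS_COLUMNS = (
    "structure", "motif_class", "residues", "composition", "contains_wc",
    "subtype", "receptor", "context", "conservation",
)


def write_report(report: CensusReport, outdir, formats=("TSV", "JSON")) -> List[Path]:
    """census.tsv + summary.json (+ conservation.tsv); stable ordering so
    re-runs are bit-identical."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    if "TSV" in formats:
        lines = ["\t".join(_CENSUS_COLUMNS)]
        for r in sorted(
            report.records,
            key=lambda r: (r.structure_id, r.motif_class, r.residues),
        ):
            lines.append(
                "\t".join(
                    [
                        r.structure_id, r.motif_class, ",".join(r.residues),
                        r.composition, str(r.contains_wc), r.subtype,
                        r.receptor, r.context, r.conservation,
                    ]
                )
            )
        p = outdir / "census.tsv"
        p.write_text("\n".join(lines) + "\n")
        written.append(p)
        if report.conservation_rows:
            lines = ["structure\talignment\tn_columns\tn_conserved"]
            for row in report.conservation_rows:
                lines.append(
                    f"{row['structure']}\t{row['alignment']}\t"
                    f"{row['n_columns']}\t{row['n_conserved']}"
                )
            p = outdir / "conservation.tsv"
            p.write_text("\n".join(lines) + "\n")
            written.append(p)
    if "JSON" in formats:
        p = outdir / "summary.json"
        p.write_text(json.dumps(summarize(report), indent=2, sort_keys=True) + "\n")
        written.append(p)
    return written
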