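"""Shared fixtures: synthetic motif scenes are built once per session
(the constrained placement is the expensive step) and reused across
modules."""

from __future__ import annotations

import pytest

from ribomotif.config import DEFAULT_CONFIG
from ribomotif.pairing import detect_base_pairs, detect_hbonds
from ribomotif.secondary_structure import build_elements, nested_skeleton
from ribomotif.structure_model import base_frames
from ribomotif.synthetic_data import GeometrySpec, build_motif

_SPECS = {
    "helix4": ("helix", {"n": 4}),
    "hairpin": ("hairpin", {}),
    "triple": ("triple", {}),
    "tilted_triple": ("tilted_triple", {}),
    "aminor_I": ("aminor", {"type": "I"}),
    "aminor_II": ("aminor", {"type": "II"}),
    "aminor_0": ("aminor", {"type": "0"}),
    "gminor_I": ("aminor", {"type": "I", "donor": "G"}),
    "zipper": ("zipper", {}),
    "pseudoknot": ("pseudoknot", {}),
    "kissing": ("kissing", {}),
    "kink_turn": ("kink_turn", {}),
    "loop_receptor": ("loop_receptor", {}),
}


@pytest.fixture(scope="session")
def scenes():
    """kind -> fully annotated scene dict (model, frames, hbonds, pairs,
    skeleton, remainder, ss)."""
    cache = {}

    def get(name):
        if name not in cache:
            kind, params = _SPECS[name]
            m = build_motif(GeometrySpec(kind=kind, params=params))
            frames = base_frames(m)
            hbonds = detect_hbonds(m, DEFAULT_CONFIG, frames)
            pairs = detect_base_pairs(m, DEFAULT_CONFIG, hbonds, frames)
            order = [n.rid for n in m.nucleotides]
            cw = [p for p in pairs if p.canonical or p.wobble]
            skeleton, remainder = nested_skeleton(cw, order)
            ss = build_elements(skeleton, m)
            cache[name] = {
                "model": m,
                "frames": frames,
                "hbonds": hbonds,
                "pairs": pairs,
                "order": order,
                "skeleton": skeleton,
                "remainder": remainder,
                "ss": ss,
            }
        return cache[name]

    return get
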