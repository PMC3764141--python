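"""Geometric thresholds for the detectors, in one place.

The published survey names its filters ("planar", "at least two hydrogen
bond interactions per base pair") without numeric criteria; the values here
are conventional crystallographic choices, frozen as defaults and loadable
from a YAML key/value file so every threshold stays visible and adjustable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class DetectionConfig:
    # hydrogen bonds (heavy-atom criteria; no hydrogen placement)
    hbond_max_distance: float = 3.5       # Angstrom, donor-acceptor
    hbond_min_angle: float = 110.0        # degrees at the donor via its antecedent
    hbond_min_distance: float = 2.2       # below this: clash / covalent, not an H-bond

    # base pairing
    pair_min_hbonds: int = 2              # base-involving bonds per accepted pair
    pair_planarity_max: float = 65.0      # degrees between base normals (loose)
    count_sugar_bonds_in_pairing: bool = False  # whether base-sugar bonds count

    # base triples
    triple_planarity_max: float = 30.0    # degrees, strict "planar interaction" filter

    # A-minor
    aminor_min_hbonds: int = 2

    # ribose zipper
    zipper_min_separation: int = 4        # |i - j| in sequence order
    zipper_min_hbonds: int = 2

    # kissing loops
    kissing_min_pairs: int = 2

    # kink-turn
    kink_axis_max_angle: float = 120.0    # degrees between stem axes
    kink_bulge_min: int = 2
    kink_bulge_max: int = 4

    # loop-receptor
    loop_receptor_min_size: int = 4
    loop_receptor_max_size: int = 5

    # conservation
    conservation_threshold: float = 0.95  # strictly greater-than
    gaps_in_denominator: bool = True

    # sequence insertion / residue matching (affine-gap global alignment)
    align_match: float = 2.0
    align_mismatch: float = -1.0
    align_open: float = -5.0
    align_extend: float = -1.0

    # superposition
    superpose_prune_cutoff: float = 2.0   # Angstrom per-pair deviation

    # receptor-pair label orientation: 5'-residue of the receptor pair first
    receptor_label_five_prime_first: bool = True

    @classmethod
    def from_yaml(cls, path) -> "DetectionConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


DEFAULT_CONFIG = DetectionConfig()
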