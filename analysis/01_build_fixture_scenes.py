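#!/usr/bin/env python
"""Generate the synthetic structure scenes and the planted-conservation
alignment that the downstream analysis steps annotate.

Writes PDB files (one per motif scene) and a Stockholm alignment under
results/fixtures/.
"""

from pathlib import Path

from ribomotif.synthetic_data import write_fixture_set

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"


def main() -> None:
    files = write_fixture_set(OUT, seed=0)
    pdb = [f for f in files if f.suffix == ".pdb"]
    sto = [f for f in files if f.suffix == ".sto"]
    print(f"wrote {len(pdb)} structure scenes and {len(sto)} alignment to {OUT}")
    for f in files:
        print(" ", f.name)


if __name__ == "__main__":
    main()
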