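"""Round-trip through PDB and robustness to side-chain disorder.

Writes a lattice to standard PDB, re-parses it, and shows that the
classification is unchanged; then adds seeded Gaussian jitter to the
side chains (backbone fixed) and shows the topology call is stable --
the descriptors depend on architecture, not on exact rotamers.
"""

import tempfile
from pathlib import Path

from crossbeta import (
    LatticeSpec,
    build_lattice,
    parse_structure,
    perturb_lattice,
    write_structure,
)
from crossbeta.config import RunConfig
from crossbeta.pipeline import analyze

structure = build_lattice(LatticeSpec(class_id=8, sequence="LYIQWL"))

with tempfile.TemporaryDirectory() as td:
    path = Path(td) / "class8.pdb"
    write_structure(structure, path)
    reread = parse_structure(path)
    print(f"wrote and re-read {len(reread.atoms)} atoms, "
          f"cell b = {reread.cell.b:.3f} A (two-strand antiparallel repeat)")
    result = analyze(reread, RunConfig())
    print(f"overall class after round-trip: {result.topology.overall.class_id}")

for seed in (0, 1, 2):
    jittered = perturb_lattice(structure, sigma=0.2, seed=seed)
    result = analyze(jittered, RunConfig())
    classes = sorted(
        {zc.class_id for zc in result.topology.per_interface.values()}
    )
    print(f"seed {seed}: 0.2 A side-chain jitter -> classes {classes}")

# Class 8 is the antiparallel up-down topology the Trp-bearing peptide
# adopts when crystallized from water; the call survives jitter because
# parity and direction are majority votes over many contacts.
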