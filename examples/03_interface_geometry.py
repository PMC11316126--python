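"""Geometric descriptors: aromatic ladders, ring pairs, termini distances.

Parallel in-register sheets stack identical side chains at the fibril
rise, producing "ladders" (Tyr, Asn, Gln). Aromatic rings across an
interface are characterized by centroid distance and interplanar angle;
chain-termini distances report how far apart the like-charged ends sit.
"""

from crossbeta import LatticeSpec, build_lattice
from crossbeta.config import RunConfig
from crossbeta.geometry import termini_distances
from crossbeta.pipeline import analyze, geometry_summary

structure = build_lattice(LatticeSpec(class_id=3, sequence="LYIQNL", rise=4.8))
result = analyze(structure, RunConfig())
summary = geometry_summary(result, RunConfig())

for lad in summary["ladders"]:
    print(f"{lad.residue_type} ladder: {lad.spacing:.2f} A spacing, "
          f"{lad.n_rungs_observed} rungs")
for g in summary["aromatic_pairs"][:2]:
    print(f"aromatic pair {g.residue_a}-{g.residue_b}: "
          f"centroid distance {g.centroid_distance:.2f} A, "
          f"interplanar angle {g.interplanar_angle:.1f} deg ({g.context})")
for f in result.interfaces:
    nn = next(r for r in termini_distances(f) if r.pair_type == "N-N")
    print(f"{f.label}: nearest N-terminus pair across the zipper {nn.minimum:.2f} A")

# The ladder spacing equals the 4.8 A rise exactly because the generator
# stacks strands by pure translation -- the same number a diffraction
# experiment reads off the fibril-axis cell edge.
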