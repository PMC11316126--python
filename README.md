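# crossbeta

Steric-zipper topology classification, solvation energetics and
interface geometry for amyloid-like peptide crystals.

Short aggregation-prone peptide segments (APRs) crystallize as
amyloid-like lattices: extended β-strands stacked at a ≈ 4.8 Å rise into
β-sheets, with pairs of sheets interdigitating their side chains across
dry *steric-zipper* interfaces. The relative arrangement of the two
sheets — parallel or antiparallel strands, face-to-face or face-to-back
surfaces, same or opposite strand direction — defines the ten standard
topology classes of amyloid-like crystals. `crossbeta` is for structural
biologists working with such crystals: it reads a deposited PDB/mmCIF
entry (or builds an idealized lattice), finds the sheets and zipper
interfaces from the crystal symmetry, assigns each interface a topology
class, estimates its stability, and measures the geometric descriptors
the field reports.

## The core quantities

**Topology class.** Each interface is reduced to three measured binary
descriptors — sheet sense, surface parity (side chains of even-numbered
residues form a strand's *face*, odd-numbered its *back*), and relative
sheet direction — and mapped through a versioned lookup table to classes
1–10. The crystal's overall topology is the class of the interface with
the largest buried area per strand.

**Formation energy.** For a double layer of 2 × 3 strands (parallel) or
2 × 6 (antiparallel) built from crystal symmetry,

E_form = Σ_i σ_i · ΔASA_i / n_strands   [kcal·mol⁻¹ per strand]

where ΔASA_i is the solvent-accessible surface area atom *i* loses on
assembly (summed over central strands only), σ_i the atomic solvation
parameter of its class (Eisenberg–McLachlan set), and the reference
state is either the isolated sheets or the isolated monomeric strands.
Stable zippers sit near the published −1.417 kcal·mol⁻¹/strand median,
weak LARKS-like interfaces near −0.443.

**Geometry.** Aromatic ring-pair centroid distances and interplanar
angles, side-chain ladder spacings along the fibril axis, and distances
between like-charged chain termini across each interface.

## Worked example

```python
from crossbeta import LatticeSpec, build_lattice
from crossbeta.config import RunConfig
from crossbeta.pipeline import analyze

structure = build_lattice(LatticeSpec(class_id=3, sequence="LYIQNL"))
result = analyze(structure, RunConfig(), with_energies=True)
for f in result.interfaces:
    zc = result.topology.per_interface[f.label]
    e = next(e for e in result.energies if e.interface_label == f.label)
    print(f.label, zc.class_id, [n for n, _ in f.contact_residues("a")],
          round(e.e_form_sheets, 2), round(e.e_form_monomers, 2))
print("overall:", result.topology.overall.class_id)
```

prints

```
S1 3 ['ASN', 'ILE', 'LEU'] -1.26 -4.47
S2 3 ['GLN', 'LEU', 'TYR'] -0.85 -4.07
overall: 3
```

The generator was asked for a class-3 lattice of the hexapeptide LYIQNL:
the self-complementary topology in which identical residues face each
other across both zippers. The pipeline measures that back from raw
coordinates — one interface packs the odd residues (Leu1/Ile3/Asn5
against themselves), the other the even residues (Tyr2/Gln4/Leu6), both
class 3. The energies say the hydrophobic odd-residue zipper (S1,
−1.26 kcal·mol⁻¹/strand from sheets) is the more stable of the two, in
the range of published stable zippers, and the monomer-reference values
(−4.5, −4.1) additionally contain the sheet-formation term.

The same pipeline runs from the shell:

```sh
crossbeta synth --class 3 --sequence LYIQNL --out class3.pdb
crossbeta classify class3.pdb
crossbeta energy class3.pdb --format json
crossbeta geometry class3.pdb
```

`examples/` contains one short narrative script per capability.

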