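# Methods

`crossbeta` analyzes amyloid-like crystal structures of short peptides:
it classifies steric-zipper interfaces into the ten cross-β topology
classes, estimates double-layer formation energies from buried surface
area, and measures the interface geometry descriptors used in the
amyloid-crystal literature. This note records the models, conventions
and numerical choices, and what the synthetic test bed does and does not
establish.

## The cross-β model and the topology classes

The package assumes the linear cross-β architecture of amyloid-like
peptide crystals: extended β-strands stacked perpendicular to a fibril
axis at a rise of ≈ 4.8 Å, grouped into β-sheets by backbone hydrogen
bonding, with pairs of sheets meeting at dry steric-zipper interfaces.
A strand's side chains alternate between two surfaces; by convention the
side chains of even-numbered residues form the strand's *face*, those of
odd-numbered residues its *back*.

A zipper interface is reduced to three binary descriptors measured from
geometry:

1. **sheet sense** — parallel or antiparallel strand stacking within
   each sheet (pairwise N→C direction dot products along the stack);
2. **surface parity** — whether the two surfaces meeting at the zipper
   have the same parity (face-to-face or back-to-back) or opposite
   parity (face-to-back). Each side's parity is a majority vote of its
   side-chain atoms within the contact cutoff, with a Cβ-projection
   fallback when the vote ties;
3. **sheet direction** — whether the facing strands run the same way
   (N-to-N / up-up) or opposite ways (N-to-C / up-down). For parallel
   sheets this is the dot product of the sheets' common N→C directions;
   for antiparallel sheets, a majority vote over nearest strand pairs
   across the interface.

The descriptor→class lookup ships as a versioned resource
(`data/zipper_classes.tsv`, version `fig1-v1`):

| class | sense | parity | direction |
|---|---|---|---|
| 1 | parallel | same | opposite |
| 2 | parallel | opposite | same |
| 3 | parallel | same | same |
| 4 | parallel | opposite | opposite |
| 5 | antiparallel | opposite | same |
| 6 | antiparallel | opposite | opposite |
| 7 | antiparallel | same | same |
| 8 | antiparallel | same | opposite |

Class 3 is the fully self-complementary arrangement — identical residues
face each other across the zipper and the sheets run parallel both along
and perpendicular to the fibril axis. Classes 9 and 10 (parallel
arrangements with no observed example) have no operational geometric
criterion in the literature this transcription follows; they are carried
as flagged placeholder rows that the measurement-driven classifier never
emits and the lattice generator refuses to build. Descriptor
combinations outside the table return `"unclassified"` — never the
nearest class.

A crystal's **overall topology** is the class of the interface with the
largest buried area per strand, with every per-interface class retained
in the report; mixed-topology crystals (a dominant class-1 interface
with minor class-4 interfaces, or the reverse) are therefore represented
faithfully.

Direction dot products within ±0.3 of zero raise an "oblique interface"
error rather than a forced label: the descriptors are only meaningful in
the linear cross-β regime.

## Pipeline conventions

- **Fibril axis**: the unit-cell axis with length in [4.3, 5.3] Å (one
  strand per repeat). If none matches, an axis in the doubled window
  [8.6, 10.6] Å is accepted as a two-strand antiparallel repeat.
  Ambiguity is an error, overridable by naming the axis.
- **Expansion**: all symmetry/lattice copies of each peptide chain whose
  centroid falls within 30 Å (default) of the asymmetric unit centroid.
  Space groups are limited to those occurring in amyloid-like peptide
  crystals (P 1, P 2, P 2₁ settings, P 2₁ 2₁ 2₁, C 2); anything else is
  an explicit error, never a silent P 1 fallback.
- **Sheets**: strand copies joined when ≥ 2 backbone N···O pairs fall
  within 3.5 Å; connected components ordered along the fibril axis.
- **Interfaces**: a sheet pair with ≥ 5 heavy-atom contact pairs within
  5.0 Å involving the central strands. Symmetry-equivalent interfaces
  (same contact-residue composition and parity pair) are reported once.
  Labels S1, S2, … are assigned by descending buried area per strand;
  ties break on the deterministic contact signature.
- **Hydrogens** are dropped on input; alternate locations keep conformer
  A (or the highest-occupancy conformer, configurable). Missing
  side-chain atoms are used as-is, and every energy reports the atom
  count actually summed so comparisons stay explicit.

All cutoffs are configuration keys (`RunConfig`), and every report embeds
the resolved configuration, the lookup-table version and the parameter
provenance. Reports are byte-deterministic: no timestamps, no paths, a
fixed sphere-point set instead of random SASA sampling.

## Formation energies

Double layers are built from crystal symmetry as 2 × 3 strands for
parallel sheets and 2 × 6 for antiparallel sheets (two-strand repeat).
Per-atom solvent-accessible surface areas are computed in the double
layer and in each reference state; the differences, restricted to the
central strand(s) of each sheet, are weighted by atomic solvation
parameters and divided by the number of central strands summed:

E_form = Σ_i σ(class_i) · [ASA_i(double layer) − ASA_i(reference)] / n_central

with reference = the isolated sheets (*E_form from sheets*, zipper
formation proper) or the isolated monomeric strands in their deposited
conformation (*E_form from monomers*, sheet + zipper formation). σ > 0
for apolar classes, so burying hydrophobic surface is favourable
(negative). Report annotation compares the sheet-formation energy to
published medians for stable zippers (−1.417 kcal·mol⁻¹/strand) and
LARKS-like weak interfaces (−0.443), with an explicit intermediate band;
the annotation never alters the numbers.

Choices worth knowing:

- **Parameters** (`data/solvation_params.tsv`): the five-class
  Eisenberg–McLachlan set (C +16, neutral N/O −6, charged O −24,
  charged N −50, S +21 cal·mol⁻¹·Å⁻², heavy-atom radii 1.90/1.70/1.40/
  1.85 Å, probe 1.4 Å). Terminal amine and carboxylate, Asp/Glu
  carboxylates and Lys/Arg side-chain nitrogens are treated as charged,
  matching the mildly acidic crystallization conditions. The file is an
  editable resource (`--params`); provenance travels in every report.
- **Divisor**: "divided by the number of strands" is read as the number
  of central strands actually summed (2 for 2 × 3, 4 for 2 × 6), since
  only central-strand atoms enter the sum. The alternative (total
  strand count) is one flag away (`divisor_convention = "total"`) and
  the divisor used is printed in every report.
- **Central-strand convention**: summing only mid-stack strands removes
  stack-edge artifacts; extending stacks from 2 × 3 to 2 × 5 moves the
  per-strand energy by < 0.001 kcal·mol⁻¹ on the synthetic test bed
  (tolerance asserted: 0.05).
- **Solvent**: crystallographic solvent (ethanol, water) is excluded
  from the energy systems by default; `include_solvent_in_energy`
  attaches expanded solvent copies within 4 Å of a sheet to that sheet's
  systems. The parameters were calibrated for water, so solvent-laden
  interfaces carry extra model error either way.
- **SASA**: Shrake–Rupley-style sphere sampling with a deterministic
  golden-angle spiral point set, 960 points per atom by default.
  An isolated sphere is exact to < 10⁻¹³ relative error; a 20-atom
  cluster agrees with a 10⁶-sample Monte-Carlo rejection oracle to
  < 0.1 % and with an independent engine (biotite) to < 0.3 %. The point
  set lives in the laboratory frame, so rigid rotation of a system moves
  energies by ≲ 0.002 kcal·mol⁻¹/strand — far below the model error and
  the report precision.

## Geometry descriptors

Aromatic rings use the six-membered carbon ring (Tyr OH and Cβ excluded,
so they cannot bias the centroid); the plane is the best-fit plane
(smallest principal direction), and interplanar angles are folded to
[0°, 90°] because ring normals have sign ambiguity. Interplanar
*distance* is the mean projection of the centroid offset onto the two
ring normals — equal to the centroid distance for parallel translated
rings, and 0 for an identical ring. Ladder spacing is the fibril-axis
separation of equivalent side chains in consecutive (translationally
equivalent) strands; antiparallel sheets report the two-strand repeat
distance, flagged as such. Termini distances are N(residue 1)–N and
terminal-carboxyl C–C distances across an interface, sorted ascending.
When several aromatic pairs exist at an interface, all pairs with
centroid distance < 8 Å are reported and the nearest pair is matched to
published values, since publications do not name the copy pair measured.

## The synthetic lattice generator

`build_ideal_strand` constructs all-heavy-atom peptides by internal
coordinates (NeRF): φ = −139°, ψ = 135°, ω = 180° (ideal β), standard
bond geometry, L-chirality via the +122.6° N–C–Cα–Cβ improper, and one
fixed rotamer per residue type for determinism. The strand is placed in
a canonical frame: N→C along +x, carbonyls along ±y (the hydrogen-bond
direction), even-residue side chains toward +z. Proline is refused (its
ring is incompatible with the ideal-strand backbone); all other standard
residues are supported.

`build_lattice` realizes a topology class by construction: sheet 1
stacks the strand by pure 4.8 Å translation (parallel) or a two-strand
Rz-related repeat (antiparallel); sheet 2 is generated by the point
operation that produces the class's descriptors — identity translation
(face-to-back, same direction), rotation about the strand axis
(face-to-face, same), about the fibril axis (face-to-face, opposite), or
about the sheet normal (face-to-back, opposite) — at 10 Å sheet spacing,
with a half-rise axial stagger for parallel classes (mirroring the screw
operations of real zipper crystals) and aligned registry for
antiparallel classes (so the one-rise shift separating up-up from
up-down stays well defined). The default emission is a minimal periodic
P 1 description whose cell regenerates the infinite sheets under lattice
translation, exercising the same expansion path as a deposited crystal;
an explicit mode emits finite stacks for controls such as widely
separated sheets.

What the synthetic bed establishes: generator → classifier round-trip
recovers every transcribed class from raw coordinates (including under
0.2 Å side-chain jitter across 20 seeds), the energy pipeline runs
end-to-end with finite negative energies in the published range
(synthetic class-3 LYIQNL: S1 −1.26, S2 −0.85 kcal·mol⁻¹/strand from
sheets), and every measured constructed quantity (rise, offsets,
spacings) is recovered exactly. What it does not establish: agreement
with experimentally refined coordinates — ideal lattices have exact
symmetry, single rotamers and no solvent, and long polar side chains of
facing sheets can interpenetrate at the idealized 10 Å spacing (no
relaxation is attempted; clash handling beyond a sanity check is out of
scope). Validation against the deposited hexapeptide structures
(per-interface energies, classes, aromatic geometry, cell constants)
lives in the test suite and requires the ~100 KB deposited coordinate
files, fetched by `scripts/fetch_deposited.py` on a networked machine.

## Problem sizes and determinism

Default problem sizes keep any single analysis around a second on one
core: 30 Å expansion radius (a few dozen strand copies), 960 sphere
points per atom, 2 × 3 / 2 × 6 energy systems (~100–250 atoms per SASA
call). The robustness suite classifies 8 classes × 21 structures with
area computation disabled (labels then follow the deterministic contact
signature), and the Monte-Carlo SASA oracle uses 10⁶ samples. All
randomness (jitter, oracle sampling) is seeded; the production pipeline
itself contains none.

## Known limitations

- Kinked strands (LARKS), heterotypic two-sequence zippers and full
  cryo-EM fibril folds are out of scope; descriptors assume the linear
  cross-β regime and error out otherwise.
- Classes 9/10 are placeholders pending an operational criterion.
- The energy model is a buried-surface-area estimate: no electrostatics
  beyond the charged-atom solvation classes, no relaxation, no entropy.
- The monomer reference uses the deposited strand conformation, not an
  idealized extended strand; if a published value used a different
  reference state, the difference is reported, not hidden.
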