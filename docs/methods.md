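# Methods

This note records the models, parameters and numerical choices behind the
package, including decisions that a different implementer could
legitimately have made differently.

## Coordinate model

Structures are read with gemmi and collapsed to a single model (the first,
or `model = N` from the configuration) with one conformer per residue: for
each atom name the highest-occupancy altloc wins, ties breaking toward the
alphabetically first altloc. Author residue numbering and insertion codes
are kept throughout, since all reports cite author numbers. Waters are
dropped; other HETATM groups are kept as hetero residues so metal sites
remain analysable; selenomethionine is mapped to methionine (SE → SD).
Covalent chain continuity is defined by C(i)–N(i+1) ≤ 2.5 Å and no
dihedral, turn or backbone H-bond is evaluated across a break.

## Secondary structure

Assignment follows the Kabsch–Sander hydrogen-bond model. The amide
hydrogen is placed 1.0 Å from N along the preceding residue's C→O
direction (reversed); prolines and fragment-starting residues have none
unless the file provides an H atom. A backbone H-bond is accepted when the
electrostatic energy

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  <  −0.5 kcal/mol,

with pairs prefiltered at Cα–Cα < 9 Å and sequence separation ≥ 2.
α-helices (H) come from two consecutive 4-turns, 3₁₀ (G) and π (I)
helices analogously but only where no H/E label stands, strands (E) and
isolated bridges (B) from parallel/antiparallel bridge patterns and their
ladders, hydrogen-bonded turns (T) from otherwise unused n-turns, and
bends (S) from >70° backbone curvature over ±2 residues.

β-turns are four-residue windows with Cα(i)–Cα(i+3) ≤ 7 Å and neither
central residue helical. Types I, I′, II, II′ and VIII are assigned when
the central φ/ψ pairs fall within ±30° of canonical values (one angle
allowed ±45°); everything else is type IV. "Second position" means
residue i+1. Helix segments are maximal H-runs of length ≥ 4; the N-cap
is the residue immediately preceding the first helical residue.

## Accessible surface area

Shrake–Rupley sampling with a deterministic golden-spiral lattice
(default 960 points/atom, probe 1.4 Å) over heavy atoms only, with
NACCESS-style element radii (C 1.87, N 1.65, O 1.40, S 1.85 Å) chosen to
absorb implicit hydrogens. Relative accessibility divides the residue
total by its extended Gly-X-Gly reference area; residues below 10%
relative ASA are "buried". Polar area is that of N/O atoms, nonpolar that
of C/S; their totals give the NP/P ratio. The lattice is validated
against the analytic sphere (isolated atom, <1% error) and a 10× denser
lattice (<2% drift), and cross-checked against an independent
implementation in the test suite.

## Non-covalent interactions

Default criteria (all configurable):

| type | criterion |
|---|---|
| IP | charged side-chain N (Arg/Lys/His) to carboxylate O (Asp/Glu) ≤ 6.0 Å, one pair per residue pair (closest atoms) |
| AAI | Phe/Tyr/Trp ring-centroid distance in [4.5, 7.0] Å |
| ASI | Cys SG / Met SD to ring centroid ≤ 5.3 Å |
| CPI | Lys NZ or Arg guanidinium centroid to ring centroid ≤ 6.0 Å |
| HB | donor–acceptor heavy atoms ≤ 3.5 Å; when a backbone amide H can be constructed additionally H…A ≤ 2.5 Å and D–H…A ≥ 90°; classed MM/MS/SS |
| HP | side-chain carbon contact < 5.0 Å between Ala/Val/Leu/Ile/Met/Phe/Trp/Tyr, once per residue pair |
| disulfide | SG–SG in [1.8, 2.5] Å |

Sequence separation must be ≥ 2 within a chain (backbone H-bonds exclude
only the peptide-bond neighbors); Trp contributes its full nine-atom ring
system; His rings are not counted as aromatic partners for AAI/ASI/CPI.
Reciprocal hydrogen bonds (donor→acceptor in both directions, as in
antiparallel sheets) are kept as distinct contacts.

Networks are connected components of the same-type interaction graph that
contain at least two interactions, reported largest first. Mixing types
in one network is deliberately an error.

## Feature vector and comparison

Nineteen parameters per structure: Aro/UP/Pro/ALI/CHG contents, R/K,
the six interaction totals, Bt2P (prolines at turn second positions),
NCap (prolines at helix N-caps), Hdip (fraction of helices with Asp/Glu
at Ncap–N3 or Lys/Arg/His at C3–Ccap), TL (Asn-Gly/Asn-Ser deamidation
hotspots), CS (non-Gly residues with φ in (10°, 140°)), NP/P and Loop
(1 − helix − strand fraction). Normalization: sequence length for
contents, interactions, CS and Loop; proline count for Bt2P/NCap; helix
count for Hdip; Asn+Gln count for TL; R/K and NP/P are used raw.

Percentage change for a thermophile/mesophile pair is
(TS_norm − MS_norm)/MS_norm. A parameter absent (zero or undefined) in
both members prints `#`; absent only in the mesophilic member prints `~`
(there is no finite change from zero); absent only in the thermophilic
member the formula yields −1.00 and stays numeric. The per-parameter
positive count over a panel counts numeric values > 0 plus `~` cells.

Prediction evaluation treats stability increase as the positive class. A
neutral experimental outcome counts against the prediction (predicted I →
false positive, predicted D → false negative). The headline ratio
TP/(TP+FP) is precision; the conventional TP/(TP+FN) is also reported,
and a symmetric neutral band swept over prediction scores generates ROC
points.

## Mutation strategies and mutants

Scans: X→Pro at turn second positions (with a φ ∈ [−90°, −30°]
compatibility flag) and helix N-caps; X→Gly at strained residues (strain
distance = Cβ to own carbonyl O); double X→Cys at pairs with Cβ–Cβ in
[3.4, 4.6] Å, Cα–Cα in [4.0, 7.5] Å and separation ≥ 4, excluding
residues already in disulfides and ranked by enclosed loop size (larger
loop, larger unfolded-state entropy reduction). Conservation scores (1–9)
come from a user alignment: the row matching the chain sequence at ≥ 95%
ungapped identity anchors columns, and the score is ceil(9p) clamped to
[1, 9] where p is the column frequency of the wild-type residue.

Mutants are built deterministically, with no minimization, so results are
exactly reproducible. When the target side chain's heavy atoms are a
subset of the wild one (X→Ala/Gly, Glu→Asp, …) the side chain is
truncated in place; otherwise it is regrown on the unchanged backbone
with ideal geometry at the most common rotamer, and steric clashes
(< 2.0 Å to another residue) are reported, never resolved. Every atom of
every unmutated residue is left bit-identical — local interaction-profile
differences are then attributable to the mutation alone. The built-in
stability score is a weighted whole-structure interaction-count delta
(weights: IP 1.0, disulfide 2.0, HB/AAI/CPI 0.5, ASI/HP 0.3); it is a
screening heuristic, not an energy function, and external predictors can
be registered as plugins.

## Synthetic structures

The fixture generator grows peptides residue-by-residue from ideal bond
lengths/angles at requested φ/ψ (NeRF construction), so canonical
conformations are produced exactly: ideal helices, extended strands,
typed β-turns, left-handed (strained) sites, residue pairs with two named
atoms at an exact distance, and tetrahedral Cys₄ metal sites. They exist
to give tests controlled geometry; they are not models of real proteins.

## Limitations

- Mutant side chains use a single fixed rotamer and no relaxation;
  absolute mutant interaction counts can differ from minimized models
  even when the wild-type profile matches.
- The built-in stability heuristic ignores strain, packing and solvation.
- His is treated as charged for ion pairs but not aromatic for ring
  interactions; alternative conventions exist.
- SASA ignores hydrogens and uses a fixed radius per element.
- Conservation requires the alignment to contain the chain sequence.
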