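# prostab

Structural profiling of protein thermostability: comparative feature
analysis of thermophilic/mesophilic structure pairs, strategy-based
scanning for stabilizing mutations, and deterministic mutant building
with local interaction-profile diffs.

The package computes, per structure, nineteen sequence/structure
parameters associated with thermostability — residue-class contents,
six classes of non-covalent interactions and their networks, proline
placement at β-turn second positions and helix N-caps, helix-dipole
stabilization, deamidation-prone Asn/Gln sites, conformationally
strained residues, nonpolar/polar surface-area ratio and loop content —
and compares them across structure pairs as percentage changes. On top
of that core it scans structures for candidate stabilizing mutations
(proline insertion, strain release, engineered disulfides, or
user-supplied lists), annotates candidates with alignment-derived
conservation scores, and rationalizes mutations by diffing the
wild-type and mutant local interaction profiles. See
[docs/methods.md](docs/methods.md) for models, parameters and
limitations.

## Worked example

Generate two synthetic 18-residue helices differing in charged versus
uncharged-polar content, and compare them as a (thermophile-like,
mesophile-like) pair:

```sh
prostab fixtures --kind ideal_helix --length 18 --sequence ADKAEAVRAALKAHAEKA --out helix_a.pdb
prostab fixtures --kind ideal_helix --length 18 --sequence ANQASAVSTALNAHASQA --out helix_b.pdb
printf 'helix_a.pdb\thelix_b.pdb\n' > pairs.tsv
prostab icaps --pairs pairs.tsv --out-dir icaps_out
```

`icaps_out/comparison.tsv` (configuration header lines elided):

```text
parameter	helix_a/helix_b	positive_count
Aro	#	0
UP	-1.00	0
Pro	#	0
ALI	0.00	0
CHG	7.00	1
R/K	~	1
IP	#	0
AAI	#	0
ASI	#	0
CPI	#	0
HB	-0.29	0
HP	0.00	0
Bt2P	#	0
NCap	#	0
Hdip	~	1
TL	#	0
CS	#	0
NP/P	-0.08	0
Loop	0.00	0
```

Cells are (TS − MS)/MS on normalized values. `#` marks a parameter
absent in both structures, `~` one present only in the first (no finite
change from zero); the positive count tallies numeric cells > 0 plus `~`
cells. Here the charged content (CHG) is 8× higher in the first helix,
its uncharged-polar content change is −1.00 (it has none), and the R/K
ratio and dipole-stabilized helix fraction exist only in the first.

Diff the local interaction profile across a salt-bridge knockout:

```sh
prostab fixtures --kind residue_pair --out pair.pdb   # Asp1 ... Lys10, OD1-NZ at 3.0 A
printf 'D1A\n' > muts.txt
prostab imutants pair.pdb --mutations muts.txt --out profiles.tsv
```

`profiles.tsv`:

```text
MutNo	Type	Chain	ResNo	ResID	IP	IPNet	AP	APNet	AS	ASNet	HB	Disul	Catpi	CatpiNet	Hphob
1	wild	A	1	D	1	-	-	-	-	-	2	-	-	-	-
1	mut	A	1	A	-	-	-	-	-	-	1	-	-	-	-
```

Truncating Asp1 to alanine loses the ion pair (IP 1 → −) and one of the
two hydrogen bonds; `-` means no interaction of that class.

Strategy scans and stability prediction:

```sh
prostab istability helix_a.pdb --strategy ncap --out candidates.tsv
prostab istability helix_a.pdb --strategy custom --mutations muts.txt --msa family.fasta
```

Each candidate row carries the strategy, the mutation(s), geometric
annotations (turn type, φ, loop size, …), an optional 1–9 conservation
score from the alignment, and the predictor's score with its I/D
(increase/decrease) call.

The same functionality is available programmatically:

```python
from prostab import load_structure, feature_vector, find_interactions

st = load_structure("helix_a.pdb")
fv = feature_vector(st)
print(fv.normalized["CHG"], len(find_interactions(st, "HB")))
```

## Configuration

All cutoffs and thresholds are configurable through a plain
`key = value` file echoed into every report header:

```sh
prostab config-template analysis.cfg
prostab icaps --config analysis.cfg structure.pdb
```
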