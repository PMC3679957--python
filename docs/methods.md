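# Methods

## Scope and model

The package analyses a labelled protein-family alignment the way
membrane-transporter comparative studies are done by hand: a curated
multiple alignment of plant MHX (vacuolar Mg²⁺/H⁺ exchanger) and NCX
(Na⁺/Ca²⁺ exchanger) sequences is scanned for columns that are totally
conserved within declared sequence subsets, for diagnostic sites that
separate subsets, and for conserved motifs; a biochemically determined
reference topology (nine transmembrane segments, two reentrant loops,
the large cytosolic loop carrying the XIP and Ca²⁺-binding-domain
overlays) is projected through the alignment to attribute conservation
to structural regions; the internal α1/α2 repeats are compared in a
residue-class alphabet; and 5′ UTRs are censused for upstream AUGs.

The package consumes alignments; it never builds them. Curated
alignments typically carry manual adjustments that no aligner
reproduces, so alignment construction is treated as input, and
alignments can be exported (aligned FASTA, relaxed PHYLIP) for external
tree tools. Tree inference itself is out of scope.

## Conservation calls

A column is conserved in subset *S* iff all members of *S* share one
residue there that is neither `-` nor `X`. This all-or-nothing rule is
deliberate: the analyses this package supports highlight only total
conservation, and a single gap or ambiguous residue is treated as
evidence against a conserved call rather than missing-at-random. The
consequences:

* `X` never matches anything, including another `X`;
* differential sites (strict and disjoint modes alike) are disqualified
  by a gap or `X` anywhere in either group;
* enlarging `conserved_in` can only shrink a rule's matched set
  (monotonicity), and strict-mode sites are always a subset of
  disjoint-mode sites — both properties are tested.

Rules are evaluated independently per column; display precedence
(red > pink > light-green > orange > dark-green > olive > gray) is a
rendering concern only, applied in `mhxscan.report`.

## Region statistics

Regions are 1-based closed intervals on one reference sequence and
must tile it exactly; totals therefore count *reference residues*, not
alignment columns, which keeps the per-region totals summing to the
reference length even when other rows carry insertions. Percent
identity is rounded half-up to an integer for display (the exact
counts are always reported alongside). Regions named `TMS*` feed the
"All TMSs" aggregate; everything else, including the reentrant loops,
counts as non-TMS.

## Topology model and projection

A `TopologyModel` stores named core regions (tiling) plus overlapping
overlays (α1, α2, XIP, CBD1/2, signal peptide) and an explicit
signal-peptide length, making mature↔precursor numbering conversion
explicit for references whose literature coordinates refer to the
mature protein. Orientation uses `in` = cytosolic for both
plasma-membrane and tonoplast proteins: the vacuolar lumen and the
extracellular space share pH and electrochemical-potential polarity,
so lumen-facing loops are `out`.

Projection maps each region's reference interval to its alignment
column span and then to the first/last non-gap residue of each target
within that span. A target fully gapped under a region yields an
explicitly flagged empty interval. Insertions private to a target that
fall *between* two regions belong to neither; this keeps projected core
regions ordered and non-overlapping for every target, which is tested.

No curated real-coordinate topology file is shipped: exact NCX1 TMS
boundaries are published as figure annotations rather than coordinate
tables, so the package provides the YAML format (and generator-emitted
models) and expects users to transcribe coordinates from the primary
topology literature they trust.

## Hydropathy and TM-segment calling

Profiles are sliding-window means of Kyte–Doolittle values, default
window 19 (a typical α-helical TMS span), with `X` contributing the
scale mean. The TM-segment caller thresholds window midpoints at mean
hydropathy 1.6 and reports maximal runs clipped to [min_len, max_len]
(defaults 9 and 25, splitting over-long runs evenly). This is a
deliberately simple, documented method intended for qualitative profile
comparison between family members; authoritative region coordinates
come from the reference topology model, not from prediction, and the
caller's output is labelled accordingly.

## Pairwise percent scores

Global alignment via Biopython's `PairwiseAligner` with BLOSUM62, gap
open 10, extend 0.1 — the convention of the classic progressive
aligners — and score = 100·identities/shorter-sequence-length, rounded
half-up. Because co-optimal alignments can differ in identity count,
the implementation takes the maximum identity count over co-optimal
alignments (capped enumeration), which makes the score well-defined
independent of traceback tie-breaking; the test suite checks it against
an independent affine-gap (Gotoh) dynamic program maximising
(score, identities) lexicographically. The denominator is configurable
(`shorter`/`longer`/`alignment`) since published "similarity scores"
vary in this choice.

## Consensus and repeat comparison

The residue-class scheme is the standard eight-class alphabet
(aromatic `@` FWYH, aliphatic `u` ILV, basic `1` HKR, acidic `2` DE,
charged `p`, hydroxylic `$` ST, methyl `m` ASC, small `o` GASC);
`p` is by construction the union of `1` and `2`, and specificity order
is set size (smaller = more specific). Per column: total conservation →
uppercase; else plurality ≥ `plurality_threshold` (default 0.7, over
all subset members, gaps counting against) → lowercase; else all
residues within one class (fraction ≥ `class_threshold`, default 1.0)
→ the most specific such class symbol; else `.`; gap-majority columns
render `-`. The 0.7/1.0/0.8 defaults are package choices recorded in
output headers — the qualitative notions they implement ("most common
residue", "most or all") have no canonical numeric values.

Repeat comparison pairs the α1 and α2 column lists position by
position, optionally after user-supplied `*`/`-` gap-placement strings
(the repeats of real exchangers need manual gapping to pair well). A
pair is `identical_in_most_or_all` when ≥ `majority_fraction`
(default 0.8) of member sequences carry the *same residue at both
positions* — a per-sequence criterion, which makes comparison of a
region with itself trivially all-identical; `similar_nature` when that
fraction of members carries residues sharing a scheme class; `none`
otherwise. The combined consensus is computed jointly, each member
contributing its residues from both repeats, approximating the
pre-duplication ancestral sequence.

## uORF census

`find_uaugs` reports every ATG in the UTR (all frames). The Kozak
classifier is the two-determinant rule (purine at −3, G at +4):
strong = both, sub-optimal = exactly one, weak = neither,
indeterminate iff a determinant lies outside the available sequence —
these four classes partition all contexts, which is tested. The
classifier is pluggable so a different consensus (e.g. a plant-specific
one) can be swapped in. Translation walks codons with the standard
code; a stop codon *starting* within the UTR terminates the uORF there
(`stopped_in_utr`); otherwise translation continues into the
downstream CDS when supplied (`overlaps_main_orf` — the uORF crosses
the main AUG) or is flagged `truncated_no_sequence`. Prevalence
summaries report exact fractions alongside percentages; display
rounding is left to callers.

## Synthetic data: what it emulates, and what it does not

The default family (the package's standard study conditions) has 30
sequences: 24 MHX across eudicot (12), monocot (8), lycophyte (2) and
bryophyte (2) taxa, plus 6 NCX outgroup members; 550 ancestral
positions tiled by a 9-TMS / 2-reentrant-loop layout with a 149-residue
central loop. Planted structure: 32 columns conserved across everything
(10 of them glycines, echoing the glycine-rich conserved core of real
exchanger families), per-region family-conserved column quotas shaped
like a real family's profile (TMS ≈ 34%, second reentrant loop 40%,
last loop 50%, central loop 8%), three strict plus five disjoint
MHX/NCX differential sites, four vascular-versus-bryophyte disjoint
sites, three conserved motif runs (6, 5, 5 columns), hydrophobic
residue pools inside every TMS, and a 25-column internal repeat
duplicated with 5 divergent positions. UTR defaults: ten eudicot genes
all carrying ≥ 1 uAUG (one gene loaded with 11), six monocot genes of
which three carry none — so group prevalences of 100% and 50% are part
of the planted conditions.

Construction guarantees make the truth *exact*: rows outside a planted
conserved subset are forced to break both strict and disjoint
patterns; background columns are never conserved within any declared
group of ≥ 2 members; substitution noise (when enabled) only ever
destroys conservation and never touches planted differential sites,
motif runs or the repeat; indels are placed only in background columns
of non-reference rows unless explicitly overridden. All randomness
flows from one integer-seeded `random.Random` with no float-dependent
branching, so equal seeds give byte-identical files.

What the generator does **not** emulate: tree-structured evolution (no
substitution models, no rate variation, no correlated columns),
realistic indel processes, biased amino-acid composition outside TMSs,
UTR secondary structure, and alignment error — the truth alignment *is*
the emitted alignment. Passing tests therefore demonstrate detector
correctness on well-defined inputs, not robustness to misalignment or
to the soft conservation gradients of real families.

## Problem sizes and numerical choices

The test suite and the acceptance script run the 30 × 550 family (with
zero and 10% noise variants and an 8-indel variant), the 16-gene UTR
set, 100 random ≤ 12-mer pairs for the pairwise oracle, and 60-mer
random sequences for the hydropathy/charge oracles — sizes chosen so a
full verification pass completes in seconds on one CPU while exercising
every code path. Ties and degenerate inputs: percent displays round
half-up; empty subsets and non-tiling regions are errors, not warnings;
a conserved-run reference that is gapped under a run reports the first
non-gap reference position and flags the gap; `molecular_weight`
rejects `X` rather than guessing a mass.

## Known limitations

* Conservation is binary (total/not); no entropy, rate or
  significance modelling.
* The TM-segment caller is a threshold method; it will merge closely
  spaced TMSs and miss weakly hydrophobic ones.
* `overlaps_main_orf` is declared from sequence geometry alone; it
  does not model reinitiation or leaky scanning.
* The repeat comparison assumes the user's (or generator's) pairing;
  it does not discover repeats de novo.
* Group labels are set-valued tags; phylogeny-aware weighting of
  sequences is out of scope.
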