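# Methods

## Scope and architecture

The pipeline screens candidate signal peptides (SPs) for a secreted protein
expressed from a fixed vector. Five stages run in order: record ingest and
QC (`records`), fusion/transcript assembly and Kozak classification
(`constructs`), secondary-structure representation, folding and energy
evaluation (`rnastruct`), the filter cascade with windowed opening energy,
SP score, Z-scores and ranking (`scoring`), and a synthetic-data generator
with exact ground truth (`synthdata`). A thin click CLI drives the library.

Database harvesting is out of scope by design: ingest is file-based (TSV or
paired FASTA), and the external predictors (SignalP 6, DeepLoc 2) and
external folders (RNAfold/MXFold2-class tools) are consumed through their
standard output formats rather than re-implemented.

## Record QC

Four flags per record: CDS retrieved, length divisible by 3 ("in frame" —
the only frame property checkable on an isolated CDS), leading ATG, and
exact translation match against the protein sequence. The SP CDS is stored
without a stop codon (it is internal to the fusion ORF), so any stop codon
is a QC failure, as is any ambiguous IUPAC base — downstream folding needs a
concrete sequence. Deduplication keys on the exact CDS string and keeps the
first occurrence in input order; `sort_by="accession"` makes the survivor
set order-independent. Internal coordinates are 0-based half-open; reports
are 1-based inclusive.

## Transcript assembly and Kozak rule

A predicted transcript is 5′UTR + SP CDS + propeptide CDS + 3′UTR + poly-A
signal region + a literal poly-A tail (default 150 A's, folded with the rest
of the molecule), transcribed T→U. The 5′UTR is transcript-level — the bases
immediately upstream of AUG — so the start codon always sits at position
`len(utr5)` (1-based 151–153 with the packaged 150-nt UTR). The packaged
default UTR is the 150-nt tail of the published pVax promoter/UTR region;
the propeptide CDS, 3′UTR and poly-A region of the packaged default vector
are seeded *synthetic* stand-ins of realistic length (the real sequences are
not shipped), giving ~1.7 kb transcripts at full scale.

Kozak strength is classified as strong iff the −3 base (UTR tail) is a
purine **and** the +4 base (first base of the SP's second codon) is G; each
sub-condition can be disabled. Because the packaged UTR ends in GCCACC the
−3 condition is always met there and the filter reduces in practice to the
+4 G check.

## Energy model

A compact 37 °C nearest-neighbor parameterisation (Turner-style constants,
kcal/mol):

* stacking energies for all ordered combinations of the six canonical pair
  types (Watson–Crick + G·U);
* hairpin/bulge/internal initiation by loop size for sizes ≤ 30, continued
  as `init(30) + 1.079·ln(n/30)` beyond;
* single-nucleotide bulges retain the helix stacking term;
* internal-loop asymmetry (Ninio): `min(3.0, 0.6·|n1 − n2|)`;
* terminal A·U/G·U penalty 0.5, charged in the loop where the helix end is
  *not* continued by a stack (hairpin closings, both closings of bulges ≥ 2
  and internal loops, multiloop closing and branch pairs);
* affine multiloops: `3.4 + 0.4·(branches + 1) + 0.0·unpaired`;
* the exterior loop contributes exactly 0 (no dangles, no exterior terminal
  penalties).

Dangling ends, terminal mismatches, coaxial stacking and the special small
internal-loop tables are deliberately omitted. The model is therefore
exactly decomposable: `total_energy` is the sum of `loop_energy` over the
loop decomposition, to machine precision — the property the windowed opening
energy relies on, and the property the conservation tests assert at 1e-9.

## Folding engines

`fold_nussinov` maximises canonical pair count with a deterministic
traceback (pair the left end with its smallest optimal partner, else leave
it unpaired); it exists as a simple, exhaustively checkable backend and is
verified against explicit structure enumeration for all tested sequences of
length ≤ 18. `fold_mfe` is a Zuker-style dynamic program over the model
above: hairpin, two-way (stack/bulge/internal, total unpaired span capped at
30 to keep the cubic constant small) and affine multiloop cases, exterior at
zero. Tie-breaks in the traceback are fixed, so folds are deterministic.
Self-consistency (`mfe == total_energy(structure)` to 1e-6) and global
optimality against enumeration at length ≤ 14 are asserted in the suite.

The built-in engine is pure Python and cubic-time: it is intended for
windows, demonstrations and tests (≲ a few hundred nt). Full-length (~1.7
kb) transcripts should be folded externally — which mirrors the screen's own
architecture, where a dedicated structure predictor produces the structure
and this package evaluates and windows it. `read_external_structure` parses
Vienna dot-bracket files (optional trailing energy, non-canonical pairs
tolerated); a reported energy is used as the MFE, otherwise the packaged
evaluator recomputes one.

## Opening energy and SP score

The window is `[start − flank, start_end + flank)` — 33 nt at the default
flank of 15, including the start codon; `anchor="a"` gives the 31-nt
alternative centred on the A alone. A loop is counted iff at least one
endpoint of its closing or branch pairs lies inside the window: opening
energy measures the cost of melting the *pairs* occluding the window, so
unpaired membership alone does not trigger inclusion. An entirely unpaired
window has opening energy 0 and the candidate is flagged unscorable
(`sp_score` returns `None` with a warning) rather than raising.

`SP score = MFE / opening energy`. Z-scores use the population SD (divisor
n) over the scored candidate set being ranked — the population form uniquely
reproduces the published benchmark summary statistics, and the ranked set is
the natural reference population. Ranking is by descending SP score with
deterministic tie-breaks (less-negative opening energy, then accession).
Reports round energies to 1 dp, SP scores to 2 dp and Z to 1 dp; full
precision is kept internally.

Exclusion thresholds are strict-below: a Sec/SPI of exactly 0.5 passes. A
missing predictor score excludes the record at that stage (conservative),
logged per accession.

## Synthetic data

`gen_record_set` fabricates candidate sets with disjoint per-record defect
categories — frame errors, missing start codons, mistranslations, duplicate
CDSs (always emitted after the clean record they copy, so first-occurrence
dedup removes exactly the duplicates), weak Kozak contexts — plus mock
predictor scores drawn from a two-component mixture straddling the 0.5
thresholds, with exact-0.5 scores injected deliberately to exercise the
boundary. Default rates (2 %/2 %/3 % QC defects, 30 % duplicates, 20 % weak
Kozak, 31 % low Sec/SPI, 0 % low extracellular) approximate the relative
stage attrition of a real screen of this kind. Everything is seeded and
deterministic; regeneration is byte-identical, and the generator emits an
expected funnel that the pipeline must (and does) match exactly.

What the generator does **not** emulate: real SP sequence composition
(hydrophobic H-regions, leucine motifs), real predictor score distributions,
and the structure statistics of a trained mRNA-structure model — synthetic
folding inputs are random sequences. Passing tests therefore demonstrate the
pipeline's bookkeeping, metrics and invariants, not predictive accuracy on
biological data.

## Problem sizes and numerical choices

The suite folds random sequences up to ~150 nt, enumerates structures
exhaustively up to length 18 (pair counts) and 14 (energies), checks energy
conservation on 1000 random structures, and runs the synthetic funnel for 20
seeds; end-to-end demonstrations use a scaled-down synthetic vector
(~150–400 nt transcripts). These sizes were chosen to keep the whole suite
under a minute while still exercising every code path at full fidelity.
Floating-point tie-breaks in tracebacks use an epsilon of 1e-7 against
energies that are multiples of 0.01 (plus occasional log-extrapolation
terms), so ties are resolved reproducibly.

## Known limitations

* The energy model omits dangles/mismatch/coaxial terms, so absolute MFEs
  differ from full Turner-model folders; rankings of similar-length
  transcripts are affected much less, and external structures + reported
  energies bypass the limitation entirely.
* "In frame" cannot be checked against a genomic record for an isolated CDS;
  divisibility by 3 is the implemented interpretation.
* Whether the published opening-energy extraction summed loop energies or
  per-bond energies is not fully specified; the ≥ 1-endpoint loop rule
  implemented here is documented as this package's interpretation.
* The benchmark fixture stores opening energies as printed integers
  consistent with printed MFE / SP-score pairs (the published table layout
  runs numeric columns together).
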