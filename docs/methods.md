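# Methods

`panprimer` designs degenerate PCR primer pairs from a nucleotide multiple
sequence alignment (MSA) or a single template. This note documents the
models and procedures it implements, the parameters that matter, the
conventions chosen where several defensible readings existed, and the
limits of what the synthetic-fixture tests demonstrate.

## Pipeline overview

1. **Input.** Multi-FASTA (aligned or not) or Clustal. A collection is
   treated as aligned when all sequences have equal length *and* contain at
   least one gap, or when the caller says so explicitly; equal length alone
   is not alignment evidence. Unaligned multi-sequence input is delegated
   to an external MAFFT executable (`--globalpair` or `--localpair`,
   `--maxiterate 1000`); the adapter is injectable so the pipeline is
   testable without the binary, and a missing binary produces an
   actionable error rather than a crash.
2. **Consensus.** The alignment is restructured into per-column profiles
   (counts of A/C/G/T/gap across sequences; degenerate input codes
   contribute 1/fold to each member base). Each column receives:
   the single most common base if its ratio is at least the
   `majority_threshold` (default 0.9) and gaps are scarce; a deletion mark
   if the gap fraction reaches `gap_threshold` (default 0.5); otherwise the
   smallest IUPAC code covering every base whose frequency is at least
   `minor_threshold` (default 0.1). These cutoffs minimize consensus
   degeneracy while still covering recurrent variation; they are
   config-exposed because no canonical values exist. Ties for the top base
   break deterministically A < C < G < T.
3. **Conserved regions.** Maximal runs of fold-1, non-gap consensus
   columns at least one primer long (default 18). Coordinates are 0-based,
   half-open, on the forward consensus measured from the 5' end; regions
   can be exported as BED. A feasibility check requires some region pair
   (possibly one region) to span the minimum amplicon (default 100 bp,
   forward 5' start to reverse 5' start); if none does, the consensus is
   reported and the run ends with a notice, not an error.
4. **Candidates.** Every window of 18-30 columns inside the scope
   (conserved regions, or the whole template / a user range in filtration
   mode) is generated in both orientations, hard-filtered, and
   penalty-scored. Filtration mode is the default for single sequences.
5. **Pairing.** Both candidate lists are sorted by accrued penalty
   (ties: 5' start, then length). The forward x reverse cross product is
   enumerated lazily in exact combined-penalty order via a heap merge and
   examined in blocks of 1600 pairs; pairs that satisfy the amplicon, Tm
   and annealing constraints are accepted greedily, never reusing a primer
   sequence, until five pairs are found or the stream ends. Because the
   enumeration order is exactly the sorted order of the full cross
   product, the blocked algorithm returns precisely the greedy top five of
   the brute-force enumeration; the test suite verifies this equivalence
   against an O(n^2) oracle. The block size is a processing granularity
   (logging/batching), not an approximation knob.

## Thermodynamics

Duplex formation enthalpy/entropy are nearest-neighbor sums over
dinucleotide stacks plus initiation terms per terminal base (G/C vs A/T)
and a symmetry entropy correction for self-complementary oligos. The
shipped table (`data/nn_unified.tsv`, versioned, swappable) is the unified
oligonucleotide parameter set referenced to 1 M NaCl; reverse-complement
stacks share parameters, and a unit test pins every entry to its published
free-energy value at 37 C.

Melting temperature of a concrete oligo:

    Tm [K] = 1000 * dH / (dS + R * ln(CT / b));  Tm [C] = Tm - 273.15
                                                 + 16.6 * log10([Na+])

with R = 1.987 cal/(mol K), total strand concentration CT = 50 nM, b = 4
for non-self-complementary duplexes (1 for self-complementary), and 50 mM
monovalent salt — all config-exposed. The salt term is applied additively
after the Kelvin-to-Celsius conversion, the convention of the two-state
oligo model; the grouping is otherwise ambiguous when the formula is
written on one line. The implementation is cross-checked in the tests
against Biopython's independent `Tm_NN` code path to 0.01 C.

A degenerate primer is a mix of up to `expansion_cap` (64) concrete
species. Hard Tm filtering uses the min and max over expansions (every
species must sit inside the acceptable range, conservative); ranking and
pair matching use the mean (stable under small expansions).

Product annealing temperature uses the GC/length formula

    Tm_product = 81.5 + 0.41 * %GC + 16.6 * log10([K+]) - 675 / length

with [K+] defaulting to the same monovalent concentration. The 81.5
constant and the division by length are the standard form of this
formula; a variant omitting them yields non-physical values.

## Hard filters

A primer is disqualified by any of (vocabulary in parentheses is the
report label):

* **Degeneracy.** Any degenerate code in the first or last three bases;
  any N (4-fold) anywhere; more than one 3-fold code; more than two
  2-fold codes.
* **Deletions** (windows drawn from a gapped consensus). A deletion mark
  in a terminal trimer; more than three consecutive marks; more than six
  total; or a gap-free length under the size minimum.
* **GC content.** Expected GC fraction outside 40-60% (inclusive).
  Degenerate codes contribute fractionally: S counts 1, W counts 0, other
  2-folds 0.5, 3-folds (G/C members)/3, N 0.5.
* **Repeats.** Tandem (in-place) k-mer duplication for k = 2, 3, 4: a
  dinucleotide repeated more than twice beyond its first copy
  (ATATAT passes, ATATATAT fails), a trinucleotide more than once, any
  tandem tetranucleotide. Counting tandem duplications rather than global
  occurrences is deliberate: short motifs recur by chance in nearly every
  20-mer, and the benchmark panels bundled with the package contain
  accepted primers with repeated-but-dispersed k-mers; in-place repeats
  are the slippage-prone structures the filter is after. Degenerate
  primers are evaluated worst-case over expansions.
* **Comp. ends.** The 5' terminal trimer is the reverse complement of the
  3' terminal trimer. Mutually complementary primer ends let two copies of
  the primer anneal 3'-over-5' and extend, the classic end-mediated dimer
  geometry. The alternative reading — 3' trimer complementary to *any*
  internal site — was rejected because it disqualifies several primers the
  bundled benchmark panels accept.
* **Size.** Gap-free length outside 18-30 bp.
* **Temp** (test mode only). Any expansion's Tm outside [50, 65] C,
  boundaries inclusive. In design mode an out-of-range Tm accrues penalty
  instead (1 penalty unit per degree C of excursion, on the mean), so
  near-miss candidates still rank; the hard form would otherwise empty
  the candidate lists whenever a template offers only short windows.

## Penalty rules

Penalties never disqualify; they order the candidate lists (and pair
selection, additively). Weights default to 1.0 per hit and are
config-exposed; only relative ranking matters.

* **Hairpins.** One unit per window matching the triloop motif (5-bp
  window, complementary first/last base, G second, A second-to-last) or
  the tetraloop motif (same geometry on a 6-bp window). The tetraloop
  geometry mirrors the triloop by symmetry; this is the one place where
  the motif definition was genuinely open, and it is isolated in a single
  function.
* **3' dimerization.** One unit when the free energy of the 3' terminal
  5-mer is below -3.0 kcal/mol (strict), worst case over expansions —
  e.g. a primer ending GGTGG (dG ~ -4.6) is penalized.
* **GC clamp.** One unit when more than 3 of the last 5 bases can be G/C.
  Kept as a penalty, not a hard filter, matching its role as a ranking
  criterion: a heavy 3' clamp promotes mispriming but does not by itself
  invalidate a primer.

## Test and search modes

`evaluate_primer` (CLI verb `test`) runs every hard filter and penalty
rule on user-supplied primers and reports the failed-filter labels; an
invalid string yields a per-primer error entry. `search_primer` (verb
`search`) looks for an exact, case-insensitive match in the candidate
list of the requested orientation and reports its 1-based rank; a miss is
pipelined into test mode so the user sees why the primer would not have
been designed. No alignment against the template is attempted — a query
need not match the MSA at all.

Three published third-party primer panels (from PrimerDesign-M, DegePrime
and ConsensusPrimer runs on nitrogenase and phage major-capsid targets)
ship in `panels.py` as regression inputs for test mode. Under this
package's filters the heavily degenerate panel fails 10/10 (every forward
for both excess degeneracy and GC content), and the documented
complementary-ends and 70%-GC spot checks reproduce exactly. One caveat
is deliberate and visible in the test suite: the five vnfD forward
primers of the thirty-primer panel, which the original evaluation of
these panels accepted, melt around 41-43 C under the unified
nearest-neighbor convention and therefore fail the 50 C floor here. No
standard parameter set reproduces that evaluation's temperature calls
(two primers with identical length and GC content received opposite
verdicts there, which no composition-based formula can separate, and the
stack-level search documented in the project notes found no separating
parameterization either), so this package keeps the physically standard
convention and the corresponding regression test records the discrepancy
by failing rather than hiding it.

## Synthetic fixtures

`generate_fixture_msa` manufactures alignments with *planted* conserved
blocks: block columns are identical across sequences; every other column
mutates per sequence at `divergence_rate` (always to a different base)
and gaps at `gap_rate`. Defaults (8 sequences, 360 columns, two 45-bp
blocks, divergence 1.0, gap rate 0.05 in the shipped scenarios) emulate
the regime the conserved-region path targets: islands of perfect
conservation in an otherwise saturated alignment, as between distantly
related homologs. Deterministic under a seed, byte-identical output.

What the fixture does *not* emulate: phylogenetic correlation between
sequences (mutations are i.i.d.), indel structure longer than single
columns, compositional bias, and partially conserved regions (real
alignments have columns at 70-90% identity; the fixture's are either
perfect or saturated). Passing the planted-recovery tests therefore shows
the region finder and consensus coding are correct on unambiguous input,
not that the thresholds are optimal for borderline real-world columns.

## Pairing constraints

A pair is accepted when: the reverse window starts at or after the
forward window ends; the amplicon (reverse window end minus forward
window start, forward coordinates) reaches `min_amplicon`; the mean-Tm
difference between the primers is at most 1.0 C; and the annealing
temperatures of the two primers differ by less than 5 C. Annealing
temperature uses the Rychlik combination Ta = 0.3 Tm_primer +
0.7 Tm_product - 14.9, whose product term is shared within a pair, so the
default predicate reduces to a scaled Tm difference. An alternative
reading — each primer's Tm within 5 C of the product annealing
temperature itself — is available via `annealing_rule="product"`, but it
is not the default because primer Tm (40-55 C) and product Tm (75-85 C
for a 100+ bp amplicon) never sit within 5 C of each other, which would
reject every pair.

## Numerical and degenerate-input choices

* Boundaries are inclusive wherever a range is stated (GC 40-60%, Tm
  50-65 C, size 18-30); the dimer threshold is strict (`< -3.0`).
* The expansion cap (64) bounds all worst-case-over-expansions loops; a
  primer that passes the degeneracy filter has at most 12 expansions, so
  the cap only guards pathological direct input to test mode.
* Tm is not evaluated for primers shorter than 8 bp or beyond the
  expansion cap; such primers have already failed Size or Degeneracy and
  their report says "Tm not evaluated".
* Empty input files, empty primers, uracil, and non-IUPAC characters are
  errors naming the offending record and position. `.` gaps are
  normalized to `-`; case is folded to uppercase.
* Candidate ranking and pair selection are fully deterministic: stable
  sorts with explicit tie-breaks, and a heap order that is provably the
  lexicographic (penalty sum, forward index, reverse index) order.

## Problem sizes used in the shipped checks

The acceptance script evaluates the three bundled panels (10 + 30
primers), one design run on an 8 x 360 planted-block alignment, ten
80 x 80 pairing-oracle instances, 1000 random degeneracy masks for the
region finder, and 1000 random 18-30-mers for the Tm symmetry and
monotonicity properties. These sizes keep a full run under a second while
exercising every code path; the pairing oracle size (6400 combinations
per instance) is chosen so the brute-force reference itself stays exact.

## Known limitations

* No divalent-cation (Mg2+) or dNTP salt corrections, no dangling-end
  parameters, no partition-function secondary structure: hairpin and
  dimer risk are motif/endpoint heuristics, as specified.
* Cross-dimerization between the forward and reverse primer of a pair is
  not scored (only each primer's own 3' end stability).
* No mispriming screen against a genomic background.
* Protein input and RNA are out of scope; DNA only.
* The consensus model weights all sequences equally; a clade
  over-represented in the input pulls the consensus toward itself.
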