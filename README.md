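# panprimer

Degenerate PCR primer design for multiple sequence alignments.

PCR fails most often because of poor primers. When the target is not one
sequence but a *family* of homologs — a phage marker gene across
environmental samples, a nitrogenase gene across diazotrophs — a single
primer pair must bind them all. `panprimer` builds a minimal-degeneracy
IUPAC consensus from an MSA, finds the conserved regions where a primer
matches every sequence exactly, enumerates and hard-filters every
candidate window by explicit quality rules, scores residual risk
(hairpins, 3' dimerization, heavy GC clamps) as penalties, and selects up
to five optimized primer pairs. It is written for microbial ecologists,
phylogeneticists and molecular biologists who need primers for diverse
targets without a reference-sequence bias, and for anyone who wants an
explicit, testable implementation of the standard primer-quality rules.

## The model

**Consensus and conserved regions.** Each alignment column gets the
smallest IUPAC code covering its recurrent bases (majority base alone at
>= 90%, deletion mark at >= 50% gaps, minor alleles included at >= 10%).
Maximal runs of non-degenerate, non-gap columns of at least one primer
length (18 bp) are conserved regions; primers are drawn from them
(or, for single sequences, from all windows — the filtration path).

**Thermodynamics.** Duplex stability is the nearest-neighbor model with
the unified parameter set (1 M NaCl reference):

    ΔG°_total = Σᵢ nᵢ ΔG°ᵢ + ΔG°_init(term G/C) + ΔG°_init(term A/T) + ΔG°_sym

    Tm = 1000·ΣΔH / (ΣΔS + R·ln(C_T/b)) − 273.15 + 16.6·log₁₀[Na⁺]

with C_T = 50 nM primer, b = 4 (1 if self-complementary), 50 mM
monovalent salt, acceptable range 50–65 °C. Product annealing temperature
is 81.5 + 0.41·%GC + 16.6·log₁₀[K⁺] − 675/ℓ.

**Filters.** A candidate is disqualified by: degenerate codes in a
terminal trimer, any N, >1 three-fold or >2 two-fold codes; deletions in
a terminal trimer, >3 consecutive or >6 total, or gap-free length under
18; GC outside 40–60%; tandem k-mer repeats (more than two extra
dinucleotide copies, more than one extra trinucleotide copy, any tandem
tetranucleotide); mutually complementary 5'/3' terminal trimers; length
outside 18–30 bp; melting temperature outside 50–65 °C. Hairpin motifs,
a 3'-terminal 5-mer below −3 kcal/mol, and >3 G/C in the last five bases
add ranking penalties without disqualifying.

**Pairing.** Candidates are sorted by accrued penalty; the forward ×
reverse cross product is walked in exact combined-penalty order in blocks
of 1600 and pairs are accepted greedily — amplicon ≥ 100 bp, ΔTm ≤ 1 °C,
annealing compatibility < 5 °C, no primer reused — until five pairs are
found. The blocked search provably returns the brute-force optimum.

See `docs/methods.md` for every convention, default and limitation.

## Worked example

Generate a synthetic alignment with two planted 45-bp conserved blocks,
then design primers for it:

```
$ panprimer fixture --n-seqs 8 --length 360 --blocks 50:45,250:45 \
      --divergence 1.0 --seed 11 -o demo_msa.fasta
$ panprimer design demo_msa.fasta --aligned
```

The report (`.dgp` format: sectioned, tab-separated) shows the consensus,
the recovered conserved regions — exactly the planted blocks —

```
[conserved-regions]
start	end	length
50	95	45
250	295	45
```

the ranked candidate lists, and the optimized pairs:

```
[pairs]
pair	forward	f_index	f_length	reverse	r_index	r_length	amplicon	tm_diff	annealing_tm	penalty
1	TCGCAATTCCAATGAAGTTAGAAACCG	60	27	GCAACTACGAGACCATTTCATGAGTTT	254	27	221	0.43	77.60	1.000
2	TATCGCAATTCCAATGAAGTTAGAAACCGC	58	30	GCAACTACGAGACCATTTCATGAGTTTGT	252	29	223	0.40	77.44	2.000
```

Pair 1 pairs a forward primer starting at consensus position 60 (0-based,
5' end) with a reverse primer whose window ends at position 281, giving a
221-bp amplicon; the primers' mean melting temperatures differ by
0.43 °C and the product anneals near 77.6 °C. Both primers sit inside the
planted conserved blocks, so they match all eight input sequences
exactly. Penalties accrue here from sub-50 °C melting temperatures
(penalized per degree in design mode, which ranks shorter windows lower
rather than discarding them).

Evaluate existing primers against every filter (test mode):

```
$ panprimer test GTGCAGCGAGTGCATCCCGG WGCACGCCGTGRTSAAGGGC ACGT
primer	verdict	filters_failed	penalty
GTGCAGCGAGTGCATCCCGG	FAIL	GC content	penalty=2.00
WGCACGCCGTGRTSAAGGGC	FAIL	Degeneracy, GC content	penalty=2.00
ACGT	FAIL	Size	penalty=0.00
```

The first primer is 70% GC; the second carries a degenerate W in its
first trimer plus three 2-fold codes. `panprimer search` additionally
reports whether a primer appears in the design's candidate list and at
what rank, piping misses through test mode.

As a library:

```python
from panprimer import RunConfig, generate_fixture_msa, run_design

coll = generate_fixture_msa(8, 360, [(50, 45), (250, 45)],
                            divergence_rate=1.0, seed=11)
result = run_design(RunConfig(), coll=coll)
print(len(result.pairs), result.pairs[0].amplicon_len)   # 5 221
```

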