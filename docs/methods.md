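# Methods

`gbsmap` implements a genetic-map-guided genome finishing workflow for an F2
intercross between two inbred lines, together with a fully ground-truthed
synthetic study generator used to exercise and score every stage. This note
records the models, the defaults and why they hold, the numerical choices,
and what the synthetic data does and does not demonstrate.

## The synthetic study

The simulator emulates the data-generating process of a reduced-representation
genotyping experiment on a biparental cross:

* **Parents.** Two fully homozygous haplotypes: parent A drawn uniformly over
  {A,C,G,T}; each position independently mutated to a distinct base in parent
  B with probability `snv_rate`. Only SNVs — no indels or structural variants
  — matching the exact-k-mer genotyping model downstream.
* **F2 population.** Each individual is two independent gametes. Per gamete
  and chromosome the crossover count is Poisson(`crossover_mean`), breakpoint
  positions are uniform, and founder labels alternate from a fair coin: no
  crossover interference. Expected genetic length is therefore
  100·`crossover_mean` cM per chromosome (1 Morgan = one expected crossover
  per transmitted gamete).
* **Library and sequencing.** Both haplotype mosaics of an individual are
  digested in silico with ApeKI (site GCWGC, cut G^CWGC; the site set is its
  own reverse complement, so forward-strand scanning finds every site and
  overlapping sites each cut). Fragments inside the size-selection window
  contribute Poisson(`mean_depth`) single-end reads per remnant-bearing end;
  a read is barcode + fragment sequence starting at the CWGC remnant,
  truncated (never padded) to `read_length` total. The bottom-strand read
  starts at the 3-base 5' overhang of the downstream cut, so both reads of a
  fragment begin with the remnant, as a real ApeKI library does. Errors are
  i.i.d. substitutions on the genomic portion only; barcodes are error-free
  and quality is a constant 'I' (Phred 40).
* **Draft assembly.** Parent A's genome is cut into `n_contigs` at random
  positions (minimum length enforced). Chimeric contigs are built by
  carve-out: two segments from *different* chromosomes are reserved first and
  concatenated into one contig, the remainder is fragmented around them, so
  the contigs still cover each chromosome exactly once and every marker
  remains single-copy. The junction offset is the length of the first
  segment.

Defaults encode the study design the generator targets — a 9-chromosome
genome, a 288-individual F2 population, single-end 100-bp reads, k = 51,
14-kb consensus windows — with desk-scale choices elsewhere: 500-kb
chromosomes, SNV rate 0.002/bp (dense enough that most 14-kb windows carry
several marker sites), crossover mean 1.5 (0.3 cM/kb, so adjacent windows
sit ~4 cM apart), mean depth 4 per fragment end and size selection
60–400 bp (typical ApeKI GBS figures, config-exposed rather than
asserted).

What the simulator deliberately reproduces beyond the textbook model:
**allele-specific dropout**. An SNV that creates or destroys an ApeKI site,
or moves a fragment across the size-selection boundary, silences one
haplotype's reads locally. Windows dominated by such loci genotype
heterozygotes as homozygotes. What it does not model: indels, repeats and
multi-copy sequence (markers would multi-map), PCR duplicates,
quality-score variation, barcode sequencing errors, and crossover
interference. Passing tests therefore demonstrate correctness of the
inference machinery under SNV-only divergence and single-copy sequence, not
robustness to repeat-rich genomes.

## Marker discovery and placement

Canonical k-mers (lexicographic minimum of a window and its reverse
complement; k odd so the form is unambiguous) are counted exactly with a
2-bit packing: a k ≤ 64 k-mer is a pair of uint64 words whose lexicographic
order equals string order, so canonicalisation, counting, and lookup are all
exact integer operations — no hashing approximation anywhere (64-bit mixed
keys are used only as sort keys and always verified against the full
packing).

A k-mer x is A-diagnostic iff count_A(x) ≥ `min_count` and count_B(x) ≤
`max_other`, and some single-base substitution y of x (in either
orientation) passes the symmetric test. All qualifying pairs are kept — one
SNV yields up to k overlapping pairs — deduplicated by canonical pair.
Counting from genomes uses 1/0; counting from reads should raise
`min_count` (e.g. 3) to suppress error k-mers. Placement is exact and
unique: a pair is anchored where its matching allele occurs exactly once
across the assembly (the assembly derives from parent A, so normally the A
allele); the partner inherits the locus. Zero-hit, multi-hit and
both-alleles-present pairs are rejected with reasons. Exact matching
replaces a read aligner deliberately: markers are exact parental sequences,
so alignment would add heuristics without adding reach.

## Genotyping and consensus binning

Demultiplexing assigns a read to the unique sample whose barcode plus a
remnant-matching 4-mer prefixes it, longest barcode first; the barcode is
trimmed, the remnant retained, everything else is kept as `unassigned` so
assigned + unassigned partition the input. Exact matching is the default
(simulated barcodes are error-free); `max_mismatch` exists for real data.

Every k-window of every read is looked up against both orientations of every
placed allele; a read may hit several loci and counts at each. Calls from
allele counts (a, b): AA if a ≥ `min_allele` and b = 0 (BB symmetric), AB if
both ≥ 1, else NA. `min_allele` = 2 suppresses singleton errors while
keeping heterozygotes callable at modest depth; the exact thresholds are
documented package decisions, config-exposed.

Raw calls are binned into windows of `window` = 14,000 bp anchored at
position 0 of each contig (terminal window truncated; anchoring is a fixed
documented choice). Per individual and window the consensus is the strictly
most frequent genotype among non-NA calls if it occurs ≥ `min_calls` times
and beats every rival; ties or thin evidence give U (unknown). AB counts
symmetrically with the homozygote classes — strict plurality over
{AA, AB, BB}.

## Linkage map

Pairwise recombination fractions come from the F2 codominant two-locus
likelihood: with c = 1 − r the 3×3 joint class probabilities are c²/4, cr/2,
r²/4 on the corners and edges and (c² + r²)/2 for the double heterozygote
(both phases pooled). Maximisation is a dense grid (step 0.001 on [0.001,
0.5]) with vectorised golden-section refinement — deterministic, no EM
ambiguity; r̂ = 0 exactly when no recombinant class is observed. LOD is
log10 L(r̂)/L(0.5). Estimates from fewer than 10 informative pairs are
flagged unreliable.

**Segregation screening.** Each window locus gets a chi-square p-value
against 1:2:1. Windows with p < `distortion_alpha` (default 1e-6) are
flagged in the outputs and excluded from rf estimation and from misjoin
tracks — but raw calls are never altered. This is a model precondition, not
cosmetic filtering: the two-locus likelihood assumes Mendelian marginals,
and two dropout windows distorted toward the same homozygote on different
chromosomes otherwise fake tight linkage (LOD ≫ 6), fusing linkage groups.

Grouping is single linkage: connected components of the graph with an edge
wherever r̂ ≤ `max_rf` (0.35) and LOD ≥ `min_lod` (6). With ≈ 90
informative individuals a true r = 0.04 between adjacent windows gives LOD
far above 6, while the probability that any of ~5·10⁴ unlinked pairs reaches
LOD 6 is negligible, so the thresholds separate chromosomes cleanly.
Ordering within a group: minimum spanning tree of the r̂-weighted complete
subgraph; its weighted diameter path is the backbone; remaining loci are
inserted at the adjacency that minimises the objective increase; polishing
reverses windows of ≤ 6 loci while the count objective — Σ over adjacent
pairs of r̂·n_informative, the expected number of recombinant gametes —
improves. The objective is asserted never to increase during polishing. The
orientation of each group is arbitrary (a map is defined up to reversal).
Cumulative positions are prefix sums of the Kosambi map function
d = 25·ln((1+2r)/(1−2r)) cM over adjacent pairs; adjacent r̂ ≥ 0.5 is
clamped to 0.499 with a warning.

## Misjoin detection and scaffolding

For each contig, windows (minus distortion-flagged ones) form a haplotype
track. At every adjacent boundary, over individuals non-U in both windows,
the switch fraction is the fraction whose genotype differs. For genuinely
adjacent windows it is ≈ the inter-window recombination fraction (≪ 0.1 at
the default density); for a cross-chromosome junction the two sides are
independent 1:2:1 draws, so the expected fraction is 1 − (1/16 + 1/4 + 1/16)
= 0.625. `min_switch` = 0.5 sits between the two regimes; `min_informative`
= 20 suppresses thin boundaries. Runs of adjacent qualifying boundaries
(the window containing the junction can trip both its edges) merge to the
single max-fraction boundary. Splits happen only at window boundaries — the
detection resolution; sub-window refinement is out of scope — and parts
`<contig>.1`, `<contig>.2` concatenate back to the original sequence.
Because splits land on window boundaries, map loci are renamed to parts by
pure coordinate shifting; nothing is re-estimated.

Parts are assigned to the group holding the majority of their mapped
windows (several groups ⇒ conflict flag, a candidate undetected chimera);
oriented by the sign of the Kendall correlation between window bp midpoints
and cM positions ('?' when fewer than two distinct positions, emitted as
'+' with the flag); ordered by median cM with lexicographic tie-break; and
joined with 100-N gaps. The AGP v2.1 table (W rows and U gap rows with
gap_type "map", linkage "yes", evidence "map") is validated by an
independent checker (1-based inclusive coordinates, exact tiling,
consecutive part numbers, component spans) and round-trips bit-exactly to
the emitted FASTA. Parts with no mapped windows are emitted as standalone
scaffolds rather than forced into a pseudomolecule.

## Evaluation against truth

The simulator's TruthSet scores every stage: consensus accuracy against the
majority truth genotype over each window's SNVs; per-group |Kendall tau|
between map order and true bp order on the group's majority chromosome
(absolute value — reversal freedom); junction recall/precision with a ± one
window tolerance; contig order |tau| and orientation accuracy after fixing
each group's polarity by the sign of its order correlation.

## Problem sizes

The bundled studies run at desk scale: the main replication uses 9
chromosomes × 500 kb, 96 individuals and a 60-contig assembly (with and
without 3 planted chimeras, sharing one simulated read set — diagnostic-pair
counts are assembly-independent, so the expensive scan runs once); the
exact-finishing check uses 2 × 250 kb at the same genetic density with 96
individuals; the demultiplexing study uses the full 288 barcoded individuals
on a small genome. The unit suite uses k = 5–7 toys whose diagnostic pairs
are enumerable by brute force.

## Known limitations

* Exact-match placement and genotyping cannot tolerate indels or divergence
  beyond isolated SNVs; real data would first need the same error-free
  assumptions restored by depth thresholds (`min_count`, `min_allele`).
* Single-linkage grouping can chain through a mis-genotyped window in
  principle; the distortion screen removes the observed failure mode, but
  repeat-induced mis-placement (absent from the simulator) could produce
  others.
* Ordering is pairwise-likelihood based, not multipoint; at very tight
  spacing (r̂ below sampling error) local order is only resolved up to
  noise, which the windowed ripple does not overcome.
* Orientation of parts with a single mapped window is undecidable ('?'); they
  are emitted forward with a flag.
* Gap length 100 is a convention, not an estimate of physical gap size.
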