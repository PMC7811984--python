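# Methods

This note records the models, parameter choices and numerical conventions
behind `ampliclade`, and what the synthetic fixtures do and do not show.

## Coordinates and alphabets

All coordinates are 0-based, half-open. Strands are '+'/'−', where '−'
means a feature was found on the reverse complement. Nucleotide input is
folded to upper case and 'U' maps to 'T'; FASTQ is Phred+33 only (a quality
character below '!' is rejected rather than auto-detected as Phred+64).
IUPAC ambiguity codes are first-class throughout: each code denotes a set
of concrete bases, and two codes "match" iff their sets intersect.

## Conservation scan

For an aligned clade, the score of a column is the count of its most
frequent concrete base (A/C/G/T) divided by the number of counted rows;
gaps and ambiguity codes are never the dominant base. Gap handling is a
policy: with `count` (the default) gaps stay in the denominator, so gappy
columns score low — deliberately conservative, since a gappy region is a
poor primer site; with `ignore` they are dropped from it. A window score is
the mean over its columns, window = 20 nt by default. Candidate regions are
exposed as ranked windows, not a hard cutoff: no numeric conservation
threshold is imposed because the step from "conserved region" to "primer
endpoints" is a design judgement; `enumerate_candidates` automates it only
up to ranking and the degeneracy/GC constraints below.

## Degenerate primers

`consensus_primer` takes the minimal IUPAC code covering all observed bases
per window column, guaranteeing every reference in the window is matched
with zero mismatches — the property that lets a small panel of sets
collectively cover a whole clade. It refuses windows containing gaps, and
refuses (naming the ambiguous columns) when the degeneracy product exceeds
the cap. Degeneracy is the product over positions of the concrete-base
count of each code. Only length (default range 20–29 nt, matching the
published sets) and degeneracy are constrained; an optional GC-content band
(S counts 1, W counts 0, other codes by their G/C share) is available but
off by default. Melting temperature, hairpin and dimer screens are out of
scope. The six published CODHech primer sets are built in with their clade
assignments and expected amplicon sizes.

## In-silico PCR

Primer–template matching is ungapped on both strands, with set-intersection
semantics for template ambiguity codes (a template N matches anything, so a
warning is emitted when a template is more than 5% N). The mismatch budget
is ⌊frac · primer length⌋ with frac = 0.10 by default — 2 mismatches for
all of the 20–29-nt built-in primers. A product pairs a forward-primer site
with a facing reverse-primer site on the other strand, is reported 5′→3′
from the forward primer, and must fall in a size window (default
50–5000 bp); nested products are all reported, and the "best" hit is the
one with fewest total mismatches, ties to the shorter then leftmost
product.

## Pairwise identity and the species threshold

Identities come from a true global alignment (end gaps penalized) under the
EDNAFULL matrix with affine gaps: a gap of length L costs
gap_open + L · gap_extend, defaults 10.0 and 0.5. Identity is
100 · identical columns / alignment length, gap columns included, reported
to 0.1 — the convention the EMBOSS needle family prints. Because co-optimal
alignments can differ in identity, the two sequences are canonically
ordered before aligning, making the reported identity symmetric. The
alignment engine is Biopython's `PairwiseAligner` (which permits adjacent
insertion/deletion runs, each opening its own gap); the test suite pins its
scores to an independently written affine DP on short sequences.

The threshold sweep classifies each labeled pair as same-species when its
identity is ≥ the cutoff (inclusive, consistent with the ≥ 94.5% assignment
rule downstream), tabulates TP/FP/TN/FN over the 80–100% grid in 0.1 steps
(carried internally in exact tenths to avoid float drift), and computes
precision, recall and F = 2PR/(P+R), with F defined 0 where P + R = 0 so
the grid stays total. Because plateaus of equal F are the rule, the optimum
is reported as the full contiguous interval of cutoffs attaining the
maximum. Region-trimmed variants replace each reference by its amplicon
interior (primer tracts excluded); references a set does not amplify are
dropped with a warning.

## Amplicon pipeline

Read QC keeps merged reads of ≥ 200 nt with zero N and all bases ≥ Q20.
Dereplication is exact and full-length, ordered by abundance descending
with lexicographic sequence tie-breaks, so the pipeline is fully
deterministic — no stage consumes randomness.

Denoising is a greedy centroid pass in that order. A unique u joins the
first centroid c (in founding order) satisfying both gates: identity ≥
0.979 — the clustering identity calibrated by the threshold analysis, so a
unique below it always founds its own OTU regardless of skew — and
abundance(u)/abundance(c) ≤ β(d) = 1/2^(αd + 1) with α = 2. Here d is the
edit distance (substitutions and indels each count 1) of a global
edit-distance alignment computed with edlib, and abundance(c) is the
centroid's *founding* unique abundance, not its accumulated total.
Otherwise u founds a centroid iff its abundance is ≥ 8; smaller orphans are
discarded, with read counts conserved and reported per stage.

Chimera removal uses the perfect single-crossover model: walking OTUs in
decreasing abundance, a candidate is removed iff two already-retained
parents, each ≥ 16× as abundant, split it at one crossover into a prefix
identical to one parent and a suffix identical to the other (a candidate
wholly contained in a single parent is not chimeric). Multi-crossover
models are out of scope.

Target filtering translates each OTU in six frames and locally aligns every
frame against the reference proteins (BLOSUM62, gap open 11 / extend 1).
Raw scores S become bit scores via the gapped Karlin–Altschul constants for
that matrix/gap combination, b = (λS − ln K)/ln 2 with λ = 0.267,
K = 0.041. An OTU is a target iff its best hit reaches 80 bits and the
hit's interval on the reference protein lies inside the primer set's target
region (supplied per reference in protein coordinates). Species assignment
then takes the maximum-identity reference over the amplicon region
(region-based rather than full-length, since OTUs are fragments): the call
is that reference's species at ≥ 94.5% identity, inclusive, else "novel".

Finally, all dereplicated reads are mapped back onto the retained OTUs at
the 97.9% clustering identity (best hit wins), and the mapped abundances
are the reported OTU quantities. This read-mapping step is standard
practice in UNOISE-style workflows and is what makes compositions
quantitative: the denoiser's skew gate deliberately discards rarer error
variants, and the discard rate depends on centroid abundance, so
denoiser-internal abundances alone would bias compositions toward abundant
templates. Mock-community compositions are restricted to target OTUs
before normalization, and compared by signed per-label deltas, L1 and
Bray–Curtis = L1/2.

## Synthetic fixtures

`simulate_gene_family` plants a genus/species/strain hierarchy: each genus
(clade) gets a random stop-codon-free ancestor (frame 0) carrying one
concrete expansion of each of its primer sets' binding tracts at fixed
offsets, chosen so no stop codon falls wholly inside a tract; every
reference therefore has a clean protein translation for the translated
search. Species ancestors and strains accumulate substitutions at disjoint
positions, with per-level counts derived from the planted identity ranges
(inter-species default 0.85–0.93, intra 0.98–1.00, intra strictly above
inter), so realized pairwise identities land inside the ranges by
construction rather than on average. Substitutions avoid creating stop
codons and never touch primer tracts — except in designated edge taxa,
which receive exactly ⌊0.1 · primer length⌋ planted tract mismatches,
putting them precisely at the default in-silico PCR budget. Inter-species
substitutions are down-weighted inside the amplicon interior
(`region_conservation` = 0.4), reflecting that primer target regions sit in
the conserved parts of a functional gene; this is the feature that makes
region-trimmed threshold optima sit at or above full-length ones.

`simulate_reads` draws template amplicon interiors multinomially, applies
i.i.d. substitution errors (uniform alternative base) and, at the chimera
rate, single-crossover splices of two drawn templates. Qualities are
two-valued — Q35 on correct bases, Q15 on planted errors — a threshold
model, not a learned profile. Note that the default QC floor of Q20 removes
every read carrying a planted error; tests that exercise denoising and
mapping on noisy reads therefore run the pipeline with min_q = 15
explicitly. Indel errors are exposed but default to 0, since the planted
amplicons are length-homogeneous. Both generators are byte-deterministic
under their seeds and emit planted truth (taxonomy, site coordinates,
per-read origin) alongside the data.

What the fixtures do *not* emulate: sequencer error profiles
(quality-by-cycle, motif bias), indel-rich platforms, paired-end merging
artifacts, horizontal transfer between clades, and reference databases with
mislabeled taxonomy. Passing tests demonstrate correctness of the
algorithms under the planted model, not performance on real runs.

## Problem sizes

The default test fixtures use gene families of 8–24 members with 900–1200-nt
genes, and mock runs of 30,000 reads over ~450-nt amplicons; threshold
recovery uses 20 independent seeds. These sizes give stable statistics
(multinomial standard errors well below the tested tolerances) while
keeping the full suite under a minute of compute.

## Known limitations

- The denoiser compares each unique against every current centroid
  (quadratic in centroids); fine at amplicon scale, not built for millions
  of uniques.
- primersearch-style matching is ungapped; a true indel in a binding site
  is invisible.
- The chimera model requires exact parent segments; chimeras with
  post-splice errors are caught only if denoising merges them first.
- Translated search is exhaustive local alignment, not a seeded heuristic;
  it honors the same bit-score contract as fast aligners but is meant for
  OTU-scale inputs.
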