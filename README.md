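# ampliclade

Clade-specific degenerate primer design, in-silico PCR, species-identity
threshold calibration and functional-gene amplicon OTU profiling.

## The problem

Hydrogenogenic carboxydotrophs — microorganisms that oxidize CO and evolve
H₂ — are marked by gene clusters coupling an anaerobic Ni,Fe carbon monoxide
dehydrogenase (CODH) to an energy-converting hydrogenase (ECH). Such
"CODHech" genes are too rare to see in bulk metagenomes, so detecting the
organisms calls for a targeted assay: degenerate PCR primers specific to the
CODHech subclades of interest, plus an amplicon-sequencing pipeline that
turns the resulting reads into species-resolved gene variants (OTUs).
`ampliclade` implements that dry-lab arc end to end, for CODHech genes and
for any gene family with comparable clade structure:

1. **Conservation scan** — for an aligned clade, the per-column dominant-base
   ratio averaged over a 20-nt sliding window locates candidate primer
   regions.
2. **Degenerate primers** — the minimal IUPAC covering code per window
   column yields a primer matching every clade member with zero mismatches;
   its *degeneracy* is ∏ᵢ |code(i)|, the number of concrete oligos it
   represents. The six published CODHech primer sets (E4a_p1, F4a_p1,
   F4a_p2, F4c1_p1, F4c1_p2, F4c2_p1) ship as built-ins.
3. **In-silico PCR** — ungapped scanning of both template strands with
   base-set intersection semantics for IUPAC codes, allowing
   ⌊0.10 · primer length⌋ mismatches per primer, pairs facing binding sites
   into predicted products.
4. **Species identity threshold** — all C(n,2) pairwise identities of
   taxonomically labeled reference genes (true global Needleman–Wunsch,
   EDNAFULL, gap open 10.0 / extend 0.5, identity over the full alignment
   length) are swept over cutoffs 80–100% in 0.1 steps; at each cutoff
   P = TP/(TP+FP), R = TP/(TP+FN) and F = 2PR/(P+R) score the "same species"
   call, and the plateau of cutoffs maximizing F is the calibrated species
   threshold.
5. **Amplicon pipeline** — merged reads are quality-filtered (≥ 200 nt,
   no N, all Q ≥ 20), dereplicated, denoised UNOISE3-style (a unique merges
   into a centroid d differences away only if its abundance skew is
   ≤ β(d) = 1/2^(αd+1), α = 2, identity ≥ 0.979; uniques under abundance 8
   never found an OTU), purged of single-crossover chimeras (parent skew
   ≥ 16), filtered to genuine target-gene fragments by six-frame translated
   search against reference proteins (BLOSUM62, bit score ≥ 80, hit inside
   the primer target region), assigned to species at ≥ 94.5% identity to the
   closest reference (else "novel"), and quantified by mapping all reads
   back onto the retained OTUs at the 97.9% clustering identity.
6. **Mock evaluation** — observed target-OTU compositions are compared with
   expected compositions (e.g. from qPCR copy numbers) by per-label deltas,
   L1 and Bray–Curtis.

A seeded synthetic-data generator (`ampliclade.synth_fixtures`) produces
gene families with planted taxonomy, primer sites and identity structure,
and read sets with controlled error and chimera processes, so every stage
is testable against known truth.

## Worked example

`examples/05_amplicon_pipeline.py` simulates a four-gene mock community
(planted copy numbers 500 : 250 : 125 : 63), draws 30,000 merged reads with
1% substitution error and 0.5% chimeras, and runs the full pipeline with the
F4c1_p1 primer set:

```
per-stage report:
  total_reads                  30000
  qc_reads                     30000
  unique_sequences             29456
  denoised_chimera_free_reads  29386
  otus                         4
  target_otus                  4

OTU table:
   otu_id  abundance  rel_abundance  is_target    best_ref  identity      species_call
F4c1_p1_1      15821       0.538386       True F4c1_g1s1t1     100.0 G1F4c1 species1_1
F4c1_p1_2       7795       0.265262       True F4c1_g1s2t1     100.0 G1F4c1 species1_2
F4c1_p1_3       3813       0.129756       True F4c1_g1s3t1     100.0 G1F4c1 species1_3
F4c1_p1_4       1957       0.066596       True F4c1_g1s4t1     100.0 G1F4c1 species1_4

Bray-Curtis between planted and observed composition: 0.0053
```

All four planted genes are recovered as target OTUs identical to their
sources, and the relative abundances (0.538, 0.265, 0.130, 0.067) match the
planted fractions (0.533, 0.267, 0.133, 0.067) to within Bray–Curtis 0.005 —
the assay is both specific and quantitative on this mock. The other
examples cover the conservation scan, consensus primer design, in-silico
PCR coverage, and the threshold grid search (which on a planted family
reports e.g. `max F = 1.000 for cutoffs in [91.4, 98.2]%` full-length and a
higher `[93.9, 98.5]%` on the amplicon region alone).

## Command line

The same stages are available as subcommands of a single entry point:

```sh
ampliclade scan      --msa aligned.fa --out profile.tsv
ampliclade design    --msa aligned.fa --max-degeneracy 64 --out candidates.tsv
ampliclade ispcr     --refs refs.fa --mismatch 0.10 --out hits.tsv
ampliclade threshold --refs refs.fa --tax taxonomy.tsv --out curve.tsv
ampliclade classify  --fastq merged.fq --set F4c1_p1 --refs refs.fa \
                     --ref-proteins prot.faa --tax taxonomy.tsv \
                     --regions regions.tsv --out-table otus.tsv
ampliclade mockeval  --copies copies.tsv --otu-table otus.tsv --out cmp.tsv
ampliclade simulate  family --out fixtures/ --seed 1
```

Defaults are the published workflow settings; a TOML file passed as
`ampliclade --config conf.toml …` supplies per-subcommand defaults that
flags override, and every run logs its effective configuration.

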