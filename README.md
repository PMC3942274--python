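# chondriome

Heteroplasmy, synteny and ORF analysis for circular organellar genomes,
with a truth-tracked mitotype-mixture read simulator.

## The problem

Plant mitochondrial genomes are not a single molecule: each cell carries a
*chondriome* — a population of mitochondrial genome variants (*mitotypes*)
at different stoichiometric levels. In alloplasmic lines (nucleus from one
species, cytoplasm from another, produced by substitution backcrossing),
nuclear–mitochondrial incompatibility accelerates genome rearrangement,
shifts mitotype stoichiometry, and gives rise to novel chimeric open reading
frames of the kind associated with cytoplasmic male sterility (CMS).
Deep single-end sequencing of a mitochondrial genome makes all of this
measurable: within-line heteroplasmy shows up as positions where a minor
allele rises above the sequencing-noise floor, and between-line comparison
of consensus genomes reveals SNPs, coding changes, gene-order rearrangement
and species-specific ORFs.

`chondriome` implements that full analysis as a tested, reusable pipeline
for anyone comparing circular organellar genomes — an alloplasmic line
against its two parents being the motivating design case.

## What it computes

* **Heteroplasmic SNPs (HSNPs).** From a read pileup, position *i* is
  heteroplasmic when depth `d_i ≥ 10` and the single most frequent
  non-major base satisfies `n_minor / d_i > 0.10` (strict; per-allele;
  indels never trigger a call). Dense runs of HSNPs (gap ≤ 150 bp, ≥ 3
  members by default) are chained into HSNP blocks. Genome space below 10×
  is masked out and its excluded fraction reported.
* **Inter-genome SNPs and coding changes.** Homologous regions between
  consensus genomes are found with NCBI `blastn` (both strands, circular
  via a doubled subject), retained at identity ≥ 0.95 and ≥ 200 aligned
  columns; mismatch columns become SNPs (gap columns are excluded). SNPs in
  coding sequence are annotated in `ref/alt^codon` notation, e.g. `E/A^57`
  for a substitution at CDS nucleotide 170 (`⌈170/3⌉ = 57`), with
  synonymous changes reported as `No change`.
* **Contig joining.** Two contigs merge only when a suffix/prefix overlap
  exceeds 100 bp with dissimilarity (mismatches + gap columns) below 1%.
* **Synteny and rearrangement.** Gene orders are signed circular
  permutations. Rearrangement between genomes is the signed circular
  breakpoint count on the induced subpermutation of shared genes: the
  number of adjacencies `x→y` of one order absent from the other (an
  adjacency survives as `-y→-x` on the opposite strand). Maximal runs of
  conserved adjacencies are synteny blocks; isolated conserved pairs are
  reported separately, and block bp totals as a genome fraction.
* **ORFs.** ATG-to-stop spans ≥ 300 bp (stop included), both strands,
  longest span per stop codon, one wrap of the origin allowed. An ORF is
  unique to its genome when homologous alignments cover ≤ 95% of its
  length against *every* other genome. Chimeric ORFs are decomposed into
  donor-gene fragments by greedy score-ordered tiling of local alignments.
* **Simulation with truth.** A master circular genome with planted genes
  and repeats; mitotypes derived by substitutions, segment reversals and
  deletions (with exact truth edit lists); 454-style single-end reads
  (truncated-normal lengths, mean 449 bp) drawn from the stoichiometric
  mixture with per-base errors, emitted as FASTQ plus truth SAM against the
  master coordinates, alongside truth tables.

## Worked example

Simulate the default two-mitotype chondriome (50 kb circle, 30 genes, two
1 kb repeats; mitotypes at 0.8/0.2 differing by 200 substitutions; 100×
coverage, 1% error), then call heteroplasmy and scan ORFs:

```
$ chondriome simulate --seed 7 --outdir demo
$ chondriome hsnp demo/reads.sam demo/master.fasta \
      --vcf-out demo/hsnps.vcf --blocks-out demo/blocks.bed
200 HSNPs (92 in 25 blocks, 108 singletons)
$ chondriome orf demo/master.fasta --out demo/orfs.tsv
40 ORFs, 32124 bp (64.2% of genome)
```

All 200 planted heteroplasmic positions are recovered, with none spurious;
92 fall close enough together to chain into 25 blocks. The VCF carries
depth and minor-allele fraction per call:

```
master  367  .  C  A  .  PASS  DP=98;AF=0.3265
master  642  .  T  A  .  PASS  DP=98;AF=0.2449
```

`chondriome analyze --config cfg.yaml` runs the whole comparison (pileup →
HSNPs → pairwise SNPs → synteny → ORF uniqueness) for any set of genomes
and writes per-stage TSV/VCF/BED/GFF3 files plus a consolidated
`report.json` echoing every threshold in force.

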