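# Methods

This note documents the models and procedures `chondriome` implements, the
parameters that matter, what the simulator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Coordinates and circularity

All internal coordinates are 0-based half-open on the forward strand of a
circular molecule; intervals may run past the origin, in which case `end`
exceeds the genome length and arithmetic is modulo the length. 1-based
coordinates appear only in human-facing output (VCF positions, GFF3, and
`ref/alt^codon` coding-change labels). SAM has no circular convention, so
alignments are emitted against the linearized master; a read that wraps the
origin (or crosses a rearrangement breakpoint) becomes multiple records
sharing one read name, with records after the first flagged supplementary.

## Heteroplasmy model and caller

A chondriome is a stoichiometric mixture of mitotypes. At a pileup column
of depth `d` (reads whose alignment consumes the reference there: CIGAR
M/=/X/D; soft clips ignored), the caller reports a heteroplasmic SNP when

* `d ≥ min_depth` (default 10; "at least 10×" is inclusive), and
* `n_minor / d > min_minor_frac` (default 0.10, strict inequality),

where the major allele is the most frequent base (ties broken A<C<G<T) and
the minor allele is the single most frequent remaining base. The rule is
deliberately per-allele: two rare alleles jointly above 10% do not call.
Insertion/deletion evidence never triggers a call; deletions still count
toward depth, as do ambiguous (N) bases, both of which can only dilute the
minor fraction — the conservative direction for a strict threshold.
Positions below `min_depth` form the coverage mask, reported as excluded
intervals, bp and genome fraction (4 decimals).

HSNP blocks are greedy left-to-right chains: consecutive calls at most
`block_max_gap` bp apart (default 150) join a chain; chains with at least
`block_min_count` members (default 3) become blocks, everything else is a
singleton. The block parameters are configurable defaults — density
clustering has no canonical definition, so the chain rule was chosen for
being order-independent, O(n), and trivially auditable. The summary
reports `n_total = n_in_blocks + n_singletons` and genome bp per HSNP
(absent, not a division error, when there are no calls).

### False-positive expectation

On a homoplasmic genome with per-base substitution error rate `e` (errors
uniform over the three alternative bases), the three alternative-base
counts at a depth-`d` column are multinomial with success probability
`e/3` each. The probability that the largest reaches the call threshold
`t(d) = min{k : k > 0.1 d}` is computed exactly by inclusion–exclusion to
third order using binomial tail sums; columns are independent because
per-base errors are, so the expected count and its variance sum over the
realized column depths. The packaged control runs at 20× mean depth with
`e = 0.05`: deliberately harsher than realistic pyrosequencing error
(~1%), because at 100×/1% the strict >10% rule admits a vanishing
expectation (~10⁻⁷ calls per genome) and a comparison against it would
have no statistical power. At 20×/5% the expectation is in the thousands
with standard deviation ≈ 50, so the 3-SD agreement check sharply tests
both the caller and the formula.

### Recovery scoring

The recovery experiment plants 200 distinguishing substitutions in a 0.2
minor mitotype at 100× and scores calls against the planted positions.
The minor-fraction error is measured against the *realized* per-column
fraction of reads drawn from the minor mitotype (available from the truth
alignments), not the nominal 0.2: at depth ~100 the binomial sampling of
reads alone moves per-column fractions off the nominal value by
`σ√(2/π) ≈ 0.032` on average, which is read-sampling noise, not caller
error. The nominal-fraction MAE is reported alongside for transparency.

## Inter-genome comparison

Homology search runs NCBI `blastn` (`-task blastn`, word size 15, dust
off) with the subject genome doubled so alignments may cross the subject's
origin; subject coordinates are normalized modulo the length and
doubling duplicates removed. Retained alignments need ≥ 200 columns
(≥ 50 for ORF-sized queries) and identity ≥ 0.95 — the cutoff is
inclusive, reading "95% as the cutoff" as pass-at-threshold. Identity is
recomputed from the alignment rows as matches/columns rather than trusting
the search tool's rounding. SNPs are the mismatch columns, deduplicated by
position pair; alleles are always reported on the forward strand of each
genome (minus-strand alignments complement the subject allele). Because
the query is linear, homology crossing the *query's* origin is reported as
two alignments; rotate the query to probe a specific junction.

Coding changes: for a substitution at 1-based CDS position `n`, the codon
ordinal is `⌈n/3⌉`; reference and mutated codons are translated with the
standard table and reported as `ref/alt^codon`, or `No change` when
synonymous. Minus-strand genes convert genome-forward positions and
alleles onto the coding strand first. A frameshift helper applies a
deletion, translates the shifted frame, and maps the first stop codon back
to original gene coordinates; the packaged synthetic reconstruction (a
generator labelled as such — no real gene sequence is shipped) pins a
4-base deletion at positions 134–137 and verifies the premature stop's
first base lands at position 158.

Contig joining locates candidate suffix/prefix overlaps by shared exact
21-mers and verifies each with a global (edlib) alignment of the implied
overlap; the join requires strictly more than 100 overlap columns and
dissimilarity (edit distance over columns, so gaps count) strictly below
1%. Refusal is a value carrying the failed rule, not an exception. When
the overlap contains net indels the junction cut may shift by up to the
overlap's gap count — bounded by the 1% rule, and irrelevant for the
near-identical overlaps the rule admits.

The false-positive rate over conserved space globally aligns each region
pair believed identical and reports mismatch columns per compared bp
(denominator: total length of the first region of each pair).

## Synteny

Gene orders are signed circular permutations built from annotations sorted
by start coordinate; duplicated gene names get deterministic `-1, -2, …`
suffixes by coordinate order (alternative copy matchings are out of
scope). Genes present in only one genome are dropped before any distance
computation (induced subpermutation). The breakpoint count is the number
of adjacencies of one induced order absent from the other, signs
respected, circularly; it is symmetric and invariant under rotation and
global strand flip, an exhaustively tested property up to 7 genes. A
single reversal costs ≤ 2 breakpoints, a single transposition 3. This is
an adjacency-break count, not a reversal-distance (Hannenhalli–Pevzner)
reconstruction of biological events — estimating the *minimal event
series* is a non-goal.

Synteny blocks are maximal circular runs of conserved adjacencies
(whole-block inversion allowed). Note one consequence of circularity: the
two flanks around a single reversed segment are themselves adjacent
through the origin, so they merge into one conserved block — a 10-gene
order with genes 4–7 reversed yields one inverted 4-gene block plus one
6-gene block, not three blocks as a linear reading would suggest. Isolated
conserved pairs (runs of exactly two genes) are reported separately from
larger blocks. Block bp spans come from the minimum start / maximum end of
member genes and are summed (overlap rejected) into a genome fraction.

## ORFs

An ORF is an ATG-to-stop span, stop codon included in the length, minimum
300 bp (inclusive — whether published ORF lengths include the stop is
ambiguous; the inclusive convention is declared here). Scanning walks all
three frames of both strands over the doubled sequence, so origin-wrapping
ORFs are found naturally; per stop codon only the longest qualifying span
is kept (suppressing nested ATG starts), spans longer than the genome are
impossible by construction, and ids are assigned from 0 in (start, strand)
order. A brute-force oracle (enumerate every ATG, walk codons circularly)
backs the scanner in tests.

Uniqueness uses nucleotide-level homology (the comparison is between
genomes at the DNA level): merged query coverage per subject genome, with
an ORF unique iff coverage ≤ 0.95 against every other genome — so 96%
coverage anywhere disqualifies. Chimera decomposition collects all local
alignments between an ORF and a donor-gene database (`blastn-short`, word
size 7), keeps hits ≥ 30 query bp at ≥ 90% identity, and tiles the query
greedily by descending match count (ties: longer segment, then
lexicographic gene id); candidates overlapping already-tiled intervals are
trimmed to the free region rather than discarded, which keeps fragment
boundaries within a few bp of truth when neighbouring alignments
over-extend. Uncovered query intervals are reported as unassigned.

## Simulator

`generate_master` packs non-overlapping protein genes (ATG + stop-free
interior + stop, random strand, lengths a multiple of 3 in the configured
range) and verbatim repeat pairs into random background sequence, gap
sizes multinomial. `derive_mitotype` applies disjoint reversals and
deletions to a master-coordinate map, then random substitutions that never
recreate the reference base; the truth edit list replays to the exact
mitotype sequence (substitutions, then reversals, then deletions), and
annotations are lifted — genes fully inside a reversal flip strand and
order, genes touching a deletion or straddling a reversal boundary are
dropped.

`simulate_reads` draws each read's mitotype by its stoichiometric
fraction, its length from a truncated normal (mean 449 bp, sd 100,
bounds [100, 1000] — the single-end pyrosequencing regime being emulated),
and its start uniformly on the circle. Substitution errors hit each base
independently (default rate parameterized per run; the recovery experiment
uses 1%) choosing uniformly among the three alternatives, with error
offsets recorded. Truth alignments are derived from the mitotype→master
coordinate map: collinear runs become M operations, same-strand jumps
become D operations, and runs split at strand changes and the origin.
An optional 1-bp indel error mode exists purely to stress the pileup
builder and is restricted to substitution-only mitotypes.

Not emulated: flowgram/quality-score structure, homopolymer-specific error
profiles, chimeric reads, chloroplast/nuclear contamination, and library
or copy-number biases. Passing recovery tests therefore demonstrate the
caller's behaviour under idealized mapping (truth alignments, no mapping
ambiguity); on real data, mapping error in repeats would add false signal
the coverage mask and thresholds must absorb.

Scenario defaults — two mitotypes at 0.8/0.2 with 200 distinguishing
substitutions on a 50 kb master with 30 genes and two 1 kb repeats, 100×
coverage — are the package's desk-scale stand-in for a ~430 kb molecule at
61–133×: no published per-line mitotype composition exists to copy, and
0.8/0.2 places the minor allele comfortably above threshold while leaving
sampling noise visible. The 50 kb size keeps the full pipeline (including
the SAM round trip) in seconds without changing any per-column statistics.

## Determinism and numerics

Every random choice flows through an explicit integer seed (numpy
`default_rng`); there is no global random state, and identical configs
produce byte-identical outputs. Threshold comparisons use the same
floating-point expression in the caller and the analytic expectation so
boundary columns cannot disagree. Division-by-zero cases (no HSNPs, no
compared bp, fewer than two shared genes) are explicit absent values or
rejections, never NaNs.

## Known limitations

* Homology requires the external `blastn` executable; there is no pure-
  Python fallback.
* Multi-copy gene alleles are compared by their designated representative
  sequence; allele-abundance-aware comparison is out of scope.
* Query-origin-crossing homology is split in two (rotate the query to
  inspect a junction).
* The breakpoint count bounds, but does not reconstruct, biological
  recombination events.
* The simulator's truth SAM stands in for a mapper; no alignment algorithm
  is provided.
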