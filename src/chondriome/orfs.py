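"""ORF discovery on circular genomes, species-uniqueness classification and
chimeric ORF decomposition.

An ORF is an ATG-to-stop span (stop codon included) of at least 300 bp on
either strand; per stop codon the longest qualifying span is reported, which
suppresses nested shorter ATG variants. ORFs may wrap the circular origin
once. An ORF is unique to its genome when homologous alignments against
every other genome cover at most 95% of its length. Chimeric ORFs -- novel
reading frames stitched from fragments of functional mitochondrial genes, a
hallmark of cytoplasmic-male-sterility-associated loci -- are decomposed by
greedy tiling of gene-vs-ORF local alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .compare import run_blastn
from .genome import STOP_CODONS, CircularGenome, revcomp, translate, percent_of_genome
from .thresholds import DEFAULT_THRESHOLDS, AnalysisThresholds


@dataclass
class OrfRecord:
    """An open reading frame. ``start``/``end`` are 0-based half-open on the
    forward strand; ``end`` exceeds the genome length when the ORF wraps the
    origin. ``sequence`` is the coding strand (ATG..stop)."""

    orf_id: int
    start: int
    end: int
    strand: str
    sequence: str = field(repr=False)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def protein(self) -> str:
        return translate(self.sequence)[:-1]


@dataclass
class OrfComparison:
    orf_id: int
    coverages: dict[str, float]  # subject genome id -> homologous coverage
    unique: bool

    @property
    def best_coverage(self) -> float:
        return max(self.coverages.values()) if self.coverages else 0.0


@dataclass(frozen=True)
class ChimeraSegment:
    source_gene: str
    query_interval: tuple[int, int]  # 0-based half-open in the ORF
    source_interval: tuple[int, int]  # forward coords in the donor gene
    identity: float
    strand: str


@dataclass
class ChimeraDecomposition:
    segments: list[ChimeraSegment]
    unassigned: list[tuple[int, int]]


def scan_orfs(
    genome: CircularGenome,
    thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS,
) -> list[OrfRecord]:
    """Scan both strands and all frames of the circular genome for ORFs of
    at least ``orf_min_len`` bp (stop included), allowing a single wrap of
    the origin. Ids are assigned from 0 in (start, strand) order."""
    L = genome.length
    found: dict[tuple[int, str], tuple[int, int]] = {}  # (stop key, strand) -> (fstart, length)

    for strand in "+-":
        s = genome.sequence if strand == "+" else revcomp(genome.sequence)
        ds = s + s
        for frame in range(3):
            cur_atg = None
            for c0 in range(frame, 2 * L - 2, 3):
                codon = ds[c0 : c0 + 3]
                if codon in STOP_CODONS:
                    if cur_atg is not None:
                        length = c0 + 3 - cur_atg
                        if thresholds.orf_min_len <= length <= L:
                            if strand == "+":
                                fstart = cur_atg % L
                                stop_key = c0 % L
                            else:
                                fstart = (2 * L - (c0 + 3)) % L
                                stop_key = (2 * L - (c0 + 3)) % L
                            key = (stop_key, strand)
                            if key not in found or found[key][1] < length:
                                found[key] = (fstart, length)
                    cur_atg = None
                elif codon == "ATG" and cur_atg is None:
                    cur_atg = c0

    records = []
    for (stop_key, strand), (fstart, length) in found.items():
        fwd = genome.fetch(fstart, fstart + length)
        seq = fwd if strand == "+" else revcomp(fwd)
        records.append((fstart, strand, length, seq))
    records.sort(key=lambda r: (r[0], r[1]))
    return [
        OrfRecord(orf_id=i, start=fs, end=fs + ln, strand=st, sequence=seq)
        for i, (fs, st, ln, seq) in enumerate(records)
    ]


def orf_genome_fraction(orfs: list[OrfRecord], genome_length: int) -> tuple[int, float]:
    """Summed ORF lengths (overlaps counted per ORF) and the percentage of
    the genome they represent, rounded to one decimal."""
    total = sum(o.length for o in orfs)
    return total, percent_of_genome(total, genome_length, ndigits=1)


def _merged_coverage(intervals: list[tuple[int, int]], length: int) -> float:
    if not intervals:
        return 0.0
    intervals = sorted(intervals)
    covered = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    covered += cur_e - cur_s
    return min(covered / length, 1.0)


def classify_unique(
    query_orfs: list[OrfRecord],
    other_genomes: list[CircularGenome],
    thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS,
    min_alignment_len: int = 50,
) -> list[OrfComparison]:
    """Classify ORFs as unique to their genome by homologous coverage.

    For each other genome, every ORF is searched against the doubled subject
    (nucleotide level, both strands); alignments at >= 95% identity and at
    least ``min_alignment_len`` columns are merged on the query, and the ORF
    is unique iff coverage <= ``orf_unique_max_cov`` against EVERY other
    genome ("95% or less of the query size").
    """
    if not other_genomes:
        raise ValueError("at least one other genome required")
    queries = [(f"orf{o.orf_id}", o.sequence) for o in query_orfs]
    by_len = {f"orf{o.orf_id}": o.length for o in query_orfs}
    coverages: dict[int, dict[str, float]] = {o.orf_id: {} for o in query_orfs}
    for other in other_genomes:
        hits: dict[str, list[tuple[int, int]]] = {qid: [] for qid, _ in queries}
        if queries:
            for h in run_blastn(
                queries, (other.id, other.doubled()), word_size=11
            ):
                matches = sum(
                    1 for x, y in zip(h.qseq, h.sseq) if x == y and x != "-"
                )
                cols = len(h.qseq)
                if cols < min_alignment_len:
                    continue
                if matches / cols < thresholds.homology_min_identity:
                    continue
                hits[h.qid].append((h.qstart, h.qend))
        for qid, intervals in hits.items():
            orf_id = int(qid[3:])
            coverages[orf_id][other.id] = _merged_coverage(intervals, by_len[qid])
    eps = 1e-12
    return [
        OrfComparison(
            orf_id=o.orf_id,
            coverages=coverages[o.orf_id],
            unique=all(
                cov <= thresholds.orf_unique_max_cov + eps
                for cov in coverages[o.orf_id].values()
            ),
        )
        for o in query_orfs
    ]


def _trim_to_free(
    seg: ChimeraSegment, taken: list[tuple[int, int]], min_segment: int
) -> ChimeraSegment | None:
    """Trim a candidate segment to the largest query interval not already
    tiled; drop it when the remainder falls below ``min_segment``.

    The donor-gene interval is shifted by the same amounts (exact for
    ungapped alignments, approximate within the alignment's few gap columns
    otherwise); for minus-strand hits the donor coordinates move oppositely.
    """
    s, e = seg.query_interval
    free = [(s, e)]
    for ts, te in taken:
        nxt = []
        for fs, fe in free:
            if te <= fs or ts >= fe:
                nxt.append((fs, fe))
                continue
            if fs < ts:
                nxt.append((fs, ts))
            if te < fe:
                nxt.append((te, fe))
        free = nxt
    if not free:
        return None
    fs, fe = max(free, key=lambda iv: iv[1] - iv[0])
    if fe - fs < min_segment:
        return None
    if (fs, fe) == (s, e):
        return seg
    dl, dr = fs - s, e - fe
    ss, se = seg.source_interval
    if seg.strand == "+":
        source = (ss + dl, se - dr)
    else:
        source = (ss + dr, se - dl)
    return ChimeraSegment(
        source_gene=seg.source_gene,
        query_interval=(fs, fe),
        source_interval=source,
        identity=seg.identity,
        strand=seg.strand,
    )


def decompose_chimera(
    orf: OrfRecord,
    gene_db: list[tuple[str, str]],
    min_segment: int = 30,
    min_identity: float = 0.90,
) -> ChimeraDecomposition:
    """Decompose an ORF into donor-gene fragments by greedy tiling.

    All local alignments between the ORF and each gene are collected; HSPs
    of at least ``min_segment`` query bp at identity >= ``min_identity`` are
    tiled greedily by descending alignment score (ties: longer segment, then
    lexicographic gene id) into non-overlapping query segments. Query
    intervals no segment covers are reported as unassigned.
    """
    if not gene_db:
        raise ValueError("gene_db must be non-empty")
    candidates = []
    for gene_id, gene_seq in sorted(gene_db):
        for h in run_blastn(
            [("orf", orf.sequence)],
            (gene_id, gene_seq),
            word_size=7,
            evalue=1e-3,
            task="blastn-short",
        ):
            matches = sum(1 for x, y in zip(h.qseq, h.sseq) if x == y and x != "-")
            cols = len(h.qseq)
            qspan = h.qend - h.qstart
            identity = matches / cols if cols else 0.0
            if qspan < min_segment or identity < min_identity:
                continue
            score = matches  # matches as alignment score proxy
            candidates.append(
                (
                    -score,
                    -qspan,
                    gene_id,
                    ChimeraSegment(
                        source_gene=gene_id,
                        query_interval=(h.qstart, h.qend),
                        source_interval=(h.sstart, h.send),
                        identity=identity,
                        strand=h.strand,
                    ),
                )
            )
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    taken: list[tuple[int, int]] = []
    segments: list[ChimeraSegment] = []
    for _, _, _, seg in candidates:
        trimmed = _trim_to_free(seg, taken, min_segment)
        if trimmed is None:
            continue
        taken.append(trimmed.query_interval)
        segments.append(trimmed)
    segments.sort(key=lambda s: s.query_interval)
    unassigned = []
    cursor = 0
    for s, e in sorted(taken):
        if s > cursor:
            unassigned.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < orf.length:
        unassigned.append((cursor, orf.length))
    return ChimeraDecomposition(segments=segments, unassigned=unassigned)
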