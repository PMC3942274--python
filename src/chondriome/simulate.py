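"""Synthetic chondriome simulator.

A chondriome is modelled as a stoichiometric mixture of 2-4 mitotypes, each
derived from a circular "master" genome by substitutions, segment reversals
and deletions. Single-end reads in the style of 454 GS FLX pyrosequencing
(mean length 449 bp, truncated-normal lengths bounded to [100, 1000] bp) are
drawn from the mixture with per-base substitution errors, and emitted together
with truth alignments against the master coordinate system plus truth tables
(planted heteroplasmic positions, mitotype fractions, edit lists). Everything
is deterministic under an explicit seed; there is no hidden global random
state.

Reads that wrap the circular origin, or that cross a structural breakpoint
(reversal boundary), are emitted as multiple SAM segments sharing one read
name, because SAM has no native circular or rearrangement-aware convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .genome import (
    COMPLEMENT,
    STOP_CODONS,
    CircularGenome,
    GeneAnnotation,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b

READ_LEN_BOUNDS = (100, 1000)


class CapacityError(ValueError):
    """Requested genes/repeats do not fit into the genome length."""


@dataclass(frozen=True)
class Edit:
    """One truth edit in master coordinates (0-based half-open).

    Replay order is: substitutions (forward-strand alleles), then reversals
    (reverse-complement the segment in place), then deletions. All intervals
    are disjoint, so the order within each kind does not matter.
    """

    kind: str  # substitution | reversal | deletion
    start: int
    end: int
    ref: str = ""
    alt: str = ""


@dataclass(frozen=True)
class ReadSimConfig:
    mean_depth: float
    read_len_mean: float = 449.0
    read_len_sd: float = 100.0
    subst_error: float = 0.0
    seed: int = 0
    #: optional homopolymer-style indel error rate; off by default because
    #: the variant caller ignores indels. Exists to stress the pileup builder.
    indel_error: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        for name in ("subst_error", "indel_error"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class Mitotype:
    """One genome variant of the chondriome plus its stoichiometric fraction.

    ``to_master_pos``/``to_master_strand`` map every mitotype position to its
    source master position and orientation; they are what the read simulator
    uses to produce truth alignments in master coordinates.
    """

    genome: CircularGenome
    fraction: float
    truth_edits: list[Edit]
    annotations: list[GeneAnnotation]
    master_id: str
    master_length: int
    to_master_pos: np.ndarray = field(repr=False)
    to_master_strand: np.ndarray = field(repr=False)

    @property
    def is_collinear(self) -> bool:
        """True when the mitotype differs from the master by substitutions
        only (identity coordinate map)."""
        return all(e.kind == "substitution" for e in self.truth_edits)


@dataclass
class SamSegment:
    ref_start: int
    strand: str  # + / -
    cigar: list[tuple[str, int]]
    seq: str  # oriented to the forward strand of the master


@dataclass
class ReadRecord:
    name: str
    sequence: str  # as sequenced (mitotype forward strand)
    mitotype_index: int
    segments: list[SamSegment]
    source_start: int = 0  # start position on the source mitotype
    error_offsets: tuple[int, ...] = ()  # read offsets carrying a simulated error

    @property
    def n_errors(self) -> int:
        return len(self.error_offsets)


@dataclass
class ReadSet:
    reads: list[ReadRecord]
    master_id: str
    master_length: int
    fractions: list[float]
    config: ReadSimConfig

    def total_bases(self) -> int:
        return sum(len(r.sequence) for r in self.reads)

    def mean_read_length(self) -> float:
        return self.total_bases() / len(self.reads)

    def origin_depth(self) -> np.ndarray:
        """Per-master-position read depth split by mitotype of origin,
        shape ``(n_mitotypes, master_length)``.

        Depth counts reference-consuming alignment columns (M and D), the
        same convention the pileup builder uses.
        """
        n_mito = len(self.fractions)
        depth = np.zeros((n_mito, self.master_length), dtype=np.int32)
        for read in self.reads:
            for seg in read.segments:
                rpos = seg.ref_start
                for op, ln in seg.cigar:
                    if op in ("M", "D"):
                        idx = (rpos + np.arange(ln)) % self.master_length
                        depth[read.mitotype_index, idx] += 1
                        rpos += ln
            # insertions consume no reference
        return depth


# ---------------------------------------------------------------------------
# master genome generation


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _random_orf(rng: np.random.Generator, length: int) -> str:
    """An ATG...stop open reading frame of ``length`` bp (multiple of 3)
    with no internal stop codon."""
    n_codons = length // 3 - 2
    codons = []
    while len(codons) < n_codons:
        codon = _random_seq(rng, 3)
        if codon not in STOP_CODONS:
            codons.append(codon)
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "ATG" + "".join(codons) + stop


def generate_master(
    length: int,
    n_genes: int,
    gene_len_range: tuple[int, int] = (300, 1500),
    n_repeats: int = 0,
    repeat_len: int = 1000,
    seed: int = 0,
) -> tuple[CircularGenome, list[GeneAnnotation]]:
    """Generate a circular master genome with planted protein genes and
    repeated sequence.

    Genes are non-overlapping, begin with ATG and end with a stop codon on
    their strand, with stop-free interiors. Each of the ``n_repeats`` distinct
    repeat elements is planted verbatim at two loci, emulating the large
    repeated sequences over which plant mitochondrial genomes recombine.
    Identical seeds give byte-identical output.
    """
    rng = np.random.default_rng(seed)
    lo, hi = gene_len_range
    if lo < 9:
        raise ValueError("minimum protein gene length is 9 bp (ATG + codon + stop)")

    gene_lens = []
    for _ in range(n_genes):
        g = int(rng.integers(lo, hi + 1))
        g -= g % 3
        gene_lens.append(max(g, 9))

    repeat_seqs = [_random_seq(rng, repeat_len) for _ in range(n_repeats)]

    items: list[tuple[str, str, str]] = []  # (kind, payload, strand)
    for i, glen in enumerate(gene_lens):
        strand = "+" if rng.random() < 0.5 else "-"
        orf = _random_orf(rng, glen)
        payload = orf if strand == "+" else revcomp(orf)
        items.append(("gene", payload, strand))
    for rep in repeat_seqs:
        items.append(("repeat", rep, "+"))
        items.append(("repeat", rep, "+"))

    total_item_len = sum(len(p) for _, p, _ in items)
    if total_item_len > length:
        raise CapacityError(
            f"cannot pack {total_item_len} bp of genes/repeats into {length} bp"
        )

    order = rng.permutation(len(items))
    slack = length - total_item_len
    n_gaps = len(items) + 1
    gaps = rng.multinomial(slack, np.full(n_gaps, 1.0 / n_gaps)) if n_gaps else []

    parts: list[str] = []
    annotations: list[GeneAnnotation] = []
    cursor = 0
    gene_no = 0
    for slot, item_idx in enumerate(order):
        gap = int(gaps[slot])
        parts.append(_random_seq(rng, gap))
        cursor += gap
        kind, payload, strand = items[item_idx]
        if kind == "gene":
            gene_no += 1
            annotations.append(
                GeneAnnotation(
                    gene_id=f"g{gene_no:03d}",
                    start=cursor,
                    end=cursor + len(payload),
                    strand=strand,
                    category="protein",
                )
            )
        parts.append(payload)
        cursor += len(payload)
    parts.append(_random_seq(rng, int(gaps[-1]) if len(items) else length))

    sequence = "".join(parts)
    assert len(sequence) == length
    annotations.sort(key=lambda a: a.start)
    return CircularGenome(id="master", sequence=sequence), annotations


# ---------------------------------------------------------------------------
# mitotype derivation


def _check_intervals(intervals: list[tuple[int, int]], length: int) -> None:
    for s, e in intervals:
        if not (0 <= s < e <= length):
            raise ValueError(f"interval ({s}, {e}) invalid for genome length {length}")
    for i, (s1, e1) in enumerate(intervals):
        for s2, e2 in intervals[i + 1:]:
            if s1 < e2 and s2 < e1:
                raise ValueError(f"overlapping edit intervals ({s1},{e1}) and ({s2},{e2})")


def derive_mitotype(
    master: CircularGenome,
    annotations: list[GeneAnnotation] | None = None,
    n_subst: int = 0,
    reversals: list[tuple[int, int]] = (),
    deletions: list[tuple[int, int]] = (),
    fraction: float = 1.0,
    seed: int = 0,
    mitotype_id: str | None = None,
) -> Mitotype:
    """Derive a mitotype from the master by reversals, deletions and random
    substitutions.

    Edit intervals are master coordinates and must be pairwise disjoint.
    Substitutions never recreate the reference base and are placed outside
    deleted segments (they land anywhere else, including inside reversals,
    where their truth record carries the forward-strand allele). Gene
    annotations are lifted through the edits: genes fully inside a reversal
    flip strand and order; genes touching a deletion or straddling a reversal
    boundary are dropped.
    """
    annotations = list(annotations or [])
    rng = np.random.default_rng(seed)
    reversals = [tuple(x) for x in reversals]
    deletions = [tuple(x) for x in deletions]
    _check_intervals(reversals + deletions, master.length)

    L = master.length
    pos = np.arange(L, dtype=np.int64)
    strand = np.ones(L, dtype=np.int8)
    for s, e in reversals:
        pos[s:e] = pos[s:e][::-1]
        strand[s:e] = -1
    keep = np.ones(L, dtype=bool)
    for s, e in deletions:
        keep[s:e] = False
    pos = pos[keep]
    strand = strand[keep]

    master_bytes = np.frombuffer(master.sequence.encode(), dtype=np.uint8)
    seq_bytes = master_bytes[pos].copy()
    rev = strand < 0
    seq_bytes[rev] = _COMP[seq_bytes[rev]]

    edits: list[Edit] = [Edit("reversal", s, e) for s, e in reversals]
    edits += [Edit("deletion", s, e, ref=master.fetch(s, e)) for s, e in deletions]

    if n_subst > len(pos):
        raise ValueError("more substitutions requested than available positions")
    if n_subst:
        sites = np.sort(rng.choice(len(pos), size=n_subst, replace=False))
        for i in sites:
            current = chr(seq_bytes[i])
            alternatives = [b for b in "ACGT" if b != current]
            alt = alternatives[rng.integers(3)]
            seq_bytes[i] = ord(alt)
            mpos = int(pos[i])
            ref_fwd = master.sequence[mpos]
            alt_fwd = alt if strand[i] > 0 else chr(_COMP[ord(alt)])
            edits.append(Edit("substitution", mpos, mpos + 1, ref=ref_fwd, alt=alt_fwd))

    # lift annotations
    del_sorted = sorted(deletions)
    deleted_before = _cumulative_deleted(del_sorted)
    lifted: list[GeneAnnotation] = []
    for ann in annotations:
        if ann.end > L:
            continue  # origin-wrapping genes are not lifted
        hit_deletion = any(ann.start < e and s < ann.end for s, e in deletions)
        if hit_deletion:
            continue
        inside = [(s, e) for s, e in reversals if s <= ann.start and ann.end <= e]
        straddles = any(
            (ann.start < e and s < ann.end) and not (s <= ann.start and ann.end <= e)
            for s, e in reversals
        )
        if straddles:
            continue
        if inside:
            s, e = inside[0]
            new_start = s + (e - ann.end)
            new_end = s + (e - ann.start)
            new_strand = "-" if ann.strand == "+" else "+"
        else:
            new_start, new_end, new_strand = ann.start, ann.end, ann.strand
        shift_s = deleted_before(new_start)
        lifted.append(
            GeneAnnotation(
                gene_id=ann.gene_id,
                start=new_start - shift_s,
                end=new_end - deleted_before(new_end),
                strand=new_strand,
                category=ann.category,
            )
        )
    lifted.sort(key=lambda a: a.start)

    mt_id = mitotype_id or f"{master.id}|derived-s{seed}"
    genome = CircularGenome(id=mt_id, sequence=seq_bytes.tobytes().decode())
    return Mitotype(
        genome=genome,
        fraction=fraction,
        truth_edits=edits,
        annotations=lifted,
        master_id=master.id,
        master_length=L,
        to_master_pos=pos,
        to_master_strand=strand,
    )


def _cumulative_deleted(sorted_deletions: list[tuple[int, int]]):
    starts = [s for s, _ in sorted_deletions]
    sizes = np.cumsum([0] + [e - s for s, e in sorted_deletions])

    def deleted_before(position: int) -> int:
        import bisect

        i = bisect.bisect_left(starts, position) if starts else 0
        # position is guaranteed not to fall inside a deletion for lifted genes
        return int(sizes[i])

    return deleted_before


def replay_edits(master: CircularGenome, edits: list[Edit]) -> str:
    """Reproduce a mitotype sequence from the master and its truth edits
    (substitutions, then reversals, then deletions)."""
    seq = list(master.sequence)
    for e in edits:
        if e.kind == "substitution":
            if seq[e.start] != e.ref:
                raise ValueError(f"substitution ref mismatch at {e.start}")
            seq[e.start] = e.alt
    for e in edits:
        if e.kind == "reversal":
            seq[e.start:e.end] = list(revcomp("".join(seq[e.start:e.end])))
    for e in sorted(edits, key=lambda x: -x.start):
        if e.kind == "deletion":
            del seq[e.start:e.end]
    return "".join(seq)


def truth_hsnp_table(
    master: CircularGenome, mitotypes: list[Mitotype]
) -> list[dict]:
    """Planted heteroplasmic positions in master coordinates.

    For each position touched by a substitution in any mitotype, reports the
    expected allele fractions among covering reads (mitotypes that deleted
    the position do not cover it) and the expected minor fraction, i.e. one
    minus the predominant allele's expected fraction.
    """
    sub_positions: set[int] = set()
    per_mito_allele: list[dict[int, str]] = []
    per_mito_deleted: list[set[int]] = []
    for mt in mitotypes:
        alleles: dict[int, str] = {}
        deleted: set[int] = set()
        for e in mt.truth_edits:
            if e.kind == "substitution":
                alleles[e.start] = e.alt
                sub_positions.add(e.start)
            elif e.kind == "deletion":
                deleted.update(range(e.start, e.end))
        per_mito_allele.append(alleles)
        per_mito_deleted.append(deleted)

    rows = []
    for p in sorted(sub_positions):
        fracs: dict[str, float] = {}
        covered = 0.0
        for mt, alleles, deleted in zip(mitotypes, per_mito_allele, per_mito_deleted):
            if p in deleted:
                continue
            base = alleles.get(p, master.sequence[p])
            fracs[base] = fracs.get(base, 0.0) + mt.fraction
            covered += mt.fraction
        if covered == 0 or len(fracs) < 2:
            continue
        fracs = {b: f / covered for b, f in fracs.items()}
        major = max(sorted(fracs), key=lambda b: fracs[b])
        minor = max(sorted(b for b in fracs if b != major), key=lambda b: fracs[b])
        rows.append(
            {
                "position": p,
                "ref": master.sequence[p],
                "major": major,
                "minor": minor,
                "minor_frac": 1.0 - fracs[major],
            }
        )
    return rows


# ---------------------------------------------------------------------------
# read simulation


def _segments_collinear(start: int, length: int, L: int, seq: str) -> list[SamSegment]:
    """Alignment segments for a read from a substitution-only mitotype:
    pure-M, split only at the circular origin."""
    if start + length <= L:
        return [SamSegment(start, "+", [("M", length)], seq)]
    first = L - start
    return [
        SamSegment(start, "+", [("M", first)], seq[:first]),
        SamSegment(0, "+", [("M", length - first)], seq[first:]),
    ]


def _segments_general(
    start: int, length: int, mito: Mitotype, seq: str
) -> list[SamSegment]:
    """Alignment segments for a read from a structurally edited mitotype.

    Walks the mitotype->master coordinate map; runs split at strand changes
    and at the master origin, and same-strand forward jumps become deletion
    (D) operations.
    """
    Lm = mito.genome.length
    L = mito.master_length
    idx = (start + np.arange(length)) % Lm
    mp = mito.to_master_pos[idx]
    ms = mito.to_master_strand[idx]

    segments: list[SamSegment] = []
    run_start = 0
    i = 0
    while i < length:
        j = i
        while j + 1 < length:
            same_strand = ms[j + 1] == ms[j]
            step = int(mp[j + 1] - mp[j])
            if not same_strand:
                break
            if ms[j] > 0 and 0 < step < L // 2 and mp[j + 1] > mp[j]:
                j += 1
                continue
            if ms[j] < 0 and 0 < -step < L // 2 and mp[j + 1] < mp[j]:
                j += 1
                continue
            break
        # emit run [i, j]
        run_mp = mp[i : j + 1]
        run_seq = seq[i : j + 1]
        if ms[i] > 0:
            cigar = _cigar_from_positions(run_mp)
            segments.append(SamSegment(int(run_mp[0]), "+", cigar, run_seq))
        else:
            cigar = _cigar_from_positions(run_mp[::-1])
            segments.append(
                SamSegment(int(run_mp[-1]), "-", cigar, revcomp(run_seq))
            )
        i = j + 1
    return segments


def _cigar_from_positions(positions: np.ndarray) -> list[tuple[str, int]]:
    """CIGAR for a strictly increasing master-position run; jumps become D."""
    ops: list[tuple[str, int]] = []
    m_run = 1
    for k in range(1, len(positions)):
        gap = int(positions[k] - positions[k - 1]) - 1
        if gap == 0:
            m_run += 1
        else:
            ops.append(("M", m_run))
            ops.append(("D", gap))
            m_run = 1
    ops.append(("M", m_run))
    merged: list[tuple[str, int]] = []
    for op, ln in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return merged


def _apply_indels(
    rng: np.random.Generator, seq: str, segment: SamSegment, rate: float
) -> tuple[str, SamSegment]:
    """Apply simple 1-bp insertion/deletion errors to a single-segment,
    pure-M read, rewriting sequence and CIGAR."""
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq, segment
    sites = sorted(rng.choice(len(seq), size=min(n, len(seq)), replace=False))
    out: list[str] = []
    cigar: list[tuple[str, int]] = []
    prev = 0

    def push(op: str, ln: int) -> None:
        if ln <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + ln)
        else:
            cigar.append((op, ln))

    for site in sites:
        push("M", site - prev)
        out.append(seq[prev:site])
        if rng.random() < 0.5:  # insertion: duplicate the base
            out.append(seq[site] + seq[site])
            push("M", 1)
            push("I", 1)
        else:  # deletion of this base
            push("D", 1)
        prev = site + 1
    push("M", len(seq) - prev)
    out.append(seq[prev:])
    new_seq = "".join(out)
    new_seg = SamSegment(segment.ref_start, segment.strand, cigar, new_seq)
    return new_seq, new_seg


def simulate_reads(mitotypes: list[Mitotype], cfg: ReadSimConfig) -> ReadSet:
    """Draw single-end reads from a stoichiometric mitotype mixture.

    Each read picks its mitotype with probability equal to its fraction,
    a truncated-normal length, a uniform start on the circle, then per-base
    substitution errors at ``cfg.subst_error`` choosing uniformly among the
    three alternative bases. Truth alignments against the master are attached
    to every read.
    """
    if not mitotypes:
        raise ValueError("at least one mitotype required")
    fractions = [m.fraction for m in mitotypes]
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"mitotype fractions must sum to 1, got {sum(fractions)}")
    master_id = mitotypes[0].master_id
    L = mitotypes[0].master_length
    if any(m.master_id != master_id or m.master_length != L for m in mitotypes):
        raise ValueError("all mitotypes must derive from the same master")
    if cfg.indel_error > 0 and not all(m.is_collinear for m in mitotypes):
        raise ValueError(
            "indel errors are only supported for substitution-only mitotypes"
        )

    rng = np.random.default_rng(cfg.seed)
    n_reads = max(1, int(round(cfg.mean_depth * L / cfg.read_len_mean)))

    mito_idx = rng.choice(len(mitotypes), size=n_reads, p=fractions)
    lo, hi = READ_LEN_BOUNDS
    a = (lo - cfg.read_len_mean) / cfg.read_len_sd
    b = (hi - cfg.read_len_mean) / cfg.read_len_sd
    lengths = truncnorm.rvs(
        a, b, loc=cfg.read_len_mean, scale=cfg.read_len_sd,
        size=n_reads, random_state=rng,
    ).astype(int)

    doubled = [m.genome.doubled() for m in mitotypes]
    reads: list[ReadRecord] = []
    for i in range(n_reads):
        mi = int(mito_idx[i])
        mito = mitotypes[mi]
        Lm = mito.genome.length
        rl = min(int(lengths[i]), Lm)
        start = int(rng.integers(Lm))
        seq = doubled[mi][start : start + rl]

        n_err = rng.binomial(rl, cfg.subst_error) if cfg.subst_error > 0 else 0
        err_sites: tuple[int, ...] = ()
        if n_err:
            err_sites = tuple(sorted(int(x) for x in rng.choice(rl, size=n_err, replace=False)))
            chars = list(seq)
            for site in err_sites:
                current = chars[site]
                alternatives = [bb for bb in "ACGT" if bb != current]
                chars[site] = alternatives[rng.integers(3)]
            seq = "".join(chars)

        if mito.is_collinear:
            segments = _segments_collinear(start, rl, L, seq)
            if cfg.indel_error > 0 and len(segments) == 1:
                seq, seg = _apply_indels(rng, seq, segments[0], cfg.indel_error)
                segments = [seg]
        else:
            segments = _segments_general(start, rl, mito, seq)

        reads.append(
            ReadRecord(
                name=f"r{i:06d}",
                sequence=seq,
                mitotype_index=mi,
                segments=segments,
                source_start=start,
                error_offsets=err_sites,
            )
        )

    return ReadSet(
        reads=reads,
        master_id=master_id,
        master_length=L,
        fractions=fractions,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# synthetic frameshift gene (stand-in generator)


def generate_frameshift_gene(
    n_codons: int = 191,
    del_start: int = 134,
    del_len: int = 4,
    stop_first_base: int = 158,
    deleted_bases: str | None = "TGTG",
    seed: int = 0,
) -> str:
    """SYNTHETIC stand-in: construct a protein-coding gene in which deleting
    ``del_len`` bases starting at 1-based position ``del_start`` frameshifts
    the reading frame so that the first stop codon of the shifted frame has
    its first base at original coordinate ``stop_first_base``.

    This generator produces an artificial sequence with the stated geometric
    properties (optionally pinning the deleted bases, e.g. a TGTG repeat
    slippage); it is NOT any real gene sequence. Used to exercise frameshift
    premature-stop arithmetic when no reference sequence is available.
    """
    length = 3 * n_codons
    mutant_stop_start = stop_first_base - del_len  # 1-based in the mutant
    if (mutant_stop_start - 1) % 3 != 0:
        raise ValueError("stop_first_base is not in-frame after the deletion")
    if deleted_bases is not None and len(deleted_bases) != del_len:
        raise ValueError("deleted_bases length must equal del_len")
    if stop_first_base + 2 > length or del_start + del_len - 1 >= stop_first_base:
        raise ValueError("inconsistent geometry")

    rng = np.random.default_rng(seed)
    for _ in range(10_000):
        codons = ["ATG"]
        for _ in range(n_codons - 2):
            while True:
                c = _random_seq(rng, 3)
                if c not in STOP_CODONS:
                    break
            codons.append(c)
        codons.append("TAA")
        seq = list("".join(codons))
        if deleted_bases is not None:
            seq[del_start - 1 : del_start - 1 + del_len] = list(deleted_bases)
        seq[stop_first_base - 1 : stop_first_base + 2] = list("TAG")
        candidate = "".join(seq)

        # original frame must stay clean (start, no internal stop, final stop)
        orig_codons = [candidate[i : i + 3] for i in range(0, length, 3)]
        if any(c in STOP_CODONS for c in orig_codons[:-1]):
            continue
        if orig_codons[-1] not in STOP_CODONS:
            continue
        # mutant frame: first stop must start exactly at mutant_stop_start
        mutant = candidate[: del_start - 1] + candidate[del_start - 1 + del_len :]
        first = None
        for i in range(0, len(mutant) - 2, 3):
            if mutant[i : i + 3] in STOP_CODONS:
                first = i + 1
                break
        if first == mutant_stop_start:
            return candidate
    raise RuntimeError("could not satisfy frameshift constraints")
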