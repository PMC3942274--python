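"""Read pileups and the coverage mask over a circular reference.

Depth at a position counts reads whose alignment consumes the reference
there (CIGAR M/=/X/D); soft-clipped bases are ignored and ambiguous (N) read
bases are excluded from the base tallies but still counted in depth. Reads
whose CIGAR is inconsistent with their sequence length are rejected
individually and the rejection count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .genome import CircularGenome
from .io import write_bed, write_tsv

_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
_N_CODE = ord("N")

# CIGAR op codes (pysam numeric): M,I,D,N,S,H,P,=,X
_QUERY_CONSUMES = {0: True, 1: True, 2: False, 3: False, 4: True,
                   5: False, 6: False, 7: True, 8: True}
_REF_CONSUMES = {0: True, 1: False, 2: True, 3: True, 4: False,
                 5: False, 6: False, 7: True, 8: True}


@dataclass
class PileupColumn:
    """Per-position base counts. ``depth = A+C+G+T+N+del``."""

    position: int
    counts: dict[str, int]
    n_count: int = 0
    del_count: int = 0
    ins_count: int = 0

    @property
    def depth(self) -> int:
        return sum(self.counts.values()) + self.n_count + self.del_count


@dataclass
class CoverageMask:
    """Genome space excluded from analysis for insufficient depth."""

    excluded_intervals: list[tuple[int, int]]
    excluded_bp: int
    excluded_fraction: float
    min_depth: int

    def to_bed(self, path, chrom: str) -> None:
        write_bed(path, self.excluded_intervals, chrom)

    def contains(self, position: int) -> bool:
        return any(s <= position < e for s, e in self.excluded_intervals)


class Pileup:
    """Array-backed pileup over the whole circular reference.

    Indexable as a lazy sequence of :class:`PileupColumn`; the numpy arrays
    (``counts`` shaped ``(4, L)`` in A,C,G,T order, ``n_count``, ``del_count``,
    ``ins_count``) are the fast path the callers use directly.
    """

    def __init__(self, length: int):
        self.length = length
        self.counts = np.zeros((4, length), dtype=np.int32)
        self.n_count = np.zeros(length, dtype=np.int32)
        self.del_count = np.zeros(length, dtype=np.int32)
        self.ins_count = np.zeros(length, dtype=np.int32)
        self.n_rejected = 0
        self.n_reads = 0

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0) + self.n_count + self.del_count

    def column(self, position: int) -> PileupColumn:
        return PileupColumn(
            position=position,
            counts={b: int(self.counts[i, position]) for i, b in enumerate("ACGT")},
            n_count=int(self.n_count[position]),
            del_count=int(self.del_count[position]),
            ins_count=int(self.ins_count[position]),
        )

    def columns(self) -> list[PileupColumn]:
        """Columns for covered positions only, in coordinate order."""
        covered = np.nonzero(self.depth > 0)[0]
        return [self.column(int(p)) for p in covered]

    def total_tallied_bases(self) -> int:
        return int(self.counts.sum() + self.n_count.sum())

    def to_tsv(self, path) -> None:
        depth = self.depth
        rows = (
            (
                int(p),
                int(depth[p]),
                *(int(self.counts[i, p]) for i in range(4)),
                int(self.del_count[p]),
                int(self.ins_count[p]),
            )
            for p in np.nonzero(depth > 0)[0]
        )
        write_tsv(path, ["pos", "depth", "A", "C", "G", "T", "del", "ins"], rows)


def build_pileup(sam_path, reference: CircularGenome) -> Pileup:
    """Tally a SAM file of alignments against ``reference`` into a pileup.

    Positions are taken modulo the reference length, so alignments emitted
    against a linearized circle wrap correctly. Insertions are attributed to
    the reference position preceding them.
    """
    pile = Pileup(reference.length)
    header_lines = []
    body_lines = []
    with open(sam_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            (header_lines if line.startswith("@") else body_lines).append(line)
    header = pysam.AlignmentHeader.from_text("\n".join(header_lines) + "\n")
    for line in body_lines:
        # parse record-by-record so one malformed read (e.g. CIGAR/SEQ length
        # mismatch) is rejected individually instead of aborting the file
        try:
            aln = pysam.AlignedSegment.fromstring(line, header)
        except ValueError:
            pile.n_rejected += 1
            continue
        if aln.is_unmapped or aln.cigartuples is None or aln.query_sequence is None:
            continue
        cig = aln.cigartuples
        seq = aln.query_sequence
        qlen = sum(ln for op, ln in cig if _QUERY_CONSUMES.get(op, False))
        if qlen != len(seq):
            pile.n_rejected += 1
            continue
        _tally(pile, aln.reference_start, cig, seq)
        pile.n_reads += 1
    return pile


def _tally(pile: Pileup, ref_start: int, cigartuples, seq: str) -> None:
    L = pile.length
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    qpos = 0
    rpos = ref_start
    for op, ln in cigartuples:
        if op in (0, 7, 8):  # M / = / X
            ref_idx = (rpos + np.arange(ln)) % L
            base_idx = _BASE_INDEX[codes[qpos : qpos + ln]]
            valid = base_idx >= 0
            np.add.at(pile.counts, (base_idx[valid], ref_idx[valid]), 1)
            is_n = codes[qpos : qpos + ln] == _N_CODE
            if is_n.any():
                np.add.at(pile.n_count, ref_idx[is_n], 1)
            qpos += ln
            rpos += ln
        elif op == 1:  # I: attach to preceding reference position
            pile.ins_count[(rpos - 1) % L] += 1
            qpos += ln
        elif op == 2:  # D
            ref_idx = (rpos + np.arange(ln)) % L
            np.add.at(pile.del_count, ref_idx, 1)
            rpos += ln
        elif op == 3:  # N skip
            rpos += ln
        elif op == 4:  # S
            qpos += ln
        # H/P consume nothing


def _depth_array(pileup, genome_length: int | None) -> tuple[np.ndarray, int]:
    if isinstance(pileup, Pileup):
        return pileup.depth, pileup.length
    if genome_length is None:
        raise ValueError("genome_length required for column-list input")
    depth = np.zeros(genome_length, dtype=np.int64)
    for col in pileup:
        depth[col.position % genome_length] += col.depth
    return depth, genome_length


def coverage_mask(pileup, genome_length: int | None = None, min_depth: int = 10) -> CoverageMask:
    """Positions with depth below ``min_depth`` (uncovered included) form the
    excluded intervals; ``depth >= min_depth`` passes ("at least 10x")."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    depth, L = _depth_array(pileup, genome_length)
    low = depth < min_depth
    padded = np.concatenate(([False], low, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    intervals = [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]
    excluded_bp = int(low.sum())
    return CoverageMask(
        excluded_intervals=intervals,
        excluded_bp=excluded_bp,
        excluded_fraction=round(excluded_bp / L, 4),
        min_depth=min_depth,
    )
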