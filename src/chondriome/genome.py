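"""Circular genome and gene-annotation primitives.

Plant mitochondrial genomes are conventionally reported as a single circular
"master" molecule even though in vivo they exist as a multipartite population
of isoforms. Everything downstream of this module treats coordinates as
0-based half-open on that circle; intervals may run past the origin, in which
case ``end`` exceeds the genome length and position arithmetic is modulo the
length. 1-based coordinates appear only in human-facing reports (VCF, the
``X/Y^n`` coding-change labels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Seq import Seq

ALPHABET = frozenset("ACGT")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
STOP_CODONS = ("TAA", "TAG", "TGA")

GENE_CATEGORIES = ("protein", "tRNA", "rRNA", "pseudo", "orf")


def revcomp(sequence: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return sequence.translate(COMPLEMENT)[::-1]


def translate(sequence: str) -> str:
    """Translate an in-frame nucleotide string with the standard table."""
    return str(Seq(sequence).translate(table=1))


def codon_index(nt_pos: int) -> int:
    """Codon ordinal (1-based) holding the 1-based nucleotide position
    relative to the start codon: ``ceil(nt_pos / 3)``."""
    if nt_pos < 1:
        raise ValueError(f"nt_pos must be >= 1, got {nt_pos}")
    return math.ceil(nt_pos / 3)


def percent_of_genome(total_bp: int, genome_length: int, ndigits: int | None = 1) -> float:
    """``100 * total_bp / genome_length`` rounded to ``ndigits`` decimals."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    pct = 100.0 * total_bp / genome_length
    return round(pct, ndigits) if ndigits is not None else pct


@dataclass(frozen=True)
class CircularGenome:
    """A circular nucleotide sequence over {A,C,G,T}.

    ``fetch`` accepts intervals that wrap the origin once (``end`` up to
    ``2 * length``), which is how every consumer in this package reads
    origin-spanning features.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        extra = set(self.sequence) - ALPHABET
        if extra:
            raise ValueError(f"genome {self.id!r} contains non-ACGT symbols: {sorted(extra)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def doubled(self) -> str:
        """The sequence concatenated with itself; linearizes the circle for
        alignment and ORF scanning (a single wrap)."""
        return self.sequence + self.sequence

    def fetch(self, start: int, end: int) -> str:
        """Substring of the circle, 0-based half-open; may wrap the origin
        once (``end`` may exceed ``length``)."""
        n = self.length
        if not 0 <= start < n:
            raise ValueError(f"start {start} outside [0, {n})")
        if not start < end <= start + n:
            raise ValueError(f"end {end} must satisfy start < end <= start + length")
        if end <= n:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[: end - n]

    def base(self, pos: int) -> str:
        return self.sequence[pos % self.length]


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus on a circular genome.

    ``start``/``end`` are 0-based half-open on the forward strand; ``end`` may
    exceed the genome length for origin-wrapping genes. ``strand`` is ``+`` or
    ``-``; the coding sequence of a ``-`` gene is the reverse complement of
    the forward-strand span.
    """

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    category: str = "protein"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.category not in GENE_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.category == "protein" and self.span < 3:
            raise ValueError("protein gene span must be >= 3 bp")

    @property
    def span(self) -> int:
        return self.end - self.start

    def coding_sequence(self, genome: CircularGenome) -> str:
        """The gene sequence on its coding strand (ATG-first for protein
        genes annotated by the generator)."""
        seq = genome.fetch(self.start, self.end)
        return revcomp(seq) if self.strand == "-" else seq


def check_annotations(annotations: list[GeneAnnotation], genome_length: int) -> None:
    """Validate uniqueness of ids and coordinate sanity against a genome."""
    seen: set[str] = set()
    for ann in annotations:
        if ann.gene_id in seen:
            raise ValueError(f"duplicate gene_id {ann.gene_id!r}")
        seen.add(ann.gene_id)
        if not 0 <= ann.start < genome_length:
            raise ValueError(f"gene {ann.gene_id!r} start outside genome")
        if ann.end > ann.start + genome_length:
            raise ValueError(f"gene {ann.gene_id!r} wraps more than once")
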