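"""Inter-genome comparison: homologous regions, consensus SNPs, coding
changes, contig joining and the false-positive rate over conserved space.

Homology search between consensus genomes runs NCBI ``blastn`` (seed-and-
extend local alignment with exact word anchors and gapped extension) against
the doubled subject sequence so that alignments may cross the circular
origin of the subject; only alignments of at least ``min_len`` columns at
identity >= 95% (inclusive) are retained. SNPs are the mismatch columns of
those alignments -- gap columns are never reported, mirroring the rule that
insertion/deletion events are excluded from SNP analysis.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import edlib

from .genome import (
    CircularGenome,
    GeneAnnotation,
    codon_index,
    revcomp,
    translate,
)
from .thresholds import DEFAULT_THRESHOLDS, AnalysisThresholds

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class LocalAlignment:
    """A retained local alignment between two genomes.

    Intervals are 0-based half-open on the forward strand of each genome;
    ``b_end`` may exceed the b genome length when the alignment wraps b's
    origin. ``a_aln``/``b_aln`` are the gapped alignment rows in query
    orientation (for ``strand == '-'`` the b row shows the reverse
    complement of b's forward strand).
    """

    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    strand: str
    identity: float
    length: int  # aligned columns
    a_aln: str
    b_aln: str


@dataclass(frozen=True)
class ConsensusSNP:
    a_pos: int
    b_pos: int
    a_base: str
    b_base: str
    gene_context: tuple[str, int] | None = None  # (gene_id, 1-based CDS position)


@dataclass(frozen=True)
class CodingChange:
    gene_id: str
    nt_pos: int
    ref_aa: str
    alt_aa: str
    codon_index: int
    label: str

    @property
    def synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa


@dataclass
class MergeResult:
    """Outcome of a contig-join attempt; refusal is a value, not an error."""

    merged: str | None
    overlap: int
    dissimilarity: float
    reason: str

    @property
    def joined(self) -> bool:
        return self.merged is not None


# ---------------------------------------------------------------------------
# blastn plumbing


def _require_blastn() -> str:
    exe = shutil.which("blastn")
    if exe is None:
        raise RuntimeError(
            "the NCBI blastn executable is required for homology search "
            "but was not found on PATH"
        )
    return exe


@dataclass
class _Hsp:
    qid: str
    qstart: int  # 0-based half-open, query forward
    qend: int
    sstart: int  # 0-based half-open on subject forward strand
    send: int
    strand: str
    length: int
    qseq: str
    sseq: str


def run_blastn(
    queries: list[tuple[str, str]],
    subject: tuple[str, str],
    word_size: int = 15,
    evalue: float = 1e-8,
    task: str = "blastn",
) -> list[_Hsp]:
    """Run blastn of ``queries`` against a single ``subject`` sequence and
    return parsed HSPs with 0-based half-open coordinates."""
    exe = _require_blastn()
    with tempfile.TemporaryDirectory(prefix="chondriome_blast_") as tmp:
        qpath = Path(tmp) / "query.fa"
        spath = Path(tmp) / "subject.fa"
        qpath.write_text("".join(f">{qid}\n{seq}\n" for qid, seq in queries))
        spath.write_text(f">{subject[0]}\n{subject[1]}\n")
        out = subprocess.run(
            [
                exe,
                "-query", str(qpath),
                "-subject", str(spath),
                "-task", task,
                "-word_size", str(word_size),
                "-evalue", str(evalue),
                "-dust", "no",
                "-soft_masking", "false",
                "-outfmt", "6 qseqid qstart qend sstart send length qseq sseq",
            ],
            capture_output=True,
            text=True,
            check=True,
        )
    hsps = []
    for line in out.stdout.splitlines():
        qid, qs, qe, ss, se, ln, qseq, sseq = line.split("\t")
        qs, qe, ss, se, ln = int(qs), int(qe), int(ss), int(se), int(ln)
        if ss <= se:
            strand, s0, s1 = "+", ss - 1, se
        else:
            strand, s0, s1 = "-", se - 1, ss
        hsps.append(
            _Hsp(
                qid=qid,
                qstart=qs - 1,
                qend=qe,
                sstart=s0,
                send=s1,
                strand=strand,
                length=ln,
                qseq=qseq.upper(),
                sseq=sseq.upper(),
            )
        )
    return hsps


def _alignment_identity(qseq: str, sseq: str) -> tuple[int, int]:
    matches = sum(1 for a, b in zip(qseq, sseq) if a == b and a != "-")
    return matches, len(qseq)


def find_homologous_regions(
    a: CircularGenome,
    b: CircularGenome,
    thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS,
    min_len: int = 200,
    word_size: int = 15,
) -> list[LocalAlignment]:
    """Homologous regions of ``a`` (query, linear) against ``b`` (subject,
    doubled so alignments may wrap b's origin), both strands.

    Retains alignments with at least ``min_len`` columns and identity at or
    above the 95% cutoff (inclusive). Subject coordinates are normalized
    modulo the subject length and duplicates from the doubling removed.
    """
    Lb = b.length
    hsps = run_blastn(
        [(a.id, a.sequence)], (b.id, b.doubled()), word_size=word_size
    )
    seen = set()
    result: list[LocalAlignment] = []
    for h in hsps:
        matches, cols = _alignment_identity(h.qseq, h.sseq)
        identity = matches / cols if cols else 0.0
        if cols < min_len or identity < thresholds.homology_min_identity:
            continue
        span = h.send - h.sstart
        if span > Lb:
            continue  # artifact of doubling: covers the subject more than once
        s0 = h.sstart % Lb
        key = (h.qstart, h.qend, s0, h.strand)
        if key in seen:
            continue
        seen.add(key)
        result.append(
            LocalAlignment(
                a_interval=(h.qstart, h.qend),
                b_interval=(s0, s0 + span),
                strand=h.strand,
                identity=identity,
                length=cols,
                a_aln=h.qseq,
                b_aln=h.sseq,
            )
        )
    result.sort(key=lambda x: (x.a_interval[0], -x.length))
    return result


def call_consensus_snps(
    alignments: list[LocalAlignment],
    b_length: int | None = None,
) -> list[ConsensusSNP]:
    """Mismatch columns of retained alignments, as substitution SNPs.

    Gap columns yield nothing. ``b`` alleles are reported on the forward
    strand of the b genome, with positions normalized modulo ``b_length``
    when given (wrap-aware). Duplicate (a_pos, b_pos) pairs arising from
    overlapping alignments are reported once.
    """
    out: dict[tuple[int, int], ConsensusSNP] = {}
    for aln in alignments:
        a_pos = aln.a_interval[0]
        if aln.strand == "+":
            b_pos = aln.b_interval[0]
            b_step = 1
        else:
            b_pos = aln.b_interval[1] - 1
            b_step = -1
        for qc, sc in zip(aln.a_aln, aln.b_aln):
            if qc != "-" and sc != "-":
                if qc != sc and qc in "ACGT" and sc in "ACGT":
                    bp = b_pos % b_length if b_length else b_pos
                    b_base = sc if aln.strand == "+" else sc.translate(_COMP)
                    key = (a_pos, bp)
                    if key not in out:
                        out[key] = ConsensusSNP(
                            a_pos=a_pos, b_pos=bp, a_base=qc, b_base=b_base
                        )
                a_pos += 1
                b_pos += b_step
            elif qc == "-":
                b_pos += b_step
            else:
                a_pos += 1
    return sorted(out.values(), key=lambda s: (s.a_pos, s.b_pos))


# ---------------------------------------------------------------------------
# coding-change annotation


def annotate_coding_change_at(
    gene_id: str, gene_sequence: str, nt_pos: int, alt_base: str
) -> CodingChange:
    """Coding-change annotation for a substitution at a 1-based position of
    an in-frame (ATG-first) coding sequence, with the alternative base given
    on the coding strand. Synonymous changes are labelled "No change"."""
    if not 1 <= nt_pos <= len(gene_sequence):
        raise ValueError(
            f"nt_pos {nt_pos} outside gene {gene_id!r} of length {len(gene_sequence)}"
        )
    ci = codon_index(nt_pos)
    codon_start = (ci - 1) * 3
    ref_codon = gene_sequence[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        raise ValueError(f"position {nt_pos} falls in a truncated terminal codon")
    offset = (nt_pos - 1) % 3
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    ref_aa = translate(ref_codon)
    alt_aa = translate(alt_codon)
    label = "No change" if ref_aa == alt_aa else f"{ref_aa}/{alt_aa}^{ci}"
    return CodingChange(
        gene_id=gene_id,
        nt_pos=nt_pos,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        codon_index=ci,
        label=label,
    )


def annotate_coding_change(
    snp: ConsensusSNP, gene: GeneAnnotation, gene_sequence: str
) -> CodingChange:
    """Annotate a consensus SNP that falls within a gene's coding span.

    ``gene_sequence`` is the coding-strand sequence starting at the ATG. The
    SNP position (on genome a, forward strand) is converted to a 1-based
    position relative to the start codon according to the gene's strand, and
    the alternative allele is complemented for minus-strand genes.
    """
    if snp.gene_context is not None:
        gene_id, nt_pos = snp.gene_context
    else:
        gene_id = gene.gene_id
        if gene.strand == "+":
            nt_pos = snp.a_pos - gene.start + 1
        else:
            nt_pos = gene.end - snp.a_pos
    alt = snp.b_base if gene.strand == "+" else snp.b_base.translate(_COMP)
    return annotate_coding_change_at(gene_id, gene_sequence, nt_pos, alt)


def frameshift_stop_position(
    gene_sequence: str, del_start: int, del_len: int
) -> int | None:
    """Apply a deletion (1-based ``del_start``, ``del_len`` bases) to a
    coding sequence, translate the shifted frame, and return the position of
    the first base of the first downstream stop codon in the ORIGINAL
    coordinate system (1-based), or None when no stop arises."""
    if not 1 <= del_start <= len(gene_sequence) - del_len + 1:
        raise ValueError("deletion outside gene")
    mutant = gene_sequence[: del_start - 1] + gene_sequence[del_start - 1 + del_len :]
    protein = translate(mutant[: len(mutant) - len(mutant) % 3])
    stop = protein.find("*")
    if stop == -1:
        return None
    mutant_pos = 3 * stop + 1  # 1-based first base of the stop codon
    return mutant_pos + del_len if mutant_pos >= del_start else mutant_pos


# ---------------------------------------------------------------------------
# contig joining


def _candidate_shifts(a: str, b: str, k: int = 21) -> list[int]:
    """Shifts s such that a[s:] may overlap b[:len(a)-s], proposed from
    shared exact k-mers."""
    window = min(len(b), len(a))
    index: dict[str, list[int]] = {}
    for j in range(0, window - k + 1):
        index.setdefault(b[j : j + k], []).append(j)
    shifts = set()
    for i in range(0, len(a) - k + 1):
        for j in index.get(a[i : i + k], ()):
            s = i - j
            if 0 < s < len(a):
                shifts.add(s)
    return sorted(shifts)  # ascending shift == descending overlap


def merge_contigs(
    a: str,
    b: str,
    thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS,
) -> MergeResult:
    """Join two contigs when a suffix of ``a`` overlaps a prefix of ``b`` by
    strictly more than ``join_min_overlap`` bp with dissimilarity strictly
    below ``join_max_dissim`` (mismatches and gap columns both count as
    differences). Refusal explains which rule failed."""
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    best: tuple[int, float] | None = None  # (overlap columns, dissimilarity)
    for s in _candidate_shifts(a, b):
        o = len(a) - s
        if o > len(b):
            continue
        a_ov = a[s:]
        b_ov = b[:o]
        res = edlib.align(a_ov, b_ov, task="path", mode="NW")
        columns = sum(
            int(n) for n, _ in re.findall(r"(\d+)([=XIDM])", res["cigar"])
        )
        dissim = res["editDistance"] / columns if columns else 1.0
        if columns > thresholds.join_min_overlap and dissim < thresholds.join_max_dissim:
            merged = a + b[o:]
            return MergeResult(merged, columns, dissim, "joined")
        if best is None or columns > best[0]:
            best = (columns, dissim)
    if best is None:
        return MergeResult(None, 0, 1.0, "no overlap detected")
    columns, dissim = best
    if columns <= thresholds.join_min_overlap:
        reason = (
            f"overlap of {columns} columns is not greater than "
            f"{thresholds.join_min_overlap} bp"
        )
    else:
        reason = (
            f"dissimilarity {dissim:.4f} is not below {thresholds.join_max_dissim}"
        )
    return MergeResult(None, columns, dissim, reason)


# ---------------------------------------------------------------------------
# false-positive rate over conserved space


def estimate_fp_rate(conserved_pairs: list[tuple[str, str]]) -> float:
    """SNP calls per compared bp across region pairs believed identical.

    Each pair is globally aligned; only mismatch columns count (indels are
    not SNPs). The denominator is the total length of the first region of
    each pair, matching how conserved gene space is tallied.
    """
    total_bp = sum(len(a) for a, _ in conserved_pairs)
    if total_bp == 0:
        raise ValueError("no bases to compare")
    mismatches = 0
    for a, b in conserved_pairs:
        res = edlib.align(a, b, task="path", mode="NW")
        ai = bi = 0
        for n_str, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
            n = int(n_str)
            if op in ("M", "=", "X"):
                mismatches += sum(
                    1 for x, y in zip(a[ai : ai + n], b[bi : bi + n]) if x != y
                )
                ai += n
                bi += n
            elif op == "I":  # insertion in query a
                ai += n
            else:  # deletion
                bi += n
    return mismatches / total_bp
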