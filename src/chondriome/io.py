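"""Readers and writers for the standard formats the pipeline exchanges.

FASTA goes through Biopython; SAM is written as plain text with a valid
``@SQ`` header (pysam reads it back downstream); GFF3, BED, VCF and TSV are
the simple tab-delimited dialects each format prescribes. All writers are
deterministic for identical inputs.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import CircularGenome, GeneAnnotation


# --- FASTA -----------------------------------------------------------------

def write_fasta(path, genomes: Iterable[CircularGenome]) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[CircularGenome]:
    return [
        CircularGenome(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


# --- GFF3 ------------------------------------------------------------------

_CATEGORY_SO = {
    "protein": "gene",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "pseudo": "pseudogene",
    "orf": "ORF",
}
_SO_CATEGORY = {v: k for k, v in _CATEGORY_SO.items()}


def write_gff3(path, seqid: str, annotations: Iterable[GeneAnnotation],
               source: str = "chondriome") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            attrs = f"ID={ann.gene_id};Name={ann.gene_id}"
            fh.write(
                "\t".join(
                    [
                        seqid,
                        source,
                        _CATEGORY_SO.get(ann.category, "gene"),
                        str(ann.start + 1),
                        str(ann.end),
                        ".",
                        ann.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[GeneAnnotation]:
    annotations = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Name") or f"{fields[0]}:{fields[3]}"
            annotations.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6] if fields[6] in "+-" else "+",
                    category=_SO_CATEGORY.get(fields[2], "protein"),
                )
            )
    return annotations


# --- FASTQ / SAM (simulated reads) ----------------------------------------

def write_fastq(path, readset) -> None:
    with open(path, "w") as fh:
        for read in readset.reads:
            fh.write(f"@{read.name}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


def cigar_string(cigar: list[tuple[str, int]]) -> str:
    return "".join(f"{ln}{op}" for op, ln in cigar)


def write_sam(path, readset) -> None:
    """Truth alignments against the master. Reads wrapping the origin or
    crossing a rearrangement breakpoint appear as multiple records sharing
    one QNAME (later records flagged supplementary)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{readset.master_id}\tLN:{readset.master_length}\n")
        fh.write("@PG\tID:chondriome\tPN:chondriome\n")
        for read in readset.reads:
            for k, seg in enumerate(read.segments):
                flag = 0
                if seg.strand == "-":
                    flag |= 16
                if k > 0:
                    flag |= 2048
                fh.write(
                    "\t".join(
                        [
                            read.name,
                            str(flag),
                            readset.master_id,
                            str(seg.ref_start + 1),
                            "60",
                            cigar_string(seg.cigar),
                            "*",
                            "0",
                            "0",
                            seg.seq,
                            "I" * len(seg.seq),
                            f"XO:i:{read.mitotype_index}",
                        ]
                    )
                    + "\n"
                )


# --- generic tabular -------------------------------------------------------

def write_tsv(path, header: list[str], rows: Iterable[Iterable]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def write_json(path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_bed(path, intervals: Iterable[tuple], chrom: str) -> None:
    """BED (0-based half-open). ``intervals`` yields (start, end[, name, score])."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join([chrom] + [str(x) for x in iv]) + "\n")


# --- VCF -------------------------------------------------------------------

def write_vcf(path, chrom: str, genome: CircularGenome, hsnps) -> None:
    """Heteroplasmic SNPs as VCF 4.2: REF = major allele, ALT = minor allele,
    INFO carries DP and AF (minor fraction). Positions are 1-based."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={genome.length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Minor allele fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for h in hsnps:
            fh.write(
                f"{chrom}\t{h.position + 1}\t.\t{h.major_allele}\t{h.minor_allele}"
                f"\t.\tPASS\tDP={h.depth};AF={h.minor_frac:.4f}\n"
            )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
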