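"""Pipeline orchestration: run a simulation scenario to disk, or analyze a
trio (or any set) of genomes end to end and emit a consolidated report.

Every threshold in force is echoed into the report for provenance, and all
randomness funnels through the config seed, so identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import yaml

from . import compare as gc
from . import heteroplasmy as hp
from . import orfs as orfmod
from . import synteny as syn
from .genome import CircularGenome, GeneAnnotation
from .io import (
    ensure_dir,
    read_fasta,
    read_gff3,
    write_fasta,
    write_fastq,
    write_gff3,
    write_json,
    write_sam,
    write_tsv,
    write_vcf,
)
from .pileup import build_pileup, coverage_mask
from .simulate import (
    ReadSimConfig,
    derive_mitotype,
    generate_master,
    simulate_reads,
    truth_hsnp_table,
)
from .thresholds import AnalysisThresholds


DEFAULT_SCENARIO = {
    "length": 50_000,
    "n_genes": 30,
    "gene_len_range": [300, 1500],
    "n_repeats": 2,
    "repeat_len": 1000,
    "mitotypes": [
        {"fraction": 0.8},
        {"fraction": 0.2, "n_subst": 200},
    ],
    "mean_depth": 100.0,
    "read_len_mean": 449.0,
    "read_len_sd": 100.0,
    "subst_error": 0.01,
}


@dataclass
class RunConfig:
    """Configuration for a simulate or analyze run.

    ``scenario`` holds simulator parameters; ``inputs`` is a list of
    ``{id, fasta, gff3, sam}`` mappings for analyze runs on existing files.
    Round-trips losslessly through YAML.
    """

    seed: int = 0
    outdir: str = "chondriome_out"
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)
    scenario: dict = field(default_factory=lambda: dict(DEFAULT_SCENARIO))
    inputs: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "thresholds": self.thresholds.to_dict(),
            "scenario": self.scenario,
            "inputs": self.inputs,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(
            seed=data.get("seed", 0),
            outdir=data.get("outdir", "chondriome_out"),
            thresholds=AnalysisThresholds.from_dict(data.get("thresholds", {})),
            scenario=data.get("scenario", dict(DEFAULT_SCENARIO)),
            inputs=list(data.get("inputs", [])),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _log(message: str) -> None:
    print(f"[chondriome] {message}", file=sys.stderr)


def _validate_scenario(sc: dict) -> None:
    if sc.get("length", 0) <= 0:
        raise ValueError("scenario.length must be positive")
    mitos = sc.get("mitotypes") or []
    if not mitos:
        raise ValueError("scenario.mitotypes must list at least one mitotype")
    total = sum(m.get("fraction", 0.0) for m in mitos)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(
            f"scenario.mitotypes fractions must sum to 1 (got {total})"
        )
    if sc.get("mean_depth", 1) <= 0:
        raise ValueError("scenario.mean_depth must be positive")


def run_simulate(config: RunConfig) -> dict:
    """Generate a scenario's chondriome dataset on disk.

    Writes master + mitotype FASTA, GFF3 annotations, FASTQ reads, the truth
    SAM and the truth tables (planted heteroplasmic positions, mitotype
    fractions, edit lists). Returns the path map.
    """
    t0 = time.monotonic()
    sc = {**DEFAULT_SCENARIO, **config.scenario}
    _validate_scenario(sc)
    out = ensure_dir(config.outdir)

    master, annotations = generate_master(
        sc["length"],
        sc["n_genes"],
        tuple(sc["gene_len_range"]),
        sc["n_repeats"],
        sc["repeat_len"],
        seed=config.seed,
    )
    mitotypes = []
    for i, m in enumerate(sc["mitotypes"]):
        mitotypes.append(
            derive_mitotype(
                master,
                annotations,
                n_subst=m.get("n_subst", 0),
                reversals=[tuple(r) for r in m.get("reversals", [])],
                deletions=[tuple(d) for d in m.get("deletions", [])],
                fraction=m["fraction"],
                seed=config.seed + 1 + i,
                mitotype_id=f"mt{i}",
            )
        )
    cfg = ReadSimConfig(
        mean_depth=sc["mean_depth"],
        read_len_mean=sc["read_len_mean"],
        read_len_sd=sc["read_len_sd"],
        subst_error=sc["subst_error"],
        seed=config.seed + 100,
    )
    readset = simulate_reads(mitotypes, cfg)

    paths = {
        "master_fasta": out / "master.fasta",
        "mitotypes_fasta": out / "mitotypes.fasta",
        "master_gff3": out / "master.gff3",
        "reads_fastq": out / "reads.fastq",
        "reads_sam": out / "reads.sam",
        "truth_hsnps": out / "truth_hsnps.tsv",
        "mitotype_fractions": out / "mitotype_fractions.tsv",
        "truth_edits": out / "truth_edits.tsv",
        "config": out / "config.yaml",
    }
    write_fasta(paths["master_fasta"], [master])
    write_fasta(paths["mitotypes_fasta"], [m.genome for m in mitotypes])
    write_gff3(paths["master_gff3"], master.id, annotations)
    write_fastq(paths["reads_fastq"], readset)
    write_sam(paths["reads_sam"], readset)
    truth = truth_hsnp_table(master, mitotypes)
    write_tsv(
        paths["truth_hsnps"],
        ["position", "ref", "major", "minor", "minor_frac"],
        (
            (r["position"], r["ref"], r["major"], r["minor"], f"{r['minor_frac']:.6f}")
            for r in truth
        ),
    )
    write_tsv(
        paths["mitotype_fractions"],
        ["mitotype", "fraction"],
        ((m.genome.id, m.fraction) for m in mitotypes),
    )
    write_tsv(
        paths["truth_edits"],
        ["mitotype", "kind", "start", "end", "ref", "alt"],
        (
            (m.genome.id, e.kind, e.start, e.end, e.ref, e.alt)
            for m in mitotypes
            for e in m.truth_edits
        ),
    )
    config.save(paths["config"])
    _log(f"simulate: wrote {len(readset.reads)} reads in {time.monotonic() - t0:.1f}s")
    return {k: str(v) for k, v in paths.items()}


@dataclass
class _GenomeInput:
    id: str
    genome: CircularGenome
    annotations: list[GeneAnnotation]
    sam: str | None


def _load_inputs(config: RunConfig) -> list[_GenomeInput]:
    if not config.inputs:
        raise ValueError("analyze requires at least one input genome")
    for spec_ in config.inputs:
        for key in ("fasta",):
            if key not in spec_:
                raise ValueError(f"input missing required field {key!r}")
        for key in ("fasta", "gff3", "sam"):
            path = spec_.get(key)
            if path and not Path(path).exists():
                raise FileNotFoundError(f"input file not found: {path}")
    loaded = []
    for spec_ in config.inputs:
        genomes = read_fasta(spec_["fasta"])
        genome = genomes[0]
        gid = spec_.get("id", genome.id)
        annotations = read_gff3(spec_["gff3"]) if spec_.get("gff3") else []
        loaded.append(
            _GenomeInput(
                id=gid, genome=genome, annotations=annotations,
                sam=spec_.get("sam"),
            )
        )
    return loaded


def run_analyze(config: RunConfig) -> dict:
    """Analyze the configured genomes end to end.

    Per genome: pileup, coverage mask and HSNP calling/blocks (when a SAM of
    reads is supplied); ORF scan. Pairwise: homologous regions + consensus
    SNP counts, synteny/rearrangement report. Across genomes: ORF
    uniqueness. Emits per-stage files plus a consolidated ``report.json``
    whose every number is traceable to one of those files.
    """
    t0 = time.monotonic()
    thresholds = config.thresholds
    inputs = _load_inputs(config)  # validates before any output
    out = ensure_dir(config.outdir)

    report: dict = {"thresholds": thresholds.to_dict(), "seed": config.seed,
                    "genomes": {}, "pairwise": {}}

    orfs_by_genome = {}
    for gi in inputs:
        gdir = ensure_dir(out / gi.id)
        entry: dict = {"length": gi.genome.length}
        if gi.sam:
            pile = build_pileup(gi.sam, gi.genome)
            mask = coverage_mask(pile, min_depth=thresholds.min_depth)
            hsnps = hp.call_hsnps(pile, thresholds, mask=None)
            blocks, singles = hp.cluster_hsnp_blocks(hsnps, thresholds)
            summary = hp.hsnp_summary(hsnps, blocks, singles, gi.genome.length)
            pile.to_tsv(gdir / "pileup.tsv")
            mask.to_bed(gdir / "mask.bed", gi.id)
            write_vcf(gdir / "hsnps.vcf", gi.id, gi.genome, hsnps)
            write_tsv(
                gdir / "hsnps.tsv",
                ["position", "major", "minor", "minor_count", "depth", "minor_frac"],
                (
                    (h.position, h.major_allele, h.minor_allele,
                     h.minor_count, h.depth, f"{h.minor_frac:.4f}")
                    for h in hsnps
                ),
            )
            from .io import write_bed

            write_bed(
                gdir / "hsnp_blocks.bed",
                ((b.start, b.end, f"n={b.n}") for b in blocks),
                gi.id,
            )
            entry["hsnp_summary"] = summary
            entry["excluded_bp"] = mask.excluded_bp
            entry["excluded_fraction"] = mask.excluded_fraction
            entry["rejected_reads"] = pile.n_rejected
        orfs = orfmod.scan_orfs(gi.genome, thresholds)
        orfs_by_genome[gi.id] = orfs
        total_bp, pct = orfmod.orf_genome_fraction(orfs, gi.genome.length)
        entry["orfs"] = {"count": len(orfs), "total_bp": total_bp, "percent": pct}
        write_gff3(
            gdir / "orfs.gff3",
            gi.id,
            [
                GeneAnnotation(
                    gene_id=f"orf{o.orf_id}",
                    start=o.start,
                    end=o.end,
                    strand=o.strand,
                    category="orf",
                )
                for o in orfs
            ],
        )
        with open(gdir / "orf_proteins.fasta", "w") as fh:
            for o in orfs:
                fh.write(f">orf{o.orf_id}\n{o.protein}\n")
        report["genomes"][gi.id] = entry
        _log(f"analyze[{gi.id}]: done at {time.monotonic() - t0:.1f}s")

    for gi, gj in combinations(inputs, 2):
        key = f"{gi.id}~{gj.id}"
        pdir = ensure_dir(out / key.replace("~", "_vs_"))
        alignments = gc.find_homologous_regions(gi.genome, gj.genome, thresholds)
        snps = gc.call_consensus_snps(alignments, b_length=gj.genome.length)
        write_tsv(
            pdir / "alignments.tsv",
            ["qstart", "qend", "sstart", "send", "strand", "identity", "length"],
            (
                (a.a_interval[0], a.a_interval[1], a.b_interval[0],
                 a.b_interval[1], a.strand, f"{a.identity:.4f}", a.length)
                for a in alignments
            ),
        )
        write_tsv(
            pdir / "snps.tsv",
            ["a_pos", "b_pos", "a_base", "b_base"],
            ((s.a_pos, s.b_pos, s.a_base, s.b_base) for s in snps),
        )
        pair_entry: dict = {
            "n_alignments": len(alignments),
            "n_snps": len(snps),
        }
        if gi.annotations and gj.annotations:
            oa = syn.gene_order_from_annotations(
                gi.annotations, genome_id=gi.id
            )
            ob = syn.gene_order_from_annotations(
                gj.annotations, genome_id=gj.id
            )
            if len(oa.names & ob.names) >= 2:
                rep = syn.compare_gene_orders(oa, ob)
                write_tsv(
                    pdir / "synteny_blocks.tsv",
                    ["genes", "orientation"],
                    (
                        (
                            ",".join(f"{'-' if s < 0 else ''}{n}" for n, s in blk.genes),
                            blk.orientation,
                        )
                        for blk in rep.blocks
                    ),
                )
                write_tsv(
                    pdir / "conserved_pairs.tsv",
                    ["gene_a", "gene_b"],
                    ((x[0], y[0]) for x, y in rep.conserved_pairs),
                )
                pair_entry["synteny"] = {
                    "common_genes": rep.common_genes,
                    "n_conserved_pairs": len(rep.conserved_pairs),
                    "n_blocks": len(rep.blocks),
                    "breakpoints": rep.breakpoints,
                    "events_estimate": rep.events_estimate,
                }
                syn.write_synteny_svg(pdir / "synteny.svg", [oa, ob])
        report["pairwise"][key] = pair_entry
        _log(f"analyze[{key}]: done at {time.monotonic() - t0:.1f}s")

    if len(inputs) >= 2:
        uniq_rows = []
        for gi in inputs:
            others = [gj.genome for gj in inputs if gj.id != gi.id]
            comps = orfmod.classify_unique(
                orfs_by_genome[gi.id], others, thresholds
            )
            n_unique = sum(1 for c in comps if c.unique)
            report["genomes"][gi.id]["unique_orfs"] = n_unique
            uniq_rows.extend(
                (gi.id, c.orf_id, f"{c.best_coverage:.4f}", int(c.unique))
                for c in comps
            )
        write_tsv(
            out / "orf_uniqueness.tsv",
            ["genome", "orf_id", "best_coverage", "unique"],
            uniq_rows,
        )

    write_json(out / "report.json", report)
    _log(f"analyze: report written in {time.monotonic() - t0:.1f}s")
    return report
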