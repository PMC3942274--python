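"""Every numeric rule of the analysis, in one configurable place.

The defaults encode the published filtering rules this pipeline implements:
a heteroplasmic SNP needs more than 10% minor-allele reads at >= 10x depth;
homologous regions between consensus genomes are kept at >= 95% identity;
ORFs must be >= 300 bp; an ORF is species-unique when homologous coverage by
every other genome is <= 95% of its length; contigs are joined only on an
overlap > 100 bp with < 1% dissimilarity.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class AnalysisThresholds:
    #: minimum read depth for a position to be analyzable ("at least 10X").
    min_depth: int = 10
    #: minor-allele read fraction that must be *exceeded* ("more than 10%").
    min_minor_frac: float = 0.10
    #: minimum number of chained HSNPs to form a block.
    block_min_count: int = 3
    #: maximum gap (bp) between consecutive HSNPs within a block.
    block_max_gap: int = 150
    #: identity cutoff for retained homologous regions (inclusive).
    homology_min_identity: float = 0.95
    #: minimum ORF length in bp, stop codon included.
    orf_min_len: int = 300
    #: maximum homologous coverage for an ORF to still count as unique.
    orf_unique_max_cov: float = 0.95
    #: contig joining requires an overlap strictly greater than this (bp).
    join_min_overlap: int = 100
    #: ... and a dissimilarity strictly below this over the overlap columns.
    join_max_dissim: float = 0.01

    def __post_init__(self) -> None:
        for name in ("min_minor_frac", "homology_min_identity",
                     "orf_unique_max_cov", "join_max_dissim"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {value}")
        for name in ("min_depth", "block_min_count", "block_max_gap",
                     "orf_min_len", "join_min_overlap"):
            value = getattr(self, name)
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisThresholds":
        return cls(**data)


DEFAULT_THRESHOLDS = AnalysisThresholds()
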