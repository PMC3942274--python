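"""End-to-end simulation experiments with known truth.

These drive the whole pipeline -- simulate a chondriome, write and re-read
the truth SAM, build the pileup, apply the coverage mask, call HSNPs -- and
score the calls against the simulator's truth tables. They are what the
package uses to demonstrate that the >10%/10x heteroplasmy rule recovers
planted mixtures and that its false-positive behaviour matches the analytic
binomial expectation.

Default problem sizes are desk-scale: a 50 kb circular genome standing in
for a ~430 kb mitochondrial master molecule, with the read length (449 bp
mean) and coverage matching the sequencing conditions being emulated.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .heteroplasmy import call_hsnps, expected_false_calls
from .io import write_sam
from .pileup import build_pileup, coverage_mask
from .simulate import (
    ReadSimConfig,
    derive_mitotype,
    generate_master,
    simulate_reads,
    truth_hsnp_table,
)
from .thresholds import DEFAULT_THRESHOLDS, AnalysisThresholds


@dataclass
class RecoveryMetrics:
    recall: float
    precision: float
    mae_realized: float  # |called minor frac - realized read-origin frac|
    mae_nominal: float   # |called minor frac - nominal mixture fraction|
    n_true: int
    n_called: int
    n_true_positive: int


@dataclass
class FalsePositiveControl:
    observed: int
    expected: float
    sd: float

    @property
    def z(self) -> float:
        return (self.observed - self.expected) / self.sd if self.sd else 0.0


def _pileup_via_sam(readset, master):
    """Round-trip the truth alignments through an actual SAM file so the
    experiment exercises the same path real data would take."""
    with tempfile.TemporaryDirectory(prefix="chondriome_exp_") as tmp:
        sam = Path(tmp) / "reads.sam"
        write_sam(sam, readset)
        return build_pileup(sam, master)


def hsnp_recovery(
    seed: int,
    length: int = 50_000,
    n_genes: int = 30,
    minor_fraction: float = 0.2,
    n_subst: int = 200,
    mean_depth: float = 100.0,
    subst_error: float = 0.01,
    thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS,
) -> RecoveryMetrics:
    """Recovery of planted heteroplasmy from a two-mitotype mixture.

    The major mitotype equals the master; the minor one carries ``n_subst``
    distinguishing substitutions. Calls are scored against the planted
    positions; the minor-fraction error is measured against the realized
    per-column fraction of reads drawn from the minor mitotype (the nominal
    mixture fraction is also reported, but at finite depth read sampling
    alone moves per-column fractions off the nominal value).
    """
    master, anns = generate_master(length, n_genes, (300, 1500), 2, 1000, seed=seed)
    major = derive_mitotype(
        master, anns, fraction=1.0 - minor_fraction, seed=seed + 1,
        mitotype_id="mt-major",
    )
    minor = derive_mitotype(
        master, anns, n_subst=n_subst, fraction=minor_fraction, seed=seed + 2,
        mitotype_id="mt-minor",
    )
    cfg = ReadSimConfig(
        mean_depth=mean_depth, subst_error=subst_error, seed=seed + 3
    )
    readset = simulate_reads([major, minor], cfg)
    pile = _pileup_via_sam(readset, master)
    mask = coverage_mask(pile, min_depth=thresholds.min_depth)
    calls = call_hsnps(pile, thresholds)

    truth = truth_hsnp_table(master, [major, minor])
    true_pos = {row["position"] for row in truth}
    called_pos = {h.position for h in calls}
    tp = called_pos & true_pos

    origin_depth = readset.origin_depth()
    minor_depth = origin_depth[1]
    total_depth = origin_depth.sum(axis=0)

    by_pos = {h.position: h for h in calls}
    abs_err_realized = []
    abs_err_nominal = []
    for p in sorted(tp):
        called_frac = by_pos[p].minor_frac
        realized = minor_depth[p] / total_depth[p] if total_depth[p] else 0.0
        abs_err_realized.append(abs(called_frac - realized))
        abs_err_nominal.append(abs(called_frac - minor_fraction))

    n_true_eval = sum(1 for row in truth if not mask.contains(row["position"]))
    return RecoveryMetrics(
        recall=len(tp) / n_true_eval if n_true_eval else 0.0,
        precision=len(tp) / len(called_pos) if called_pos else 0.0,
        mae_realized=float(np.mean(abs_err_realized)) if abs_err_realized else 0.0,
        mae_nominal=float(np.mean(abs_err_nominal)) if abs_err_nominal else 0.0,
        n_true=len(truth),
        n_called=len(called_pos),
        n_true_positive=len(tp),
    )


def false_positive_control(
    seed: int,
    length: int = 50_000,
    mean_depth: float = 20.0,
    subst_error: float = 0.05,
    thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS,
) -> FalsePositiveControl:
    """Homoplasmic control: every called HSNP is a sequencing-error artifact.

    The observed call count is compared with the exact binomial expectation
    (and its standard deviation) over the realized per-column depths. The
    default stress condition -- 20x with a 5% error rate -- is chosen so the
    expectation is large enough for the comparison to have statistical
    power; at realistic error rates the strict >10% rule yields essentially
    zero false calls at any depth above the 10x floor.
    """
    master, _ = generate_master(length, 0, (300, 1500), 0, 0, seed=seed)
    sole = derive_mitotype(master, [], fraction=1.0, seed=seed + 1,
                           mitotype_id="mt-sole")
    cfg = ReadSimConfig(
        mean_depth=mean_depth, subst_error=subst_error, seed=seed + 2
    )
    readset = simulate_reads([sole], cfg)
    pile = _pileup_via_sam(readset, master)
    calls = call_hsnps(pile, thresholds)
    expected, sd = expected_false_calls(
        pile.depth,
        error_rate=subst_error,
        min_minor_frac=thresholds.min_minor_frac,
        min_depth=thresholds.min_depth,
    )
    return FalsePositiveControl(observed=len(calls), expected=expected, sd=sd)
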