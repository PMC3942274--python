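"""Heteroplasmic SNP (HSNP) calling and block clustering.

A position is heteroplasmic when, among reads spanning it, the single most
frequent non-major base exceeds 10% of the depth and the depth is at least
10x. The rule is per-allele: two rare alleles that jointly exceed 10% do not
trigger a call. Insertions and deletions never trigger a call. Dense runs of
HSNPs are chained into HSNP blocks; isolated calls remain singletons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .pileup import Pileup, PileupColumn, CoverageMask
from .thresholds import DEFAULT_THRESHOLDS, AnalysisThresholds

_BASES = "ACGT"


@dataclass(frozen=True)
class HSNP:
    position: int
    major_allele: str
    minor_allele: str
    minor_count: int
    depth: int
    minor_frac: float


@dataclass
class HSNPBlock:
    start: int  # position of the first member
    end: int    # position after the last member (half-open)
    members: list[HSNP]

    @property
    def n(self) -> int:
        return len(self.members)


def _arrays_from_columns(columns) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    positions = np.array([c.position for c in columns], dtype=np.int64)
    counts = np.array(
        [[c.counts.get(b, 0) for c in columns] for b in _BASES], dtype=np.int64
    )
    depth = np.array([c.depth for c in columns], dtype=np.int64)
    return positions, counts, depth


def call_hsnps(
    pileup,
    thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS,
    mask: CoverageMask | None = None,
) -> list[HSNP]:
    """Call heteroplasmic SNPs from a pileup.

    ``pileup`` may be a :class:`~chondriome.pileup.Pileup` (vectorized path)
    or any iterable of :class:`~chondriome.pileup.PileupColumn`. The major
    allele is the most frequent base with ties broken A<C<G<T; the minor
    allele is the most frequent remaining base. A call requires
    ``depth >= min_depth`` and ``minor_count / depth > min_minor_frac``
    (strict). Positions inside ``mask`` are skipped entirely.
    """
    if isinstance(pileup, Pileup):
        positions = np.arange(pileup.length, dtype=np.int64)
        counts = pileup.counts.astype(np.int64)
        depth = pileup.depth.astype(np.int64)
    else:
        columns = list(pileup)
        if not columns:
            return []
        positions, counts, depth = _arrays_from_columns(columns)

    major = counts.argmax(axis=0)  # first max wins: ties break A<C<G<T
    masked = counts.copy()
    masked[major, np.arange(counts.shape[1])] = -1
    minor = masked.argmax(axis=0)
    minor_count = masked[minor, np.arange(counts.shape[1])]

    callable_ = (depth >= thresholds.min_depth) & (minor_count > 0)
    callable_ &= minor_count > thresholds.min_minor_frac * depth

    if mask is not None:
        excluded = np.zeros(len(positions), dtype=bool)
        pos_index = {int(p): i for i, p in enumerate(positions)}
        for s, e in mask.excluded_intervals:
            for p in range(s, e):
                i = pos_index.get(p)
                if i is not None:
                    excluded[i] = True
        callable_ &= ~excluded

    result = []
    for i in np.nonzero(callable_)[0]:
        d = int(depth[i])
        mc = int(minor_count[i])
        result.append(
            HSNP(
                position=int(positions[i]),
                major_allele=_BASES[int(major[i])],
                minor_allele=_BASES[int(minor[i])],
                minor_count=mc,
                depth=d,
                minor_frac=mc / d,
            )
        )
    result.sort(key=lambda h: h.position)
    return result


def cluster_hsnp_blocks(
    hsnps: list[HSNP],
    thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[HSNPBlock], list[HSNP]]:
    """Greedy left-to-right chaining of position-sorted HSNPs.

    Consecutive HSNPs at most ``block_max_gap`` bp apart join a chain; chains
    of at least ``block_min_count`` members become blocks, all other members
    fall out as singletons. Every input HSNP lands in exactly one output.
    """
    positions = [h.position for h in hsnps]
    if positions != sorted(positions):
        raise ValueError("hsnps must be sorted by position")

    blocks: list[HSNPBlock] = []
    singletons: list[HSNP] = []
    chain: list[HSNP] = []

    def flush() -> None:
        if len(chain) >= thresholds.block_min_count:
            blocks.append(
                HSNPBlock(
                    start=chain[0].position,
                    end=chain[-1].position + 1,
                    members=list(chain),
                )
            )
        else:
            singletons.extend(chain)

    for h in hsnps:
        if chain and h.position - chain[-1].position <= thresholds.block_max_gap:
            chain.append(h)
        else:
            flush()
            chain = [h]
    if chain:
        flush()
    return blocks, singletons


def hsnp_summary(
    hsnps: list[HSNP],
    blocks: list[HSNPBlock],
    singletons: list[HSNP],
    genome_length: int,
) -> dict:
    """Headline counts: total calls, block membership, and the genome-wide
    density expressed as bp per HSNP (absent when there are no calls)."""
    n_in_blocks = sum(b.n for b in blocks)
    n_total = len(hsnps)
    if n_total != n_in_blocks + len(singletons):
        raise ValueError("blocks and singletons do not partition the HSNPs")
    return {
        "n_total": n_total,
        "n_in_blocks": n_in_blocks,
        "n_singletons": len(singletons),
        "n_blocks": len(blocks),
        "bp_per_hsnp": round(genome_length / n_total) if n_total else None,
    }


# ---------------------------------------------------------------------------
# analytic false-positive expectation


def _call_threshold(depth: int, min_minor_frac: float) -> int:
    """Smallest minor count that satisfies ``count > min_minor_frac * depth``
    under the same floating-point comparison the caller uses."""
    t = int(math.floor(min_minor_frac * depth)) + 1
    while t - 1 > min_minor_frac * depth:
        t -= 1
    return t


def expected_false_calls(
    depths: np.ndarray,
    error_rate: float,
    min_minor_frac: float = 0.10,
    min_depth: int = 10,
) -> tuple[float, float]:
    """Expected number (and standard deviation) of spurious HSNP calls on a
    homoplasmic genome sequenced with per-base substitution errors.

    Errors hit each read base independently at ``error_rate`` and pick one of
    the three alternative bases uniformly, so at a column of depth ``d`` the
    three alternative-base counts are multinomial with probability
    ``error_rate / 3`` each. A false call occurs when the largest of the
    three reaches the strict >10% threshold. The probability is computed by
    inclusion-exclusion over the three alternatives, exactly to third order,
    and summed over the observed column depths (columns are independent
    because per-base errors are).
    """
    q = error_rate / 3.0
    depths = np.asarray(depths)
    depths = depths[depths >= min_depth]
    uniq, cnt = np.unique(depths, return_counts=True)

    expected = 0.0
    variance = 0.0
    for d, n_cols in zip(uniq.astype(int), cnt):
        t = _call_threshold(d, min_minor_frac)
        p1 = float(binom.sf(t - 1, d, q))
        # P(X1>=t, X2>=t): condition on X1
        p12 = 0.0
        q2 = q / (1.0 - q)
        for x1 in range(t, d + 1):
            px1 = float(binom.pmf(x1, d, q))
            if px1 < 1e-18:
                break
            p12 += px1 * float(binom.sf(t - 1, d - x1, q2))
        # P(all three >= t)
        p123 = 0.0
        q3 = q / (1.0 - 2.0 * q)
        for x1 in range(t, d + 1):
            px1 = float(binom.pmf(x1, d, q))
            if px1 < 1e-18:
                break
            inner = 0.0
            for x2 in range(t, d - x1 + 1):
                px2 = float(binom.pmf(x2, d - x1, q2))
                if px2 < 1e-18:
                    break
                inner += px2 * float(binom.sf(t - 1, d - x1 - x2, q3))
            p123 += px1 * inner
        p_call = 3.0 * p1 - 3.0 * p12 + p123
        p_call = min(max(p_call, 0.0), 1.0)
        expected += n_cols * p_call
        variance += n_cols * p_call * (1.0 - p_call)
    return expected, math.sqrt(variance)
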