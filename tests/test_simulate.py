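"""Tests for the synthetic chondriome simulator: master generation, mitotype
derivation with truth edits, and truth-tracked read simulation."""

from __future__ import annotations

import numpy as np
import pytest

from chondriome.genome import revcomp, translate
from chondriome.simulate import (
    CapacityError,
    Edit,
    ReadSimConfig,
    derive_mitotype,
    generate_frameshift_gene,
    generate_master,
    replay_edits,
    simulate_reads,
    truth_hsnp_table,
)
from chondriome.synteny import gene_order_from_annotations


class TestGenerateMaster:
    def test_deterministic_under_fixed_seed(self):
        g1, a1 = generate_master(50_000, 30, (300, 1500), 2, 1000, seed=7)
        g2, a2 = generate_master(50_000, 30, (300, 1500), 2, 1000, seed=7)
        assert g1.sequence == g2.sequence
        assert a1 == a2
        assert g1.length == 50_000
        assert len(a1) == 30

    def test_no_genes_gives_pure_random_sequence(self):
        genome, anns = generate_master(5_000, 0, (300, 1500), 0, 0, seed=3)
        assert anns == []
        assert genome.length == 5_000

    def test_infeasible_packing_raises_capacity_error(self):
        with pytest.raises(CapacityError):
            generate_master(2_000, 10, (300, 1500), 0, 0, seed=0)

    def test_every_gene_translates_start_to_stop(self):
        """Codon-table oracle: each annotated gene begins M, has no internal
        stop, and ends at a stop codon on its own strand."""
        genome, anns = generate_master(30_000, 20, (300, 900), 1, 500, seed=11)
        assert any(a.strand == "-" for a in anns)
        for ann in anns:
            protein = translate(ann.coding_sequence(genome))
            assert protein[0] == "M"
            assert protein[-1] == "*"
            assert "*" not in protein[:-1]

    def test_repeat_elements_planted_at_two_loci(self):
        genome, _ = generate_master(20_000, 0, (300, 900), 1, 500, seed=5)
        starts = {}
        for i in range(genome.length - 500 + 1):
            starts.setdefault(genome.sequence[i : i + 500], []).append(i)
        assert max(len(v) for v in starts.values()) >= 2

    def test_annotations_non_overlapping_and_sorted(self):
        _, anns = generate_master(30_000, 25, (300, 600), 0, 0, seed=2)
        for x, y in zip(anns, anns[1:]):
            assert x.end <= y.start


class TestDeriveMitotype:
    def test_no_edits_is_identity(self):
        master, anns = generate_master(10_000, 5, (300, 600), 0, 0, seed=1)
        mt = derive_mitotype(master, anns, seed=9)
        assert mt.genome.sequence == master.sequence
        assert [e for e in mt.truth_edits] == []

    def test_substitution_count_equals_hamming_distance(self):
        master, _ = generate_master(10_000, 0, (300, 600), 0, 0, seed=1)
        mt = derive_mitotype(master, [], n_subst=200, seed=4)
        hamming = sum(
            1 for x, y in zip(master.sequence, mt.genome.sequence) if x != y
        )
        assert hamming == 200

    def test_substitutions_never_recreate_reference(self):
        master, _ = generate_master(5_000, 0, (300, 600), 0, 0, seed=1)
        mt = derive_mitotype(master, [], n_subst=100, seed=8)
        for e in mt.truth_edits:
            assert e.kind == "substitution"
            assert e.ref == master.sequence[e.start]
            assert e.alt != e.ref

    def test_overlapping_edits_rejected(self):
        master, _ = generate_master(5_000, 0, (300, 600), 0, 0, seed=1)
        with pytest.raises(ValueError, match="overlap"):
            derive_mitotype(
                master, [], reversals=[(100, 500)], deletions=[(400, 600)], seed=0
            )

    @pytest.mark.parametrize(
        "n_subst,reversals,deletions",
        [
            (50, [], []),
            (0, [(2000, 4000)], []),
            (0, [], [(1000, 1500)]),
            (30, [(2000, 4000)], [(6000, 6500)]),
            (10, [(100, 900), (5000, 7000)], [(3000, 3100), (9000, 9500)]),
        ],
    )
    def test_replaying_truth_edits_reproduces_sequence(
        self, n_subst, reversals, deletions
    ):
        master, anns = generate_master(10_000, 6, (300, 600), 0, 0, seed=6)
        mt = derive_mitotype(
            master, anns, n_subst=n_subst, reversals=reversals,
            deletions=deletions, seed=13,
        )
        assert replay_edits(master, mt.truth_edits) == mt.genome.sequence

    def test_reversal_lifts_gene_order(self):
        """A reversal spanning whole genes must reverse that run of genes and
        flip their strands in the lifted order (brute-force lifting oracle)."""
        master, anns = generate_master(20_000, 10, (300, 600), 0, 0, seed=21)
        # pick a window fully containing genes 3..5
        inner = anns[3:6]
        s = inner[0].start - 10
        e = inner[-1].end + 10
        # ensure the window does not clip neighbours
        assert anns[2].end <= s and anns[6].start >= e
        mt = derive_mitotype(master, anns, reversals=[(s, e)], seed=0)

        expected = list(anns)
        flipped = [
            type(a)(
                gene_id=a.gene_id,
                start=s + (e - a.end),
                end=s + (e - a.start),
                strand="-" if a.strand == "+" else "+",
                category=a.category,
            )
            for a in inner
        ]
        expected[3:6] = sorted(flipped, key=lambda a: a.start)
        lifted = gene_order_from_annotations(mt.annotations, genome_id="mt")
        oracle = gene_order_from_annotations(expected, genome_id="oracle")
        assert lifted.order == oracle.order

    def test_gene_inside_deletion_dropped(self):
        master, anns = generate_master(20_000, 10, (300, 600), 0, 0, seed=21)
        victim = anns[4]
        mt = derive_mitotype(
            master, anns, deletions=[(victim.start, victim.end)], seed=0
        )
        assert victim.gene_id not in {a.gene_id for a in mt.annotations}
        # surviving genes still translate cleanly from the edited genome
        for a in mt.annotations:
            protein = translate(a.coding_sequence(mt.genome))
            assert protein[0] == "M" and "*" not in protein[:-1]


class TestSimulateReads:
    def _mixture(self, length=5_000, n_subst=5, seed=30):
        master, _ = generate_master(length, 0, (300, 600), 0, 0, seed=seed)
        major = derive_mitotype(master, [], fraction=0.8, seed=seed + 1)
        minor = derive_mitotype(
            master, [], n_subst=n_subst, fraction=0.2, seed=seed + 2
        )
        return master, major, minor

    def test_error_free_reads_are_substrings_of_doubled_master(self):
        master, major, _ = self._mixture()
        sole = derive_mitotype(master, [], fraction=1.0, seed=99)
        rs = simulate_reads([sole], ReadSimConfig(mean_depth=20, seed=5))
        doubled = master.doubled()
        assert all(r.sequence in doubled for r in rs.reads)

    def test_mean_read_length_within_2pct_of_target(self):
        master, major, minor = self._mixture(length=10_000)
        rs = simulate_reads(
            [major, minor], ReadSimConfig(mean_depth=50, seed=6)
        )
        assert len(rs.reads) >= 1_000
        assert abs(rs.mean_read_length() - 449) / 449 < 0.02

    def test_total_bases_within_5pct_of_target_depth(self):
        master, major, minor = self._mixture(length=10_000)
        rs = simulate_reads(
            [major, minor], ReadSimConfig(mean_depth=60, seed=7)
        )
        assert abs(rs.total_bases() - 60 * 10_000) / (60 * 10_000) < 0.05

    def test_fractions_must_sum_to_one(self):
        master, major, minor = self._mixture()
        bad = derive_mitotype(master, [], fraction=0.1, seed=1)
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_reads([major, bad], ReadSimConfig(mean_depth=10, seed=0))

    def test_mitotype_sampling_multinomially_consistent(self):
        master, major, minor = self._mixture(length=10_000)
        rs = simulate_reads(
            [major, minor], ReadSimConfig(mean_depth=60, seed=8)
        )
        n = len(rs.reads)
        share = sum(1 for r in rs.reads if r.mitotype_index == 1) / n
        se = (0.2 * 0.8 / n) ** 0.5
        assert abs(share - 0.2) <= 3 * se

    def test_pooled_minor_fraction_matches_binomial_expectation(self):
        """At a distinguishing position, the pooled read fraction carrying
        the minor allele is within 3 binomial SE of the mixture fraction."""
        master, major, minor = self._mixture(length=5_000, n_subst=5)
        rs = simulate_reads(
            [major, minor], ReadSimConfig(mean_depth=100, seed=9)
        )
        depth = rs.origin_depth()
        total = depth.sum(axis=0)
        for row in truth_hsnp_table(master, [major, minor]):
            p = row["position"]
            d = total[p]
            frac = depth[1, p] / d
            se = (0.2 * 0.8 / d) ** 0.5
            assert abs(frac - 0.2) <= 3 * se

    def test_errors_marked_and_never_recreate_source_base(self):
        """Removing the simulated errors from a read recovers an exact
        substring of its source mitotype."""
        master, major, minor = self._mixture(length=5_000)
        rs = simulate_reads(
            [major, minor],
            ReadSimConfig(mean_depth=30, subst_error=0.02, seed=10),
        )
        mitos = [major, minor]
        some_errors = 0
        for r in rs.reads[:300]:
            src = mitos[r.mitotype_index].genome.doubled()
            window = src[r.source_start : r.source_start + len(r.sequence)]
            err = set(r.error_offsets)
            some_errors += len(err)
            for i, (got, true) in enumerate(zip(r.sequence, window)):
                assert (got != true) == (i in err)
        assert some_errors > 0

    def test_wrapping_read_split_into_two_segments(self):
        master, _ = generate_master(2_000, 0, (300, 600), 0, 0, seed=40)
        sole = derive_mitotype(master, [], fraction=1.0, seed=0)
        rs = simulate_reads([sole], ReadSimConfig(mean_depth=30, seed=3))
        wrapping = [
            r for r in rs.reads if r.source_start + len(r.sequence) > 2_000
        ]
        assert wrapping
        for r in wrapping:
            assert len(r.segments) == 2
            assert r.segments[1].ref_start == 0

    def test_indel_errors_rejected_for_structural_mitotypes(self):
        master, _ = generate_master(5_000, 0, (300, 600), 0, 0, seed=41)
        mt = derive_mitotype(master, [], reversals=[(1000, 2000)], seed=0)
        with pytest.raises(ValueError, match="indel"):
            simulate_reads(
                [mt], ReadSimConfig(mean_depth=5, indel_error=0.01, seed=0)
            )


class TestFrameshiftGene:
    def test_constructed_gene_satisfies_all_constraints(self):
        gene = generate_frameshift_gene(seed=0)
        assert gene[133:137] == "TGTG"  # pinned deleted bases (1-based 134-137)
        protein = translate(gene)
        assert protein[0] == "M" and "*" not in protein[:-1]
        mutant = gene[:133] + gene[137:]
        mutant_protein = translate(mutant[: len(mutant) - len(mutant) % 3])
        first_stop_codon = mutant_protein.index("*")  # 0-based codon
        # first base of that stop codon, mapped back to original coordinates
        assert 3 * first_stop_codon + 1 + 4 == 158
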