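"""Generator correctness: every downstream test leans on these truths."""

import math

import numpy as np
import pytest

from genotax.errors import FormatError
from genotax.genome import Genome
from genotax.simulate import (CladeSim, generate_ancestor, insert_unique,
                              mutate, plant_repeat, simulate_clade,
                              simulate_reads)

from conftest import as_genome, hamming


class TestGenerateAncestor:
    def test_gc_within_binomial_ci(self):
        rep = generate_ancestor(100_000, 0.632, seed=1)
        assert 0.62 <= rep.gc <= 0.645

    def test_zero_gc_forces_at_only(self):
        rep = generate_ancestor(10, 0.0, seed=7)
        assert set(rep.seq) <= {"A", "T"}

    @pytest.mark.parametrize("length,gc", [(0, 0.5), (-5, 0.5), (100, 1.5),
                                           (100, -0.1)])
    def test_invalid_arguments_rejected(self, length, gc):
        with pytest.raises(ValueError):
            generate_ancestor(length, gc, seed=1)

    def test_deterministic_for_seed(self):
        a = generate_ancestor(5_000, 0.6, seed=42)
        b = generate_ancestor(5_000, 0.6, seed=42)
        assert a.seq == b.seq


class TestMutate:
    def test_zero_rate_is_identity(self, ancestor_20k):
        assert mutate(ancestor_20k, 0.0, seed=5).seq == ancestor_20k.seq

    def test_hamming_matches_rate(self):
        rep = generate_ancestor(200_000, 0.6, seed=11)
        out = mutate(rep, 0.05, seed=3)
        assert len(out) == len(rep)
        d = hamming(rep.seq, out.seq) / len(rep)
        assert abs(d - 0.05) <= 0.005

    def test_rate_bound_enforced(self, ancestor_20k):
        with pytest.raises(ValueError):
            mutate(ancestor_20k, 0.9, seed=1)

    def test_two_round_composition_matches_closed_form(self, ancestor_50k):
        # P(final == original) = (1-p1)(1-p2) + p1*p2/3 under the uniform
        # substitution kernel
        p1, p2 = 0.03, 0.05
        out = mutate(mutate(ancestor_50k, p1, seed=8), p2, seed=9)
        expected_diff = 1 - ((1 - p1) * (1 - p2) + p1 * p2 / 3)
        observed = hamming(ancestor_50k.seq, out.seq) / len(ancestor_50k)
        sd = math.sqrt(expected_diff * (1 - expected_diff)
                       / len(ancestor_50k))
        assert abs(observed - expected_diff) <= 5 * sd


class TestInsertUnique:
    def test_zero_fraction_is_identity(self, ancestor_20k):
        assert insert_unique(ancestor_20k, 0.0, seed=1).seq \
            == ancestor_20k.seq

    def test_length_bookkeeping(self):
        rep = generate_ancestor(100_000, 0.6, seed=4)
        out = insert_unique(rep, 0.3, seed=5)
        assert abs(len(out) - 130_000) <= 2  # block rounding only

    def test_fraction_one_rejected(self, ancestor_20k):
        with pytest.raises(ValueError):
            insert_unique(ancestor_20k, 1.0, seed=1)

    def test_original_bases_preserved_in_order(self, ancestor_20k):
        import edlib
        out = insert_unique(ancestor_20k, 0.2, seed=6)
        # original must embed as an exact subsequence: the whole edit
        # distance is accounted for by the inserted bases
        ed = edlib.align(ancestor_20k.seq, out.seq, mode="NW")["editDistance"]
        assert ed == len(out) - len(ancestor_20k)


class TestPlantRepeat:
    def test_exact_copies_at_truth_coordinates(self):
        rep = generate_ancestor(60_000, 0.6, seed=2)
        out, truth = plant_repeat(rep, 5_000, copies=2, identity=1.0, seed=3)
        (s1, e1), (s2, e2) = truth.copies
        assert out.seq[s1:e1] == out.seq[s2:e2]
        assert e1 - s1 == 5_000

    def test_copy_identity_calibrated(self):
        rep = generate_ancestor(300_000, 0.6, seed=4)
        out, truth = plant_repeat(rep, 80_000, copies=2, identity=0.97,
                                  seed=5)
        (s1, e1), (s2, e2) = truth.copies
        ident = 1 - hamming(out.seq[s1:e1], out.seq[s2:e2]) / 80_000
        assert abs(ident - 0.97) <= 0.005

    def test_single_copy_rejected(self, ancestor_20k):
        with pytest.raises(ValueError):
            plant_repeat(ancestor_20k, 1_000, copies=1, identity=1.0, seed=1)

    def test_oversized_repeat_rejected(self, ancestor_20k):
        with pytest.raises(ValueError):
            plant_repeat(ancestor_20k, 15_000, copies=2, identity=1.0,
                         seed=1)


class TestSimulateReads:
    def test_linear_replicon_never_wraps(self):
        rep = generate_ancestor(50_000, 0.6, seed=6, circular=False)
        reads, _ = simulate_reads(as_genome(rep), 10, 5_000, seed=7)
        assert not any(r.wraps_origin for r in reads)

    def test_wrap_fraction_matches_geometry(self):
        rep = generate_ancestor(100_000, 0.6, seed=8, replicon_id="chr",
                                circular=True)
        reads, _ = simulate_reads(as_genome(rep), 30, 10_000, seed=9)
        frac = np.mean([r.wraps_origin for r in reads])
        assert abs(frac - 0.1) <= 0.03

    def test_invalid_depth_rejected(self, ancestor_20k):
        with pytest.raises(ValueError):
            simulate_reads(as_genome(ancestor_20k), 0, 5_000, seed=1)

    def test_alignment_spans_conserve_read_bases(self):
        rep = generate_ancestor(80_000, 0.6, seed=10, circular=True)
        reads, recs = simulate_reads(as_genome(rep), 15, 8_000, seed=11)
        primary = sum(r.span for r in recs if not r.is_secondary)
        assert primary == sum(r.length for r in reads)

    def test_wrapping_read_split_into_two_records(self):
        rep = generate_ancestor(60_000, 0.6, seed=12, circular=True)
        reads, recs = simulate_reads(as_genome(rep), 20, 6_000, seed=13)
        by_read = {}
        for rec in recs:
            by_read.setdefault(rec.read_id, []).append(rec)
        for read in reads:
            parts = by_read[read.read_id]
            if read.wraps_origin:
                assert len(parts) == 2
                assert any(p.start == 0 for p in parts)
                assert any(p.end == len(rep) for p in parts)
                assert sum(p.span for p in parts) == read.length

    def test_read_sequence_matches_source(self):
        rep = generate_ancestor(30_000, 0.6, seed=14, circular=True)
        reads, _ = simulate_reads(as_genome(rep), 5, 4_000, seed=15)
        for read in reads[:20]:
            doubled = rep.seq + rep.seq
            assert read.seq == doubled[read.start: read.start + read.length]


class TestSimulateClade:
    TREE = "((A:1,B:1):1,(C:1,D:1):1):0;"

    def test_zero_branch_lengths_identical_sequences(self):
        sim = CladeSim("((A:0,B:0):0,(C:0,D:0):0):0;", substitution_rate=0.01)
        genomes, _ = simulate_clade(sim, 10_000, seed=1)
        seqs = {g.chromosome.seq for g in genomes.values()}
        assert len(seqs) == 1

    def test_variable_site_count_near_expectation(self):
        rate = 0.0005
        sim = CladeSim(self.TREE, substitution_rate=rate)
        genomes, truth = simulate_clade(sim, 100_000, seed=2)
        # expected variable fraction ~ 1 - exp(-rate * total branch length)
        total_branch = 6.0
        expected = (1 - math.exp(-rate * total_branch)) * 100_000
        assert abs(len(truth.variable_sites) - expected) <= 0.2 * expected

    def test_recombinant_segment_density_exceeds_background(self):
        sim = CladeSim(self.TREE, substitution_rate=0.001 / 6,
                       recomb_segments=[("B", 20_000, 30_000, 0.05)])
        genomes, truth = simulate_clade(sim, 100_000, seed=3)
        a, b = genomes["A"].chromosome.seq, genomes["B"].chromosome.seq
        diffs = np.array([i for i, (x, y) in enumerate(zip(a, b)) if x != y])
        inside = ((diffs >= 20_000) & (diffs < 30_000)).sum() / 10_000
        outside = ((diffs < 20_000) | (diffs >= 30_000)).sum() / 90_000
        assert inside >= 10 * outside

    def test_too_few_taxa_rejected(self):
        with pytest.raises(FormatError):
            simulate_clade(CladeSim("(A:1,B:1);", substitution_rate=0.01),
                           1_000, seed=1)

    def test_overlapping_recomb_segments_rejected(self):
        with pytest.raises(ValueError):
            CladeSim(self.TREE, substitution_rate=0.01,
                     recomb_segments=[("B", 100, 200, 0.05),
                                      ("B", 150, 300, 0.05)])

    def test_determinism(self):
        sim = CladeSim(self.TREE, substitution_rate=0.001)
        g1, _ = simulate_clade(sim, 20_000, seed=9)
        g2, _ = simulate_clade(sim, 20_000, seed=9)
        assert all(g1[t].chromosome.seq == g2[t].chromosome.seq for t in g1)
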