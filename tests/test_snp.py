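"""Core-SNP calling, matrix construction, masking and NJ tree building."""

import numpy as np
import pytest

from genotax import snp
from genotax.genome import Genome, Replicon
from genotax.simulate import (CladeSim, generate_ancestor, mutate,
                              simulate_clade)

from conftest import as_genome

TREE4 = "((A:1,B:1):1,(C:1,D:1):1):0;"


def clade_variant_sets(genomes, ref_taxon="A"):
    ref = genomes[ref_taxon].chromosome
    vsets = [snp.reference_variant_set(ref, ref_taxon)]
    for t in sorted(genomes):
        if t != ref_taxon:
            vsets.append(snp.call_variants(ref, genomes[t]))
    return ref, vsets


class TestCallVariants:
    def test_self_call_is_empty_and_fully_covered(self, ancestor_20k):
        vs = snp.call_variants(ancestor_20k, as_genome(ancestor_20k, "Q"))
        assert vs.variants == {}
        # only the sub-fragment trailing remainder may be uncovered
        assert vs.covered.mean() > 0.94

    def test_substitution_truth_recovered(self, ancestor_50k):
        derived = mutate(ancestor_50k, 0.01, seed=21)
        vs = snp.call_variants(ancestor_50k, as_genome(derived, "Q"))
        truth = {i for i, (x, y) in enumerate(
            zip(ancestor_50k.seq, derived.seq)) if x != y}
        truth_covered = {p for p in truth if vs.covered[p]}
        called = set(vs.variants)
        assert abs(len(called) - 500) <= 60
        jacc = len(called & truth_covered) / len(called | truth_covered)
        assert jacc >= 0.99
        # alleles, not just positions
        assert all(vs.variants[p] == derived.seq[p]
                   for p in list(called)[:50])

    def test_unrelated_query_has_empty_coverage(self, ancestor_20k):
        other = generate_ancestor(20_000, 0.5, seed=22, replicon_id="chr")
        vs = snp.call_variants(ancestor_20k, as_genome(other, "Q"))
        assert not vs.covered.any()
        assert vs.variants == {}
        assert vs.missing_fraction == 1.0


class TestBuildMatrix:
    def test_identical_strains_give_zero_columns(self, ancestor_20k):
        ref = ancestor_20k
        vsets = [snp.reference_variant_set(ref, "A"),
                 snp.call_variants(ref, as_genome(ref, "B"))]
        m = snp.build_matrix(vsets, ref)
        assert m.n_sites == 0

    def test_matrix_equals_simulation_truth(self):
        sim = CladeSim(TREE4, substitution_rate=0.001)
        genomes, truth = simulate_clade(sim, 60_000, seed=23)
        ref, vsets = clade_variant_sets(genomes)
        m = snp.build_matrix(vsets, ref)
        core = np.ones(len(ref), dtype=bool)
        for v in vsets:
            core &= v.covered
        seqs = {t: genomes[t].chromosome.seq for t in genomes}
        expected = [p for p in truth.variable_sites if core[p]]
        assert m.positions.tolist() == expected
        for ti, taxon in enumerate(m.taxa):
            for ci, pos in enumerate(m.positions.tolist()[:100]):
                assert m.states[ti, ci] == seqs[taxon][pos]

    def test_uncovered_strain_forces_empty_core(self, ancestor_20k):
        ref = ancestor_20k
        empty = snp.VariantSet("Z", {}, np.zeros(len(ref), dtype=bool),
                               len(ref))
        vsets = [snp.reference_variant_set(ref, "A"), empty]
        m = snp.build_matrix(vsets, ref)
        assert m.n_sites == 0
        assert m.missing_fraction["Z"] == 1.0

    def test_fewer_than_two_strains_rejected(self, ancestor_20k):
        with pytest.raises(ValueError):
            snp.build_matrix([snp.reference_variant_set(ancestor_20k, "A")],
                             ancestor_20k)


class TestFilterMissing:
    def _matrix(self, ref):
        full = snp.reference_variant_set(ref, "A")
        half_cov = np.zeros(len(ref), dtype=bool)
        half_cov[: len(ref) // 2] = True
        half = snp.VariantSet("H", {10: "A" if ref.seq[10] != "A" else "C"},
                              half_cov, len(ref))
        other = snp.VariantSet(
            "B", {10: "G" if ref.seq[10] != "G" else "T"},
            np.ones(len(ref), dtype=bool), len(ref))
        return snp.build_matrix([full, half, other], ref)

    def test_half_covered_taxon_excluded_at_31_percent(self, ancestor_20k):
        m = self._matrix(ancestor_20k)
        out, excluded = snp.filter_missing(m, 0.31)
        assert excluded == ["H"]
        assert "H" not in out.taxa

    def test_threshold_one_excludes_nobody(self, ancestor_20k):
        m = self._matrix(ancestor_20k)
        out, excluded = snp.filter_missing(m, 1.0)
        assert excluded == []
        assert out.taxa == m.taxa

    def test_fully_covered_taxa_identity(self):
        sim = CladeSim(TREE4, substitution_rate=0.001)
        genomes, _ = simulate_clade(sim, 30_000, seed=24)
        ref, vsets = clade_variant_sets(genomes)
        m = snp.build_matrix(vsets, ref)
        out, excluded = snp.filter_missing(m, 0.31)
        assert excluded == []
        assert out.n_sites == m.n_sites


class TestMaskRecombination:
    def test_clean_clade_converges_immediately_with_empty_mask(self):
        sim = CladeSim(TREE4, substitution_rate=0.001)
        genomes, _ = simulate_clade(sim, 60_000, seed=25)
        ref, vsets = clade_variant_sets(genomes)
        m = snp.build_matrix(vsets, ref)
        mask, masked = snp.mask_recombination(m)
        assert mask.intervals == {}
        assert mask.iterations_run == 1
        assert masked.n_sites == m.n_sites

    def test_planted_import_masked_background_spared(self):
        hits = []
        for seed in range(3):
            sim = CladeSim(TREE4, substitution_rate=0.0005,
                           recomb_segments=[("B", 30_000, 40_000, 0.05)])
            genomes, _ = simulate_clade(sim, 100_000, seed=300 + seed)
            ref, vsets = clade_variant_sets(genomes)
            m = snp.build_matrix(vsets, ref)
            mask, _ = snp.mask_recombination(m)
            bi = m.taxa.index("B")
            bsnp = m.positions[m.states[bi] != m.ref_states]
            ivs = mask.intervals.get("B", [])

            def masked_at(p):
                return any(s <= p < e for s, e in ivs)

            inside = [p for p in bsnp if 30_000 <= p < 40_000]
            outside = [p for p in bsnp if not 30_000 <= p < 40_000]
            hits.append((np.mean([masked_at(p) for p in inside]),
                         np.mean([masked_at(p) for p in outside])))
        for import_frac, background_frac in hits:
            assert import_frac >= 0.9
            assert background_frac < 0.05

    def test_max_iter_zero_is_noop(self, ancestor_20k):
        ref = ancestor_20k
        vsets = [snp.reference_variant_set(ref, "A"),
                 snp.call_variants(ref, as_genome(mutate(ref, 0.01, 26),
                                                  "B"))]
        m = snp.build_matrix(vsets, ref)
        mask, masked = snp.mask_recombination(m, max_iter=0)
        assert mask.intervals == {}
        assert mask.iterations_run == 0
        assert masked.n_sites == m.n_sites

    def test_iteration_bound_respected(self):
        sim = CladeSim(TREE4, substitution_rate=0.0005,
                       recomb_segments=[("B", 10_000, 20_000, 0.05)])
        genomes, _ = simulate_clade(sim, 50_000, seed=27)
        ref, vsets = clade_variant_sets(genomes)
        m = snp.build_matrix(vsets, ref)
        mask, _ = snp.mask_recombination(m, max_iter=2)
        assert mask.iterations_run <= 2


class TestBuildTree:
    def test_identical_pair_forms_cherry(self):
        states = np.array([["A", "A", "A"],
                           ["A", "A", "A"],
                           ["C", "G", "T"]], dtype="<U1")
        m = snp.SNPMatrix(np.array([5, 10, 15]), ["x", "y", "z"], states,
                          np.array(["A", "A", "A"], dtype="<U1"),
                          {"x": 0, "y": 0, "z": 0}, 1_000)
        t = snp.build_tree(m)
        assert not t.degenerate
        tips = {n.name for n in t.tree.tips()}
        assert tips == {"x", "y", "z"}
        # x and y are identical: their pairwise distance is 0, z is distant
        dm = snp.snp_distance_matrix(m)
        assert dm["x", "y"] == 0.0
        assert dm["x", "z"] == 1.0

    def test_distance_matrix_symmetry_and_zero_diagonal(self):
        sim = CladeSim(TREE4, substitution_rate=0.001)
        genomes, _ = simulate_clade(sim, 30_000, seed=28)
        ref, vsets = clade_variant_sets(genomes)
        m = snp.build_matrix(vsets, ref)
        dm = snp.snp_distance_matrix(m)
        arr = dm.data
        assert np.allclose(arr, arr.T)
        assert np.all(np.diag(arr) == 0)

    def test_truth_topology_recovered_without_recombination(self):
        for seed in range(3):
            sim = CladeSim(TREE4, substitution_rate=0.001)
            genomes, truth = simulate_clade(sim, 60_000, seed=400 + seed)
            ref, vsets = clade_variant_sets(genomes)
            m = snp.build_matrix(vsets, ref)
            t = snp.build_tree(m)
            assert t.tree.compare_rfd(truth.tree) == 0.0

    def test_zero_columns_yield_degenerate_star(self):
        m = snp.SNPMatrix(np.array([], dtype=np.int64), ["a", "b", "c"],
                          np.empty((3, 0), dtype="<U1"),
                          np.array([], dtype="<U1"),
                          {"a": 0, "b": 0, "c": 0}, 1_000)
        t = snp.build_tree(m)
        assert t.degenerate
        assert {n.name for n in t.tree.tips()} == {"a", "b", "c"}

    def test_fewer_than_three_taxa_rejected(self):
        m = snp.SNPMatrix(np.array([], dtype=np.int64), ["a", "b"],
                          np.empty((2, 0), dtype="<U1"),
                          np.array([], dtype="<U1"), {"a": 0, "b": 0}, 100)
        with pytest.raises(ValueError):
            snp.build_tree(m)

    def test_taxon_order_does_not_change_topology(self):
        sim = CladeSim(TREE4, substitution_rate=0.001)
        genomes, _ = simulate_clade(sim, 30_000, seed=29)
        ref, vsets = clade_variant_sets(genomes)
        m = snp.build_matrix(vsets, ref)
        m_rev = snp.build_matrix(list(reversed(vsets)), ref)
        assert snp.build_tree(m).newick == snp.build_tree(m_rev).newick
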