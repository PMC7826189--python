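"""Generators: determinism, planted structure, truth records, limits."""

import numpy as np
import pytest

from chromaforge.ogf_evolution import IndexedTree
from chromaforge.synthetic_data import (
    SynthConfig,
    generate_bundle,
    ladder_from_tree,
    random_species_tree,
    simulate_family_evolution,
    simulate_gene_trees,
    simulate_proteome,
    simulate_regions_and_reads,
    simulate_timecourse,
    substream,
)


class TestConfig:
    def test_rejects_impossible_protein_length_budget(self):
        with pytest.raises(ValueError, match="max_protein_length"):
            SynthConfig(crtp_length=500, max_protein_length=700)

    def test_rejects_read_longer_than_genome(self):
        with pytest.raises(ValueError):
            SynthConfig(genome_len=50, read_len=100)

    def test_rejects_out_of_range_fractions(self):
        with pytest.raises(ValueError):
            SynthConfig(frac_rhythmic=1.5)


class TestDeterminism:
    def test_identical_seed_gives_identical_bundle(self):
        cfg = SynthConfig(seed=7, n_proteins=30, n_planted_crtp=3, n_decoy_crtp=2,
                          n_genes_expr=40, n_gene_trees=10, n_families=20)
        b1 = generate_bundle(cfg)
        b2 = generate_bundle(cfg)
        assert [r.seq for r in b1.proteome] == [r.seq for r in b2.proteome]
        assert np.array_equal(b1.counts.values, b2.counts.values)
        assert b1.truth == b2.truth

    def test_substreams_are_independent_of_other_generators(self):
        # changing the tree count must not perturb the proteome stream
        a = SynthConfig(seed=7, n_proteins=30, n_planted_crtp=3, n_decoy_crtp=2,
                        n_gene_trees=10)
        b = SynthConfig(seed=7, n_proteins=30, n_planted_crtp=3, n_decoy_crtp=2,
                        n_gene_trees=40)
        pa, _, _ = simulate_proteome(a)
        pb, _, _ = simulate_proteome(b)
        assert [r.seq for r in pa] == [r.seq for r in pb]

    def test_different_seeds_differ(self):
        p1, _, _ = simulate_proteome(SynthConfig(seed=1, n_proteins=10, n_planted_crtp=2, n_decoy_crtp=1))
        p2, _, _ = simulate_proteome(SynthConfig(seed=2, n_proteins=10, n_planted_crtp=2, n_decoy_crtp=1))
        assert [r.seq for r in p1] != [r.seq for r in p2]


class TestFamilyEvolution:
    def test_no_loss_limit_fills_entire_gain_subtree(self):
        cfg = SynthConfig(seed=5, n_species=6, n_families=60, gain_loss_rates=(1.0, 0.0))
        tree = random_species_tree(cfg)
        matrix, truth = simulate_family_evolution(cfg, tree)
        it = IndexedTree(tree)
        for i, fam in enumerate(matrix.families):
            g = it.id_to_index[truth["families"][fam]["gain_node"]]
            expected = {
                lab for lab, inside in zip(it.leaf_order, it.subtree_leaves[g]) if inside
            }
            assert matrix.presence_set(fam) == expected
            assert truth["families"][fam]["n_losses"] == 0

    def test_terminal_gain_yields_single_species_family(self):
        cfg = SynthConfig(seed=5, n_species=5, n_families=40, gain_loss_rates=(1.0, 0.0))
        tree = random_species_tree(cfg)
        matrix, truth = simulate_family_evolution(cfg, tree)
        leaves = set(tree.leaf_labels())
        for fam in matrix.families:
            if truth["families"][fam]["gain_node"] in leaves:
                assert len(matrix.presence_set(fam)) == 1

    def test_every_family_extant_somewhere(self, small_bundle):
        assert small_bundle.families.presence.any(axis=1).all()


class TestProteome:
    def test_zero_planted_means_no_block_anywhere(self):
        cfg = SynthConfig(seed=3, n_proteins=12, n_planted_crtp=0, n_decoy_crtp=0)
        _, truth, _ = simulate_proteome(cfg)
        assert truth["planted"] == {}

    def test_planted_construction_arithmetic(self):
        cfg = SynthConfig(seed=3, n_proteins=20, n_planted_crtp=5, n_decoy_crtp=0)
        proteome, truth, _ = simulate_proteome(cfg)
        by_id = {r.id: r for r in proteome}
        for pid, info in truth["planted"].items():
            assert info["end"] - info["start"] == cfg.crtp_length
            assert info["start"] <= 49
            assert info["mature_length"] > 250
            assert len(by_id[pid].seq) == info["end"] + info["mature_length"]

    def test_decoys_flagged_with_violated_filter(self):
        cfg = SynthConfig(seed=3, n_proteins=20, n_planted_crtp=2, n_decoy_crtp=6)
        _, truth, _ = simulate_proteome(cfg)
        assert len(truth["decoys"]) == 6
        assert {d["reason"] for d in truth["decoys"].values()} == {"start", "mature"}


class TestTimecourse:
    def test_zero_amplitude_means_empty_truth(self):
        cfg = SynthConfig(seed=4, n_genes_expr=30, amplitude_over_sigma=0.0)
        _, truth = simulate_timecourse(cfg)
        assert truth["rhythmic"] == {}

    def test_planted_phase_peaks_at_its_timepoint(self):
        cfg = SynthConfig(seed=4, n_genes_expr=200, frac_rhythmic=0.5, noise_cv=0.05)
        cm, truth = simulate_timecourse(cfg)
        times = np.array([s.timepoint_h for s in cm.samples])
        idx = {g: i for i, g in enumerate(cm.genes)}
        hits = 0
        for g, phase in truth["rhythmic"].items():
            means = [cm.values[idx[g], times == t].mean() for t in (0, 6, 12, 18)]
            hits += (0, 6, 12, 18)[int(np.argmax(means))] == phase
        assert hits / len(truth["rhythmic"]) > 0.95

    def test_counts_are_nonnegative_integers(self, small_bundle):
        v = small_bundle.counts.values
        assert (v >= 0).all()
        assert np.array_equal(v, np.rint(v))


class TestGeneTrees:
    def test_class_counts_follow_config(self, small_bundle):
        truth = small_bundle.truth["gene_trees"]
        verdicts = [t["verdict"] for t in truth.values()]
        cfg = small_bundle.config
        assert verdicts.count("HGT") == round(cfg.frac_hgt * cfg.n_gene_trees)
        assert verdicts.count("EGT") == round(cfg.frac_egt * cfg.n_gene_trees)
        assert verdicts.count("discarded") == round(cfg.frac_fodder * cfg.n_gene_trees)

    def test_non_fodder_trees_meet_size_floor(self, small_bundle):
        truth = small_bundle.truth["gene_trees"]
        for tid, tree in small_bundle.gene_trees:
            if truth[tid]["verdict"] != "discarded":
                assert len(tree.leaf_labels()) >= 10

    def test_fodder_reasons_among_the_fixed_vocabulary(self, small_bundle):
        truth = small_bundle.truth["gene_trees"]
        reasons = {
            t["reason"] for t in truth.values() if t["verdict"] == "discarded"
        }
        assert reasons <= {"leaves<10", "bacteria<5", "paulinella_polyphyly"}


class TestRegionsAndReads:
    def test_zero_viral_depth_leaves_viral_uncovered(self):
        cfg = SynthConfig(seed=6, genome_len=20_000, read_depth_viral=0.0)
        regions, alignments, truth = simulate_regions_and_reads(cfg)
        viral = regions.class_intervals("viral")
        from chromaforge.region_coverage import breadth_per_class

        rep = breadth_per_class(regions, alignments, "m")
        assert rep.per_class["viral"].covered_bases == 0
        assert truth["viral"]["expected_breadth"] == 0.0

    def test_saturating_depth_approaches_full_breadth(self):
        cfg = SynthConfig(seed=6, genome_len=20_000, read_depth_viral=10.0)
        regions, alignments, truth = simulate_regions_and_reads(cfg)
        from chromaforge.region_coverage import breadth_per_class

        rep = breadth_per_class(regions, alignments, "m")
        assert rep.per_class["viral"].fraction > 0.99

    def test_reads_stay_inside_the_genome(self, small_bundle):
        for iv in small_bundle.alignments:
            assert 0 <= iv.start < iv.end <= small_bundle.config.genome_len


class TestLadder:
    def test_ladder_is_nested_along_focal_lineage(self, small_bundle):
        lad = ladder_from_tree(small_bundle.species_tree, "S1")
        assert lad.strata[-1][1] == frozenset({"S1"})
        all_species = set(small_bundle.species_tree.leaf_labels())
        covered = set().union(*(s for _, s in lad.strata))
        assert covered == all_species
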