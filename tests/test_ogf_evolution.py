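"""Dollo reconstruction, ancestral counts, relative age, rhythmic overlap."""

import numpy as np
import pytest

from chromaforge.core_io import FamilyMatrix, parse_newick
from chromaforge.ogf_evolution import (
    StratumLadder,
    ancestral_counts,
    assign_relative_age,
    dollo_reconstruct,
    rhythmic_ogf_overlap,
)

from _oracles import dollo_bruteforce, enumerate_tree_shapes


def _matrix(species, rows, fams=None):
    fams = fams or [f"OG{i}" for i in range(len(rows))]
    gene_map = {
        f: {sp: [f"{sp}|{f}"] for sp, p in zip(species, row) if p}
        for f, row in zip(fams, rows)
    }
    return FamilyMatrix(
        families=fams, species=species, presence=np.array(rows, bool), gene_map=gene_map
    )


class TestDollo:
    def test_complete_presence_gains_at_root_with_zero_losses(self):
        tree = parse_newick("((A,B),(C,D));")
        m = _matrix(["A", "B", "C", "D"], [[1, 1, 1, 1]])
        res = dollo_reconstruct(m, tree)
        root_id = res.tree.ids[-1]
        assert res.gain_node["OG0"] == root_id
        assert res.loss_branches["OG0"] == frozenset()

    def test_singleton_family_gains_on_terminal_branch(self):
        tree = parse_newick("((A,B),(C,D));")
        m = _matrix(["A", "B", "C", "D"], [[0, 0, 1, 0]])
        res = dollo_reconstruct(m, tree)
        assert res.gain_node["OG0"] == "C"
        assert res.loss_branches["OG0"] == frozenset()

    def test_caterpillar_pattern_counts_one_loss(self):
        # present in A and C, absent in B: gain at MRCA(A, C), loss into B
        tree = parse_newick("(((A,B),C),D);")
        m = _matrix(["A", "B", "C", "D"], [[1, 0, 1, 0]])
        res = dollo_reconstruct(m, tree)
        assert res.loss_branches["OG0"] == frozenset({"B"})

    def test_species_absent_from_tree_is_an_error(self):
        tree = parse_newick("(A,B);")
        m = _matrix(["A", "B", "Z"], [[1, 0, 1]])
        with pytest.raises(ValueError, match="Z"):
            dollo_reconstruct(m, tree)

    def test_matches_bruteforce_on_small_trees(self, rng):
        # exhaustive single-gain enumeration over internal-state vectors
        for tree in enumerate_tree_shapes(5):
            species = tree.leaf_labels()
            for _ in range(25):
                row = rng.integers(0, 2, size=len(species)).astype(bool)
                if not row.any():
                    continue
                m = _matrix(species, [row.tolist()])
                res = dollo_reconstruct(m, tree)
                min_losses, gain_sets = dollo_bruteforce(
                    tree, dict(zip(species, row))
                )
                assert len(res.loss_branches["OG0"]) == min_losses
                it = res.tree
                gidx = it.id_to_index[res.gain_node["OG0"]]
                gleaves = frozenset(
                    l for l, inside in zip(it.leaf_order, it.subtree_leaves[gidx]) if inside
                )
                assert gleaves in gain_sets

    def test_counts_additive_along_every_branch(self, small_bundle):
        res = dollo_reconstruct(small_bundle.families, small_bundle.species_tree)
        it = res.tree
        for v, node in enumerate(it.nodes):
            p = it.parent[v]
            if p is None:
                continue
            nid, pid = it.ids[v], it.ids[p]
            assert res.ancestral_count[nid] == (
                res.ancestral_count[pid]
                + res.branch_gains[nid]
                - res.branch_losses[nid]
            )

    def test_leaf_counts_anchor_to_observed_presence(self, small_bundle):
        res = dollo_reconstruct(small_bundle.families, small_bundle.species_tree)
        m = small_bundle.families
        for j, sp in enumerate(m.species):
            assert ancestral_counts(res, sp) == int(m.presence[:, j].sum())

    def test_unknown_node_id_is_an_error(self, small_bundle):
        res = dollo_reconstruct(small_bundle.families, small_bundle.species_tree)
        with pytest.raises(KeyError):
            ancestral_counts(res, "nosuchnode")

    def test_polytomies_handled_without_resolution(self):
        tree = parse_newick("(A,B,C,D);")
        m = _matrix(["A", "B", "C", "D"], [[1, 1, 0, 0]])
        res = dollo_reconstruct(m, tree)
        assert res.gain_node["OG0"] == res.tree.ids[-1]  # root polytomy MRCA
        assert len(res.loss_branches["OG0"]) == 2


class TestRelativeAge:
    LADDER = StratumLadder(
        [
            ("prokaryotes", frozenset({"P1", "P2"})),
            ("eukaryotes", frozenset({"E1", "E2"})),
            ("focal", frozenset({"F"})),
        ]
    )

    def test_any_prokaryote_member_makes_family_oldest(self):
        m = _matrix(["P1", "E1", "F"], [[1, 1, 1]])
        assert assign_relative_age(m, self.LADDER)["OG0"] == "prokaryotes"

    def test_focal_only_family_is_youngest(self):
        m = _matrix(["P1", "E1", "F"], [[0, 0, 1]])
        assert assign_relative_age(m, self.LADDER)["OG0"] == "focal"

    def test_adding_species_never_makes_age_younger(self):
        order = {name: i for i, name in enumerate(self.LADDER.names)}
        base = _matrix(["P1", "E1", "F"], [[0, 1, 0]])
        grown = _matrix(["P1", "E1", "F"], [[1, 1, 0]])
        a0 = assign_relative_age(base, self.LADDER)["OG0"]
        a1 = assign_relative_age(grown, self.LADDER)["OG0"]
        assert order[a1] <= order[a0]

    def test_family_outside_every_stratum_is_an_error(self):
        m = _matrix(["Q"], [[1]])
        with pytest.raises(ValueError, match="OG0"):
            assign_relative_age(m, self.LADDER)


class TestRhythmicOverlap:
    def _matrix4(self):
        species = ["W", "X", "Y", "Z"]
        rows = [[1, 1, 1, 1], [1, 1, 0, 0], [0, 0, 1, 1]]
        return _matrix(species, rows)

    def test_no_rhythmic_genes_gives_empty_intersections(self):
        m = self._matrix4()
        out = rhythmic_ogf_overlap({}, m, m.species)
        assert out.venn == {}

    def test_two_species_family_fills_one_exclusive_cell(self):
        m = self._matrix4()
        rhythmic = {"W": {"W|OG1"}, "X": {"X|OG1"}}
        out = rhythmic_ogf_overlap(rhythmic, m, m.species)
        assert out.venn == {frozenset({"W", "X"}): 1}

    def test_venn_cells_sum_to_total_rhythmic_ogfs(self, rng):
        m = self._matrix4()
        rhythmic = {
            sp: {
                f"{sp}|{fam}"
                for fam in m.families
                if sp in m.gene_map[fam] and rng.random() < 0.5
            }
            for sp in m.species
        }
        out = rhythmic_ogf_overlap(rhythmic, m, m.species)
        assert sum(out.venn.values()) == len(out.membership)

    def test_unmapped_rhythmic_gene_counted_and_skipped(self, caplog):
        m = self._matrix4()
        with caplog.at_level("WARNING", logger="chromaforge"):
            out = rhythmic_ogf_overlap({"W": {"ghost_gene"}}, m, m.species)
        assert out.n_unmapped_genes == 1
        assert out.venn == {}
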