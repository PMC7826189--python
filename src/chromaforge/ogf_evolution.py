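"""Dollo-parsimony evolution of orthologous gene families (OGFs).

Under Dollo parsimony each family is gained exactly once and may be lost any
number of times. Given a presence/absence matrix over extant species and a
rooted species tree, the most-parsimonious single-gain reconstruction is:

* the gain node of a family is the MRCA of the species that have it;
* a node below the gain is ancestrally "present" iff its subtree contains at
  least one extant member;
* a loss is charged to the branch into a node whose parent is present but
  which is itself absent.

This minimises the number of losses over all single-gain assignments (the
present set must be a rooted-connected subtree covering the extant members,
and the reconstruction above is the minimal such subtree). Polytomies need
no special handling.

Also here: phylostratigraphic relative-age assignment of families (oldest
intersecting stratum of a nested species ladder) and the cross-species
rhythmic-OGF overlap (Venn) computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import FamilyMatrix, TreeNode

logger = logging.getLogger("chromaforge")


# ---------------------------------------------------------------------------
# Indexed tree helper
# ---------------------------------------------------------------------------

class IndexedTree:
    """Postorder-indexed view of a rooted tree with stable node ids.

    Leaves are identified by their label; internal nodes by ``"node<k>"``
    with k assigned in postorder. The branch into a node shares the node's
    id.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.nodes: list[TreeNode] = list(root.postorder())
        self.index: dict[int, int] = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent: list[int | None] = [None] * len(self.nodes)
        for i, n in enumerate(self.nodes):
            for c in n.children:
                self.parent[self.index[id(c)]] = i
        self.ids: list[str] = []
        k = 0
        for n in self.nodes:
            if n.is_leaf:
                self.ids.append(n.label)
            else:
                self.ids.append(f"node{k}")
                k += 1
        self.id_to_index = {nid: i for i, nid in enumerate(self.ids)}
        self.leaf_index = {n.label: i for i, n in enumerate(self.nodes) if n.is_leaf}
        # leaf-membership matrix: subtree_leaves[i] = boolean over leaf order
        self.leaf_order = [n.label for n in self.nodes if n.is_leaf]
        leaf_pos = {lab: j for j, lab in enumerate(self.leaf_order)}
        m = np.zeros((len(self.nodes), len(self.leaf_order)), dtype=bool)
        for i, n in enumerate(self.nodes):
            if n.is_leaf:
                m[i, leaf_pos[n.label]] = True
            else:
                for c in n.children:
                    m[i] |= m[self.index[id(c)]]
        self.subtree_leaves = m

    def __len__(self) -> int:
        return len(self.nodes)


# ---------------------------------------------------------------------------
# Dollo reconstruction
# ---------------------------------------------------------------------------

@dataclass
class DolloResult:
    """Per-family gains/losses and per-node ancestral family counts."""

    tree: IndexedTree
    gain_node: dict[str, str]
    loss_branches: dict[str, frozenset[str]]
    ancestral_count: dict[str, int]
    branch_gains: dict[str, int]
    branch_losses: dict[str, int]


def dollo_reconstruct(matrix: FamilyMatrix, tree: TreeNode) -> DolloResult:
    """Most-parsimonious single-gain (Dollo) reconstruction of every family."""
    it = IndexedTree(tree)
    missing = [sp for sp in matrix.species if sp not in it.leaf_index]
    extra = [lab for lab in it.leaf_order if lab not in matrix.species]
    if missing:
        raise ValueError(
            f"species {missing[0]!r} in the family matrix is absent from the tree"
        )
    if extra:
        raise ValueError(f"tree leaf {extra[0]!r} is absent from the family matrix")

    n_nodes = len(it)
    leaf_pos = {lab: j for j, lab in enumerate(it.leaf_order)}
    col_of_species = [leaf_pos[sp] for sp in matrix.species]
    # presence over tree leaf order
    pres = np.zeros((len(matrix.families), len(it.leaf_order)), dtype=bool)
    pres[:, col_of_species] = matrix.presence

    # members in each node's subtree: (families x nodes)
    cnt = pres @ it.subtree_leaves.T.astype(int)  # int counts
    total = pres.sum(axis=1)

    gain_node: dict[str, str] = {}
    loss_branches: dict[str, frozenset[str]] = {}
    node_count = np.zeros(n_nodes, dtype=int)
    gains = np.zeros(n_nodes, dtype=int)
    losses = np.zeros(n_nodes, dtype=int)

    # ancestor-or-self matrix for gain-subtree masking
    anc = np.zeros((n_nodes, n_nodes), dtype=bool)
    for v in range(n_nodes):
        u: int | None = v
        while u is not None:
            anc[u, v] = True
            u = it.parent[u]

    parent_arr = np.array([p if p is not None else -1 for p in it.parent])

    for f, fam in enumerate(matrix.families):
        if total[f] == 0:
            raise ValueError(f"family {fam!r} present in zero species")
        full = np.flatnonzero(cnt[f] == total[f])
        g = int(full[0])  # postorder => first full node is the MRCA
        present = (cnt[f] > 0) & anc[g]
        gain_node[fam] = it.ids[g]
        gains[g] += 1
        node_count += present
        pa = parent_arr
        lost = np.flatnonzero(
            (pa >= 0) & ~present & present[np.clip(pa, 0, None)]
        )
        losses[lost] += 1
        loss_branches[fam] = frozenset(it.ids[v] for v in lost)

    return DolloResult(
        tree=it,
        gain_node=gain_node,
        loss_branches=loss_branches,
        ancestral_count={it.ids[v]: int(node_count[v]) for v in range(n_nodes)},
        branch_gains={it.ids[v]: int(gains[v]) for v in range(n_nodes)},
        branch_losses={it.ids[v]: int(losses[v]) for v in range(n_nodes)},
    )


def ancestral_counts(result: DolloResult, node: str) -> int:
    """Number of families reconstructed as present at ``node``."""
    if node not in result.ancestral_count:
        raise KeyError(f"unknown node id {node!r}")
    return result.ancestral_count[node]


def write_dollo_tables(result: DolloResult, out_dir: str | Path) -> None:
    """Write gains_losses.tsv, ancestral_counts.tsv and per_family_events.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    it = result.tree
    with open(out / "gains_losses.tsv", "w", newline="\n") as fh:
        fh.write("branch\tgains\tlosses\n")
        for nid in it.ids:
            fh.write(f"{nid}\t{result.branch_gains[nid]}\t{result.branch_losses[nid]}\n")
    with open(out / "ancestral_counts.tsv", "w", newline="\n") as fh:
        fh.write("node\tfamilies_present\n")
        for nid in it.ids:
            fh.write(f"{nid}\t{result.ancestral_count[nid]}\n")
    with open(out / "per_family_events.tsv", "w", newline="\n") as fh:
        fh.write("family\tgain_node\tloss_branches\n")
        for fam, g in result.gain_node.items():
            lb = ",".join(sorted(result.loss_branches[fam]))
            fh.write(f"{fam}\t{g}\t{lb}\n")


# ---------------------------------------------------------------------------
# Phylostratigraphy (relative age)
# ---------------------------------------------------------------------------

@dataclass
class StratumLadder:
    """Ordered phylostrata (oldest -> youngest), each a named species set.

    The youngest stratum contains the focal species alone. A family's
    relative age is the oldest stratum its presence set intersects.
    """

    strata: list[tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("ladder must have at least one stratum")
        for name, spset in self.strata:
            if not spset:
                raise ValueError(f"stratum {name!r} has an empty species set")
        if len(self.strata[-1][1]) != 1:
            raise ValueError("youngest stratum must be the focal species alone")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.strata]


def load_ladder(path: str | Path) -> StratumLadder:
    """Read a YAML ladder: ordered mapping of stratum name -> species list."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict):
        items = list(raw.items())
    else:
        items = [(d["name"], d["species"]) for d in raw]
    return StratumLadder([(name, frozenset(sps)) for name, sps in items])


def assign_relative_age(matrix: FamilyMatrix, ladder: StratumLadder) -> dict[str, str]:
    """Assign each family the oldest stratum intersecting its presence set."""
    stratum_of_species: dict[str, int] = {}
    for k, (_, spset) in enumerate(ladder.strata):
        for sp in spset:
            stratum_of_species.setdefault(sp, k)
    ages: dict[str, str] = {}
    for i, fam in enumerate(matrix.families):
        ranks = [
            stratum_of_species[sp]
            for sp, p in zip(matrix.species, matrix.presence[i])
            if p and sp in stratum_of_species
        ]
        if not ranks:
            raise ValueError(
                f"family {fam!r} intersects no stratum of the ladder"
            )
        ages[fam] = ladder.strata[min(ranks)][0]
    return ages


# ---------------------------------------------------------------------------
# Cross-species rhythmic-OGF overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    """Rhythmic-OGF membership per species and exclusive Venn cardinalities."""

    membership: dict[str, frozenset[str]]  # family -> species where rhythmic
    venn: dict[frozenset[str], int]  # exclusive cell -> count
    species_subset: list[str]
    n_unmapped_genes: int


def rhythmic_ogf_overlap(
    rhythmic_genes_per_species: Mapping[str, set[str]],
    matrix: FamilyMatrix,
    species_subset: Sequence[str],
) -> OverlapResult:
    """Overlap of diurnally rhythmic OGFs across species.

    An OGF counts as rhythmic in a species iff at least one of its genes in
    that species is rhythmic. Returns per-family membership over
    ``species_subset`` plus all exclusive Venn cell cardinalities (cells sum
    to the total number of rhythmic OGFs). Rhythmic genes that resolve to no
    family are logged, counted and skipped.
    """
    fam_of_gene = matrix.family_of_gene()
    membership: dict[str, set[str]] = {}
    unmapped = 0
    for sp in species_subset:
        for g in rhythmic_genes_per_species.get(sp, set()):
            fam = fam_of_gene.get(g)
            if fam is None:
                unmapped += 1
                continue
            membership.setdefault(fam, set()).add(sp)
    if unmapped:
        logger.warning(
            "rhythmic_ogf_overlap: %d rhythmic genes not found in any family", unmapped
        )
    venn: dict[frozenset[str], int] = {}
    frozen = {fam: frozenset(sps) for fam, sps in membership.items()}
    for sps in frozen.values():
        venn[sps] = venn.get(sps, 0) + 1
    return OverlapResult(
        membership=frozen,
        venn=venn,
        species_subset=list(species_subset),
        n_unmapped_genes=unmapped,
    )
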