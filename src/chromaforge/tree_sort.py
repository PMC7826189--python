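"""Phylogenetic sorting of gene trees for HGT/EGT candidacy.

Each gene tree is screened for a well-supported clade in which the focal
*Paulinella* sequences nest (near-)exclusively among a donor group —
bacteria at large for horizontal gene transfer (HGT), cyanobacteria (with at
least one alpha-cyanobacterium) for endosymbiotic gene transfer (EGT).
Because the rooting of a gene tree is arbitrary, every internal edge is
evaluated from both sides, so verdicts are invariant under re-rooting.

Screening thresholds follow the sorting parameters used in practice:
minimum bipartition support 70 (percent scale), clade exclusivity 0.95
(fraction of the clade's leaves that belong to the target set), and a
minimum proportion 0.7 of the tree's target leaves that the clade must
contain. Trees are first run through discard filters: fewer than 10 leaves,
fewer than 5 bacterial taxa, or *Paulinella* sequences that are not
monophyletic on any rooting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core_io import TreeNode

logger = logging.getLogger("chromaforge")

GROUPS = (
    "query",
    "other_paulinella",
    "bacteria",
    "cyanobacteria",
    "alpha_cyanobacteria",
    "eukarya",
    "archaea",
    "unknown",
)

#: Subgroup containment: a leaf's group implies membership of these groups.
_EXPANSION: dict[str, frozenset[str]] = {
    "query": frozenset({"query"}),
    "other_paulinella": frozenset({"other_paulinella"}),
    "bacteria": frozenset({"bacteria"}),
    "cyanobacteria": frozenset({"cyanobacteria", "bacteria"}),
    "alpha_cyanobacteria": frozenset({"alpha_cyanobacteria", "cyanobacteria", "bacteria"}),
    "eukarya": frozenset({"eukarya"}),
    "archaea": frozenset({"archaea"}),
    "unknown": frozenset({"unknown"}),
}


class TaxonGroupMap:
    """Resolve leaf labels to taxonomic groups.

    Exact label assignments take precedence; otherwise the longest matching
    label prefix wins. An unresolvable leaf is an error (assign ``unknown``
    explicitly to tolerate it).
    """

    def __init__(
        self,
        exact: Mapping[str, str] | None = None,
        prefixes: Mapping[str, str] | None = None,
    ):
        self.exact = dict(exact or {})
        self.prefixes = dict(prefixes or {})
        for g in list(self.exact.values()) + list(self.prefixes.values()):
            if g not in GROUPS:
                raise ValueError(f"unknown taxon group {g!r}")

    def resolve(self, label: str) -> str:
        if label in self.exact:
            return self.exact[label]
        best = None
        for pref, grp in self.prefixes.items():
            if label.startswith(pref) and (best is None or len(pref) > len(best[0])):
                best = (pref, grp)
        if best is None:
            raise KeyError(f"leaf label {label!r} resolves to no taxon group")
        return best[1]

    def in_group(self, label: str, group: str) -> bool:
        return group in _EXPANSION[self.resolve(label)]


def load_groups(path: str | Path) -> TaxonGroupMap:
    """Read a two-column TSV mapping leaf-label prefixes to groups."""
    prefixes: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pref, grp = line.split("\t")[:2]
            prefixes[pref] = grp
    return TaxonGroupMap(prefixes=prefixes)


@dataclass
class SortParams:
    """Thresholds of the clade-sorting screen (support on the 0-100 scale)."""

    min_support: float = 70.0
    min_prop_target: float = 0.7
    clade_exclusivity: float = 0.95
    min_leaves: int = 10
    min_bacteria: int = 5
    donor_group: str = "bacteria"

    def __post_init__(self) -> None:
        if not (0 < self.min_prop_target <= 1 and 0 < self.clade_exclusivity <= 1):
            raise ValueError("fractions must be in (0, 1]")
        if not (0 <= self.min_support <= 100):
            raise ValueError("min_support must be in [0, 100]")


@dataclass
class CladeCandidate:
    """One side of an internal edge that passes the sorting screen."""

    leaves: frozenset[str]
    support: float
    node_id: str
    tally: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.leaves)


@dataclass
class SortOutcome:
    tree_id: str
    verdict: str  # HGT | EGT | negative | discarded
    discard_reason: str | None = None
    clade: CladeCandidate | None = None


def reroot_at_leaf(tree: TreeNode, leaf_label: str) -> TreeNode:
    """Reroot on the terminal edge of ``leaf_label`` (topology-preserving).

    Verdicts must be invariant under this operation: sorting evaluates the
    unrooted topology. Edge supports travel with their edges when parent
    pointers are reversed.
    """
    parent_of: dict[int, TreeNode] = {}
    for node in tree.preorder():
        for c in node.children:
            parent_of[id(c)] = node
    target = next((n for n in tree.postorder() if n.label == leaf_label), None)
    if target is None or not target.is_leaf:
        raise ValueError(f"no leaf {leaf_label!r} in tree")

    def detached(node: TreeNode, excluded: TreeNode | None, go_up: bool) -> TreeNode:
        """Copy of ``node`` viewed from one of its edges.

        Downward children are copied as-is; when ``go_up`` the former parent
        is re-hung as an extra child, with the reversed edge keeping this
        node's support annotation.
        """
        kids = [c for c in node.children if c is not excluded]
        new = TreeNode(
            label=node.label if node.is_leaf else "",
            support=node.support,
            branch_length=node.branch_length,
        )
        new.children = [detached(k, None, False) for k in kids]
        if go_up:
            parent = parent_of.get(id(node))
            if parent is not None:
                up = detached(parent, node, True)
                up.support = node.support
                if up.children or up.label:
                    new.children.append(up)
        return new

    parent = parent_of.get(id(target))
    if parent is None:
        return tree
    rest = detached(parent, target, True)
    rest.support = target.support  # the terminal edge's own annotation
    new_root = TreeNode(children=[
        TreeNode(label=target.label, branch_length=target.branch_length),
        rest,
    ])
    # collapse unary internal nodes left over from the old root
    def collapse(node: TreeNode) -> TreeNode:
        node.children = [collapse(c) for c in node.children]
        if len(node.children) == 1 and not node.is_leaf:
            child = node.children[0]
            if child.support is None:
                child.support = node.support
            return child
        return node

    new_root.children = [collapse(c) for c in new_root.children]
    return new_root


def _bipartitions(tree: TreeNode) -> list[tuple[frozenset[str], float]]:
    """All edge sides of the unrooted topology with their supports.

    Each internal edge contributes both of its sides; the two root-child
    edges of a rooted binary representation collapse to one unrooted edge
    (support merged as the max of the annotations present).
    """
    all_leaves = frozenset(tree.leaf_labels())
    by_side: dict[frozenset[str], float] = {}

    def register(side: frozenset[str], support: float) -> None:
        if not side or side == all_leaves:
            return
        prev = by_side.get(side)
        by_side[side] = support if prev is None else max(prev, support)

    for node in tree.postorder():
        if node is tree:
            continue
        under = frozenset(node.leaf_labels())
        support = node.support if node.support is not None else 0.0
        register(under, support)
        register(all_leaves - under, support)
    return sorted(by_side.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))


def apply_discard_filters(
    tree: TreeNode, groups: TaxonGroupMap, params: SortParams
) -> str | None:
    """Return a discard reason, or None when the tree passes.

    Reasons, checked in order: too few leaves, too few bacterial taxa,
    non-monophyletic *Paulinella* sequences (on every rooting).
    """
    labels = tree.leaf_labels()
    resolved = {lab: groups.resolve(lab) for lab in labels}  # raises on unknowns
    if len(labels) < params.min_leaves:
        return f"leaves<{params.min_leaves}"
    n_bact = sum(1 for lab in labels if "bacteria" in _EXPANSION[resolved[lab]])
    if n_bact < params.min_bacteria:
        return f"bacteria<{params.min_bacteria}"
    pauli = frozenset(
        lab for lab in labels if resolved[lab] in ("query", "other_paulinella")
    )
    if len(pauli) > 1 and pauli != frozenset(labels):
        sides = {side for side, _ in _bipartitions(tree)}
        if pauli not in sides:
            return "paulinella_polyphyly"
    return None


def find_target_clades(
    tree: TreeNode,
    groups: TaxonGroupMap,
    params: SortParams,
    donor_group: str | None = None,
) -> list[CladeCandidate]:
    """Edge sides passing the support/exclusivity/proportion screen.

    The target set is {query, other_paulinella, donor group}. A side
    qualifies when (a) its bipartition support >= min_support, (b) at least
    ``clade_exclusivity`` of its leaves are target, (c) it holds at least
    ``min_prop_target`` of all target leaves in the tree, and (d) it
    contains at least one query leaf and one donor leaf. Candidates are
    returned smallest-first.
    """
    donor = donor_group or params.donor_group
    labels = tree.leaf_labels()
    if len(labels) < 4:
        raise ValueError("tree has <4 leaves: no internal edge to evaluate")

    def is_target(lab: str) -> bool:
        g = groups.resolve(lab)
        return g in ("query", "other_paulinella") or donor in _EXPANSION[g]

    target_total = sum(1 for lab in labels if is_target(lab))
    out: list[CladeCandidate] = []
    for side, support in _bipartitions(tree):
        if len(side) < 2:
            continue
        n_target = sum(1 for lab in side if is_target(lab))
        n_query = sum(1 for lab in side if groups.resolve(lab) == "query")
        n_donor = sum(1 for lab in side if donor in _EXPANSION[groups.resolve(lab)])
        if support < params.min_support:
            continue
        if n_target / len(side) < params.clade_exclusivity:
            continue
        if target_total == 0 or n_target < params.min_prop_target * target_total:
            continue
        if n_query < 1 or n_donor < 1:
            continue
        tally: dict[str, int] = {}
        for lab in side:
            g = groups.resolve(lab)
            tally[g] = tally.get(g, 0) + 1
        out.append(
            CladeCandidate(
                leaves=side, support=support, node_id=f"side_of_{min(side)}", tally=tally
            )
        )
    out.sort(key=lambda c: (c.size, sorted(c.leaves)))
    return out


def sort_tree(
    tree: TreeNode,
    groups: TaxonGroupMap,
    params: SortParams | None = None,
    tree_id: str = "",
) -> SortOutcome:
    """Classify one gene tree as HGT, EGT, negative, or discarded.

    Discard filters run first. EGT — a supported cyanobacterial clade
    holding the query together with at least one alpha-cyanobacterium —
    overrides HGT. The reported clade is the smallest qualifying one.
    """
    params = params or SortParams()
    reason = apply_discard_filters(tree, groups, params)
    if reason is not None:
        return SortOutcome(tree_id=tree_id, verdict="discarded", discard_reason=reason)

    egt = [
        c
        for c in find_target_clades(tree, groups, params, donor_group="cyanobacteria")
        if any(groups.resolve(lab) == "alpha_cyanobacteria" for lab in c.leaves)
    ]
    if egt:
        return SortOutcome(tree_id=tree_id, verdict="EGT", clade=egt[0])
    hgt = find_target_clades(tree, groups, params, donor_group="bacteria")
    if hgt:
        return SortOutcome(tree_id=tree_id, verdict="HGT", clade=hgt[0])
    return SortOutcome(tree_id=tree_id, verdict="negative")


def sort_trees(
    trees: Iterable[tuple[str, TreeNode]],
    groups: TaxonGroupMap,
    params: SortParams | None = None,
) -> list[SortOutcome]:
    return [sort_tree(t, groups, params, tree_id=tid) for tid, t in trees]


def write_verdicts(outcomes: Sequence[SortOutcome], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("tree_id\tverdict\tdiscard_reason\tclade_size\tclade_support\n")
        for o in outcomes:
            size = o.clade.size if o.clade else ""
            sup = format(o.clade.support, "g") if o.clade else ""
            fh.write(f"{o.tree_id}\t{o.verdict}\t{o.discard_reason or ''}\t{size}\t{sup}\n")
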