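"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by exhaustive enumeration or a direct
textbook algorithm, sharing no code path with the implementation it
checks.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np

from chromaforge.core_io import TreeNode


# ---------------------------------------------------------------------------
# Smith-Waterman: quadratic affine-gap DP (Gotoh), plain Python
# ---------------------------------------------------------------------------

def sw_score(a: str, b: str, sub, gap_open: int = -11, gap_extend: int = -1) -> float:
    """Optimal local alignment score; a gap of length k scores
    gap_open + k * gap_extend."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(
                H[i][j - 1] + gap_open + gap_extend, E[i][j - 1] + gap_extend
            )
            F[i][j] = max(
                H[i - 1][j] + gap_open + gap_extend, F[i - 1][j] + gap_extend
            )
            s = float(sub[a[i - 1], b[j - 1]])
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


# ---------------------------------------------------------------------------
# Dollo parsimony: exhaustive single-gain enumeration
# ---------------------------------------------------------------------------

def enumerate_tree_shapes(n_leaves: int) -> list[TreeNode]:
    """All rooted (multifurcating) tree shapes with exactly n labelled
    leaves L1..Ln, one representative labelling per shape."""

    def shapes(n: int) -> list:
        # shape = tuple of child shapes (sorted), leaf = ()
        if n == 1:
            return [()]
        out = set()

        def partitions(k: int, max_part: int):
            if k == 0:
                yield []
                return
            for p in range(min(k, max_part), 0, -1):
                for rest in partitions(k - p, p):
                    yield [p] + rest

        for part in partitions(n, n - 1):
            if len(part) < 2:
                continue
            child_lists = [shapes(p) for p in part]
            for combo in itertools.product(*child_lists):
                out.add(tuple(sorted(combo)))
        return sorted(out)

    def build(shape, counter) -> TreeNode:
        if shape == ():
            counter[0] += 1
            return TreeNode(label=f"L{counter[0]}")
        return TreeNode(children=[build(c, counter) for c in shape])

    result = []
    for shape in shapes(n_leaves):
        counter = [0]
        result.append(build(shape, counter))
    return result


def dollo_bruteforce(tree: TreeNode, presence: dict[str, bool]) -> tuple[int, set[str]]:
    """Minimum loss count over all valid single-gain state assignments.

    Enumerates every assignment of present/absent to internal nodes with
    leaves fixed to the observed states, keeps those where the present set
    is connected with a single topmost node (the gain), and returns
    (min_losses, set of optimal gain-node frozensets-of-leaves) — the gain
    node is identified by its subtending leaf set.
    """
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    parent = {}
    for n in nodes:
        for c in n.children:
            parent[id(c)] = n
    leaves_under = {
        id(n): frozenset(n.leaf_labels()) for n in nodes
    }
    best = None
    best_gains: set = set()
    for bits in itertools.product([False, True], repeat=len(internal)):
        state = {id(n): b for n, b in zip(internal, bits)}
        for n in nodes:
            if n.is_leaf:
                state[id(n)] = presence[n.label]
        present_nodes = [n for n in nodes if state[id(n)]]
        if not present_nodes:
            continue
        # single gain: exactly one present node whose parent is absent/none
        gains = [
            n
            for n in present_nodes
            if id(n) not in parent or not state[id(parent[id(n)])]
        ]
        if len(gains) != 1:
            continue
        losses = sum(
            1
            for n in nodes
            if id(n) in parent and state[id(parent[id(n)])] and not state[id(n)]
        )
        if best is None or losses < best:
            best = losses
            best_gains = {leaves_under[id(gains[0])]}
        elif losses == best:
            best_gains.add(leaves_under[id(gains[0])])
    return best, best_gains


# ---------------------------------------------------------------------------
# JTK null: exhaustive permutation enumeration
# ---------------------------------------------------------------------------

def jtk_null_enumeration(sizes: tuple[int, ...]) -> dict[int, float]:
    """Exact pmf of Kendall S by enumerating all n! orderings (n <= 8)."""
    n = sum(sizes)
    ref = np.repeat(np.arange(len(sizes)), sizes)
    iu = np.triu_indices(n, k=1)
    dr = np.sign(ref[iu[0]] - ref[iu[1]])
    perms = np.array(list(itertools.permutations(range(n))))
    dx = np.sign(perms[:, iu[0]] - perms[:, iu[1]])
    s = (dx * dr[None, :]).sum(axis=1)
    cnt = Counter(s.tolist())
    total = perms.shape[0]
    return {int(k): v / total for k, v in cnt.items()}


# ---------------------------------------------------------------------------
# Profile Viterbi: exhaustive path enumeration (tiny profiles)
# ---------------------------------------------------------------------------

def viterbi_bruteforce(profile, seq: str) -> float:
    """Best local profile-sequence path score by explicit enumeration.

    Paths enter at any match state/residue for free, move through
    match/insert/delete states with the profile's transition costs
    (inserts emit at background, log-odds 0), and exit at any match state.
    """
    from chromaforge.core_io import PROTEIN_ALPHABET

    aa_index = {aa: i for i, aa in enumerate(PROTEIN_ALPHABET)}
    K = profile.n_match
    t = profile.transitions
    lo = profile.log_odds
    L = len(seq)

    def emit(i: int, j: int) -> float:
        ai = aa_index.get(seq[i])
        return float(lo[j, ai]) if ai is not None else 0.0

    best = 0.0
    # state: (i next residue index, j next match state index, prev state)
    def extend(i: int, j: int, prev: str, score: float):
        nonlocal best
        if prev == "M":
            best = max(best, score)
        if i <= L - 1 and j <= K - 1:  # match next
            cost = {"M": t["MM"], "I": t["IM"], "D": t["DM"]}[prev]
            extend(i + 1, j + 1, "M", score + cost + emit(i, j))
        if i <= L - 1 and prev in ("M", "I"):  # insert
            cost = t["MI"] if prev == "M" else t["II"]
            extend(i + 1, j, "I", score + cost)
        if j <= K - 1 and prev in ("M", "D"):  # delete
            cost = t["MD"] if prev == "M" else t["DD"]
            extend(i, j + 1, "D", score + cost)

    for i0 in range(L):
        for j0 in range(K):
            extend(i0 + 1, j0 + 1, "M", emit(i0, j0))
    return best


# ---------------------------------------------------------------------------
# Coverage: per-base boolean counting
# ---------------------------------------------------------------------------

def breadth_bruteforce(region_ivs, aln_ivs, genome_len: int = 10_000) -> tuple[int, int]:
    """(covered_bases, total_bases) of a region set by per-base counting."""
    region_mask = np.zeros(genome_len, dtype=bool)
    for s, e in region_ivs:
        region_mask[s:e] = True
    aln_mask = np.zeros(genome_len, dtype=bool)
    for s, e in aln_ivs:
        aln_mask[s:e] = True
    return int((region_mask & aln_mask).sum()), int(region_mask.sum())
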