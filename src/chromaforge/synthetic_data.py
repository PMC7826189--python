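"""Seeded synthetic inputs for every pipeline stage, with ground truth.

Each generator emulates the statistical structure its downstream stage
assumes — proteomes with planted N-terminal crTP-like blocks, OGF
presence/absence evolved under single-gain/multiple-loss dynamics, gene
trees with planted donor clades, cosine-rhythmic replicated count
matrices, and short-read alignments over labelled viral/non-viral region
blocks — and returns a machine-readable truth record alongside the data.

All randomness flows from one root seed; every generator draws from an
independent substream keyed by its name, so adding a generator never
perturbs the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import (
    CountMatrix,
    FamilyMatrix,
    Interval,
    SampleMeta,
    SequenceRecord,
    TreeNode,
    write_bed,
    write_counts,
    write_fasta,
    write_newick,
    write_ogf_table,
)
from .crtp_predict import DEFAULT_BACKGROUND, sample_background_sequence
from .ogf_evolution import IndexedTree
from .region_coverage import RegionClassMap
from .tree_sort import TaxonGroupMap

_AAS = list(DEFAULT_BACKGROUND)
_AA_P = np.array([DEFAULT_BACKGROUND[a] for a in _AAS])
_AA_P = _AA_P / _AA_P.sum()


@dataclass
class SynthConfig:
    """One seeded configuration for the whole synthetic bundle.

    Defaults mirror the study design the pipeline targets: a 4-timepoint
    (0/6/12/18 h) x 3-replicate diurnal series, ~200-aa transit peptides,
    and a clear viral vs non-viral read-depth contrast.
    """

    seed: int = 0
    # gene-family evolution
    n_species: int = 8
    n_families: int = 300
    gain_loss_rates: tuple[float, float] = (1.0, 0.1)  # (gain weight, per-branch loss prob)
    # proteome / crTP planting
    n_proteins: int = 500
    crtp_length: int = 200
    n_planted_crtp: int = 50
    n_decoy_crtp: int = 20
    n_diverged_crtp: int = 0
    diverged_mutation: float = 0.65
    n_seed_crtps: int = 10
    seed_noise: float = 0.10  # per-position substitution rate of the crTP family
    max_protein_length: int = 700
    # expression time course
    n_genes_expr: int = 1200
    frac_rhythmic: float = 1.0 / 6.0
    amplitude_over_sigma: float = 3.0
    timepoints_h: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0)
    n_replicates: int = 3
    noise_cv: float = 0.2
    baseline_range: tuple[float, float] = (200.0, 1000.0)
    # gene trees
    n_gene_trees: int = 200
    frac_hgt: float = 0.4
    frac_egt: float = 0.2
    frac_fodder: float = 0.1
    # regions and reads
    genome_len: int = 100_000
    frac_viral: float = 0.3
    n_region_blocks: int = 10
    read_len: int = 100
    read_depth_nonviral: float = 0.8
    read_depth_viral: float = 0.03

    def __post_init__(self) -> None:
        for name in ("n_species", "n_families", "n_proteins", "crtp_length",
                     "n_genes_expr", "n_gene_trees", "genome_len", "read_len",
                     "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_rhythmic", "frac_hgt", "frac_egt", "frac_fodder",
                     "frac_viral", "diverged_mutation", "seed_noise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_planted_crtp > self.n_proteins:
            raise ValueError("n_planted_crtp exceeds n_proteins")
        if self.crtp_length + 250 + 50 > self.max_protein_length:
            raise ValueError(
                "max_protein_length too small for prefix + crTP + mature tail"
            )
        if self.read_len > self.genome_len:
            raise ValueError("read_len exceeds genome_len")
        if self.amplitude_over_sigma < 0:
            raise ValueError("amplitude_over_sigma must be >= 0")


def substream(config: SynthConfig, name: str) -> np.random.Generator:
    """Independent RNG substream keyed by (root seed, generator name)."""
    return np.random.default_rng([config.seed, zlib.crc32(name.encode()) & 0x7FFFFFFF])


# ---------------------------------------------------------------------------
# Species tree and gene-family evolution
# ---------------------------------------------------------------------------

def random_species_tree(config: SynthConfig) -> TreeNode:
    """Random rooted binary species tree over S1..Sn (random splits)."""
    rng = substream(config, "species_tree")
    labels = [f"S{i + 1}" for i in range(config.n_species)]

    def build(names: list[str]) -> TreeNode:
        if len(names) == 1:
            return TreeNode(label=names[0], branch_length=0.1)
        k = int(rng.integers(1, len(names)))
        left, right = names[:k], names[k:]
        return TreeNode(
            children=[build(left), build(right)],
            support=100.0,
            branch_length=0.1,
        )

    perm = [labels[i] for i in rng.permutation(config.n_species)]
    root = build(perm)
    root.branch_length = None
    return root


def simulate_family_evolution(
    config: SynthConfig, species_tree: TreeNode | None = None
) -> tuple[FamilyMatrix, dict]:
    """Evolve OGF presence/absence under single-gain / multiple-loss rules.

    Each family originates once on a uniformly chosen branch (the root
    counts as a branch, giving families ancestral to all species); every
    branch below the gain then loses the family independently with the
    configured probability, with no regain below a loss. Families that end
    up extant nowhere are discarded and regenerated (bounded retries).

    Returns the matrix and a truth record with each family's gain node and
    realised loss branches (node ids as in
    :class:`~chromaforge.ogf_evolution.IndexedTree`).
    """
    tree = species_tree if species_tree is not None else random_species_tree(config)
    it = IndexedTree(tree)
    rng = substream(config, "family_evolution")
    loss_p = config.gain_loss_rates[1]
    if not (0.0 <= loss_p <= 1.0):
        raise ValueError("loss probability must be in [0, 1]")

    n_nodes = len(it)
    children_of = [
        [it.index[id(c)] for c in node.children] for node in it.nodes
    ]
    root_idx = n_nodes - 1  # postorder: root last

    families: list[str] = []
    rows: list[np.ndarray] = []
    gene_map: dict[str, dict[str, list[str]]] = {}
    truth_fams: dict[str, dict] = {}
    max_attempts = 200 * config.n_families
    attempts = 0
    f = 0
    while f < config.n_families:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "family regeneration attempts exhausted (loss rate too high?)"
            )
        gain = int(rng.integers(0, n_nodes))
        present = np.zeros(n_nodes, dtype=bool)
        losses: list[int] = []
        # preorder walk from the gain node
        stack = [gain]
        present[gain] = True
        while stack:
            v = stack.pop()
            for c in children_of[v]:
                if rng.random() < loss_p:
                    losses.append(c)
                else:
                    present[c] = True
                    stack.append(c)
        leaf_presence = {
            it.ids[v]
            for v in range(n_nodes)
            if it.nodes[v].is_leaf and present[v]
        }
        if not leaf_presence:
            continue
        fam = f"OG{f + 1:04d}"
        families.append(fam)
        row = np.array([sp in leaf_presence for sp in it.leaf_order])
        rows.append(row)
        gene_map[fam] = {sp: [f"{sp}|{fam}"] for sp in sorted(leaf_presence)}
        truth_fams[fam] = {
            "gain_node": it.ids[gain],
            "loss_branches": sorted(it.ids[v] for v in losses),
            "n_losses": len(losses),
        }
        f += 1

    matrix = FamilyMatrix(
        families=families,
        species=list(it.leaf_order),
        presence=np.array(rows),
        gene_map=gene_map,
    )
    truth = {"families": truth_fams, "loss_prob": loss_p}
    return matrix, truth


def ladder_from_tree(tree: TreeNode, focal: str):
    """Phylostratum ladder along the root-to-focal path (oldest first)."""
    from .ogf_evolution import StratumLadder

    path: list[TreeNode] = []

    def descend(node: TreeNode) -> bool:
        if node.is_leaf:
            if node.label == focal:
                path.append(node)
                return True
            return False
        for c in node.children:
            if descend(c):
                path.append(node)
                return True
        return False

    if not descend(tree):
        raise ValueError(f"focal species {focal!r} not in tree")
    path.reverse()  # root .. focal
    strata: list[tuple[str, frozenset[str]]] = []
    for depth, node in enumerate(path[:-1]):
        on_path = path[depth + 1]
        sibs: set[str] = set()
        for c in node.children:
            if c is not on_path:
                sibs.update(c.leaf_labels())
        if sibs:
            strata.append((f"stratum{depth + 1}", frozenset(sibs)))
    strata.append((focal, frozenset({focal})))
    return StratumLadder(strata)


# ---------------------------------------------------------------------------
# Proteome with planted crTPs
# ---------------------------------------------------------------------------

def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = _AAS[int(rng.integers(0, 20))]
    return "".join(out)


def simulate_proteome(
    config: SynthConfig,
) -> tuple[list[SequenceRecord], dict, list[SequenceRecord]]:
    """Proteome with planted crTP blocks, filter-violating decoys, and
    validated-crTP stand-ins.

    Planted proteins are prefix (0-49 aa) + noisy copy of a shared crTP
    consensus + mature tail (> 250 aa). Decoys carry the same block but
    violate exactly one positional filter (block starting after residue 50,
    or mature tail <= 250 aa) and must be rejected downstream. Optional
    "diverged" proteins carry a heavily mutated block: detectable by
    pairwise homology to a clean crTP but not by the profile, exercising
    the reciprocal-extension route. Background proteins are i.i.d. draws
    from the amino-acid background.
    """
    rng = substream(config, "proteome")
    consensus = sample_background_sequence(rng, config.crtp_length)

    n_special = config.n_planted_crtp + config.n_decoy_crtp + config.n_diverged_crtp
    if n_special > config.n_proteins:
        raise ValueError("planted + decoy + diverged exceeds n_proteins")

    records: list[SequenceRecord] = []
    truth: dict = {
        "consensus": consensus,
        "planted": {},
        "decoys": {},
        "diverged": {},
        "background": [],
    }

    k = 0
    for _ in range(config.n_planted_crtp):
        k += 1
        pid = f"P{k:04d}"
        prefix = int(rng.integers(0, 50))
        tail = int(rng.integers(260, 341))
        block = _mutate(rng, consensus, config.seed_noise)
        seq = (
            sample_background_sequence(rng, prefix)
            + block
            + sample_background_sequence(rng, tail)
        )
        records.append(SequenceRecord(id=pid, seq=seq))
        truth["planted"][pid] = {
            "start": prefix,
            "end": prefix + config.crtp_length,
            "mature_length": tail,
        }
    for d in range(config.n_decoy_crtp):
        k += 1
        pid = f"P{k:04d}"
        block = _mutate(rng, consensus, config.seed_noise)
        if d % 2 == 0:  # violates the start filter only
            prefix = int(rng.integers(60, 121))
            tail = int(rng.integers(260, 341))
            reason = "start"
        else:  # violates the mature-length filter only
            prefix = int(rng.integers(0, 50))
            tail = int(rng.integers(80, 201))
            reason = "mature"
        seq = (
            sample_background_sequence(rng, prefix)
            + block
            + sample_background_sequence(rng, tail)
        )
        records.append(SequenceRecord(id=pid, seq=seq))
        truth["decoys"][pid] = {"reason": reason, "start": prefix}
    for _ in range(config.n_diverged_crtp):
        k += 1
        pid = f"P{k:04d}"
        prefix = int(rng.integers(0, 50))
        tail = int(rng.integers(260, 341))
        block = _mutate(rng, consensus, config.diverged_mutation)
        seq = (
            sample_background_sequence(rng, prefix)
            + block
            + sample_background_sequence(rng, tail)
        )
        records.append(SequenceRecord(id=pid, seq=seq))
        truth["diverged"][pid] = {"start": prefix, "end": prefix + config.crtp_length}
    for _ in range(config.n_proteins - n_special):
        k += 1
        pid = f"P{k:04d}"
        length = int(rng.integers(300, 601))
        records.append(
            SequenceRecord(id=pid, seq=sample_background_sequence(rng, length))
        )
        truth["background"].append(pid)

    perm = rng.permutation(len(records))
    records = [records[i] for i in perm]

    seed_crtps = [
        SequenceRecord(
            id=f"VAL{j + 1:03d}", seq=_mutate(rng, consensus, config.seed_noise)
        )
        for j in range(config.n_seed_crtps)
    ]
    return records, truth, seed_crtps


# ---------------------------------------------------------------------------
# Diurnal expression time course
# ---------------------------------------------------------------------------

def simulate_timecourse(config: SynthConfig) -> tuple[CountMatrix, dict]:
    """Replicated diurnal counts with a planted rhythmic fraction.

    Rhythmic genes follow mean(t) = baseline * (1 + a * cos(2*pi*(t - phi)
    / 24)) with phi drawn from the sampled timepoints and the relative
    amplitude a chosen so that (absolute amplitude) / (noise sd) equals
    ``amplitude_over_sigma``; replicate noise is mean-preserving lognormal
    with the configured CV; values are rounded to integer counts.
    """
    rng = substream(config, "timecourse")
    lo, hi = config.baseline_range
    if lo <= 0:
        raise ValueError("baseline must be positive")
    n = config.n_genes_expr
    a = config.amplitude_over_sigma * config.noise_cv
    n_rhythmic = int(round(config.frac_rhythmic * n)) if a > 0 else 0

    genes = [f"g{i + 1:05d}" for i in range(n)]
    rhythmic_idx = rng.choice(n, size=n_rhythmic, replace=False) if n_rhythmic else np.array([], int)
    phases = rng.choice(config.timepoints_h, size=n_rhythmic)
    baselines = rng.uniform(lo, hi, size=n)

    samples = [
        SampleMeta(condition="CL", timepoint_h=t, replicate=r + 1)
        for t in config.timepoints_h
        for r in range(config.n_replicates)
    ]
    times = np.array([s.timepoint_h for s in samples])

    mean = np.tile(baselines[:, None], (1, len(samples)))
    phase_of: dict[str, float] = {}
    for j, gi in enumerate(rhythmic_idx):
        mean[gi] = baselines[gi] * (
            1.0 + a * np.cos(2 * np.pi * (times - phases[j]) / 24.0)
        )
        phase_of[genes[gi]] = float(phases[j])

    sigma_ln = np.sqrt(np.log1p(config.noise_cv**2))
    noise = np.exp(
        rng.normal(0.0, sigma_ln, size=mean.shape) - sigma_ln**2 / 2.0
    )
    values = np.rint(mean * noise)
    matrix = CountMatrix(genes=genes, samples=samples, values=values)
    truth = {
        "rhythmic": phase_of,
        "amplitude_rel": a,
        "amplitude_over_sigma": config.amplitude_over_sigma,
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# Gene trees with planted HGT/EGT clades
# ---------------------------------------------------------------------------

DEFAULT_GROUP_PREFIXES = {
    "KR01_": "query",
    "Pchr_": "other_paulinella",
    "BAC_": "bacteria",
    "CYA_": "cyanobacteria",
    "ACY_": "alpha_cyanobacteria",
    "EUK_": "eukarya",
    "ARC_": "archaea",
}


def default_taxon_groups() -> TaxonGroupMap:
    return TaxonGroupMap(prefixes=DEFAULT_GROUP_PREFIXES)


def _random_clade(
    rng: np.random.Generator, leaves: list[str], support: float | None = None
) -> TreeNode:
    """Random binary subtree over the given leaves, internal support high."""
    if len(leaves) == 1:
        return TreeNode(label=leaves[0], branch_length=0.1)
    k = int(rng.integers(1, len(leaves)))
    sup = support if support is not None else float(rng.integers(85, 101))
    return TreeNode(
        children=[_random_clade(rng, leaves[:k]), _random_clade(rng, leaves[k:])],
        support=sup,
        branch_length=0.1,
    )


def _names(prefix: str, n: int, offset: int = 0) -> list[str]:
    return [f"{prefix}{offset + i + 1:03d}" for i in range(n)]


def simulate_gene_trees(
    config: SynthConfig, taxon_groups: TaxonGroupMap | None = None
) -> tuple[list[tuple[str, TreeNode]], dict]:
    """Gene trees with planted HGT/EGT clades, negatives and filter-fodder.

    HGT-true trees nest the query exclusively among non-cyano bacteria with
    support 100 on the planted edge; EGT-true trees nest it among
    alpha-cyanobacteria inside a cyanobacterial clade; negative trees place
    it among eukaryotes (with a separate bacterial clade so discard filters
    pass); fodder trees violate exactly one discard filter, recorded in
    truth.
    """
    rng = substream(config, "gene_trees")
    n = config.n_gene_trees
    n_hgt = int(round(config.frac_hgt * n))
    n_egt = int(round(config.frac_egt * n))
    n_fod = int(round(config.frac_fodder * n))
    n_neg = n - n_hgt - n_egt - n_fod
    if min(n_hgt, n_egt, n_fod, n_neg) < 0:
        raise ValueError("tree-class fractions exceed 1")

    trees: list[tuple[str, TreeNode]] = []
    truth: dict = {}

    def planted_hgt(i: int) -> TreeNode:
        nb = int(rng.integers(6, 10))
        ne = int(rng.integers(3, 6))
        bact = _names("BAC_", nb, offset=i * 20)
        euks = _names("EUK_", ne, offset=i * 20)
        inner = _random_clade(rng, bact[1:])
        donor = TreeNode(
            children=[
                TreeNode(
                    children=[
                        TreeNode(label=f"KR01_g{i + 1:03d}", branch_length=0.1),
                        TreeNode(label=bact[0], branch_length=0.1),
                    ],
                    support=100.0,
                    branch_length=0.1,
                ),
                inner,
            ],
            support=100.0,
            branch_length=0.1,
        )
        return TreeNode(children=[donor, _random_clade(rng, euks)], support=100.0)

    def planted_egt(i: int) -> TreeNode:
        na = int(rng.integers(3, 5))
        nc = int(rng.integers(2, 4))
        ne = int(rng.integers(4, 7))
        alphas = _names("ACY_", na, offset=i * 20)
        cyans = _names("CYA_", nc, offset=i * 20)
        euks = _names("EUK_", ne, offset=i * 20)
        alpha_clade = TreeNode(
            children=[
                TreeNode(
                    children=[
                        TreeNode(label=f"KR01_g{i + 1:03d}", branch_length=0.1),
                        TreeNode(label=alphas[0], branch_length=0.1),
                    ],
                    support=100.0,
                    branch_length=0.1,
                ),
                _random_clade(rng, alphas[1:]),
            ],
            support=100.0,
            branch_length=0.1,
        )
        cyano_clade = TreeNode(
            children=[alpha_clade, _random_clade(rng, cyans)],
            support=100.0,
            branch_length=0.1,
        )
        return TreeNode(children=[cyano_clade, _random_clade(rng, euks)], support=100.0)

    def negative(i: int) -> TreeNode:
        nb = int(rng.integers(5, 9))
        ne = int(rng.integers(4, 7))
        bact = _names("BAC_", nb, offset=i * 20)
        euks = _names("EUK_", ne, offset=i * 20)
        euk_clade = TreeNode(
            children=[
                TreeNode(
                    children=[
                        TreeNode(label=f"KR01_g{i + 1:03d}", branch_length=0.1),
                        TreeNode(label=euks[0], branch_length=0.1),
                    ],
                    support=float(rng.integers(85, 101)),
                    branch_length=0.1,
                ),
                _random_clade(rng, euks[1:]),
            ],
            support=float(rng.integers(85, 101)),
            branch_length=0.1,
        )
        return TreeNode(
            children=[euk_clade, _random_clade(rng, bact)], support=100.0
        )

    def fodder(i: int, kind: int) -> tuple[TreeNode, str]:
        if kind == 0:  # too few leaves (8 < 10)
            bact = _names("BAC_", 5, offset=i * 20)
            euks = _names("EUK_", 2, offset=i * 20)
            tree = TreeNode(
                children=[
                    TreeNode(
                        children=[
                            TreeNode(label=f"KR01_g{i + 1:03d}", branch_length=0.1),
                            _random_clade(rng, bact),
                        ],
                        support=100.0,
                        branch_length=0.1,
                    ),
                    _random_clade(rng, euks),
                ],
                support=100.0,
            )
            return tree, "leaves<10"
        if kind == 1:  # too few bacterial taxa (4 < 5)
            bact = _names("BAC_", 4, offset=i * 20)
            euks = _names("EUK_", 6, offset=i * 20)
            tree = TreeNode(
                children=[
                    TreeNode(
                        children=[
                            TreeNode(label=f"KR01_g{i + 1:03d}", branch_length=0.1),
                            _random_clade(rng, bact),
                        ],
                        support=100.0,
                        branch_length=0.1,
                    ),
                    _random_clade(rng, euks),
                ],
                support=100.0,
            )
            return tree, "bacteria<5"
        # two Paulinella leaves on opposite sides of every edge
        bact = _names("BAC_", 6, offset=i * 20)
        euks = _names("EUK_", 4, offset=i * 20)
        left = TreeNode(
            children=[
                TreeNode(label=f"KR01_g{i + 1:03d}a", branch_length=0.1),
                _random_clade(rng, bact),
            ],
            support=100.0,
            branch_length=0.1,
        )
        right = TreeNode(
            children=[
                TreeNode(label=f"KR01_g{i + 1:03d}b", branch_length=0.1),
                _random_clade(rng, euks),
            ],
            support=100.0,
            branch_length=0.1,
        )
        return TreeNode(children=[left, right], support=100.0), "paulinella_polyphyly"

    i = 0
    for _ in range(n_hgt):
        tid = f"tree{i + 1:04d}"
        trees.append((tid, planted_hgt(i)))
        truth[tid] = {"verdict": "HGT"}
        i += 1
    for _ in range(n_egt):
        tid = f"tree{i + 1:04d}"
        trees.append((tid, planted_egt(i)))
        truth[tid] = {"verdict": "EGT"}
        i += 1
    for _ in range(n_neg):
        tid = f"tree{i + 1:04d}"
        trees.append((tid, negative(i)))
        truth[tid] = {"verdict": "negative"}
        i += 1
    for j in range(n_fod):
        tid = f"tree{i + 1:04d}"
        tree, reason = fodder(i, j % 3)
        trees.append((tid, tree))
        truth[tid] = {"verdict": "discarded", "reason": reason}
        i += 1
    return trees, truth


# ---------------------------------------------------------------------------
# Regions and reads
# ---------------------------------------------------------------------------

def _breadth_se(depth: float, read_len: int, block_lengths: list[int]) -> float:
    """Analytic SE of the breadth fraction under the Poisson read model.

    Base x is uncovered iff no read start falls in its length-L window
    (rate lam = depth / L per position), so P(covered) = 1 - exp(-depth);
    bases closer than L share window positions, giving
    Cov(d) = exp(-lam * (L + d)) - exp(-2 * depth) for |x - y| = d < L.
    """
    lam = depth / read_len
    p_unc = np.exp(-depth)
    var_total = 0.0
    total = sum(block_lengths)
    d = np.arange(1, read_len)
    cov = np.exp(-lam * (read_len + d)) - p_unc**2
    for t in block_lengths:
        var = t * p_unc * (1 - p_unc)
        w = np.clip(t - d, 0, None)
        var += 2.0 * float((w * cov).sum())
        var_total += var
    return float(np.sqrt(var_total) / total) if total else 0.0


def simulate_regions_and_reads(
    config: SynthConfig,
) -> tuple[RegionClassMap, list[Interval], dict]:
    """Alternating viral/non-viral blocks with class-specific read depth.

    Read starts are Poisson-placed at rate depth/read_len per position over
    each block (window extended read_len - 1 upstream, reads clipped to the
    block), so each base's coverage count is exactly Poisson(depth) and the
    expected breadth is exactly 1 - exp(-depth). Truth records the analytic
    expectation and its standard error per class.
    """
    if not (0.0 < config.frac_viral < 1.0):
        raise ValueError("frac_viral must be in (0, 1)")
    rng = substream(config, "regions_reads")
    contig = "chr1"
    half = config.n_region_blocks // 2
    n_viral = max(half, 1)
    n_nonviral = config.n_region_blocks - n_viral
    viral_total = int(config.genome_len * config.frac_viral)
    nonviral_total = config.genome_len - viral_total

    blocks: list[tuple[int, int, str]] = []
    pos = 0
    for b in range(config.n_region_blocks):
        if b % 2 == 0:
            length = nonviral_total // n_nonviral
            cls = "nonviral"
        else:
            length = viral_total // n_viral
            cls = "viral"
        if b == config.n_region_blocks - 1:
            length = config.genome_len - pos
        blocks.append((pos, pos + length, cls))
        pos += length

    regions = RegionClassMap(
        intervals=[Interval(contig, s, e, cls) for s, e, cls in blocks]
    )

    depth_of = {"viral": config.read_depth_viral, "nonviral": config.read_depth_nonviral}
    L = config.read_len
    alignments: list[Interval] = []
    ridx = 0
    for s, e, cls in blocks:
        depth = depth_of[cls]
        if depth <= 0:
            continue
        lam = depth / L
        window = (e - s) + L - 1
        n_reads = int(rng.poisson(lam * window))
        starts = rng.integers(s - (L - 1), e, size=n_reads)
        for st in sorted(starts.tolist()):
            a, b2 = max(st, s), min(st + L, e)
            if a < b2:
                ridx += 1
                alignments.append(Interval(contig, int(a), int(b2), f"read{ridx}"))

    truth = {
        cls: {
            "depth": depth_of[cls],
            "expected_breadth": float(1.0 - np.exp(-depth_of[cls])),
            "breadth_se": _breadth_se(
                depth_of[cls], L, [e - s for s, e, c in blocks if c == cls]
            ),
            "total_bases": sum(e - s for s, e, c in blocks if c == cls),
        }
        for cls in ("viral", "nonviral")
    }
    return regions, alignments, truth


# ---------------------------------------------------------------------------
# Whole-bundle generation
# ---------------------------------------------------------------------------

@dataclass
class SynthBundle:
    """Everything the pipeline consumes, plus ground truth."""

    config: SynthConfig
    species_tree: TreeNode
    families: FamilyMatrix
    proteome: list[SequenceRecord]
    seed_crtps: list[SequenceRecord]
    counts: CountMatrix
    gene_trees: list[tuple[str, TreeNode]]
    regions: RegionClassMap
    alignments: list[Interval]
    truth: dict


def generate_bundle(config: SynthConfig) -> SynthBundle:
    """Generate the full synthetic input bundle from one configuration."""
    species_tree = random_species_tree(config)
    families, fam_truth = simulate_family_evolution(config, species_tree)
    proteome, prot_truth, seed_crtps = simulate_proteome(config)
    counts, tc_truth = simulate_timecourse(config)
    gene_trees, tree_truth = simulate_gene_trees(config)
    regions, alignments, cov_truth = simulate_regions_and_reads(config)
    return SynthBundle(
        config=config,
        species_tree=species_tree,
        families=families,
        proteome=proteome,
        seed_crtps=seed_crtps,
        counts=counts,
        gene_trees=gene_trees,
        regions=regions,
        alignments=alignments,
        truth={
            "family_evolution": fam_truth,
            "proteome": prot_truth,
            "timecourse": tc_truth,
            "gene_trees": tree_truth,
            "coverage": cov_truth,
        },
    )


def write_bundle(bundle: SynthBundle, out_dir: str | Path) -> None:
    """Write the bundle as plain-text files plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.proteome, out / "proteome.faa")
    write_fasta(bundle.seed_crtps, out / "seeds.faa")
    write_ogf_table(bundle.families, out / "ogf.tsv")
    write_newick(bundle.species_tree, out / "species_tree.nwk")
    tree_dir = out / "gene_trees"
    tree_dir.mkdir(exist_ok=True)
    for tid, tree in bundle.gene_trees:
        write_newick(tree, tree_dir / f"{tid}.nwk")
    write_counts(bundle.counts, out / "counts.tsv")
    write_bed(bundle.regions.intervals, out / "regions.bed")
    write_bed(bundle.alignments, out / "alignments.bed")
    with open(out / "truth.json", "w", newline="\n") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
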