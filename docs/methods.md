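# Methods

`chromaforge` implements, at desk scale, the bespoke computational stages of
a comparative-genomics study of a chromatophore-bearing amoeba: predicting
chromatophore-targeted proteins by their N-terminal transit peptide (crTP),
reconstructing orthologous-gene-family (OGF) gain/loss history under Dollo
parsimony, sorting gene trees for horizontal and endosymbiotic gene transfer
(HGT/EGT), calling diurnally rhythmic genes with a JTK-style nonparametric
test, classifying "dark" genes by homology, and comparing breadth of read
coverage across labelled genomic region classes. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Pairwise homology layer

All similarity searches (crTP seed discovery, reciprocal extension,
cross-species candidate matching, dark-gene classification) run through one
deterministic, exhaustive local-alignment engine: Smith–Waterman with affine
gaps, scored with BLOSUM62, gap open −11 / extend −1 (a gap of length *k*
costs 11 + *k*), the community defaults of the heuristic tools this layer
stands in for. The dynamic programming itself is Biopython's
`PairwiseAligner` (C implementation); the test suite checks it against an
independent, plain-Python quadratic Gotoh DP on random pairs. X residues
score 0 against everything.

Significance uses Karlin–Altschul statistics, E = *K·m·n·*exp(−λ*S*), with
the standard gapped parameters λ = 0.267, *K* = 0.041 and *n* = total
residues of the searched database. No edge-effect or composition correction
is applied: every downstream use is thresholding (1e−20 for seed discovery,
1e−10 for phylogenomic-grade hits and reciprocal extension, 1e−5 for
annotation/dark-gene calls) with orders-of-magnitude margins on the
synthetic data.

A protein is **dark** iff its best hit against the reference database has
E > 1e−5 or it has no hit at all. Dark fractions depend entirely on the
reference database supplied; the package makes no claim about any
particular database release.

## crTP prediction

The crTP is modelled as a position-specific profile with match, insert and
delete states.

1. **Seeds.** Validated crTPs from a sister species are searched against
   the focal proteome; proteome members hit at E ≤ 1e−20 become seeds, and
   the matched region is retained.
2. **Alignment.** Seed regions are aligned progressively in discovery
   order: each new sequence is aligned globally to the running column
   profile (mean BLOSUM62 score against observed column residues, linear
   gap penalty −6), and profile gaps propagate to earlier rows. The crTP
   family is strongly conserved, so this simple scheme suffices; a curated
   alignment can be supplied instead and overrides it.
3. **Profile.** Columns with ≤ 50 % gaps become match states. Emissions are
   (count + 0.5) / (total + 20 × 0.5), converted to log2-odds against a
   Swiss-Prot-like background composition. Transition probabilities
   (M→M/I/D, I→I/M, D→D/M) are estimated from the alignment's gap structure
   with Laplace smoothing and shared across positions.
4. **Calibration.** The profile's null score distribution is fitted on
   i.i.d.-background decoys (default 1,000, length = match states + 50,
   fixed seed): the maximum local Viterbi score per decoy is collected and
   a Gumbel law fitted by the method of moments (λ = π/(σ√6),
   μ = mean − γ/λ). Thereafter E(S) = *n*<sub>db</sub>·exp(−λ(S − μ)).
   Calibration is a modelling choice of this package; other profile tools
   calibrate differently.
5. **Scan.** Each protein is aligned to the profile by Viterbi, local in
   both sequence and profile (free flanking sequence; entry/exit at any
   match state; inserts emit at background, so indels cost transitions
   only). Viterbi rather than a forward sum because the positional filter
   needs unambiguous hit boundaries. A candidate must pass all three
   filters: E ≤ 1e−5, first aligned residue within the first 50 positions
   (0-based start ≤ 49), and mature length (sequence after the crTP) > 250
   aa. Rejected proteins record exactly which filters failed.
6. **Reciprocal extension.** Each predicted crTP region is reused as a
   pairwise query against the not-yet-detected proteins (E ≤ 1e−10 — chosen
   to match the phylogenomic threshold, since no separate value is
   standard — same positional filters, best E per protein). With a sharp
   profile the profile route strictly dominates pairwise detection under
   uniform divergence, so on the synthetic bundle this route adds nothing;
   it exists for the real-data regime where a profile built from a narrow
   seed set misses diverged subfamilies. Its mechanics (filters,
   deduplication, route labels) are tested by withholding proteins from
   the scan.
7. **Shared set.** Candidates of two species are paired by reciprocal best
   hit (bit score, full-length alignment, E ≤ 1e−10 both ways); each id
   appears in at most one pair.

The Viterbi recurrence is checked against exhaustive path enumeration on
profiles with ≤ 5 match states; delete chains use a prefix-max formulation
so the per-row update stays vectorised.

## Dollo parsimony on OGFs

Each family is gained exactly once and may be lost repeatedly. For a family
with extant presence set *S* on a rooted species tree (polytomies allowed):
the gain node is MRCA(*S*); a node below the gain is ancestrally present
iff its subtree contains a member of *S*; a loss is charged to the branch
into a present-parent/absent-child pair. This reconstruction is the
minimal-loss single-gain assignment (the present set must be a rooted
connected subtree covering *S*, and this is the smallest such subtree);
the suite verifies it against exhaustive enumeration of all internal-state
vectors on every rooted shape with ≤ 6 leaves. Per-node ancestral counts
satisfy count(v) = count(parent) + gains(branch) − losses(branch) on every
branch, and leaf counts equal the observed presence data. Families observed
in a single species still receive a gain on the terminal branch. On
simulated single-gain/multiple-loss histories, inferred losses never exceed
the realised losses (parsimony is a lower bound), and with loss
probability 0 the reconstruction matches the generating process exactly.

**Relative age.** A stratum ladder (ordered species sets, oldest →
youngest, youngest = the focal species alone) assigns each family the
oldest stratum its presence set intersects. The ladder ships as editable
user data (YAML), not code. Adding species to a family can only keep its
age or make it older.

**Rhythmic-OGF overlap.** An OGF is rhythmic in a species iff ≥ 1 of its
genes there is rhythmic; the exclusive Venn cells over a species subset sum
to the total number of rhythmic OGFs.

## JTK rhythmicity with exact tie-corrected null

For gene expression sampled at timepoints {0, 6, 12, 18} h × 3 replicates
(period fixed at 24 h — four points at 6-h spacing cannot resolve other
periods), the test statistic is Kendall's S between the observations and a
cosine reference cos(2π(t − lag)/24) evaluated at the timepoints, for each
phase lag. Replicates share their timepoint's reference value, so the
reference has tied groups; ties in the data use sign(0) = 0.

The null distribution of S — all orderings of the data equally likely
against a fixed tied reference — is computed exactly: merging reference
groups one at a time, the concordant-pair count contributed by each merge
is an independent Mann–Whitney variable whose generating function is a
Gaussian binomial coefficient; the pmf of the Jonckheere–Terpstra sum is
their convolution, and S = 2·JT − M with M the number of between-group
pairs. The suite checks this against exhaustive permutation enumeration for
every tie pattern with n ≤ 8 (agreement to < 1e−12 in CDF).

The reported p is the minimum two-tailed exact p over the *distinct*
reference rankings, Bonferroni-multiplied by their number. Lag/sign
combinations that induce the same ranking are counted once: at the 4-point
design, the sign flip of lag ℓ equals lag ℓ + 12, so there are 4 distinct
tests, not 8, and double-counting duplicates would only penalise identical
tests twice. A cosine and the usual asymmetric-triangle reference induce
identical rankings at this design, so only the cosine is implemented.
Constant data yield S = 0, p = 1. The per-gene p is thresholded at the
conventional p < 0.01 without multiplicity correction across genes; a
Benjamini–Hochberg column is emitted alongside for users who want it.
Bonferroni over lags plus the discrete null make the test conservative:
empirical size on null genes runs at ~0.2–0.6 % at the 1 % threshold.

**DEG filtering** keeps genes with padj < 0.05 and |log2FC| > 1, both
strict, from externally produced differential-expression tables; the
rhythmic∩DEG intersection is plain set arithmetic with sizes logged.

## Gene-tree sorting for HGT/EGT

Leaves resolve to taxon groups (query, other *Paulinella*, bacteria ⊃
cyanobacteria ⊃ α-cyanobacteria, eukaryotes, archaea, unknown) by exact
label or longest prefix. Because gene-tree rootings are arbitrary, every
internal edge is evaluated from both sides; the two root-child edges of a
rooted representation collapse to one unrooted edge with the maximum of
their support annotations. Missing supports count as 0 (conservative).

Discard filters run first, in order: < 10 leaves; < 5 bacterial taxa;
multiple *Paulinella* sequences that are not one side of any edge
("polyphyly on every rooting"). A side of an edge is a candidate transfer
clade when (a) its support ≥ 70, (b) ≥ 95 % of its leaves belong to the
target set {query ∪ other *Paulinella* ∪ donor group}, (c) it contains
≥ 70 % of the tree's target leaves, and (d) it holds at least one query and
one donor leaf. The 70 % proportion is taken over target leaves *present in
the tree* (the denominator is not otherwise defined in common usage; this
matches the sorting tools practitioners use). EGT — donor = cyanobacteria
with ≥ 1 α-cyanobacterium in the clade — overrides HGT (donor = bacteria);
otherwise the tree is negative. The smallest qualifying clade is reported.
Verdicts are invariant under re-rooting and can only move toward
"negative" as `min_support` is raised. Alignment-quality screening of the
underlying alignments is out of scope; trees arrive as inputs.

## Region-class coverage

Region classes are unions of labelled half-open intervals (overlaps within
a class are merged). Breadth per class = |union(alignments) ∩
union(class)| / |union(class)|, computed by sweep-line union plus
two-pointer intersection and verified against per-base boolean counting.
Depth is deliberately not computed — the comparison of interest is the
fraction of bases touched at all, per alignment-mode label. All coordinates
are 0-based half-open (BED convention); SAM input is converted at the
boundary using reference-consuming CIGAR operations only; strand is
ignored throughout.

## Synthetic data: what it emulates, and what it does not

One root seed drives every generator through independent substreams keyed
by generator name (PCG64 via `numpy.random.default_rng([seed, crc32(name)])`),
so adding a generator never perturbs the others and identical seeds give
bit-identical bundles.

* **Family evolution** plants each family's gain on a uniformly chosen
  branch (the root included) and loses it independently per descendant
  branch (default loss probability 0.1), with regeneration of extinct
  families; the truth records gain node and realised losses.
* **Proteome** (default 500 proteins): 50 planted proteins = prefix
  (0–49 aa) + crTP block (noisy copy of a shared 200-aa consensus, 10 %
  per-position substitution — the family is strongly conserved) + mature
  tail (260–340 aa > 250); 20 decoys violate exactly one positional filter
  (block starting after residue 50, or mature tail 80–200 aa); the rest are
  i.i.d. background. Validated-crTP stand-ins are further noisy copies of
  the consensus.
* **Time course** (default 1,200 genes, 1/6 rhythmic): rhythmic mean
  baseline·(1 + a·cos(2π(t − φ)/24)) with φ drawn from the sampled
  timepoints; lognormal mean-preserving replicate noise with CV 0.2; a set
  so amplitude/σ = 3; counts rounded to integers. JTK is rank-based, so
  the exact noise family is secondary.
* **Gene trees** (default 200: 80 HGT, 40 EGT, 60 negative, 20 fodder):
  HGT trees nest the query among non-cyano bacteria with support 100 on the
  planted edge; EGT trees nest it among α-cyanobacteria inside a
  cyanobacterial clade; negatives place it inside a eukaryote clade with a
  separate bacterial clade so the discard filters pass; fodder trees
  violate exactly one discard filter each.
* **Regions and reads**: alternating viral/non-viral blocks (default 30 %
  viral of 100 kb); read starts Poisson at rate depth/L per position over
  each block's window extended L − 1 upstream and clipped to the block, so
  each base's coverage count is exactly Poisson(depth) and expected breadth
  is exactly 1 − e^(−depth), with the analytic SE from the window-overlap
  covariance recorded in truth. Default depths 0.8 (non-viral) and 0.03
  (viral) put the expected breadths (~55 % vs ~3 %) in the strongly
  contrasting regime such comparisons address.

The generators share none of the analysis code paths, but they are
idealised: proteins have i.i.d. backgrounds and indel-free crTP blocks;
expression noise is uncorrelated across genes and timepoints; gene trees
are built from clean planted topologies with high supports rather than
inferred from alignments; reads have no mapping error or bias. Passing the
recovery benchmarks therefore demonstrates correctness of the algorithms
under their stated assumptions — not robustness to the noise structure of
real sequencing data.

## Problem sizes and determinism

The shipped benchmarks run on one CPU in a few minutes: the Dollo oracle
sweeps every rooted shape with ≤ 6 leaves × 500 random presence patterns;
the JTK null is enumerated for all 254 tie patterns with n ≤ 8; alignment
and coverage oracles use 200 pairs and 100 instances; the end-to-end demo
uses the default bundle above. These sizes are the package's chosen
desk-scale study conditions. All floating output in reports is printed with
fixed formats, and two runs with the same seed produce byte-identical
reports and truth files.

## Known limitations

* E-values (pairwise and profile) are approximate; they are fit for
  thresholding, not for fine-grained ranking near the cutoff.
* The Gumbel calibration assumes i.i.d.-background decoys; biased-composition
  proteomes would need composition-matched decoys.
* The progressive seed aligner has no iterative refinement; badly diverged
  or indel-rich seed sets deserve an external alignment (supported).
* Dollo parsimony undercounts losses by construction when gains sit above
  the MRCA of the extant members; ancestral counts are parsimony
  reconstructions, not rate-model estimates.
* The sorting screen implements the quantitative filters only; judgements
  like "the alignment lacks conserved regions" are left to the user.
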