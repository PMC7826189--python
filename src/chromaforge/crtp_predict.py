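"""Chromatophore transit-peptide (crTP) import-candidate prediction.

Long proteins imported into the chromatophore carry a conserved ~200-aa
N-terminal transit peptide. The prediction pipeline mirrors how such
candidates are found in practice:

1. *seed discovery* — validated crTPs from a sister species are searched
   against the focal proteome (pairwise local alignment, E <= 1e-20);
2. *profile build* — the matched regions are multiply aligned and turned
   into a position-specific profile (match states at columns with <= 50%
   gaps; emissions with pseudocount 0.5, log-odds vs background);
3. *calibration* — the profile's local-alignment score distribution on
   i.i.d. background decoys is fitted with a Gumbel law (method of
   moments), giving E-values E(S) = n_db * exp(-lambda * (S - mu));
4. *scan* — every protein is aligned to the profile by Viterbi over
   match/insert/delete states with free flanking regions; a candidate must
   satisfy E <= 1e-5, first aligned residue within the first 50 positions,
   and a mature protein (sequence after the crTP) longer than 250 aa;
5. *reciprocal extension* — each predicted crTP region is used as a
   pairwise query against the not-yet-detected proteins (E <= 1e-10, same
   positional filters), catching family members the profile missed;
6. *shared set* — candidates of two species are paired by reciprocal best
   hit on the full-length sequences (E <= 1e-10).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import PROTEIN_ALPHABET, SequenceRecord
from . import homology

logger = logging.getLogger("chromaforge")

#: Average amino-acid composition (Swiss-Prot-like), normalised to 1.
DEFAULT_BACKGROUND: dict[str, float] = {}
_raw_bg = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37, "Q": 3.93,
    "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96, "L": 9.66, "K": 5.84,
    "M": 2.42, "F": 3.86, "P": 4.70, "S": 6.56, "T": 5.34, "W": 1.08,
    "Y": 2.92, "V": 6.87,
}
_total = sum(_raw_bg.values())
DEFAULT_BACKGROUND = {aa: v / _total for aa, v in _raw_bg.items()}

_AA_INDEX = {aa: i for i, aa in enumerate(PROTEIN_ALPHABET)}

#: E-values are clamped away from zero so they stay strictly positive.
_MIN_EVALUE = 1e-300


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class SeedMatch:
    """A proteome member matching a validated crTP, with the matched span."""

    record: SequenceRecord
    region: tuple[int, int]  # half-open on the protein
    evalue: float


@dataclass
class SeedAlignment:
    """Gapped alignment of seed crTP regions ('-' = gap)."""

    members: list[SequenceRecord]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("seed alignment needs >=2 members")
        lengths = {len(m.seq) for m in self.members}
        if len(lengths) != 1:
            raise ValueError("aligned sequences differ in length")
        ncol = lengths.pop()
        if not any(
            all(m.seq[c] != "-" for m in self.members) for c in range(ncol)
        ):
            raise ValueError("alignment has no gap-free column")

    @property
    def n_columns(self) -> int:
        return len(self.members[0].seq)


@dataclass
class ProfileModel:
    """Position-specific profile with affine state transitions.

    ``emissions[j]`` are per-residue probabilities of match state j (sum to
    1); ``log_odds`` their log2 ratio to ``background``. Transitions are
    log2 probabilities shared across positions. ``calibration`` holds the
    Gumbel null fitted on background decoys, required before scanning.
    """

    emissions: np.ndarray  # (n_match, 20) probabilities
    transitions: dict[str, float]  # log2 p for MM, MI, MD, IM, II, DM, DD
    background: np.ndarray  # (20,) probabilities
    calibration: tuple[float, float] | None = None  # (gumbel_mu, gumbel_lambda)
    log_odds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.emissions.ndim != 2 or self.emissions.shape[1] != 20:
            raise ValueError("emissions must be (n_match, 20)")
        if not np.allclose(self.emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("emission rows must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        self.log_odds = np.log2(self.emissions / self.background[None, :])

    @property
    def n_match(self) -> int:
        return self.emissions.shape[0]


@dataclass
class CrTPHit:
    """One predicted crTP on a protein (coordinates 0-based half-open)."""

    protein_id: str
    score_bits: float
    evalue: float
    start: int
    end: int
    mature_length: int
    route: str = "hmm"  # "hmm" | "extension"


@dataclass
class ScanResult:
    """Accepted hits plus, per rejected protein, the filters it failed."""

    hits: list[CrTPHit]
    rejections: dict[str, list[str]]  # protein_id -> subset of {evalue, start, mature}


@dataclass
class ImportCandidateSet:
    """Combined candidates of one species (profile route + extension route)."""

    hmm_hits: list[CrTPHit]
    extension_hits: list[CrTPHit]
    proteome: dict[str, SequenceRecord]

    def __post_init__(self) -> None:
        a = {h.protein_id for h in self.hmm_hits}
        b = {h.protein_id for h in self.extension_hits}
        if a & b:
            raise ValueError(f"hit routes overlap on {sorted(a & b)}")

    @property
    def combined(self) -> list[CrTPHit]:
        return list(self.hmm_hits) + list(self.extension_hits)

    @property
    def ids(self) -> set[str]:
        return {h.protein_id for h in self.combined}


# ---------------------------------------------------------------------------
# Seed discovery and alignment
# ---------------------------------------------------------------------------

def find_seeds(
    validated_crtps: Sequence[SequenceRecord],
    proteome: Sequence[SequenceRecord],
    cutoff: float = 1e-20,
    matrix: homology.SubstitutionMatrix | None = None,
) -> list[SeedMatch]:
    """Proteome members hit by any validated crTP at E <= ``cutoff``.

    The matched region on the proteome member is retained for the seed
    alignment. Zero seeds is an error: the pipeline cannot proceed and the
    cutoff should be relaxed.
    """
    matrix = matrix or homology.blosum62()
    aligner = homology._make_aligner(matrix)
    db_residues = sum(len(p.seq) for p in proteome)
    best: dict[str, SeedMatch] = {}
    order: list[str] = []
    for prot in proteome:
        # score-only pass; align for coordinates only when the pair passes
        top_q, top_s = None, 0.0
        for q in validated_crtps:
            s = float(aligner.score(q.seq, prot.seq))
            if s > top_s:
                top_q, top_s = q, s
        if top_q is None:
            continue
        ev = homology.estimate_evalue(
            top_s, len(top_q.seq), db_residues, matrix.ka_lambda, matrix.ka_k
        )
        if ev > cutoff:
            continue
        h = homology.smith_waterman(top_q, prot, matrix, db_residues=db_residues)
        if h is not None and h.evalue <= cutoff:
            order.append(prot.id)
            best[prot.id] = SeedMatch(
                record=prot, region=(h.t_start, h.t_end), evalue=h.evalue
            )
    if not best:
        raise ValueError(
            f"no seeds found at E <= {cutoff:g}; relax the cutoff or check inputs"
        )
    return [best[pid] for pid in order]


def _profile_columns(rows: list[str]) -> np.ndarray:
    """Residue counts per column of a list of equal-length gapped strings."""
    ncol = len(rows[0])
    counts = np.zeros((ncol, 20))
    for row in rows:
        for c, aa in enumerate(row):
            i = _AA_INDEX.get(aa)
            if i is not None:
                counts[c, i] += 1
    return counts


def progressive_align(
    seeds: Sequence[SeedMatch] | Sequence[SequenceRecord],
    source: str = "progressive",
) -> SeedAlignment:
    """Progressive alignment of seed regions, in discovery order.

    Each sequence is aligned globally to the running column profile
    (average BLOSUM62 score against the column's residues, linear gap
    penalty); profile gaps are propagated to all previous rows. Adequate
    for the strongly conserved crTP family; a hand-curated alignment can be
    supplied instead wherever a :class:`SeedAlignment` is accepted.
    """
    recs: list[SequenceRecord] = []
    for s in seeds:
        if isinstance(s, SeedMatch):
            a, b = s.region
            recs.append(SequenceRecord(id=s.record.id, seq=s.record.seq[a:b]))
        else:
            recs.append(s)
    if len(recs) < 2:
        raise ValueError("need >=2 seeds to align")

    blosum = homology.blosum62().scores
    gap = -6.0
    rows = [recs[0].seq]
    for rec in recs[1:]:
        counts = _profile_columns(rows)
        occ = counts.sum(axis=1)
        # column score against each residue: mean BLOSUM62 over observed
        col_scores = np.zeros((counts.shape[0], 20))
        sub = np.array(
            [[blosum[a, b] for b in PROTEIN_ALPHABET] for a in PROTEIN_ALPHABET]
        )
        nz = occ > 0
        col_scores[nz] = (counts[nz] @ sub) / occ[nz, None]
        seq_idx = np.array([_AA_INDEX.get(aa, -1) for aa in rec.seq])
        n, m = counts.shape[0], len(rec.seq)
        dp = np.zeros((n + 1, m + 1))
        dp[:, 0] = gap * np.arange(n + 1)
        dp[0, :] = gap * np.arange(m + 1)
        ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up(del seq gap), 2 left
        for i in range(1, n + 1):
            sc = np.where(seq_idx >= 0, col_scores[i - 1][np.clip(seq_idx, 0, 19)], 0.0)
            diag = dp[i - 1, :-1] + sc
            up = dp[i - 1, 1:] + gap
            row = dp[i]
            for j in range(1, m + 1):
                left = row[j - 1] + gap
                best = diag[j - 1]
                p = 0
                if up[j - 1] > best:
                    best, p = up[j - 1], 1
                if left > best:
                    best, p = left, 2
                row[j] = best
                ptr[i, j] = p
        # traceback
        i, j = n, m
        new_rows = [""] * len(rows)
        new_seq = ""
        while i > 0 or j > 0:
            if i > 0 and j > 0 and ptr[i, j] == 0:
                for k in range(len(rows)):
                    new_rows[k] = rows[k][i - 1] + new_rows[k]
                new_seq = rec.seq[j - 1] + new_seq
                i, j = i - 1, j - 1
            elif i > 0 and (j == 0 or ptr[i, j] == 1):
                for k in range(len(rows)):
                    new_rows[k] = rows[k][i - 1] + new_rows[k]
                new_seq = "-" + new_seq
                i -= 1
            else:
                for k in range(len(rows)):
                    new_rows[k] = "-" + new_rows[k]
                new_seq = rec.seq[j - 1] + new_seq
                j -= 1
        rows = new_rows + [new_seq]
    members = [
        SequenceRecord(id=r.id, seq=row) for r, row in zip(recs, rows)
    ]
    return SeedAlignment(members=members, source=source)


# ---------------------------------------------------------------------------
# Profile build and calibration
# ---------------------------------------------------------------------------

def build_profile(
    seeds: SeedAlignment,
    background: Mapping[str, float] | None = None,
    pseudocount: float = 0.5,
    max_gap_fraction: float = 0.5,
    min_match_states: int = 10,
) -> ProfileModel:
    """Build a position-specific profile from a seed alignment.

    Columns with at most ``max_gap_fraction`` gaps become match states.
    Emission probabilities are (count + pseudocount) / (total + 20 *
    pseudocount); transition probabilities are estimated from the observed
    gap structure with Laplace smoothing.
    """
    bg_map = dict(background) if background is not None else DEFAULT_BACKGROUND
    bg = np.array([bg_map[aa] for aa in PROTEIN_ALPHABET])
    bg = bg / bg.sum()

    rows = [m.seq for m in seeds.members]
    ncol = seeds.n_columns
    nrow = len(rows)
    gap_frac = np.array(
        [sum(r[c] == "-" for r in rows) / nrow for c in range(ncol)]
    )
    match_cols = [c for c in range(ncol) if gap_frac[c] <= max_gap_fraction]
    if not match_cols:
        raise ValueError("no columns qualify as match states")
    if len(match_cols) < min_match_states:
        raise ValueError(
            f"only {len(match_cols)} match states; need >= {min_match_states}"
        )

    counts = _profile_columns(rows)[match_cols]
    emis = (counts + pseudocount) / (
        counts.sum(axis=1, keepdims=True) + 20.0 * pseudocount
    )

    # Transition counts from per-row state strings over columns:
    # M (residue at match col), D (gap at match col), I (residue at insert col).
    is_match = np.zeros(ncol, dtype=bool)
    is_match[match_cols] = True
    trans = {k: 1.0 for k in ("MM", "MI", "MD", "IM", "II", "DM", "DD")}  # Laplace
    for r in rows:
        states = []
        for c in range(ncol):
            if is_match[c]:
                states.append("M" if r[c] != "-" else "D")
            elif r[c] != "-":
                states.append("I")
        for a, b in zip(states, states[1:]):
            if a + b in trans:
                trans[a + b] += 1.0
    out = {}
    for src, dests in (("M", "MID"), ("I", "IM"), ("D", "DM")):
        tot = sum(trans[src + d] for d in dests)
        for d in dests:
            out[src + d] = math.log2(trans[src + d] / tot)
    return ProfileModel(emissions=emis, transitions=out, background=bg)


def sample_background_sequence(
    rng: np.random.Generator, length: int, background: Mapping[str, float] | None = None
) -> str:
    bg_map = dict(background) if background is not None else DEFAULT_BACKGROUND
    aas = list(bg_map)
    p = np.array([bg_map[a] for a in aas])
    p = p / p.sum()
    return "".join(rng.choice(aas, size=length, p=p))


def calibrate_profile(
    profile: ProfileModel,
    n_decoys: int = 1000,
    decoy_length: int | None = None,
    seed: int = 0,
) -> ProfileModel:
    """Fit the Gumbel null of the profile's local Viterbi score.

    Decoys are drawn i.i.d. from the profile background; the maximum local
    score per decoy is collected and (mu, lambda) fitted by the method of
    moments: lambda = pi / (sd * sqrt(6)), mu = mean - euler_gamma / lambda.
    E-values thereafter are E(S) = n_db * exp(-lambda * (S - mu)).
    """
    if n_decoys < 200:
        raise ValueError("need >= 200 decoys for a stable fit")
    if decoy_length is None:
        decoy_length = profile.n_match + 50
    rng = np.random.default_rng(seed)
    bg_map = {aa: p for aa, p in zip(PROTEIN_ALPHABET, profile.background)}
    scores = np.empty(n_decoys)
    for d in range(n_decoys):
        seq = sample_background_sequence(rng, decoy_length, bg_map)
        scores[d] = viterbi_score(profile, seq)
    sd = scores.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate decoy score distribution (zero variance)")
    lam = math.pi / (sd * math.sqrt(6.0))
    mu = float(scores.mean()) - np.euler_gamma / lam
    profile.calibration = (mu, lam)
    return profile


def profile_evalue(profile: ProfileModel, score: float, n_db: int) -> float:
    if profile.calibration is None:
        raise ValueError("profile is uncalibrated; run calibrate_profile first")
    mu, lam = profile.calibration
    return max(n_db * math.exp(-lam * (score - mu)), _MIN_EVALUE)


# ---------------------------------------------------------------------------
# Viterbi alignment of profile to sequence
# ---------------------------------------------------------------------------

def _viterbi_matrices(
    profile: ProfileModel, seq: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill local Viterbi matrices M, I, D (rows = residues, cols = states).

    Local in both sequence and profile: a path may enter at any match state
    with no cost and exit at any match state; flanking sequence is free.
    Inserts emit at background (log-odds 0), so inserts and deletes cost
    transitions only.
    """
    K = profile.n_match
    t = profile.transitions
    lo = profile.log_odds  # (K, 20)
    idx = np.array([_AA_INDEX.get(aa, -1) for aa in seq])
    L = len(seq)
    NEG = -1e30
    M = np.full((L + 1, K + 1), NEG)
    I = np.full((L + 1, K + 1), NEG)
    D = np.full((L + 1, K + 1), NEG)
    for i in range(1, L + 1):
        ai = idx[i - 1]
        emit = lo[:, ai] if ai >= 0 else np.zeros(K)  # X scores 0
        prevM, prevI, prevD = M[i - 1], I[i - 1], D[i - 1]
        best_in = np.maximum.reduce(
            [
                np.full(K, 0.0),  # free entry
                prevM[:-1] + t["MM"],
                prevI[:-1] + t["IM"],
                prevD[:-1] + t["DM"],
            ]
        )
        M[i, 1:] = emit + best_in
        I[i, 1:] = np.maximum(prevM[1:] + t["MI"], prevI[1:] + t["II"])
        # D along the state axis within row i: prefix-max formulation
        # D[i, j] = max_{k < j} M[i, k] + MD + (j-1-k) * DD
        a = M[i, 1:K] + t["MD"] - np.arange(1, K) * t["DD"]
        if K > 1:
            run = np.maximum.accumulate(a)
            D[i, 2:] = run + np.arange(2, K + 1) * t["DD"] - t["DD"]
    return M, I, D


def viterbi_score(profile: ProfileModel, seq: str) -> float:
    """Best local profile-sequence alignment score in bits (>= 0)."""
    M, _, _ = _viterbi_matrices(profile, seq)
    return float(max(M[:, 1:].max(), 0.0))


def viterbi_align(profile: ProfileModel, seq: str) -> tuple[float, int, int]:
    """Best local alignment: (score_bits, start, end) on the sequence.

    ``start`` is the 0-based index of the first aligned residue, ``end``
    the exclusive index after the last aligned residue. Ties resolve to the
    smallest (start, end).
    """
    M, I, D = _viterbi_matrices(profile, seq)
    body = M[:, 1:]
    score = float(body.max())
    if score <= 0.0:
        return 0.0, 0, 0
    # smallest end residue among optimal exits, then smallest state
    ends = np.argwhere(np.isclose(body, score))
    i_end, j_end = min((int(r) for r, _ in ends)), None
    for r, c in ends:
        if int(r) == i_end:
            j_end = int(c) + 1 if j_end is None else min(j_end, int(c) + 1)
    t = profile.transitions
    lo = profile.log_odds
    idx = np.array([_AA_INDEX.get(aa, -1) for aa in seq])
    i, j, state = i_end, j_end, "M"
    tol = 1e-9
    while True:
        if state == "M":
            ai = idx[i - 1]
            emit = float(lo[j - 1, ai]) if ai >= 0 else 0.0
            rest = M[i, j] - emit
            # prefer extending the alignment (smallest start); entry last
            if abs(M[i - 1, j - 1] + t["MM"] - rest) <= tol:
                i, j = i - 1, j - 1
            elif abs(I[i - 1, j - 1] + t["IM"] - rest) <= tol:
                i, j, state = i - 1, j - 1, "I"
            elif abs(D[i - 1, j - 1] + t["DM"] - rest) <= tol:
                i, j, state = i - 1, j - 1, "D"
            else:
                start = i - 1
                break
        elif state == "I":
            if abs(M[i - 1, j] + t["MI"] - I[i, j]) <= tol:
                i, state = i - 1, "M"
            else:
                i, state = i - 1, "I"
        else:  # D
            if abs(M[i, j - 1] + t["MD"] - D[i, j]) <= tol:
                j, state = j - 1, "M"
            else:
                j, state = j - 1, "D"
    return score, start, i_end


# ---------------------------------------------------------------------------
# Scan, extension, shared set
# ---------------------------------------------------------------------------

def scan_proteome(
    profile: ProfileModel,
    proteome: Sequence[SequenceRecord],
    evalue_cutoff: float = 1e-5,
    max_start: int = 50,
    min_mature: int = 250,
) -> ScanResult:
    """Scan every protein with the calibrated profile and apply the filters.

    A hit is reported iff E <= ``evalue_cutoff`` AND the crTP starts within
    the first ``max_start`` residues (1-based position <= 50) AND the
    mature protein is longer than ``min_mature`` aa. At most one hit per
    protein. Rejected proteins record which filters failed.
    """
    if profile.calibration is None:
        raise ValueError("profile is uncalibrated; run calibrate_profile first")
    n_db = len(proteome)
    hits: list[CrTPHit] = []
    rejections: dict[str, list[str]] = {}
    for prot in proteome:
        score, start, end = viterbi_align(profile, prot.seq)
        ev = profile_evalue(profile, score, n_db)
        mature = len(prot.seq) - end
        failed = []
        if ev > evalue_cutoff:
            failed.append("evalue")
        if start > max_start - 1:
            failed.append("start")
        if mature <= min_mature:
            failed.append("mature")
        if failed:
            rejections[prot.id] = failed
            if ev <= evalue_cutoff:
                logger.info(
                    "scan_proteome: %s rejected (%s): E=%.2g start=%d mature=%d",
                    prot.id, ",".join(failed), ev, start, mature,
                )
            continue
        hits.append(
            CrTPHit(
                protein_id=prot.id,
                score_bits=score,
                evalue=ev,
                start=start,
                end=end,
                mature_length=mature,
                route="hmm",
            )
        )
    return ScanResult(hits=hits, rejections=rejections)


def extend_candidates(
    hmm_hits: Sequence[CrTPHit],
    proteome: Sequence[SequenceRecord],
    cutoff: float = 1e-10,
    max_start: int = 50,
    min_mature: int = 250,
    matrix: homology.SubstitutionMatrix | None = None,
) -> list[CrTPHit]:
    """Recover crTP proteins the profile missed, by pairwise homology.

    Each predicted crTP region is used as a local-alignment query against
    the proteins not already detected; targets passing the same positional
    filters at E <= ``cutoff`` are reported (best E per protein).
    """
    matrix = matrix or homology.blosum62()
    aligner = homology._make_aligner(matrix)
    found = {h.protein_id for h in hmm_hits}
    by_id = {p.id: p for p in proteome}
    rest = [p for p in proteome if p.id not in found]
    db_residues = sum(len(p.seq) for p in rest)
    best: dict[str, CrTPHit] = {}
    for hit in hmm_hits:
        src = by_id[hit.protein_id]
        query = SequenceRecord(
            id=f"{hit.protein_id}:crtp", seq=src.seq[hit.start:hit.end]
        )
        for target in rest:
            # score-only prefilter before materialising coordinates
            s = float(aligner.score(query.seq, target.seq))
            ev = homology.estimate_evalue(
                s, len(query.seq), db_residues, matrix.ka_lambda, matrix.ka_k
            )
            if ev > cutoff:
                continue
            h = homology.smith_waterman(query, target, matrix, db_residues=db_residues)
            if h is None or h.evalue > cutoff:
                continue
            mature = len(target.seq) - h.t_end
            if h.t_start > max_start - 1 or mature <= min_mature:
                continue
            prev = best.get(target.id)
            if prev is None or h.evalue < prev.evalue:
                best[target.id] = CrTPHit(
                    protein_id=target.id,
                    score_bits=h.bits,
                    evalue=h.evalue,
                    start=h.t_start,
                    end=h.t_end,
                    mature_length=mature,
                    route="extension",
                )
    return [best[pid] for pid in sorted(best)]


def predict_import_candidates(
    proteome: Sequence[SequenceRecord],
    validated_crtps: Sequence[SequenceRecord],
    seed_alignment: SeedAlignment | None = None,
    seed_cutoff: float = 1e-20,
    scan_cutoff: float = 1e-5,
    extension_cutoff: float = 1e-10,
    max_start: int = 50,
    min_mature: int = 250,
    n_decoys: int = 1000,
    calibration_seed: int = 0,
) -> tuple[ImportCandidateSet, ScanResult, ProfileModel]:
    """Full pipeline: seeds -> profile -> calibrate -> scan -> extend."""
    if seed_alignment is None:
        seeds = find_seeds(validated_crtps, proteome, cutoff=seed_cutoff)
        seed_alignment = progressive_align(seeds)
    profile = build_profile(seed_alignment)
    calibrate_profile(profile, n_decoys=n_decoys, seed=calibration_seed)
    scan = scan_proteome(
        profile, proteome, evalue_cutoff=scan_cutoff,
        max_start=max_start, min_mature=min_mature,
    )
    ext = extend_candidates(
        scan.hits, proteome, cutoff=extension_cutoff,
        max_start=max_start, min_mature=min_mature,
    )
    cand = ImportCandidateSet(
        hmm_hits=scan.hits,
        extension_hits=ext,
        proteome={p.id: p for p in proteome},
    )
    return cand, scan, profile


def shared_candidates(
    set_a: ImportCandidateSet,
    set_b: ImportCandidateSet,
    evalue_cutoff: float = 1e-10,
) -> list[tuple[str, str]]:
    """Import candidates shared between two species.

    Reciprocal best hits (by bit score, full-length pairwise alignment)
    between the two candidate sets at E <= ``evalue_cutoff``; each id
    appears in at most one pair.
    """
    recs_a = [set_a.proteome[i] for i in sorted(set_a.ids)]
    recs_b = [set_b.proteome[i] for i in sorted(set_b.ids)]
    if not recs_a or not recs_b:
        return []
    return homology.reciprocal_best_hits(recs_a, recs_b, evalue_cutoff=evalue_cutoff)


def write_hits_table(candidates: ImportCandidateSet, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("protein_id\tbits\tevalue\tstart\tend\tmature_length\troute\n")
        for h in candidates.combined:
            fh.write(
                f"{h.protein_id}\t{h.score_bits:.2f}\t{h.evalue:.3g}\t"
                f"{h.start}\t{h.end}\t{h.mature_length}\t{h.route}\n"
            )
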