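"""crTP prediction: profile arithmetic, calibration, Viterbi, filters, routes."""

import numpy as np
import pytest

from chromaforge.core_io import PROTEIN_ALPHABET, SequenceRecord
from chromaforge.crtp_predict import (
    DEFAULT_BACKGROUND,
    ImportCandidateSet,
    ProfileModel,
    SeedAlignment,
    build_profile,
    calibrate_profile,
    extend_candidates,
    find_seeds,
    predict_import_candidates,
    profile_evalue,
    progressive_align,
    sample_background_sequence,
    scan_proteome,
    shared_candidates,
    viterbi_align,
    viterbi_score,
)
from chromaforge.synthetic_data import SynthConfig, simulate_proteome

from _oracles import viterbi_bruteforce


@pytest.fixture(scope="module")
def proteome_fixture():
    cfg = SynthConfig(
        seed=11,
        n_proteins=60,
        n_planted_crtp=8,
        n_decoy_crtp=4,
        n_seed_crtps=6,
    )
    return cfg, *simulate_proteome(cfg)


@pytest.fixture(scope="module")
def pipeline(proteome_fixture):
    cfg, proteome, truth, seeds = proteome_fixture
    cand, scan, profile = predict_import_candidates(
        proteome, seeds, n_decoys=300, calibration_seed=cfg.seed
    )
    return proteome, truth, cand, scan, profile


class TestFindSeeds:
    def test_exact_copies_of_validated_are_recovered(self, rng):
        vals = [
            SequenceRecord(f"v{i}", "".join(rng.choice(list(PROTEIN_ALPHABET), 200)))
            for i in range(5)
        ]
        proteome = [SequenceRecord(f"p{i}", v.seq) for i, v in enumerate(vals)]
        proteome += [
            SequenceRecord("bg", "".join(rng.choice(list(PROTEIN_ALPHABET), 300)))
        ]
        seeds = find_seeds(vals, proteome)
        assert {s.record.id for s in seeds} == {f"p{i}" for i in range(5)}

    def test_unrelated_proteome_raises_zero_seed_error(self, rng):
        vals = [SequenceRecord("v", "".join(rng.choice(list(PROTEIN_ALPHABET), 200)))]
        proteome = [
            SequenceRecord("p", "".join(rng.choice(list(PROTEIN_ALPHABET), 300)))
        ]
        with pytest.raises(ValueError, match="relax"):
            find_seeds(vals, proteome)

    def test_planted_blocks_found_without_background(self, proteome_fixture):
        cfg, proteome, truth, seeds = proteome_fixture
        found = {s.record.id for s in find_seeds(seeds, proteome)}
        assert set(truth["planted"]) <= found
        assert not (found & set(truth["background"]))


class TestBuildProfile:
    def test_hand_computed_emission_with_pseudocount(self):
        # column (A, A, C): P(A) = (2 + 0.5) / (3 + 20 * 0.5) = 0.19231
        rows = ["A" + "M" * 11, "A" + "M" * 11, "C" + "M" * 11]
        aln = SeedAlignment(
            members=[SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)]
        )
        prof = build_profile(aln, min_match_states=1)
        a_idx = PROTEIN_ALPHABET.index("A")
        assert prof.emissions[0, a_idx] == pytest.approx((2 + 0.5) / (3 + 10))

    def test_identical_gapfree_seeds_make_all_columns_match(self, rng):
        seq = "".join(rng.choice(list(PROTEIN_ALPHABET), 30))
        aln = SeedAlignment(members=[SequenceRecord(f"s{i}", seq) for i in range(4)])
        prof = build_profile(aln)
        assert prof.n_match == 30
        for j, aa in enumerate(seq):
            assert prof.emissions[j].argmax() == PROTEIN_ALPHABET.index(aa)

    def test_majority_gap_column_excluded(self):
        rows = ["AM" + "K" * 10, "-M" + "K" * 10, "-M" + "K" * 10]
        aln = SeedAlignment(
            members=[SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)]
        )
        prof = build_profile(aln, min_match_states=1)
        assert prof.n_match == 11  # first column is 2/3 gaps

    def test_emission_rows_sum_to_one(self, pipeline):
        *_, profile = pipeline
        assert np.allclose(profile.emissions.sum(axis=1), 1.0, atol=1e-9)


class TestCalibration:
    def test_fixed_seed_reproduces_fit(self, pipeline):
        *_, profile = pipeline
        p2 = build_profile(
            SeedAlignment(
                members=[
                    SequenceRecord(
                        "a", "".join(np.random.default_rng(0).choice(list(PROTEIN_ALPHABET), 40))
                    )
                ]
                * 3
            )
        )
        c1 = calibrate_profile(p2, n_decoys=250, seed=42).calibration
        p3 = build_profile(
            SeedAlignment(
                members=[
                    SequenceRecord(
                        "a", "".join(np.random.default_rng(0).choice(list(PROTEIN_ALPHABET), 40))
                    )
                ]
                * 3
            )
        )
        c2 = calibrate_profile(p3, n_decoys=250, seed=42).calibration
        assert c1 == c2

    def test_decoy_median_evalue_near_half_database(self, pipeline):
        # self-consistency of the fitted null on fresh decoys
        *_, profile = pipeline
        rng = np.random.default_rng(99)
        n_db = 200
        evs = []
        for _ in range(n_db):
            seq = sample_background_sequence(rng, profile.n_match + 50)
            evs.append(profile_evalue(profile, viterbi_score(profile, seq), n_db))
        med = float(np.median(evs))
        assert 0.2 * n_db < med < 1.5 * n_db

    def test_planted_block_evalue_far_below_cutoff(self, pipeline):
        proteome, truth, cand, scan, profile = pipeline
        planted = next(iter(truth["planted"]))
        rec = next(p for p in proteome if p.id == planted)
        ev = profile_evalue(profile, viterbi_score(profile, rec.seq), len(proteome))
        assert ev < 1e-20

    def test_too_few_decoys_rejected(self, pipeline):
        *_, profile = pipeline
        with pytest.raises(ValueError):
            calibrate_profile(profile, n_decoys=50)


class TestViterbi:
    def _toy(self, rng, K):
        emis = rng.dirichlet(np.ones(20) * 0.3, size=K)
        trans = {}
        for src, dests in (("M", "MID"), ("I", "IM"), ("D", "DM")):
            p = rng.dirichlet(np.ones(len(dests)) * 2)
            for d, pi in zip(dests, p):
                trans[src + d] = float(np.log2(pi))
        bg = np.array([DEFAULT_BACKGROUND[a] for a in PROTEIN_ALPHABET])
        return ProfileModel(emissions=emis, transitions=trans, background=bg / bg.sum())

    def test_matches_exhaustive_path_enumeration(self, rng):
        for _ in range(40):
            prof = self._toy(rng, int(rng.integers(2, 6)))
            seq = "".join(rng.choice(list(PROTEIN_ALPHABET), int(rng.integers(1, 8))))
            assert viterbi_score(prof, seq) == pytest.approx(
                viterbi_bruteforce(prof, seq), abs=1e-9
            )

    def test_align_coordinates_bound_the_reported_score(self, rng):
        prof = self._toy(rng, 5)
        seq = "".join(rng.choice(list(PROTEIN_ALPHABET), 20))
        score, start, end = viterbi_align(prof, seq)
        assert score == pytest.approx(viterbi_score(prof, seq))
        if score > 0:
            assert 0 <= start < end <= len(seq)


class TestScanFilters:
    def test_planted_hits_match_construction(self, pipeline):
        proteome, truth, cand, scan, profile = pipeline
        by_id = {h.protein_id: h for h in scan.hits}
        for pid, info in truth["planted"].items():
            assert pid in by_id, f"planted {pid} missed"
            h = by_id[pid]
            assert abs(h.start - info["start"]) <= 3
            assert abs(h.mature_length - info["mature_length"]) <= 3

    def test_every_decoy_rejected_for_its_planted_reason(self, pipeline):
        proteome, truth, cand, scan, profile = pipeline
        for pid, info in truth["decoys"].items():
            assert pid not in cand.ids
            assert info["reason"] in scan.rejections[pid]

    def test_background_rejected_on_evalue(self, pipeline):
        proteome, truth, cand, scan, profile = pipeline
        for pid in truth["background"]:
            assert "evalue" in scan.rejections[pid]

    def test_uncalibrated_profile_refuses_to_scan(self, pipeline):
        proteome, truth, cand, scan, profile = pipeline
        bare = ProfileModel(
            emissions=profile.emissions,
            transitions=profile.transitions,
            background=profile.background,
        )
        with pytest.raises(ValueError, match="uncalibrated"):
            scan_proteome(bare, proteome[:2])

    def test_scan_is_deterministic(self, pipeline):
        proteome, truth, cand, scan, profile = pipeline
        again = scan_proteome(profile, proteome)
        assert [(h.protein_id, h.score_bits, h.start) for h in again.hits] == [
            (h.protein_id, h.score_bits, h.start) for h in scan.hits
        ]


class TestExtension:
    def test_nothing_to_add_when_scan_found_everything(self, pipeline):
        proteome, truth, cand, scan, profile = pipeline
        assert extend_candidates(scan.hits, proteome) == []

    def test_recovers_proteins_withheld_from_the_scan(self, proteome_fixture):
        # scan a subset; extension must pull back the withheld planted
        # proteins by pairwise homology, and still reject every decoy
        cfg, proteome, truth, seeds = proteome_fixture
        planted = sorted(truth["planted"])
        withheld = set(planted[:3])
        subset = [p for p in proteome if p.id not in withheld]
        cand, scan, profile = predict_import_candidates(
            subset, seeds, n_decoys=300, calibration_seed=cfg.seed
        )
        ext = extend_candidates(scan.hits, proteome)
        assert {h.protein_id for h in ext} == withheld
        assert all(h.route == "extension" for h in ext)
        assert not ({h.protein_id for h in ext} & set(truth["decoys"]))

    def test_routes_must_not_overlap(self, pipeline):
        proteome, truth, cand, scan, profile = pipeline
        if scan.hits:
            with pytest.raises(ValueError):
                ImportCandidateSet(
                    hmm_hits=scan.hits,
                    extension_hits=[scan.hits[0]],
                    proteome={p.id: p for p in proteome},
                )

    def test_combined_counts_each_protein_once(self, pipeline):
        proteome, truth, cand, scan, profile = pipeline
        assert len(cand.combined) == len(cand.hmm_hits) + len(cand.extension_hits)
        assert len({h.protein_id for h in cand.combined}) == len(cand.combined)


class TestSharedCandidates:
    def _set_from(self, recs):
        from chromaforge.crtp_predict import CrTPHit

        hits = [
            CrTPHit(r.id, 100.0, 1e-30, 0, min(50, len(r.seq)), len(r.seq) - 50)
            for r in recs
        ]
        return ImportCandidateSet(
            hmm_hits=hits, extension_hits=[], proteome={r.id: r for r in recs}
        )

    def test_identical_candidate_sets_pair_perfectly(self, rng):
        base = [
            SequenceRecord(f"a{i}", "".join(rng.choice(list(PROTEIN_ALPHABET), 300)))
            for i in range(4)
        ]
        other = [SequenceRecord(f"b{i}", r.seq) for i, r in enumerate(base)]
        pairs = shared_candidates(self._set_from(base), self._set_from(other))
        assert pairs == [(f"a{i}", f"b{i}") for i in range(4)]

    def test_orthologs_at_80pct_identity_recovered_exactly(self, rng):
        aas = list(PROTEIN_ALPHABET)
        base = ["".join(rng.choice(aas, 300)) for _ in range(3)]

        def mutate(s):
            out = list(s)
            for i in range(len(out)):
                if rng.random() < 0.2:
                    out[i] = aas[int(rng.integers(0, 20))]
            return "".join(out)

        set_a = [SequenceRecord(f"a{i}", s) for i, s in enumerate(base)]
        set_a.append(SequenceRecord("a_only", "".join(rng.choice(aas, 300))))
        set_b = [SequenceRecord(f"b{i}", mutate(s)) for i, s in enumerate(base)]
        set_b.append(SequenceRecord("b_only", "".join(rng.choice(aas, 300))))
        pairs = shared_candidates(self._set_from(set_a), self._set_from(set_b))
        assert pairs == [(f"a{i}", f"b{i}") for i in range(3)]

    def test_disjoint_unrelated_sets_share_nothing(self, rng):
        a = [SequenceRecord("a", "".join(rng.choice(list(PROTEIN_ALPHABET), 300)))]
        b = [SequenceRecord("b", "".join(rng.choice(list(PROTEIN_ALPHABET), 300)))]
        assert shared_candidates(self._set_from(a), self._set_from(b)) == []


class TestProgressiveAlign:
    def test_equal_length_noisy_copies_align_gapfree(self, rng):
        base = "".join(rng.choice(list(PROTEIN_ALPHABET), 40))
        seqs = []
        for i in range(4):
            s = list(base)
            for j in range(len(s)):
                if rng.random() < 0.1:
                    s[j] = PROTEIN_ALPHABET[int(rng.integers(0, 20))]
            seqs.append(SequenceRecord(f"s{i}", "".join(s)))
        aln = progressive_align(seqs)
        assert aln.n_columns == 40
        assert all("-" not in m.seq for m in aln.members)
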