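import pytest
from Bio.Align import substitution_matrices

from kincascade.core_io import GeneModel, GenomeAnnotation, SequenceRecord
from kincascade.homology import (
    Pssm,
    call_homolog_pairs,
    find_candidates,
    global_align,
    pssm_scan,
    remove_redundancy,
)
from .conftest import random_protein
from .oracles import brute_force_global_score

BLOSUM62 = substitution_matrices.load("BLOSUM62")


class TestGlobalAlign:
    def test_self_alignment_identity_one(self, rng):
        for _ in range(10):
            s = random_protein(rng, int(rng.integers(5, 50)))
            res = global_align(s, s)
            assert res.identity == 1.0
            assert res.query_coverage == res.subject_coverage == 1.0

    def test_single_mismatch_identity(self):
        assert global_align("MK", "ML").identity == 0.5

    def test_score_symmetric(self, rng):
        for _ in range(20):
            a = random_protein(rng, int(rng.integers(3, 25)))
            b = random_protein(rng, int(rng.integers(3, 25)))
            assert global_align(a, b).score == global_align(b, a).score

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "MK")

    def test_score_matches_exhaustive_enumeration(self, rng):
        """NW affine score equals brute force over every alignment."""
        for _ in range(40):
            a = random_protein(rng, int(rng.integers(1, 7)))
            b = random_protein(rng, int(rng.integers(1, 7)))
            got = global_align(a, b).score
            want = brute_force_global_score(a, b, BLOSUM62, 10.0, 1.0)
            assert got == pytest.approx(want)


class TestFindCandidates:
    def test_exact_seed_copy_found(self, rng):
        seed = SequenceRecord("seed1", random_protein(rng, 80))
        prot = SequenceRecord("p1", seed.seq)
        decoy = SequenceRecord("d1", random_protein(rng, 80))
        out = find_candidates([prot, decoy], [seed])
        assert [(pid, sid) for pid, sid, _ in out] == [("p1", "seed1")]
        assert out[0][2].identity == 1.0

    def test_monotone_in_identity_threshold(self, rng):
        seeds = [SequenceRecord("s", random_protein(rng, 60))]
        prots = []
        for i in range(6):
            base = list(seeds[0].seq)
            for j in rng.integers(0, 60, size=i * 8):
                base[j] = "A"
            prots.append(SequenceRecord(f"p{i}", "".join(base)))
        lo = {p for p, _, _ in find_candidates(prots, seeds, 0.4, 0.5)}
        hi = {p for p, _, _ in find_candidates(prots, seeds, 0.8, 0.5)}
        assert hi <= lo

    def test_prefilter_agrees_with_full_search(self, small_config):
        from kincascade.synthetic import gen_proteome

        records, truth = gen_proteome(small_config)
        seeds = [r for r in records if r.id.startswith("KIN_MAPK")][:2]
        on = find_candidates(records, seeds, prefilter=True)
        off = find_candidates(records, seeds, prefilter=False)
        assert [(p, s) for p, s, _ in on] == [(p, s) for p, s, _ in off]

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError, match="empty seed"):
            find_candidates([], [])


class TestPssm:
    def test_consensus_scores_highest_at_planted_offset(self, rng):
        seeds = ["HRDLKPEN"] * 6 + ["HRDIKPEN"] * 2
        profile = Pssm.from_alignment(seeds)
        seq = random_protein(rng, 30) + "HRDLKPEN" + random_protein(rng, 30)
        hits = pssm_scan(seq, profile, threshold=10.0)
        assert hits, "consensus window should clear the threshold"
        best_off = max(hits, key=lambda h: h[1])[0]
        assert best_off == 30

    def test_uniform_random_sequence_high_threshold_empty(self, rng):
        profile = Pssm.from_alignment(["HRDLKPEN"] * 5)
        assert pssm_scan(random_protein(rng, 100), profile, 30.0) == []

    def test_window_scores_equal_hand_summed_columns(self):
        profile = Pssm.from_alignment(["ACDE", "ACDE", "ACDF"])
        [(_, score)] = pssm_scan("ACDE", profile, threshold=-100.0)
        hand = sum(
            profile.scores[j, "ACDEFGHIKLMNPQRSTVWY".index(r)]
            for j, r in enumerate("ACDE"))
        assert score == pytest.approx(hand)

    def test_width_longer_than_sequence_empty(self):
        profile = Pssm.from_alignment(["ACDE"] * 3)
        assert pssm_scan("AC", profile, 0.0) == []


def _two_gene_annotation():
    genes = [
        GeneModel("gA", "1A", "+", 100, 500,
                  transcripts=[("gA.1", 300), ("gA.2", 450)]),
        GeneModel("gB", "1A", "+", 1000, 1500, transcripts=[("gB.1", 200)]),
    ]
    return GenomeAnnotation(genes)


class TestRemoveRedundancy:
    def test_longest_isoform_kept(self, rng):
        ann = _two_gene_annotation()
        recs = [
            SequenceRecord("gA.1", random_protein(rng, 300)),
            SequenceRecord("gA.2", random_protein(rng, 450)),
            SequenceRecord("gB.1", random_protein(rng, 200)),
        ]
        kept, flags = remove_redundancy(recs, ann)
        assert sorted(r.id for r in kept) == ["gA.2", "gB.1"]
        assert flags == {}

    def test_identical_sequences_across_genes_flagged(self, rng):
        ann = _two_gene_annotation()
        shared = random_protein(rng, 120)
        recs = [SequenceRecord("gA.1", shared), SequenceRecord("gB.1", shared)]
        kept, flags = remove_redundancy(recs, ann)
        assert len(kept) == 2
        assert set(flags) == {"gA.1", "gB.1"}
        assert sorted(flags["gA.1"]) == ["gA", "gB"]

    def test_unmapped_candidate_rejected(self, rng):
        ann = _two_gene_annotation()
        with pytest.raises(KeyError, match="nowhere.1"):
            remove_redundancy(
                [SequenceRecord("nowhere.1", random_protein(rng, 50))], ann)


class TestHomologPairs:
    def test_identical_pair_reciprocal_best(self, rng):
        s = random_protein(rng, 100)
        pairs = call_homolog_pairs(
            [SequenceRecord("a", s), SequenceRecord("b", s)])
        assert len(pairs) == 1
        assert pairs[0].key == ("a", "b")
        assert pairs[0].reciprocal_best
        assert pairs[0].identity == 1.0

    def test_dissimilar_decoys_yield_nothing(self, rng):
        members = [SequenceRecord(f"d{i}", random_protein(rng, 100))
                   for i in range(3)]
        assert call_homolog_pairs(members, min_identity=0.9) == []

    def test_planted_families_recovered(self, rng):
        fams = []
        for f in range(3):
            base = random_protein(rng, 150)
            for m in range(2):
                mutated = list(base)
                for j in rng.integers(0, 150, size=8):
                    mutated[j] = "A"
                fams.append(SequenceRecord(f"f{f}_m{m}", "".join(mutated)))
        pairs = call_homolog_pairs(fams, min_identity=0.7, min_coverage=0.8)
        got = {p.key for p in pairs}
        want = {(f"f{f}_m0", f"f{f}_m1") for f in range(3)}
        assert got == want


class TestIdentifyFamily:
    def test_union_of_alignment_and_profile_routes(self, rng):
        from kincascade.homology import identify_family

        seed = SequenceRecord("seed", random_protein(rng, 80))
        similar = SequenceRecord("p_sim", seed.seq)
        motif_only = SequenceRecord(
            "p_prof", random_protein(rng, 40) + "HRDLKPEN"
            + random_protein(rng, 40))
        decoy = SequenceRecord("p_decoy", random_protein(rng, 80))
        profile = Pssm.from_alignment(["HRDLKPEN"] * 6)
        got = identify_family([similar, motif_only, decoy], [seed],
                              profile=profile, profile_threshold=15.0)
        assert got == ["p_prof", "p_sim"]
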