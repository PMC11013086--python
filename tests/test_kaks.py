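import math

import numpy as np
import pytest

from kincascade.core_io import GeneModel, GenomeAnnotation
from kincascade.homology import HomologPair
from kincascade.kaks import (
    CodonAlignment,
    classify_duplication,
    detect_synteny,
    divergence_time,
    ng86,
)
from .oracles import exhaustive_blocks


class TestCodonAlignment:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            CodonAlignment("ATGATG", "ATG")

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            CodonAlignment("ATGA", "ATGA")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop codon"):
            CodonAlignment("ATGTAAATG", "ATGTACATG")


class TestNg86:
    def test_identical_pair(self):
        r = ng86(CodonAlignment("TTT" * 9, "TTT" * 9))
        assert r.S == pytest.approx(3.0)
        assert r.Sd == r.Nd == 0.0
        assert r.Ks == r.Ka == 0.0

    def test_hand_worked_single_synonymous_difference(self):
        r = ng86(CodonAlignment("TTT" * 9, "TTT" * 8 + "TTC"))
        assert r.S == pytest.approx(3.0)
        assert r.Sd == 1.0
        assert r.pS == pytest.approx(1 / 3)
        assert r.Ks == pytest.approx(0.4408, abs=1e-4)
        assert r.Ka == 0.0
        assert r.omega == 0.0

    def test_correction_domain_flagged(self):
        r = ng86(CodonAlignment("TTT", "TTC"))
        assert r.pS == pytest.approx(3.0)
        assert math.isnan(r.Ks)
        assert "pS" in r.flag
        assert r.high_pS

    def test_site_counts_sum_to_sequence_length(self, rng):
        from kincascade.synthetic import _NONSTOP

        for _ in range(30):
            codons = int(rng.integers(2, 40))
            a = "".join(_NONSTOP[i] for i in
                        rng.integers(0, len(_NONSTOP), size=codons))
            b = "".join(_NONSTOP[i] for i in
                        rng.integers(0, len(_NONSTOP), size=codons))
            r = ng86(CodonAlignment(a, b))
            assert r.S + r.N == pytest.approx(3 * codons)

    def test_pathway_averaging_two_differences(self):
        # TTT (F) vs TTA (L) plus CCC vs CCC: single nonsyn step
        r = ng86(CodonAlignment("TTTCCC", "TTACCC"))
        assert r.Nd == 1.0 and r.Sd == 0.0
        # GGG (G) vs GGA|AGA: two paths, one syn+nonsyn each order
        r2 = ng86(CodonAlignment("GGGCCC", "AGACCC"))
        assert r2.Sd + r2.Nd == pytest.approx(2.0)


class TestDating:
    def test_grass_clock_rate_example(self):
        assert divergence_time(0.013, 6.5e-9) == pytest.approx(1.000, abs=1e-9)

    def test_zero_ks(self):
        assert divergence_time(0.0) == 0.0

    def test_linearity(self, rng):
        for _ in range(10):
            ks = float(rng.uniform(0.01, 2.0))
            assert divergence_time(2 * ks) == pytest.approx(
                2 * divergence_time(ks))

    def test_nan_propagates(self):
        assert math.isnan(divergence_time(float("nan")))


def _annotation_two_chroms(n=12):
    genes = []
    for chrom in ("1A", "1B", "2A"):
        for i in range(n):
            gid = f"{chrom}_g{i + 1:02d}"
            genes.append(GeneModel(gid, chrom, "+", 1000 * (i + 1),
                                   1000 * (i + 1) + 500))
    return GenomeAnnotation(genes)


def _pair(ann, ra, rb, ca="1A", cb="1B"):
    return HomologPair(f"{ca}_g{ra:02d}", f"{cb}_g{rb:02d}")


class TestSynteny:
    def test_perfect_run_one_block(self):
        ann = _annotation_two_chroms()
        pairs = [_pair(ann, i, i) for i in (1, 2, 3)]
        blocks = detect_synteny(pairs, ann, min_block=3)
        assert len(blocks) == 1
        assert blocks[0].length == 3
        assert blocks[0].orientation == "+"

    def test_scrambled_run_no_block(self):
        ann = _annotation_two_chroms()
        pairs = [_pair(ann, 1, 3), _pair(ann, 2, 1), _pair(ann, 3, 2)]
        assert detect_synteny(pairs, ann, min_block=3) == []

    def test_inverted_run_detected(self):
        ann = _annotation_two_chroms()
        pairs = [_pair(ann, 1, 5), _pair(ann, 2, 4), _pair(ann, 3, 3)]
        blocks = detect_synteny(pairs, ann, min_block=3)
        assert len(blocks) == 1
        assert blocks[0].orientation == "-"

    def test_gap_limit_respected(self):
        ann = _annotation_two_chroms()
        pairs = [_pair(ann, 1, 1), _pair(ann, 2, 2), _pair(ann, 12, 12)]
        assert detect_synteny(pairs, ann, min_block=3, max_gap=5) == []

    def test_missing_gene_rejected(self):
        ann = _annotation_two_chroms()
        with pytest.raises(KeyError):
            detect_synteny([HomologPair("1A_g01", "zzz")], ann)

    def test_matches_exhaustive_search_on_random_instances(self, rng):
        """Greedy chain extraction equals brute-force subsequence search."""
        ann = _annotation_two_chroms()
        for _ in range(60):
            n_anchors = int(rng.integers(3, 11))
            ra = rng.choice(np.arange(1, 13), size=n_anchors, replace=False)
            rb = rng.choice(np.arange(1, 13), size=n_anchors, replace=False)
            pairs = [_pair(ann, int(a), int(b)) for a, b in zip(ra, rb)]
            max_gap = int(rng.integers(2, 12))
            got = detect_synteny(pairs, ann, min_block=3, max_gap=max_gap)
            coords = sorted(
                (ann.gene_rank[p.a], ann.gene_rank[p.b]) for p in pairs)
            want = exhaustive_blocks(coords, min_block=3, max_gap=max_gap)
            got_sets = [
                (sorted((a, b) for a, b, _ in blk.anchors), blk.orientation)
                for blk in got]
            want_sets = [
                (sorted(coords[i] for i in idxs), orient)
                for idxs, orient in want]
            assert got_sets == want_sets


class TestClassifyDuplication:
    def test_adjacent_ranks_tandem(self):
        ann = _annotation_two_chroms()
        pair = HomologPair("1A_g01", "1A_g02")
        assert classify_duplication(pair, ann, []).kind == "tandem"

    def test_block_anchor_segmental(self):
        ann = _annotation_two_chroms()
        pairs = [_pair(ann, i, i) for i in (1, 2, 3)]
        blocks = detect_synteny(pairs, ann, min_block=3)
        assert classify_duplication(pairs[0], ann, blocks).kind == "segmental"

    def test_isolated_cross_chromosome_dispersed(self):
        ann = _annotation_two_chroms()
        pair = HomologPair("1A_g01", "2A_g09")
        assert classify_duplication(pair, ann, []).kind == "dispersed"

    def test_far_same_chromosome_pair_not_tandem(self):
        ann = _annotation_two_chroms()
        pair = HomologPair("1A_g01", "1A_g12")
        assert classify_duplication(pair, ann, [], tandem_gap=5).kind == "dispersed"

    def test_unplaced_bin_excluded_from_tandem(self):
        genes = [GeneModel(f"Un_g{i}", "Un", "+", 100 * i, 100 * i + 50)
                 for i in (1, 2)]
        ann = GenomeAnnotation(genes)
        pair = HomologPair("Un_g1", "Un_g2")
        assert classify_duplication(pair, ann, []).kind == "dispersed"

    def test_layout_truth_recovered(self, small_config):
        from kincascade.synthetic import gen_layout

        ann, pairs, truth = gen_layout(small_config)
        blocks = detect_synteny(pairs, ann)
        calls = {
            (p.a, p.b): classify_duplication(p, ann, blocks).kind
            for p in pairs
        }
        for a, b, kind in truth.itertuples(index=False, name=None):
            assert calls[(a, b)] == kind
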