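import numpy as np
import pytest

from kincascade.motifs import classify_proteome, classify_tier
from kincascade.synthetic import (
    CtDesign,
    SynthesisConfig,
    gen_codon_pairs,
    gen_ct,
    gen_expression,
    gen_layout,
    gen_promoters,
    gen_proteome,
    write_gff3,
)


class TestDeterminism:
    def test_proteome_identical_for_same_seed(self, small_config):
        r1, t1 = gen_proteome(small_config)
        r2, t2 = gen_proteome(small_config)
        assert [(r.id, r.seq) for r in r1] == [(r.id, r.seq) for r in r2]
        assert t1.equals(t2)

    def test_layout_gff_identical_for_same_seed(self, small_config, tmp_path):
        outs = []
        for name in ("a.gff3", "b.gff3"):
            ann, _, _ = gen_layout(small_config)
            p = tmp_path / name
            write_gff3(ann, p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_ct_and_expression_identical_for_same_seed(self, small_config):
        ct1, _ = gen_ct(small_config)
        ct2, _ = gen_ct(small_config)
        assert ct1.rows.equals(ct2.rows)
        em1, _ = gen_expression(small_config)
        em2, _ = gen_expression(small_config)
        assert em1.values.equals(em2.values)

    def test_different_seeds_differ(self, small_config):
        other = SynthesisConfig(**{**small_config.__dict__, "seed": 43})
        r1, _ = gen_proteome(small_config)
        r2, _ = gen_proteome(other)
        assert [r.seq for r in r1] != [r.seq for r in r2]


class TestProteome:
    def test_empty_design_rejected(self):
        cfg = SynthesisConfig(tier_counts={t: 0 for t in (
            "MAPK", "MAP2K", "MEKK", "RAF", "ZIK", "MAP4K")})
        with pytest.raises(ValueError, match="empty design"):
            gen_proteome(cfg)

    def test_mapk_members_contain_signature(self):
        cfg = SynthesisConfig(seed=3, tier_counts={
            "MAPK": 2, "MAP2K": 0, "MEKK": 0, "RAF": 0, "ZIK": 0, "MAP4K": 0},
            decoy_count=0)
        records, truth = gen_proteome(cfg)
        assert len(records) == 2
        for rec in records:
            call = classify_tier(rec)
            assert call.tier == "MAPK"
            off = int(truth.loc[rec.id, "motif_offset"])
            assert any(h.offset == off for h in call.supporting)

    def test_decoys_have_no_signature(self, small_config):
        records, truth = gen_proteome(small_config)
        for rec in records:
            if rec.id.startswith("DECOY"):
                assert classify_tier(rec).tier == "unclassified"

    def test_truth_recovery_across_seeds(self):
        """Planted tier recovered for every record on several seeds."""
        for seed in range(5):
            cfg = SynthesisConfig(seed=seed, tier_counts={
                "MAPK": 3, "MAP2K": 2, "MEKK": 2, "RAF": 3, "ZIK": 2,
                "MAP4K": 3}, decoy_count=5)
            records, truth = gen_proteome(cfg)
            for call in classify_proteome(records):
                want = truth.loc[call.seq_id, "tier"]
                got = "decoy" if call.tier == "unclassified" else call.tier
                assert got == want


class TestLayout:
    def test_tandem_array_consecutive_ranks(self, small_config):
        ann, pairs, truth = gen_layout(small_config)
        tandem = truth[truth["class"] == "tandem"]
        for a, b, _ in tandem.itertuples(index=False, name=None):
            ga, gb = ann.gene(a), ann.gene(b)
            assert ga.chromosome == gb.chromosome
            size = dict(small_config.tandem_arrays)[ga.chromosome]
            assert abs(ann.gene_rank[a] - ann.gene_rank[b]) <= size - 1

    def test_block_anchors_order_consistent(self, small_config):
        ann, pairs, truth = gen_layout(small_config)
        seg = truth[truth["class"] == "segmental"]
        by_block = {}
        for a, b, _ in seg.itertuples(index=False, name=None):
            key = (ann.gene(a).chromosome, ann.gene(b).chromosome)
            by_block.setdefault(key, []).append(
                (ann.gene_rank[a], ann.gene_rank[b]))
        for anchors in by_block.values():
            anchors.sort()
            rb = [b for _, b in anchors]
            assert rb == sorted(rb)

    def test_oversized_array_rejected(self):
        cfg = SynthesisConfig(
            chromosomes=[("1A", 1_000_000, 5)],
            tandem_arrays=[("1A", 9)], synteny_blocks=[], dispersed_pairs=0)
        with pytest.raises(ValueError, match="exceeds gene count"):
            gen_layout(cfg)


class TestCodonPairs:
    def test_zero_proposals_identical_pair(self):
        cfg = SynthesisConfig(seed=5, omega_settings=[(0.5, 20, 0)],
                              pairs_per_setting=3)
        records, truth = gen_codon_pairs(cfg)
        for i in range(0, len(records), 2):
            assert records[i].seq == records[i + 1].seq
        assert (truth["syn_accepted"] == 0).all()
        assert (truth["nonsyn_accepted"] == 0).all()

    def test_tiny_omega_accepts_almost_only_synonymous(self):
        cfg = SynthesisConfig(seed=5, omega_settings=[(1e-9, 100, 50)],
                              pairs_per_setting=5)
        _, truth = gen_codon_pairs(cfg)
        assert (truth["nonsyn_accepted"] == 0).all()
        assert (truth["syn_accepted"] > 0).any()

    def test_nonpositive_codon_count_rejected(self):
        cfg = SynthesisConfig(omega_settings=[(0.5, 0, 10)],
                              pairs_per_setting=1)
        with pytest.raises(ValueError, match="codon count"):
            gen_codon_pairs(cfg)

    def test_pairs_are_valid_codon_alignments(self, small_config):
        from kincascade.kaks import CodonAlignment

        records, _ = gen_codon_pairs(small_config)
        for i in range(0, len(records), 2):
            aln = CodonAlignment(records[i].seq, records[i + 1].seq)
            assert aln.n_codons * 3 == len(records[i].seq)

    def test_estimates_consistent_with_truth_counts(self):
        """NG86 omega tracks the generator's accepted-count ratio."""
        from kincascade.kaks import CodonAlignment, ng86

        cfg = SynthesisConfig(seed=7, omega_settings=[(0.2, 200, 60)],
                              pairs_per_setting=30)
        records, truth = gen_codon_pairs(cfg)
        est = []
        for i in range(0, len(records), 2):
            r = ng86(CodonAlignment(records[i].seq, records[i + 1].seq))
            if not np.isnan(r.omega):
                est.append(r.omega)
        assert 0.1 <= float(np.mean(est)) <= 0.35

    def test_bias_shrinks_with_codon_length(self):
        from kincascade.kaks import CodonAlignment, ng86

        means = {}
        for codons, m in ((100, 30), (1000, 300)):
            cfg = SynthesisConfig(seed=11, omega_settings=[(0.2, codons, m)],
                                  pairs_per_setting=30)
            records, _ = gen_codon_pairs(cfg)
            est = [ng86(CodonAlignment(records[i].seq,
                                       records[i + 1].seq)).omega
                   for i in range(0, len(records), 2)]
            means[codons] = float(np.nanmean(est))
        assert abs(means[1000] - 0.2) <= abs(means[100] - 0.2) + 0.05


class TestPromoters:
    def test_planted_counts_exact(self, small_config):
        from kincascade.promoters import default_catalog, scan_elements

        cat = default_catalog()
        records, truth = gen_promoters(small_config, cat)
        assert len(records) == small_config.n_promoters
        expected = {
            name: small_config.promoter_plants.get(name, 0)
            for name in cat.names()
        }
        for rec in records:
            assert len(rec.seq) == small_config.promoter_length
            assert scan_elements(rec, cat).counts == expected

    def test_no_plants_all_zero(self):
        from kincascade.promoters import default_catalog, scan_elements

        cfg = SynthesisConfig(seed=2, n_promoters=3, promoter_plants={})
        cat = default_catalog()
        records, truth = gen_promoters(cfg, cat)
        assert truth.empty
        for rec in records:
            assert set(scan_elements(rec, cat).counts.values()) == {0}

    def test_capacity_limit_rejected(self):
        cfg = SynthesisConfig(promoter_plants={"ABRE": 200},
                              promoter_length=100)
        with pytest.raises(ValueError, match="capacity"):
            gen_promoters(cfg)


class TestExpressionAndCt:
    def test_planted_effect_visible(self):
        from kincascade.synthetic import ExprDesign

        cfg = SynthesisConfig(seed=3, expr_design=ExprDesign(
            n_genes=10, effects={(0, "drought"): 3.0}, noise_sd=0.05))
        em, truth = gen_expression(cfg)
        dr = em.values.filter(like="drought_").iloc[0].mean()
        ct = em.values.filter(like="control_").iloc[0].mean()
        assert np.log2(dr / ct) == pytest.approx(3.0, abs=0.5)

    def test_noiseless_ct_exact_ddct(self):
        cfg = SynthesisConfig(seed=4, ct_design=CtDesign(
            noise_sd=0.0, fold_changes={("g1", "drought"): 4.0}))
        table, _ = gen_ct(cfg)
        rows = table.rows
        dct = rows["ct_target"] - rows["ct_reference"]
        g1d = dct[(rows["gene"] == "g1")
                  & (rows["condition"] == "drought")].to_numpy()
        g1c = dct[(rows["gene"] == "g1")
                  & (rows["condition"] == "control")].to_numpy()
        assert (g1c - g1d == 2.0).all()  # ddCt exactly -2 per replicate

    def test_reference_ct_constant_in_expectation(self):
        cfg = SynthesisConfig(seed=6, ct_design=CtDesign(
            replicates=200, noise_sd=0.3))
        table, _ = gen_ct(cfg)
        by_cond = table.rows.groupby("condition")["ct_reference"].mean()
        assert by_cond.max() - by_cond.min() < 0.15
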