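"""Generators: planted structure, statistical calibration, determinism."""

import numpy as np
import pandas as pd
import pytest

from pleioscan import igr
from pleioscan import synthetic_data as syn


class TestSummaryStats:
    def test_null_z_pairs_uncorrelated_when_no_overlap(self):
        cfg = syn.SimulationConfig(seed=2, n_snps=10_000,
                                   overlap_correlation=0.0)
        a, b = syn.gen_summary_stats(cfg)
        z_a = (a["BETA"] / a["SE"]).to_numpy()
        z_b = (b["BETA"] / b["SE"]).to_numpy()
        r = np.corrcoef(z_a, z_b)[0, 1]
        assert abs(r) < 3 / np.sqrt(cfg.n_snps)

    def test_null_univariate_p_calibrated(self):
        cfg = syn.SimulationConfig(seed=4, n_snps=20_000)
        a, _ = syn.gen_summary_stats(cfg)
        frac = (a["P"] < 0.05).mean()
        # exact binomial 99% CI around 0.05 at n=2e4
        from scipy import stats as sps
        lo, hi = sps.binom.ppf([0.005, 0.995], cfg.n_snps, 0.05) / cfg.n_snps
        assert lo <= frac <= hi

    def test_planted_loci_shift_z_means(self):
        cfg = syn.SimulationConfig(seed=5, n_snps=1000,
                                   planted_loci=((7, 6.0, -4.0),))
        a, b = syn.gen_summary_stats(cfg)
        assert (a["BETA"] / a["SE"]).iloc[7] > 2.0
        assert (b["BETA"] / b["SE"]).iloc[7] < -1.0

    def test_se_follows_gwas_approximation(self):
        cfg = syn.SimulationConfig(seed=6, n_snps=200)
        a, _ = syn.gen_summary_stats(cfg)
        expect = 1 / np.sqrt(2 * a["N"] * a["MAF"] * (1 - a["MAF"]))
        assert np.allclose(a["SE"], expect)

    def test_planted_index_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            syn.gen_summary_stats(syn.SimulationConfig(
                seed=0, n_snps=100, planted_loci=((100, 1.0, 1.0),)))

    def test_deterministic_rerun(self):
        cfg = syn.SimulationConfig(seed=9, n_snps=100)
        a1, b1 = syn.gen_summary_stats(cfg)
        a2, b2 = syn.gen_summary_stats(cfg)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)


class TestOrthologSets:
    def test_module_planted_at_identical_offsets_in_two_species(self):
        cfg = syn.SimulationConfig(seed=7)
        case, _ = syn.gen_ortholog_sets(cfg)
        assert set(case.planted_offsets) >= {"human"}
        assert len(case.planted_offsets) >= 2
        offs = list(case.planted_offsets.values())
        assert offs[0] == offs[1]  # zero jitter -> identical relative offsets
        for sp, starts in case.planted_offsets.items():
            for start, mid in zip(starts, cfg.module_motifs):
                cons = syn.DEMO_MOTIF_CONSENSI[mid]
                assert case.windows[sp][start:start + len(cons)] == cons

    def test_single_species_rejected(self):
        with pytest.raises(ValueError, match="n_species"):
            syn.gen_ortholog_sets(syn.SimulationConfig(seed=0, n_species=1))

    def test_module_longer_than_window_rejected(self):
        cfg = syn.SimulationConfig(seed=0, window_bp=20)
        with pytest.raises(ValueError, match="longer than window"):
            syn.gen_ortholog_sets(cfg)

    def test_background_sets_lack_planted_module(self):
        cfg = syn.SimulationConfig(seed=7, n_background_sets=20)
        _, bg = syn.gen_ortholog_sets(cfg)
        cons = syn.DEMO_MOTIF_CONSENSI["M1"]
        hits = sum(cons in s.windows["human"] for s in bg)
        assert hits <= 1  # chance occurrences only


class TestAlleleCounts:
    def test_balanced_fold_at_high_depth(self):
        cfg = syn.SimulationConfig(seed=8, imbalance_fold=1.0, depth=100_000,
                                   n_variants=1)
        t = syn.gen_allele_counts(cfg)
        fold = t["HAP1"].sum() / t["HAP2"].sum()
        assert 0.98 <= fold <= 1.02

    def test_planted_fold_recovered_within_ci(self):
        cfg = syn.SimulationConfig(seed=8)  # defaults: fold 1.9, 20x50 reads
        t = syn.gen_allele_counts(cfg)
        k1, n = int(t["HAP1"].sum()), int(t[["HAP1", "HAP2"]].sum().sum())
        from scipy import stats as sps
        lo, hi = sps.binomtest(k1, n).proportion_ci(0.95)
        assert lo <= 1.9 / 2.9 <= hi

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            syn.gen_allele_counts(syn.SimulationConfig(seed=0, depth=0))


class TestPeakDataset:
    def test_noiseless_positives_contain_exact_consensus(self):
        cfg = syn.SimulationConfig(seed=3, n_pos=50, n_neg=50, seq_length=60,
                                   motif_noise=0.0)
        seqs, labels, offsets, _ = syn.gen_peak_dataset(cfg)
        for i in range(cfg.n_pos):
            off = offsets[i]
            assert seqs[i][off:off + len(cfg.motif_consensus)] == \
                cfg.motif_consensus

    def test_variant_truth_labels_match_positions(self):
        cfg = syn.SimulationConfig(seed=3, n_pos=50, n_neg=50, seq_length=80)
        seqs, _, offsets, variants = syn.gen_peak_dataset(cfg)
        ml = len(cfg.motif_consensus)
        for v in variants:
            off = offsets[v.seq_index]
            assert seqs[v.seq_index][v.pos] == v.ref
            assert v.alt != v.ref
            if v.disrupting:
                assert off <= v.pos < off + ml
            else:
                assert v.pos < off - 10 or v.pos >= off + ml + 10

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_peak_dataset(syn.SimulationConfig(seed=0, n_pos=0))

    def test_same_seed_identical_sequences(self):
        cfg = syn.SimulationConfig(seed=12, n_pos=30, n_neg=30, seq_length=60)
        s1, *_ = syn.gen_peak_dataset(cfg)
        s2, *_ = syn.gen_peak_dataset(cfg)
        assert s1 == s2


class TestEpigenomeFixture:
    def test_flat_clade_signals_when_fold_one(self):
        epi = syn.gen_epigenome_fixture(
            syn.SimulationConfig(seed=1, clade_fold=1.0))
        assert set(epi.leaf_signals.values()) == {1.0}

    def test_enriched_clade_signal_exact(self):
        epi = syn.gen_epigenome_fixture(
            syn.SimulationConfig(seed=1, clade_fold=2.0))
        for leaf, v in epi.leaf_signals.items():
            assert v == (2.0 if leaf in epi.enriched_leaves else 1.0)

    def test_unknown_clade_rejected(self):
        with pytest.raises(ValueError, match="clade"):
            syn.gen_epigenome_fixture(
                syn.SimulationConfig(seed=1, enriched_clade="nope"))

    def test_planted_kmer_counts_are_exact(self, epigenome_fixture):
        epi = epigenome_fixture
        cfg = syn.SimulationConfig(seed=11)
        assert len(igr.find_anchors(epi.genome, cfg.kmer)) == \
            len(epi.kmer_positions)
        assert len(igr.find_anchors(epi.genome, cfg.kmer_alt)) == \
            len(epi.kmer_alt_positions)

    def test_absent_kmer_yields_no_anchors(self):
        epi = syn.gen_epigenome_fixture(
            syn.SimulationConfig(seed=1, n_kmer_sites=0))
        with pytest.warns(UserWarning, match="no genomic occurrence"):
            assert igr.find_anchors(epi.genome,
                                    syn.SimulationConfig().kmer) == []

    def test_track_elevated_only_near_planted_kmers(self, epigenome_fixture):
        epi = epigenome_fixture
        s = epi.kmer_positions[0]
        assert epi.track[s] == 2.0
        assert epi.track[epi.kmer_alt_positions[0]] == 1.0
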