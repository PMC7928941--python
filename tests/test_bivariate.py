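"""Bivariate statistics: closed forms, oracles, calibration, filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pleioscan import bivariate as bv
from pleioscan import synthetic_data as syn


def _stats_frame(rows):
    return pd.DataFrame(rows, columns=bv.SUMMARY_COLUMNS)


def _row(snp, a1="A", a2="G", beta=0.1, se=0.05, chrom=1, bp=100):
    return [snp, chrom, bp, a1, a2, beta, se, 0.05, 10_000, 0.3]


class TestHarmonize:
    def test_identical_alleles_keep_z(self):
        a = _stats_frame([_row("rs1")])
        b = _stats_frame([_row("rs1", beta=0.2)])
        paired = bv.harmonize(a, b)
        assert paired.table["Z_A"].iloc[0] == pytest.approx(2.0)
        assert paired.table["Z_B"].iloc[0] == pytest.approx(4.0)

    def test_swapped_alleles_flip_sign(self):
        a = _stats_frame([_row("rs1", "A", "G")])
        b = _stats_frame([_row("rs1", "G", "A", beta=0.2)])
        paired = bv.harmonize(a, b)
        assert paired.table["Z_B"].iloc[0] == pytest.approx(-4.0)

    def test_strand_complement_swap_flips_sign(self):
        a = _stats_frame([_row("rs1", "A", "G")])
        b = _stats_frame([_row("rs1", "C", "T", beta=0.2)])  # comp of G/A
        paired = bv.harmonize(a, b)
        assert paired.table["Z_B"].iloc[0] == pytest.approx(-4.0)

    def test_ambiguous_snp_dropped_and_counted(self):
        a = _stats_frame([_row("rs1", "A", "T"), _row("rs2")])
        b = _stats_frame([_row("rs1", "A", "T"), _row("rs2")])
        paired = bv.harmonize(a, b)
        assert list(paired.table["SNP"]) == ["rs2"]
        assert paired.n_dropped_ambiguous == 1

    def test_irreconcilable_alleles_dropped_with_count(self):
        a = _stats_frame([_row("rs1", "A", "G"), _row("rs2")])
        b = _stats_frame([_row("rs1", "A", "C"), _row("rs2")])
        paired = bv.harmonize(a, b)
        assert list(paired.table["SNP"]) == ["rs2"]
        assert paired.n_dropped_mismatch == 1

    def test_zero_overlap_rejected(self):
        a = _stats_frame([_row("rs1")])
        b = _stats_frame([_row("rs2")])
        with pytest.raises(ValueError, match="shared"):
            bv.harmonize(a, b)


class TestNullCorrelation:
    def test_perfectly_correlated_clamped(self):
        z = np.random.default_rng(0).normal(size=500)
        t = pd.DataFrame({"Z_A": z, "Z_B": z})
        paired = bv.PairedSummaryStats(t, np.eye(2))
        R = bv.estimate_null_correlation(paired)
        assert R[0, 1] == pytest.approx(0.999)

    def test_independent_z_near_zero(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame({"Z_A": rng.normal(size=10_000),
                          "Z_B": rng.normal(size=10_000)})
        R = bv.estimate_null_correlation(bv.PairedSummaryStats(t, np.eye(2)),
                                         truncation_correction=False)
        assert abs(R[0, 1]) < 0.03

    @pytest.mark.parametrize("r_true", [0.3, 0.5])
    def test_generator_overlap_recovered(self, r_true):
        cfg = syn.SimulationConfig(seed=4, n_snps=50_000,
                                   overlap_correlation=r_true)
        paired = bv.harmonize(*syn.gen_summary_stats(cfg))
        R = bv.estimate_null_correlation(paired)
        assert R[0, 1] == pytest.approx(r_true, abs=0.02)

    def test_too_few_null_snps_rejected(self):
        t = pd.DataFrame({"Z_A": np.full(50, 5.0), "Z_B": np.full(50, 5.0)})
        with pytest.raises(ValueError, match="null SNPs"):
            bv.estimate_null_correlation(bv.PairedSummaryStats(t, np.eye(2)))


class TestShom:
    def test_zero_z_gives_p_one(self):
        s, p = bv.shom(np.zeros(2), np.eye(2), np.ones(2))
        assert s == 0 and p == 1

    def test_antisymmetric_effects_cancel(self):
        s, _ = bv.shom(np.array([3.0, -3.0]), np.eye(2), np.ones(2))
        assert s == pytest.approx(0.0)

    def test_closed_form_and_monte_carlo_null(self, rng):
        s, p = bv.shom(np.array([2.0, 2.0]), np.eye(2), np.ones(2))
        assert s == pytest.approx(8.0)
        z = rng.normal(size=(200_000, 2))
        stat = (z.sum(axis=1)) ** 2 / 2
        freq = (stat >= 8.0).mean()
        assert freq == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / 2e5))

    def test_single_trait_reduces_to_z_squared(self):
        for z in (0.3, -1.7, 4.2):
            s, p = bv.shom(np.array([z]), np.eye(1), np.array([2.0]))
            assert abs(s - z * z) < 1e-12
            assert abs(p - 2 * sps.norm.sf(abs(z))) < 1e-12

    def test_non_positive_denominator_rejected(self):
        R = np.array([[1.0, -1.0], [-1.0, 1.0]])  # w'Rw = 0 for equal w
        with pytest.raises(ValueError):
            bv.shom(np.ones(2), R, np.ones(2))


class TestShet:
    def test_zero_z_scores_zero(self):
        assert bv.shet(np.zeros(2), np.eye(2), np.ones(2)) == 0

    def test_single_survivor_reduces_to_z_squared(self):
        s = bv.shet(np.array([5.0, 0.0]), np.eye(2), np.ones(2),
                    threshold_grid=[1.0])
        assert s == pytest.approx(25.0)

    def test_matches_brute_force_oracle(self, rng):
        """shet equals the max over the grid of shom restricted to the
        surviving trait subset, computed by independent enumeration."""
        R = np.array([[1.0, 0.3], [0.3, 1.0]])
        w = np.array([1.3, 0.9])
        grid = bv.DEFAULT_SHET_GRID
        z = rng.multivariate_normal([0, 0], R, size=2000)
        vec = bv.shet_vector(z[:, 0], z[:, 1], R, w, grid)
        for i in range(z.shape[0]):
            best = 0.0
            for t in grid:
                idx = [j for j in range(2) if abs(z[i, j]) >= t]
                if not idx:
                    continue
                zz = z[i, idx]
                ww = w[idx]
                RR = R[np.ix_(idx, idx)]
                best = max(best, float(ww @ zz) ** 2 / float(ww @ RR @ ww))
            assert vec[i] == pytest.approx(best, rel=1e-12)
            assert bv.shet(z[i], R, w, grid) == pytest.approx(best, rel=1e-12)


class TestGammaNull:
    def test_parameter_recovery(self, rng):
        v = rng.gamma(shape=2.0, scale=1.0, size=100_000)
        shape, scale, _ = bv.fit_gamma_null(v)
        assert 1.95 <= shape <= 2.05

    def test_p_monotone_in_statistic(self, rng):
        v = rng.gamma(2.0, 1.0, size=5000)
        _, _, p = bv.fit_gamma_null(v)
        assert p[np.argmax(v)] <= p[np.argsort(v)[len(v) // 2]]

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate|constant"):
            bv.fit_gamma_null(np.full(2000, 3.0))


class TestDlc:
    def test_zero_z(self):
        s, p = bv.dlc(np.zeros(2), np.eye(2))
        assert s == 0 and p == 1

    def test_identity_R_closed_form_vs_monte_carlo(self, rng):
        s, p = bv.dlc(np.array([2.0, 2.0]), np.eye(2))
        assert s == pytest.approx(8.0)
        z = rng.normal(size=(200_000, 2))
        freq = ((z ** 2).sum(axis=1) >= 8.0).mean()
        assert freq == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / 2e5))

    def test_near_singular_R_rejected(self):
        R = np.array([[1.0, 0.9999999], [0.9999999, 1.0]])
        with pytest.raises(ValueError, match="singular"):
            bv.dlc(np.ones(2), R)


class TestSelectPleiotropic:
    @pytest.mark.parametrize("ps,expect_pass,expect_flags", [
        ((1e-7, 1e-4, 1e-3), True, (True, True, True)),
        ((1e-5, 1e-8, 1e-8), False, (False, False, True)),
        ((1e-7, 0.2, 1e-4), False, (True, True, False)),
    ])
    def test_printed_criteria(self, ps, expect_pass, expect_flags):
        call = bv.select_pleiotropic(*ps)
        assert call.passes is expect_pass
        assert call.criterion_flags == expect_flags

    def test_published_lead_snp_passes_filter(self):
        """The central published locus (bivariate 1.83e-7; univariate
        2.96e-3 and 2.26e-6) must pass, which pins the ratio criterion to
        the weaker univariate p (the strict both-traits reading rejects
        it with ratio 0.081)."""
        call = bv.select_pleiotropic(1.83e-7, 2.96e-3, 2.26e-6)
        assert call.passes
        strict = bv.select_pleiotropic(1.83e-7, 2.96e-3, 2.26e-6,
                                       ratio_any=False)
        assert not strict.passes

    @given(st.floats(1e-30, 1.0), st.floats(1e-30, 1.0),
           st.floats(1e-30, 1.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_bivariate_p(self, pb, pa, pvb):
        """Decreasing the bivariate p never flips a pass to a fail."""
        if bv.select_pleiotropic(pb, pa, pvb).passes:
            assert bv.select_pleiotropic(pb / 10, pa, pvb).passes

    def test_strict_both_traits_ratio_mode(self):
        # ratio holds vs trait A only: default (any) passes, strict fails
        ps = (1e-7, 1e-4, 1e-6)
        assert bv.select_pleiotropic(*ps).passes
        assert not bv.select_pleiotropic(*ps, ratio_any=False).passes


class TestClumping:
    def _calls(self, rows):
        return pd.DataFrame(rows,
                            columns=["SNP", "CHR", "BP", "P_BIVAR", "PASS"])

    def test_nearby_snps_share_locus_with_best_lead(self):
        out = bv.clump_loci(self._calls([
            ["a", 1, 100_000, 1e-8, True],
            ["b", 1, 110_000, 1e-7, True]]))
        assert out["LOCUS"].tolist() == [0, 0]
        assert out["LEAD"].tolist() == [True, False]

    def test_chromosomes_split_loci(self):
        out = bv.clump_loci(self._calls([
            ["a", 1, 100, 1e-8, True],
            ["b", 2, 100, 1e-8, True]]))
        assert out["LOCUS"].nunique() == 2

    def test_tie_breaks_by_position(self):
        out = bv.clump_loci(self._calls([
            ["b", 1, 10_000, 1e-8, True],
            ["a", 1, 100, 1e-8, True]]))
        lead = out[out["LEAD"]]
        assert len(lead) == 1 and lead["BP"].iloc[0] == 100

    def test_non_passing_snps_unassigned(self):
        out = bv.clump_loci(self._calls([
            ["a", 1, 100, 1e-8, True],
            ["b", 1, 200, 0.5, False]]))
        assert out.loc[1, "LOCUS"] == -1


class TestPipelineRecovery:
    def test_planted_loci_recovered(self):
        """Strongly pleiotropic planted loci pass the three-criterion
        filter and come out as clumped loci (>= 90% recovery)."""
        planted = tuple((i * 500, 5.9, 5.9) for i in range(10))
        cfg = syn.SimulationConfig(seed=13, n_snps=5000,
                                   overlap_correlation=0.3,
                                   planted_loci=planted)
        paired = bv.harmonize(*syn.gen_summary_stats(cfg))
        bv.estimate_null_correlation(paired)
        res = bv.bivariate_scan(paired, method="shom")
        planted_ids = {f"rs{i}" for i, _, _ in planted}
        hit = res[res["SNP"].isin(planted_ids) & res["PASS"]]
        assert len(hit) >= 9
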