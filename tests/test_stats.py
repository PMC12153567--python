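import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import oracles
from flygroup import stats


class TestRepresentatives:
    def test_constant_trials(self):
        assert stats.trial_representatives([2, 2, 2]) == (2.0, 0.0, 0.0)

    def test_cv_is_sd_over_mean(self):
        m, sd, cv = stats.trial_representatives([5, 15])
        assert (m, cv) == (10.0, sd / 10.0)

    def test_zero_mean_cv_missing(self):
        _, _, cv = stats.trial_representatives([-1, 1])
        assert math.isnan(cv)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            stats.trial_representatives([1.0])


class TestFriedman:
    def test_perfect_agreement_closed_form(self):
        # 8 blocks, 4 treatments, identical ordering: chi2 = 24
        m = np.tile([1.0, 2.0, 3.0, 4.0], (8, 1)) + np.arange(8)[:, None] * 10
        res = stats.friedman_test(m)
        assert res.statistic == pytest.approx(24.0)

    def test_fully_tied_blocks_zero(self):
        res = stats.friedman_test(np.ones((5, 3)))
        assert (res.statistic, res.p) == (0.0, 1.0)

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(8, 4))
        ours = stats.friedman_test(m)
        chi2, p = sps.friedmanchisquare(*m.T)
        assert ours.statistic == pytest.approx(chi2)
        assert ours.p == pytest.approx(p)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        m = rng.uniform(1, 10, size=(6, 5))
        a = stats.friedman_test(m)
        b = stats.friedman_test(np.log(m) ** 3 + 2)  # strictly increasing map
        assert a.statistic == pytest.approx(b.statistic)

    def test_k2_reduces_to_sign_ordering(self):
        # with two treatments and no within-block ties, chi2 depends only on
        # how many blocks prefer treatment 1: rank sums (n + w, 2n - w)
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = rng.normal(size=(8, 2))
            w = int((m[:, 0] > m[:, 1]).sum())
            n = m.shape[0]
            r1 = n + (n - w)  # losers contribute rank 1, winners rank 2
            r2 = n + w
            expected = 12.0 / (n * 2 * 3) * (r1**2 + r2**2) - 3 * n * 3
            assert stats.friedman_test(m).statistic == pytest.approx(expected)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            stats.friedman_test(np.ones((1, 4)))


class TestWilcoxonExact:
    @pytest.mark.parametrize(
        "diffs, w, p3",
        [
            (list(range(1, 9)), 0.0, 0.008),  # all one sign
            ([-1, 2, 3, 4, 5, 6, 7, 8], 1.0, 0.016),
            ([-1, 2, -3, 4, 5, 6, 7, 8], 4.0, 0.055),
        ],
    )
    def test_combinatorially_forced_pairs_at_n8(self, diffs, w, p3):
        res = stats.wilcoxon_signed_rank(diffs)
        assert res.statistic == w
        assert round(res.p, 3) == p3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sign_pattern_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        d = rng.integers(-20, 20, size=n).astype(float)
        d[d == 0] = 1.0
        res = stats.wilcoxon_signed_rank(d)
        w_o, p_o = oracles.wilcoxon_min_rank_sum_p(list(d))
        assert res.statistic == pytest.approx(w_o)
        assert res.p == pytest.approx(p_o)

    def test_matches_scipy_exact_mode(self):
        rng = np.random.default_rng(3)
        d = rng.normal(size=10)  # continuous: no ties, no zeros
        ours = stats.wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, mode="exact")
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue)

    def test_zeros_dropped(self):
        a = stats.wilcoxon_signed_rank([0.0, 1, 2, 3, 4])
        b = stats.wilcoxon_signed_rank([1, 2, 3, 4])
        assert (a.statistic, a.p, a.n) == (b.statistic, b.p, 4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            stats.wilcoxon_signed_rank([0.0, 0.0, 0.0])

    def test_normal_approximation_beyond_cutoff(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.5, 1, size=25)
        res = stats.wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, mode="approx", correction=False)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestPairedPermutation:
    def test_all_positive_n8(self):
        res = stats.paired_permutation([3, 1, 4, 1.5, 5, 9, 2.6, 5.3])
        assert res.p == pytest.approx(2 / 256)

    def test_two_opposite_differences(self):
        assert stats.paired_permutation([1.0, -1.0]).p == 1.0

    def test_scale_invariance(self):
        d = [0.5, -1.2, 3.0, 2.2, -0.1]
        assert stats.paired_permutation(d).p == stats.paired_permutation(
            [x * 7.3 for x in d]
        ).p

    def test_all_zero_p_one(self):
        assert stats.paired_permutation([0.0, 0.0, 0.0]).p == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(size=int(rng.integers(2, 11)))
        res = stats.paired_permutation(d)
        assert res.p == pytest.approx(oracles.permutation_mean_p(list(d)))
        assert res.statistic == pytest.approx(d.mean())

    def test_monte_carlo_beyond_cutoff_is_seeded(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.3, 1, size=20)
        a = stats.paired_permutation(d, seed=42)
        b = stats.paired_permutation(d, seed=42)
        assert a.p == b.p
        assert 0 < a.p <= 1


class TestRmAnova:
    def test_pure_subject_offsets_give_zero_f(self):
        y = np.zeros((4, 2, 3)) + np.arange(4)[:, None, None] * 5.0
        res = stats.rm_anova_two_way(y)
        assert res["A"].statistic == pytest.approx(0.0)
        assert res["B"].statistic == pytest.approx(0.0)

    def test_pure_factor_effect_detected(self):
        y = np.zeros((4, 2, 3))
        y[:, 1, :] = 1.0  # exact A effect, zero noise
        res = stats.rm_anova_two_way(y)
        assert res["A"].p == pytest.approx(0.0)
        assert res["B"].statistic == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_ss_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(4, 2, 3))
        res = stats.rm_anova_two_way(y)
        f_a, f_b, f_ab = oracles.rm_anova_f(y.tolist())
        assert res["A"].statistic == pytest.approx(f_a, abs=1e-10)
        assert res["B"].statistic == pytest.approx(f_b, abs=1e-10)
        assert res["A×B"].statistic == pytest.approx(f_ab, abs=1e-10)

    def test_missing_cells_rejected(self):
        y = np.ones((3, 2, 2))
        y[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="unbalanced"):
            stats.rm_anova_two_way(y)


class TestMultiplicity:
    def test_pair_counts(self):
        assert stats.count_pairs(4) == 6
        assert stats.count_pairs(6) == 15
        assert stats.count_pairs(2) == 1

    def test_adjusted_alphas(self):
        assert stats.adjust_alpha(0.05, 6) == pytest.approx(0.0083, abs=5e-5)
        assert stats.adjust_alpha(0.05, 15) == pytest.approx(0.00333, abs=5e-6)
        assert stats.adjust_alpha(0.05, 1) == 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            stats.count_pairs(1)
        with pytest.raises(ValueError):
            stats.adjust_alpha(0.05, 0)


@pytest.fixture(scope="module")
def comparison_tidy():
    rng = np.random.default_rng(17)
    areas = ["food-provision", "center-diffusion", "intermediate", "edge"]
    phases = ["PI", "PII", "PIII", "P-S", "SI", "SII"]
    rows = []
    for strain in ("wild", "mutant"):
        for trial in range(1, 9):
            for i, a in enumerate(areas):
                for j, p in enumerate(phases):
                    rows.append(
                        {
                            "trial": f"t{trial}",
                            "strain": strain,
                            "area": a,
                            "phase": p,
                            "parameter": "speed",
                            "value": rng.lognormal(0.1 * i - 0.05 * j, 0.3),
                        }
                    )
    return pd.DataFrame(rows)


class TestRunComparisons:
    def test_six_area_pairs_per_phase_at_divided_alpha(self, comparison_tidy):
        res = stats.run_comparisons(comparison_tidy)
        sub = res[
            (res.strain == "wild") & (res.factor == "area") & (res.held == "PI")
            & (res.test == "wilcoxon")
        ]
        assert len(sub) == 6
        assert np.allclose(sub.adjusted_alpha, 0.05 / 6)

    def test_fifteen_phase_pairs_per_area(self, comparison_tidy):
        res = stats.run_comparisons(comparison_tidy)
        sub = res[
            (res.strain == "wild") & (res.factor == "phase") & (res.held == "edge")
            & (res.test == "permutation")
        ]
        assert len(sub) == 15
        assert np.allclose(sub.adjusted_alpha, 0.05 / 15)

    def test_coupled_cells_total_24(self, comparison_tidy):
        n_areas = comparison_tidy.area.nunique()
        n_phases = comparison_tidy.phase.nunique()
        assert n_areas * n_phases == 24
        res = stats.run_comparisons(comparison_tidy)
        strain_rows = res[res.factor == "strain"]
        # both tests in each of the 24 (area, phase) cells
        assert len(strain_rows) == 24 * 2

    def test_friedman_precedes_pairwise(self, comparison_tidy):
        res = stats.run_comparisons(comparison_tidy)
        fr = res[(res.test == "friedman") & (res.factor == "area")]
        assert len(fr[fr.strain == "wild"]) == 6  # one screen per phase


class TestTypeIError:
    def test_permutation_level_under_null(self):
        # symmetric null: exact test at n = 8 should reject at <= alpha
        rng = np.random.default_rng(2024)
        n_sim, alpha = 2000, 0.05
        rejections = 0
        for _ in range(n_sim):
            d = rng.normal(0, 1, size=8)
            if stats.paired_permutation(d).p < alpha:
                rejections += 1
        rate = rejections / n_sim
        se = math.sqrt(alpha * (1 - alpha) / n_sim)
        assert rate <= alpha + 2 * se
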