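"""Spearman concordance, bootstrap null, attenuation slope, paired comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from episeq import (
    DegenerateNullError,
    InsufficientDataError,
    ParameterError,
    SingularFitError,
    attenuation_fit,
    bootstrap_null_concordance,
    merge_by_gene,
    paired_group_comparison,
    spearman_rho,
)
from conftest import make_de_table
from oracles import signed_rank_exact_p, spearman_reference


def _merged(a_vals, b_vals, genes=None):
    genes = genes or [f"g{i:04d}" for i in range(len(a_vals))]
    a = make_de_table(genes, a_vals, label="A")
    b = make_de_table(genes, b_vals, label="B")
    return merge_by_gene(a, b)


class TestSpearmanRho:
    def test_monotone_linear_map_is_perfect(self):
        x = np.array([3.0, 1.0, 7.0, 2.0])
        assert spearman_rho(x, 2 * x + 1) == pytest.approx(1.0)

    def test_reversal_is_minus_one(self):
        x = np.arange(10.0)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_aligned_ties_still_perfect(self):
        assert spearman_rho([1, 2, 2, 4], [10, 20, 20, 40]) == pytest.approx(1.0)

    def test_matches_hand_rank_computation(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            x = np.round(rng.normal(size=30), 1)
            y = np.round(rng.normal(size=30), 1)
            assert spearman_rho(x, y) == pytest.approx(spearman_reference(x, y))

    def test_missing_pairs_dropped(self):
        x = [1.0, np.nan, 3.0, 4.0]
        y = [1.0, 2.0, 3.0, 4.0]
        assert spearman_rho(x, y) == pytest.approx(1.0)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            spearman_rho([1.0, 2.0], [1.0, 2.0])

    @given(seed=st.integers(0, 300))
    @settings(max_examples=40, derandomize=True)
    def test_invariant_under_increasing_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=20), rng.normal(size=20)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(base)
        assert spearman_rho(x, y**3) == pytest.approx(base)


class TestBootstrapNull:
    def test_selected_equal_to_universe_is_degenerate(self):
        rng = np.random.default_rng(0)
        merged = _merged(rng.normal(size=50), rng.normal(size=50))
        with pytest.raises(DegenerateNullError):
            bootstrap_null_concordance(merged, merged.genes, n_iter=200, seed=0)

    def test_same_seed_reproduces_null_exactly(self):
        rng = np.random.default_rng(1)
        merged = _merged(rng.normal(size=300), rng.normal(size=300))
        sel = set(list(merged.genes)[:40])
        r1 = bootstrap_null_concordance(merged, sel, n_iter=500, seed=42)
        r2 = bootstrap_null_concordance(merged, sel, n_iter=500, seed=42)
        assert (r1.null_mean, r1.null_sd, r1.z_score) == (
            r2.null_mean,
            r2.null_sd,
            r2.z_score,
        )

    def test_null_summary_stable_across_n_iter(self):
        rng = np.random.default_rng(2)
        merged = _merged(rng.normal(size=500), rng.normal(size=500))
        sel = set(sorted(merged.genes)[:50])
        a = bootstrap_null_concordance(merged, sel, n_iter=10_000, seed=1)
        b = bootstrap_null_concordance(merged, sel, n_iter=20_000, seed=2)
        assert a.null_mean == pytest.approx(b.null_mean, abs=0.01)
        assert a.null_sd == pytest.approx(b.null_sd, rel=0.1)

    def test_planted_concordance_detected(self):
        rng = np.random.default_rng(3)
        signal = rng.normal(size=400)
        a = np.concatenate([signal + 0.1 * rng.normal(size=400), rng.normal(size=600)])
        b = np.concatenate([0.5 * signal + 0.1 * rng.normal(size=400), rng.normal(size=600)])
        merged = _merged(a, b)
        sel = {f"g{i:04d}" for i in range(400)}
        res = bootstrap_null_concordance(merged, sel, n_iter=2000, seed=5)
        assert res.z_score > 4
        assert res.log_p_one_sided < np.log(0.001)

    def test_n_iter_floor(self):
        merged = _merged([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ParameterError):
            bootstrap_null_concordance(merged, {"g0000", "g0001", "g0002"}, n_iter=10)

    def test_selected_outside_merged_rejected(self):
        merged = _merged([1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0])
        with pytest.raises(ParameterError):
            bootstrap_null_concordance(
                merged, {"g0000", "g0001", "alien"}, n_iter=200, seed=0
            )


class TestAttenuationFit:
    def test_identity_fit(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        merged = _merged(x, x)
        fit = attenuation_fit(merged, merged.genes, response="A", predictor="B")
        assert fit.beta_upstream == pytest.approx(1.0)
        assert fit.beta0 == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noiseless_half_slope_zero_width_ci(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        merged = _merged(0.5 * x, x)
        fit = attenuation_fit(merged, merged.genes, response="A", predictor="B")
        assert fit.beta_upstream == pytest.approx(0.5)
        assert fit.ci95[0] == pytest.approx(0.5, abs=1e-9)
        assert fit.ci95[1] == pytest.approx(0.5, abs=1e-9)

    def test_ci_uses_t_distribution_small_sample(self):
        rng = np.random.default_rng(8)
        x = np.arange(1.0, 7.0)
        y = 0.4 * x + rng.normal(0, 0.05, size=6)
        merged = _merged(y, x)
        fit = attenuation_fit(merged, merged.genes, response="A", predictor="B")
        # hand computation of the t-based CI with n - 2 = 4 df
        from scipy import stats as ss

        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        se = np.sqrt(resid @ resid / 4 / ((x - x.mean()) @ (x - x.mean())))
        half = ss.t.ppf(0.975, 4) * se
        assert fit.beta_upstream == pytest.approx(slope)
        assert fit.ci95[0] == pytest.approx(slope - half)
        assert fit.ci95[1] == pytest.approx(slope + half)

    def test_zero_predictor_variance(self):
        merged = _merged([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        with pytest.raises(SingularFitError):
            attenuation_fit(merged, merged.genes, response="A", predictor="B")


class TestPairedGroupComparison:
    def test_identical_fold_changes_give_p_one(self):
        x = np.arange(8.0)
        merged = _merged(x, x)
        res = paired_group_comparison(merged, merged.genes)
        assert res.p_value == 1.0 and res.all_zero

    def test_six_positive_differences_exact_p(self):
        a = np.array([1.1, 2.2, 3.3, 4.4, 5.5, 6.6])
        b = a - np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        merged = _merged(a, b)
        res = paired_group_comparison(merged, merged.genes)
        assert res.p_value == pytest.approx(0.03125)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            a = rng.normal(size=9)
            b = rng.normal(size=9)
            merged = _merged(a, b)
            res = paired_group_comparison(merged, merged.genes)
            assert res.p_value == pytest.approx(signed_rank_exact_p(a - b))

    def test_medians_reported_per_dataset(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        b = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        res = paired_group_comparison(_merged(a, b), {f"g{i:04d}" for i in range(5)})
        assert res.median_a == pytest.approx(3.0)
        assert res.median_b == pytest.approx(2.0)

    def test_group_too_small(self):
        merged = _merged([1.0, 2.0, 3.0, 4.0], [0.0, 1.0, 2.0, 3.0])
        with pytest.raises(InsufficientDataError):
            paired_group_comparison(merged, {"g0000", "g0001", "g0002"})

    def test_type_one_error_calibrated_under_equal_effects(self):
        """Equal true effects with independent noise on both sides: the paired
        test rejects at ~alpha."""
        rejections = 0
        n_seeds = 500
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            signal = rng.normal(size=20)
            a = signal + 0.2 * rng.normal(size=20)
            b = signal + 0.2 * rng.normal(size=20)
            res = paired_group_comparison(_merged(a, b), {f"g{i:04d}" for i in range(20)})
            rejections += res.p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / n_seeds)
        assert abs(rejections / n_seeds - 0.05) <= 3 * se

    def test_ttest_switch(self):
        rng = np.random.default_rng(23)
        a, b = rng.normal(size=12), rng.normal(size=12)
        res = paired_group_comparison(_merged(a, b), {f"g{i:04d}" for i in range(12)}, method="ttest")
        from scipy import stats as ss

        assert res.p_value == pytest.approx(ss.ttest_rel(a, b).pvalue)
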