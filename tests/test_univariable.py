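"""Univariable MR estimators: Wald ratio, IVW, Egger, weighted median, conmix."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrchain import (
    contamination_mixture,
    egger,
    ivw,
    wald_ratio,
    weighted_median,
)
from mrchain.validation import contamination_experiment, egger_oracle, ivw_oracle

from conftest import make_harmonized


class TestWaldRatio:
    def test_identity_instrument(self):
        assert wald_ratio(1.0, 0.01, 0.3, 0.02).beta == pytest.approx(0.3)

    def test_first_order_formula(self):
        est = wald_ratio(0.1, 0.0, 0.05, 0.02)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)

    def test_second_order_se_matches_monte_carlo(self):
        bx, sx, by, sy = 0.1, 0.01, 0.05, 0.02
        est = wald_ratio(bx, sx, by, sy, second_order=True)
        rng = np.random.default_rng(99)
        draws = rng.normal(by, sy, 1_000_000) / rng.normal(bx, sx, 1_000_000)
        assert est.se == pytest.approx(np.std(draws), rel=0.02)


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        h = make_harmonized([0.1], [0.01], [0.05], [0.02])
        est = ivw(h)
        ref = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)

    def test_exact_proportionality_gives_zero_q(self):
        bx = np.array([0.02, 0.05, 0.08])
        h = make_harmonized(bx, 0.001 * np.ones(3), 0.7 * bx, 0.01 * np.ones(3))
        est = ivw(h, model="random")
        assert est.beta == pytest.approx(0.7)
        assert est.info["q"] == pytest.approx(0.0, abs=1e-20)
        # with Q = 0 the random-effects SE equals the fixed-effects SE
        assert est.se == pytest.approx(ivw(h, model="fixed").se)

    def test_matches_wls_oracle_to_ten_digits(self, clean_harmonized):
        est = ivw(clean_harmonized, model="fixed")
        beta, se = ivw_oracle(clean_harmonized)
        assert est.beta == pytest.approx(beta, rel=1e-10)
        assert est.se == pytest.approx(se, rel=1e-10)

    def test_fixed_equals_ratio_weighted_mean(self, clean_harmonized):
        h = clean_harmonized
        est = ivw(h, model="fixed")
        w = h.beta_x**2 / h.se_y**2
        ratios = h.beta_y / h.beta_x
        assert est.beta == pytest.approx(np.sum(w * ratios) / np.sum(w), rel=1e-12)

    def test_all_zero_exposure_betas_raise(self):
        h = make_harmonized([0.0, 0.0], [0.01] * 2, [0.01, 0.02], [0.01] * 2)
        with pytest.raises(ValueError):
            ivw(h)

    @given(c=st.floats(0.1, 10), flip=st.booleans())
    def test_scale_and_sign_equivariance(self, c, flip):
        rng = np.random.default_rng(11)
        bx = rng.uniform(0.02, 0.08, 25) * rng.choice([-1, 1], 25)
        sy = rng.uniform(0.005, 0.02, 25)
        by = 0.3 * bx + rng.normal(0, sy)
        h = make_harmonized(bx, 0.002, by, sy)
        base = ivw(h, model="fixed").beta
        sgn = -1.0 if flip else 1.0
        h2 = make_harmonized(c * bx, c * 0.002, sgn * by, sy)
        assert ivw(h2, model="fixed").beta == pytest.approx(sgn * base / c, rel=1e-9)


class TestEgger:
    def test_matches_normal_equations_oracle(self, clean_harmonized):
        slope, intercept = egger(clean_harmonized)
        oi, osl = egger_oracle(clean_harmonized)
        assert slope.beta == pytest.approx(osl, rel=1e-10)
        assert intercept.beta == pytest.approx(oi, rel=1e-6, abs=1e-12)

    def test_constant_outcome_shift_moves_intercept_only(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.02, 0.08, 20)  # positive: orientation is a no-op
        sy = np.full(20, 0.01)
        by = 0.4 * bx + rng.normal(0, sy)
        h1 = make_harmonized(bx, 0.002, by, sy)
        h2 = make_harmonized(bx, 0.002, by + 0.03, sy)
        s1, i1 = egger(h1)
        s2, i2 = egger(h2)
        assert s2.beta == pytest.approx(s1.beta, rel=1e-9)
        assert i2.beta - i1.beta == pytest.approx(0.03, rel=1e-9)

    def test_requires_three_snps(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        with pytest.raises(ValueError):
            egger(h)

    def test_intercept_coverage_without_pleiotropy(self):
        """Zero-pleiotropy simulation: intercept CI covers 0 in >= 93% of 500 reps."""
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(500):
            bx0 = rng.uniform(0.015, 0.08, 40) * rng.choice([-1, 1], 40)
            sy = np.full(40, 0.0086)
            by = 0.3 * bx0 + rng.normal(0, sy)
            bx = bx0 + rng.normal(0, 0.0025, 40)
            _, intercept = egger(make_harmonized(bx, 0.0025, by, sy))
            hits += intercept.ci_low <= 0 <= intercept.ci_high
        assert hits / 500 >= 0.93


class TestWeightedMedian:
    def test_equal_weight_median(self):
        # ratios 0.2, 0.5, 0.9 with equal weights -> 0.5
        bx = np.ones(3)
        by = np.array([0.2, 0.5, 0.9])
        h = make_harmonized(bx, 0.01, by, np.ones(3) * 0.05)
        assert weighted_median(h, n_boot=100, seed=0).beta == pytest.approx(0.5)

    def test_degenerate_equal_ratios(self):
        bx = np.array([0.02, 0.05, 0.08])
        h = make_harmonized(bx, 1e-6 * np.ones(3), 0.6 * bx, 1e-6 * np.ones(3))
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.6, abs=1e-3)
        assert est.se < 1e-3

    def test_estimate_within_ratio_range(self, clean_harmonized):
        est = weighted_median(clean_harmonized, n_boot=50, seed=2)
        ratios = clean_harmonized.beta_y / clean_harmonized.beta_x
        assert ratios.min() <= est.beta <= ratios.max()

    def test_seeded_bootstrap_reproducible(self, clean_harmonized):
        a = weighted_median(clean_harmonized, seed=7)
        b = weighted_median(clean_harmonized, seed=7)
        assert a.se == b.se

    def test_robust_to_forty_percent_invalid(self):
        """Directional contamination: the median stays near truth, IVW drifts."""
        res = contamination_experiment(seed=21, n_rep=60)
        assert abs(res["wm_mean"] - 0.3) < abs(res["ivw_mean"] - 0.3)
        assert res["wm_bias_se_ratio"] < res["ivw_bias_se_ratio"]


class TestContaminationMixture:
    def test_single_snp_is_ratio(self):
        h = make_harmonized([0.1], [0.01], [0.05], [0.02])
        res = contamination_mixture(h)
        assert res.estimate.beta == pytest.approx(0.5, abs=1e-2)
        assert res.valid_snps == h.snp_ids

    def test_profile_maximum_at_estimate(self, clean_harmonized):
        res = contamination_mixture(clean_harmonized)
        grid, ll = res.profile[:, 0], res.profile[:, 1]
        assert grid[np.argmax(ll)] == res.estimate.beta
        assert res.estimate.ci_low <= res.estimate.beta <= res.estimate.ci_high

    def test_agrees_with_ivw_when_all_valid(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.04, 0.08, 50) * rng.choice([-1, 1], 50)
        sy = np.full(50, 0.002)  # tight outcome SEs
        by = 0.25 * bx + rng.normal(0, sy)
        h = make_harmonized(bx, 1e-4, by, sy)
        cm = contamination_mixture(h).estimate
        e = ivw(h)
        joint_se = np.hypot(cm.se, e.se)
        assert abs(cm.beta - e.beta) < joint_se

    def test_recovers_planted_invalid_classification(self):
        """30% of 100 SNPs shifted by +0.5: >= 80% classification accuracy."""
        rng = np.random.default_rng(8)
        k, k_inv = 100, 30
        bx = rng.uniform(0.04, 0.08, k) * rng.choice([-1, 1], k)
        sy = np.full(k, 0.002)
        shift = np.zeros(k)
        shift[:k_inv] = 0.5
        by = (0.2 + shift) * bx + rng.normal(0, sy)
        h = make_harmonized(bx, 1e-4, by, sy)
        res = contamination_mixture(h)
        predicted_invalid = set(res.invalid_snps)
        true_invalid = set(h.snp_ids[:k_inv])
        correct = sum(
            (s in predicted_invalid) == (s in true_invalid) for s in h.snp_ids
        )
        assert correct / k >= 0.80

    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_scale_equivariance(self, c, clean_harmonized):
        h = clean_harmonized
        base = contamination_mixture(h).estimate.beta
        h2 = make_harmonized(c * h.beta_x, c * h.se_x, h.beta_y, h.se_y)
        assert contamination_mixture(h2).estimate.beta == pytest.approx(base / c, rel=1e-9)

    def test_sign_equivariance(self, clean_harmonized):
        h = clean_harmonized
        base = contamination_mixture(h).estimate.beta
        h2 = make_harmonized(h.beta_x, h.se_x, -h.beta_y, h.se_y)
        assert contamination_mixture(h2).estimate.beta == pytest.approx(-base, rel=1e-9)
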