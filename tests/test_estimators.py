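"""Univariable estimators: Wald ratio, IVW, MR-Egger, weighted median, modes."""

import numpy as np
import pytest

from mrpipe.estimators import (
    InsufficientInstrumentsError,
    egger,
    ivw,
    mode_estimator,
    wald_ratio,
    weighted_median,
)
from mrpipe.estimators import _weighted_median_rows

from conftest import make_harmonized, random_harmonized


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,sx,by,sy,beta,se",
        [
            (0.1, 0.01, 0.05, 0.02, 0.5, 0.2),
            (0.1, 0.01, 0.0, 0.02, 0.0, 0.2),
            (-0.2, 0.01, 0.05, 0.02, -0.25, 0.1),
        ],
    )
    def test_ratio_and_first_order_se(self, bx, sx, by, sy, beta, se):
        est = wald_ratio(bx, sx, by, sy)
        assert est.beta == pytest.approx(beta)
        assert est.se == pytest.approx(se)

    def test_zero_exposure_beta_is_error(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)

    def test_second_order_se_is_larger(self):
        first = wald_ratio(0.1, 0.05, 0.05, 0.02)
        second = wald_ratio(0.1, 0.05, 0.05, 0.02, second_order=True)
        assert second.se > first.se


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        h = make_harmonized([0.1], [0.01], [0.05], [0.02])
        est = ivw(h)
        ref = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.beta == ref.beta
        assert est.se == ref.se
        assert est.pval == ref.pval
        assert est.method == "ivw"

    def test_identical_ratios_give_zero_q_fixed_model(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(bx, [0.01] * 3, 0.4 * bx, [0.02] * 3)
        est = ivw(h)
        assert est.beta == pytest.approx(0.4)
        assert est.q_stat == pytest.approx(0.0, abs=1e-20)
        assert est.model == "fixed"

    def test_matches_weighted_regression_oracle(self, rng):
        import statsmodels.api as sm

        h = random_harmonized(rng, k=10)
        fit = sm.WLS(h.beta_y, h.beta_x[:, None], weights=1.0 / h.se_y**2).fit()
        assert ivw(h).beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_reorder_and_joint_signflip_invariance(self, rng):
        h = random_harmonized(rng, k=15)
        base = ivw(h).beta
        perm = rng.permutation(15)
        assert ivw(h.subset(perm)).beta == pytest.approx(base, rel=1e-12)
        flipped = make_harmonized(-h.beta_x, h.se_x, -h.beta_y, h.se_y)
        assert ivw(flipped).beta == pytest.approx(base, rel=1e-12)

    def test_random_effects_se_never_below_fixed(self, rng):
        bx = rng.uniform(0.1, 0.3, 20)
        by = 0.2 * bx + rng.normal(0, 0.2, 20)  # gross heterogeneity
        h = make_harmonized(bx, [0.01] * 20, by, [0.02] * 20)
        est = ivw(h)
        fixed_se = 1.0 / np.sqrt(np.sum(bx**2 / 0.02**2))
        assert est.model == "random"
        assert est.se >= fixed_se

    def test_or_scale_consistency(self, rng):
        est = ivw(random_harmonized(rng))
        assert est.odds_ratio == pytest.approx(np.exp(est.beta), abs=1e-12)
        lo, hi = est.or_ci
        assert lo < est.odds_ratio < hi


class TestEgger:
    def test_exact_proportional_data(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_harmonized(bx, [0.01] * 4, 0.3 * bx, [0.02] * 4)
        est = egger(h)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_recovery(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_harmonized(bx, [0.01] * 4, 0.02 + 0.3 * bx, [0.02] * 4)
        est = egger(h)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert est.egger_intercept == pytest.approx(0.02, abs=1e-12)

    def test_matches_wls_oracle(self, rng):
        import statsmodels.api as sm

        h = random_harmonized(rng, k=20)
        x = sm.add_constant(h.beta_x)
        fit = sm.WLS(h.beta_y, x, weights=1.0 / h.se_y**2).fit()
        est = egger(h)
        assert est.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)

    def test_needs_three_instruments(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.06], [0.02] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            egger(h)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        h = make_harmonized([0.1] * 3, [0.01] * 3, [0.01, 0.05, 0.09], [0.02] * 3)
        est = weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_matches_interpolation_oracle(self, rng):
        h = random_harmonized(rng, k=9)
        r = h.beta_y / h.beta_x
        w = h.beta_x**2 / h.se_y**2
        order = np.argsort(r)
        r, w = r[order], w[order]
        p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
        expected = np.interp(0.5, p, r)
        est = weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(expected, abs=1e-12)

    def test_dominant_weight_pulls_to_its_ratio(self):
        # one SNP with >50% of total weight at ratio 0.4
        bx = np.array([1.0, 0.1, 0.1])
        by = np.array([0.4, 0.09, 0.095])
        h = make_harmonized(bx, [0.01] * 3, by, [0.02] * 3)
        est = weighted_median(h, n_boot=50, seed=1)
        assert abs(est.beta - 0.4) < abs(est.beta - 0.9)

    def test_vectorized_rows_agree_with_loop(self, rng):
        r = rng.normal(size=(5, 7))
        w = rng.uniform(0.1, 2.0, size=(5, 7))
        batch = _weighted_median_rows(r, w)
        for i in range(5):
            single = _weighted_median_rows(r[i : i + 1], w[i : i + 1])[0]
            assert batch[i] == pytest.approx(single, abs=1e-14)


class TestModes:
    def test_majority_atom(self):
        h = make_harmonized(
            [0.1] * 4, [0.005] * 4, [0.03, 0.03, 0.03, 0.09], [0.01] * 4
        )
        est = mode_estimator(h, weighted=False, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.3, abs=0.05)

    def test_degenerate_identical_ratios(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(bx, [0.01] * 3, 0.7 * bx, [0.02] * 3)
        est = mode_estimator(h, weighted=True, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.7)

    def test_bimodal_plurality_wins(self, rng):
        # 60% of instruments valid at ratio 0.2, 40% invalid at 1.0
        k_valid, k_invalid = 12, 8
        bx = rng.uniform(0.2, 0.4, k_valid + k_invalid)
        sy = np.full(k_valid + k_invalid, 0.003)
        by = np.concatenate([0.2 * bx[:k_valid], 1.0 * bx[k_valid:]])
        by = by + rng.normal(0, sy)
        h = make_harmonized(bx, [0.01] * (k_valid + k_invalid), by, sy)
        est = mode_estimator(h, weighted=False, n_boot=100, seed=2)
        assert abs(est.beta - 0.2) < 2.5 * est.se
        assert abs(est.beta - 0.2) < abs(est.beta - 1.0)

    def test_invalid_phi_rejected(self, rng):
        with pytest.raises(ValueError):
            mode_estimator(random_harmonized(rng), phi=0.0, n_boot=10, seed=1)
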