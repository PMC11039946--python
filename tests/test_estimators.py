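import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrkit import (
    HarmonizedDataset,
    InsufficientInstrumentsError,
    egger_regression,
    estimate_to_summary,
    ivw_random_effects,
    wald_ratio,
    weighted_median,
)


def dataset(beta_exp, beta_out, se_out, se_exp=None):
    beta_exp = np.asarray(beta_exp, dtype=float)
    se_exp = np.full_like(beta_exp, 0.005) if se_exp is None else np.asarray(se_exp)
    return HarmonizedDataset.from_arrays(beta_exp, se_exp, beta_out, se_out)


# ---------------------------------------------------------------- oracles

def wls_through_origin_oracle(x, y, w):
    """Weighted regression through the origin via generic normal equations."""
    xs = np.sqrt(w) * np.asarray(x)
    ys = np.sqrt(w) * np.asarray(y)
    beta, *_ = np.linalg.lstsq(xs[:, None], ys, rcond=None)
    return float(beta[0])


def wls_with_intercept_oracle(x, y, w):
    xs = np.sqrt(w)[:, None] * np.column_stack([np.ones_like(x), x])
    ys = np.sqrt(w) * np.asarray(y)
    coef, *_ = np.linalg.lstsq(xs, ys, rcond=None)
    return float(coef[0]), float(coef[1])


def weighted_quantile_oracle(values, weights, q=0.5):
    """Brute-force interpolated weighted quantile (centred cumulative)."""
    order = np.argsort(values)
    v, w = np.asarray(values)[order], np.asarray(weights)[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(q, s, v))


# ------------------------------------------------------------- wald ratio

class TestWaldRatio:
    def test_zero_outcome_effect(self):
        assert wald_ratio(0.2, 0.01, 0.0, 0.02).beta == 0.0

    def test_direct_arithmetic(self):
        est = wald_ratio(0.2, 0.01, 0.06, 0.02)
        assert est.beta == pytest.approx(0.3, rel=1e-12)
        assert est.se == pytest.approx(0.1, rel=1e-12)

    def test_negative_exposure_effect(self):
        est = wald_ratio(-0.2, 0.01, 0.06, 0.02)
        assert est.beta == pytest.approx(-0.3, rel=1e-12)
        assert est.se == pytest.approx(0.1, rel=1e-12)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.06, 0.02)


# -------------------------------------------------------------------- IVW

class TestIvwRandomEffects:
    def test_single_snp_equals_wald_ratio(self):
        data = dataset([0.2], [0.06], [0.02])
        est = ivw_random_effects(data)
        ref = wald_ratio(0.2, 0.005, 0.06, 0.02)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)

    def test_identical_copies_shrink_base_se_with_floor(self):
        one = ivw_random_effects(dataset([0.1], [0.03], [0.01]))
        k = 4
        many = ivw_random_effects(dataset([0.1] * k, [0.03] * k, [0.01] * k))
        assert many.beta == pytest.approx(one.beta, rel=1e-12)
        # Q = 0 so dispersion floors at 1: reported SE is the fixed-effect SE
        assert many.se == pytest.approx(one.se / np.sqrt(k), rel=1e-12)

    def test_matches_generic_regression_oracle(self, toy_harmonized):
        est = ivw_random_effects(toy_harmonized)
        x, y = toy_harmonized.beta_exp, toy_harmonized.beta_out
        w = 1.0 / toy_harmonized.se_out**2
        assert est.beta == pytest.approx(wls_through_origin_oracle(x, y, w), abs=1e-10)

    def test_sign_flip_invariance(self, toy_harmonized):
        base = ivw_random_effects(toy_harmonized)
        rec = toy_harmonized.records.copy()
        rec.loc[[1, 3], ["beta_exp", "beta_out"]] *= -1
        flipped = ivw_random_effects(
            HarmonizedDataset.from_arrays(
                rec["beta_exp"], rec["se_exp"], rec["beta_out"], rec["se_out"]
            )
        )
        assert flipped.beta == pytest.approx(base.beta, rel=1e-12)
        assert flipped.se == pytest.approx(base.se, rel=1e-12)

    def test_order_invariance(self, toy_harmonized):
        base = ivw_random_effects(toy_harmonized)
        rec = toy_harmonized.records.sample(frac=1, random_state=1)
        shuffled = ivw_random_effects(
            HarmonizedDataset.from_arrays(
                rec["beta_exp"], rec["se_exp"], rec["beta_out"], rec["se_out"]
            )
        )
        assert shuffled.beta == pytest.approx(base.beta, rel=1e-12)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            ivw_random_effects(dataset([0.0, 0.0], [0.01, 0.02], [0.01, 0.01]))

    def test_se_never_below_fixed_effect(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.uniform(0.05, 0.2, 6)
            y = 0.2 * x + rng.normal(0, 0.05, 6)
            s = rng.uniform(0.005, 0.02, 6)
            est = ivw_random_effects(dataset(x, y, s))
            base = np.sqrt(1.0 / np.sum(x**2 / s**2))
            assert est.se >= base - 1e-15


# ----------------------------------------------------------------- Egger

class TestEggerRegression:
    def test_exact_line_through_origin(self):
        x = np.array([0.05, 0.1, 0.15, 0.2])
        data = dataset(x, 0.4 * x, [0.01] * 4)
        est, itest = egger_regression(data)
        assert est.beta == pytest.approx(0.4, abs=1e-10)
        assert itest.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_generic_regression_oracle(self):
        x = np.array([0.06, 0.11, 0.09, 0.17])
        y = np.array([0.031, 0.020, 0.045, 0.039])
        s = np.array([0.010, 0.012, 0.008, 0.011])
        est, itest = egger_regression(dataset(x, y, s))
        b0, b1 = wls_with_intercept_oracle(x, y, 1.0 / s**2)
        assert est.beta == pytest.approx(b1, abs=1e-10)
        assert itest.intercept == pytest.approx(b0, abs=1e-10)

    def test_orientation_flips_negative_exposure_betas(self):
        x = np.array([0.06, -0.11, 0.09, -0.17])
        y = np.array([0.031, 0.020, 0.045, 0.039])
        s = np.array([0.010, 0.012, 0.008, 0.011])
        est, itest = egger_regression(dataset(x, y, s))
        b0, b1 = wls_with_intercept_oracle(
            np.abs(x), np.sign(x) * y, 1.0 / s**2
        )
        assert est.beta == pytest.approx(b1, abs=1e-10)
        assert itest.intercept == pytest.approx(b0, abs=1e-10)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger_regression(dataset([0.1, 0.2], [0.03, 0.05], [0.01, 0.01]))


# -------------------------------------------------------- weighted median

class TestWeightedMedian:
    def test_equal_weight_three_ratios(self):
        # ratios {0.1, 0.3, 0.9} with equal weights -> middle ratio
        x = np.array([0.1, 0.1, 0.1])
        y = np.array([0.01, 0.03, 0.09])
        s = np.array([0.01, 0.01, 0.01])
        est = weighted_median(dataset(x, y, s), n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.3, abs=1e-12)

    def test_all_ratios_equal(self):
        x = np.array([0.1, 0.2, 0.15, 0.12])
        est = weighted_median(dataset(x, 0.25 * x, [0.01] * 4), n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.25, abs=1e-12)
        assert est.se < 0.05

    def test_matches_weighted_quantile_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0.05, 0.2, 6)
        y = 0.3 * x + rng.normal(0, 0.02, 6)
        s = rng.uniform(0.005, 0.02, 6)
        est = weighted_median(dataset(x, y, s), n_boot=10, seed=0)
        oracle = weighted_quantile_oracle(y / x, (x / s) ** 2)
        assert est.beta == pytest.approx(oracle, abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        ratios=st.lists(
            st.floats(-2, 2, allow_nan=False), min_size=3, max_size=9
        ).filter(lambda r: len(r) % 2 == 1)
    )
    def test_equal_weights_odd_n_equals_sample_median(self, ratios):
        x = np.full(len(ratios), 0.1)
        y = 0.1 * np.asarray(ratios)
        s = np.full(len(ratios), 0.01)
        est = weighted_median(dataset(x, y, s), n_boot=5, seed=0)
        assert est.beta == pytest.approx(float(np.median(ratios)), abs=1e-9)

    def test_bootstrap_is_seed_reproducible(self):
        data = dataset([0.1, 0.12, 0.09, 0.2], [0.03, 0.05, 0.02, 0.07],
                       [0.01, 0.02, 0.01, 0.015])
        a = weighted_median(data, n_boot=200, seed=5)
        b = weighted_median(data, n_boot=200, seed=5)
        assert a.se == b.se

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(dataset([0.1, 0.2], [0.03, 0.05], [0.01, 0.01]))


# -------------------------------------------------------------- reporting

class TestEstimateToSummary:
    def test_null_effect(self):
        t = estimate_to_summary(0.0, 0.1, binary_outcome=True)
        assert t.point == 1.0
        assert t.pval == 1.0
        assert t.ci_low * t.ci_high == pytest.approx(1.0, rel=1e-12)

    def test_published_or_triple(self):
        # log-OR and SE back-derived from a published OR/CI/P report
        t = estimate_to_summary(-0.6330, 0.2877, binary_outcome=True)
        assert t.point == pytest.approx(0.531, abs=1e-3)
        assert t.ci_low == pytest.approx(0.302, abs=1e-3)
        assert t.ci_high == pytest.approx(0.933, abs=1e-3)
        assert t.pval == pytest.approx(0.028, abs=2e-3)

    def test_published_beta_triple_stays_linear(self):
        t = estimate_to_summary(-0.100, 0.0411, binary_outcome=False)
        assert t.point == pytest.approx(-0.100)
        assert t.ci_low == pytest.approx(-0.180, abs=1e-3)
        assert t.ci_high == pytest.approx(-0.019, abs=1e-3)
        assert t.pval == pytest.approx(0.015, abs=2e-3)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        beta=st.floats(-3, 3, allow_nan=False),
        se=st.floats(0.01, 2, allow_nan=False),
    )
    def test_or_is_geometric_mean_of_ci(self, beta, se):
        t = estimate_to_summary(beta, se, binary_outcome=True)
        assert np.sqrt(t.ci_low * t.ci_high) == pytest.approx(t.point, rel=1e-9)
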