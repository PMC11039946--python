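import numpy as np
import pytest

from mrkit import (
    HarmonizedDataset,
    InsufficientInstrumentsError,
    cochrans_q,
    egger_intercept_test,
    ivw_random_effects,
    mr_presso,
    run_sensitivity,
)


def dataset(beta_exp, beta_out, se_out, se_exp=None):
    beta_exp = np.asarray(beta_exp, dtype=float)
    se_exp = np.full_like(beta_exp, 0.005) if se_exp is None else np.asarray(se_exp)
    return HarmonizedDataset.from_arrays(beta_exp, se_exp, beta_out, se_out)


def planted_outlier_data(seed, n=20, theta=0.3, shift=10.0):
    """Clean instruments plus one SNP whose outcome beta is shifted by
    ``shift`` outcome SEs (pleiotropy)."""
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(0.05, 0.12, n)
    se_exp = np.full(n, 0.003)
    se_out = np.full(n, 0.01)
    x = gamma + rng.normal(0, se_exp)
    y = theta * gamma + rng.normal(0, se_out)
    y[0] += shift * se_out[0]
    return dataset(x, y, se_out, se_exp)


class TestCochransQ:
    def test_identical_ratios_give_zero_q(self):
        x = np.array([0.1, 0.2, 0.15])
        data = dataset(x, 0.3 * x, [0.01] * 3)
        beta = ivw_random_effects(data).beta
        q, df, p = cochrans_q(data, beta)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_matches_term_by_term_sum(self, toy_harmonized):
        beta = ivw_random_effects(toy_harmonized).beta
        q, df, _ = cochrans_q(toy_harmonized, beta)
        x, y, s = (
            toy_harmonized.beta_exp,
            toy_harmonized.beta_out,
            toy_harmonized.se_out,
        )
        brute = sum(
            (xi / si) ** 2 * (yi / xi - beta) ** 2 for xi, yi, si in zip(x, y, s)
        )
        assert q == pytest.approx(brute, abs=1e-10)
        assert df == toy_harmonized.n_snp - 1

    def test_q_drives_ivw_dispersion(self, toy_harmonized):
        """The random-effects SE inflation equals sqrt(max(1, Q/(n-1)))."""
        est = ivw_random_effects(toy_harmonized)
        q, df, _ = cochrans_q(toy_harmonized, est.beta)
        x, s = toy_harmonized.beta_exp, toy_harmonized.se_out
        base = np.sqrt(1.0 / np.sum(x**2 / s**2))
        assert est.se == pytest.approx(base * np.sqrt(max(1.0, q / df)), rel=1e-12)

    def test_heterogeneity_raises_mean_q(self):
        """Pleiotropic scatter inflates Q relative to a clean simulation."""
        def mean_q(sigma_alpha, seed0):
            qs = []
            for seed in range(seed0, seed0 + 60):
                rng = np.random.default_rng(seed)
                gamma = rng.uniform(0.05, 0.12, 10)
                alpha = rng.normal(0, sigma_alpha, 10)
                x = gamma + rng.normal(0, 0.003, 10)
                y = 0.2 * gamma + alpha + rng.normal(0, 0.01, 10)
                d = dataset(x, y, [0.01] * 10)
                qs.append(cochrans_q(d, ivw_random_effects(d).beta)[0])
            return np.mean(qs)

        assert mean_q(0.02, 100) > 2 * mean_q(0.0, 100)

    def test_requires_two_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            cochrans_q(dataset([0.1], [0.03], [0.01]), 0.3)


class TestEggerInterceptTest:
    def test_zero_intercept(self):
        assert egger_intercept_test(0.0, 0.01) == 1.0

    def test_quantile_identity(self):
        assert egger_intercept_test(1.96 * 0.01, 0.01) == pytest.approx(0.05, abs=1e-3)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            egger_intercept_test(0.1, 0.0)


class TestMrPresso:
    def test_requires_four_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_presso(dataset([0.1] * 3, [0.03] * 3, [0.01] * 3))

    def test_planted_outlier_flagged(self):
        data = planted_outlier_data(seed=1)
        res = mr_presso(data, n_sim=500, seed=1)
        assert "snp1" in res.outliers
        assert res.global_pval < 0.05
        assert res.corrected is not None

    def test_corrected_estimate_removes_outlier_bias(self):
        data = planted_outlier_data(seed=2, theta=0.3)
        naive = ivw_random_effects(data).beta
        res = mr_presso(data, n_sim=500, seed=2)
        assert res.corrected is not None
        assert abs(res.corrected.beta - 0.3) < abs(naive - 0.3)
        assert res.distortion_pval is not None
        assert 0 < res.distortion_pval <= 1

    def test_clean_data_rarely_flags(self):
        flagged = 0
        for seed in range(10):
            data = planted_outlier_data(seed=seed, shift=0.0)
            res = mr_presso(data, n_sim=300, seed=seed)
            flagged += len(res.outliers)
            assert res.global_pval > 1 / 301  # never exactly zero
        assert flagged <= 2

    def test_seed_reproducible_and_order_invariant(self):
        data = planted_outlier_data(seed=3)
        a = mr_presso(data, n_sim=400, seed=9)
        b = mr_presso(data, n_sim=400, seed=9)
        assert a.global_pval == b.global_pval
        perm = np.random.default_rng(0).permutation(data.n_snp)
        shuffled = HarmonizedDataset.from_arrays(
            data.beta_exp[perm], data.se_exp[perm],
            data.beta_out[perm], data.se_out[perm],
            snp_ids=data.snp_ids[perm],
        )
        c = mr_presso(shuffled, n_sim=400, seed=9)
        assert set(c.outliers) == set(a.outliers)
        # MC p over permuted input differs only by simulation noise
        assert abs(c.global_pval - a.global_pval) < 0.05

    def test_mc_pvalues_never_zero(self):
        data = planted_outlier_data(seed=4, shift=30.0)
        res = mr_presso(data, n_sim=200, seed=0)
        assert res.global_pval >= 1 / 201
        assert all(p > 0 for p in res.outlier_pvals.values())


class TestRunSensitivity:
    def test_small_set_availability_rules(self):
        data = dataset([0.1, 0.2], [0.03, 0.05], [0.01, 0.012])
        est = {"ivw_re": ivw_random_effects(data)}
        rep = run_sensitivity(data, est, n_sim=100, seed=0)
        assert rep.q_stat is not None
        assert rep.egger_intercept is None
        assert rep.presso_global_pval is None
        assert "egger_intercept" in rep.unavailable
        assert "mr_presso" in rep.unavailable

    def test_three_snps_egger_but_no_presso(self):
        data = dataset([0.1, 0.2, 0.15], [0.03, 0.05, 0.04], [0.01] * 3)
        est = {"ivw_re": ivw_random_effects(data)}
        rep = run_sensitivity(data, est, n_sim=100, seed=0)
        assert rep.egger_intercept is not None
        assert "mr_presso" in rep.unavailable

    def test_full_battery_populated(self):
        data = planted_outlier_data(seed=5, shift=0.0, n=10)
        est = {"ivw_re": ivw_random_effects(data)}
        rep = run_sensitivity(data, est, n_sim=300, seed=0)
        assert rep.q_stat is not None and rep.q_df == 9
        assert rep.egger_intercept_pval is not None
        assert rep.presso_global_pval is not None
        assert rep.unavailable == {}
        d = rep.to_dict()
        assert d["n_snp"] == 10

    def test_correction_improves_bias_with_planted_outlier(self):
        data = planted_outlier_data(seed=6, n=10)
        est = {"ivw_re": ivw_random_effects(data)}
        rep = run_sensitivity(data, est, n_sim=500, seed=1)
        assert rep.presso_outliers
        assert abs(rep.presso_corrected.beta - 0.3) < abs(est["ivw_re"].beta - 0.3)

    def test_requires_ivw(self):
        data = planted_outlier_data(seed=7)
        with pytest.raises(ValueError):
            run_sensitivity(data, {}, n_sim=10)
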