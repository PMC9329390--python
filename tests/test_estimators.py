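import itertools

import numpy as np
import pytest
from scipy import stats

from causalmr import (HarmonizedSet, SimConfig, cochran_q, contamination_mixture,
                      egger, harmonize, ivw, simulate_two_sample, wald_ratio,
                      weighted_median)


def ratio_set(theta, sigma):
    """HarmonizedSet whose Wald ratios are exactly theta with SEs sigma."""
    theta = np.asarray(theta, float)
    sigma = np.asarray(sigma, float)
    return HarmonizedSet.from_arrays(np.ones_like(theta), np.full_like(theta, 1e-8),
                                     theta, sigma)


class TestWaldRatio:
    def test_arithmetic(self):
        assert wald_ratio(0.1, 0.01, 0.02, 0.01) == pytest.approx((0.2, 0.1))

    def test_null_outcome(self):
        theta, _ = wald_ratio(0.1, 0.01, 0.0, 0.01)
        assert theta == 0.0

    def test_zero_exposure_errors(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.02, 0.01)


class TestIVW:
    def test_two_instrument_hand_oracle(self, two_ratio_set):
        # weights 100 and 25: estimate (50+7.5)/125, fixed se 125^-1/2
        res, q = ivw(two_ratio_set, model="fixed")
        assert res.estimate == pytest.approx(0.46, abs=1e-12)
        assert res.se == pytest.approx(125**-0.5, abs=1e-12)
        assert q.q == pytest.approx(0.8, abs=1e-12)
        assert q.df == 1

    def test_single_instrument_equals_wald(self):
        hs = ratio_set([0.37], [0.11])
        res, q = ivw(hs)
        assert res.estimate == pytest.approx(0.37)
        assert res.se == pytest.approx(0.11)
        assert q is None

    def test_homogeneous_ratios(self):
        hs = ratio_set([0.3, 0.3, 0.3], [0.1, 0.2, 0.3])
        fixed, q = ivw(hs, model="fixed")
        random, _ = ivw(hs, model="multiplicative_random")
        assert q.q == pytest.approx(0.0, abs=1e-20)
        assert fixed.se == pytest.approx(random.se)

    def test_equals_zero_intercept_wls(self):
        """IVW is algebraically the slope of weighted least squares of
        beta_out on beta_exp through the origin with weights se_out^-2
        (independent route via statsmodels)."""
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.02, 0.1, 12)
        by = 0.3 * bx + rng.normal(0, 0.01, 12)
        sy = rng.uniform(0.005, 0.02, 12)
        hs = HarmonizedSet.from_arrays(bx, np.full(12, 1e-8), by, sy)
        res, _ = ivw(hs, model="fixed")
        wls = sm.WLS(by, bx[:, None], weights=sy**-2).fit()
        assert res.estimate == pytest.approx(wls.params[0], abs=1e-12)

    def test_q_permutation_invariant(self, two_ratio_set):
        perm = two_ratio_set.select(["v1", "v0"])
        assert cochran_q(perm).q == pytest.approx(cochran_q(two_ratio_set).q)

    def test_empty_set_errors(self):
        hs = ratio_set([0.1], [0.1]).select([])
        with pytest.raises(ValueError):
            ivw(hs)


class TestEgger:
    def test_exact_linear_fit(self):
        bx = np.array([0.02, 0.05, 0.08, 0.11])
        by = 0.1 + 0.4 * bx
        hs = HarmonizedSet.from_arrays(bx, np.full(4, 1e-8), by,
                                       [0.01, 0.02, 0.015, 0.01])
        res = egger(hs)
        assert res.intercept == pytest.approx(0.1, abs=1e-10)
        assert res.slope.estimate == pytest.approx(0.4, abs=1e-10)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(8)
        bx = rng.uniform(0.02, 0.1, 10)
        by = 0.05 + 0.3 * bx + rng.normal(0, 0.01, 10)
        sy = rng.uniform(0.01, 0.03, 10)
        hs = HarmonizedSet.from_arrays(bx, np.full(10, 1e-8), by, sy)
        flip = np.where(rng.random(10) < 0.5, -1.0, 1.0)
        hs_flipped = HarmonizedSet.from_arrays(bx * flip, np.full(10, 1e-8),
                                               by * flip, sy)
        a, b = egger(hs), egger(hs_flipped)
        assert a.slope.estimate == pytest.approx(b.slope.estimate)
        assert a.intercept == pytest.approx(b.intercept)
        assert a.intercept_pvalue == pytest.approx(b.intercept_pvalue)

    def test_too_few_instruments(self):
        hs = ratio_set([0.1, 0.2], [0.1, 0.1])
        with pytest.raises(ValueError):
            egger(hs)

    def test_intercept_test_calibrated_under_balanced_pleiotropy(self):
        """With mean-zero pleiotropy the intercept test should reject at
        roughly its nominal level."""
        rej = 0
        R = 200
        for s in range(R):
            exp, out, _ = simulate_two_sample(
                SimConfig(seed=90_000 + s, pleiotropy_mode="balanced"))
            hs = harmonize(exp, out)
            rej += egger(hs).intercept_pvalue < 0.05
        se = np.sqrt(0.05 * 0.95 / R)
        assert abs(rej / R - 0.05) <= 3 * se


class TestWeightedMedian:
    def test_equal_weight_interpolation(self):
        hs = ratio_set([0.1, 0.2, 0.6], [1.0, 1.0, 1.0])
        res = weighted_median(hs, n_boot=10, seed=0)
        assert res.estimate == pytest.approx(0.2)

    def test_dominant_instrument(self):
        hs = ratio_set([0.1, 0.9, 0.5], [1e-6, 10.0, 10.0])
        res = weighted_median(hs, n_boot=10, seed=0)
        assert res.estimate == pytest.approx(0.1, abs=1e-3)

    def test_majority_weight_breakdown(self):
        """>= 50% of weight on ratios exactly theta* pins the estimate there,
        for every placement of the majority within 5 instruments."""
        theta_star = 0.25
        for majority in itertools.combinations(range(5), 3):
            theta = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
            sigma = np.full(5, 10.0)
            theta[list(majority)] = theta_star
            sigma[list(majority)] = 0.5  # weight 4 each vs 0.01: >50% total
            res = weighted_median(ratio_set(theta, sigma), n_boot=10, seed=0)
            assert res.estimate == pytest.approx(theta_star, abs=1e-9)

    def test_bounds_and_shift(self):
        rng = np.random.default_rng(5)
        theta = rng.normal(0.2, 0.3, 9)
        sigma = rng.uniform(0.05, 0.5, 9)
        res = weighted_median(ratio_set(theta, sigma), n_boot=10, seed=1)
        assert theta.min() <= res.estimate <= theta.max()
        shifted = weighted_median(ratio_set(theta + 1.0, sigma), n_boot=10, seed=1)
        assert shifted.estimate == pytest.approx(res.estimate + 1.0, abs=1e-9)

    def test_seeded_bootstrap_reproducible(self, two_ratio_set):
        hs = ratio_set([0.1, 0.2, 0.3, 0.5], [0.1, 0.2, 0.1, 0.3])
        a = weighted_median(hs, n_boot=200, seed=42)
        b = weighted_median(hs, n_boot=200, seed=42)
        assert a.se == b.se


def _conmix_enumeration_oracle(theta, sigma, psi):
    """Brute force over all valid/invalid classifications: for each subset the
    profile-optimal estimate is the inverse-variance mean of its members;
    return the global maximizer of the joint log-likelihood."""
    best_ll, best_t = -np.inf, np.nan
    L = len(theta)
    inv_sd = np.sqrt(sigma**2 + psi**2)
    for mask in itertools.product([0, 1], repeat=L):
        mask = np.array(mask, bool)
        ll = float(np.sum(-0.5 * (theta[~mask] / inv_sd[~mask]) ** 2
                          - np.log(inv_sd[~mask])))
        if mask.any():
            w = sigma[mask] ** -2
            t = np.sum(w * theta[mask]) / np.sum(w)
            ll += float(np.sum(-0.5 * ((theta[mask] - t) / sigma[mask]) ** 2
                               - np.log(sigma[mask])))
        else:
            t = 0.0
        if ll > best_ll:
            best_ll, best_t = ll, t
    return best_t


class TestContaminationMixture:
    def test_consensus(self):
        hs = ratio_set([0.3, 0.3, 0.3, 0.3], [0.1, 0.1, 0.1, 0.1])
        res = contamination_mixture(hs, psi=0.5)
        assert res.estimate == pytest.approx(0.3, abs=1e-3)
        assert len(res.valid_set) == 4
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            theta = rng.normal(0.2, 0.2, 8)
            sigma = rng.uniform(0.05, 0.2, 8)
            psi = 0.4
            res = contamination_mixture(ratio_set(theta, sigma), psi=psi,
                                        grid_size=20001)
            oracle = _conmix_enumeration_oracle(theta, sigma, psi)
            grid_step = (theta.max() - theta.min() + 6 * sigma.max()) / 20000
            assert res.estimate == pytest.approx(oracle, abs=2 * grid_step)

    def test_outlier_cluster_excluded(self):
        rng = np.random.default_rng(5)
        theta = np.concatenate([rng.normal(0.2, 0.05, 90),
                                rng.normal(1.0, 0.05, 10)])
        hs = ratio_set(theta, np.full(100, 0.05))
        res = contamination_mixture(hs)
        assert res.estimate == pytest.approx(0.2, abs=0.03)
        outlier_ids = {f"v{i}" for i in range(90, 100)}
        assert not (set(res.valid_set) & outlier_ids)

    def test_order_invariance(self):
        theta = [0.1, 0.5, 0.2, 0.25]
        sigma = [0.05, 0.3, 0.1, 0.07]
        a = contamination_mixture(ratio_set(theta, sigma), psi=0.3)
        b = contamination_mixture(ratio_set(theta[::-1], sigma[::-1]), psi=0.3)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)

    def test_large_psi_approaches_ivw(self):
        rng = np.random.default_rng(9)
        theta = rng.normal(0.3, 0.05, 20)
        sigma = rng.uniform(0.04, 0.08, 20)
        hs = ratio_set(theta, sigma)
        res = contamination_mixture(hs, psi=50.0, grid_size=40001)
        ivw_est, _ = ivw(hs, model="fixed")
        assert res.estimate == pytest.approx(ivw_est.estimate, abs=5e-3)

    def test_invalid_psi(self):
        hs = ratio_set([0.1, 0.2], [0.1, 0.1])
        with pytest.raises(ValueError):
            contamination_mixture(hs, psi=-1.0)
        with pytest.raises(ValueError):
            contamination_mixture(hs, grid_size=2)


def test_ivw_type1_error_calibrated_under_null():
    """theta = 0, no pleiotropy: IVW rejects at ~nominal 5%."""
    rej = 0
    R = 200
    for s in range(R):
        exp, out, _ = simulate_two_sample(
            SimConfig(seed=95_000 + s, true_effect=0.0))
        hs = harmonize(exp, out)
        rej += ivw(hs)[0].pvalue < 0.05
    se = np.sqrt(0.05 * 0.95 / R)
    assert abs(rej / R - 0.05) <= 3 * se
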