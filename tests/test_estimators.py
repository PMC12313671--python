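"""Causal-effect estimators: worked examples, oracles, invariances."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mrpath.estimators import (
    EstimatorError,
    egger,
    estimate_all,
    ivw,
    max_likelihood,
    mode_estimator,
    wald_ratio,
    weighted_median,
)
from mrpath.sumstats import InstrumentTable

from conftest import make_table, random_table


class TestWaldRatio:
    def test_direct_ratio_arithmetic(self):
        t = make_table([0.1], [0.01], [0.05], [0.01])
        est = wald_ratio(t)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome_gives_p_one(self):
        est = wald_ratio(make_table([0.1], [0.01], [0.0], [0.01]))
        assert est.beta == 0.0 and est.pval == pytest.approx(1.0)

    def test_joint_sign_flip_is_invariant(self):
        a = wald_ratio(make_table([0.1], [0.01], [0.05], [0.01]))
        b = wald_ratio(make_table([-0.1], [0.01], [-0.05], [0.01]))
        assert a.beta == b.beta and a.se == b.se

    def test_zero_exposure_effect_is_degenerate(self):
        with pytest.raises(EstimatorError):
            wald_ratio(make_table([0.0], [0.01], [0.05], [0.01]))


class TestIVW:
    def test_hand_computed_weighted_mean(self, ivw_hand_table):
        est = ivw(ivw_hand_table, model="fixed")
        assert est.beta == pytest.approx(0.4, abs=1e-12)
        assert est.se == pytest.approx(1 / np.sqrt(200), abs=1e-12)

    def test_exact_line_recovers_slope_with_no_heterogeneity(self):
        bx = np.array([0.1, 0.2, 0.3])
        t = make_table(bx, [0.01] * 3, 0.7 * bx, [0.01] * 3)
        fixed = ivw(t, model="fixed")
        random = ivw(t, model="multiplicative_random")
        assert fixed.beta == pytest.approx(0.7, abs=1e-12)
        assert random.se == fixed.se  # Q = 0 -> no inflation

    def test_duplicating_every_snp_halves_the_variance(self, ivw_hand_table):
        d = ivw_hand_table.data
        dup = pd.concat([d, d.assign(variant_id=d["variant_id"] + "_b")], ignore_index=True)
        t2 = InstrumentTable(dup, provenance="test-fixture")
        e1 = ivw(ivw_hand_table, model="fixed")
        e2 = ivw(t2, model="fixed")
        assert e2.beta == pytest.approx(e1.beta, abs=1e-12)
        assert e2.se == pytest.approx(e1.se / np.sqrt(2), abs=1e-12)

    def test_single_snp_directs_to_wald_ratio(self):
        with pytest.raises(EstimatorError, match="wald_ratio"):
            ivw(make_table([0.1], [0.01], [0.05], [0.01]))

    def test_matches_weighted_least_squares_oracle(self, rng):
        """Independent route: statsmodels WLS through the origin."""
        for _ in range(100):
            t = random_table(rng, k=int(rng.integers(2, 15)))
            bx, _, by, sy = t.arrays()
            oracle = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
            est = ivw(t, model="fixed")
            assert abs(est.beta - oracle.params[0]) < 1e-10


class TestMaxLikelihood:
    def test_reduces_to_ivw_when_exposure_noise_vanishes(self, rng):
        for _ in range(20):
            t = random_table(rng, k=8)
            d = t.data.copy()
            d["se_exp"] = 1e-8
            t0 = InstrumentTable(d, provenance="test-fixture")
            assert max_likelihood(t0).beta == pytest.approx(
                ivw(t0, model="fixed").beta, abs=1e-6
            )

    def test_exact_line_recovers_slope(self):
        bx = np.array([0.1, 0.2, 0.3])
        t = make_table(bx, [0.01] * 3, 0.25 * bx, [0.01] * 3)
        assert max_likelihood(t).beta == pytest.approx(0.25, abs=1e-8)


class TestEgger:
    def test_exact_fit_recovers_intercept_and_slope(self):
        bx = np.array([0.1, 0.2, 0.3])
        t = make_table(bx, [0.01] * 3, 0.1 + 0.3 * bx, [0.01] * 3)
        est, intercept, se_int, p_int = egger(t)
        assert intercept == pytest.approx(0.1, abs=1e-12)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert est.extra["overdispersion"] == 1.0  # RSS ~ 0, floored

    def test_matches_statsmodels_wls_oracle(self, rng):
        for _ in range(50):
            t = random_table(rng, k=int(rng.integers(3, 12)))
            bx, _, by, sy = t.arrays()
            flip = bx < 0
            bx2, by2 = np.where(flip, -bx, bx), np.where(flip, -by, by)
            oracle = sm.WLS(by2, sm.add_constant(bx2), weights=1.0 / sy**2).fit()
            est, intercept, _, _ = egger(t)
            assert abs(est.beta - oracle.params[1]) < 1e-10
            assert abs(intercept - oracle.params[0]) < 1e-10

    def test_orientation_makes_sign_of_exposure_irrelevant(self, rng):
        t = random_table(rng, k=8)
        d = t.data.copy()
        d.loc[:3, ["beta_exp", "beta_out"]] *= -1  # re-code some effect alleles
        t2 = InstrumentTable(d, provenance="test-fixture")
        assert egger(t)[0].beta == pytest.approx(egger(t2)[0].beta, abs=1e-12)

    def test_too_few_instruments(self):
        with pytest.raises(EstimatorError):
            egger(make_table([0.1, 0.2], [0.01] * 2, [0.05, 0.06], [0.01] * 2))


def _percentile_oracle(ratios, weights):
    """Brute-force interpolated weighted percentile at 0.5."""
    pairs = sorted(zip(ratios, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    grid = []
    for r, w in pairs:
        grid.append(((cum + w / 2) / total, r))
        cum += w
    ps = [p for p, _ in grid]
    rs = [r for _, r in grid]
    if 0.5 <= ps[0]:
        return rs[0]
    if 0.5 >= ps[-1]:
        return rs[-1]
    for (p0, r0), (p1, r1) in zip(grid, grid[1:]):
        if p0 <= 0.5 <= p1:
            return r0 + (0.5 - p0) / (p1 - p0) * (r1 - r0)


class TestWeightedMedian:
    def test_equal_weights_take_middle_ratio(self):
        t = make_table([0.1] * 3, [0.01] * 3, [0.02, 0.05, 0.09], [0.01] * 3)
        est = weighted_median(t, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_dominant_snp_drives_the_estimate(self):
        # middle SNP carries 60% of the weight, symmetrically placed
        t = make_table(
            [0.1, np.sqrt(3) * 0.1, 0.1], [0.01] * 3,
            [0.02, np.sqrt(3) * 0.05, 0.09], [0.01] * 3,
        )
        est = weighted_median(t, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_matches_brute_force_percentile_oracle(self, rng):
        for _ in range(50):
            k = int(rng.integers(3, 8))
            t = random_table(rng, k=k)
            bx, _, by, sy = t.arrays()
            expected = _percentile_oracle(list(by / bx), list(bx**2 / sy**2))
            est = weighted_median(t, n_boot=10, seed=0)
            assert est.beta == pytest.approx(expected, abs=1e-12)


class TestModeEstimators:
    def test_identical_ratios_return_the_common_value(self):
        bx = np.array([0.1, 0.2, 0.4])
        t = make_table(bx, [0.01] * 3, 0.3 * bx, [0.01] * 3)
        est = mode_estimator(t, weighted=False, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.3)

    def test_majority_cluster_wins_with_equal_weights(self):
        bx = np.full(4, 0.1)
        by = np.array([0.02, 0.021, 0.019, 0.09])
        t = make_table(bx, [0.01] * 4, by, [0.01] * 4)
        est = mode_estimator(t, weighted=False, n_boot=50, seed=1)
        assert 0.19 <= est.beta <= 0.21

    def test_weighted_mode_follows_the_weight_not_the_count(self):
        # 3-SNP majority cluster at ratio 0.2 with tiny weight; 2-SNP minority
        # cluster at 0.8 carrying ~99% of total weight
        bx = np.array([0.02, 0.021, 0.022, 0.4, 0.41])
        by = np.array([0.004, 0.0042, 0.0044, 0.32, 0.328])
        t = make_table(bx, [0.01] * 5, by, [0.01] * 5)
        simple = mode_estimator(t, weighted=False, n_boot=50, seed=1)
        weighted = mode_estimator(t, weighted=True, n_boot=50, seed=1)
        assert abs(simple.beta - 0.2) < 0.05
        assert abs(weighted.beta - 0.8) < 0.05


class TestDispatch:
    def test_single_instrument_gets_wald_only(self):
        ests = estimate_all(make_table([0.1], [0.01], [0.05], [0.01]), seed=1)
        assert [e.method for e in ests] == ["wald_ratio"]
        assert ests[0].extra["primary"]

    def test_two_instruments_get_ivw_and_ml(self, ivw_hand_table):
        ests = estimate_all(ivw_hand_table, seed=1)
        assert [e.method for e in ests] == ["ivw", "max_likelihood"]

    def test_multi_instrument_full_method_set(self, rng):
        ests = estimate_all(random_table(rng, k=10), seed=1, n_boot_median=20, n_boot_mode=20)
        assert [e.method for e in ests] == [
            "ivw", "max_likelihood", "egger", "weighted_median", "simple_mode", "weighted_mode",
        ]
        assert sum(e.extra.get("primary", False) for e in ests) == 1
        assert ests[0].method == "ivw"

    def test_row_order_does_not_change_deterministic_methods(self, rng):
        t = random_table(rng, k=9)
        perm = InstrumentTable(
            t.data.sample(frac=1.0, random_state=7).reset_index(drop=True),
            provenance="test-fixture",
        )
        for fn in (lambda x: ivw(x).beta, lambda x: egger(x)[0].beta,
                   lambda x: weighted_median(x, n_boot=5, seed=0).beta):
            assert fn(t) == pytest.approx(fn(perm), abs=1e-12)


class TestInvariances:
    @pytest.mark.parametrize("c", [2.0, -0.5, 10.0])
    def test_exposure_rescaling_divides_every_estimate(self, rng, c):
        t = random_table(rng, k=8)
        d = t.data.copy()
        d["beta_exp"] *= c
        d["se_exp"] = d["se_exp"].abs() * abs(c)
        t2 = InstrumentTable(d, provenance="test-fixture")
        for fn in (
            lambda x: ivw(x).beta,
            lambda x: max_likelihood(x).beta,
            lambda x: egger(x)[0].beta,
            lambda x: weighted_median(x, n_boot=5, seed=0).beta,
        ):
            assert fn(t2) == pytest.approx(fn(t) / c, rel=1e-6)

    def test_negating_outcome_negates_every_estimate(self, rng):
        t = random_table(rng, k=8)
        d = t.data.copy()
        d["beta_out"] *= -1.0
        t2 = InstrumentTable(d, provenance="test-fixture")
        for fn in (
            lambda x: ivw(x).beta,
            lambda x: max_likelihood(x).beta,
            lambda x: egger(x)[0].beta,
            lambda x: weighted_median(x, n_boot=5, seed=0).beta,
        ):
            assert fn(t2) == pytest.approx(-fn(t), rel=1e-6)
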