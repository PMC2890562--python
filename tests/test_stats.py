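"""Correlation statistics, bootstrap and permutation inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from mirconcord.stats import (
    PAIRING_LABELS,
    between_platform_correlation,
    bootstrap_ci,
    build_log_ratios,
    familywise_correct,
    lin_ccc,
    permutation_diff_test,
    platform_vs_qpcr_correlation,
    spearman_rho,
    within_platform_correlation,
)
from mirconcord.types import (
    ArrayDesign,
    CollapsedExpression,
    LogRatioSet,
    ValidationError,
)


def rank_pearson(x, y):
    """Independent mid-rank Pearson oracle."""
    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [1.0, 3.0, 2.0, 4.0]
        assert spearman_rho(x, y) == pytest.approx(rank_pearson(x, y), abs=1e-12)

    def test_nan_pairs_removed(self):
        x = [1.0, 2.0, np.nan, 3.0, 4.0]
        y = [2.0, 4.0, 1.0, 6.0, np.nan]
        assert spearman_rho(x, y) == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            spearman_rho([1.0, 2.0], [3.0, 4.0])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        data=st.lists(
            st.tuples(st.integers(-1000, 1000), st.integers(-1000, 1000)),
            min_size=4,
            max_size=40,
        )
    )
    def test_invariant_under_monotone_transform(self, data):
        from hypothesis import assume

        x = np.array([d[0] for d in data]) / 10.0
        y = np.array([d[1] for d in data]) / 10.0
        assume(np.unique(x).size > 1 and np.unique(y).size > 1)
        rho = spearman_rho(x, y)
        assert spearman_rho(np.exp(x / 50.0), y) == pytest.approx(rho, abs=1e-9)
        assert spearman_rho(x, 3.0 * y + 2.0) == pytest.approx(rho, abs=1e-9)


class TestLinCCC:
    def test_identity_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert lin_ccc(x, x).estimate == pytest.approx(1.0)

    def test_shifted_line_known_value(self):
        est = lin_ccc([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert est.estimate == pytest.approx(4.0 / 7.0, abs=1e-12)

    def test_direct_formula_oracle(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, 50)
        y = 0.5 * x + rng.normal(0.3, 0.8, 50)
        sxy = np.cov(x, y, bias=True)[0, 1]
        expected = 2 * sxy / (x.var() + y.var() + (x.mean() - y.mean()) ** 2)
        assert lin_ccc(x, y).estimate == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_pearson(self):
        rng = np.random.default_rng(14)
        for _ in range(200):
            n = rng.integers(3, 30)
            x = rng.normal(rng.normal(0, 2), rng.uniform(0.1, 3), n)
            y = rng.normal(rng.normal(0, 2), rng.uniform(0.1, 3), n)
            if x.std() == 0 or y.std() == 0:
                continue
            ccc = lin_ccc(x, y).estimate
            r = np.corrcoef(x, y)[0, 1]
            assert abs(ccc) <= abs(r) + 1e-12

    def test_equals_pearson_iff_same_moments(self):
        rng = np.random.default_rng(15)
        x = rng.normal(0, 1, 40)
        y = x + rng.normal(0, 0.5, 40)
        y = (y - y.mean()) / y.std() * x.std() + x.mean()  # match moments
        est = lin_ccc(x, y)
        assert est.estimate == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(16)
        x = rng.normal(0, 1, 60)
        y = x + rng.normal(0, 0.4, 60)
        est = lin_ccc(x, y)
        assert est.ci_low <= est.estimate <= est.ci_high
        assert est.se > 0

    def test_double_constant_rejected(self):
        with pytest.raises(ValidationError):
            lin_ccc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])


class TestBootstrap:
    def test_constant_statistic_collapses(self):
        x = np.arange(10.0)
        se, lo, hi = bootstrap_ci(lambda a, b: 0.7, x, x, B=300, seed=1)
        assert se == pytest.approx(0.0, abs=1e-12)
        assert lo == 0.7 and hi == 0.7

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(17)
        x = rng.normal(0, 1, 40)
        y = x + rng.normal(0, 0.6, 40)
        a = bootstrap_ci(spearman_rho, x, y, B=400, seed=9)
        b = bootstrap_ci(spearman_rho, x, y, B=400, seed=9)
        assert a == b

    def test_small_B_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_ci(spearman_rho, np.arange(10.0), np.arange(10.0), B=50, seed=0)

    def test_degenerate_majority_rejected(self):
        x = np.array([1.0] * 19 + [2.0])  # most resamples are constant
        with pytest.raises(ValidationError):
            bootstrap_ci(spearman_rho, x, x, B=300, seed=0)


def _lr_from_pairings(pairings: pd.DataFrame, platform="P") -> LogRatioSet:
    present = pd.Series(True, index=pairings.index)
    return LogRatioSet(platform, pairings, present)


class TestWithinPlatform:
    def _noise_free(self, n=30, seed=18):
        rng = np.random.default_rng(seed)
        r = rng.normal(0, 1, n)
        pairings = pd.DataFrame(
            {c: r for c in PAIRING_LABELS},
            index=[f"m{i}" for i in range(n)],
        )
        return _lr_from_pairings(pairings)

    def test_noise_free_is_one(self):
        est = within_platform_correlation(self._noise_free(), B=0)
        assert est.estimate == pytest.approx(1.0)
        assert est.n == 30

    def test_antithetic_is_minus_one(self):
        lr = self._noise_free()
        pairings = lr.pairings.copy()
        pairings["r22"] = -pairings["r11"]
        pairings["r21"] = -pairings["r12"]
        est = within_platform_correlation(_lr_from_pairings(pairings), B=0)
        assert est.estimate == pytest.approx(-1.0)

    def test_cross_pairing_average_matches_oracle(self):
        rng = np.random.default_rng(19)
        t = rng.normal(0, 1.5, 80)
        pairings = pd.DataFrame(
            {c: t + rng.normal(0, 0.4, 80) for c in PAIRING_LABELS},
            index=[f"m{i}" for i in range(80)],
        )
        est = within_platform_correlation(_lr_from_pairings(pairings), B=0)
        expected = 0.5 * (
            rank_pearson(pairings["r11"], pairings["r22"])
            + rank_pearson(pairings["r12"], pairings["r21"])
        )
        assert est.estimate == pytest.approx(expected, abs=1e-12)

    def test_replicate_relabeling_symmetry(self):
        # swapping both Ref1 replicates together with both Ref2 replicates
        # maps (r11,r12,r21,r22) -> (r22,r21,r12,r11) and must not change
        # the estimate
        rng = np.random.default_rng(20)
        t = rng.normal(0, 1.5, 60)
        pairings = pd.DataFrame(
            {c: t + rng.normal(0, 0.5, 60) for c in PAIRING_LABELS},
            index=[f"m{i}" for i in range(60)],
        )
        swapped = pairings.rename(
            columns={"r11": "r22", "r22": "r11", "r12": "r21", "r21": "r12"}
        )
        a = within_platform_correlation(_lr_from_pairings(pairings), B=0)
        b = within_platform_correlation(_lr_from_pairings(swapped), B=0)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)

    def test_non_2x2_design_refused(self):
        pairings = pd.DataFrame(
            {"r11": np.arange(10.0), "r12": np.arange(10.0)},
            index=[f"m{i}" for i in range(10)],
        )
        with pytest.raises(ValidationError):
            within_platform_correlation(_lr_from_pairings(pairings), B=0)


class TestBetweenPlatformAndQpcr:
    def _pair(self, n=40, noise=0.0, seed=21):
        rng = np.random.default_rng(seed)
        t = rng.normal(0, 1.5, n)
        idx = [f"m{i}" for i in range(n)]
        mk = lambda eps: pd.DataFrame(
            {c: t + rng.normal(0, eps, n) if eps else t for c in PAIRING_LABELS},
            index=idx,
        )
        return _lr_from_pairings(mk(noise), "A"), _lr_from_pairings(mk(noise), "B"), t, idx

    def test_identical_platforms_correlate_perfectly(self):
        lra, lrb, _, _ = self._pair()
        est = between_platform_correlation(lra, lrb, B=0)
        assert est.estimate == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self):
        lra, lrb, _, idx = self._pair()
        transformed = _lr_from_pairings(np.exp(lrb.pairings / 3.0), "B")
        est = between_platform_correlation(lra, transformed, B=0)
        assert est.estimate == pytest.approx(1.0)

    def test_noise_decreases_agreement(self):
        medians = []
        for noise in (0.1, 0.5, 1.0):
            vals = []
            for seed in range(10):
                lra, lrb, _, _ = self._pair(n=100, noise=noise, seed=100 + seed)
                vals.append(between_platform_correlation(lra, lrb, B=0).estimate)
            medians.append(np.median(vals))
        assert medians[0] > medians[1] > medians[2]

    def test_qpcr_sign_flip_identity(self):
        lra, _, t, idx = self._pair()
        ct_diff = pd.Series(-lra.mean_log_ratio.to_numpy(), index=idx)
        detected = pd.Series(True, index=idx)
        est = platform_vs_qpcr_correlation(lra, ct_diff, detected, B=0)
        assert est.estimate == pytest.approx(1.0)
        est2 = platform_vs_qpcr_correlation(lra, -ct_diff, detected, B=0)
        assert est2.estimate == pytest.approx(-1.0)


class TestBuildLogRatios:
    def test_all_pairings_enumerated(self):
        arrays = [
            ArrayDesign("A1", {"Cy3": "Ref1"}, 1),
            ArrayDesign("A2", {"Cy3": "Ref1"}, 2),
            ArrayDesign("A3", {"Cy3": "Ref2"}, 1),
            ArrayDesign("A4", {"Cy3": "Ref2"}, 2),
        ]
        values = pd.DataFrame(
            {"A1.Cy3": [8.0], "A2.Cy3": [8.0], "A3.Cy3": [2.0], "A4.Cy3": [4.0]},
            index=pd.Index(["miR-a"], name="mirna"),
        )
        absent = pd.DataFrame(False, index=values.index, columns=values.columns)
        expr = CollapsedExpression("P", "one", values, absent, arrays)
        lr = build_log_ratios(expr, values_are_log2=False)
        assert lr.pairings.loc["miR-a"].tolist() == [2.0, 1.0, 2.0, 1.0]
        assert lr.mean_log_ratio.loc["miR-a"] == pytest.approx(1.5)

    def test_equal_pools_give_zero(self):
        arrays = [
            ArrayDesign("A1", {"Cy3": "Ref1"}, 1),
            ArrayDesign("A2", {"Cy3": "Ref2"}, 1),
        ]
        values = pd.DataFrame(
            {"A1.Cy3": [5.0, 7.0], "A2.Cy3": [5.0, 7.0]},
            index=pd.Index(["a", "b"], name="mirna"),
        )
        absent = pd.DataFrame(False, index=values.index, columns=values.columns)
        lr = build_log_ratios(
            CollapsedExpression("P", "one", values, absent, arrays),
            values_are_log2=False,
        )
        assert (lr.pairings.to_numpy() == 0).all()

    def test_nonpositive_intensity_yields_nan(self):
        arrays = [
            ArrayDesign("A1", {"Cy3": "Ref1"}, 1),
            ArrayDesign("A2", {"Cy3": "Ref2"}, 1),
        ]
        values = pd.DataFrame(
            {"A1.Cy3": [0.0], "A2.Cy3": [4.0]}, index=pd.Index(["a"], name="mirna")
        )
        absent = pd.DataFrame(False, index=values.index, columns=values.columns)
        lr = build_log_ratios(
            CollapsedExpression("P", "one", values, absent, arrays),
            values_are_log2=False,
        )
        assert np.isnan(lr.pairings.iloc[0, 0])

    def test_brute_force_pairing_enumeration(self):
        rng = np.random.default_rng(22)
        arrays = [
            ArrayDesign("A1", {"Cy3": "Ref1"}, 1),
            ArrayDesign("A2", {"Cy3": "Ref1"}, 2),
            ArrayDesign("A3", {"Cy3": "Ref2"}, 1),
            ArrayDesign("A4", {"Cy3": "Ref2"}, 2),
        ]
        values = pd.DataFrame(
            rng.lognormal(5, 1, (20, 4)),
            index=pd.Index([f"m{i}" for i in range(20)], name="mirna"),
            columns=["A1.Cy3", "A2.Cy3", "A3.Cy3", "A4.Cy3"],
        )
        absent = pd.DataFrame(False, index=values.index, columns=values.columns)
        lr = build_log_ratios(
            CollapsedExpression("P", "one", values, absent, arrays),
            values_are_log2=False,
        )
        for m in values.index:
            expected = {
                f"r{i}{j}": np.log2(values.loc[m, f"A{i}.Cy3"])
                - np.log2(values.loc[m, f"A{j + 2}.Cy3"])
                for i in (1, 2)
                for j in (1, 2)
            }
            for label, val in expected.items():
                assert lr.pairings.loc[m, label] == pytest.approx(val, abs=1e-12)


class TestPermutation:
    def test_identical_platforms_null(self):
        rng = np.random.default_rng(23)
        ref = rng.normal(0, 1, 40)
        p1 = ref + rng.normal(0, 0.5, 40)
        res = permutation_diff_test(ref, p1, p1.copy(), n_perm=500, seed=3)
        assert res.observed_diff == pytest.approx(0.0)
        assert res.p_value > 0.9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(24)
        ref = rng.normal(0, 1, 30)
        p1 = ref + rng.normal(0, 0.8, 30)
        p2 = ref + rng.normal(0, 1.5, 30)
        a = permutation_diff_test(ref, p1, p2, n_perm=500, seed=7)
        b = permutation_diff_test(ref, p1, p2, n_perm=500, seed=7)
        assert a.p_value == b.p_value and a.observed_diff == b.observed_diff

    def test_vectorized_null_matches_loop_oracle(self):
        rng = np.random.default_rng(25)
        ref = rng.normal(0, 1, 25)
        p1 = ref + rng.normal(0, 1, 25)
        p2 = ref + rng.normal(0, 1, 25)
        res = permutation_diff_test(ref, p1, p2, n_perm=400, seed=11)
        from scipy.stats import spearmanr

        rng2 = np.random.default_rng(11)
        swap = rng2.random((400, 25)) < 0.5
        obs = spearmanr(p1, ref).statistic - spearmanr(p2, ref).statistic
        count = 0
        for k in range(400):
            a = np.where(swap[k], p2, p1)
            b = np.where(swap[k], p1, p2)
            d = spearmanr(a, ref).statistic - spearmanr(b, ref).statistic
            if abs(d) >= abs(obs) - 1e-12:
                count += 1
        assert res.p_value == pytest.approx((1 + count) / 401)

    def test_minimum_permutations_enforced(self):
        with pytest.raises(ValidationError):
            permutation_diff_test(
                np.arange(5.0), np.arange(5.0), np.arange(5.0), n_perm=10
            )


class TestFamilywise:
    def test_single_p_unchanged(self):
        assert familywise_correct([0.03]) == pytest.approx([0.03])

    def test_holm_by_hand(self):
        adjusted = familywise_correct([0.01, 0.04])
        assert adjusted == pytest.approx([0.02, 0.04])

    def test_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(26)
        p = rng.uniform(0.001, 1, 12)
        adj = familywise_correct(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            familywise_correct([])
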