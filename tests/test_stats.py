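"""Mann-Whitney, Spearman, descriptive summaries and cohort tables."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dmvquant.phantom import CohortSpec, generate_cohort
from dmvquant.stats import (compare_groups, correlation_table, describe,
                            format_mean_sd, holm_adjust, mann_whitney,
                            spearman_corr)


def u_null_counts(n1, n2):
    """Independent oracle: the exact tie-free null distribution of U by
    the classic count recursion f(n1, n2, u)."""
    max_u = n1 * n2
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(a, b):
        if a == 0 or b == 0:
            out = np.zeros(max_u + 1)
            out[0] = 1.0
            return tuple(out)
        fa = np.array(f(a - 1, b))
        fb = np.array(f(a, b - 1))
        out = np.zeros(max_u + 1)
        # adding the largest element to sample 1 contributes b to U
        out[b:] += fa[:max_u + 1 - b]
        out += fb
        return tuple(out)

    return np.array(f(n1, n2))


def oracle_exact_p(n1, n2, u_obs):
    counts = u_null_counts(n1, n2)
    mu = n1 * n2 / 2.0
    us = np.arange(len(counts))
    keep = np.abs(us - mu) >= abs(u_obs - mu) - 1e-12
    return counts[keep].sum() / counts.sum()


class TestMannWhitney:
    def test_fully_separated_samples(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.u == 0.0
        assert r.method == "exact"
        # 2 of the C(6,3)=20 labelings are as or more extreme
        assert r.p_two_sided == pytest.approx(0.1)

    def test_identical_multisets_are_degenerate_symmetric(self):
        r = mann_whitney([1, 2, 2, 5], [1, 2, 2, 5])
        assert r.u == pytest.approx(8.0)  # n1 n2 / 2
        assert r.p_two_sided == pytest.approx(1.0)

    def test_all_values_tied(self):
        r = mann_whitney([3, 3, 3], [3, 3, 3, 3])
        assert r.u == 6.0 and r.z == 0.0 and r.p_two_sided == 1.0

    def test_exact_matches_enumeration_oracle_all_small_sizes(self):
        """Exact-mode p equals the count-recursion oracle for every
        achievable U at every group size up to 7 (tie-free)."""
        for n1, n2 in itertools.product(range(1, 8), repeat=2):
            for u_target in range(n1 * n2 + 1):
                # construct a tie-free sample achieving U = u_target:
                # x_i beats u_target of the y's in total
                x, y = _sample_with_u(n1, n2, u_target)
                r = mann_whitney(x, y, mode="exact")
                assert r.u == u_target
                assert r.p_two_sided == pytest.approx(
                    oracle_exact_p(n1, n2, u_target), abs=1e-12)

    def test_exact_matches_scipy_on_random_tiefree(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            x = rng.normal(size=int(rng.integers(2, 9)))
            y = rng.normal(size=int(rng.integers(2, 9)))
            mine = mann_whitney(x, y, mode="exact")
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact")
            assert mine.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_mode_matches_scipy_without_continuity(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=40), rng.normal(0.3, 1, size=35)
        mine = mann_whitney(x, y, mode="normal")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert mine.p_two_sided == pytest.approx(ref.pvalue, rel=1e-10)

    def test_tie_corrected_sigma_matches_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 4, size=30).astype(float)
        y = rng.integers(0, 4, size=25).astype(float)
        mine = mann_whitney(x, y, mode="normal")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert mine.p_two_sided == pytest.approx(ref.pvalue, rel=1e-10)

    def test_exact_and_normal_agree_for_moderate_n(self):
        """With the continuity correction the normal approximation tracks
        the exact p within 0.02 at every achievable U for n1 = n2 = 8."""
        for u in range(8 * 8 + 1):
            x, y = _sample_with_u(8, 8, u)
            pe = mann_whitney(x, y, mode="exact").p_two_sided
            pn = mann_whitney(x, y, mode="normal",
                              continuity=True).p_two_sided
            assert abs(pe - pn) < 0.02

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=12), rng.normal(size=15)
        a = mann_whitney(x, y, mode="normal")
        b = mann_whitney(np.exp(x), np.exp(y), mode="normal")
        assert a.u == b.u and a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_u_bounds(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=9), rng.normal(size=11)
        r = mann_whitney(x, y)
        assert 0 <= r.u <= 9 * 11

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])

    def test_forced_exact_beyond_cap_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            mann_whitney(rng.normal(size=20), rng.normal(size=20),
                         mode="exact")


def _sample_with_u(n1, n2, u):
    """Tie-free samples (x, y) with first-sample U exactly u: x_i counts
    how many y's it exceeds; greedy decomposition of u."""
    beats = []
    remaining = u
    for _ in range(n1):
        b = min(remaining, n2)
        beats.append(b)
        remaining -= b
    assert remaining == 0
    y = np.arange(1.0, n2 + 1)
    # place x_i strictly between y_b and y_{b+1}, all values distinct
    x = np.array([b + (i + 1.0) / (n1 + 1.0) for i, b in enumerate(beats)])
    return x, y


class TestSpearman:
    def test_monotone_relationship_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        r = spearman_corr(x, np.exp(x))
        assert r.rho == pytest.approx(1.0)

    def test_hand_computed_example(self):
        assert spearman_corr([1, 2, 3], [3, 1, 2]).rho == pytest.approx(-0.5)

    def test_matches_bruteforce_rank_pearson_with_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 8, size=n).astype(float)
            y = (x + rng.integers(0, 6, size=n)).astype(float)
            if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
                continue
            rx, ry = sps.rankdata(x), sps.rankdata(y)
            brute = np.corrcoef(rx, ry)[0, 1]
            assert spearman_corr(x, y).rho == pytest.approx(brute,
                                                            abs=1e-12)

    def test_symmetry_and_sign_flip(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=20), rng.normal(size=20)
        a = spearman_corr(x, y)
        assert a.rho == pytest.approx(spearman_corr(y, x).rho)
        assert spearman_corr(x, -y).rho == pytest.approx(-a.rho)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 1, 1], [1, 2, 3])

    def test_midranks_convention(self):
        assert sps.rankdata([1, 1, 2]).tolist() == [1.5, 1.5, 3.0]


class TestDescribe:
    def test_basic(self):
        d = describe([1, 2, 3])
        assert d.mean == 2.0 and d.sd == pytest.approx(1.0)
        assert (d.min, d.max, d.n) == (1.0, 3.0, 3)

    def test_single_value_has_no_sd(self):
        assert describe([4.2]).sd is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            describe([])

    def test_presentation_format(self):
        rng = np.random.default_rng(8)
        vals = np.clip(np.rint(rng.normal(12.46, 5.58, 400)), 1, 31)
        text = format_mean_sd(describe(vals))
        # "12.46 ± 5.58 (1–31)"-style presentation
        assert "±" in text and "(" in text and "–" in text


class TestCompareGroups:
    def test_effect_direction_recovered_on_simulated_cohorts(self):
        """Term > preterm DMV width recovered in most simulated cohorts
        generated at the default group parameters."""
        wins = 0
        for seed in range(25):
            cohort = generate_cohort(CohortSpec(), seed=seed)
            t = compare_groups(cohort, "term", ["dmv_width_mm"])
            row = t.iloc[0]
            means = {row["level_1"]: row["mean_1"],
                     row["level_2"]: row["mean_2"]}
            if means["term"] > means["preterm"]:
                wins += 1
        assert wins >= 23  # >= 90% of seeds

    def test_single_level_factor_rejected(self):
        cohort = generate_cohort(CohortSpec(n_subjects=50), seed=0)
        cohort["term"] = "term"
        with pytest.raises(ValueError, match="exactly 2"):
            compare_groups(cohort, "term", ["dmv_width_mm"])

    def test_all_absent_outcome_skipped_with_warning(self):
        cohort = generate_cohort(CohortSpec(n_subjects=60), seed=1)
        cohort["tsv_right_mm"] = np.nan
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            t = compare_groups(cohort, "term",
                               ["dmv_width_mm", "tsv_right_mm"])
        assert any("tsv_right_mm" in str(x.message) for x in w)
        assert list(t["outcome"]) == ["dmv_width_mm"]

    def test_pairwise_deletion_of_absent_values(self):
        cohort = generate_cohort(CohortSpec(n_subjects=400), seed=2)
        t = compare_groups(cohort, "term", ["dmv_count", "tsv_left_mm"])
        n_dmv = t.loc[t.outcome == "dmv_count", ["n_1", "n_2"]].sum(axis=1)
        n_tsv = t.loc[t.outcome == "tsv_left_mm", ["n_1", "n_2"]].sum(axis=1)
        assert int(n_dmv.iloc[0]) == 400
        assert int(n_tsv.iloc[0]) == int(cohort["tsv_left_mm"].count())

    def test_null_factor_rejects_at_alpha(self):
        """Comparing across a factor unrelated to the outcome rejects at
        roughly the nominal rate."""
        rej = 0
        n_seeds = 60
        for seed in range(n_seeds):
            cohort = generate_cohort(CohortSpec(n_subjects=200), seed=seed)
            t = compare_groups(cohort, "delivery", ["dmv_curvature"])
            rej += t["p"].iloc[0] < 0.05
        assert rej / n_seeds < 0.15

    def test_significance_stars(self):
        cohort = generate_cohort(CohortSpec(n_subjects=317), seed=3)
        t = compare_groups(cohort, "term", ["dmv_count", "dmv_width_mm"],
                           adjust="holm")
        assert set(t["significance"]) <= {"", "*", "**"}
        assert (t["p_holm"] >= t["p"] - 1e-15).all()

    def test_holm_adjustment_values(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04, 0.03]),
                                   [0.03, 0.06, 0.06])


class TestCorrelationTable:
    def test_shape_and_values(self):
        cohort = generate_cohort(CohortSpec(n_subjects=500), seed=4)
        t = correlation_table(cohort, ["tsv_left_mm", "acv_left_mm"],
                              ["dmv_count", "dmv_width_mm"])
        assert list(t["variable"]) == ["tsv_left_mm", "acv_left_mm"]
        sub = cohort.dropna(subset=["tsv_left_mm"])
        expect = sps.spearmanr(sub["tsv_left_mm"], sub["dmv_count"])[0]
        assert t.loc[0, "rho_dmv_count"] == pytest.approx(expect)
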