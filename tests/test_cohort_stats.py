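"""ANOVA / Kruskal-Wallis formula checks against oracles and invariances."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from msycnv.cohort_stats import (
    anova_oneway,
    compare_cohorts,
    comparison_frame,
    kruskal_wallis,
    pairwise_grid,
)
from msycnv.droplet import GENES


class TestAnova:
    def test_identical_groups_are_null(self):
        assert anova_oneway({"a": [2, 2, 2], "b": [2, 2, 2]}) == (0.0, 1.0)

    def test_hand_computed_f(self):
        f, p = anova_oneway({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert f == pytest.approx(13.5)
        assert p == pytest.approx(sps.f.sf(13.5, 1, 4))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_on_unbalanced_groups(self, seed):
        rng = np.random.default_rng(seed)
        groups = {
            "a": rng.normal(0, 1, 4),
            "b": rng.normal(0.5, 1, 11),
            "c": rng.normal(1, 2, 1),  # single-value group kept
        }
        f, p = anova_oneway(groups)
        ref = sps.f_oneway(*groups.values())
        assert f == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_relabel_and_permute_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 5)
        base = anova_oneway({"x": a, "y": b})
        assert anova_oneway({"y": b[::-1], "x": a[::-1]}) == pytest.approx(base)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            anova_oneway({"a": [1.0]})
        with pytest.raises(ValueError):
            anova_oneway({"a": [1.0], "b": [2.0]})  # no within-group df


class TestKruskalWallis:
    def test_degenerate_identical_values(self):
        assert kruskal_wallis({"a": [1.0], "b": [1.0]}) == (0.0, 1.0)

    def test_hand_computed_h_no_ties(self):
        h, p = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert h == pytest.approx(12 / 42 * 13.5)  # = 27/7 ~ 3.857
        assert p == pytest.approx(sps.chi2.sf(h, 1))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = {
            "a": np.round(rng.normal(0, 1, 9), 1),
            "b": np.round(rng.normal(0.5, 1, 6), 1),
        }
        h, p = kruskal_wallis(groups)
        ref = sps.kruskal(*groups.values())
        assert h == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_exhaustive_permutation_on_six_points(self):
        """On 3-vs-3 inputs the permutation p-value is an exact count over
        all 20 assignments, and H matches a brute-force rank computation."""
        values = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]}
        h, p = kruskal_wallis(values, method="permutation")
        pooled = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        ranks = sps.rankdata(pooled)
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            ra = ranks[list(combo)]
            rb = ranks[[i for i in range(6) if i not in combo]]
            hh = 12 / (6 * 7) * (3 * (ra.mean() - 3.5) ** 2 + 3 * (rb.mean() - 3.5) ** 2)
            total += 1
            count += hh >= h - 1e-12
        assert total == 20
        assert p == pytest.approx(count / 20)
        assert h == pytest.approx(12 / 42 * 13.5)

    def test_chi2_close_to_permutation_at_n30(self):
        rng = np.random.default_rng(5)
        groups = {
            "a": rng.normal(0, 1, 10),
            "b": rng.normal(0.7, 1, 10),
            "c": rng.normal(0.3, 1, 10),
        }
        _, p_chi = kruskal_wallis(groups)
        _, p_perm = kruskal_wallis(
            groups, method="permutation", n_permutations=20_000,
            rng=np.random.default_rng(11),
        )
        assert abs(p_chi - p_perm) < 0.03

    @given(st.sampled_from([math.exp, lambda x: x**3, lambda x: 2 * x + 7]))
    def test_h_invariant_under_monotone_transform(self, f):
        groups = {"a": [0.1, 0.4, 1.2, 0.9], "b": [1.5, 2.0, 0.2]}
        h0, _ = kruskal_wallis(groups)
        h1, _ = kruskal_wallis({k: [f(x) for x in v] for k, v in groups.items()})
        assert h1 == pytest.approx(h0)

    def test_f_not_invariant_under_monotone_transform(self):
        groups = {"a": [0.1, 0.4, 1.2, 0.9], "b": [1.5, 2.0, 0.2]}
        f0, _ = anova_oneway(groups)
        f1, _ = anova_oneway({k: [math.exp(x) for x in v] for k, v in groups.items()})
        assert f1 != pytest.approx(f0)


def _profiles(sizes, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for label, n in sizes.items():
        for _ in range(n):
            i += 1
            row = {"sample_id": f"s{i}", "breed": label, "cohort": "normal"}
            for g in GENES:
                row[f"{g}_mean"] = rng.normal(5 + (shift if label == "hi" else 0), 1)
            rows.append(row)
    return pd.DataFrame(rows)


class TestCompareCohorts:
    def test_min_group_size_excludes_and_reports(self):
        profiles = _profiles({"a": 1, "b": 4, "c": 6, "hi": 10})
        results = compare_cohorts(profiles, "breed", min_group_size=5)
        assert results[0].n_groups == 2
        assert results[0].excluded_groups == ("a", "b")

    def test_sensitivity_to_small_groups_is_concordant(self):
        """Including or excluding tiny groups leaves a strong between-group
        signal significant under both tests."""
        profiles = _profiles({"a": 2, "b": 12, "hi": 12}, shift=3.0, seed=4)
        full = {r.gene: r for r in compare_cohorts(profiles, "breed")}
        trimmed = {
            r.gene: r
            for r in compare_cohorts(profiles, "breed", min_group_size=5)
        }
        for gene in GENES:
            assert (full[gene].P1 < 0.01) == (trimmed[gene].P1 < 0.01)
            assert (full[gene].P2 < 0.01) == (trimmed[gene].P2 < 0.01)

    def test_pvalue_suppression(self):
        profiles = _profiles({"a": 5, "b": 5})
        res = compare_cohorts(profiles, "breed", report_pvalues=False)
        assert all(math.isnan(r.P1) and math.isnan(r.P2) for r in res)
        assert all(r.F_stat >= 0 for r in res)

    def test_holm_annotation_is_no_smaller_than_raw(self):
        profiles = _profiles({"a": 6, "hi": 6}, shift=1.0, seed=2)
        res = compare_cohorts(profiles, "breed", holm=True)
        for r in res:
            assert r.P1_holm >= r.P1 - 1e-12
            assert r.P2_holm >= r.P2 - 1e-12

    def test_unknown_grouping_rejected(self):
        with pytest.raises(KeyError):
            compare_cohorts(_profiles({"a": 2, "b": 2}), "herd")

    def test_pairwise_grid_layout(self):
        profiles = _profiles({"bi_CO": 6, "uni_CO": 18, "normal": 28}, seed=9)
        profiles["cohort"] = profiles["breed"]
        grid = pairwise_grid(
            profiles,
            "cohort",
            [
                ("bi_vs_uni", ["bi_CO"], ["uni_CO"]),
                ("co_all_vs_normal", ["bi_CO", "uni_CO"], ["normal"]),
            ],
        )
        assert set(grid["contrast"]) == {"bi_vs_uni", "co_all_vs_normal"}
        assert len(grid) == 2 * len(GENES)
        row = grid[(grid.contrast == "co_all_vs_normal") & (grid.gene == "TSPY")]
        assert int(row["n_left"].iloc[0]) == 24 and int(row["n_right"].iloc[0]) == 28

    def test_frame_serialization(self):
        res = compare_cohorts(_profiles({"a": 5, "b": 5}), "breed")
        df = comparison_frame(res)
        assert {"gene", "F", "P1", "H", "P2", "n_groups", "n_total"} <= set(df.columns)
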