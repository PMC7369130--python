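from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from dmrcall import (ConfigurationError, UndefinedRatioError, ValidationError,
                     call_differential_sites, fisher_exact_two_sided,
                     joint_coverage_filter, methylation_ratio,
                     pool_counts_by_arm, site_fisher_test, site_tests)
from dmrcall.diffmeth import is_degenerate, restrict_tables

from conftest import count_table


def fisher_enumeration(a, b, c, d):
    """Exact two-sided Fisher p by integer-arithmetic enumeration of the
    hypergeometric support (point-probability rule with the 1e-7 guard)."""
    n1, big_k, big_n = a + b, a + c, a + b + c + d
    w_obs = comb(big_k, a) * comb(big_n - big_k, n1 - a)
    lo, hi = max(0, n1 + big_k - big_n), min(big_k, n1)
    total = 0
    for k in range(lo, hi + 1):
        w = comb(big_k, k) * comb(big_n - big_k, n1 - k)
        if w * 10**7 <= w_obs * (10**7 + 1):
            total += w
    return total / comb(big_n, n1)


class TestMethylationRatio:
    def test_basic_arithmetic(self):
        assert methylation_ratio(5, 15) == 0.25
        assert methylation_ratio(0, 7) == 0.0

    def test_zero_coverage_is_error(self):
        with pytest.raises(UndefinedRatioError):
            methylation_ratio(0, 0)


class TestJointCoverageFilter:
    @staticmethod
    def tables_with_coverages(coverages):
        return {f"s{i}": count_table([("chr1", 100, c, 0)])
                for i, c in enumerate(coverages)}

    def test_site_retained_when_all_samples_reach_threshold(self):
        pos = joint_coverage_filter(self.tables_with_coverages([5, 6, 9, 5]), 5)
        assert pos["pos"].tolist() == [100]

    def test_site_dropped_when_one_sample_below_threshold(self):
        pos = joint_coverage_filter(self.tables_with_coverages([5, 4, 9, 5]), 5)
        assert len(pos) == 0

    def test_site_absent_from_one_sample_dropped(self, four_sample_tables):
        tables, _ = four_sample_tables
        pos = joint_coverage_filter(tables, 5)
        # chr2:10 exists only in s_heat_2; chr1 sites are shared
        assert pos["chrom"].unique().tolist() == ["chr1"]
        assert pos["pos"].tolist() == [100, 150, 300]

    def test_empty_sample_set_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            joint_coverage_filter({}, 5)

    def test_raising_threshold_never_adds_positions(self, four_sample_tables):
        tables, _ = four_sample_tables
        loose = joint_coverage_filter(tables, 3)
        strict = joint_coverage_filter(tables, 6)
        loose_set = set(map(tuple, loose.to_numpy()))
        strict_set = set(map(tuple, strict.to_numpy()))
        assert strict_set <= loose_set


class TestPooling:
    def test_counts_sum_within_arm(self, four_sample_tables):
        tables, design = four_sample_tables
        pos = joint_coverage_filter(tables, 5)
        pooled = pool_counts_by_arm(restrict_tables(tables, pos), design, "F", "liver")
        row = pooled[pooled["pos"] == 100].iloc[0]
        assert (row["ctrl_meth"], row["ctrl_unmeth"]) == (5, 15)
        assert (row["heat_meth"], row["heat_unmeth"]) == (17, 3)

    def test_single_sample_per_arm_passes_through(self):
        tables = {"p_ctrl": count_table([("chr1", 5, 3, 7)]),
                  "p_heat": count_table([("chr1", 5, 8, 2)])}
        design = pd.DataFrame({"sample_id": ["p_ctrl", "p_heat"],
                               "father_group": ["F", "F"],
                               "arm": ["control", "heat"],
                               "organ": ["testis", "testis"],
                               "pooled": [True, True]})
        pooled = pool_counts_by_arm(tables, design, "F", "testis")
        assert pooled.iloc[0][["ctrl_meth", "ctrl_unmeth", "heat_meth",
                               "heat_unmeth"]].tolist() == [3, 7, 8, 2]

    def test_missing_arm_is_configuration_error(self):
        tables = {"only_ctrl": count_table([("chr1", 5, 3, 7)])}
        design = pd.DataFrame({"sample_id": ["only_ctrl"], "father_group": ["F"],
                               "arm": ["control"], "organ": ["liver"],
                               "pooled": [False]})
        with pytest.raises(ConfigurationError):
            pool_counts_by_arm(tables, design, "F", "liver")


class TestFisher:
    @pytest.mark.parametrize("table, expected", [
        ((10, 0, 0, 10), 2 / 184756),     # both extreme tables of the support
        ((5, 5, 5, 5), 1.0),              # identical proportions
        ((2, 0, 0, 2), 1 / 3),            # 6 tables, two extremes at 1/6 each
    ])
    def test_known_tables(self, table, expected):
        assert site_fisher_test(*table) == pytest.approx(expected, abs=1e-12)
        assert fisher_enumeration(*table) == pytest.approx(expected, abs=1e-15)

    def test_zero_margin_table_degenerate_p_one(self):
        assert site_fisher_test(0, 10, 0, 12) == 1.0
        pooled = pd.DataFrame({"chrom": ["chr1"], "pos": [1], "ctrl_meth": [0],
                               "ctrl_unmeth": [10], "heat_meth": [0],
                               "heat_unmeth": [12]})
        assert is_degenerate(pooled).all()

    def test_empty_arm_rejected(self):
        with pytest.raises(ValidationError):
            site_fisher_test(0, 0, 5, 5)

    @settings(derandomize=True, max_examples=200)
    @given(st.tuples(*(st.integers(0, 40) for _ in range(4))))
    def test_matches_scipy_and_enumeration(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0:
            return
        ours = site_fisher_test(a, b, c, d)
        ref = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)
        assert ours == pytest.approx(fisher_enumeration(a, b, c, d), abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(*(st.integers(0, 30) for _ in range(4))))
    def test_arm_swap_symmetry(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0:
            return
        assert site_fisher_test(a, b, c, d) == pytest.approx(
            site_fisher_test(c, d, a, b), rel=1e-12)

    def test_vectorised_form_matches_scalar(self):
        rng = np.random.default_rng(0)
        a, b, c, d = rng.integers(0, 50, size=(4, 200))
        a += 1; c += 1  # non-empty arms
        vec = fisher_exact_two_sided(a, b, c, d)
        for i in range(0, 200, 17):
            assert vec[i] == pytest.approx(
                site_fisher_test(a[i], b[i], c[i], d[i]), rel=1e-12)


class TestCallDifferentialSites:
    def make_sites(self, rows):
        frame = pd.DataFrame(rows, columns=["chrom", "pos", "p_value", "delta"])
        frame["direction"] = np.where(frame["delta"] > 0, "hyper",
                                      np.where(frame["delta"] < 0, "hypo", "none"))
        return frame

    def test_threshold_is_strict(self):
        sites = self.make_sites([("chr1", 1, 0.04, 0.3),
                                 ("chr1", 2, 0.05, 0.4),
                                 ("chr1", 3, 0.9, -0.1)])
        called = call_differential_sites(sites, alpha=0.05)
        assert called["pos"].tolist() == [1]
        assert called["direction"].tolist() == ["hyper"]

    def test_zero_delta_never_called(self):
        sites = self.make_sites([("chr1", 1, 0.001, 0.0)])
        assert len(call_differential_sites(sites, alpha=0.05)) == 0

    def test_all_null_sites_give_empty_call_set(self):
        sites = self.make_sites([("chr1", i, 1.0, 0.1) for i in range(5)])
        assert len(call_differential_sites(sites, alpha=0.05)) == 0

    def test_direction_consistent_with_delta_sign(self, four_sample_tables):
        tables, design = four_sample_tables
        pos = joint_coverage_filter(tables, 5)
        pooled = pool_counts_by_arm(restrict_tables(tables, pos), design, "F", "liver")
        sites = site_tests(pooled)
        assert ((sites["delta"] > 0) == (sites["direction"] == "hyper")).all()
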