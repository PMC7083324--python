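"""Visit-grid alignment, exclusions, QC comparisons, standardization and
the Spearman correlation screens."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from ehrssm import (
    ExclusionCriteria,
    apply_exclusions,
    baseline_comparison,
    load_cohort,
    read_cohort,
    save_cohort,
    spearman_matrices,
    standardize,
)
from ehrssm.cohort import ExclusionReport


def make_frame(rows, blood=("glucose", "hdl"), env=("bmi",)):
    cols = ["pid", "year", *blood, *env]
    return pd.DataFrame(rows, columns=cols)


SCHEMA = {"pid": "pid", "year": "year", "blood": ["glucose", "hdl"], "env": ["bmi"]}


class TestLoadCohort:
    def test_gap_years_become_missing_visits(self):
        # attendance in 2009, 2010, 2013, 2014 maps to t = 1, 2, 5, 6
        df = make_frame(
            [["a", y, 1.0, 2.0, 22.0] for y in (2009, 2010, 2013, 2014)]
        )
        ds = load_cohort(df, SCHEMA)
        s = ds.participants[0]
        assert s.obs_times == frozenset({1, 2, 5, 6})
        assert s.T_k == 6
        assert np.isnan(s.y[2]).all() and np.isnan(s.y[3]).all()

    def test_single_visit_degenerate_series(self):
        ds = load_cohort(make_frame([["a", 2010, 1.0, 2.0, 22.0]]), SCHEMA)
        assert ds.participants[0].obs_times == frozenset({1})
        assert ds.participants[0].T_k == 1

    def test_row_order_invariance(self):
        rows = [
            ["a", 2009, 1.0, 2.0, 22.0],
            ["b", 2010, 3.0, 4.0, 25.0],
            ["a", 2010, 1.5, 2.5, 23.0],
            ["b", 2012, 3.5, 4.5, 26.0],
        ]
        ds1 = load_cohort(make_frame(rows), SCHEMA)
        ds2 = load_cohort(make_frame(list(reversed(rows))), SCHEMA)
        assert ds1.pids == ds2.pids
        for s1, s2 in zip(ds1.participants, ds2.participants):
            np.testing.assert_array_equal(s1.y, s2.y)
            assert s1.obs_times == s2.obs_times

    def test_duplicate_pid_year_raises(self):
        df = make_frame(
            [["a", 2009, 1.0, 2.0, 22.0], ["a", 2009, 1.1, 2.1, 22.5]]
        )
        with pytest.raises(ValueError, match="a"):
            load_cohort(df, SCHEMA)

    def test_non_numeric_cell_raises_with_column(self):
        df = make_frame([["a", 2009, "high", 2.0, 22.0]])
        with pytest.raises(ValueError, match="glucose"):
            load_cohort(df, SCHEMA)

    def test_missing_cells_masked_not_dropped(self):
        df = make_frame([["a", 2009, np.nan, 2.0, 22.0], ["a", 2010, 1.0, np.nan, 23.0]])
        ds = load_cohort(df, SCHEMA)
        s = ds.participants[0]
        assert np.isnan(s.y[0, 0]) and s.y[0, 1] == 2.0
        assert s.y[1, 0] == 1.0 and np.isnan(s.y[1, 1])


class TestExclusions:
    def build(self, n_med=3, n_single=2, n_plain=5):
        rows = []
        pid = 0
        for _ in range(n_plain):
            rows += [[f"p{pid}", 2009, 1.0, 2.0, 22.0, 0], [f"p{pid}", 2010, 1.0, 2.0, 22.0, 0]]
            pid += 1
        for _ in range(n_med):
            rows += [[f"p{pid}", 2009, 1.0, 2.0, 22.0, 1], [f"p{pid}", 2010, 1.0, 2.0, 22.0, 1]]
            pid += 1
        for _ in range(n_single):
            rows += [[f"p{pid}", 2009, 1.0, 2.0, 22.0, 0]]
            pid += 1
        df = pd.DataFrame(rows, columns=["pid", "year", "glucose", "hdl", "bmi", "meds"])
        return load_cohort(df, {**SCHEMA, "medication": "meds"})

    def test_counts_and_retained_fraction(self):
        ds = self.build()
        out, report = apply_exclusions(
            ds, ExclusionCriteria(exclude_medication=True, min_visits=2)
        )
        assert report.n_excluded_medication == 3
        assert report.n_excluded_few_visits == 2
        assert out.K == report.n_retained == 5
        assert report.retained_fraction == pytest.approx(0.5)

    def test_counts_partition_the_input(self):
        ds = self.build(n_med=4, n_single=3, n_plain=6)
        _, report = apply_exclusions(
            ds, ExclusionCriteria(exclude_medication=True, min_visits=2)
        )
        total = (
            report.n_excluded_age
            + report.n_excluded_medication
            + report.n_excluded_few_visits
            + report.n_retained
        )
        assert total == report.n_input == ds.K

    def test_empty_criteria_is_identity(self):
        ds = self.build()
        out, report = apply_exclusions(ds, ExclusionCriteria())
        assert out.K == ds.K
        assert report.n_retained == ds.K

    def test_printed_retention_arithmetic(self):
        # 429 retained of 1,196 screened is a 35.9% retention
        report = ExclusionReport(n_input=1196, n_excluded_medication=533,
                                 n_excluded_few_visits=104, n_excluded_age=130,
                                 n_retained=429)
        assert report.retained_percent == pytest.approx(35.9, abs=0.05)


class TestBaselineComparison:
    def two_cohorts(self, shift=0.0, n=20, rng=None):
        rng = rng or np.random.default_rng(0)
        rows_a = [[f"a{i}", 2009, v, 1.0, 22.0] for i, v in enumerate(rng.normal(0, 1, n))]
        rows_a += [[f"a{i}", 2010, 0.0, 1.0, 22.0] for i in range(n)]
        rows_b = [[f"b{i}", 2009, v + shift, 1.0, 22.0] for i, v in enumerate(rng.normal(0, 1, n))]
        rows_b += [[f"b{i}", 2010, 0.0, 1.0, 22.0] for i in range(n)]
        return load_cohort(make_frame(rows_a), SCHEMA), load_cohort(make_frame(rows_b), SCHEMA)

    def test_bonferroni_threshold_39_features_2_groups(self):
        a, b = self.two_cohorts()
        table = baseline_comparison(a, b, ["glucose"], alpha=0.05, n_comparison_groups=2)
        # the table's threshold generalizes 0.05 / (n_features x n_groups)
        assert table.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 2)

    def test_identical_groups_p_one(self):
        a, _ = self.two_cohorts()
        table = baseline_comparison(a, a, ["glucose"])
        assert table["p_value"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_large_shift_detected_and_exact_enumeration_at_n5(self):
        a, b = self.two_cohorts(shift=10.0)
        table = baseline_comparison(a, b, ["glucose"])
        assert table["p_value"].iloc[0] < 1e-4

        # exact null enumeration of the rank-sum statistic at n = m = 5
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 5), rng.normal(0.5, 1, 5)
        u_obs = sstats.mannwhitneyu(x, y, alternative="two-sided", method="exact").statistic
        pooled = np.concatenate([x, y])
        ranks = sstats.rankdata(pooled)
        stats = []
        for comb in itertools.combinations(range(10), 5):
            rank_sum = ranks[list(comb)].sum()
            stats.append(rank_sum - 5 * 6 / 2)  # U statistic of the "x" group
        stats = np.array(stats)
        u_lo, u_hi = min(u_obs, 25 - u_obs), max(u_obs, 25 - u_obs)
        p_exact = np.mean((stats <= u_lo) | (stats >= u_hi))
        p_scipy = sstats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p_scipy == pytest.approx(p_exact, abs=1e-12)

    def test_undefined_p_for_tiny_group(self):
        a, b = self.two_cohorts()
        # blank out all but one first-visit value in b
        for s in b.participants[1:]:
            s.y[0, 0] = np.nan
        table = baseline_comparison(a, b, ["glucose"])
        assert np.isnan(table["p_value"].iloc[0])


class TestStandardize:
    def test_unit_sample_variance_and_zero_mean(self):
        df = make_frame([["a", 2009 + i, v, v * 2, 20.0 + v] for i, v in enumerate([1.0, 2.0, 3.0])])
        ds = load_cohort(df, SCHEMA)
        out, norm = standardize(ds)
        col = out.participants[0].y[:, 0]
        assert np.nanmean(col) == pytest.approx(0.0, abs=1e-12)
        assert np.nanvar(col, ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_roundtrip_identity(self, small_synthetic):
        raw = small_synthetic["raw"]
        std, norm = standardize(raw)
        for s_raw, s_std in zip(raw.participants, std.participants):
            back = norm.invert_y(s_std.y)
            np.testing.assert_allclose(back, s_raw.y, atol=1e-10)
            np.testing.assert_allclose(norm.invert_z(s_std.z), s_raw.z, atol=1e-10)

    def test_masks_preserved_and_excluded_from_moments(self):
        df = make_frame(
            [["a", 2009, 1.0, np.nan, 22.0], ["a", 2010, 2.0, 1.0, 23.0],
             ["b", 2009, 3.0, 2.0, 24.0]]
        )
        ds = load_cohort(df, SCHEMA)
        out, _ = standardize(ds)
        pooled = np.concatenate([s.y for s in out.participants])
        assert np.isnan(pooled[0, 1])
        assert np.nanmean(pooled[:, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_column_raises(self):
        df = make_frame([["a", 2009, 5.0, 1.0, 22.0], ["a", 2010, 5.0, 2.0, 23.0]])
        with pytest.raises(ValueError, match="glucose"):
            standardize(load_cohort(df, SCHEMA))


class TestSpearman:
    def build_panel(self, rng, K=10, T=5):
        rows = []
        for k in range(K):
            base = rng.normal()
            for t in range(T):
                g = base + rng.normal(0, 0.5)
                rows.append([f"p{k}", 2009 + t, g, np.exp(g), 20 + rng.normal()])
        return load_cohort(make_frame(rows), SCHEMA)

    def test_unit_diagonal_and_monotone_transform(self):
        ds = self.build_panel(np.random.default_rng(0))
        levels, diffs = spearman_matrices(ds)
        assert np.allclose(np.diag(levels.values), 1.0)
        # hdl = exp(glucose) pooled over 50 points: rank correlation exactly 1
        assert levels.loc["glucose", "hdl"] == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(5)
        ds = self.build_panel(rng, K=1, T=5)
        levels, _ = spearman_matrices(ds)
        y = np.array([s.y for s in ds.participants]).reshape(-1, 2)
        r1 = sstats.rankdata(y[:, 0])
        r2 = sstats.rankdata(y[:, 1])
        oracle = np.corrcoef(r1, r2)[0, 1]
        assert levels.loc["glucose", "hdl"] == pytest.approx(oracle, abs=1e-12)

    def test_diffs_use_only_consecutive_observed_pairs(self):
        # observed at {1, 3}: no consecutive pair, so no contribution
        df = make_frame([["a", 2009, 1.0, 2.0, 22.0], ["a", 2011, 3.0, 1.0, 23.0]])
        ds = load_cohort(df, SCHEMA)
        _, diffs = spearman_matrices(ds)
        off_diag = diffs.values[~np.eye(3, dtype=bool)]
        assert np.isnan(off_diag).all()


def test_cohort_archive_roundtrip(tmp_path, small_synthetic):
    ds, norm = small_synthetic["cohort"], small_synthetic["norm"]
    path = tmp_path / "cohort.json"
    save_cohort(ds, path, norm)
    ds2, norm2 = read_cohort(path)
    assert ds2.pids == ds.pids
    for s1, s2 in zip(ds.participants, ds2.participants):
        np.testing.assert_allclose(
            np.nan_to_num(s1.y, nan=-999), np.nan_to_num(s2.y, nan=-999), atol=1e-12
        )
        assert s1.obs_times == s2.obs_times
    np.testing.assert_allclose(norm2.y_loc, norm.y_loc)
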