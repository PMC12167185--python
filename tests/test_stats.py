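"""Rank tests against brute-force enumeration oracles; summaries."""

import itertools

import numpy as np
import pytest

from mpmri import io, simulate, stats
from mpmri.exceptions import InputError


def brute_force_mann_whitney_p(x, y):
    """Exact two-sided p by enumerating every labeling of the pooled data.

    p = P(min(U1, U2) <= observed min) under random relabeling.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_of(labels):
        xs = [pooled[i] for i in labels]
        ys = [pooled[i] for i in range(len(pooled)) if i not in labels]
        u1 = sum(1 for a in xs for b in ys if a > b) \
            + 0.5 * sum(1 for a in xs for b in ys if a == b)
        return min(u1, n1 * len(ys) - u1)

    obs = u_of(tuple(range(n1)))
    count = 0
    total = 0
    for labels in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if u_of(set(labels)) <= obs + 1e-12:
            count += 1
    return count / total


def brute_force_wilcoxon_p(diffs):
    """Exact two-sided p by enumerating all sign assignments of |d| ranks."""
    d = np.asarray([v for v in diffs if v != 0], dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    obs = min(w_pos, w_neg)
    n = d.size
    count = 0
    for signs in itertools.product([1, -1], repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s > 0)
        wn = ranks.sum() - wp
        if min(wp, wn) <= obs + 1e-12:
            count += 1
    return count / 2 ** n


class TestMannWhitney:
    def test_disjoint_samples_exact_p(self):
        r = stats.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0
        assert r.p_value == pytest.approx(0.1)  # 2 / C(6,3)
        assert r.method == "exact"

    def test_identical_samples_p_one(self):
        r = stats.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert r.p_value == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(5):
            x = rng.permutation(np.arange(12.0))[:6]
            y = np.setdiff1d(np.arange(12.0), x)
            r = stats.mann_whitney_u(x, y)
            assert r.method == "exact"
            assert r.p_value == pytest.approx(
                brute_force_mann_whitney_p(x, y), abs=1e-12)

    def test_all_small_tie_free_datasets_match_oracle(self, rng):
        """Exhaustive-ish check across sizes n, m <= 6."""
        for n, m in [(2, 2), (3, 4), (5, 5), (6, 4), (6, 6)]:
            vals = rng.normal(size=n + m)
            r = stats.mann_whitney_u(vals[:n], vals[n:])
            assert r.p_value == pytest.approx(
                brute_force_mann_whitney_p(vals[:n], vals[n:]), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(size=7), rng.normal(size=9) + 0.5
        p1 = stats.mann_whitney_u(x, y).p_value
        p2 = stats.mann_whitney_u(np.exp(x), np.exp(y)).p_value
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_large_samples_use_approximation(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        r = stats.mann_whitney_u(x, y)
        assert "approximation" in r.method

    def test_missing_values_dropped(self):
        r = stats.mann_whitney_u([1, 2, np.nan, 3], [4, 5, 6, np.nan])
        assert (r.n1, r.n2) == (3, 3)

    def test_empty_after_deletion_raises(self):
        with pytest.raises(InputError):
            stats.mann_whitney_u([np.nan], [1.0, 2.0])


class TestWilcoxon:
    def test_all_positive_differences_exact_p(self):
        before = [1.0, 2.0, 3.0, 4.0, 5.0]
        after = [2.0, 4.0, 3.5, 7.0, 5.3]
        r = stats.wilcoxon_signed_rank(before, after)
        assert r.statistic == 0
        assert r.p_value == pytest.approx(2 / 2 ** 5)
        assert r.method == "exact"

    def test_before_equals_after_degenerate(self):
        with pytest.warns(UserWarning, match="zero"):
            r = stats.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert r.p_value == 1.0

    def test_pairwise_deletion_bookkeeping(self, rng):
        before = rng.normal(size=10)
        after = before + rng.normal(0.3, 1.0, 10)
        before_missing = before.copy()
        before_missing[[1, 4, 7]] = np.nan
        r = stats.wilcoxon_signed_rank(before_missing, after)
        assert r.n_pairs == 7
        keep = np.isfinite(before_missing)
        direct = stats.wilcoxon_signed_rank(before[keep], after[keep])
        assert r.p_value == pytest.approx(direct.p_value, abs=1e-12)
        assert r.statistic == pytest.approx(direct.statistic)

    def test_matches_sign_flip_enumeration(self, rng):
        for n in (4, 6, 8, 10):
            d = rng.normal(0.4, 1.0, n)
            r = stats.wilcoxon_signed_rank(np.zeros(n), d)
            assert r.method == "exact"
            assert r.p_value == pytest.approx(brute_force_wilcoxon_p(d),
                                              abs=1e-12)

    def test_no_complete_pairs_raises(self):
        with pytest.raises(InputError):
            stats.wilcoxon_signed_rank([np.nan, np.nan], [1.0, 2.0])


class TestSpearman:
    def _table(self, columns: dict) -> io.CohortTable:
        records = []
        n = len(next(iter(columns.values())))
        for i in range(n):
            for param, vals in columns.items():
                records.append(dict(
                    subject_id=f"s{i:02d}", group="therapy",
                    timepoint="baseline", parameter=param,
                    value=vals[i], units=""))
        return io.CohortTable.from_records(records)

    def test_perfect_monotone_pairs(self):
        x = np.arange(10.0)
        table = self._table({"a": x, "b": np.exp(x), "c": -x ** 3})
        cm = stats.spearman_matrix(table)
        i, j, k = (cm.parameters.index(p) for p in ("a", "b", "c"))
        assert cm.rho[i, j] == pytest.approx(1.0)
        assert cm.rho[i, k] == pytest.approx(-1.0)

    def test_matches_rank_formula_on_tie_free_data(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        table = self._table({"a": x, "b": y})
        cm = stats.spearman_matrix(table)
        rx = np.argsort(np.argsort(x))
        ry = np.argsort(np.argsort(y))
        d2 = np.sum((rx - ry) ** 2)
        n = 10
        expected = 1 - 6 * d2 / (n * (n ** 2 - 1))
        i, j = cm.parameters.index("a"), cm.parameters.index("b")
        assert cm.rho[i, j] == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        cm1 = stats.spearman_matrix(self._table({"a": x, "b": y}))
        cm2 = stats.spearman_matrix(
            self._table({"a": np.tanh(x), "b": y ** 3}))
        assert cm1.rho[0, 1] == pytest.approx(cm2.rho[0, 1], abs=1e-12)

    def test_constant_column_gives_nan(self):
        table = self._table({"a": np.arange(5.0), "b": np.ones(5)})
        cm = stats.spearman_matrix(table)
        i, j = cm.parameters.index("a"), cm.parameters.index("b")
        assert np.isnan(cm.rho[i, j])

    def test_pairwise_complete_counts(self):
        x = np.arange(8.0)
        y = x.copy()
        y[[0, 3]] = np.nan
        cm = stats.spearman_matrix(self._table({"a": x, "b": y}))
        i, j = cm.parameters.index("a"), cm.parameters.index("b")
        assert cm.n[i, j] == 6


class TestGroupSummary:
    def test_mean_and_sample_sd(self):
        records = [dict(subject_id=f"s{i}", group="therapy",
                        timepoint="baseline", parameter="ADC",
                        value=v, units="") for i, v in enumerate([1., 2., 3.])]
        table = io.CohortTable.from_records(records)
        s = stats.group_summary(table)
        row = s[(s.group == "therapy") & (s.timepoint == "baseline")].iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)
        assert row["n"] == 3

    def test_single_value_sd_nan(self):
        table = io.CohortTable.from_records([dict(
            subject_id="s0", group="control", timepoint="follow_up",
            parameter="PV", value=12.0, units="")])
        s = stats.group_summary(table)
        row = s[(s.group == "control") & (s.timepoint == "follow_up")].iloc[0]
        assert np.isnan(row["sd"]) and row["n"] == 1

    def test_synthetic_cohort_means_near_design(self, cohort_table):
        table, _ = cohort_table
        s = stats.group_summary(table)
        dist = simulate.DEFAULT_COHORT_DISTRIBUTIONS["ADC"]
        for group in ("therapy", "control"):
            mean, sd = dist[(group, "follow_up")]
            row = s[(s.parameter == "ADC") & (s.group == group)
                    & (s.timepoint == "follow_up")].iloc[0]
            se = sd / np.sqrt(row["n"])
            assert abs(row["mean"] - mean) < 2.5 * se


class TestStudyReport:
    def test_raw_p_only_no_adjustment_column(self, cohort_table):
        table, _ = cohort_table
        report = stats.run_study_statistics(table)
        assert "p_value" in report.columns
        assert not any("adjust" in c or "corrected" in c
                       for c in report.columns)

    def test_wilcoxon_n_pairs_equals_complete_pairs(self, cohort_table):
        table, truth = cohort_table
        row = stats.run_study_statistics(table)
        sel = row[(row.parameter == "ADC")
                  & (row.comparison == "baseline_vs_follow_up@therapy")]
        n_missing = sum(1 for s, m in truth["missing_baseline"].items()
                        if m and s.startswith("therapy"))
        assert int(sel.iloc[0]["n1"]) == 14 - n_missing
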