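"""Exact-test oracles, aggregation coverage, and resource-table parsing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hrrbench.compare_stats import (
    TestMethod,
    aggregate_metrics,
    benjamini_hochberg,
    parse_realtime,
    parse_vmem,
    pp_curve,
    summarize_resources,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation under test)


def signed_rank_oracle(x, y):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    p_le = (ws <= w_obs + 1e-9).mean()
    p_ge = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2 * min(p_le, p_ge))


def rank_sum_oracle(a, b):
    """Two-sided exact p by enumerating all C(na+nb, na) labelings."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na = a.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    us = []
    for comb in itertools.combinations(range(pooled.size), na):
        us.append(ranks[list(comb)].sum() - na * (na + 1) / 2)
    us = np.asarray(us)
    p_le = (us <= u_obs + 1e-9).mean()
    p_ge = (us >= u_obs - 1e-9).mean()
    return min(1.0, 2 * min(p_le, p_ge))


# ---------------------------------------------------------------------------


class TestAggregateMetrics:
    def _frame(self, values, titer=1):
        return pd.DataFrame(
            {
                "method_id": "m",
                "reference_id": "r",
                "human_titer": titer,
                "mcc": values,
            }
        )

    def test_identical_values_zero_width(self):
        agg = aggregate_metrics(self._frame([0.5, 0.5, 0.5]), ["mcc"])
        row = agg.iloc[0]
        assert row["sd"] == 0 and row["ci_low"] == row["ci_high"] == 0.5

    def test_two_point_symmetry(self):
        agg = aggregate_metrics(self._frame([0.0, 1.0]), ["mcc"])
        row = agg.iloc[0]
        assert row["mean"] == 0.5
        assert row["ci_high"] - 0.5 == pytest.approx(0.5 - row["ci_low"])

    def test_single_row_degenerate_flag(self):
        agg = aggregate_metrics(self._frame([0.7]), ["mcc"])
        assert bool(agg.iloc[0]["degenerate_ci"])

    def test_row_order_invariance(self, rng):
        df = pd.concat(
            [self._frame(rng.random(5), titer=t) for t in (1, 2, 3)], ignore_index=True
        )
        shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
        a = aggregate_metrics(df, ["mcc"]).reset_index(drop=True)
        b = aggregate_metrics(shuffled, ["mcc"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_t_interval_coverage_near_nominal(self, rng):
        """Empirical 95% CI coverage over 1,000 normal samples within ±2%."""
        n, hits = 8, 0
        for _ in range(1000):
            vals = rng.normal(0.0, 1.0, size=n)
            agg = aggregate_metrics(self._frame(vals), ["mcc"]).iloc[0]
            hits += agg["ci_low"] <= 0.0 <= agg["ci_high"]
        assert abs(hits / 1000 - 0.95) < 0.02


class TestSignedRank:
    def test_all_zero_differences(self):
        res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0 and "ALL_ZERO" in res.flags

    def test_n5_all_positive_two_sided(self):
        res = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 2, 3, 4, 5])
        assert res.method is TestMethod.EXACT
        assert res.p_value == pytest.approx(0.0625)

    def test_matches_enumeration_oracle_random(self, rng):
        """200 random small instances: exact p equals the 2^n enumeration."""
        for _ in range(200):
            n = int(rng.integers(1, 11))
            x = rng.normal(size=n)
            y = x + rng.normal(scale=0.8, size=n)
            # integer-ish values sometimes, to exercise ties and zeros
            if rng.random() < 0.5:
                x, y = np.round(x * 2) / 2, np.round(y * 2) / 2
            res = wilcoxon_signed_rank(x, y)
            assert res.p_value == pytest.approx(signed_rank_oracle(x, y), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 15))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = wilcoxon_signed_rank(x, y)
            ref = sps.wilcoxon(x, y, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approx_used_beyond_threshold(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        res = wilcoxon_signed_rank(x, y)
        assert res.method is TestMethod.NORMAL_APPROX
        ref = sps.wilcoxon(x, y, alternative="two-sided", method="approx", correction=True)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_type_one_error_calibration(self, rng):
        """Rejection rate under the paired null ≈ alpha (2,000 reps, ±0.015)."""
        rejects = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            if wilcoxon_signed_rank(x, y).p_value <= 0.05:
                rejects += 1
        # exact attainable size at n=12 is 174/4096 ≈ 0.0425 (discrete null)
        assert abs(rejects / reps - 0.0425) < 0.015


class TestRankSum:
    def test_identical_multisets(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_disjoint_samples_minimal_p(self):
        res = wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
        assert res.method is TestMethod.EXACT
        assert res.statistic == 0
        assert res.p_value == pytest.approx(0.1)  # 2/20 labelings

    def test_matches_enumeration_oracle_random(self, rng):
        for _ in range(200):
            na = int(rng.integers(2, 7))
            nb = int(rng.integers(2, 13 - na))
            a = rng.normal(size=na)
            b = rng.normal(loc=rng.normal(), size=nb)
            if rng.random() < 0.5:
                a, b = np.round(a), np.round(b)
            res = wilcoxon_rank_sum(a, b)
            assert res.p_value == pytest.approx(rank_sum_oracle(a, b), abs=1e-12)


class TestPPCurve:
    def test_identical_samples_on_diagonal(self, rng):
        x = rng.normal(size=200)
        pp = pp_curve(x, x)
        assert np.allclose(pp["x_quantile"], pp["y_quantile"])

    def test_constant_shift(self, rng):
        x = rng.normal(size=500)
        pp = pp_curve(x, x + 2.5)
        assert np.allclose(pp["y_quantile"] - pp["x_quantile"], 2.5)

    def test_matches_independent_quantiles(self, rng):
        x, y = rng.normal(size=300), rng.normal(size=400)
        pp = pp_curve(x, y, percentiles=[10, 50, 90])
        assert pp["x_quantile"].tolist() == list(np.percentile(x, [10, 50, 90]))
        assert pp["y_quantile"].tolist() == list(np.percentile(y, [10, 50, 90]))


class TestResources:
    def test_unit_parsing(self):
        assert parse_realtime("350ms") == pytest.approx(0.35)
        assert parse_realtime("1h 2m 3s") == 3723
        assert parse_realtime("6.42m") == pytest.approx(385.2)
        assert parse_vmem("1.2 GB") == pytest.approx(1200.0)
        assert parse_vmem("512 MB") == 512
        assert parse_vmem("100 KB") == pytest.approx(0.1)
        with pytest.raises(ValueError):
            parse_realtime("eleven")

    def test_summary_and_comparisons(self):
        rows = []
        for v in (1.0, 2.0, 3.0):
            rows.append({"method": "fast", "realtime": f"{v}s", "peak_vmem": "100 MB"})
        for v in (10.0, 11.0, 12.0):
            rows.append({"method": "slow", "realtime": f"{v}s", "peak_vmem": "4 GB"})
        rows.append({"method": "slow", "realtime": "junk", "peak_vmem": "4 GB"})
        res = summarize_resources(pd.DataFrame(rows))
        assert res.n_skipped == 1
        med = res.per_method.set_index(["method", "quantity"])["median"]
        assert med[("fast", "realtime_s")] == 2.0
        comp = res.comparisons.set_index("quantity").loc["realtime_s"]
        assert comp["p_value"] == pytest.approx(0.1)  # disjoint, exact minimal p

    def test_single_method_no_comparisons(self):
        df = pd.DataFrame([{"method": "only", "realtime": "1s", "peak_vmem": "1 MB"}])
        res = summarize_resources(df)
        assert len(res.comparisons) == 0

    def test_bh_adjustment_matches_statsmodels(self, rng):
        p = rng.random(20)
        from statsmodels.stats.multitest import multipletests

        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(benjamini_hochberg(p), ref)
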