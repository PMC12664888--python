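"""Aggregation and between-configuration statistics.

Per-titer metric aggregation uses a Student-t 95% confidence band (honest at
the benchmark's typical n of a few dozen cells). The nonparametric tests —
Wilcoxon signed-rank for paired method/reference comparisons and
Wilcoxon–Mann–Whitney rank-sum for unpaired resource comparisons — are
implemented from first principles with *exact* small-sample null
distributions, falling back to the tie-corrected, continuity-corrected
normal approximation for larger samples.

Exact signed-rank nulls are computed by convolving the rank generating
function Π(1 + z^{r_i}) over all 2^n sign assignments (ranks doubled so
mid-ranks from ties stay integral); exact rank-sum nulls enumerate all
C(n_a+n_b, n_a) group labelings. Two-sided p-values double the smaller tail
and cap at 1.

Resource tables use the common workflow-trace dialect (columns ``method``,
``realtime``, ``peak_vmem`` with unit suffixes such as ``ms``/``s``/``m`` and
``KB``/``MB``/``GB``).
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestMethod",
    "PairedTestResult",
    "aggregate_metrics",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "pp_curve",
    "summarize_resources",
    "benjamini_hochberg",
]

SIGNED_RANK_EXACT_MAX = 25
RANK_SUM_EXACT_MAX = 12


class TestMethod(Enum):
    EXACT = "EXACT"
    NORMAL_APPROX = "NORMAL_APPROX"


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    n_pairs_used: int
    method: TestMethod
    flags: FrozenSet[str] = frozenset()


# ---------------------------------------------------------------------------
# Aggregation


def aggregate_metrics(
    rows: pd.DataFrame,
    metrics: Sequence[str],
    group_cols: Sequence[str] = ("method_id", "reference_id", "human_titer"),
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Mean and t-based confidence band per group for each metric.

    95% CI = mean ± t_{0.975, n−1} · sd/√n. Groups with n == 1 get a
    zero-width band and ``degenerate_ci=True``. Output order is deterministic
    (sorted group keys), so aggregation is invariant to input row order.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    out = []
    for key, grp in rows.groupby(list(group_cols), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        for metric in metrics:
            vals = grp[metric].to_numpy(dtype=float)
            n = len(vals)
            mean = float(np.mean(vals))
            if n > 1:
                sd = float(np.std(vals, ddof=1))
                half = sps.t.ppf(0.5 + confidence / 2, n - 1) * sd / math.sqrt(n)
                degenerate = False
            else:
                sd, half, degenerate = 0.0, 0.0, True
            out.append(
                dict(zip(group_cols, key))
                | {
                    "metric": metric,
                    "mean": mean,
                    "sd": sd,
                    "n": n,
                    "ci_low": mean - half,
                    "ci_high": mean + half,
                    "degenerate_ci": degenerate,
                }
            )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _signed_rank_exact_sf(ranks2: np.ndarray, w2: float) -> Tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) under the exact null, ranks doubled to ints."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2i = int(round(w2))
    p_le = counts[: w2i + 1].sum()
    p_ge = counts[w2i:].sum()
    return float(p_le), float(p_ge)


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_threshold: int = SIGNED_RANK_EXACT_MAX,
    zero_method: str = "discard",
) -> PairedTestResult:
    """Paired Wilcoxon signed-rank test.

    Zero differences are discarded (classic Wilcoxon; ``zero_method="pratt"``
    keeps them in the ranking but never in the statistic); ties get average
    ranks. The statistic reported is W+ (sum of ranks of positive
    differences). Exact null by sign-assignment enumeration for usable
    n ≤ ``exact_threshold``; otherwise normal approximation with tie and
    continuity corrections. All differences zero → p = 1 with ALL_ZERO flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 1")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if zero_method not in ("discard", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")

    d = x - y
    if zero_method == "discard":
        d = d[d != 0]
        if d.size == 0:
            return PairedTestResult(0.0, 1.0, 0, TestMethod.EXACT, frozenset({"ALL_ZERO"}))
        ranks = sps.rankdata(np.abs(d))
    else:  # pratt: zeros ranked but dropped from the statistic
        if np.all(d == 0):
            return PairedTestResult(0.0, 1.0, 0, TestMethod.EXACT, frozenset({"ALL_ZERO"}))
        ranks_all = sps.rankdata(np.abs(d))
        keep = d != 0
        ranks = ranks_all[keep]
        d = d[keep]
    n = d.size
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_threshold and zero_method == "discard":
        p_le, p_ge = _signed_rank_exact_sf(2 * ranks, 2 * w_plus)
        method = TestMethod.EXACT
    else:
        mean = n * (n + 1) / 4
        tie_term = 0.0
        _, t_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((t_counts**3 - t_counts) / 48).sum())
        var = n * (n + 1) * (2 * n + 1) / 24 - tie_term
        sd = math.sqrt(var) if var > 0 else float("nan")
        # continuity correction toward the mean
        p_ge = float(sps.norm.sf((w_plus - 0.5 - mean) / sd)) if var > 0 else 1.0
        p_le = float(sps.norm.cdf((w_plus + 0.5 - mean) / sd)) if var > 0 else 1.0
        method = TestMethod.NORMAL_APPROX

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2 * min(p_le, p_ge))
    return PairedTestResult(w_plus, p, n, method)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann–Whitney U)


def wilcoxon_rank_sum(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
    exact_threshold: int = RANK_SUM_EXACT_MAX,
) -> PairedTestResult:
    """Unpaired Wilcoxon rank-sum test; statistic is U for sample ``a``.

    Exact null by enumeration of all C(n_a+n_b, n_a) labelings when
    n_a + n_b ≤ ``exact_threshold``; otherwise tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2)

    if na + nb <= exact_threshold:
        us = []
        idx_all = range(na + nb)
        for comb in itertools.combinations(idx_all, na):
            r = ranks[list(comb)].sum()
            us.append(r - na * (na + 1) / 2)
        us = np.asarray(us)
        p_le = float((us <= u_a + 1e-12).mean())
        p_ge = float((us >= u_a - 1e-12).mean())
        method = TestMethod.EXACT
    else:
        n = na + nb
        mean = na * nb / 2
        _, t_counts = np.unique(pooled, return_counts=True)
        tie = float((t_counts**3 - t_counts).sum())
        var = na * nb / 12 * ((n + 1) - tie / (n * (n - 1)))
        sd = math.sqrt(var) if var > 0 else float("nan")
        p_ge = float(sps.norm.sf((u_a - 0.5 - mean) / sd)) if var > 0 else 1.0
        p_le = float(sps.norm.cdf((u_a + 0.5 - mean) / sd)) if var > 0 else 1.0
        method = TestMethod.NORMAL_APPROX

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2 * min(p_le, p_ge))
    return PairedTestResult(u_a, p, na + nb, method)


# ---------------------------------------------------------------------------
# Percentile-percentile curve


def pp_curve(
    x: Sequence[float],
    y: Sequence[float],
    percentiles: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Quantiles of two distributions on a common percentile grid (default 1..99)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both distributions must be non-empty")
    if percentiles is None:
        percentiles = np.arange(1, 100)
    percentiles = np.asarray(percentiles, dtype=float)
    return pd.DataFrame(
        {
            "percentile": percentiles,
            "x_quantile": np.percentile(x, percentiles),
            "y_quantile": np.percentile(y, percentiles),
        }
    )


# ---------------------------------------------------------------------------
# Resource (runtime / memory) summaries


_TIME_UNITS = {"ms": 1e-3, "s": 1.0, "m": 60.0, "h": 3600.0, "d": 86400.0}
_MEM_UNITS = {"B": 1 / 1e6, "KB": 1e-3, "MB": 1.0, "GB": 1e3, "TB": 1e6}


def parse_realtime(value) -> float:
    """Trace realtime → seconds. Accepts numbers or strings like '1h 2m 3.5s', '350ms'."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if math.isnan(value):
            raise ValueError("NaN realtime")
        return float(value)
    text = str(value).strip()
    tokens = re.findall(r"([0-9]*\.?[0-9]+)\s*(ms|s|m|h|d)\b", text)
    if not tokens or not re.fullmatch(r"(?:[0-9]*\.?[0-9]+\s*(?:ms|s|m|h|d)\s*)+", text):
        raise ValueError(f"unparseable realtime {value!r}")
    return sum(float(num) * _TIME_UNITS[unit] for num, unit in tokens)


def parse_vmem(value) -> float:
    """Trace peak_vmem → megabytes. Accepts numbers (MB) or '1.2 GB', '512 MB', '100 KB'."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if math.isnan(value):
            raise ValueError("NaN vmem")
        return float(value)
    m = re.fullmatch(r"\s*([0-9]*\.?[0-9]+)\s*(B|KB|MB|GB|TB)\s*", str(value))
    if not m:
        raise ValueError(f"unparseable peak_vmem {value!r}")
    return float(m.group(1)) * _MEM_UNITS[m.group(2)]


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m, dtype=float)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank of this p-value
        running = min(running, p[idx] * m / i)
        adj[idx] = running
    return np.clip(adj, 0, 1)


@dataclass
class ResourceSummary:
    per_method: pd.DataFrame
    comparisons: pd.DataFrame
    n_skipped: int


def summarize_resources(
    trace_table: pd.DataFrame,
    method_col: str = "method",
    realtime_col: str = "realtime",
    vmem_col: str = "peak_vmem",
) -> ResourceSummary:
    """Per-method median/IQR of runtime and peak memory, with pairwise
    rank-sum comparisons (BH-adjusted). Malformed rows are skipped and
    counted."""
    rows = []
    skipped = 0
    for _, row in trace_table.iterrows():
        try:
            rows.append(
                {
                    "method": str(row[method_col]),
                    "realtime_s": parse_realtime(row[realtime_col]),
                    "peak_vmem_mb": parse_vmem(row[vmem_col]),
                }
            )
        except (ValueError, KeyError):
            skipped += 1
    clean = pd.DataFrame(rows, columns=["method", "realtime_s", "peak_vmem_mb"])

    summaries = []
    for method, grp in clean.groupby("method", sort=True):
        for col in ("realtime_s", "peak_vmem_mb"):
            v = grp[col].to_numpy()
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            summaries.append(
                {"method": method, "quantity": col, "median": med, "iqr_low": q1, "iqr_high": q3, "n": len(v)}
            )
    per_method = pd.DataFrame(
        summaries, columns=["method", "quantity", "median", "iqr_low", "iqr_high", "n"]
    )

    comp_rows = []
    methods = sorted(clean["method"].unique())
    for qty in ("realtime_s", "peak_vmem_mb"):
        for m1, m2 in itertools.combinations(methods, 2):
            res = wilcoxon_rank_sum(
                clean.loc[clean["method"] == m1, qty],
                clean.loc[clean["method"] == m2, qty],
            )
            comp_rows.append(
                {
                    "quantity": qty,
                    "method_a": m1,
                    "method_b": m2,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "test_method": res.method.value,
                }
            )
    comparisons = pd.DataFrame(
        comp_rows,
        columns=["quantity", "method_a", "method_b", "statistic", "p_value", "test_method"],
    )
    if len(comparisons):
        comparisons["p_adjusted"] = benjamini_hochberg(comparisons["p_value"])
    else:
        comparisons["p_adjusted"] = pd.Series(dtype=float)
    return ResourceSummary(per_method, comparisons, skipped)
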