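"""Statistical battery for the cohort of TDCH variables.

The analysis mirrors standard practice for bounded, skewed area proportions:

* normality screening per variable and group with the Lilliefors-corrected
  Kolmogorov–Smirnov test (mean and SD estimated from the sample; the null
  distribution of the statistic is obtained by seeded Monte Carlo and cached
  per sample size) and the Shapiro–Wilk test;
* group differences by the Mann–Whitney U test (mid-ranks, tie-corrected
  variance, continuity-corrected normal approximation; exact enumeration of
  all group assignments when n*m <= 64) when any group fails normality, or a
  two-sample t test when all pass;
* paired visit comparisons by a one-sample Student's t on the per-subject
  differences — algebraically identical to the "paired two-sample" t.

Lilliefors p values above 0.2 are reported as the lower bound "0.200" with a
flag, matching the convention of packaged significance tables.  No multiple-
testing correction is applied by default (seven raw p values are reported);
Bonferroni and Benjamini–Hochberg adjustments are available as options.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError, StatTestError

__all__ = [
    "TestResult",
    "lilliefors_ks",
    "shapiro_wilk",
    "mann_whitney",
    "paired_t",
    "group_compare",
    "format_table",
]

LILLIEFORS_BOUND = 0.2


@dataclass(frozen=True)
class TestResult:
    """One test's outcome plus the per-group summary used in report tables."""

    name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    summary: dict = field(default_factory=dict)
    p_lower_bound: bool = False  # True when p is reported as ">= bound"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise AnalysisError(f"p value outside [0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# normality


def _lilliefors_statistic(x: np.ndarray) -> float:
    m, s = x.mean(), x.std(ddof=1)
    if s == 0:
        raise StatTestError("constant sample: normality test undefined")
    z = np.sort((x - m) / s)
    cdf = sps.norm.cdf(z)
    n = len(z)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max((ecdf_hi - cdf).max(), (cdf - ecdf_lo).max()))


_NULL_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _lilliefors_null(n: int, n_mc: int) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of the statistic for size n.

    Seeded from (n, n_mc) only, so the null is deterministic and independent
    of the data; cached because it is reused across variables and replicates.
    """
    key = (n, n_mc)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(615243 + 7 * n + n_mc)
        sims = rng.standard_normal((n_mc, n))
        stats = np.empty(n_mc)
        for i in range(n_mc):
            stats[i] = _lilliefors_statistic(sims[i])
        _NULL_CACHE[key] = np.sort(stats)
    return _NULL_CACHE[key]


def lilliefors_ks(sample, n_mc: int = 10_000) -> TestResult:
    """Kolmogorov–Smirnov normality test with Lilliefors correction.

    The KS distance is computed against a normal with the sample's own mean
    and SD; the p value is the Monte-Carlo tail probability of that distance
    under a true normal of the same size.  p >= 0.2 is flagged as a lower
    bound of the true significance.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 4:
        raise StatTestError("Lilliefors test needs n >= 4")
    d = _lilliefors_statistic(x)
    null = _lilliefors_null(len(x), n_mc)
    p = float((null >= d).sum() + 1) / (len(null) + 1)
    lower = p >= LILLIEFORS_BOUND
    return TestResult(
        name="lilliefors_ks",
        statistic=d,
        p_value=min(p, 1.0) if not lower else LILLIEFORS_BOUND,
        n=(len(x),),
        p_lower_bound=lower,
    )


def shapiro_wilk(sample) -> TestResult:
    x = np.asarray(sample, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise StatTestError("Shapiro–Wilk test needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise StatTestError("constant sample: normality test undefined")
    w, p = sps.shapiro(x)
    return TestResult(name="shapiro_wilk", statistic=float(w), p_value=float(p), n=(len(x),))


# ---------------------------------------------------------------------------
# group comparison


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0)


def mann_whitney(x, y, method: str = "auto") -> TestResult:
    """Two-sided Mann–Whitney U test.

    ``method``: "exact" enumerates every C(n+m, n) assignment of the pooled
    values to the first group (valid under ties; feasible for small samples),
    "asymptotic" uses the tie-corrected, continuity-corrected normal
    approximation, and "auto" picks exact when n*m <= 64.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise StatTestError("both samples must be non-empty")
    u = _u_statistic(x, y)
    if method == "auto":
        method = "exact" if n * m <= 64 else "asymptotic"
    if method == "exact":
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        offset = n * (n + 1) / 2.0
        us = np.fromiter(
            (sum(c) - offset for c in combinations(ranks, n)), dtype=float
        )
        n_tot = len(us)
        p_le = float((us <= u + 1e-9).sum()) / n_tot
        p_ge = float((us >= u - 1e-9).sum()) / n_tot
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * m / 2.0
        pooled = np.concatenate([x, y])
        _, t_counts = np.unique(pooled, return_counts=True)
        N = n + m
        tie_term = ((t_counts**3 - t_counts).sum()) / (N * (N - 1))
        var = n * m / 12.0 * (N + 1 - tie_term)
        if var == 0:
            p = 1.0
        else:
            z = (abs(u - mean) - 0.5) / math.sqrt(var)
            p = 2.0 * sps.norm.sf(max(z, 0.0))
    summary = {
        "x": _median_iqr(x),
        "y": _median_iqr(y),
    }
    return TestResult(
        name="mann_whitney",
        statistic=u,
        p_value=min(float(p), 1.0),
        n=(n, m),
        summary=summary,
    )


def _median_iqr(x: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"median": float(med), "iqr": float(q3 - q1)}


def _mean_sd(x: np.ndarray) -> dict[str, float]:
    return {"mean": float(x.mean()), "sd": float(x.std(ddof=1))}


def paired_t(first, second) -> TestResult:
    """One-sample Student's t on the paired differences (second − first)."""
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape:
        raise StatTestError("paired samples must have equal length")
    if len(a) < 2:
        raise StatTestError("paired t needs n >= 2")
    d = b - a
    if np.ptp(d) == 0:
        raise StatTestError("zero-variance differences: t statistic undefined")
    t, p = sps.ttest_1samp(d, 0.0)
    return TestResult(
        name="paired_t",
        statistic=float(t),
        p_value=float(p),
        n=(len(d),),
        summary={"first": _mean_sd(a), "second": _mean_sd(b), "diff": _mean_sd(d)},
    )


def two_sample_t(x, y) -> TestResult:
    """Student's two-sample t (pooled variance), used on the normal route."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return TestResult(
        name="two_sample_t",
        statistic=float(t),
        p_value=float(p),
        n=(len(x), len(y)),
        summary={"x": _mean_sd(x), "y": _mean_sd(y)},
    )


# ---------------------------------------------------------------------------
# cohort-level comparison


def group_compare(
    cohort: pd.DataFrame,
    variables: list[str] | None = None,
    *,
    paired: bool = False,
    route_by_normality: bool = True,
    normality_alpha: float = 0.05,
    lilliefors_mc: int = 10_000,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Compare each variable between the two groups (or paired visits).

    For every variable both normality tests are run per group; when routing
    is enabled the comparison is Mann–Whitney if *any* group looks non-normal
    (either test p < ``normality_alpha``), else a t-based comparison.  Paired
    mode matches the two visits per subject and always uses the one-sample t
    on the differences; the normality block is still reported so the routing
    decision is visible.

    Returns a tidy DataFrame, one row per variable, with normality blocks and
    the comparison's statistic, p value and per-group summaries.  Variables
    that are constant in both groups are reported as test errors without
    aborting the rest.  ``adjust`` in {None, "bonferroni", "fdr_bh"} adds an
    adjusted-p column.
    """
    import re

    variables = variables or [c for c in cohort.columns if re.fullmatch(r"V\d+", c)]
    if paired:
        groups = _paired_groups(cohort)
    else:
        labels = sorted(cohort["group"].unique())
        if len(labels) != 2:
            raise AnalysisError(f"expected exactly two groups, found {labels}")
        groups = {lab: cohort[cohort["group"] == lab] for lab in labels}
    rows = []
    for var in variables:
        try:
            rows.append(
                _compare_one(
                    var, groups, paired, route_by_normality, normality_alpha,
                    lilliefors_mc,
                )
            )
        except StatTestError as exc:
            rows.append({"variable": var, "error": str(exc)})
    table = pd.DataFrame(rows)
    if adjust:
        table["p_adjusted"] = _adjust_p(table["p_value"].to_numpy(), adjust)
    return table


def _paired_groups(cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    if "visit" not in cohort:
        raise AnalysisError("paired mode needs a 'visit' column")
    first = cohort[cohort["visit"] == "first"].set_index("subject_id").sort_index()
    second = cohort[cohort["visit"] == "second"].set_index("subject_id").sort_index()
    common = first.index.intersection(second.index)
    if len(common) < 2:
        raise AnalysisError("paired mode needs >= 2 subjects with both visits")
    return {"first": first.loc[common], "second": second.loc[common]}


def _compare_one(
    var: str,
    groups: dict[str, pd.DataFrame],
    paired: bool,
    route: bool,
    alpha: float,
    lilliefors_mc: int,
) -> dict:
    (name_a, df_a), (name_b, df_b) = groups.items()
    xa = df_a[var].to_numpy(dtype=float)
    xb = df_b[var].to_numpy(dtype=float)
    if not paired:  # undefined values (e.g. an undefined VR) are dropped
        xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
    row: dict = {"variable": var}
    normal = True
    for gname, x in ((name_a, xa), (name_b, xb)):
        lil = lilliefors_ks(x, n_mc=lilliefors_mc)
        sw = shapiro_wilk(x)
        row[f"ks_stat_{gname}"] = lil.statistic
        row[f"ks_p_{gname}"] = lil.p_value
        row[f"ks_p_lower_bound_{gname}"] = lil.p_lower_bound
        row[f"sw_stat_{gname}"] = sw.statistic
        row[f"sw_p_{gname}"] = sw.p_value
        if min(lil.p_value, sw.p_value) < alpha:
            normal = False
    use_parametric = normal if route else False
    if paired:
        res = paired_t(xa, xb)
    elif use_parametric:
        res = two_sample_t(xa, xb)
    else:
        res = mann_whitney(xa, xb)
    row["test"] = res.name
    row["statistic"] = res.statistic
    row["p_value"] = res.p_value
    for gname, x in ((name_a, xa), (name_b, xb)):
        if res.name in ("paired_t", "two_sample_t"):
            s = _mean_sd(x)
            row[f"center_{gname}"], row[f"spread_{gname}"] = s["mean"], s["sd"]
        else:
            s = _median_iqr(x)
            row[f"center_{gname}"], row[f"spread_{gname}"] = s["median"], s["iqr"]
    row["n_" + name_a], row["n_" + name_b] = len(xa), len(xb)
    return row


def _adjust_p(p: np.ndarray, method: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if method == "fdr_bh":
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise AnalysisError(f"unknown adjustment {method!r}")


def format_table(table: pd.DataFrame) -> str:
    """Human-readable report: 'center (spread)' per group plus the p value."""
    lines = []
    group_cols = [c.removeprefix("center_") for c in table.columns if c.startswith("center_")]
    header = ["Variable"] + [f"{g} center (spread)" for g in group_cols] + ["Test", "P value"]
    lines.append("\t".join(header))
    for _, row in table.iterrows():
        if "error" in row and isinstance(row.get("error"), str) and row.get("error"):
            lines.append(f"{row['variable']}\t[test error: {row['error']}]")
            continue
        cells = [str(row["variable"])]
        for g in group_cols:
            cells.append(f"{row[f'center_{g}']:.3f} ({row[f'spread_{g}']:.3f})")
        cells.append(str(row["test"]))
        cells.append(f"{row['p_value']:.3f}")
        lines.append("\t".join(cells))
    return "\n".join(lines)
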