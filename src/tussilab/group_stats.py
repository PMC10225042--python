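"""Descriptive statistics and nonparametric group comparisons.

The comparison layer mirrors the study design: per-feature medians,
quartiles, extrema and percentile-bootstrap 95% confidence intervals for the
medians, with a two-sided Wilcoxon signed-rank test for paired contrasts
(same subjects produce both maneuvers) and a two-sided Mann-Whitney U test
for independent contrasts.  Tests run at the token level; p-values are
reported raw (no multiple-testing correction) and flagged at alpha = 0.05.

Exact p-values are computed by enumerating the permutation distribution for
small samples — including mid-ranked ties, via the shift (characteristic
polynomial) algorithm on doubled ranks — and by a normal approximation with
tie and continuity corrections otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

DEFAULT_BOOTSTRAP_B = 2000
DEFAULT_ALPHA = 0.05
WILCOXON_EXACT_MAX_N = 25
MANN_WHITNEY_EXACT_MAX_N = 20


@dataclass(frozen=True)
class FeatureDescriptives:
    """Five-number summary plus a bootstrap CI for the median."""

    q1: float
    median: float
    q3: float
    minimum: float
    maximum: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ComparisonResult:
    feature: str
    test: str                  # "wilcoxon" | "mann_whitney"
    statistic: float
    p_value: float
    n1: int
    n2: int
    significant: bool


@dataclass(frozen=True)
class Contrast:
    """A two-level group contrast over a cohort column.

    ``paired`` selects the Wilcoxon signed-rank test with tokens matched on
    ``pair_keys``; otherwise the Mann-Whitney U test is used.
    """

    column: str
    level_a: str
    level_b: str
    paired: bool
    pair_keys: tuple[str, ...] = ("subject", "token")


def descriptives(
    values,
    n_boot: int = DEFAULT_BOOTSTRAP_B,
    seed: int | np.random.Generator = 0,
) -> FeatureDescriptives:
    """Quartiles (linear interpolation), extrema, and a percentile-bootstrap
    95% CI of the median over ``n_boot`` seeded resamples."""
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("descriptives of an empty sample")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    boot_idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boot_medians = np.median(x[boot_idx], axis=1)
    ci_low, ci_high = np.percentile(boot_medians, [2.5, 97.5])
    return FeatureDescriptives(
        q1=float(q1), median=float(med), q3=float(q3),
        minimum=float(x.min()), maximum=float(x.max()),
        ci_low=float(ci_low), ci_high=float(ci_high),
    )


def _two_sided_from_counts(counts: np.ndarray, stat_doubled: int) -> float:
    """Two-sided p from an exact discrete null distribution.

    ``counts[s]`` holds the multiplicity of statistic value s (doubled to
    keep mid-ranks integral).  p = 2 * min(P(S <= s), P(S >= s)), capped at 1;
    the observed point mass belongs to both tails.
    """
    total = counts.sum()
    lo = counts[: stat_doubled + 1].sum() / total
    hi = counts[stat_doubled:].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def _signed_rank_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Distribution of the doubled positive-rank sum over all sign patterns."""
    counts = np.zeros(int(doubled_ranks.sum()) + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    x,
    y,
    feature: str = "",
    alpha: float = DEFAULT_ALPHA,
    exact_max_n: int = WILCOXON_EXACT_MAX_N,
) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; tied absolute differences receive
    mid-ranks.  For n <= ``exact_max_n`` retained pairs the p-value is exact
    over all 2^n sign assignments (shift algorithm); beyond that a normal
    approximation with tie and continuity corrections is used.  The reported
    statistic is W+, the positive-rank sum.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("degenerate pairing: all differences are zero")
    ranks = sstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        doubled = np.rint(2.0 * ranks).astype(np.int64)
        counts = _signed_rank_counts(doubled)
        p = _two_sided_from_counts(counts, int(round(2.0 * w_plus)))
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_counts**3 - tie_counts, dtype=np.float64) / 48.0
        dev = w_plus - mean
        z = (dev - 0.5 * np.sign(dev)) / math.sqrt(var)
        p = float(2.0 * sstats.norm.sf(abs(z)))
        p = min(1.0, p)
    return ComparisonResult(
        feature=feature, test="wilcoxon", statistic=w_plus, p_value=p,
        n1=n, n2=n, significant=p < alpha,
    )


def _rank_sum_counts(n1: int, n: int) -> np.ndarray:
    """Number of n1-subsets of ranks 1..n attaining each rank sum."""
    max_sum = n1 * n - n1 * (n1 - 1) // 2
    # dp[k, s] = number of k-subsets of {1..j} with sum s, built over j
    dp = np.zeros((n1 + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for j in range(1, n + 1):
        for k in range(min(j, n1), 0, -1):
            dp[k, j:] += dp[k - 1, :-j] if j else dp[k - 1]
    return dp[n1]


def mann_whitney_u(
    x,
    y,
    feature: str = "",
    alpha: float = DEFAULT_ALPHA,
    exact_max_n: int = MANN_WHITNEY_EXACT_MAX_N,
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test for independent samples.

    U = #{(i,j): x_i > y_j} + 0.5 #{x_i = y_j}.  Exact enumeration over all
    C(n1+n2, n1) group labelings when n1 + n2 <= ``exact_max_n`` and the
    pooled data are tie-free; otherwise a normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sstats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    n = n1 + n2
    if n <= exact_max_n and not has_ties:
        counts = _rank_sum_counts(n1, n)
        # rank sums are integers here; U and R1 differ by a constant
        p = _two_sided_from_counts_int(counts, int(round(r1)))
    else:
        mean = n1 * n2 / 2.0
        tie_term = np.sum(tie_counts**3 - tie_counts, dtype=np.float64)
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0  # all pooled values identical
        else:
            dev = u - mean
            z = (dev - 0.5 * np.sign(dev)) / math.sqrt(var)
            p = min(1.0, float(2.0 * sstats.norm.sf(abs(z))))
    return ComparisonResult(
        feature=feature, test="mann_whitney", statistic=float(u), p_value=p,
        n1=n1, n2=n2, significant=p < alpha,
    )


def _two_sided_from_counts_int(counts: np.ndarray, stat: int) -> float:
    total = counts.sum()
    lo = counts[: stat + 1].sum() / total
    hi = counts[stat:].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def compare_groups(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    contrast: Contrast,
    feature_cols=None,
    alpha: float = DEFAULT_ALPHA,
) -> list[ComparisonResult]:
    """Run the contrast's rank test on every feature column.

    ``features`` must carry a ``file_id`` column joining it to the cohort
    table.  For a paired contrast, tokens are matched on
    ``contrast.pair_keys``; unmatched keys raise an error listing the
    orphans.  A feature that is constant across both groups yields p = 1
    (documented degenerate behavior) rather than an error.
    """
    merged = features.merge(cohort, on="file_id", validate="one_to_one")
    levels = (contrast.level_a, contrast.level_b)
    present = set(merged[contrast.column])
    missing = [lv for lv in levels if lv not in present]
    if missing:
        raise ValueError(f"contrast level(s) {missing} absent from column "
                         f"{contrast.column!r}")
    if feature_cols is None:
        feature_cols = [c for c in features.columns
                        if c != "file_id" and np.issubdtype(features[c].dtype, np.number)]
    ga = merged[merged[contrast.column] == contrast.level_a]
    gb = merged[merged[contrast.column] == contrast.level_b]

    if contrast.paired:
        keys = list(contrast.pair_keys)
        ia = ga.set_index(keys)
        ib = gb.set_index(keys)
        orphans = ia.index.symmetric_difference(ib.index)
        if len(orphans):
            raise ValueError(f"unmatched pairing keys: {list(orphans)}")
        ib = ib.loc[ia.index]

    results = []
    for col in feature_cols:
        if contrast.paired:
            a = ia[col].to_numpy(dtype=np.float64)
            b = ib[col].to_numpy(dtype=np.float64)
            if np.all(a == b):
                results.append(ComparisonResult(
                    feature=col, test="wilcoxon", statistic=math.nan,
                    p_value=1.0, n1=a.size, n2=b.size, significant=False))
                continue
            res = wilcoxon_signed_rank(a, b, feature=col, alpha=alpha)
        else:
            a = ga[col].to_numpy(dtype=np.float64)
            b = gb[col].to_numpy(dtype=np.float64)
            res = mann_whitney_u(a, b, feature=col, alpha=alpha)
        results.append(res)
    return results


def descriptives_table(
    features: pd.DataFrame,
    feature_cols=None,
    n_boot: int = DEFAULT_BOOTSTRAP_B,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature descriptives in the reporting layout (Q1/Med/Q3/Min/Max/CI)."""
    if feature_cols is None:
        feature_cols = [c for c in features.columns
                        if c != "file_id" and np.issubdtype(features[c].dtype, np.number)]
    rng = np.random.default_rng(seed)
    rows = []
    for col in feature_cols:
        d = descriptives(features[col].dropna().to_numpy(), n_boot=n_boot, seed=rng)
        rows.append({
            "feature": col, "q1": d.q1, "median": d.median, "q3": d.q3,
            "min": d.minimum, "max": d.maximum,
            "median_ci_low": d.ci_low, "median_ci_high": d.ci_high,
        })
    return pd.DataFrame(rows)
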