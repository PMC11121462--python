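"""Statistical reporting surface: descriptive summaries, one-way ANOVA,
Tukey(-Kramer) compact letter displays, Kruskal-Wallis, and the Pearson
correlation matrix with significance stars.

Conventions (matching the descriptive tables this module reproduces):

* sample SD with the n-1 denominator; the 95 % CI is the two-sided
  t-interval mean +/- t(0.975, n-1) * sd / sqrt(n);
* quantiles by linear interpolation between order statistics (the common
  "type 7" spreadsheet rule);
* correlation stars at raw p < 0.05 / 0.01 / 0.001 with no multiplicity
  adjustment;
* Tukey pairwise p-values from the studentized-range distribution with the
  Tukey-Kramer unequal-n standard error; letters by insert-and-absorb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .data_model import PARAMETERS, SampleTable

__all__ = [
    "DescriptiveSummary",
    "TestResult",
    "LetterDisplay",
    "CorrelationMatrix",
    "describe",
    "ci_mean",
    "oneway_anova",
    "tukey_hsd",
    "kruskal_wallis",
    "pearson_matrix",
    "significance_stars",
]


@dataclass(frozen=True)
class DescriptiveSummary:
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    var: float
    min: float
    max: float
    q25: float
    median: float
    q75: float
    ci_defined: bool = True


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple[float, ...] | None
    p_value: float
    method: str
    degenerate: bool = False


@dataclass(frozen=True)
class LetterDisplay:
    """Compact letter display: groups sharing a letter are indistinguishable
    at level alpha under the Tukey-adjusted pairwise tests."""

    letters: tuple[str, ...]
    pairwise_p: dict[tuple[int, int], float]
    alpha: float


@dataclass(frozen=True)
class CorrelationMatrix:
    parameters: tuple[str, ...]
    r: np.ndarray
    p: np.ndarray
    stars: tuple[tuple[str, ...], ...]
    n: int


def describe(values: Sequence[float], level: float = 0.95) -> DescriptiveSummary:
    """Descriptive summary with a two-sided t confidence interval.

    For n == 1 the CI is undefined and flagged (``ci_defined=False`` with
    the mean in both bounds).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("describe requires at least one value")
    n = int(x.size)
    mean = float(np.mean(x))
    if n >= 2:
        sd = float(np.std(x, ddof=1))
        lo, hi = ci_mean(mean, sd, n, level)
        ci_defined = True
    else:
        sd = 0.0
        lo = hi = mean
        ci_defined = False
    q25, med, q75 = np.quantile(x, [0.25, 0.5, 0.75])  # linear interpolation
    return DescriptiveSummary(
        n=n,
        mean=mean,
        sd=sd,
        ci_low=lo,
        ci_high=hi,
        var=sd**2,
        min=float(np.min(x)),
        max=float(np.max(x)),
        q25=float(q25),
        median=float(med),
        q75=float(q75),
        ci_defined=ci_defined,
    )


def ci_mean(mean: float, sd: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Closed-form t-interval for a mean from (mean, sd, n)."""
    if n < 2:
        raise ValueError("CI requires n >= 2")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    t = sps.t.ppf(1 - (1 - level) / 2, n - 1)
    half = t * sd / np.sqrt(n)
    return float(mean - half), float(mean + half)


def _as_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in gs):
        raise ValueError("every group needs at least one value")
    return gs


def oneway_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Classical one-way fixed-effects ANOVA; df = (k-1, N-k).

    If every value in every group is identical the decomposition is empty
    and the result is F = 0, p = 1 (flagged degenerate).
    """
    gs = _as_groups(groups)
    if not any(g.size >= 2 for g in gs):
        raise ValueError("at least one group needs n >= 2")
    k = len(gs)
    n_total = sum(g.size for g in gs)
    df = (k - 1, n_total - k)
    allv = np.concatenate(gs)
    if np.ptp(allv) == 0:
        return TestResult(0.0, df, 1.0, "oneway-anova", degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*gs)
    if not np.isfinite(f):  # zero within-group variance
        return TestResult(float("inf"), df, 0.0, "oneway-anova", degenerate=True)
    return TestResult(float(f), df, float(p), "oneway-anova")


def _tukey_pairwise(gs: list[np.ndarray]) -> tuple[dict[tuple[int, int], float], float, float]:
    k = len(gs)
    n_total = sum(g.size for g in gs)
    dfw = n_total - k
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs)
    if dfw <= 0 or ssw <= 0:
        raise ValueError("Tukey HSD needs positive pooled within-group variance")
    msw = ssw / dfw
    pvals: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(k), 2):
        se = np.sqrt(msw / 2 * (1 / gs[i].size + 1 / gs[j].size))  # Tukey-Kramer
        q = abs(gs[i].mean() - gs[j].mean()) / se
        pvals[(i, j)] = float(sps.studentized_range.sf(q, k, dfw))
    return pvals, msw, dfw


def _compact_letters(k: int, significant: set[tuple[int, int]]) -> tuple[str, ...]:
    """Insert-and-absorb compact letter display.

    Columns start as one all-group set; each significant pair splits every
    column containing both members; columns that become subsets of another
    are absorbed.  Deterministic in input order.
    """
    columns: list[set[int]] = [set(range(k))]
    for i, j in sorted(significant):
        new_cols: list[set[int]] = []
        for col in columns:
            if i in col and j in col:
                new_cols.append(col - {i})
                new_cols.append(col - {j})
            else:
                new_cols.append(col)
        # absorb duplicates / subsets, preserving first-seen order
        absorbed: list[set[int]] = []
        for col in new_cols:
            if any(col <= other for other in absorbed):
                continue
            absorbed = [o for o in absorbed if not (o < col)] + [col]
        columns = absorbed
    # letters in order of each column's smallest member for stable output
    columns.sort(key=lambda c: min(c) if c else k)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for ci, col in enumerate(columns):
        for g in sorted(col):
            letters[g] += alphabet[ci % len(alphabet)]
    return tuple(letters)


def tukey_hsd(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> LetterDisplay:
    """Tukey(-Kramer) pairwise comparisons summarized as compact letters.

    Two groups share a letter iff their adjusted p >= alpha; every group
    receives at least one letter.
    """
    gs = _as_groups(groups)
    pvals, _, _ = _tukey_pairwise(gs)
    significant = {pair for pair, p in pvals.items() if p < alpha}
    letters = _compact_letters(len(gs), significant)
    return LetterDisplay(letters=letters, pairwise_p=pvals, alpha=alpha)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Rank-based k-group test with tie correction, chi-square reference.

    All-tied input leaves H undefined; the result is flagged degenerate
    with H = 0, p = 1.
    """
    gs = _as_groups(groups)
    n_total = sum(g.size for g in gs)
    if n_total < 3:
        raise ValueError("Kruskal-Wallis needs N >= 3")
    df = (len(gs) - 1,)
    allv = np.concatenate(gs)
    if np.ptp(allv) == 0:
        return TestResult(0.0, df, 1.0, "kruskal-wallis", degenerate=True)
    h, p = sps.kruskal(*gs)
    return TestResult(float(h), df, float(p), "kruskal-wallis")


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_matrix(
    table: SampleTable, parameters: Sequence[str] = PARAMETERS
) -> CorrelationMatrix:
    """Pairwise Pearson matrix over the measurement columns.

    Two-sided p-values from the exact t transform; stars at raw 0.05 / 0.01
    / 0.001 thresholds.  A zero-variance column leaves its pairs undefined
    (r = NaN, no star).
    """
    if len(table) < 3:
        raise ValueError("correlation matrix needs at least 3 records")
    cols = {p: np.asarray(table.values(p), dtype=float) for p in parameters}
    k = len(parameters)
    r = np.eye(k)
    pm = np.zeros((k, k))
    stars = [["" for _ in range(k)] for _ in range(k)]
    for i, j in combinations(range(k), 2):
        x, y = cols[parameters[i]], cols[parameters[j]]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r[i, j] = r[j, i] = np.nan
            pm[i, j] = pm[j, i] = np.nan
            continue
        rr, pp = sps.pearsonr(x, y)
        r[i, j] = r[j, i] = float(rr)
        pm[i, j] = pm[j, i] = float(pp)
        stars[i][j] = stars[j][i] = significance_stars(float(pp))
    return CorrelationMatrix(
        parameters=tuple(parameters),
        r=r,
        p=pm,
        stars=tuple(tuple(row) for row in stars),
        n=len(table),
    )
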