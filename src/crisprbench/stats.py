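"""Comparison statistics for per-site editing results.

Sites are grouped by the expression level of the targeted gene (FPKM < 25 vs
>= 25, the threshold that splits the benchmark loci into two roughly equal
groups), optionally filtered to each enzyme's optimal spacer-length window,
and compared with two-sample tests: the Wilcoxon rank-sum test (exact,
tie-aware permutation null for small samples; normal approximation with tie
correction otherwise), Welch's or paired t-test, and the two-sample
Kolmogorov-Smirnov test. Raw p-values are reported by default;
Benjamini-Hochberg adjustment is available as a helper.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .nucleases import get_profile

__all__ = [
    "SiteResult",
    "TestResult",
    "DegenerateInputError",
    "split_by_expression",
    "filter_optimal_lengths",
    "compare_groups",
    "exact_rank_sum",
    "adjust_pvalues",
]

EXPRESSION_THRESHOLD_FPKM = 25.0


class DegenerateInputError(ValueError):
    """Both groups have zero variance; the test statistic is undefined."""


@dataclass(frozen=True)
class SiteResult:
    """One editing measurement at one site with user-supplied metadata."""

    site_id: str
    nuclease: str
    spacer_len: int
    fpkm: float | None
    editing_pct: float
    assay: str = "deep_seq"

    def __post_init__(self) -> None:
        if not (0.0 <= self.editing_pct <= 100.0):
            raise ValueError("editing_pct must lie in [0, 100]")
        if self.fpkm is not None and self.fpkm < 0:
            raise ValueError("fpkm must be >= 0")
        if self.assay not in ("deep_seq", "t7e1", "rflp"):
            raise ValueError(f"unknown assay {self.assay!r}")


def split_by_expression(
    results: Sequence[SiteResult], threshold: float = EXPRESSION_THRESHOLD_FPKM
) -> tuple[list[SiteResult], list[SiteResult]]:
    """Partition sites into (low, high) expression groups at the FPKM threshold.

    Strict ``fpkm < threshold`` goes low, ``>= threshold`` goes high. Sites
    missing an FPKM value are excluded with a warning carrying the count.
    """
    low, high, missing = [], [], 0
    for r in results:
        if r.fpkm is None or (isinstance(r.fpkm, float) and math.isnan(r.fpkm)):
            missing += 1
        elif r.fpkm < threshold:
            low.append(r)
        else:
            high.append(r)
    if missing:
        warnings.warn(f"excluded {missing} site(s) with missing FPKM", stacklevel=2)
    return low, high


def filter_optimal_lengths(
    results: Sequence[SiteResult], nuclease: str
) -> list[SiteResult]:
    """Sites whose spacer length lies in the enzyme's optimal window
    (SpCas9 17-22 nt inclusive; SaCas9 >= 21 nt; NmCas9, AsCpf1, LbCpf1 >= 19 nt)."""
    lo, hi = get_profile(nuclease).optimal_spacer_range
    return [r for r in results if lo <= r.spacer_len <= hi]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    test: str
    method: str


def exact_rank_sum(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Exact two-sided rank-sum test by exhaustive permutation enumeration.

    The statistic is the midrank sum W of sample ``a`` over the pooled data;
    the null enumerates all C(n, n_a) assignments of the pooled midranks, so
    ties are handled exactly. Two-sided p-value:
    P(|W - E[W]| >= |w_obs - E[W]|).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, n = len(a), len(a) + len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    w_obs = ranks[:na].sum()
    ew = na * (n + 1) / 2.0
    dev = abs(w_obs - ew)
    total = math.comb(n, na)
    hits = 0
    for idx in combinations(range(n), na):
        w = ranks[list(idx)].sum()
        if abs(w - ew) >= dev - 1e-12:
            hits += 1
    return TestResult(float(w_obs), hits / total, "wilcoxon_rank_sum", "exact_permutation")


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    test: str = "wilcoxon_rank_sum",
    paired: bool = False,
    exact_max_n: int = 20,
) -> TestResult:
    """Two-sample comparison; two-sided p-values throughout.

    ``wilcoxon_rank_sum``: exact permutation null for combined n <=
    ``exact_max_n``, otherwise the normal approximation with tie correction
    (paired variant: signed-rank test). ``t_test``: Welch by default, paired
    on request. ``ks_test``: two-sample Kolmogorov-Smirnov.
    """
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    min_n = 3 if test == "t_test" else 2
    if len(a) < min_n or len(b) < min_n:
        raise ValueError(f"each group needs n >= {min_n} for {test}")
    if paired and len(a) != len(b):
        raise ValueError("paired comparison requires equal-length groups")

    if test == "wilcoxon_rank_sum":
        if paired:
            res = sps.wilcoxon(a, b)
            return TestResult(float(res.statistic), float(res.pvalue), test, "signed_rank")
        if len(a) + len(b) <= exact_max_n:
            return exact_rank_sum(a, b)
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return TestResult(float(res.statistic), float(res.pvalue), test, "normal_approx_tie_corrected")
    if test == "t_test":
        if np.var(a) == 0 and np.var(b) == 0:
            raise DegenerateInputError("both groups have zero variance")
        if paired:
            res = sps.ttest_rel(a, b)
            return TestResult(float(res.statistic), float(res.pvalue), test, "paired")
        res = sps.ttest_ind(a, b, equal_var=False)
        return TestResult(float(res.statistic), float(res.pvalue), test, "welch")
    if test == "ks_test":
        res = sps.ks_2samp(a, b)
        return TestResult(float(res.statistic), float(res.pvalue), test, "two_sample_ks")
    raise ValueError(f"unknown test {test!r}")


def adjust_pvalues(pvalues: Iterable[float], method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini-Hochberg by default)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(list(pvalues), method=method)[1]
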