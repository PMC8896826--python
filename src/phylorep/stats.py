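"""Rank-based two-sample statistics and the representativeness check.

The subsampling pipeline is validated by comparing the distribution of
patristic distances from the focal (host) ortholog in the selected subset
against the same distances in the full ortholog set, with a two-sided
Wilcoxon rank-sum (Mann-Whitney) test.  A large p-value means the selected
subset is statistically indistinguishable from the full set in its distance
distribution, i.e. representative.

The rank-sum test here is self-contained because the exact variant must
enumerate the permutation distribution over the observed pooled multiset
(mid-ranks under ties), and the asymptotic variant needs the tie-corrected
variance and optional continuity correction spelled out explicitly:

    sigma^2 = (n1 n2 / 12) * [ (N + 1) - sum_t (t^3 - t) / (N (N - 1)) ]

with t running over tie-group sizes and N = n1 + n2.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tree import PatristicMatrix, distances_from

__all__ = [
    "RankTestResult",
    "KruskalResult",
    "RepresentativenessReport",
    "rank_sum_test",
    "kruskal_wallis",
    "representativeness_report",
]

EXACT_SIZE_LIMIT = 25  # largest pooled sample for exact enumeration


@dataclass
class RankTestResult:
    u: float  # Mann-Whitney U of the first sample
    w: float  # rank-sum of the first sample
    z: float | None  # normal-approximation z (None for exact)
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    n1: int
    n2: int
    tie_group_sizes: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "U": self.u,
            "W": self.w,
            "z": self.z,
            "p_two_sided": self.p_two_sided,
            "method": self.method,
            "n1": self.n1,
            "n2": self.n2,
        }


@dataclass
class KruskalResult:
    h: float
    df: int
    p: float
    n_groups: int
    n_total: int


def _check_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise ValueError(f"sample {name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"sample {name} contains non-finite values")
    return arr


def rank_sum_test(
    x,
    y,
    alternative: str = "two_sided",
    method: str = "auto",
    continuity: bool = True,
) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney test.

    ``method`` is ``auto`` (exact when n1+n2 <= 25, else normal), ``exact``
    or ``normal``.  The exact p enumerates the permutation distribution of
    the rank-sum over the observed pooled multiset; ties are handled with
    mid-ranks in both variants.
    """
    if alternative != "two_sided":
        raise ValueError("only the two-sided alternative is supported")
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    x = _check_sample(x, "x")
    y = _check_sample(y, "y")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # mid-ranks
    w = float(ranks[:n1].sum())
    u = w - n1 * (n1 + 1) / 2.0
    ties = tuple(sorted(Counter(pooled.tolist()).values(), reverse=True))

    use_exact = method == "exact" or (method == "auto" and n1 + n2 <= EXACT_SIZE_LIMIT)
    if use_exact:
        p = _exact_two_sided_p(ranks, n1)
        return RankTestResult(u, w, None, p, "exact", n1, n2, ties)

    z, p = _normal_two_sided(u, n1, n2, ties, continuity)
    return RankTestResult(u, w, z, p, "normal_approx", n1, n2, ties)


def _exact_two_sided_p(ranks: np.ndarray, n1: int) -> float:
    """Exact two-sided p by dynamic programming over the pooled mid-ranks.

    Doubled mid-ranks are integers, so the distribution of the doubled
    rank-sum W2 of a uniformly random size-n1 subset is computed exactly
    with integer counts; the two-sided p doubles the smaller tail of the
    (symmetric) permutation distribution.
    """
    r2 = np.rint(ranks * 2).astype(np.int64)
    maxs = int(r2.sum())
    # dp[k, s] = number of size-k subsets with doubled rank-sum s
    dp = np.zeros((n1 + 1, maxs + 1), dtype=np.int64)
    dp[0, 0] = 1
    for val in r2:
        v = int(val)
        for k in range(n1, 0, -1):
            dp[k, v:] += dp[k - 1, : maxs + 1 - v]
    dist = dp[n1]
    n_total = int(dist.sum())
    w2_obs = int(np.rint(ranks[:n1].sum() * 2))
    lo = int(dist[: w2_obs + 1].sum())
    hi = int(dist[w2_obs:].sum())
    p = 2.0 * min(lo, hi) / n_total
    return min(1.0, p)


def _normal_two_sided(
    u: float, n1: int, n2: int, ties: tuple[int, ...], continuity: bool
) -> tuple[float, float]:
    n = n1 + n2
    tie_term = sum(t**3 - t for t in ties)
    var = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0, 1.0
    mu = n1 * n2 / 2.0
    diff = u - mu
    if continuity:
        diff = math.copysign(max(abs(diff) - 0.5, 0.0), diff) if diff != 0 else 0.0
    z = diff / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return z, p


def kruskal_wallis(groups) -> KruskalResult:
    """Kruskal-Wallis rank ANOVA with tie correction.

    H = 12 / (N (N+1)) * sum_c R_c^2 / n_c - 3 (N+1), divided by
    1 - sum_t (t^3 - t) / (N^3 - N); p from chi-square with (C-1) df.
    """
    arrays = [_check_sample(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for arr in arrays:
        r = ranks[start : start + len(arr)]
        h += r.sum() ** 2 / len(arr)
        start += len(arr)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = Counter(pooled.tolist())
    correction = 1.0 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    if correction <= 0:
        # all observations identical: no rank variation at all
        return KruskalResult(0.0, len(arrays) - 1, 1.0, len(arrays), n)
    h /= correction
    h = max(h, 0.0)
    df = len(arrays) - 1
    p = float(sps.chi2.sf(h, df))
    return KruskalResult(float(h), df, p, len(arrays), n)


@dataclass
class RepresentativenessReport:
    n_full: int
    n_selected: int
    test: RankTestResult
    quantiles_full: dict[str, float]
    quantiles_selected: dict[str, float]

    @property
    def p_two_sided(self) -> float:
        return self.test.p_two_sided

    def to_dict(self) -> dict:
        return {
            "n_full": self.n_full,
            "n_selected": self.n_selected,
            "p_two_sided": self.test.p_two_sided,
            "method": self.test.method,
            "quantiles_full": self.quantiles_full,
            "quantiles_selected": self.quantiles_selected,
        }


def _quantiles(values: np.ndarray) -> dict[str, float]:
    qs = np.quantile(values, [0.0, 0.25, 0.5, 0.75, 1.0])
    return dict(zip(["min", "q25", "median", "q75", "max"], map(float, qs)))


def representativeness_report(
    matrix: PatristicMatrix,
    focal: str,
    selected,
    method: str = "auto",
    continuity: bool = True,
) -> RepresentativenessReport:
    """Compare selected-subset vs full-set distances from the focal leaf.

    ``selected`` is a RepresentativeSet or an iterable of leaf labels.  The
    selected sample is a subset of the full sample (the focal leaf is
    excluded from both), mirroring how subset representativeness is
    conventionally assessed against the complete reference set.
    """
    labels = getattr(selected, "labels", None) or list(selected)
    full = distances_from(matrix, focal)
    sel_labels = [lab for lab in labels if lab != focal]
    if not sel_labels:
        raise ValueError("no selected leaves left after excluding the focal")
    missing = [lab for lab in sel_labels if lab not in full.index]
    if missing:
        raise KeyError(f"selected leaves not in matrix: {missing}")
    sel = full.loc[sel_labels]
    test = rank_sum_test(full.values, sel.values, method=method, continuity=continuity)
    return RepresentativenessReport(
        n_full=len(full),
        n_selected=len(sel),
        test=test,
        quantiles_full=_quantiles(full.values),
        quantiles_selected=_quantiles(sel.values),
    )
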