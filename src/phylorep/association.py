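"""Phenotype-phylogeny association via the correlation ratio.

The headline statistic is the correlation ratio eta between a categorical
outcome (did a heterologous ortholog complement the host knockout?) and a
continuous covariate (patristic distance of the ortholog from the host's
own sequence):

    eta^2 = sum_c n_c (mean_c - grand_mean)^2 / sum_i (y_i - grand_mean)^2

i.e. the between-group fraction of the total variance of the distances;
eta is its positive square root.  eta near 1 means outcome classes occupy
distinct distance ranges (strong phylogenetic signal in the phenotype);
eta near 0 means the outcome is unrelated to distance from the host.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import RankTestResult, rank_sum_test
from .tree import PatristicMatrix, distances_from

__all__ = [
    "EtaResult",
    "correlation_ratio",
    "outcome_distance_association",
    "trait_crosstab",
]

POSITIVE_TOKENS = ("+", "partial")
NEGATIVE_TOKENS = ("-",)
DROPPED_TOKENS = ("NT", "?", "detection_NT")


@dataclass
class EtaResult:
    eta: float
    eta_squared: float
    group_n: dict[str, int]
    group_means: dict[str, float]
    grand_mean: float
    ss_between: float
    ss_total: float

    def to_dict(self) -> dict:
        return {
            "eta": self.eta,
            "eta_squared": self.eta_squared,
            "group_n": self.group_n,
            "group_means": self.group_means,
            "grand_mean": self.grand_mean,
        }


def correlation_ratio(labels, values) -> EtaResult:
    """Correlation ratio eta of ``values`` across categories in ``labels``."""
    labels = np.asarray(labels)
    values = np.asarray(values, dtype=float)
    if labels.shape[0] != values.shape[0]:
        raise ValueError("labels and values must have equal length")
    if len(values) < 2:
        raise ValueError("need at least 2 observations")
    if not np.all(np.isfinite(values)):
        raise ValueError("values contain non-finite entries")
    cats = sorted(set(labels.tolist()), key=str)
    if len(cats) < 2:
        raise ValueError("association undefined: only one category present")
    grand = float(values.mean())
    ss_total = float(((values - grand) ** 2).sum())
    if ss_total <= 0:
        raise ValueError("association undefined: zero total variance")
    group_n: dict[str, int] = {}
    group_means: dict[str, float] = {}
    ss_between = 0.0
    for c in cats:
        mask = labels == c
        n_c = int(mask.sum())
        mean_c = float(values[mask].mean())
        group_n[str(c)] = n_c
        group_means[str(c)] = mean_c
        ss_between += n_c * (mean_c - grand) ** 2
    eta2 = min(1.0, ss_between / ss_total)
    return EtaResult(
        eta=float(np.sqrt(eta2)),
        eta_squared=float(eta2),
        group_n=group_n,
        group_means=group_means,
        grand_mean=grand,
        ss_between=float(ss_between),
        ss_total=ss_total,
    )


def binarize_outcome(series: pd.Series, partial_positive: bool = True) -> pd.Series:
    """Map outcome tokens to {positive, negative}; untested/unknown dropped."""
    positives = set(POSITIVE_TOKENS) if partial_positive else {"+"}
    negatives = set(NEGATIVE_TOKENS) | (set() if partial_positive else {"partial"})

    def _map(tok):
        tok = str(tok)
        if tok in positives:
            return "positive"
        if tok in negatives:
            return "negative"
        if tok in DROPPED_TOKENS:
            return None
        raise ValueError(f"unknown outcome token {tok!r}")

    mapped = series.map(_map)
    return mapped.dropna()


def outcome_distance_association(
    table: pd.DataFrame,
    matrix: PatristicMatrix,
    focal: str,
    outcome_column: str,
    include_focal: bool = True,
    partial_positive: bool = True,
    key_column: str = "species_strain",
) -> tuple[EtaResult, RankTestResult]:
    """Associate a screen outcome with patristic distance from the focal.

    Rows are joined to tree leaves by ``key_column``; the outcome is
    binarized (``partial`` counts positive by default, not-tested and
    unknown entries are dropped); eta and a two-sided rank-sum test between
    the positive- and negative-group distances are both reported.
    """
    if outcome_column not in table.columns:
        raise KeyError(f"outcome column {outcome_column!r} not in table")
    if key_column not in table.columns:
        raise KeyError(f"key column {key_column!r} not in table")

    dist = distances_from(matrix, focal)
    keys = table[key_column]
    unjoinable = [
        k for k in keys if k not in dist.index and k != focal
    ]
    if unjoinable:
        raise KeyError(f"table rows with no matching tree leaf: {unjoinable}")

    outcome = binarize_outcome(table.set_index(key_column)[outcome_column], partial_positive)
    if not include_focal:
        outcome = outcome.drop(focal, errors="ignore")
    if outcome.nunique() < 2:
        raise ValueError("association undefined: only one outcome category after filtering")

    distances = np.array(
        [0.0 if k == focal else dist.loc[k] for k in outcome.index], dtype=float
    )
    eta = correlation_ratio(outcome.values, distances)
    pos = distances[outcome.values == "positive"]
    neg = distances[outcome.values == "negative"]
    test = rank_sum_test(pos, neg)
    return eta, test


def trait_crosstab(
    table: pd.DataFrame, row_trait: str, col_outcome: str
) -> pd.DataFrame:
    """Contingency table of a host trait against an outcome, with margins.

    Missing entries surface as an explicit ``unknown`` category rather than
    being dropped.
    """
    for col in (row_trait, col_outcome):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in table")
    if len(table) == 0:
        return pd.DataFrame(
            {"All": [0]}, index=pd.Index(["All"], name=row_trait)
        ).rename_axis(col_outcome, axis=1)
    rows = table[row_trait].fillna("unknown").replace({"?": "unknown"})
    cols = table[col_outcome].fillna("unknown").replace({"?": "unknown"})
    return pd.crosstab(rows, cols, margins=True, margins_name="All")
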