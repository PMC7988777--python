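"""Rank-based group comparison for per-fish severities.

The comparison used on notochord severities: a Kruskal–Wallis omnibus test
(tie-corrected H against the chi-square upper tail), Dunn's pairwise post hoc
z tests on the pooled mid-ranks, and Bonferroni adjustment of the pairwise
p-values.  A tie-aware Mann–Whitney U is provided for two-group comparisons
(exact enumeration for small untied samples, normal approximation with
continuity correction otherwise).

Kruskal–Wallis and Mann–Whitney delegate to scipy, whose tie-corrected
statistics match the standard formulas:

    H = [12 / (N(N+1))] * sum_i n_i R̄_i² − 3(N+1),  corrected by
    H / (1 − sum_t (t³ − t) / (N³ − N))

Dunn's test is implemented here (1964 form, pooled tie correction):

    z_ij = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − sum_t (t³−t) / (12(N−1)))
                               · (1/n_i + 1/n_j)]

One-way ANOVA, also used in the original comparisons, is deliberately a thin
delegation to :func:`scipy.stats.f_oneway`; Kruskal–Wallis is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupData:
    """Labelled groups of real-valued observations."""

    labels: tuple[str, ...]
    values: tuple[np.ndarray, ...]

    @classmethod
    def from_mapping(cls, groups: Mapping[str, Sequence[float]]) -> "GroupData":
        labels = tuple(groups)
        values = tuple(np.asarray(groups[g], dtype=float) for g in labels)
        return cls(labels, values)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, value_col: str = "severity", group_col: str = "group"
    ) -> "GroupData":
        out: dict[str, np.ndarray] = {}
        for g in dict.fromkeys(df[group_col]):
            out[str(g)] = df.loc[df[group_col] == g, value_col].to_numpy(dtype=float)
        return cls.from_mapping(out)

    def __post_init__(self):
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values length mismatch")
        for lab, v in zip(self.labels, self.values):
            if len(v) == 0:
                raise ValueError(f"group {lab!r} is empty")

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.values)


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    df: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float


def kruskal_wallis(data: GroupData) -> StatResult:
    """Tie-corrected Kruskal–Wallis H with a chi-square p (df = k − 1).

    All observations identical is a well-defined degenerate case: H = 0,
    p = 1.
    """
    if len(data.labels) < 2:
        raise ValueError("Kruskal–Wallis needs at least two groups")
    if data.n_total < 3:
        raise ValueError("Kruskal–Wallis needs at least three observations")
    pooled = np.concatenate(data.values)
    if np.all(pooled == pooled[0]):
        return StatResult(statistic=0.0, p_value=1.0, df=len(data.labels) - 1)
    h, p = sps.kruskal(*data.values)
    return StatResult(statistic=float(h), p_value=float(p), df=len(data.labels) - 1)


def dunn_posthoc(data: GroupData, adjust: str = "bonferroni") -> list[PairwiseComparison]:
    """Dunn's pairwise z tests on pooled mid-ranks, Bonferroni-adjusted.

    Comparisons are returned for every unordered pair in label order; the
    adjusted p is ``min(1, p_raw * m)`` for m pairs (``adjust="none"`` keeps
    the raw p).
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError("adjust must be 'bonferroni' or 'none'")
    k = len(data.labels)
    if k < 2:
        raise ValueError("Dunn's test needs at least two groups")
    pooled = np.concatenate(data.values)
    n = len(pooled)
    ranks = sps.rankdata(pooled)  # mid-ranks
    # per-group mean ranks
    mean_ranks = []
    start = 0
    for v in data.values:
        mean_ranks.append(ranks[start : start + len(v)].mean())
        start += len(v)
    # pooled tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    var_base = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    m = k * (k - 1) // 2
    out: list[PairwiseComparison] = []
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = len(data.values[i]), len(data.values[j])
            se = np.sqrt(var_base * (1.0 / ni + 1.0 / nj))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = float(2.0 * sps.norm.sf(abs(z)))
            p_adj = p_raw if adjust == "none" else min(1.0, p_raw * m)
            out.append(
                PairwiseComparison(
                    group_a=data.labels[i],
                    group_b=data.labels[j],
                    z=float(z),
                    p_raw=p_raw,
                    p_adjusted=p_adj,
                )
            )
    return out


#: largest n_a * n_b for which the exact Mann–Whitney null is used (no ties)
EXACT_MW_LIMIT = 400


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Two-sided Mann–Whitney U (U reported for the first sample).

    Exact null distribution when the samples are untied and
    ``n_a * n_b <= EXACT_MW_LIMIT``; otherwise the normal approximation with
    tie-corrected variance and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(a) * len(b) <= EXACT_MW_LIMIT:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return StatResult(statistic=float(res.statistic), p_value=float(res.pvalue))


def one_way_anova(data: GroupData) -> StatResult:
    """Classic one-way ANOVA, delegated to scipy (not a bespoke surface)."""
    f, p = sps.f_oneway(*data.values)
    return StatResult(statistic=float(f), p_value=float(p), df=len(data.labels) - 1)


def comparisons_frame(comparisons: list[PairwiseComparison]) -> pd.DataFrame:
    """Tabular form of a Dunn result (comparison, z, p_raw, p_adjusted)."""
    return pd.DataFrame(
        [
            {
                "group_a": c.group_a,
                "group_b": c.group_b,
                "z": c.z,
                "p_raw": c.p_raw,
                "p_adjusted": c.p_adjusted,
            }
            for c in comparisons
        ]
    )
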