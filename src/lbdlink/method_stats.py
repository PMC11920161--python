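"""Nonparametric comparison of method configurations over multiple datasets.

Implements the standard procedure for comparing k methods over N datasets by
mean rank: rank methods within each dataset (best = 1, average ranks on
ties), compute the Friedman chi-square statistic and its Iman–Davenport
F-form

    chi2_F = 12N / (k(k+1)) * [ sum_j Rbar_j^2 - k(k+1)^2 / 4 ]
    F_F    = (N-1) chi2_F / (N(k-1) - chi2_F)

compare F_F against the F(k-1, (k-1)(N-1)) critical value, and — when the
omnibus test rejects — apply the Nemenyi post-hoc test with critical
difference CD = q_alpha * sqrt(k(k+1) / (6N)), where q_alpha is the
two-tailed studentized-range critical value at infinite degrees of freedom
divided by sqrt(2).

Critical F values are computed numerically from the F distribution rather
than read from coarse printed tables, so they can differ from table lookups
in the second decimal place (e.g. 2.2444 for df (8, 32), where a df2=30
table row reads 2.27).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankMatrix",
    "StatsResult",
    "rank_rows",
    "friedman_statistic",
    "f_critical",
    "nemenyi_cd",
    "significance_report",
    "load_rank_matrix",
    "load_hoc_benchmark",
]

# Two-tailed studentized-range critical values at infinite df, k = 2..10.
# Dividing by sqrt(2) yields the Nemenyi q_alpha constants (1.960, 2.343, ...
# at alpha = 0.05). Stored unrounded-by-sqrt2 so the critical difference keeps
# full precision.
_STUDENTIZED_RANGE_INF = {
    0.05: {2: 2.772, 3: 3.314, 4: 3.633, 5: 3.858, 6: 4.030,
           7: 4.170, 8: 4.286, 9: 4.387, 10: 4.474},
    0.10: {2: 2.326, 3: 2.902, 4: 3.240, 5: 3.478, 6: 3.661,
           7: 3.808, 8: 3.931, 9: 4.037, 10: 4.129},
}


@dataclass
class RankMatrix:
    """Datasets × methods table of mean ranks (lower is better)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("rank matrix contains missing entries")
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValueError("rank matrix needs at least 2 datasets and 2 methods")
        self.data = self.data.astype(float)

    @property
    def n_datasets(self) -> int:
        return self.data.shape[0]

    @property
    def n_methods(self) -> int:
        return self.data.shape[1]

    @property
    def methods(self) -> list[str]:
        return list(self.data.columns)


def load_rank_matrix(path: str | Path) -> RankMatrix:
    """Read a TSV with dataset rows, method columns, and header row/column."""
    return RankMatrix(pd.read_csv(path, sep="\t", index_col=0))


def load_hoc_benchmark(vocab: str = "evaluation") -> RankMatrix:
    """Published mean gold-B ranks of closed-discovery methods on HOC1–HOC5.

    ``evaluation``: nine method/input-representation combinations (the
    embedding-prediction model, the MLP closed-discovery ranker, and the
    triplet-scoring CD-2 network, each with average/concat/Hadamard inputs)
    scored against the evaluation vocabularies. ``comprehensive``: the six
    combinations reported against the comprehensive vocabularies.
    """
    if vocab not in ("evaluation", "comprehensive"):
        raise ValueError("vocab must be 'evaluation' or 'comprehensive'")
    name = f"hoc_mean_ranks_{vocab}.tsv"
    with resources.files("lbdlink.data").joinpath(name).open() as fh:
        return RankMatrix(pd.read_csv(fh, sep="\t", index_col=0))


def rank_rows(matrix: RankMatrix) -> pd.DataFrame:
    """Within-dataset method ranks, best entry = 1, average ranks on ties."""
    ranked = np.apply_along_axis(stats.rankdata, 1, matrix.data.to_numpy())
    return pd.DataFrame(ranked, index=matrix.data.index, columns=matrix.data.columns)


def friedman_statistic(matrix: RankMatrix) -> tuple[float, float]:
    """Friedman chi-square and its Iman–Davenport F-form.

    Raises on the degenerate case chi2_F = N(k-1) (perfectly consistent
    ranking across every dataset), where the F-form is undefined.
    """
    ranks = rank_rows(matrix).to_numpy()
    n, k = ranks.shape
    mean_ranks = ranks.mean(axis=0)
    chi2 = 12.0 * n / (k * (k + 1)) * (np.sum(mean_ranks ** 2) - k * (k + 1) ** 2 / 4.0)
    denom = n * (k - 1) - chi2
    if abs(denom) < 1e-12:
        raise ZeroDivisionError(
            "Iman-Davenport statistic undefined: chi2_F equals N(k-1) "
            "(method ordering is identical in every dataset)")
    ff = (n - 1) * chi2 / denom
    return float(chi2), float(ff)


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """(1 - alpha) quantile of the F distribution, computed numerically."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    return float(stats.f.ppf(1.0 - alpha, df1, df2))


def nemenyi_cd(k: int, n: int, alpha: float = 0.05,
               q: float | None = None) -> tuple[float, float]:
    """Nemenyi q_alpha constant and critical difference for k methods, N datasets.

    ``q`` overrides the built-in studentized-range constants (needed for k
    outside 2..10 or untabled alpha levels).
    """
    if k < 2 or n < 1:
        raise ValueError("need k >= 2 methods and N >= 1 datasets")
    if q is None:
        try:
            q = _STUDENTIZED_RANGE_INF[alpha][k] / np.sqrt(2.0)
        except KeyError:
            raise ValueError(
                f"no built-in q constant for k={k}, alpha={alpha}; supply q") from None
    cd = q * np.sqrt(k * (k + 1) / (6.0 * n))
    return float(q), float(cd)


@dataclass
class StatsResult:
    """Full omnibus + post-hoc comparison report."""

    ranks: pd.DataFrame
    mean_ranks: pd.Series
    chi2_f: float
    f_f: float
    df1: int
    df2: int
    critical_value: float
    alpha: float
    reject: bool
    q_alpha: float | None = None
    cd: float | None = None
    significant_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    groups: list[list[str]] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"Friedman chi2_F = {self.chi2_f:.4f}, Iman-Davenport F_F = {self.f_f:.4f}",
            f"critical value F({self.df1}, {self.df2}) at alpha={self.alpha} = {self.critical_value:.4f}",
            "decision: " + ("reject H0 (some methods differ)" if self.reject
                            else "accept H0 (no significant differences)"),
        ]
        if self.reject and self.cd is not None:
            lines.append(f"Nemenyi q = {self.q_alpha:.4f}, CD = {self.cd:.4f}")
            for m1, m2, diff in self.significant_pairs:
                lines.append(f"  {m1} vs {m2}: mean-rank gap {diff:.3f} > CD")
            for grp in self.groups:
                lines.append("  group: " + ", ".join(grp))
        return "\n".join(lines)


def significance_report(matrix: RankMatrix, alpha: float = 0.05) -> StatsResult:
    """Omnibus Friedman/Iman–Davenport decision plus Nemenyi grouping.

    When the within-row ranking is perfectly consistent across all datasets
    the F-form diverges; that extreme is treated as a rejection at any alpha.
    """
    ranks = rank_rows(matrix)
    mean_ranks = ranks.mean(axis=0)
    n, k = matrix.n_datasets, matrix.n_methods
    df1, df2 = k - 1, (k - 1) * (n - 1)
    cv = f_critical(alpha, df1, df2)
    try:
        chi2, ff = friedman_statistic(matrix)
    except ZeroDivisionError:
        chi2 = float(n * (k - 1))
        ff = float("inf")
    reject = ff > cv
    result = StatsResult(ranks=ranks, mean_ranks=mean_ranks, chi2_f=chi2, f_f=ff,
                         df1=df1, df2=df2, critical_value=cv, alpha=alpha, reject=reject)
    if not reject:
        return result

    q_alpha, cd = nemenyi_cd(k, n, alpha)
    result.q_alpha, result.cd = q_alpha, cd
    methods = list(mean_ranks.index)
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(mean_ranks.iloc[i] - mean_ranks.iloc[j])
            if diff >= cd:
                result.significant_pairs.append((methods[i], methods[j], float(diff)))
    # groups: maximal sets whose pairwise mean-rank gaps are all below CD;
    # with a single gap threshold these are intervals in mean-rank order
    order = mean_ranks.sort_values().index.tolist()
    values = mean_ranks.sort_values().to_numpy()
    windows = []
    for i in range(k):
        j = i
        while j + 1 < k and values[j + 1] - values[i] < cd:
            j += 1
        windows.append((i, j))
    for i, j in windows:
        if any(a <= i and j <= b and (a, b) != (i, j) for a, b in windows):
            continue
        result.groups.append(order[i:j + 1])
    return result
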