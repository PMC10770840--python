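"""Channel ranking: Friedman test and Nemenyi post-hoc critical distance.

The three color channels are compared per metric with a nonparametric
repeated-measures design: subjects (or subject-videos) are blocks, channels
are groups. Within each block the channel values are ranked (rank 1 =
best under the metric's direction); the Friedman statistic

    chi2_F = 12 n / (k (k+1)) * [ sum_j R_j^2 - k (k+1)^2 / 4 ]

with mean ranks R_j is referred to a chi-squared distribution with k-1
degrees of freedom. When the Friedman test is significant, the Nemenyi
procedure compares mean ranks pairwise against the critical distance

    CD = q_alpha * sqrt( k (k+1) / (6 n) )

where q_alpha is the Studentized range quantile (k groups, infinite df)
divided by sqrt(2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata, studentized_range

from .errors import StatsPreconditionError
from .metrics import METRIC_NAMES
from .traces import CHANNELS

#: Whether rank 1 means the smallest (lower-is-better) or largest value.
METRIC_DIRECTIONS = {"dtw": "lower", "r": "higher", "rmse": "lower",
                     "delta_bpm": "lower"}

#: Studentized-range quantiles divided by sqrt(2), infinite df, for
#: k = 2..10 groups (the tabulation commonly used with the Nemenyi CD).
Q_ALPHA_TABLE = {
    0.05: {2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850,
           7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164},
    0.10: {2: 1.645, 3: 2.052, 4: 2.291, 5: 2.459, 6: 2.589,
           7: 2.693, 8: 2.780, 9: 2.855, 10: 2.920},
}


@dataclass
class RankMatrix:
    """Blocks x groups value table with within-block ranks."""

    values: pd.DataFrame           # index = blocks, columns = groups
    direction: str = "lower"
    ranks: pd.DataFrame = field(init=False)
    mean_ranks: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        if self.direction not in ("lower", "higher"):
            raise StatsPreconditionError(f"unknown direction {self.direction!r}")
        vals = self.values.to_numpy(dtype=float)
        if self.values.shape[1] < 3:
            raise StatsPreconditionError("need at least 3 groups (k >= 3)")
        signed = vals if self.direction == "lower" else -vals
        ranks = np.vstack([rankdata(row, method="average") for row in signed])
        self.ranks = pd.DataFrame(ranks, index=self.values.index,
                                  columns=self.values.columns)
        self.mean_ranks = self.ranks.mean(axis=0)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class FriedmanResult:
    chi2_f: float
    df: int
    p_value: float


@dataclass
class NemenyiResult:
    cd: float
    alpha: float
    mean_ranks: pd.Series
    diffs: pd.DataFrame            # tidy: group_a, group_b, rank_diff, p_value, significant
    gated: bool = True             # False when run without a significant Friedman test


def build_rank_matrix(summaries: pd.DataFrame, metric: str,
                      direction: str | None = None,
                      block_cols: tuple = ("subject",),
                      group_col: str = "channel") -> RankMatrix:
    """Pivot per-video summaries into a blocks x channels rank matrix.

    Blocks with a missing value for any channel are dropped with a warning.
    ``direction`` defaults to the metric's registered direction.
    """
    direction = direction or METRIC_DIRECTIONS[metric]
    df = summaries.copy()
    if len(block_cols) == 1:
        block = df[block_cols[0]]
    else:
        block = df[list(block_cols)].astype(str).agg("|".join, axis=1)
    wide = df.assign(_block=block).pivot_table(index="_block", columns=group_col,
                                               values=metric, aggfunc="mean")
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        dropped = wide.index[incomplete].tolist()
        warnings.warn(f"dropping {len(dropped)} incomplete block(s): {dropped}",
                      stacklevel=2)
        wide = wide.loc[~incomplete]
    order = [c for c in CHANNELS if c in wide.columns] or list(wide.columns)
    return RankMatrix(values=wide[order], direction=direction)


def friedman_statistic(m: RankMatrix) -> FriedmanResult:
    """Friedman chi-squared statistic on mean ranks, p from chi2(k-1).

    Uses the uncorrected statistic (mid-ranks for ties, no tie correction).
    A fully tied matrix gives statistic 0 and p = 1.
    """
    n, k = m.n, m.k
    if n < 2:
        raise StatsPreconditionError("Friedman test needs at least 2 blocks")
    r = m.mean_ranks.to_numpy()
    stat = 12.0 * n / (k * (k + 1)) * (np.sum(r ** 2) - k * (k + 1) ** 2 / 4.0)
    stat = max(stat, 0.0)
    return FriedmanResult(chi2_f=float(stat), df=k - 1,
                          p_value=float(chi2.sf(stat, k - 1)))


def q_alpha(k: int, alpha: float = 0.05, method: str = "table") -> float:
    """Nemenyi q: Studentized range quantile (infinite df) over sqrt(2)."""
    if method == "table":
        try:
            return Q_ALPHA_TABLE[alpha][k]
        except KeyError:
            raise StatsPreconditionError(
                f"no tabulated q for alpha={alpha}, k={k}; use method='distribution'")
    if method == "distribution":
        return float(studentized_range.ppf(1 - alpha, k, np.inf) / np.sqrt(2))
    raise StatsPreconditionError(f"unknown q_alpha method {method!r}")


def nemenyi_cd(k: int, n: int, alpha: float = 0.05,
               method: str = "table") -> float:
    """Critical distance for mean-rank differences: q_a sqrt(k(k+1)/(6n))."""
    if k < 2 or n < 1:
        raise StatsPreconditionError("need k >= 2 groups and n >= 1 blocks")
    return q_alpha(k, alpha, method) * np.sqrt(k * (k + 1) / (6.0 * n))


def nemenyi_pairwise(m: RankMatrix, alpha: float = 0.05,
                     friedman: FriedmanResult | None = None) -> NemenyiResult:
    """All-pairs Nemenyi comparison of mean ranks.

    A pair differs significantly when |R_i - R_j| exceeds the critical
    distance; two-sided p-values come from the Studentized range
    distribution. The procedure is meant to follow a significant Friedman
    test; if called without one, a warning is issued and the result is
    flagged ``gated=False`` (values are still returned).
    """
    fr = friedman if friedman is not None else friedman_statistic(m)
    gated = fr.p_value <= alpha
    if not gated:
        warnings.warn(
            f"Nemenyi requested without a significant Friedman test "
            f"(p={fr.p_value:.3g} > alpha={alpha}); results flagged", stacklevel=2)
    k, n = m.k, m.n
    cd = nemenyi_cd(k, n, alpha)
    scale = np.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    for a, b in combinations(m.mean_ranks.index, 2):
        diff = abs(float(m.mean_ranks[a] - m.mean_ranks[b]))
        q_stat = diff / scale * np.sqrt(2)
        p = float(np.clip(studentized_range.sf(q_stat, k, np.inf), 0.0, 1.0))
        rows.append({"group_a": a, "group_b": b, "rank_diff": diff,
                     "p_value": p, "significant": diff > cd})
    return NemenyiResult(cd=float(cd), alpha=alpha, mean_ranks=m.mean_ranks,
                         diffs=pd.DataFrame(rows), gated=gated)


def rank_channels(summaries: pd.DataFrame, grouping: str | None = None,
                  metrics: tuple = METRIC_NAMES, alpha: float = 0.05,
                  block_cols: tuple = ("subject",)) -> pd.DataFrame:
    """Per-group, per-metric channel comparison report.

    ``grouping`` is a column of ``summaries`` (e.g. ``"activity"``) or None
    for one pooled group. Returns a tidy frame with one row per group x
    metric x channel carrying the channel mean and mean rank, plus the
    group-level Friedman p and the Nemenyi pairwise p-values. Groups with
    fewer than 2 complete blocks are skipped with a warning.
    """
    if grouping is None:
        groups = [("all", summaries)]
    else:
        groups = list(summaries.groupby(grouping))
    rows = []
    for gname, gdf in groups:
        for metric in metrics:
            if metric not in gdf.columns or gdf[metric].isna().all():
                continue
            try:
                rm = build_rank_matrix(gdf, metric, block_cols=block_cols)
            except StatsPreconditionError:
                warnings.warn(f"group {gname!r}: cannot rank metric {metric!r}",
                              stacklevel=2)
                continue
            if rm.n < 2:
                warnings.warn(f"group {gname!r}: fewer than 2 blocks, skipped",
                              stacklevel=2)
                continue
            fr = friedman_statistic(rm)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nem = nemenyi_pairwise(rm, alpha=alpha, friedman=fr)
            pair_p = {f"p_{r.group_a}_vs_{r.group_b}": r.p_value
                      for r in nem.diffs.itertuples()}
            for ch in rm.values.columns:
                rows.append({"group": gname, "metric": metric, "channel": ch,
                             "mean_value": float(gdf.loc[gdf["channel"] == ch, metric].mean()),
                             "mean_rank": float(rm.mean_ranks[ch]),
                             "n_blocks": rm.n,
                             "friedman_chi2": fr.chi2_f,
                             "friedman_p": fr.p_value,
                             "nemenyi_cd": nem.cd,
                             **pair_p})
    return pd.DataFrame(rows)
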