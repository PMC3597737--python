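"""Group statistics: Friedman repeated-measures test with Dunn's post-test,
and Spearman rank correlation.

The experimental design is a blocked one: every species pair (block) yields
one value per gene (treatment), so differences between genes are tested
with the Friedman test — a one-way repeated-measures ANOVA on within-block
ranks that assumes no distribution — followed by Dunn's post-test on rank
sums for all gene pairs.  Blocks with a missing or undefined value for any
gene (e.g. the mean indel size of a zero-indel pair) are dropped listwise
before ranking.

Friedman and Spearman delegate to scipy.stats (`friedmanchisquare` is
tie-corrected; `spearmanr` uses mid-ranks and the t approximation); Dunn's
post-test for the Friedman design is implemented here since scipy and
statsmodels do not provide it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, ParameterError

ALPHA_STARS: tuple[tuple[float, str], ...] = (
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)


@dataclass
class BlockedMatrix:
    """n blocks (species pairs) x k treatments (genes) of one metric."""

    blocks: list[str]
    treatments: list[str]
    values: np.ndarray  # shape (n, k); NaN marks an undefined cell

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.blocks), len(self.treatments)):
            raise ParameterError("values shape does not match block/treatment labels")
        if len(self.treatments) < 2:
            raise ParameterError("need at least 2 treatments")

    def complete(self) -> "BlockedMatrix":
        """Listwise deletion: drop every block with any undefined value."""
        keep = ~np.isnan(self.values).any(axis=1)
        return BlockedMatrix(
            [b for b, k in zip(self.blocks, keep) if k],
            list(self.treatments),
            self.values[keep],
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, block_col: str, treatment_col: str, value_col: str
    ) -> "BlockedMatrix":
        wide = frame.pivot(index=block_col, columns=treatment_col, values=value_col)
        return cls(list(wide.index), list(wide.columns), wide.to_numpy())


def _ranked(m: BlockedMatrix) -> tuple[np.ndarray, int, int]:
    complete = m.complete()
    n, k = complete.values.shape
    if n < 2:
        raise ParameterError(f"need >= 2 complete blocks, got {n}")
    ranks = sps.rankdata(complete.values, axis=1)  # mid-ranks within blocks
    return ranks, n, k


def friedman(m: BlockedMatrix) -> tuple[float, float]:
    """Tie-corrected Friedman chi-square statistic and p-value (df = k-1).

    chi2 = (12/(nk(k+1)) * sum_j R_j^2 - 3n(k+1)) / C with the tie
    correction C = 1 - sum(t^3 - t)/(n k (k^2 - 1)) over within-block tie
    groups of size t.  Agrees with scipy.stats.friedmanchisquare for k >= 3
    but also accepts k = 2.
    """
    ranks, n, k = _ranked(m)
    if np.all(ranks == ranks[:, :1]):
        raise DegenerateDataError("all values tied within every block")
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * k * (k * k - 1))
    col_rank_sums = ranks.sum(axis=0)
    statistic = (
        12.0 / (n * k * (k + 1)) * float(np.sum(col_rank_sums**2))
        - 3.0 * n * (k + 1)
    ) / correction
    p = float(sps.chi2.sf(statistic, k - 1))
    return float(statistic), p


@dataclass
class DunnComparison:
    treatment_i: str
    treatment_j: str
    z: float
    p_adjusted: float  # Bonferroni over k(k-1)/2 comparisons, capped at 1
    stars: str


def stars_for_p(p: float) -> str:
    for alpha, stars in ALPHA_STARS:
        if p < alpha:
            return stars
    return "ns"


def dunn_posttest(m: BlockedMatrix) -> list[DunnComparison]:
    """Dunn's post-test on Friedman mean ranks, all treatment pairs.

    z = |R̄_i - R̄_j| / sqrt(k(k+1)/(6n)); two-sided normal p multiplied by
    the number of comparisons k(k-1)/2 (Bonferroni, as Dunn prescribed).
    """
    ranks, n, k = _ranked(m)
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    n_comparisons = k * (k - 1) // 2
    out: list[DunnComparison] = []
    for i in range(k):
        for j in range(i + 1, k):
            z = abs(mean_ranks[i] - mean_ranks[j]) / se
            p = min(1.0, 2.0 * sps.norm.sf(z) * n_comparisons)
            out.append(
                DunnComparison(
                    m.treatments[i], m.treatments[j], float(z), float(p),
                    stars_for_p(p),
                )
            )
    return out


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks) with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ParameterError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("correlation undefined for a constant vector")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def ols_r_squared(x, y) -> float:
    """r² of an ordinary least-squares line of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = sps.linregress(x, y)
    return float(res.rvalue**2)


def group_stats_table(
    matrices: dict[str, BlockedMatrix],
) -> pd.DataFrame:
    """Friedman + Dunn summary for several metrics, one row per comparison."""
    rows = []
    for metric, m in matrices.items():
        stat, p = friedman(m)
        for c in dunn_posttest(m):
            rows.append(
                {
                    "metric": metric,
                    "friedman_chi2": stat,
                    "friedman_p": p,
                    "treatment_i": c.treatment_i,
                    "treatment_j": c.treatment_j,
                    "dunn_z": c.z,
                    "dunn_p_adj": c.p_adjusted,
                    "stars": c.stars,
                }
            )
    return pd.DataFrame(rows)
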