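"""Nonparametric group comparison and boxplot summaries of cell counts.

Cell counts per scan site are small-sample, non-normal data, so the
default two-group test is the Mann-Whitney U (exact by complete
enumeration for small samples without ties, otherwise a normal
approximation with tie and continuity corrections).  Three or more groups
use Kruskal-Wallis with Dunn's post hoc pairwise z tests and a
configurable multiplicity adjustment (Bonferroni by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stack_model import ConfigurationError, PipelineError

EXACT_MAX_N = 16  # combined sample size up to which the exact branch runs


@dataclass(frozen=True)
class GroupSamples:
    """A labelled group of final cell counts."""

    group_label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.values) == 0:
            raise PipelineError(f"group {self.group_label!r} is empty")


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # min(U1, U2)
    u1: float
    u2: float
    p_value: float
    method: str  # "exact" or "normal_approx"


def _rank_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """U1 and U2 via midrank sums."""
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return u1, n1 * n2 - u1


def mann_whitney_u(x: GroupSamples, y: GroupSamples) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    The exact branch enumerates all C(n1+n2, n1) rank assignments and is
    used when the combined sample size is at most 16 and no value is tied;
    its p-value is the fraction of assignments whose min(U1, U2) does not
    exceed the observed one.  Otherwise the normal approximation applies,
    with tie correction of the variance and a 0.5 continuity correction.
    """
    xs, ys = np.asarray(x.values), np.asarray(y.values)
    n1, n2 = len(xs), len(ys)
    u1, u2 = _rank_u(xs, ys)
    u = min(u1, u2)
    pooled = np.concatenate([xs, ys])
    has_ties = len(np.unique(pooled)) < len(pooled)

    if n1 + n2 <= EXACT_MAX_N and not has_ties:
        order = np.argsort(pooled)
        n = n1 + n2
        count = 0
        total = 0
        for combo in combinations(range(n), n1):
            # ranks of this assignment (values are distinct, ranks = positions+1)
            rank_sum = sum(np.searchsorted(pooled[order], pooled[list(combo)]) + 1)
            u1p = rank_sum - n1 * (n1 + 1) / 2.0
            if min(u1p, n1 * n2 - u1p) <= u + 1e-9:
                count += 1
            total += 1
        return MannWhitneyResult(u, u1, u2, count / total, "exact")

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return MannWhitneyResult(u, u1, u2, 1.0, "normal_approx")
    num = min(0.0, u - mu + 0.5)  # continuity correction toward the mean
    z = num / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.cdf(z))
    return MannWhitneyResult(u, u1, u2, float(p), "normal_approx")


@dataclass(frozen=True)
class KruskalDunnResult:
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, z, p_raw, p_adjusted


def _adjust(p_values: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return p_values
    m = len(p_values)
    if method == "bonferroni":
        return np.minimum(1.0, p_values * m)
    if method == "holm":
        order = np.argsort(p_values)
        adjusted = np.empty(m)
        running_max = 0.0
        for i, idx in enumerate(order):
            running_max = max(running_max, (m - i) * p_values[idx])
            adjusted[idx] = min(1.0, running_max)
        return adjusted
    raise ConfigurationError(f"unknown adjustment {method!r}")


def kruskal_wallis_dunn(
    groups: Sequence[GroupSamples], adjustment: str = "bonferroni"
) -> KruskalDunnResult:
    """Kruskal-Wallis H test with Dunn's pairwise post hoc z tests.

    Requires at least three groups; for exactly two, use
    :func:`mann_whitney_u` instead.  H carries the usual tie correction and
    is referred to a chi-squared distribution with k-1 degrees of freedom.
    Dunn's z for a pair divides the mean-rank difference by
    sqrt((N(N+1)/12 - tie term)(1/n_i + 1/n_j)).
    """
    if len(groups) < 3:
        raise PipelineError(
            "kruskal_wallis_dunn needs >= 3 groups; "
            "for two groups use mann_whitney_u"
        )
    samples = [np.asarray(g.values) for g in groups]
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:  # scipy rejects all-identical input
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*samples)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    offset = 0
    for s in samples:
        mean_ranks.append(ranks[offset : offset + len(s)].mean())
        offset += len(s)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term

    rows = []
    for i, j in combinations(range(len(groups)), 2):
        ni, nj = len(samples[i]), len(samples[j])
        se = np.sqrt(base_var * (1.0 / ni + 1.0 / nj))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append((groups[i].group_label, groups[j].group_label, z, min(1.0, p_raw)))
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    table["p_adjusted"] = _adjust(table["p_raw"].to_numpy(), adjustment)
    return KruskalDunnResult(float(h), float(p), table)


def summarize_boxplot(
    groups: Sequence[GroupSamples], out_path: Optional[Path | str] = None
) -> pd.DataFrame:
    """Tukey-style boxplot summary; optionally writes the figure to disk.

    Quartiles use linear interpolation; whiskers extend to the most extreme
    data point within 1.5 x IQR of the box; points beyond are outliers.
    """
    rows = []
    for g in groups:
        vals = np.asarray(g.values, dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        in_lo = vals[vals >= q1 - 1.5 * iqr]
        in_hi = vals[vals <= q3 + 1.5 * iqr]
        lower_whisker = in_lo.min() if in_lo.size else q1
        upper_whisker = in_hi.max() if in_hi.size else q3
        outliers = vals[(vals < lower_whisker) | (vals > upper_whisker)]
        rows.append(
            {
                "group": g.group_label,
                "n": len(vals),
                "mean": vals.mean(),
                "median": med,
                "q1": q1,
                "q3": q3,
                "iqr": iqr,
                "lower_whisker": lower_whisker,
                "upper_whisker": upper_whisker,
                "n_outliers": int(outliers.size),
            }
        )
    table = pd.DataFrame(rows)
    if out_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(groups), 4))
        ax.boxplot(
            [g.values for g in groups],
            tick_labels=[g.group_label for g in groups],
            whis=1.5,
            showmeans=True,
        )
        ax.set_ylabel("final cell count")
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return table
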