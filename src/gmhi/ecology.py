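"""Per-sample ecology metrics and nonparametric comparison statistics.

Shannon diversity (natural log), species richness, the 80% abundance
coverage (smallest number of species jointly reaching 80% of a sample),
Bray-Curtis dissimilarity, and the group-comparison statistics used for
cohort contrasts: Cliff's delta, the two-sided Mann-Whitney U test, and
Spearman correlation with a Fisher-z confidence interval.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis as _braycurtis

from .profiles import AbundanceTable
from .scoring import DEFAULT_PRESENCE_THRESHOLD

#: switch to exact Mann-Whitney enumeration at or below this group size
EXACT_MWU_MAX_N = 8


def shannon(sample: Sequence[float], base: float = math.e) -> float:
    """Shannon diversity H' = -sum p log p over positive proportions.

    Natural log by default (the common ecology convention); abundances
    are renormalized internally so counts or percentages are accepted.
    """
    arr = np.asarray(sample, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative abundances")
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-zero sample")
    p = arr[arr > 0] / total
    return float(-(p * (np.log(p) / math.log(base))).sum())


def richness(sample: Sequence[float], mode: str = "positive",
             presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD) -> int:
    """Observed number of species: any positive abundance, or thresholded."""
    arr = np.asarray(sample, dtype=float)
    if mode == "positive":
        return int((arr > 0).sum())
    if mode == "threshold":
        return int((arr >= presence_threshold).sum())
    raise ValueError(f"unknown richness mode {mode!r}")


def coverage80(sample: Sequence[float], target: float = 0.80) -> int:
    """Smallest number of top-abundance species reaching >= target coverage."""
    if not 0 < target <= 1:
        raise ValueError("target must be in (0, 1]")
    arr = np.asarray(sample, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-zero sample")
    ordered = np.sort(arr)[::-1]
    cum = np.cumsum(ordered)
    # tiny relative slack so e.g. eight 0.1s reach 0.8 despite float rounding
    goal = target * total * (1.0 - 1e-12)
    return int(np.searchsorted(cum, goal, side="left") + 1)


def bray_curtis(a: Sequence[float], b: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/(sum a + sum b), in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must be aligned")
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("both samples are all-zero")
    return float(_braycurtis(a, b))


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's delta: [#(x_i > y_j) - #(x_i < y_j)] / (|x| |y|), in [-1, 1].

    Computed exactly from the tie-corrected Mann-Whitney U statistic
    (U counts ties as 1/2, so 2U/(mn) - 1 equals the pair-count formula).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not len(x) or not len(y):
        raise ValueError("empty input")
    u1 = stats.mannwhitneyu(x, y, alternative="two-sided",
                            method="asymptotic").statistic
    return float(2.0 * u1 / (len(x) * len(y)) - 1.0)


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 alternative: str = "two-sided") -> tuple[float, float]:
    """Two-sided (by default) Mann-Whitney U test; returns (U, p).

    Exact enumeration of the null distribution when the smaller group has
    at most 8 observations, tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not len(x) or not len(y):
        raise ValueError("empty input")
    method = "exact" if min(len(x), len(y)) <= EXACT_MWU_MAX_N else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def spearman_ci(x: Sequence[float], y: Sequence[float],
                level: float = 0.95) -> tuple[float, float, float, float]:
    """Spearman rho with Fisher-z CI and a t-test p-value (n-2 df).

    Returns (rho, ci_low, ci_high, p). Ties get average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must be the same length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    rho, p = stats.spearmanr(x, y)
    if abs(rho) >= 1.0:
        return float(rho), float(rho), float(rho), float(p)
    z = math.atanh(rho)
    se = 1.0 / math.sqrt(n - 3)
    crit = stats.norm.ppf(0.5 + level / 2.0)
    return (float(rho), math.tanh(z - crit * se), math.tanh(z + crit * se),
            float(p))


# ---------------------------------------------------------------------------
# table-level summaries
# ---------------------------------------------------------------------------

def ecology_metrics(table: AbundanceTable,
                    richness_mode: str = "positive") -> pd.DataFrame:
    """Shannon, richness, and 80% abundance coverage for every sample."""
    rows = []
    for sid in table.sample_ids:
        vec = table.data.loc[sid].to_numpy()
        rows.append({
            "sample_id": sid,
            "shannon": shannon(vec),
            "richness": richness(vec, mode=richness_mode),
            "coverage80": coverage80(vec),
        })
    return pd.DataFrame(rows).set_index("sample_id")


def compare_groups(values: pd.Series, groups: pd.Series,
                   reference: str, other: str) -> dict:
    """Mann-Whitney + Cliff's delta contrast of one metric between two groups."""
    x = values[groups == reference].to_numpy()
    y = values[groups == other].to_numpy()
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 samples")
    u, p = mann_whitney(x, y)
    return {
        "n_reference": len(x), "n_other": len(y),
        "median_reference": float(np.median(x)),
        "median_other": float(np.median(y)),
        "U": u, "p": p, "cliffs_delta": cliffs_delta(x, y),
    }
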