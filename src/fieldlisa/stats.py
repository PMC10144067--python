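"""Rank-based similarity tests for germplasm replicates.

If the field were homogeneous, the three replicate plots of one
germplasm should carry exchangeable plant heights; a significant
Kruskal–Wallis test among the replicates therefore signals an
environmental (spatial) effect rather than a genetic one.  Pairwise
follow-up uses Dunn's z on the pooled tie-corrected ranks with
Benjamini–Hochberg adjustment per germplasm.  Two-group comparisons
(e.g. soil moisture of the low- vs high-altitude region) use the
Wilcoxon rank-sum test, exact for small tie-free samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateVarianceError, InvalidInputError

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "wilcoxon_rank_sum",
    "star_code",
    "germplasm_similarity",
]


@dataclass
class TestResult:
    """Kruskal–Wallis result for one germplasm's replicate plots."""

    germplasm: str
    H: float
    df: int
    p_value: float
    stars: str
    pairwise: pd.DataFrame  # plot_a, plot_b, z, p_raw, p_adjusted


def _check_groups(groups) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InvalidInputError(f"need >= 2 groups, got {len(groups)}")
    if any(len(g) == 0 for g in groups):
        raise InvalidInputError("every group needs at least one value")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size < 2:
        raise DegenerateVarianceError("all values identical; rank tests are undefined")
    return groups


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square p-value.

    Returns ``(H, df, p)`` with df = number of groups − 1.
    """
    groups = _check_groups(groups)
    H, p = stats.kruskal(*groups)
    return float(H), len(groups) - 1, float(p)


def dunn_posthoc(groups, labels=None) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks, BH-adjusted.

    For the pair (a, b):

        z = (meanrank_a − meanrank_b) /
            sqrt((n(n+1)/12 − T/(12(n−1))) * (1/n_a + 1/n_b)),

    with tie correction T = Σ(t³ − t) over tied groups of size t.  Two-
    sided normal p-values are adjusted with the Benjamini–Hochberg
    step-up over the comparison family of these groups.
    """
    groups = _check_groups(groups)
    if labels is None:
        labels = list(range(1, len(groups) + 1))
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)

    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(((counts**3) - counts).sum())
    var_base = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))

    rows = []
    for a, b in combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
        rows.append((labels[a], labels[b], z, p))
    out = pd.DataFrame(rows, columns=["plot_a", "plot_b", "z", "p_raw"])
    out["p_adjusted"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum test of two samples.

    Returns ``(W, p)`` where W is the rank sum of sample ``a`` under
    average ranks.  The p-value is exact (full enumeration of rank
    assignments) when min(n_a, n_b) <= 8 and there are no ties, and uses
    the normal approximation without continuity correction otherwise.
    ``alternative`` is "two-sided", "less" (a shifted below b) or
    "greater".
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InvalidInputError("both samples need at least one value")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method, use_continuity=False)
    w = float(res.statistic) + len(a) * (len(a) + 1) / 2.0  # U -> rank sum of a
    return w, float(res.pvalue)


def star_code(p_value: float) -> str:
    """Significance coding: ``**`` for p < 0.01, ``*`` for p < 0.1, else empty."""
    if not 0 < p_value <= 1:
        raise InvalidInputError(f"p-value must be in (0, 1], got {p_value}")
    if p_value < 0.01:
        return "**"
    if p_value < 0.1:
        return "*"
    return ""


def germplasm_similarity(
    plants: pd.DataFrame,
    value_col: str = "height_est",
    group_col: str = "germplasm",
    plot_col: str = "plot_id",
) -> list[TestResult]:
    """Replicate-similarity tests for every germplasm with >= 2 plots.

    For each germplasm the plant heights of its replicate plots form the
    Kruskal–Wallis groups; Dunn's post hoc runs on the same family.
    Germplasms whose values are degenerate (all identical) are skipped.
    """
    required = {value_col, group_col, plot_col}
    if not required <= set(plants.columns):
        raise InvalidInputError(f"plant table needs columns {sorted(required)}")
    data = plants
    if "outlier" in data.columns:
        data = data[~data["outlier"]]

    results = []
    for germ, gdf in data.groupby(group_col, sort=True):
        plot_ids = sorted(gdf[plot_col].unique())
        if len(plot_ids) < 2:
            continue
        groups = [gdf.loc[gdf[plot_col] == pid, value_col].to_numpy() for pid in plot_ids]
        try:
            H, df, p = kruskal_wallis(groups)
        except DegenerateVarianceError:
            continue
        pairwise = dunn_posthoc(groups, labels=plot_ids)
        results.append(TestResult(germplasm=str(germ), H=H, df=df, p_value=p, stars=star_code(p), pairwise=pairwise))
    return results
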