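"""Sex- and age-effect statistics.

Rank-based two-group and multi-group comparisons as used in indirect
reference-interval studies: Mann-Whitney U (with Cohen's d as the effect
size on the raw scale), Spearman rank correlation, tie-corrected
Kruskal-Wallis, and Dunn's post hoc pairwise z tests with a configurable
multiplicity adjustment (Bonferroni by default; its cap at 1.0 matches how
such tables are conventionally printed).

Mann-Whitney p-values are exact for combined n <= 20 — computed by full
enumeration of the permutation distribution of U on pooled midranks, which
also handles ties coherently (identical samples give p = 1) — and use the
tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TwoSampleResult",
    "CorrelationResult",
    "MultiGroupResult",
    "mann_whitney",
    "cohens_d",
    "spearman",
    "kruskal_wallis",
    "dunn_posthoc",
]

EXACT_MAX_N = 20
ADJUSTMENTS = ("none", "bonferroni", "holm")


@dataclass
class TwoSampleResult:
    u_statistic: float
    z_normalized: float
    p_value: float
    cohens_d: float
    exact: bool


@dataclass
class CorrelationResult:
    rho: float
    p_value: float


@dataclass
class MultiGroupResult:
    h_statistic: float
    p_value: float
    dunn_table: pd.DataFrame


def cohens_d(x, y) -> float:
    """Standardized mean difference with the pooled (n1+n2-2) SD."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("Cohen's d needs at least 2 observations per group")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return 0.0
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def _u_from_ranks(rank_sum_x: float, nx: int) -> float:
    return rank_sum_x - nx * (nx + 1) / 2.0


def _exact_two_sided_p(pooled_ranks: np.ndarray, nx: int, u_obs: float) -> float:
    """Two-sided p by full enumeration of C(n, nx) midrank assignments."""
    n = pooled_ranks.size
    ny = n - nx
    center = nx * ny / 2.0
    dev_obs = abs(u_obs - center)
    total = comb(n, nx)
    hits = 0
    for idx in combinations(range(n), nx):
        u = _u_from_ranks(pooled_ranks[list(idx)].sum(), nx)
        if abs(u - center) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def mann_whitney(x, y) -> TwoSampleResult:
    """Two-sided Mann-Whitney U with midranks, plus Cohen's d.

    U reported for the first sample; z is the tie-corrected normal
    standardization (0 when the exact path is taken and n is tiny).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_x = _u_from_ranks(ranks[:nx].sum(), nx)
    n = nx + ny
    # tie-corrected normal standardization (reported alongside either path)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var_u = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = 0.0 if var_u == 0 else (u_x - nx * ny / 2.0) / np.sqrt(var_u)
    if n <= EXACT_MAX_N:
        p = _exact_two_sided_p(ranks, nx, u_x)
        exact = True
    else:
        if var_u == 0:
            raise ValueError("degenerate pooled sample: all values tied")
        p = float(2.0 * stats.norm.sf(abs(z)))
        exact = False
    d = cohens_d(x, y) if min(nx, ny) >= 2 else float("nan")
    return TwoSampleResult(float(u_x), float(z), float(min(p, 1.0)), d, exact)


def spearman(x, y) -> CorrelationResult:
    """Spearman rho (Pearson on midranks) with the t-approximation p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        raise ValueError("zero rank variance")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p))


def kruskal_wallis(groups, adjustment: str = "bonferroni") -> MultiGroupResult:
    """Tie-corrected Kruskal-Wallis H with Dunn's post hoc table."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
    return MultiGroupResult(float(h), float(p), dunn_posthoc(groups, adjustment=adjustment))


def dunn_posthoc(groups, adjustment: str = "bonferroni", labels=None) -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled midranks.

    z_ij = (rbar_i - rbar_j) / SE with the tie-corrected SE
    sqrt((N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j)), T = sum(t^3 - t).
    The sign follows the first-listed group (negative when the second group
    ranks higher).  Adjusted p capped at 1.
    """
    if adjustment not in ADJUSTMENTS:
        raise ValueError(f"unknown adjustment {adjustment!r}; choose from {ADJUSTMENTS}")
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if labels is None:
        labels = [f"g{i + 1}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    sizes = [g.size for g in groups]
    splits = np.cumsum(sizes)[:-1]
    mean_ranks = [r.mean() for r in np.split(ranks, splits)]
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = np.sum(counts**3 - counts)
    base_var = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        zij = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = float(2.0 * stats.norm.sf(abs(zij)))
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": float(zij), "p_raw": p_raw})
    table = pd.DataFrame(rows)
    m = len(table)
    if adjustment == "none":
        adj = table["p_raw"].to_numpy()
    elif adjustment == "bonferroni":
        adj = np.minimum(1.0, table["p_raw"].to_numpy() * m)
    else:  # holm
        order = np.argsort(table["p_raw"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank_pos, idx in enumerate(order):
            running = max(running, (m - rank_pos) * table["p_raw"].iloc[idx])
            adj[idx] = min(1.0, running)
    table["p_adjusted"] = adj
    return table
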