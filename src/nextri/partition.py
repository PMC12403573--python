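"""Harris-Boyd partitioning and CLSI-style nonparametric reference limits.

The Harris-Boyd criterion decides whether two candidate strata (sexes, or
age bands) deserve separate reference intervals: the standardized mean
difference ``z = |m_a - m_b| / sqrt(s_a^2/n_a + s_b^2/n_b)`` is compared
with the sample-size-dependent threshold ``z* = 3 * sqrt(n_avg / 120)``
(``n_avg`` the arithmetic mean group size); partitioning is warranted when
``z > z*``.

Upper reference limits are one-sided nonparametric percentiles: the URL is
the 97.5th percentile at rank ``r = p*(n+1)`` with linear interpolation
between order statistics, and its 90% CI is the narrowest symmetric-in-rank
pair of order statistics whose exact binomial coverage reaches 90%, with a
seeded percentile-bootstrap fallback when no such pair exists near the
sample edge.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .cohort import Cohort

__all__ = [
    "GroupSummary",
    "PartitionDecision",
    "ReferenceInterval",
    "harris_boyd",
    "nonparametric_url",
    "choose_partitions",
]


@dataclass(frozen=True)
class GroupSummary:
    """(n, mean, sd) of one candidate stratum."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(n=v.size, mean=float(v.mean()), sd=float(v.std(ddof=1)))


@dataclass(frozen=True)
class PartitionDecision:
    label: str
    z: float
    z_star: float
    partition: bool


@dataclass(frozen=True)
class ReferenceInterval:
    """One-sided reference interval: [0, URL] with a CI on the URL."""

    label: str
    lower: float
    url: float
    ci90_low: float
    ci90_high: float
    n: int
    ci_method: str = "exact-binomial"


def harris_boyd(a: GroupSummary, b: GroupSummary, label: str = "") -> PartitionDecision:
    """Harris-Boyd partition test on two group summaries."""
    if a.sd == 0 and b.sd == 0:
        raise ValueError("both groups have zero SD; z undefined")
    z = abs(a.mean - b.mean) / np.sqrt(a.sd**2 / a.n + b.sd**2 / b.n)
    n_avg = (a.n + b.n) / 2.0
    z_star = 3.0 * np.sqrt(n_avg / 120.0)
    return PartitionDecision(label=label, z=float(z), z_star=float(z_star), partition=bool(z > z_star))


def _interp_order_stat(sorted_values: np.ndarray, rank: float) -> float:
    """Order statistic at (1-based) possibly fractional rank, clamped to range."""
    n = sorted_values.size
    rank = min(max(rank, 1.0), float(n))
    lo = int(np.floor(rank))
    frac = rank - lo
    if lo >= n:
        return float(sorted_values[-1])
    return float(sorted_values[lo - 1] + frac * (sorted_values[lo] - sorted_values[lo - 1]))


def nonparametric_url(
    values,
    p: float = 0.975,
    ci: float = 0.90,
    label: str = "",
    seed: int | None = None,
    n_boot: int = 2000,
) -> ReferenceInterval:
    """Nonparametric URL at rank p*(n+1) with an order-statistic CI.

    Requires n >= 20; warns below n = 120 (the CLSI minimum for a valid
    90% CI on the 97.5th percentile).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 20:
        raise ValueError(f"n = {n} too small for the {p:.3%} percentile; need >= 20")
    if n < 120:
        warnings.warn(f"n = {n} < 120: CI on the URL is unreliable", stacklevel=2)
    r = p * (n + 1)
    url = _interp_order_stat(v, r)

    lo0, hi0 = int(np.floor(r)), int(np.ceil(r))
    if hi0 == lo0:
        hi0 += 1
    ci_method = "exact-binomial"
    ci_lo = ci_hi = None
    for d in range(n):
        l, u = max(1, lo0 - d), min(n, hi0 + d)
        # coverage P(X_(l) <= true percentile < X_(u)) = P(l <= K <= u-1), K ~ Bin(n, p)
        cover = stats.binom.cdf(u - 1, n, p) - stats.binom.cdf(l - 1, n, p)
        if cover >= ci:
            ci_lo, ci_hi = v[l - 1], v[u - 1]
            break
        if l == 1 and u == n:
            break
    if ci_lo is None:  # edge-infeasible: percentile bootstrap fallback
        ci_method = "bootstrap"
        rng = np.random.default_rng(seed)
        boot = np.empty(n_boot)
        for b in range(n_boot):
            sample = np.sort(rng.choice(v, size=n, replace=True))
            boot[b] = _interp_order_stat(sample, r)
        alpha = (1.0 - ci) / 2.0
        ci_lo, ci_hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return ReferenceInterval(
        label=label,
        lower=0.0,
        url=url,
        ci90_low=float(min(ci_lo, url)),
        ci90_high=float(max(ci_hi, url)),
        n=n,
        ci_method=ci_method,
    )


def choose_partitions(cohort: Cohort, splits) -> list[PartitionDecision]:
    """Evaluate Harris-Boyd for each candidate split, in input order.

    A split is ``("sex",)`` (males vs females) or ``("age", cut)`` (ages
    <= cut-1 vs >= cut on integer years).
    """
    df = cohort.data
    decisions = []
    for split in splits:
        kind = split[0]
        if kind == "sex":
            a = df.loc[df["sex"] == "M", "progrp"]
            b = df.loc[df["sex"] == "F", "progrp"]
            label = "sex:M|F"
        elif kind == "age":
            cut = int(split[1])
            a = df.loc[df["age"] < cut, "progrp"]
            b = df.loc[df["age"] >= cut, "progrp"]
            label = f"age:<{cut}|>={cut}"
        else:
            raise ValueError(f"unknown split kind {kind!r}")
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"split {label}: a stratum is empty or too small")
        decisions.append(
            harris_boyd(GroupSummary.from_values(a), GroupSummary.from_values(b), label=label)
        )
    return decisions


def decisions_to_json(decisions: list[PartitionDecision], path: str | Path | None = None) -> str:
    payload = [
        {"label": d.label, "z": d.z, "z_star": d.z_star, "partition": d.partition}
        for d in decisions
    ]
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def intervals_to_csv(intervals: list[ReferenceInterval], path: str | Path | None = None) -> str:
    lines = ["stratum,lower,url,ci90_low,ci90_high,n"]
    for ri in intervals:
        lines.append(f"{ri.label},{ri.lower:g},{ri.url:.4f},{ri.ci90_low:.4f},{ri.ci90_high:.4f},{ri.n}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
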