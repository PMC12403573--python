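"""Flagging-rate evaluation of reference-interval rules.

A URL rule — piecewise-constant (partitioned) or a continuous 97.5th
centile curve — is applied to a cohort and the fraction of results strictly
above the applicable URL is tabulated per age decade.  Because a reference
interval covers the central 95% of a healthy population, the one-sided
theoretical flagging rate is 2.5%; a rule whose observed per-decade rates
sit closer to 2.5% describes the population's age structure better.
Printed rates use round-half-up, matching laboratory-table conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rounding import rate_percent, round_half_up
from .cohort import Cohort
from .model import CentileCurve

__all__ = [
    "AgeBinning",
    "URLRule",
    "FlaggingReport",
    "flagging_table",
    "percent_change",
    "cohort_summary",
    "compare_rules",
]

THEORETICAL_RATE = 2.5


@dataclass(frozen=True)
class AgeBinning:
    """Closed integer-age decades; default 20-29 ... 70-80."""

    edges: tuple[int, ...] = (20, 30, 40, 50, 60, 70, 81)

    def __post_init__(self) -> None:
        if len(self.edges) < 2 or any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        return [f"{a}-{b - 1}" for a, b in zip(self.edges, self.edges[1:])]

    def assign(self, ages) -> np.ndarray:
        """Bin index per age; -1 when outside the span."""
        ages = np.asarray(ages)
        idx = np.searchsorted(np.asarray(self.edges), ages, side="right") - 1
        idx[(ages < self.edges[0]) | (ages > self.edges[-1] - 1)] = -1
        return idx


@dataclass(frozen=True)
class URLRule:
    """URL as a function of age: partitioned bands or a continuous curve."""

    kind: str  # "partitioned" | "continuous"
    bands: tuple[tuple[int, int, float], ...] = ()  # (age_lo, age_hi, url)
    curve: CentileCurve | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind == "partitioned":
            if not self.bands:
                raise ValueError("partitioned rule needs bands")
            spans = sorted(self.bands)
            for (a_lo, a_hi, _), nxt in zip(spans, spans[1:]):
                if nxt[0] != a_hi + 1:
                    raise ValueError("partitioned bands must tile the age span without gaps/overlap")
        elif self.kind == "continuous":
            if self.curve is None:
                raise ValueError("continuous rule needs a centile curve")
        else:
            raise ValueError(f"unknown rule kind {self.kind!r}")

    def url_at(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        if self.kind == "continuous":
            return np.asarray(self.curve(ages), dtype=float)
        out = np.full(ages.shape, np.nan)
        for a_lo, a_hi, url in self.bands:
            out[(ages >= a_lo) & (ages <= a_hi)] = url
        if np.isnan(out).any():
            missing = np.unique(ages[np.isnan(out)])[:5]
            raise ValueError(f"no URL band covers ages {missing}")
        return out


@dataclass
class FlaggingReport:
    """Per-decade flag counts for one URL rule; conserves totals."""

    rule_name: str
    binning: AgeBinning
    table: pd.DataFrame  # bin, n, flagged, rate_percent
    total_n: int
    total_flagged: int
    total_rate_percent: float

    def __post_init__(self) -> None:
        if self.table["n"].sum() != self.total_n or self.table["flagged"].sum() != self.total_flagged:
            raise AssertionError("flagging report does not conserve counts")

    def to_csv(self, path: str | Path | None = None) -> str:
        df = self.table.copy()
        total = pd.DataFrame(
            [{"bin": "total", "n": self.total_n, "flagged": self.total_flagged,
              "rate_percent": self.total_rate_percent}]
        )
        text = pd.concat([df, total], ignore_index=True).to_csv(index=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def flagging_table(cohort: Cohort, rule: URLRule, bins: AgeBinning | None = None) -> FlaggingReport:
    """Tabulate strict-exceedance flagging per age decade."""
    bins = bins or AgeBinning()
    ages = cohort.data["age"].to_numpy()
    idx = bins.assign(ages)
    if (idx < 0).any():
        bad = cohort.data.loc[idx < 0, "subject_id"].head(10).tolist()
        raise ValueError(f"records outside the binning span: {bad}")
    urls = rule.url_at(ages)
    flagged = cohort.values > urls  # strict: a value equal to the URL is inside the RI
    rows = []
    for b, label in enumerate(bins.labels):
        m = idx == b
        n_b, f_b = int(m.sum()), int(flagged[m].sum())
        rows.append(
            {"bin": label, "n": n_b, "flagged": f_b,
             "rate_percent": rate_percent(f_b, n_b) if n_b else float("nan")}
        )
    table = pd.DataFrame(rows)
    total_n, total_flagged = int(len(cohort)), int(flagged.sum())
    return FlaggingReport(
        rule_name=rule.name or rule.kind,
        binning=bins,
        table=table,
        total_n=total_n,
        total_flagged=total_flagged,
        total_rate_percent=rate_percent(total_flagged, total_n),
    )


def percent_change(a: float, b: float) -> float:
    """(b - a)/a * 100, rounded half-up to one decimal."""
    if a <= 0:
        raise ValueError("baseline must be > 0")
    return round_half_up((b - a) / a * 100.0, 1)


def cohort_summary(cohort: Cohort, bins: AgeBinning | None = None) -> pd.DataFrame:
    """Per (decade, sex) n / median / IQR table with per-sex totals.

    Quartiles use the linear (n-1)p convention shared across the package.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    bins = bins or AgeBinning()
    df = cohort.data
    idx = bins.assign(df["age"].to_numpy())
    rows = []
    for sex in ("M", "F"):
        for b, label in enumerate(bins.labels):
            v = df.loc[(idx == b) & (df["sex"] == sex), "progrp"].to_numpy()
            rows.append(_summary_row(label, sex, v))
        v = df.loc[df["sex"] == sex, "progrp"].to_numpy()
        rows.append(_summary_row("total", sex, v))
    return pd.DataFrame(rows)


def _summary_row(label, sex, v):
    if v.size == 0:
        return {"bin": label, "sex": sex, "n": 0, "median": float("nan"), "iqr": float("nan")}
    q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return {"bin": label, "sex": sex, "n": int(v.size), "median": float(q2), "iqr": float(q3 - q1)}


def compare_rules(report_a: FlaggingReport, report_b: FlaggingReport) -> dict:
    """Per-decade deviation from the theoretical 2.5% and the winning rule."""
    if list(report_a.table["bin"]) != list(report_b.table["bin"]):
        raise ValueError("reports use different binnings")
    if report_a.total_n != report_b.total_n:
        raise ValueError("reports cover different cohorts")
    bins_out = []
    for (_, ra), (_, rb) in zip(report_a.table.iterrows(), report_b.table.iterrows()):
        dev_a = abs(ra["rate_percent"] - THEORETICAL_RATE)
        dev_b = abs(rb["rate_percent"] - THEORETICAL_RATE)
        winner = "tie" if dev_a == dev_b else (report_a.rule_name if dev_a < dev_b else report_b.rule_name)
        bins_out.append(
            {"bin": ra["bin"], "rate_a": ra["rate_percent"], "rate_b": rb["rate_percent"],
             "deviation_a": round_half_up(dev_a, 2), "deviation_b": round_half_up(dev_b, 2),
             "winner": winner}
        )
    return {
        "rule_a": report_a.rule_name,
        "rule_b": report_b.rule_name,
        "bins": bins_out,
        "wins_a": sum(1 for r in bins_out if r["winner"] == report_a.rule_name),
        "wins_b": sum(1 for r in bins_out if r["winner"] == report_b.rule_name),
        "range_a": [float(report_a.table["rate_percent"].min()), float(report_a.table["rate_percent"].max())],
        "range_b": [float(report_b.table["rate_percent"].min()), float(report_b.table["rate_percent"].max())],
        "total_rate_a": report_a.total_rate_percent,
        "total_rate_b": report_b.total_rate_percent,
    }


def comparison_to_json(summary: dict, path: str | Path | None = None) -> str:
    text = json.dumps(summary, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
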