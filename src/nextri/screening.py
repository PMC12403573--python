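"""Eligibility screening and preprocessing.

Screening applies the study's eligibility funnel in a fixed rule order —
duplicates, residency, age window, NSE negativity, creatinine — attributing
each excluded record to the first rule it fails, so the ledger partitions
the input exactly.  NSE negativity is strict ``<`` (a value exactly at the
threshold is excluded); creatinine excludes strictly ``> 133`` umol/L.
Records with missing NSE/creatinine pass those rules.

Preprocessing follows the usual indirect-RI recipe: Lilliefors-corrected
Kolmogorov-Smirnov normality check, Box-Cox transform chosen by profile
maximum likelihood, and single-pass Tukey fences (k = 1.5) computed on the
transformed values of the full screened cohort.  Quartiles use linear
interpolation between order statistics at position (n-1)p.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from ._rounding import round_half_up
from .cohort import Cohort

__all__ = [
    "ScreeningConfig",
    "ScreeningLedger",
    "TransformResult",
    "OutlierMask",
    "screen_cohort",
    "ks_normality",
    "box_cox",
    "tukey_outliers",
    "remove_outliers",
]

RULE_ORDER = ["duplicate", "non_resident", "age", "nse", "creatinine"]


@dataclass(frozen=True)
class ScreeningConfig:
    age_min: int = 20
    age_max: int = 80
    nse_male_max: float = 16.4
    nse_female_under50_max: float = 14.47
    nse_female_50plus_max: float = 17.25
    creatinine_max: float = 133.0
    require_resident: bool = True
    drop_duplicates: bool = True

    def __post_init__(self) -> None:
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be < age_max")
        for name in ("nse_male_max", "nse_female_under50_max", "nse_female_50plus_max", "creatinine_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ScreeningLedger:
    """Per-rule exclusion counts; partitions the input exactly."""

    initial: int
    excluded: dict[str, int]
    retained: int
    retention_percent: float

    def __post_init__(self) -> None:
        if self.initial != self.retained + sum(self.excluded.values()):
            raise AssertionError("ledger does not conserve records")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "initial": self.initial,
            "excluded": {r: self.excluded.get(r, 0) for r in RULE_ORDER},
            "retained": self.retained,
            "retention_percent": self.retention_percent,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class TransformResult:
    """Box-Cox output: power, transformed values, optional pre-shift."""

    lambda_: float
    transformed: np.ndarray
    shift: float = 0.0


@dataclass
class OutlierMask:
    """Tukey-fence mask: flagged iff value outside [Q1 - k*IQR, Q3 + k*IQR]."""

    flags: np.ndarray
    lower_fence: float
    upper_fence: float
    k: float = 1.5


def screen_cohort(cohort: Cohort, config: ScreeningConfig | None = None) -> tuple[Cohort, ScreeningLedger]:
    """Apply the eligibility funnel; returns retained cohort and ledger."""
    config = config or ScreeningConfig()
    df = cohort.data
    if len(df) == 0:
        raise ValueError("cannot screen an empty cohort")
    n = len(df)
    reason = pd.Series(pd.NA, index=df.index, dtype="object")

    def mark(mask, rule):
        mask = mask & reason.isna()
        reason[mask] = rule

    if config.drop_duplicates:
        if "timestamp" in df.columns:
            keep = df.sort_values("timestamp", kind="stable").drop_duplicates("subject_id").index
            mark(~df.index.isin(keep), "duplicate")
        else:
            mark(df["subject_id"].duplicated(keep="first"), "duplicate")
    if config.require_resident:
        mark(~df["resident"].astype(bool), "non_resident")
    mark((df["age"] < config.age_min) | (df["age"] > config.age_max), "age")
    nse = df["nse"]
    thr = np.where(
        df["sex"] == "M",
        config.nse_male_max,
        np.where(df["age"] < 50, config.nse_female_under50_max, config.nse_female_50plus_max),
    )
    mark(nse.notna() & (nse.to_numpy() >= thr), "nse")
    crea = df["creatinine"]
    mark(crea.notna() & (crea > config.creatinine_max), "creatinine")

    retained_mask = reason.isna()
    excluded = {r: int((reason == r).sum()) for r in RULE_ORDER}
    retained = int(retained_mask.sum())
    ledger = ScreeningLedger(
        initial=n,
        excluded=excluded,
        retained=retained,
        retention_percent=round_half_up(retained / n * 100.0, 1),
    )
    out = cohort.subset(retained_mask.to_numpy(), provenance=cohort.provenance + "|screened")
    return out, ledger


def ks_normality(values) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality test with estimated mean/SD (Lilliefors).

    Requires n >= 5 and non-degenerate input; returns (statistic, p).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError(f"need at least 5 observations, got {values.size}")
    if np.ptp(values) == 0:
        raise ValueError("degenerate input: zero variance")
    stat, p = lilliefors(values, dist="norm", pvalmethod="approx")
    return float(stat), float(p)


def box_cox(values, lambda_: float | None = None) -> TransformResult:
    """Box-Cox transform; lambda by profile MLE unless forced.

    transformed = (y**lambda - 1)/lambda for lambda != 0, log(y) at 0.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if lambda_ is None:
        transformed, lam = stats.boxcox(values)
        return TransformResult(float(lam), np.asarray(transformed))
    return TransformResult(float(lambda_), stats.boxcox(values, lmbda=lambda_))


def tukey_outliers(values, k: float = 1.5) -> OutlierMask:
    """Single-pass Tukey fences under the (n-1)p linear quartile convention."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError(f"need at least 4 observations, got {values.size}")
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return OutlierMask(flags=(values < lo) | (values > hi), lower_fence=float(lo), upper_fence=float(hi), k=k)


def remove_outliers(cohort: Cohort, k: float = 1.5) -> tuple[Cohort, OutlierMask, TransformResult]:
    """Box-Cox the analyte, flag Tukey outliers once, drop them.

    The transform is fitted on the full screened cohort (not per stratum)
    and the fences are applied in transformed units; monotonicity of the
    transform means the same records would be extreme on the raw scale.
    """
    tr = box_cox(cohort.values)
    mask = tukey_outliers(tr.transformed, k=k)
    kept = cohort.subset(~mask.flags, provenance=cohort.provenance + "|outliers_removed")
    return kept, mask, tr
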