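"""Cohort container and CSV dialect.

A cohort is a table of subjects with columns
``subject_id,age,sex,progrp,nse,creatinine,resident``: integer age in years,
sex coded ``M``/``F``, ProGRP in pg/mL (strictly positive), optional NSE
(ug/L) and creatinine (umol/L) which may be missing, and a residency flag.
The CSV dialect writes missing optional values as empty fields and the
residency flag as ``1``/``0``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

COLUMNS = ["subject_id", "age", "sex", "progrp", "nse", "creatinine", "resident"]
SEXES = ("M", "F")


@dataclass
class Cohort:
    """Ordered collection of subject records plus a provenance note."""

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        self.data = df = df.loc[:, COLUMNS].reset_index(drop=True)
        if df["subject_id"].duplicated().any() and self.provenance != "unscreened":
            # duplicates are only legal in raw (unscreened) input
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].head(3).tolist()
            raise ValueError(f"duplicate subject_id values: {dupes}...")
        if len(df) and (df["progrp"] <= 0).any():
            raise ValueError("progrp values must be strictly positive")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ages(self) -> np.ndarray:
        return self.data["age"].to_numpy(dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.data["progrp"].to_numpy(dtype=float)

    def to_csv(self, path: str | Path | None = None) -> str | None:
        df = self.data.copy()
        df["resident"] = df["resident"].astype(bool).astype(int)
        if path is None:
            buf = io.StringIO()
            df.to_csv(buf, index=False)
            return buf.getvalue()
        df.to_csv(path, index=False)
        return None

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str | None = None) -> "Cohort":
        df = pd.read_csv(
            path,
            dtype={"subject_id": str, "age": int, "sex": str},
        )
        df["resident"] = df["resident"].map(_parse_bool)
        return cls(df, provenance=provenance if provenance is not None else str(path))

    def subset(self, mask, provenance: str | None = None) -> "Cohort":
        prov = provenance if provenance is not None else self.provenance
        return Cohort(self.data.loc[mask].reset_index(drop=True), provenance=prov)


def _parse_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "t", "yes")
    return bool(v)
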