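import numpy as np
import pandas as pd
import pytest

from nextri.cohort import Cohort
from nextri.simulate import default_config, generate_cohort


@pytest.fixture(scope="session")
def study_config():
    """Default generator settings: Table-1 group structure, seed 7."""
    return default_config(seed=7)


@pytest.fixture(scope="session")
def study_cohort(study_config):
    return generate_cohort(study_config)


@pytest.fixture(scope="session")
def fitted_study_model(study_cohort):
    """The centile model fitted once on the default cohort (edf 5)."""
    from nextri.model import BCPECentileModel

    return BCPECentileModel.from_cohort(study_cohort).fit(target_edf=5.0)


def make_cohort(ages, values, sexes=None, **extra):
    """Small hand-built cohort for unit tests."""
    n = len(ages)
    df = pd.DataFrame(
        {
            "subject_id": extra.pop("subject_id", [f"T{i:04d}" for i in range(n)]),
            "age": np.asarray(ages, dtype=int),
            "sex": sexes if sexes is not None else ["M"] * n,
            "progrp": np.asarray(values, dtype=float),
            "nse": extra.pop("nse", [np.nan] * n),
            "creatinine": extra.pop("creatinine", [np.nan] * n),
            "resident": extra.pop("resident", [True] * n),
        }
    )
    return Cohort(df, provenance=extra.pop("provenance", "unscreened"))
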