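import numpy as np
import pandas as pd
import pytest

from mediassoc.io import load_reference_tables
from mediassoc.types import RECORD_COLUMNS


@pytest.fixture(scope="session")
def tables():
    """Shipped per-stratum genotype count tables, keyed by (label, stratum)."""
    return {(t.label, t.stratum): t for t in load_reference_tables()}


def make_records(
    dosage,
    status=None,
    cpd=None,
    age=None,
    sex=None,
    smoking_status=None,
    duration_years=None,
    family_history=None,
):
    """Build a canonical records frame from plain arrays (defaults filled in)."""
    dosage = np.asarray(dosage)
    n = len(dosage)

    def col(value, default):
        if value is None:
            return default
        arr = np.asarray(value, dtype=object)
        return arr if arr.shape else np.full(n, value, dtype=object)

    df = pd.DataFrame(
        {
            "id": [f"T{i:05d}" for i in range(n)],
            "status": col(status, np.full(n, "case", dtype=object)),
            "dosage": dosage.astype(int),
            "age": col(age, np.full(n, 60.0)),
            "sex": col(sex, np.full(n, "female", dtype=object)),
            "smoking_status": col(smoking_status, np.full(n, "current", dtype=object)),
            "cpd": col(cpd, np.full(n, np.nan)),
            "duration_years": col(duration_years, np.full(n, np.nan)),
            "family_history": col(family_history, np.full(n, None, dtype=object)),
        }
    )
    for c in ("age", "cpd", "duration_years"):
        df[c] = pd.to_numeric(df[c])
    return df[list(RECORD_COLUMNS)]
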