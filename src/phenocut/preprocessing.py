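"""Derived indices, WHO BMI classification, normality testing and exclusions.

Implements the standard clinical derivations used before clustering: mean
arterial pressure (MAP), WHO BMI categories, the Friedewald lipid formulas,
Geary's normality test (ratio of mean absolute deviation to standard
deviation), conditional log-transformation of skewed columns, and the
cohort-level exclusion rules (diabetes under treatment, undetermined serum
insulin).
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FriedewaldInvalid",
    "mean_arterial_pressure",
    "classify_bmi",
    "classify_bmi_series",
    "friedewald",
    "geary_test",
    "log_transform_if_nonnormal",
    "apply_exclusions",
    "derive_columns",
]

BMI_CLASSES = ("underweight", "normal", "overweight", "obese_1", "obese_2",
               "obese_3")

#: left-closed WHO BMI band edges (kg/m²)
_BMI_EDGES = (18.5, 25.0, 30.0, 35.0, 40.0)


class FriedewaldInvalid(ValueError):
    """Triglycerides above 400 mg/dL: the Friedewald formula does not apply."""


def mean_arterial_pressure(sbp, dbp):
    """MAP = DBP + (SBP − DBP)/3, in mmHg.

    Accepts scalars or arrays; systolic must be >= diastolic > 0.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if np.any(dbp <= 0):
        raise ValueError("diastolic pressure must be positive")
    if np.any(sbp < dbp):
        raise ValueError("systolic pressure must be >= diastolic pressure")
    out = dbp + (sbp - dbp) / 3.0
    return float(out) if out.ndim == 0 else out


def classify_bmi(bmi: float) -> str:
    """WHO BMI category for a single value; bands are left-closed."""
    if not bmi > 0:
        raise ValueError(f"bmi must be positive, got {bmi}")
    idx = int(np.searchsorted(_BMI_EDGES, bmi, side="right"))
    return BMI_CLASSES[idx]


def classify_bmi_series(bmi) -> pd.Series:
    """Vectorized :func:`classify_bmi`."""
    arr = np.asarray(bmi, dtype=float)
    if np.any(~(arr > 0)):
        raise ValueError("bmi must be positive")
    idx = np.searchsorted(_BMI_EDGES, arr, side="right")
    return pd.Series(np.take(BMI_CLASSES, idx), index=getattr(bmi, "index", None))


def friedewald(tchol, hdl, tag):
    """LDL and VLDL (mg/dL) from total cholesterol, HDL-C and triglycerides.

    VLDL = TAG/5 and LDL = TC − HDL − VLDL; only valid for TAG <= 400 mg/dL
    (beyond that, lipoprotein fractions must be measured directly).
    """
    tchol = np.asarray(tchol, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tag = np.asarray(tag, dtype=float)
    if np.any(tag > 400.0):
        raise FriedewaldInvalid("triglycerides exceed 400 mg/dL")
    vldl = tag / 5.0
    ldl = tchol - hdl - vldl
    if ldl.ndim == 0:
        return float(ldl), float(vldl)
    return ldl, vldl


def geary_test(values) -> tuple[float, float, float]:
    """Geary's normality test.

    The statistic is ``a`` = mean absolute deviation / population standard
    deviation.  Under normality E[a] = sqrt(2/pi) with asymptotic standard
    deviation 0.2123/sqrt(n); returns ``(a, z, p)`` with a two-sided normal
    p-value.  Requires n >= 8 and nonzero variance.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 8:
        raise ValueError(f"geary_test requires n >= 8, got {n}")
    mu = x.mean()
    sd = x.std()  # population SD
    if sd == 0:
        raise ValueError("geary_test undefined for zero-variance sample")
    a = np.abs(x - mu).mean() / sd
    z = (a - math.sqrt(2.0 / math.pi)) / (0.2123 / math.sqrt(n))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(a), float(z), float(p)


def log_transform_if_nonnormal(
    df: pd.DataFrame, columns: Iterable[str], alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Replace skewed columns by their natural log.

    Each listed column is Geary-tested; when the test rejects normality at
    ``alpha`` the column is replaced by ``log(x)`` (requiring all values
    strictly positive) and re-tested.  Returns the new frame and a transform
    log ``{column: {"transformed", "p_before", "p_after"}}``.
    """
    out = df.copy()
    log: dict[str, dict] = {}
    for col in columns:
        _, _, p_before = geary_test(out[col].to_numpy())
        entry = {"transformed": False, "p_before": p_before, "p_after": None}
        if p_before < alpha:
            vals = out[col].to_numpy(dtype=float)
            if np.any(~(vals > 0)):
                raise ValueError(
                    f"column {col!r} selected for log transform has "
                    f"non-positive values"
                )
            out[col] = np.log(vals)
            _, _, p_after = geary_test(out[col].to_numpy())
            entry.update(transformed=True, p_after=p_after)
        log[col] = entry
    return out, log


def apply_exclusions(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop rows flagged diabetic or with undetermined insulin.

    Per-reason counts may overlap when a row carries both flags; the total
    counts each excluded row once.
    """
    diabetic = df["diabetes_flag"].astype(bool)
    no_insulin = df["insulin_missing"].astype(bool)
    either = diabetic | no_insulin
    counts = {
        "diabetes": int(diabetic.sum()),
        "insulin_missing": int(no_insulin.sum()),
        "excluded_total": int(either.sum()),
    }
    return df.loc[~either].copy(), counts


def derive_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Attach MAP, BMI class and lipid-derived columns to a cohort table."""
    out = df.copy()
    out["map"] = mean_arterial_pressure(out["sbp"].to_numpy(),
                                        out["dbp"].to_numpy())
    out["bmi_class"] = classify_bmi_series(out["bmi"])
    out["non_hdl"] = out["tchol"] - out["hdl"]
    out["tag_hdl_ratio"] = out["tag"] / out["hdl"]
    # Friedewald only where applicable; rows above 400 mg/dL stay NaN-flagged
    valid = out["tag"] <= 400.0
    vldl = np.where(valid, out["tag"] / 5.0, np.nan)
    out["vldl"] = vldl
    out["ldl"] = np.where(valid, out["tchol"] - out["hdl"] - vldl, np.nan)
    out["friedewald_invalid"] = ~valid
    return out
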