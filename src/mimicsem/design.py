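"""Structural-model design matrix built from raw covariate columns.

Coding conventions: female = 1, Nagasaki = 1, distal (>3 km) = 1,
city-by-distal product term, smoking as two dummies with never-smokers as
the reference, age centered at the sample mean with the quadratic term
computed *after* centering, dose in weighted Gy untransformed.
"""

from __future__ import annotations

import pandas as pd

from . import names as N


def build_design(df: pd.DataFrame, age_center: float | None = None) -> pd.DataFrame:
    """Design columns for the structural model from raw covariates.

    Parameters
    ----------
    df : table with the raw covariate columns (age, sex, city, location,
        smoking, weighted dose)
    age_center : value to center age at; defaults to the sample mean of the
        supplied table. The value used is recorded in ``out.attrs``.

    Returns
    -------
    DataFrame with the columns in :data:`mimicsem.names.COVARIATES`.
    """
    if age_center is None:
        age_center = float(df[N.AGE_EXAM].mean())
    age_c = df[N.AGE_EXAM] - age_center
    nagasaki = (df[N.CITY].str.lower() == "nagasaki").astype(float)
    distal = (df[N.LOCATION_ATB].str.lower() == "distal").astype(float)
    out = pd.DataFrame(
        {
            N.DOSE: df[N.DOSE_WGY].astype(float),
            N.AGE_C: age_c,
            N.AGE_C2: age_c**2,
            N.FEMALE: (df[N.SEX].str.lower() == "female").astype(float),
            N.NAGASAKI: nagasaki,
            N.DISTAL: distal,
            N.NAGASAKI_X_DISTAL: nagasaki * distal,
            N.SMK_CURRENT: (df[N.SMOKING] == "current").astype(float),
            N.SMK_PAST: (df[N.SMOKING] == "past").astype(float),
        },
        index=df.index,
    )
    out.attrs["age_center"] = age_center
    return out


def attach_design(df: pd.DataFrame, age_center: float | None = None) -> pd.DataFrame:
    """Return ``df`` with the design columns appended (existing ones replaced)."""
    design = build_design(df, age_center=age_center)
    out = df.drop(columns=[c for c in design.columns if c in df.columns]).join(design)
    out.attrs.update(df.attrs)
    out.attrs["age_center"] = design.attrs["age_center"]
    return out
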