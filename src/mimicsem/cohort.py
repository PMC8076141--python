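"""Cohort preparation: derivations, eligibility exclusions, validity filters.

Turns a raw participant table (one row per invited person, with covariates,
exclusion flags, surgery-site flags and 14 clinical indicators) into the
analysis table consumed by the SEM engine. The steps are, in order:

1. eligibility exclusions (hemodialysis, refusers, in-utero exposure,
   missing radiation dose, missing smoking information), with a reconciled
   exclusion log;
2. side-specific validity masking (implausible ankle-brachial index values,
   pulse-wave velocity invalidated by low same-side ABI, measurements
   affected by prior vascular surgery);
3. rescaling of selected indicators to the scale on which the model is fit
   (ABI multiplied by 10; brachial-ankle PWV carried in m/s).

Missing indicator values are encoded as NaN throughout and never removed:
the downstream estimator handles them by full-information maximum
likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import names as N

#: Multiplicative factors applied by :func:`rescale_indicators`.
RESCALE_FACTORS: dict[str, float] = {N.ABI_L: 10.0, N.ABI_R: 10.0}

#: df.attrs key recording whether indicators are on the natural or fitting scale.
SCALE_ATTR = "indicator_scale"

ABI_UPPER_LIMIT = 1.4  # ABI above this is considered an invalid measurement
ABI_LOWER_LIMIT = 0.9  # baPWV is invalid when same-side ABI is below this

#: Indicators masked for each surgery site.
SURGERY_MASKS: dict[str, tuple[str, ...]] = {
    N.SURGERY_CAROTID: (N.IMT_CCA_L, N.IMT_CCA_R, N.IMT_ICA_L, N.IMT_ICA_R),
    N.SURGERY_PERIPHERAL: (N.ABI_L, N.ABI_R, N.UT_L, N.UT_R, N.BAPWV_L, N.BAPWV_R, N.AI, N.CSBP),
    N.SURGERY_AORTA: (
        N.ABI_L,
        N.ABI_R,
        N.UT_L,
        N.UT_R,
        N.BAPWV_L,
        N.BAPWV_R,
        N.AI,
        N.CSBP,
        N.THORACIC_CALC,
        N.ABDOMINAL_CALC,
    ),
}

# Eligibility exclusion reasons in application order.
EXCLUSION_ORDER = ("hemodialysis", "refuser", "in_utero", "missing_dose", "missing_smoking")


def weighted_dose(gamma: float, neutron: float) -> float:
    """Weighted skin dose in Gy: gamma dose plus ten times the neutron dose.

    The factor 10 is the conventional relative biological effectiveness
    weight for the (smaller) neutron component in atomic-bomb dosimetry.
    """
    gamma = np.asarray(gamma, dtype=float)
    neutron = np.asarray(neutron, dtype=float)
    if np.any(gamma < 0) or np.any(neutron < 0):
        raise ValueError("dose components must be non-negative")
    out = gamma + 10.0 * neutron
    return float(out) if out.ndim == 0 else out


def classify_smoking(history: list[tuple[int, bool]]) -> str:
    """Classify a smoking report history into never / current / past.

    ``history`` is a list of ``(year, smoking_reported)`` entries from
    periodic surveys. "Current" means any positive report during the
    examination window 2010-2014; "past" means a positive report in
    1963-2010 but none in 2010-2014; "never" otherwise (including an
    empty history).
    """
    for year, _ in history:
        if not 1963 <= year <= 2014:
            raise ValueError(f"survey year {year} outside 1963-2014")
    if any(flag for year, flag in history if 2010 <= year <= 2014):
        return "current"
    if any(flag for year, flag in history if year < 2010):
        return "past"
    return "never"


def abdominal_score(grades) -> int:
    """Total abdominal aortic calcification score: sum of eight region grades.

    Each of the eight aortic-wall regions (anterior/posterior at L1-L4) is
    graded 0-3; the total score therefore ranges 0-24.
    """
    grades = list(grades)
    if len(grades) != 8:
        raise ValueError(f"expected 8 region grades, got {len(grades)}")
    for g in grades:
        if g not in (0, 1, 2, 3):
            raise ValueError(f"grade {g!r} not in {{0, 1, 2, 3}}")
    return int(sum(grades))


@dataclass
class ExclusionLog:
    """Accounting of eligibility exclusions in application order."""

    n_invited: int = 0
    counts: dict[str, int] = field(default_factory=dict)
    ids: dict[str, list] = field(default_factory=dict)
    n_analyzed: int = 0

    def reconcile(self) -> bool:
        """True when invited minus all exclusions equals analyzed."""
        return self.n_invited - sum(self.counts.values()) == self.n_analyzed

    def to_frame(self) -> pd.DataFrame:
        rows = [("invited", self.n_invited)]
        remaining = self.n_invited
        for reason in EXCLUSION_ORDER:
            c = self.counts.get(reason, 0)
            remaining -= c
            rows.append((f"excluded: {reason}", c))
        rows.append(("analyzed", remaining))
        return pd.DataFrame(rows, columns=["step", "n"])


def apply_eligibility(raw: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Remove ineligible records and log the arithmetic invited -> analyzed.

    Exclusions, in order: known hemodialysis (a pre-invitation criterion,
    kept here as a guard), refusers, participants exposed in utero, then
    records with missing radiation dose and missing smoking information.
    """
    log = ExclusionLog(n_invited=len(raw))
    df = raw
    masks = {
        "hemodialysis": df.get(N.HEMODIALYSIS, pd.Series(False, index=df.index)).fillna(False).astype(bool),
        "refuser": df.get(N.REFUSER, pd.Series(False, index=df.index)).fillna(False).astype(bool),
        "in_utero": df.get(N.IN_UTERO, pd.Series(False, index=df.index)).fillna(False).astype(bool),
    }
    for reason in ("hemodialysis", "refuser", "in_utero"):
        m = masks[reason].loc[df.index]
        log.counts[reason] = int(m.sum())
        log.ids[reason] = list(df.loc[m, N.ID]) if N.ID in df else list(df.index[m])
        df = df.loc[~m]
    m_dose = df[N.DOSE_WGY].isna()
    log.counts["missing_dose"] = int(m_dose.sum())
    log.ids["missing_dose"] = list(df.loc[m_dose, N.ID]) if N.ID in df else list(df.index[m_dose])
    df = df.loc[~m_dose]
    m_smk = df[N.SMOKING].isna() | (df[N.SMOKING] == "unknown")
    log.counts["missing_smoking"] = int(m_smk.sum())
    log.ids["missing_smoking"] = list(df.loc[m_smk, N.ID]) if N.ID in df else list(df.index[m_smk])
    df = df.loc[~m_smk].copy()
    log.n_analyzed = len(df)
    df.attrs[SCALE_ATTR] = raw.attrs.get(SCALE_ATTR, "natural")
    return df, log


def apply_validity_filters(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask physiologically invalid or surgery-affected measurements.

    Rules (side-specific, applied to the measured pre-mask values, so the
    operation is idempotent and order-stable):

    - ABI on a side is masked when it exceeds 1.4 (implausible reading);
    - baPWV on a side is masked when the *measured* same-side ABI is
      below 0.9 (pulse-wave timing unreliable in obstructed limbs);
    - prior carotid surgery masks the four IMT values; peripheral-artery
      surgery masks ABI, UT, baPWV, AI and cSBP; aortic surgery masks
      those plus both calcification scores.

    Returns the filtered table and a log of masked counts per rule.
    Record count is unchanged; masking never un-masks.
    """
    df = cohort.copy()
    log_rows: list[tuple[str, str, int]] = []

    for abi_col, pwv_col in ((N.ABI_L, N.BAPWV_L), (N.ABI_R, N.BAPWV_R)):
        abi_vals = df[abi_col]
        high = abi_vals > ABI_UPPER_LIMIT
        low = abi_vals < ABI_LOWER_LIMIT
        # the two rules key on opposite tails of the same measured value,
        # so masking ABI first cannot hide a low value from the baPWV rule
        df.loc[high, abi_col] = np.nan
        n_pwv = int((low & df[pwv_col].notna()).sum())
        df.loc[low, pwv_col] = np.nan
        log_rows.append((f"abi_gt_{ABI_UPPER_LIMIT}", abi_col, int(high.sum())))
        log_rows.append((f"abi_lt_{ABI_LOWER_LIMIT}", pwv_col, n_pwv))

    for flag, cols in SURGERY_MASKS.items():
        m = df.get(flag, pd.Series(False, index=df.index)).fillna(False).astype(bool)
        for col in cols:
            n = int((m & df[col].notna()).sum())
            df.loc[m, col] = np.nan
            log_rows.append((flag, col, n))

    log = pd.DataFrame(log_rows, columns=["rule", "indicator", "n_masked"])
    df.attrs[SCALE_ATTR] = cohort.attrs.get(SCALE_ATTR, "natural")
    return df, log


def rescale_indicators(cohort: pd.DataFrame, bapwv_unit: str = "m/s") -> pd.DataFrame:
    """Rescale indicators to the fitting scale (ABI x 10; baPWV in m/s).

    ABI is multiplied by 10 so its variance is commensurate with the other
    indicators, which helps optimizer conditioning. baPWV is modeled in
    m/s; instruments report cm/s, so pass ``bapwv_unit='cm/s'`` to divide
    by 100 on ingestion. Missing values stay missing. A scale flag stored
    in ``df.attrs`` makes double application an error;
    :func:`unscale_indicators` inverts the transform.
    """
    if cohort.attrs.get(SCALE_ATTR, "natural") == "fitting":
        raise ValueError("indicators are already on the fitting scale")
    if bapwv_unit not in ("m/s", "cm/s"):
        raise ValueError(f"unknown baPWV unit {bapwv_unit!r}")
    df = cohort.copy()
    for col, factor in RESCALE_FACTORS.items():
        df[col] = df[col] * factor
    if bapwv_unit == "cm/s":
        for col in (N.BAPWV_L, N.BAPWV_R):
            df[col] = df[col] / 100.0
    df.attrs[SCALE_ATTR] = "fitting"
    return df


def unscale_indicators(cohort: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`rescale_indicators` (back to the natural scale)."""
    if cohort.attrs.get(SCALE_ATTR, "natural") != "fitting":
        raise ValueError("indicators are not on the fitting scale")
    df = cohort.copy()
    for col, factor in RESCALE_FACTORS.items():
        df[col] = df[col] / factor
    df.attrs[SCALE_ATTR] = "natural"
    return df


def natural_scale_factor(indicator: str) -> float:
    """Factor converting a fitting-scale effect back to natural units."""
    return 1.0 / RESCALE_FACTORS.get(indicator, 1.0)


def prepare_cohort(
    raw: pd.DataFrame, bapwv_unit: str = "m/s"
) -> tuple[pd.DataFrame, ExclusionLog, pd.DataFrame]:
    """Run the full preparation chain: eligibility -> validity -> rescale."""
    eligible, excl_log = apply_eligibility(raw)
    filtered, validity_log = apply_validity_filters(eligible)
    prepared = rescale_indicators(filtered, bapwv_unit=bapwv_unit)
    return prepared, excl_log, validity_log


def write_cohort_csv(cohort: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write a cohort table as CSV with empty-string missing markers.

    A comment header records the generating seed and the indicator scale so
    round-trips preserve the double-rescale guard.
    """
    with open(path, "w") as fh:
        scale = cohort.attrs.get(SCALE_ATTR, "natural")
        fh.write(f"# mimicsem cohort; scale={scale}; seed={seed}\n")
        cohort.to_csv(fh, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv`."""
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    scale = "natural"
    for part in header.strip("#\n ").split(";"):
        key, _, value = part.strip().partition("=")
        if key == "scale":
            scale = value
    df.attrs[SCALE_ATTR] = scale
    return df
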