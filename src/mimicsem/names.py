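"""Canonical column names for indicators, covariates, and factors.

Every module addresses the cohort table through these constants, so a single
renaming here propagates through the generator, the cleaning rules, the SEM
engine and the reports.
"""

from __future__ import annotations

# The 14 clinical indicators, in the fixed order used by the measurement model.
BAPWV_L = "bapwv_l"
BAPWV_R = "bapwv_r"
AI = "ai"
CSBP = "csbp"
THORACIC_CALC = "thoracic_calc"
ABDOMINAL_CALC = "abdominal_calc"
IMT_CCA_L = "imt_cca_l"
IMT_CCA_R = "imt_cca_r"
IMT_ICA_L = "imt_ica_l"
IMT_ICA_R = "imt_ica_r"
ABI_L = "abi_l"
ABI_R = "abi_r"
UT_L = "ut_l"
UT_R = "ut_r"

INDICATORS: tuple[str, ...] = (
    BAPWV_L,
    BAPWV_R,
    AI,
    CSBP,
    THORACIC_CALC,
    ABDOMINAL_CALC,
    IMT_CCA_L,
    IMT_CCA_R,
    IMT_ICA_L,
    IMT_ICA_R,
    ABI_L,
    ABI_R,
    UT_L,
    UT_R,
)

# Latent atherosclerotic pathologies.
STIFFNESS = "stiffness"
CALCIFICATION = "calcification"
PLAQUE = "plaque"
FACTORS: tuple[str, ...] = (STIFFNESS, CALCIFICATION, PLAQUE)

# Which indicators load on which factor.
FACTOR_INDICATORS: dict[str, tuple[str, ...]] = {
    STIFFNESS: (BAPWV_L, BAPWV_R, AI, CSBP),
    CALCIFICATION: (THORACIC_CALC, ABDOMINAL_CALC),
    PLAQUE: (IMT_CCA_L, IMT_CCA_R, IMT_ICA_L, IMT_ICA_R, ABI_L, ABI_R, UT_L, UT_R),
}

# Design-matrix columns for the structural model (dose in weighted Gy, age
# centered at the sample mean, age squared computed after centering, dummy
# codings: female=1, Nagasaki=1, distal=1, never-smoker as reference).
DOSE = "dose"
AGE_C = "age_c"
AGE_C2 = "age_c2"
FEMALE = "female"
NAGASAKI = "nagasaki"
DISTAL = "distal"
NAGASAKI_X_DISTAL = "nagasaki_x_distal"
SMK_CURRENT = "smk_current"
SMK_PAST = "smk_past"

COVARIATES: tuple[str, ...] = (
    DOSE,
    AGE_C,
    AGE_C2,
    FEMALE,
    NAGASAKI,
    DISTAL,
    NAGASAKI_X_DISTAL,
    SMK_CURRENT,
    SMK_PAST,
)

# Covariate sets per latent factor.
FACTOR_COVARIATES: dict[str, tuple[str, ...]] = {
    STIFFNESS: (DOSE, AGE_C, NAGASAKI, DISTAL, NAGASAKI_X_DISTAL),
    CALCIFICATION: (
        DOSE,
        AGE_C,
        AGE_C2,
        FEMALE,
        NAGASAKI,
        DISTAL,
        NAGASAKI_X_DISTAL,
        SMK_CURRENT,
        SMK_PAST,
    ),
    PLAQUE: (DOSE, AGE_C, NAGASAKI, DISTAL, NAGASAKI_X_DISTAL, SMK_CURRENT, SMK_PAST),
}

# Residual (measurement-error) correlations retained in the final model.
RESIDUAL_CORR_PAIRS: tuple[tuple[str, str], ...] = (
    (AI, CSBP),
    (IMT_CCA_L, IMT_CCA_R),
    (ABI_L, ABI_R),
    (UT_L, UT_R),
)

# The single direct covariate-to-indicator path in the final model.
DIRECT_PATHS: tuple[tuple[str, str], ...] = ((FEMALE, AI),)

# Raw-cohort bookkeeping columns.
ID = "id"
SUBCOHORT = "subcohort"
AGE_EXAM = "age_exam"
AGE_EXPOSURE = "age_exposure"
SEX = "sex"
CITY = "city"
LOCATION_ATB = "location_atb"
SMOKING = "smoking"
DOSE_GAMMA = "dose_gamma"
DOSE_NEUTRON = "dose_neutron"
DOSE_WGY = "dose_wgy"
IN_UTERO = "in_utero"
REFUSER = "refuser"
HEMODIALYSIS = "hemodialysis"
SURGERY_CAROTID = "surgery_carotid"
SURGERY_PERIPHERAL = "surgery_peripheral"
SURGERY_AORTA = "surgery_aorta"

COVARIATE_RAW_COLUMNS: tuple[str, ...] = (
    ID,
    SUBCOHORT,
    AGE_EXAM,
    AGE_EXPOSURE,
    SEX,
    CITY,
    LOCATION_ATB,
    SMOKING,
    DOSE_GAMMA,
    DOSE_NEUTRON,
    DOSE_WGY,
    IN_UTERO,
    REFUSER,
    HEMODIALYSIS,
    SURGERY_CAROTID,
    SURGERY_PERIPHERAL,
    SURGERY_AORTA,
)

LEFT_RIGHT_PAIRS: dict[str, tuple[str, str]] = {
    "bapwv": (BAPWV_L, BAPWV_R),
    "imt_cca": (IMT_CCA_L, IMT_CCA_R),
    "imt_ica": (IMT_ICA_L, IMT_ICA_R),
    "abi": (ABI_L, ABI_R),
    "ut": (UT_L, UT_R),
}
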