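"""Synthetic cohort generator: calibration, determinism, missingness,
discretization, configuration validation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mimicsem import names as N
from mimicsem.cohort import apply_validity_filters, prepare_cohort
from mimicsem.simulate import (
    GeneratingParameters,
    GeneratorConfig,
    abdominal_region_grades,
    assemble_raw_population,
    gen_covariates,
    gen_outcomes,
    impose_missingness_and_artifacts,
)


# -- covariates -------------------------------------------------------------
def test_stratum_counts_are_exact(default_config):
    cov = gen_covariates(default_config, seed=1)
    counts = cov["stratum"].value_counts().sort_index()
    assert tuple(counts) == default_config.stratum_counts
    assert len(cov) == default_config.n_total


def test_all_female_degenerate_proportion(default_config):
    cfg = dataclasses.replace(default_config, female_prop=(1.0,) * 5)
    cov = gen_covariates(cfg, seed=2)
    assert (cov[N.SEX] == "female").all()


def test_distal_only_in_lowest_stratum(default_config):
    cov = gen_covariates(default_config, seed=3)
    distal = cov[cov[N.LOCATION_ATB] == "distal"]
    assert (distal["stratum"] == 1).all()
    assert len(distal) > 0


def test_grand_mean_dose_calibration(default_config):
    """Monte-Carlo check against the configured stratum means/counts: the
    overall mean dose should sit within 3 SE of 0.301 weighted Gy."""
    target = float(np.average(default_config.stratum_mean_doses,
                              weights=default_config.stratum_counts))
    se = 0.65 / np.sqrt(default_config.n_total)  # published SD over sqrt(n)
    means = [gen_covariates(default_config, seed=s)[N.DOSE_WGY].mean()
             for s in range(6)]
    for m in means:
        assert abs(m - target) < 3 * se
    assert abs(np.mean(means) - target) < 2 * se


def test_stratum_dose_means_and_zero_mass(default_config):
    cov = gen_covariates(default_config, seed=4)
    assert int((cov[N.DOSE_WGY] == 0).sum()) == default_config.n_zero_dose
    for s, (m, n_s) in enumerate(zip(default_config.stratum_mean_doses,
                                     default_config.stratum_counts), start=1):
        sub = cov.loc[cov["stratum"] == s, N.DOSE_WGY]
        lo, hi = default_config.stratum_bounds[s - 1]
        assert sub.min() >= lo and sub.max() <= min(hi, default_config.max_dose)
        assert abs(sub.mean() - m) < 4 * sub.std() / np.sqrt(n_s) + 1e-9
    assert cov[N.DOSE_WGY].max() <= default_config.max_dose


def test_subcohort_mixture_age_dose_confounding(default_config):
    cov = gen_covariates(default_config, seed=5)
    exp = cov[cov[N.SUBCOHORT] == "expansion"]
    pri = cov[cov[N.SUBCOHORT] == "primary"]
    assert len(exp) == default_config.n_expansion == 1703
    assert exp[N.AGE_EXAM].mean() < pri[N.AGE_EXAM].mean() - 5
    assert exp[N.DOSE_WGY].mean() == pytest.approx(0.096, abs=0.01)
    assert pri[N.DOSE_WGY].mean() == pytest.approx(0.52, abs=0.02)
    assert cov[[N.DOSE_WGY, N.AGE_EXAM]].corr().iloc[0, 1] > 0.1


def test_weighted_dose_components_consistent(default_config):
    cov = gen_covariates(default_config, seed=6)
    np.testing.assert_allclose(
        cov[N.DOSE_GAMMA] + 10 * cov[N.DOSE_NEUTRON], cov[N.DOSE_WGY], rtol=1e-9
    )


# -- outcomes ---------------------------------------------------------------
def test_null_generating_model_gives_independent_noise(default_config):
    params = GeneratingParameters(
        loadings={k: 0.0 for k in GeneratingParameters().loadings},
        structural={k: 0.0 for k in GeneratingParameters().structural},
        residual_corr={},
        direct={},
    )
    cov = gen_covariates(default_config, seed=7)
    out = gen_outcomes(cov, params, seed=8, config=default_config)
    cont = [i for i in N.INDICATORS if i not in (N.THORACIC_CALC, N.ABDOMINAL_CALC)]
    for ind in cont:
        mu, sd = default_config.indicator_means_sds[ind]
        assert out[ind].mean() == pytest.approx(mu, abs=4 * sd / np.sqrt(3274))
        assert out[ind].std() == pytest.approx(sd, rel=0.05)
    corr = out[cont].corr().to_numpy()
    off = corr[~np.eye(len(cont), dtype=bool)]
    assert np.abs(off).max() < 0.08


def test_ut_pair_correlation_matches_model_implied(default_config):
    """Sample left/right upstroke-time correlation approximates
    lambda_L*lambda_R + r*sqrt((1-lambda_L^2)(1-lambda_R^2))."""
    params = GeneratingParameters()
    lam_l = params.loadings[(N.UT_L, N.PLAQUE)]
    lam_r = params.loadings[(N.UT_R, N.PLAQUE)]
    r = params.residual_corr[(N.UT_L, N.UT_R)]
    implied = lam_l * lam_r + r * np.sqrt((1 - lam_l**2) * (1 - lam_r**2))
    cov = gen_covariates(default_config, seed=9)
    out = gen_outcomes(cov, params, seed=10, config=default_config)
    sample = out[[N.UT_L, N.UT_R]].corr().iloc[0, 1]
    assert sample == pytest.approx(implied, abs=0.03)


def test_calcification_marginals_match_calibration(default_config):
    cov = gen_covariates(default_config, seed=11)
    out = gen_outcomes(cov, GeneratingParameters(), seed=12, config=default_config)
    thor = out[N.THORACIC_CALC]
    abd = out[N.ABDOMINAL_CALC]
    assert set(np.unique(thor)) <= {0.0, 1.0, 2.0, 3.0}
    assert abd.min() >= 0 and abd.max() <= 24
    assert thor.mean() == pytest.approx(1.12, abs=0.06)
    assert thor.std() == pytest.approx(0.81, abs=0.05)
    assert abd.mean() == pytest.approx(4.71, abs=0.4)
    assert abd.std() == pytest.approx(5.04, abs=0.4)
    assert (abd == 0).mean() > 0.15  # zero mode


def test_discretization_monotone_in_latent_score(default_config):
    z = np.linspace(-3, 3, 500)
    g1 = abdominal_region_grades(z, default_config, np.random.default_rng(0)).sum(axis=1)
    g2 = abdominal_region_grades(z + 0.4, default_config, np.random.default_rng(0)).sum(axis=1)
    assert (g2 >= g1).all()
    assert (np.diff(np.sort(g1)) >= 0).all()


def test_non_pd_generating_correlation_rejected(default_config):
    params = GeneratingParameters(factor_resid_corr={
        (N.STIFFNESS, N.CALCIFICATION): 0.99,
        (N.STIFFNESS, N.PLAQUE): -0.99,
        (N.CALCIFICATION, N.PLAQUE): 0.99,
    })
    cov = gen_covariates(default_config, seed=13).iloc[:200]
    with pytest.raises(ValueError):
        gen_outcomes(cov, params, seed=14, config=default_config)


# -- missingness ------------------------------------------------------------
def test_zero_missing_config_is_identity(default_config):
    cfg = dataclasses.replace(
        default_config,
        missing_counts={k: 0 for k in default_config.missing_counts},
        n_abi_high=(0, 0), n_abi_low=(0, 0), n_rise_time=0,
        n_surgery={N.SURGERY_CAROTID: 0, N.SURGERY_PERIPHERAL: 0, N.SURGERY_AORTA: 0},
    )
    cov = gen_covariates(cfg, seed=15)
    out = gen_outcomes(cov, GeneratingParameters(), seed=16, config=cfg)
    masked = impose_missingness_and_artifacts(out, cfg, seed=17)
    pd.testing.assert_frame_equal(masked, out)


def test_final_missing_counts_exact_after_validity_filters(prepared_cohort,
                                                           default_config):
    for ind, target in default_config.missing_counts.items():
        assert int(prepared_cohort[ind].isna().sum()) == target, ind


def test_mar_missingness_targets_older_participants(default_config):
    cov = gen_covariates(default_config, seed=18)
    out = gen_outcomes(cov, GeneratingParameters(), seed=19, config=default_config)
    masked = impose_missingness_and_artifacts(out, default_config, seed=20)
    miss = masked[N.BAPWV_L].isna()
    assert masked.loc[miss, N.AGE_EXAM].mean() > masked.loc[~miss, N.AGE_EXAM].mean()


def test_null_mar_mechanism_is_age_independent(default_config):
    """With the age coefficient at zero, missingness does not track age."""
    cfg = dataclasses.replace(default_config, missing_age_coef=0.0)
    cov = gen_covariates(cfg, seed=21)
    out = gen_outcomes(cov, GeneratingParameters(), seed=22, config=cfg)
    tstats = []
    for s in range(6):
        masked = impose_missingness_and_artifacts(out, cfg, seed=100 + s)
        miss = masked[N.BAPWV_L].isna()
        a, b = masked.loc[miss, N.AGE_EXAM], masked.loc[~miss, N.AGE_EXAM]
        t = (a.mean() - b.mean()) / np.sqrt(a.var() / len(a) + b.var() / len(b))
        tstats.append(t)
    assert np.mean(np.square(tstats)) < 4.0  # ~1 under the null


def test_missing_count_exceeding_n_is_an_error(default_config):
    cfg = dataclasses.replace(
        default_config,
        missing_counts={**default_config.missing_counts, N.AI: 4000},
    )
    with pytest.raises(ValueError):
        cfg.validate()


# -- invited population -----------------------------------------------------
def test_invited_population_counts(raw_population, default_config):
    assert len(raw_population) == 4123
    assert int(raw_population[N.REFUSER].sum()) == 247
    assert int(raw_population[N.IN_UTERO].sum()) == 321
    assert int(raw_population[N.DOSE_WGY].isna().sum()) == 273
    assert int(raw_population[N.SMOKING].isna().sum()) == 8


def test_same_seed_reproduces_identical_population(default_config):
    a = assemble_raw_population(default_config, seed=99)
    b = assemble_raw_population(default_config, seed=99)
    pd.testing.assert_frame_equal(a, b)


def test_different_seed_changes_population(default_config):
    a = assemble_raw_population(default_config, seed=99)
    b = assemble_raw_population(default_config, seed=100)
    assert not a[N.DOSE_WGY].equals(b[N.DOSE_WGY])


# -- configuration validation -----------------------------------------------
def test_unreachable_stratum_mean_rejected(default_config):
    cfg = dataclasses.replace(
        default_config,
        stratum_mean_doses=(0.001, 0.45, 0.72, 1.36, 3.09),  # 2*0.45 > 0.5
    )
    with pytest.raises(ValueError):
        cfg.validate()


def test_stratum_counts_must_sum(default_config):
    cfg = dataclasses.replace(default_config, stratum_counts=(1, 2, 3, 4, 5))
    with pytest.raises(ValueError):
        cfg.validate()


def test_expansion_allocation_bounded_by_stratum(default_config):
    cfg = dataclasses.replace(default_config,
                              expansion_per_stratum=(2000, 1407, 0, 0, 0))
    with pytest.raises(ValueError):
        cfg.validate()
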