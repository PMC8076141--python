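"""Study pipeline: final-model structure, indirect effects, comparator,
direct-effect scan mechanics, sensitivity switches."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mimicsem import names as N
from mimicsem.analysis import (
    DIRECT_SCAN_ALPHA,
    age_equivalence_ratio,
    build_final_model,
    comparator_coef_mask,
    direct_effect_scan,
    indicator_factor,
    indirect_effects,
    ordinary_regression,
    run_primary,
    sensitivity,
)
from mimicsem.cohort import SCALE_ATTR
from mimicsem.design import attach_design
from mimicsem.estimators import MimicSEM, standardize
from mimicsem.modelspec import FREE, ModelSpec, implied_moments
from mimicsem.simulate import GeneratingParameters, GeneratorConfig, gen_covariates, gen_outcomes

from conftest import make_small_mimic


# -- final model structure --------------------------------------------------
def test_final_model_counts():
    spec = build_final_model()
    assert len(spec.free_loadings) == 14
    per_factor = {f: 0 for f in N.FACTORS}
    for _, f in spec.free_loadings:
        per_factor[f] += 1
    assert per_factor == {N.STIFFNESS: 4, N.CALCIFICATION: 2, N.PLAQUE: 8}
    assert len(spec.factor_corr_pairs) == 3
    assert set(spec.residual_corr_pairs) == {
        (N.AI, N.CSBP), (N.IMT_CCA_L, N.IMT_CCA_R),
        (N.ABI_L, N.ABI_R), (N.UT_L, N.UT_R),
    }
    assert spec.direct == ((N.FEMALE, N.AI),)


def test_factor_covariate_sets():
    spec = build_final_model()
    stiff = {c for c, f in spec.structural if f == N.STIFFNESS}
    calc = {c for c, f in spec.structural if f == N.CALCIFICATION}
    plaque = {c for c, f in spec.structural if f == N.PLAQUE}
    # smoking and sex absent for stiffness; age squared only for calcification
    assert N.SMK_CURRENT not in stiff and N.FEMALE not in stiff
    assert N.AGE_C2 in calc and N.FEMALE in calc
    assert N.AGE_C2 not in plaque and N.SMK_PAST in plaque
    assert all(N.DOSE in s for s in (stiff, calc, plaque))


def test_age_equivalence_ratio():
    assert age_equivalence_ratio(0.15, 0.062) == pytest.approx(2.42, abs=0.01)
    with pytest.raises(ValueError):
        age_equivalence_ratio(0.1, 0.0)


# -- indirect effects -------------------------------------------------------
def test_indirect_effect_equals_finite_difference(fitted_final_model):
    """The per-Gy indirect effect equals d(implied mean)/d(dose)."""
    model, data = fitted_final_model
    eff = indirect_effects(model).set_index("indicator")
    spec = model.spec
    x0 = np.zeros((1, spec.q))
    x1 = x0.copy()
    dose_idx = spec.covariates.index(N.DOSE)
    h = 1e-6
    x1[0, dose_idx] = h
    mu0, _ = model.implied_moments(x0)
    mu1, _ = model.implied_moments(x1)
    fd = (mu1 - mu0)[0] / h  # fitting scale
    from mimicsem.cohort import natural_scale_factor

    for j, ind in enumerate(spec.indicators):
        assert eff.loc[ind, "effect_per_gy"] == pytest.approx(
            fd[j] * natural_scale_factor(ind), abs=1e-6
        )


def test_indirect_effects_zero_when_dose_paths_zero():
    spec = ModelSpec(
        indicators=N.INDICATORS, factors=N.FACTORS, covariates=N.COVARIATES,
        loadings={(i, indicator_factor(i)): FREE for i in N.INDICATORS},
        structural=tuple((c, f) for f in N.FACTORS
                         for c in N.FACTOR_COVARIATES[f] if c != N.DOSE),
    )
    m = MimicSEM(spec=spec)
    m.theta_ = np.concatenate([
        np.full(14, 0.5), np.zeros(len(spec.structural)), np.zeros(14),
        np.ones(14), np.zeros(0),
    ])
    # dose is not in the structural set at all -> no dose paths -> all zero
    eff = indirect_effects(m)
    assert np.allclose(eff["effect_per_gy"], 0.0)


# -- comparator -------------------------------------------------------------
def test_comparator_equals_per_indicator_ols_on_complete_data(default_config):
    cfg = dataclasses.replace(
        default_config,
        missing_counts={k: 0 for k in default_config.missing_counts},
        n_abi_high=(0, 0), n_abi_low=(0, 0), n_rise_time=0,
        n_surgery={N.SURGERY_CAROTID: 0, N.SURGERY_PERIPHERAL: 0, N.SURGERY_AORTA: 0},
    )
    cov = gen_covariates(cfg, seed=31).iloc[:800].reset_index(drop=True)
    out = gen_outcomes(cov, GeneratingParameters(), seed=32, config=cfg)
    from mimicsem.cohort import rescale_indicators, natural_scale_factor

    prepared = rescale_indicators(out)
    comp = ordinary_regression(prepared, compute_indices=False)
    data = attach_design(prepared)
    spec = build_final_model()
    mask = comparator_coef_mask(spec)
    dose_idx = spec.covariates.index(N.DOSE)
    X = data[list(spec.covariates)].to_numpy()
    for j, ind in enumerate(spec.indicators):
        cols = np.nonzero(mask[j])[0]
        D = np.column_stack([np.ones(len(data)), X[:, cols]])
        beta, *_ = np.linalg.lstsq(D, data[ind].to_numpy(), rcond=None)
        ols_dose = beta[1 + list(cols).index(dose_idx)]
        got = comp.dose_effects.set_index("indicator").loc[ind, "effect_per_gy"]
        assert got == pytest.approx(ols_dose * natural_scale_factor(ind), abs=1e-4)


def test_mimic_beats_comparator_aic_on_mimic_data(prepared_cohort):
    report = run_primary(prepared_cohort, compute_indices=False)
    comp = ordinary_regression(prepared_cohort, compute_indices=False)
    assert report.model.aic() < comp.aic
    assert comp.n_used == report.n_used


# -- primary report ---------------------------------------------------------
def test_run_primary_report_contents(prepared_cohort):
    report = run_primary(prepared_cohort, compute_indices=True)
    assert report.n_used == 3274
    assert report.model.converged_
    assert set(report.r2.index) == set(N.FACTORS)
    assert ((report.r2 > 0) & (report.r2 < 1)).all()
    # one row per free parameter
    assert len(report.table) == report.model.spec.n_free
    assert report.indices.cfi > 0.9
    assert report.indices.rmsea < 0.08
    # standardized loadings for baPWV should be near the generating 0.98
    row = report.table.set_index("parameter")
    assert row.loc["loading:bapwv_l~stiffness", "standardized"] == pytest.approx(0.98, abs=0.02)


def test_run_primary_requires_fitting_scale(prepared_cohort):
    natural = prepared_cohort.copy()
    natural.attrs[SCALE_ATTR] = "natural"
    with pytest.raises(ValueError):
        run_primary(natural)


# -- direct-effect scan -----------------------------------------------------
def test_direct_scan_threshold_is_bonferroni_003():
    assert DIRECT_SCAN_ALPHA == 0.003


def _toy_scan_pvalues(df):
    from conftest import small_mimic_spec
    from mimicsem.estimators import warm_start_for
    from scipy.stats import norm as norm_dist

    spec = small_mimic_spec()
    base = MimicSEM(spec=spec).fit(df)
    pvals, zvals = {}, {}
    for ind in spec.indicators:
        new = spec.with_free("direct", ("x", ind))
        est = MimicSEM(spec=new, start=warm_start_for(new, base)).fit(df)
        k = new.param_names().index(f"direct:x->{ind}")
        se = float(np.sqrt(est.vcov()[k, k]))
        z = est.theta_[k] / se
        zvals[ind] = z
        pvals[ind] = 2 * norm_dist.sf(abs(z))
    return pvals, zvals


def test_direct_scan_detects_injected_effect():
    """An injected direct covariate effect on one indicator is flagged and
    carries the largest test statistic. (When the base model is misspecified
    the one-at-a-time refits can redistribute signal to other indicators, so
    only the ranking, not the others' nulls, is asserted here.)"""
    df = make_small_mimic(1500, seed=77, gamma=0.4, direct={"y3": 0.35})
    pvals, zvals = _toy_scan_pvalues(df)
    assert pvals["y3"] < 0.003
    assert max(zvals, key=lambda i: abs(zvals[i])) == "y3"


def test_direct_scan_quiet_under_null():
    """With no direct effects in the generating model, no indicator reaches
    the Bonferroni threshold on a fixed-seed dataset."""
    df = make_small_mimic(1500, seed=78, gamma=0.4)
    pvals, _ = _toy_scan_pvalues(df)
    assert min(pvals.values()) > 0.003


# -- sensitivity ------------------------------------------------------------
def test_sensitivity_dose_restriction_counts(prepared_cohort):
    n2 = int((prepared_cohort[N.DOSE_WGY] <= 2.0).sum())
    rep = sensitivity(prepared_cohort, "dose_le_2", compute_indices=False)
    assert rep.n_used == n2
    n1 = int((prepared_cohort[N.DOSE_WGY] <= 1.0).sum())
    rep1 = sensitivity(prepared_cohort, "dose_le_1", compute_indices=False)
    assert rep1.n_used == n1
    assert n1 < n2 < 3274


def test_sensitivity_drop_expansion(prepared_cohort):
    rep = sensitivity(prepared_cohort, "drop_expansion", compute_indices=False)
    expected = int((prepared_cohort[N.SUBCOHORT] != "expansion").sum())
    assert rep.n_used == expected == 1571


def test_sensitivity_quadratic_dose_adds_three_terms(prepared_cohort):
    rep = sensitivity(prepared_cohort, "quadratic_dose", compute_indices=False)
    quad = [p for p in rep.table["parameter"] if p.startswith("structural:dose2->")]
    assert len(quad) == 3
    # quadratic generating value is zero: estimates should be small
    vals = rep.table.set_index("parameter").loc[quad, "standardized"]
    assert np.abs(vals).max() < 0.2


def test_sensitivity_log_transform_runs_and_keeps_dose_effects(prepared_cohort):
    rep = sensitivity(prepared_cohort, "log_transform", compute_indices=False)
    assert rep.model.converged_
    std = rep.table.set_index("parameter")
    assert std.loc["structural:dose->calcification", "standardized"] == pytest.approx(
        0.15, abs=0.12
    )


def test_sensitivity_unknown_mode_rejected(prepared_cohort):
    with pytest.raises(ValueError):
        sensitivity(prepared_cohort, "nope")
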