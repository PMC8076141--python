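"""Cleaning rules: dose weighting, smoking classification, calcification
scoring, eligibility accounting, validity masking, rescaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mimicsem import names as N
from mimicsem.cohort import (
    SCALE_ATTR,
    ExclusionLog,
    abdominal_score,
    apply_eligibility,
    apply_validity_filters,
    classify_smoking,
    read_cohort_csv,
    rescale_indicators,
    unscale_indicators,
    weighted_dose,
    write_cohort_csv,
)


# -- weighted dose ----------------------------------------------------------
@pytest.mark.parametrize("gamma, neutron, expected", [
    (1.0, 0.1, 2.0),
    (0.0, 0.0, 0.0),
    (0.5, 0.0, 0.5),
])
def test_weighted_dose_examples(gamma, neutron, expected):
    assert weighted_dose(gamma, neutron) == pytest.approx(expected)


def test_weighted_dose_rejects_negative():
    with pytest.raises(ValueError):
        weighted_dose(-0.1, 0.0)
    with pytest.raises(ValueError):
        weighted_dose(0.1, -0.01)


@given(g=st.floats(0, 10), nu=st.floats(0, 1))
def test_weighted_dose_formula(g, nu):
    assert weighted_dose(g, nu) == pytest.approx(g + 10 * nu, rel=1e-12)


# -- smoking ----------------------------------------------------------------
def test_smoking_current_past_never():
    assert classify_smoking([(2012, True)]) == "current"
    assert classify_smoking([(1970, True)]) == "past"
    assert classify_smoking([(1970, True), (2011, False)]) == "past"
    assert classify_smoking([(1970, False), (2012, False)]) == "never"
    assert classify_smoking([]) == "never"
    # a current report dominates any earlier history
    assert classify_smoking([(1970, True), (2013, True)]) == "current"


def test_smoking_rejects_out_of_range_year():
    with pytest.raises(ValueError):
        classify_smoking([(1950, True)])


# -- abdominal score --------------------------------------------------------
def test_abdominal_score_examples():
    assert abdominal_score([3] * 8) == 24
    assert abdominal_score([0] * 8) == 0
    assert abdominal_score([1, 0, 2, 0, 0, 3, 0, 0]) == 6


def test_abdominal_score_validation():
    with pytest.raises(ValueError):
        abdominal_score([4] + [0] * 7)
    with pytest.raises(ValueError):
        abdominal_score([0] * 7)


@given(st.lists(st.integers(0, 3), min_size=8, max_size=8))
def test_abdominal_score_is_sum(grades):
    assert abdominal_score(grades) == sum(grades)


# -- eligibility ------------------------------------------------------------
def test_eligibility_accounting(raw_population):
    """Printed exclusion counts reconcile invited -> analyzed exactly."""
    cohort, log = apply_eligibility(raw_population)
    assert log.n_invited == 4123
    assert log.counts["refuser"] == 247
    assert log.counts["in_utero"] == 321
    after_first = log.n_invited - log.counts["hemodialysis"] \
        - log.counts["refuser"] - log.counts["in_utero"]
    assert after_first == 3555
    assert log.counts["missing_dose"] == 273
    assert log.counts["missing_smoking"] == 8
    assert log.n_analyzed == len(cohort) == 3274
    assert log.reconcile()
    frame = log.to_frame()
    assert frame.iloc[-1]["n"] == 3274


def test_eligibility_identity_when_nothing_flagged():
    df = pd.DataFrame({
        N.ID: ["a", "b"],
        N.DOSE_WGY: [0.1, 0.2],
        N.SMOKING: ["never", "past"],
    })
    out, log = apply_eligibility(df)
    pd.testing.assert_frame_equal(out.reset_index(drop=True), df)
    assert sum(log.counts.values()) == 0 and log.reconcile()


# -- validity filters -------------------------------------------------------
def _mini_cohort(**overrides):
    base = {ind: [1.0] for ind in N.INDICATORS}
    base[N.ABI_L] = [1.13]
    base[N.ABI_R] = [1.14]
    for flag in (N.SURGERY_CAROTID, N.SURGERY_PERIPHERAL, N.SURGERY_AORTA):
        base[flag] = [False]
    base.update(overrides)
    return pd.DataFrame(base)


def test_high_abi_masked_side_specifically():
    df = _mini_cohort(**{N.ABI_L: [1.45]})
    out, _ = apply_validity_filters(df)
    assert np.isnan(out[N.ABI_L].iloc[0])
    assert out[N.ABI_R].iloc[0] == 1.14


def test_low_abi_masks_same_side_bapwv_but_not_abi():
    df = _mini_cohort(**{N.ABI_L: [0.85], N.BAPWV_L: [17.0], N.BAPWV_R: [18.0]})
    out, _ = apply_validity_filters(df)
    assert np.isnan(out[N.BAPWV_L].iloc[0])
    assert out[N.ABI_L].iloc[0] == 0.85
    assert out[N.BAPWV_R].iloc[0] == 18.0


def test_surgery_masking_by_site():
    df = _mini_cohort(**{N.SURGERY_CAROTID: [True]})
    out, _ = apply_validity_filters(df)
    for ind in (N.IMT_CCA_L, N.IMT_CCA_R, N.IMT_ICA_L, N.IMT_ICA_R):
        assert np.isnan(out[ind].iloc[0])
    for ind in (N.ABI_L, N.UT_L, N.BAPWV_L):
        assert not np.isnan(out[ind].iloc[0])

    df = _mini_cohort(**{N.SURGERY_AORTA: [True]})
    out, _ = apply_validity_filters(df)
    for ind in (N.ABI_L, N.UT_R, N.BAPWV_L, N.AI, N.CSBP,
                N.THORACIC_CALC, N.ABDOMINAL_CALC):
        assert np.isnan(out[ind].iloc[0])
    assert not np.isnan(out[N.IMT_CCA_L].iloc[0])


def test_validity_filtering_idempotent_and_count_preserving(raw_population):
    cohort, _ = apply_eligibility(raw_population)
    once, _ = apply_validity_filters(cohort)
    twice, _ = apply_validity_filters(once)
    assert len(once) == len(cohort)
    pd.testing.assert_frame_equal(once, twice)
    # masking never un-masks
    for ind in N.INDICATORS:
        before = cohort[ind].isna()
        after = once[ind].isna()
        assert (after | ~before).all()


# -- rescaling --------------------------------------------------------------
def test_rescale_abi_by_ten_and_round_trip():
    df = _mini_cohort(**{N.ABI_L: [1.13], N.UT_L: [np.nan]})
    out = rescale_indicators(df)
    assert out[N.ABI_L].iloc[0] == pytest.approx(11.3)
    assert out[N.BAPWV_L].iloc[0] == df[N.BAPWV_L].iloc[0]  # m/s kept
    assert np.isnan(out[N.UT_L].iloc[0])  # missing propagates
    back = unscale_indicators(out)
    assert back[N.ABI_L].iloc[0] == pytest.approx(1.13, rel=1e-12)


def test_rescale_twice_is_an_error():
    df = _mini_cohort()
    out = rescale_indicators(df)
    with pytest.raises(ValueError):
        rescale_indicators(out)


def test_bapwv_cm_per_s_loader_option():
    df = _mini_cohort(**{N.BAPWV_L: [1840.0], N.BAPWV_R: [1830.0]})
    out = rescale_indicators(df, bapwv_unit="cm/s")
    assert out[N.BAPWV_L].iloc[0] == pytest.approx(18.4)


def test_cohort_csv_round_trip(tmp_path):
    df = _mini_cohort()
    scaled = rescale_indicators(df)
    path = tmp_path / "cohort.csv"
    write_cohort_csv(scaled, path, seed=7)
    loaded = read_cohort_csv(path)
    assert loaded.attrs[SCALE_ATTR] == "fitting"
    assert loaded[N.ABI_L].iloc[0] == pytest.approx(11.3)
    with pytest.raises(ValueError):
        rescale_indicators(loaded)
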