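"""Model specification: validation, packing, transforms, implied moments."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mimicsem.modelspec import FREE, ModelSpec, implied_moments


def two_factor_spec():
    return ModelSpec(
        indicators=("y1", "y2", "y3", "y4"),
        factors=("f1", "f2"),
        covariates=("x",),
        loadings={("y1", "f1"): FREE, ("y2", "f1"): FREE,
                  ("y3", "f2"): FREE, ("y4", "f2"): FREE},
        factor_corr_pairs=(("f1", "f2"),),
        residual_corr_pairs=(("y1", "y2"),),
        structural=(("x", "f1"),),
        direct=(("x", "y3"),),
    )


# -- validation -------------------------------------------------------------
def test_rejects_unknown_names():
    with pytest.raises(ValueError):
        ModelSpec(indicators=("y1",), factors=("f",),
                  loadings={("nope", "f"): FREE})
    with pytest.raises(ValueError):
        ModelSpec(indicators=("y1",), factors=("f",),
                  loadings={("y1", "f"): FREE},
                  residual_corr_pairs=(("y1", "zz"),))


def test_rejects_unanchored_factor():
    with pytest.raises(ValueError):
        ModelSpec(indicators=("y1", "y2"), factors=("f1", "f2"),
                  loadings={("y1", "f1"): FREE, ("y2", "f2"): 0.0})


def test_rejects_overlapping_residual_pairs():
    with pytest.raises(ValueError):
        ModelSpec(indicators=("y1", "y2", "y3"), factors=("f",),
                  loadings={("y1", "f"): FREE, ("y2", "f"): FREE, ("y3", "f"): FREE},
                  residual_corr_pairs=(("y1", "y2"), ("y2", "y3")))


# -- packing and transforms -------------------------------------------------
def test_block_layout_and_names():
    spec = two_factor_spec()
    names = spec.param_names()
    assert len(names) == spec.n_free
    assert names[0] == "loading:y1~f1"
    assert "factor_corr:f1~f2" in names
    assert "structural:x->f1" in names
    assert "direct:x->y3" in names
    assert names.count("intercept:y1") == 1
    assert spec.n_free == 4 + 1 + 1 + 1 + 4 + 4 + 1


@given(st.integers(0, 10_000))
def test_transform_round_trip(seed):
    spec = two_factor_spec()
    rng = np.random.default_rng(seed)
    theta = rng.normal(size=spec.n_free)
    b = spec.blocks()
    theta[b["factor_corr"]] = rng.uniform(-0.95, 0.95)
    theta[b["resid_corr"]] = rng.uniform(-0.95, 0.95)
    theta[b["resid_var"]] = rng.uniform(0.05, 5.0, size=4)
    back = spec.to_natural(spec.to_unconstrained(theta))
    np.testing.assert_allclose(back, theta, rtol=1e-10)


def test_matrices_place_parameters():
    spec = two_factor_spec()
    theta = np.zeros(spec.n_free)
    b = spec.blocks()
    theta[b["loading"]] = [0.9, 0.8, 0.7, 0.6]
    theta[b["factor_corr"]] = [0.5]
    theta[b["structural"]] = [0.3]
    theta[b["direct"]] = [0.2]
    theta[b["intercept"]] = [1, 2, 3, 4]
    theta[b["resid_var"]] = [1.0, 1.0, 4.0, 1.0]
    theta[b["resid_corr"]] = [0.25]
    lam, psi, B, K, nu, rv, rc, Theta = spec.matrices(theta)
    assert lam[0, 0] == 0.9 and lam[2, 1] == 0.7 and lam[0, 1] == 0.0
    assert psi[0, 1] == psi[1, 0] == 0.5 and psi[0, 0] == 1.0
    assert B[0, 0] == 0.3 and B[1, 0] == 0.0
    assert K[2, 0] == 0.2
    # residual covariance = corr times sqrt of the two variances
    assert Theta[0, 1] == pytest.approx(0.25 * np.sqrt(1.0 * 1.0))
    assert Theta[2, 2] == 4.0


def test_fixed_loading_value_is_honored():
    spec = ModelSpec(indicators=("y1", "y2"), factors=("f",),
                     loadings={("y1", "f"): 1.0, ("y2", "f"): FREE})
    theta = np.zeros(spec.n_free)
    theta[spec.blocks()["loading"]] = [0.5]
    theta[spec.blocks()["resid_var"]] = [1.0, 1.0]
    lam, *_ = spec.matrices(theta)
    assert lam[0, 0] == 1.0 and lam[1, 0] == 0.5


# -- implied moments --------------------------------------------------------
def test_zero_loadings_give_pure_residual_covariance():
    spec = ModelSpec(indicators=("y1", "y2"), factors=("f",),
                     loadings={("y1", "f"): FREE, ("y2", "f"): FREE})
    theta = np.zeros(spec.n_free)
    theta[spec.blocks()["resid_var"]] = [2.0, 3.0]
    mu, sigma = implied_moments(spec, theta)
    np.testing.assert_allclose(sigma, np.diag([2.0, 3.0]))


def test_hand_algebra_one_factor():
    spec = ModelSpec(indicators=("y1", "y2"), factors=("f",),
                     loadings={("y1", "f"): FREE, ("y2", "f"): FREE})
    theta = np.zeros(spec.n_free)
    b = spec.blocks()
    theta[b["loading"]] = [1.0, 1.0]
    theta[b["resid_var"]] = [1.0, 1.0]
    _, sigma = implied_moments(spec, theta)
    np.testing.assert_allclose(sigma, [[2.0, 1.0], [1.0, 2.0]])


def test_mean_chain_product():
    spec = ModelSpec(indicators=("y",), factors=("f",), covariates=("dose",),
                     loadings={("y", "f"): FREE}, structural=(("dose", "f"),))
    theta = np.zeros(spec.n_free)
    b = spec.blocks()
    theta[b["loading"]] = [2.0]
    theta[b["structural"]] = [0.5]
    theta[b["resid_var"]] = [1.0]
    mu, _ = implied_moments(spec, theta, X=np.array([[1.0]]))
    assert mu[0, 0] == pytest.approx(1.0)  # nu + lambda*gamma*dose = 0 + 2*0.5*1


# -- modifications and serialization ---------------------------------------
def test_with_free_adds_exactly_one_parameter():
    spec = two_factor_spec()
    for kind, pair in [("residual_corr", ("y3", "y4")), ("direct", ("x", "y1")),
                       ("structural", ("x", "f2")), ("loading", ("y1", "f2"))]:
        new = spec.with_free(kind, pair)
        assert new.n_free == spec.n_free + 1
    with pytest.raises(ValueError):
        spec.with_free("direct", ("x", "y3"))  # already free
    with pytest.raises(ValueError):
        spec.with_free("factor_corr", ("f2", "f1"))  # already free (reversed)


def test_dict_round_trip():
    spec = two_factor_spec()
    clone = ModelSpec.from_dict(spec.to_dict())
    assert clone.param_names() == spec.param_names()
    assert clone.fixed_loadings == spec.fixed_loadings
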