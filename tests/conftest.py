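"""Shared fixtures: toy models, a full-size synthetic cohort, fitted models."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from mimicsem import names as N
from mimicsem.analysis import build_final_model
from mimicsem.cohort import prepare_cohort
from mimicsem.design import attach_design
from mimicsem.estimators import MimicSEM
from mimicsem.modelspec import FREE, ModelSpec
from mimicsem.simulate import GeneratorConfig, assemble_raw_population

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


TOY3_LOADINGS = np.array([0.8, 0.6, 0.7])
TOY3_RESID = np.array([0.36, 0.64, 0.51])
TOY3_INTERCEPTS = np.array([1.0, -0.5, 2.0])


@pytest.fixture(scope="session")
def toy3_spec() -> ModelSpec:
    """Just-identified one-factor model with three indicators."""
    return ModelSpec(
        indicators=("y1", "y2", "y3"),
        factors=("f",),
        loadings={("y1", "f"): FREE, ("y2", "f"): FREE, ("y3", "f"): FREE},
    )


def make_toy3(n: int, seed: int, missing_frac: float = 0.0) -> pd.DataFrame:
    """Data from the three-indicator toy, optionally with MCAR holes."""
    rng = np.random.default_rng(seed)
    f = rng.normal(size=n)
    Y = TOY3_INTERCEPTS + f[:, None] * TOY3_LOADINGS \
        + rng.normal(size=(n, 3)) * np.sqrt(TOY3_RESID)
    if missing_frac > 0:
        holes = rng.random(size=Y.shape) < missing_frac
        # never blank out a full record
        holes[holes.all(axis=1), 0] = False
        Y[holes] = np.nan
    return pd.DataFrame(Y, columns=["y1", "y2", "y3"])


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def raw_population(default_config) -> pd.DataFrame:
    return assemble_raw_population(default_config, seed=20260101)


@pytest.fixture(scope="session")
def prepared_cohort(raw_population):
    prepared, excl_log, validity_log = prepare_cohort(raw_population)
    return prepared


@pytest.fixture(scope="session")
def fitted_final_model(prepared_cohort):
    """The final MIMIC model fit once on the session cohort."""
    data = attach_design(prepared_cohort)
    model = MimicSEM(spec=build_final_model()).fit(data)
    assert model.converged_
    return model, data


def small_mimic_spec() -> ModelSpec:
    """One-factor, four-indicator MIMIC toy with one covariate."""
    return ModelSpec(
        indicators=("y1", "y2", "y3", "y4"),
        factors=("f",),
        covariates=("x",),
        loadings={(y, "f"): FREE for y in ("y1", "y2", "y3", "y4")},
        structural=(("x", "f"),),
    )


def make_small_mimic(n: int, seed: int, gamma: float = 0.4,
                     direct: dict | None = None) -> pd.DataFrame:
    """Data from the one-factor MIMIC toy (factor residual variance 1)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    f = gamma * x + rng.normal(size=n)
    lam = np.array([0.9, 0.7, 0.6, 0.8])
    th = np.array([0.4, 0.5, 0.6, 0.45])
    Y = f[:, None] * lam + rng.normal(size=(n, 4)) * np.sqrt(th)
    if direct:
        for ind, kappa in direct.items():
            j = ["y1", "y2", "y3", "y4"].index(ind)
            Y[:, j] += kappa * x
    df = pd.DataFrame(Y, columns=["y1", "y2", "y3", "y4"])
    df["x"] = x
    return df
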