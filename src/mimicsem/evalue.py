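"""E-value sensitivity analysis for standardized linear-model coefficients.

The E-value is the minimum strength of association, on the risk-ratio scale,
that an unmeasured confounder would need to have with both the exposure and
the outcome, conditional on the measured covariates, to fully explain away an
observed exposure-outcome association.

For a linear-model coefficient the approximate conversion goes through a
standardized mean difference: with outcome residual standard deviation ``s``,
a coefficient ``b`` for a one-unit exposure contrast gives ``d = b / s`` and
an approximate risk ratio ``RR = exp(0.91 * d)``; the E-value is then
``RR + sqrt(RR * (RR - 1))`` (after inverting risk ratios below 1).

Here the outcome is a latent factor standardized to unit total variance, so
``s = sqrt(1 - R^2)`` with ``R^2`` the proportion of factor variance explained
by the structural covariates, and the exposure contrast is 1 Gy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class EValueResult:
    """E-values for a standardized dose coefficient and its confidence bound.

    Attributes
    ----------
    estimate : float
        Standardized coefficient (SD of the latent factor per unit exposure).
    ci : tuple of float or None
        95% confidence interval of the coefficient, if supplied.
    resid_sd : float
        Residual SD used for the standardized-mean-difference conversion.
    rr : float
        Approximate risk ratio corresponding to the point estimate.
    evalue : float
        E-value of the point estimate.
    evalue_ci : float or None
        E-value of the CI limit closer to the null; 1.0 if the CI crosses
        the null; None when no CI was supplied.
    """

    estimate: float
    ci: tuple[float, float] | None
    resid_sd: float
    rr: float
    evalue: float
    evalue_ci: float | None


def _evalue_from_rr(rr: float) -> float:
    """E-value of a risk ratio (risk ratios below 1 are inverted first)."""
    if rr <= 0:
        raise ValueError(f"risk ratio must be positive, got {rr}")
    if rr < 1.0:
        rr = 1.0 / rr
    if rr == 1.0:
        return 1.0
    return rr + math.sqrt(rr * (rr - 1.0))


def _rr_from_coef(b: float, resid_sd: float) -> float:
    return math.exp(0.91 * b / resid_sd)


def evalue_ols(
    estimate: float,
    ci: tuple[float, float] | None = None,
    r2: float = 0.0,
) -> EValueResult:
    """E-value for a standardized coefficient from a linear structural model.

    Parameters
    ----------
    estimate : float
        Standardized coefficient per 1-unit (here 1 Gy) exposure contrast,
        with the outcome standardized to unit total SD.
    ci : (lo, hi), optional
        95% confidence interval for the coefficient.
    r2 : float
        Proportion of outcome variance explained by the model covariates;
        the conversion uses the residual SD ``sqrt(1 - r2)``.

    Returns
    -------
    EValueResult

    Examples
    --------
    >>> res = evalue_ols(0.15, ci=(0.070, 0.23), r2=0.27)
    >>> round(res.evalue, 2), round(res.evalue_ci, 2)
    (1.62, 1.37)
    """
    if not 0.0 <= r2 < 1.0:
        raise ValueError(f"r2 must be in [0, 1), got {r2}")
    resid_sd = math.sqrt(1.0 - r2)
    rr = _rr_from_coef(estimate, resid_sd)
    evalue = _evalue_from_rr(rr)

    evalue_ci: float | None = None
    if ci is not None:
        lo, hi = ci
        if lo > hi:
            raise ValueError(f"confidence interval {ci} has lo > hi")
        if lo <= 0.0 <= hi:
            # CI crosses the null: no confounding needed to move it there.
            evalue_ci = 1.0
        else:
            limit = lo if estimate > 0 else hi
            evalue_ci = _evalue_from_rr(_rr_from_coef(limit, resid_sd))
    return EValueResult(
        estimate=estimate,
        ci=ci,
        resid_sd=resid_sd,
        rr=rr,
        evalue=evalue,
        evalue_ci=evalue_ci,
    )
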