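"""Estimators: MIMIC SEM and unstructured Gaussian FIML reference models.

`MimicSEM` fits the latent-variable model declared by a
:class:`~mimicsem.modelspec.ModelSpec` by full-information maximum
likelihood with analytic gradients, using quasi-Newton (L-BFGS-B)
optimization on an unconstrained reparameterization (log variances,
Fisher-z correlations). `GaussianFIML` fits unrestricted multivariate
Gaussian mean/covariance models with the same likelihood machinery; it
provides the saturated model (chi-square reference), the independence
baseline (CFI reference), and the uncorrelated-regression comparator.

Both follow scikit-learn estimator conventions: constructor parameters are
hyper-parameters, `fit(data)` consumes a DataFrame, and fitted state lives
in trailing-underscore attributes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2 as chi2_dist
from sklearn.base import BaseEstimator

from .fiml import FimlData, NonPDError, fiml_loglik_parts
from .modelspec import FREE, ModelSpec

_PENALTY = 1e12


def saturated_param_count(p: int, q: int) -> int:
    """Free parameters of the saturated conditional-Gaussian model."""
    return p * (q + 1) + p * (p + 1) // 2


# ---------------------------------------------------------------------------
# MIMIC estimator
# ---------------------------------------------------------------------------
class MimicSEM(BaseEstimator):
    """MIMIC structural equation model fit by FIML.

    Parameters
    ----------
    spec : ModelSpec
        Declares indicators, factors, covariates and free parameters.
    max_iter : int
        L-BFGS-B iteration cap.
    gtol, ftol : float
        Optimizer tolerances (projected-gradient norm, relative objective
        change).
    start : array or None
        Natural-scale starting vector; defaults to a moment-based start
        (loadings at the indicator sample SD, residual variances at half
        the sample variance, remaining coefficients at zero).

    Attributes (after fit)
    ----------------------
    theta_ : natural-scale estimates in spec order
    params_ : pandas Series of estimates indexed by parameter name
    loglik_ : maximized FIML log-likelihood
    n_used_ : records contributing to the likelihood
    df_model_ : saturated free-parameter count minus model free parameters
    converged_, n_iter_, grad_norm_ : convergence report
    X_mean_, X_cov_ : covariate sample moments (used for standardization)
    """

    def __init__(self, spec: ModelSpec = None, max_iter: int = 1000, gtol: float = 1e-5,
                 ftol: float = 1e-11, start=None):
        self.spec = spec
        self.max_iter = max_iter
        self.gtol = gtol
        self.ftol = ftol
        self.start = start

    # -- data extraction ----------------------------------------------------
    def _extract(self, data: pd.DataFrame):
        spec = self.spec
        missing = [c for c in spec.indicators + spec.covariates if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks columns {missing}")
        Y = data.loc[:, list(spec.indicators)].to_numpy(dtype=float)
        X = data.loc[:, list(spec.covariates)].to_numpy(dtype=float) if spec.q else None
        return Y, X

    # -- internal standardization -------------------------------------------
    # The model is fit on z-scored indicators and variance-scaled covariates
    # (an exact reparameterization that conditions the optimization), and the
    # estimates are mapped back to the data scale afterwards.
    def _scale_jacobian(self, y_scale: np.ndarray, x_scale: np.ndarray) -> np.ndarray:
        """Per-parameter factor mapping scaled-space to natural estimates."""
        spec = self.spec
        iind = {v: k for k, v in enumerate(spec.indicators)}
        icov = {v: k for k, v in enumerate(spec.covariates)}
        b = spec.blocks()
        s = np.ones(spec.n_free)
        s[b["loading"]] = [y_scale[iind[i]] for i, _ in spec.free_loadings]
        s[b["structural"]] = [1.0 / x_scale[icov[c]] for c, _ in spec.structural]
        s[b["direct"]] = [y_scale[iind[i]] / x_scale[icov[c]] for c, i in spec.direct]
        s[b["intercept"]] = y_scale
        s[b["resid_var"]] = y_scale**2
        return s

    def _theta_to_scaled(self, theta, y_loc, y_scale, x_scale):
        s = self._scale_jacobian(y_scale, x_scale)
        out = np.asarray(theta, dtype=float) / s
        b = self.spec.blocks()
        out[b["intercept"]] -= y_loc / y_scale
        return out

    def _theta_to_natural(self, theta_s, y_loc, y_scale, x_scale):
        s = self._scale_jacobian(y_scale, x_scale)
        out = np.asarray(theta_s, dtype=float).copy()
        b = self.spec.blocks()
        out[b["intercept"]] += y_loc / y_scale
        return out * s

    def _default_start(self, Y: np.ndarray) -> np.ndarray:
        spec = self.spec
        sd = np.array([np.nanstd(Y[:, j], ddof=1) if np.isfinite(Y[:, j]).any() else 1.0
                       for j in range(spec.p)])
        sd = np.where(np.isfinite(sd) & (sd > 0), sd, 1.0)
        mean = np.array([np.nanmean(Y[:, j]) if np.isfinite(Y[:, j]).any() else 0.0
                         for j in range(spec.p)])
        iind = {v: k for k, v in enumerate(spec.indicators)}
        theta = np.zeros(spec.n_free)
        b = spec.blocks()
        theta[b["loading"]] = [sd[iind[i]] for i, _ in spec.free_loadings]
        theta[b["intercept"]] = mean
        theta[b["resid_var"]] = 0.5 * sd**2
        return theta

    # -- objective ----------------------------------------------------------
    def _objective(self, t: np.ndarray, data: FimlData):
        spec = self.spec
        with np.errstate(over="ignore"):
            theta = spec.to_natural(t)
        if not np.isfinite(theta).all():
            return _PENALTY, np.zeros_like(t)
        lam, psi, B, K, nu, resid_var, resid_corr, Theta = spec.matrices(theta)
        sigma = lam @ psi @ lam.T + Theta
        if data.X is not None:
            MU = nu[None, :] + data.X @ (lam @ B + K).T
        else:
            MU = np.broadcast_to(nu, data.Y.shape)
        try:
            ll, Gs, Gmu = fiml_loglik_parts(MU, sigma, data, want_grad=True)
        except NonPDError:
            return _PENALTY, np.zeros_like(t)

        b = spec.blocks()
        grad = np.zeros(spec.n_free)
        iind = {v: k for k, v in enumerate(spec.indicators)}
        ifac = {v: k for k, v in enumerate(spec.factors)}
        icov = {v: k for k, v in enumerate(spec.covariates)}

        if data.X is not None:
            Mgrad = Gmu.T @ data.X  # p x q
        else:
            Mgrad = np.zeros((spec.p, max(spec.q, 1)))
        gnu = Gmu.sum(axis=0)

        gLam = 2.0 * Gs @ lam @ psi
        if spec.q:
            gLam = gLam + Mgrad @ B.T
        grad[b["loading"]] = [gLam[iind[i], ifac[f]] for i, f in spec.free_loadings]

        gPsi = lam.T @ Gs @ lam
        fc = np.array([2.0 * gPsi[ifac[a], ifac[c]] for a, c in spec.factor_corr_pairs])
        psi_vals = theta[b["factor_corr"]]
        grad[b["factor_corr"]] = fc * (1.0 - psi_vals**2)  # chain through tanh

        if spec.structural:
            gB = lam.T @ Mgrad
            grad[b["structural"]] = [gB[ifac[f], icov[c]] for c, f in spec.structural]
        if spec.direct:
            grad[b["direct"]] = [Mgrad[iind[i], icov[c]] for c, i in spec.direct]

        grad[b["intercept"]] = gnu

        # residual variances (log scale); off-diagonal Theta entries depend
        # on the variances through the sqrt(theta_j theta_k) factor
        gvar_t = resid_var * np.diag(Gs).copy()
        for r, (a, c) in zip(resid_corr, spec.residual_corr_pairs):
            j, k = iind[a], iind[c]
            cov_jk = Theta[j, k]
            gvar_t[j] += Gs[j, k] * cov_jk
            gvar_t[k] += Gs[j, k] * cov_jk
        grad[b["resid_var"]] = gvar_t

        rc = np.empty(len(spec.residual_corr_pairs))
        for idx, (r, (a, c)) in enumerate(zip(resid_corr, spec.residual_corr_pairs)):
            j, k = iind[a], iind[c]
            rc[idx] = 2.0 * Gs[j, k] * np.sqrt(resid_var[j] * resid_var[k]) * (1.0 - r**2)
        grad[b["resid_corr"]] = rc

        return -ll, -grad

    # -- fit ----------------------------------------------------------------
    def fit(self, data: pd.DataFrame, y=None):
        spec = self.spec
        if spec is None:
            raise ValueError("a ModelSpec is required")
        Y, X = self._extract(data)
        with np.errstate(all="ignore"):
            y_loc = np.nanmean(Y, axis=0)
            y_scale = np.nanstd(Y, axis=0)
        y_loc = np.where(np.isfinite(y_loc), y_loc, 0.0)
        y_scale = np.where(np.isfinite(y_scale) & (y_scale > 0), y_scale, 1.0)
        if X is not None:
            x_scale = X.std(axis=0)
            x_scale = np.where(x_scale > 0, x_scale, 1.0)
            Xs = X / x_scale
        else:
            x_scale = np.ones(0)
            Xs = None
        Ys = (Y - y_loc) / y_scale
        fdata = FimlData(Ys, Xs)
        n_obs_per_col = np.sum(~np.isnan(Y), axis=0)
        ll_offset = -float(np.sum(n_obs_per_col * np.log(y_scale)))
        self._y_loc_, self._y_scale_, self._x_scale_ = y_loc, y_scale, x_scale
        self._ll_offset_ = ll_offset

        if self.start is not None:
            theta0 = self._theta_to_scaled(self.start, y_loc, y_scale, x_scale)
        else:
            theta0 = self._default_start(Ys)
        t0 = spec.to_unconstrained(theta0)

        res = minimize(
            self._objective, t0, args=(fdata,), jac=True, method="L-BFGS-B",
            options={"maxiter": self.max_iter, "maxfun": 10 * self.max_iter,
                     "ftol": self.ftol, "gtol": self.gtol},
        )
        self.theta_ = self._theta_to_natural(spec.to_natural(res.x), y_loc, y_scale, x_scale)
        self._t_ = res.x
        self.loglik_ = -float(res.fun) + ll_offset
        self.converged_ = bool(res.success) and res.fun < _PENALTY / 2
        self.n_iter_ = int(res.nit)
        self.grad_norm_ = float(np.max(np.abs(res.jac)))
        self.n_records_ = fdata.n_total
        self.n_used_ = fdata.n_used
        self.n_all_missing_ = fdata.n_all_missing
        self.df_model_ = saturated_param_count(spec.p, spec.q) - spec.n_free
        self.params_ = pd.Series(self.theta_, index=spec.param_names())
        if X is not None:
            self.X_mean_ = X.mean(axis=0)
            self.X_cov_ = np.cov(X, rowvar=False, ddof=0).reshape(spec.q, spec.q)
        else:
            self.X_mean_ = np.zeros(0)
            self.X_cov_ = np.zeros((0, 0))
        self._fdata_ = fdata
        return self

    # -- post-fit utilities -------------------------------------------------
    def implied_moments(self, X: np.ndarray | None = None):
        """Implied (mu, sigma) at the estimates for covariate rows X."""
        from .modelspec import implied_moments

        return implied_moments(self.spec, self.theta_, X)

    def loglik_at(self, theta: np.ndarray) -> float:
        """FIML log-likelihood at an arbitrary natural-scale vector."""
        theta_s = self._theta_to_scaled(theta, self._y_loc_, self._y_scale_, self._x_scale_)
        t = self.spec.to_unconstrained(theta_s)
        f, _ = self._objective(t, self._fdata_)
        return -f + self._ll_offset_

    def observed_information(self, step: float = 1e-5) -> np.ndarray:
        """Observed information in the unconstrained space.

        Forward finite differences of the analytic gradient; adequate for
        Wald standard errors.
        """
        t = self._t_
        _, g0 = self._objective(t, self._fdata_)
        H = np.empty((t.size, t.size))
        for j in range(t.size):
            tj = t.copy()
            h = step * max(1.0, abs(t[j]))
            tj[j] += h
            _, gj = self._objective(tj, self._fdata_)
            H[j] = (gj - g0) / h
        return 0.5 * (H + H.T)

    def vcov(self, step: float = 1e-5) -> np.ndarray:
        """Variance matrix of the natural-scale estimates (delta method)."""
        H = self.observed_information(step=step)
        cov_t = np.linalg.pinv(H)
        # elementwise transforms -> diagonal Jacobian d(natural)/d(unconstrained),
        # combining the tanh/exp chains with the internal standardization factors
        b = self.spec.blocks()
        J = self._scale_jacobian(self._y_scale_, self._x_scale_)
        J[b["factor_corr"]] = 1.0 - self.theta_[b["factor_corr"]] ** 2
        J[b["resid_var"]] = self.theta_[b["resid_var"]]
        J[b["resid_corr"]] = 1.0 - self.theta_[b["resid_corr"]] ** 2
        return cov_t * np.outer(J, J)

    def aic(self) -> float:
        return -2.0 * self.loglik_ + 2.0 * self.spec.n_free


# ---------------------------------------------------------------------------
# Unstructured Gaussian reference models
# ---------------------------------------------------------------------------
class GaussianFIML(BaseEstimator):
    """Unrestricted conditional-Gaussian model fit by the same FIML core.

    Mean structure: ``mu_i = nu + C x_i`` with an optional boolean mask on
    the coefficient matrix ``C`` (used by the uncorrelated-regression
    comparator, where each indicator gets its own covariate subset).
    Covariance: unrestricted (``'full'``, via a Cholesky factor) or
    ``'diagonal'``.

    With no covariates and a diagonal covariance this is the independence
    baseline model used by the comparative fit index; with all covariates
    and a full covariance it is the saturated model whose likelihood anchors
    the model chi-square.
    """

    def __init__(self, indicators=(), covariates=(), coef_mask=None,
                 cov_structure="full", max_iter: int = 3000, gtol: float = 1e-5,
                 ftol: float = 1e-11):
        self.indicators = indicators
        self.covariates = covariates
        self.coef_mask = coef_mask
        self.cov_structure = cov_structure
        self.max_iter = max_iter
        self.gtol = gtol
        self.ftol = ftol

    # parameter layout: [nu (p)] [C at mask positions] [cov params]
    def _layout(self):
        p = len(self.indicators)
        q = len(self.covariates)
        mask = np.asarray(self.coef_mask, dtype=bool) if self.coef_mask is not None \
            else np.ones((p, q), dtype=bool)
        if mask.shape != (p, q):
            raise ValueError(f"coef_mask must have shape {(p, q)}")
        n_coef = int(mask.sum())
        if self.cov_structure == "full":
            n_cov = p * (p + 1) // 2
        elif self.cov_structure == "diagonal":
            n_cov = p
        else:
            raise ValueError(f"unknown cov_structure {self.cov_structure!r}")
        return p, q, mask, n_coef, n_cov

    @property
    def n_free_(self) -> int:
        p, q, mask, n_coef, n_cov = self._layout()
        return p + n_coef + n_cov

    def _unpack(self, t, p, mask, n_coef):
        q = mask.shape[1]
        nu = t[:p]
        C = np.zeros((p, q))
        C[mask] = t[p:p + n_coef]
        covpar = t[p + n_coef:]
        if self.cov_structure == "full":
            L = np.zeros((p, p))
            il = np.tril_indices(p)
            L[il] = covpar
            diag = np.arange(p)
            L[diag, diag] = np.exp(np.diag(L))
            sigma = L @ L.T
            return nu, C, sigma, L
        sigma = np.diag(np.exp(covpar))
        return nu, C, sigma, None

    def _objective(self, t, fdata, p, mask, n_coef):
        nu, C, sigma, L = self._unpack(t, p, mask, n_coef)
        if fdata.X is not None:
            MU = nu[None, :] + fdata.X @ C.T
        else:
            MU = np.broadcast_to(nu, fdata.Y.shape)
        try:
            ll, Gs, Gmu = fiml_loglik_parts(MU, sigma, fdata, want_grad=True)
        except NonPDError:
            return _PENALTY, np.zeros_like(t)
        grad = np.zeros_like(t)
        grad[:p] = Gmu.sum(axis=0)
        if fdata.X is not None and n_coef:
            grad[p:p + n_coef] = (Gmu.T @ fdata.X)[mask]
        if self.cov_structure == "full":
            GL = 2.0 * Gs @ L
            diag = np.arange(p)
            GL[diag, diag] *= np.diag(L)  # chain through exp on the diagonal
            grad[p + n_coef:] = GL[np.tril_indices(p)]
        else:
            grad[p + n_coef:] = np.diag(Gs) * np.diag(sigma)
        return -ll, -grad

    def _start(self, Y, X, p, mask):
        """Per-indicator complete-observation least squares."""
        q = mask.shape[1]
        nu = np.zeros(p)
        C = np.zeros((p, q))
        resid_var = np.ones(p)
        for j in range(p):
            obs = ~np.isnan(Y[:, j])
            yj = Y[obs, j]
            if yj.size == 0:
                continue
            cols = np.nonzero(mask[j])[0] if X is not None else np.array([], dtype=int)
            if X is not None and cols.size and yj.size > cols.size + 1:
                D = np.column_stack([np.ones(yj.size), X[obs][:, cols]])
                beta, *_ = np.linalg.lstsq(D, yj, rcond=None)
                nu[j] = beta[0]
                C[j, cols] = beta[1:]
                r = yj - D @ beta
                resid_var[j] = max(float(r @ r / yj.size), 1e-8)
            else:
                nu[j] = float(yj.mean())
                resid_var[j] = max(float(yj.var()), 1e-8)
        t = [nu]
        t.append(C[mask])
        if self.cov_structure == "full":
            L = np.diag(np.sqrt(resid_var))
            Lpar = np.zeros((p, p))
            il = np.tril_indices(p)
            Lpar[il] = L[il]
            diag = np.arange(p)
            Lpar[diag, diag] = np.log(np.diag(L))
            t.append(Lpar[il])
        else:
            t.append(np.log(resid_var))
        return np.concatenate(t)

    def fit(self, data: pd.DataFrame, y=None):
        p, q, mask, n_coef, n_cov = self._layout()
        Y = data.loc[:, list(self.indicators)].to_numpy(dtype=float)
        X = data.loc[:, list(self.covariates)].to_numpy(dtype=float) if q else None
        # internal standardization (exact reparameterization) for conditioning
        with np.errstate(all="ignore"):
            y_loc = np.nanmean(Y, axis=0)
            y_scale = np.nanstd(Y, axis=0)
        y_loc = np.where(np.isfinite(y_loc), y_loc, 0.0)
        y_scale = np.where(np.isfinite(y_scale) & (y_scale > 0), y_scale, 1.0)
        if X is not None:
            x_scale = X.std(axis=0)
            x_scale = np.where(x_scale > 0, x_scale, 1.0)
            Xs = X / x_scale
        else:
            x_scale = np.ones(q)
            Xs = None
        Ys = (Y - y_loc) / y_scale
        n_obs_per_col = np.sum(~np.isnan(Y), axis=0)
        ll_offset = -float(np.sum(n_obs_per_col * np.log(y_scale)))
        fdata = FimlData(Ys, Xs)

        complete = not np.isnan(Y).any()
        if complete and self.cov_structure == "full" and bool(mask.all()):
            # complete data, saturated mean and covariance: closed form
            n = Y.shape[0]
            if Xs is not None:
                D = np.column_stack([np.ones(n), Xs])
                beta, *_ = np.linalg.lstsq(D, Ys, rcond=None)
                nu_s, C_s = beta[0], beta[1:].T
                R = Ys - D @ beta
            else:
                nu_s, C_s = Ys.mean(axis=0), np.zeros((p, q))
                R = Ys - nu_s
            sigma_s = R.T @ R / n
            sign, logdet = np.linalg.slogdet(sigma_s)
            ll = -0.5 * n * (p * np.log(2 * np.pi) + logdet + p)
            self.nu_ = y_loc + nu_s * y_scale
            C = C_s * y_scale[:, None]
            self.coef_ = C / x_scale[None, :] if q else C
            self.sigma_ = sigma_s * np.outer(y_scale, y_scale)
            self.loglik_ = float(ll) + ll_offset
            self.converged_ = True
            self.n_iter_ = 0
            self.n_used_ = fdata.n_used
            self.n_records_ = fdata.n_total
            self._fdata_ = fdata
            self._mask_ = mask
            return self

        t0 = self._start(Ys, Xs, p, mask)
        res = minimize(
            self._objective, t0, args=(fdata, p, mask, n_coef), jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "maxfun": 10 * self.max_iter,
                     "ftol": self.ftol, "gtol": self.gtol},
        )
        nu, C, sigma, _ = self._unpack(res.x, p, mask, n_coef)
        # map back to the data scale
        C = C * y_scale[:, None]
        if q:
            C = C / x_scale[None, :]
        self.nu_ = y_loc + nu * y_scale
        self.coef_ = C
        self.sigma_ = sigma * np.outer(y_scale, y_scale)
        self.loglik_ = -float(res.fun) + ll_offset
        self.converged_ = bool(res.success) and res.fun < _PENALTY / 2
        self.n_iter_ = int(res.nit)
        self.n_used_ = fdata.n_used
        self.n_records_ = fdata.n_total
        self._fdata_ = fdata
        self._mask_ = mask
        return self

    def aic(self) -> float:
        return -2.0 * self.loglik_ + 2.0 * self.n_free_


def fit_saturated(data: pd.DataFrame, indicators, covariates=(), **kw) -> GaussianFIML:
    """Saturated reference model: unrestricted means on all covariates,
    unrestricted covariance."""
    return GaussianFIML(indicators=indicators, covariates=covariates,
                        cov_structure="full", **kw).fit(data)


def fit_baseline(data: pd.DataFrame, indicators, **kw) -> GaussianFIML:
    """Independence baseline: intercept-only means, diagonal covariance."""
    return GaussianFIML(indicators=indicators, covariates=(),
                        cov_structure="diagonal", **kw).fit(data)


# ---------------------------------------------------------------------------
# Fit indices
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class FitIndices:
    """Chi-square against the saturated model and derived indices."""

    chi2: float
    df: int
    chi2_baseline: float
    df_baseline: int
    cfi: float
    rmsea: float
    aic: float
    n: int

    def __post_init__(self):
        if self.df < 0:
            raise ValueError("model has more free parameters than the saturated model")


def fit_indices(model, saturated: GaussianFIML, baseline: GaussianFIML) -> FitIndices:
    """Compute chi-square, CFI, RMSEA and AIC for a fitted model.

    ``model`` may be a MimicSEM or GaussianFIML; all three fits must use
    identical records. chi2 = 2(ll_sat - ll_model); df is the difference in
    free-parameter counts; CFI = 1 - max(chi2-df,0)/max(chi2_b-df_b,0);
    RMSEA = sqrt(max(chi2-df,0)/(df*n)); AIC = -2 ll + 2 k.
    """
    if model.n_used_ != saturated.n_used_ or model.n_used_ != baseline.n_used_:
        raise ValueError("fit indices require models fit on identical records")
    k_model = model.spec.n_free if isinstance(model, MimicSEM) else model.n_free_
    chi2 = 2.0 * (saturated.loglik_ - model.loglik_)
    df = saturated.n_free_ - k_model
    chi2_b = 2.0 * (saturated.loglik_ - baseline.loglik_)
    df_b = saturated.n_free_ - baseline.n_free_
    denom = max(chi2_b - df_b, 0.0)
    num = max(chi2 - df, 0.0)
    cfi = 1.0 if denom == 0.0 else 1.0 - min(num / denom, 1.0)
    n = model.n_used_
    rmsea = 0.0 if df <= 0 else float(np.sqrt(num / (df * n)))
    aic = -2.0 * model.loglik_ + 2.0 * k_model
    return FitIndices(chi2=chi2, df=df, chi2_baseline=chi2_b, df_baseline=df_b,
                      cfi=cfi, rmsea=rmsea, aic=aic, n=n)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------
@dataclass
class StandardizedSolution:
    """Estimates rescaled to latent-factor and indicator SDs.

    Covariates are deliberately left on their natural scale, so structural
    coefficients read "factor SDs per covariate unit" (e.g. per Gy).
    """

    loadings: pd.Series
    factor_corr: pd.Series
    structural: pd.Series
    direct: pd.Series
    residual_corr: pd.Series
    factor_sd: pd.Series
    indicator_sd: pd.Series
    r2: pd.Series

    def as_series(self) -> pd.Series:
        parts = [s for s in (self.loadings, self.factor_corr, self.structural,
                             self.direct, self.residual_corr) if len(s)]
        return pd.concat(parts) if parts else pd.Series(dtype=float)


def standardize(model: MimicSEM) -> StandardizedSolution:
    """Standardized solution of a fitted MIMIC model.

    Factor SDs come from the model-implied total factor variance
    ``diag(B S_x B' + Psi)`` with ``S_x`` the sample covariate covariance;
    indicator SDs from the implied total indicator variance (structural,
    measurement and direct-effect contributions). Residual correlations are
    already scale-free. ``r2`` is the share of factor variance explained by
    the covariates: ``1 - psi_ff / Var(f)``.
    """
    spec = model.spec
    lam, psi, B, K, nu, resid_var, resid_corr, Theta = spec.matrices(model.theta_)
    if spec.q:
        Sx = model.X_cov_
        var_f = np.diag(B @ Sx @ B.T + psi)
        A = lam @ B + K
        total = A @ Sx @ A.T + lam @ psi @ lam.T + Theta
    else:
        var_f = np.diag(psi)
        total = lam @ psi @ lam.T + Theta
    if np.any(var_f <= 0) or np.any(np.diag(total) <= 0):
        raise ValueError("non-positive implied variance; cannot standardize")
    sd_f = np.sqrt(var_f)
    sd_y = np.sqrt(np.diag(total))

    iind = {v: k for k, v in enumerate(spec.indicators)}
    ifac = {v: k for k, v in enumerate(spec.factors)}
    load = pd.Series({
        f"loading:{i}~{f}": lam[iind[i], ifac[f]] * sd_f[ifac[f]] / sd_y[iind[i]]
        for i, f in list(spec.free_loadings) + list(spec.fixed_loadings)
    })
    # factor residual correlations: correlations of the zeta residuals
    fcorr = pd.Series({
        f"factor_corr:{a}~{c}": psi[ifac[a], ifac[c]]
        / np.sqrt(psi[ifac[a], ifac[a]] * psi[ifac[c], ifac[c]])
        for a, c in spec.factor_corr_pairs
    })
    b = spec.blocks()
    struct = pd.Series({
        f"structural:{c}->{f}": model.theta_[b["structural"]][k] / sd_f[ifac[f]]
        for k, (c, f) in enumerate(spec.structural)
    })
    direct = pd.Series({
        f"direct:{c}->{i}": model.theta_[b["direct"]][k] / sd_y[iind[i]]
        for k, (c, i) in enumerate(spec.direct)
    })
    rcorr = pd.Series({
        f"resid_corr:{a}~{c}": resid_corr[k]
        for k, (a, c) in enumerate(spec.residual_corr_pairs)
    })
    r2 = pd.Series({f: 1.0 - psi[ifac[f], ifac[f]] / var_f[ifac[f]] for f in spec.factors})
    return StandardizedSolution(
        loadings=load, factor_corr=fcorr, structural=struct, direct=direct,
        residual_corr=rcorr,
        factor_sd=pd.Series(sd_f, index=spec.factors),
        indicator_sd=pd.Series(sd_y, index=spec.indicators),
        r2=r2,
    )


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------
@dataclass
class BootstrapResult:
    """Percentile bootstrap intervals for a vector of model quantities."""

    estimates: pd.Series
    lower: pd.Series
    upper: pd.Series
    level: float
    n_replicates: int
    n_failed: int
    samples: np.ndarray

    @property
    def failure_rate(self) -> float:
        return self.n_failed / max(self.n_replicates, 1)


def bootstrap_ci(
    model: MimicSEM,
    data: pd.DataFrame,
    extract,
    B: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> BootstrapResult:
    """Participant-resampling percentile bootstrap.

    Parameters
    ----------
    model : fitted MimicSEM (its estimates warm-start every replicate)
    data : the table the model was fit on; the resampling unit is the row
    extract : callable(fitted MimicSEM, data) -> pandas Series of quantities
    B : number of replicates
    seed : RNG seed; replicates are reproducible for a fixed seed
    level : interval coverage (percentile convention)

    Non-converged replicates are dropped and counted; a failure rate above
    10% is reported via ``failure_rate`` for the caller to surface.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    point = extract(model, data)
    samples = np.full((B, point.size), np.nan)
    n_failed = 0
    n = len(data)
    for rep in range(B):
        idx = rng.integers(0, n, size=n)
        boot = data.iloc[idx].reset_index(drop=True)
        est = MimicSEM(spec=model.spec, max_iter=model.max_iter,
                       gtol=model.gtol, ftol=model.ftol, start=model.theta_)
        try:
            est.fit(boot)
        except Exception:
            n_failed += 1
            continue
        if not est.converged_:
            n_failed += 1
            continue
        samples[rep] = extract(est, boot).to_numpy()
    ok = ~np.isnan(samples).any(axis=1)
    alpha = (1.0 - level) / 2.0
    if ok.sum() >= 2:
        lo = np.quantile(samples[ok], alpha, axis=0)
        hi = np.quantile(samples[ok], 1.0 - alpha, axis=0)
    else:
        lo = np.full(point.size, np.nan)
        hi = np.full(point.size, np.nan)
    return BootstrapResult(
        estimates=point,
        lower=pd.Series(lo, index=point.index),
        upper=pd.Series(hi, index=point.index),
        level=level, n_replicates=B, n_failed=n_failed, samples=samples,
    )


# ---------------------------------------------------------------------------
# Likelihood-ratio modification scan
# ---------------------------------------------------------------------------
def warm_start_for(new_spec: ModelSpec, fitted: MimicSEM) -> np.ndarray:
    """Map a fitted parameter vector onto a modified spec by name.

    New free parameters start at zero (variances at the fitted residual
    variance when present, else one).
    """
    old = dict(zip(fitted.spec.param_names(), fitted.theta_))
    theta = np.zeros(new_spec.n_free)
    b = new_spec.blocks()
    theta[b["resid_var"]] = 1.0
    for k, name in enumerate(new_spec.param_names()):
        if name in old:
            theta[k] = old[name]
    return theta


def lr_scan(model: MimicSEM, data: pd.DataFrame, candidates) -> pd.DataFrame:
    """One-at-a-time likelihood-ratio scan over fixed parameters.

    For each ``(kind, pair)`` candidate currently fixed in the spec, refits
    the model with that parameter freed (warm-started at the base solution)
    and reports ``delta_chi2 = 2 * (ll_free - ll_base)`` with its 1-df
    chi-square p-value, sorted by decreasing improvement. Candidates that
    are already free are skipped with a note.

    This is a likelihood-ratio stand-in for score-test modification
    indices: asymptotically equivalent, numerically different.
    """
    rows = []
    for kind, pair in candidates:
        try:
            new_spec = model.spec.with_free(kind, tuple(pair))
        except ValueError as exc:
            rows.append({"kind": kind, "pair": tuple(pair), "delta_chi2": np.nan,
                         "p": np.nan, "note": str(exc)})
            continue
        est = MimicSEM(spec=new_spec, max_iter=model.max_iter, gtol=model.gtol,
                       ftol=model.ftol, start=warm_start_for(new_spec, model))
        est.fit(data)
        d = max(2.0 * (est.loglik_ - model.loglik_), 0.0)
        rows.append({"kind": kind, "pair": tuple(pair), "delta_chi2": d,
                     "p": float(chi2_dist.sf(d, 1)), "note": ""})
    out = pd.DataFrame(rows)
    return out.sort_values("delta_chi2", ascending=False, na_position="last").reset_index(drop=True)
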