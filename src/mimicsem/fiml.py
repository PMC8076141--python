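"""Full-information maximum likelihood for multivariate normal data.

Each record contributes the Gaussian log-density of its *observed*
sub-vector under the corresponding sub-matrix of the model-implied moments,
which is the correct likelihood under missingness at random. Records are
grouped by missingness pattern so each pattern's covariance sub-matrix is
factorized once; the result is invariant to record order.

The module returns, alongside the log-likelihood, the analytic derivatives
with respect to the implied covariance matrix (as a symmetric-matrix
gradient ``G`` such that ``d loglik = trace(G dSigma)``) and to the
per-record implied means. Model classes chain these through their own
parameterizations.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

_LOG_2PI = float(np.log(2.0 * np.pi))


class NonPDError(ValueError):
    """Raised when an implied covariance matrix is not positive definite."""


class FimlData:
    """Missingness-pattern grouping of an indicator matrix.

    Parameters
    ----------
    Y : (n, p) float array with NaN for missing entries
    X : (n, q) float covariate matrix or None; must be complete

    Attributes
    ----------
    n_total : number of input records
    n_used : records with at least one observed indicator
    n_all_missing : records contributing nothing to the likelihood
    patterns : list of (obs_idx, rows) pairs
    """

    def __init__(self, Y: np.ndarray, X: np.ndarray | None = None):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2:
            raise ValueError("Y must be 2-dimensional")
        self.Y = Y
        self.n_total, self.p = Y.shape
        if X is not None:
            X = np.asarray(X, dtype=float)
            if X.shape[0] != self.n_total:
                raise ValueError("X and Y row counts differ")
            if np.isnan(X).any():
                raise ValueError("covariates must be complete")
        self.X = X

        obs = ~np.isnan(Y)
        any_obs = obs.any(axis=1)
        self.n_all_missing = int((~any_obs).sum())
        self.n_used = int(any_obs.sum())
        self.patterns: list[tuple[np.ndarray, np.ndarray]] = []
        if self.n_used == 0:
            return
        uniq, inverse = np.unique(obs, axis=0, return_inverse=True)
        for g in range(uniq.shape[0]):
            if not uniq[g].any():
                continue
            rows = np.nonzero(inverse == g)[0]
            self.patterns.append((np.nonzero(uniq[g])[0], rows))


def fiml_loglik_parts(
    MU: np.ndarray, sigma: np.ndarray, data: FimlData, want_grad: bool = False
):
    """FIML log-likelihood and its moment-space gradients.

    Parameters
    ----------
    MU : (n, p) implied mean per record
    sigma : (p, p) implied covariance
    data : FimlData
    want_grad : also return (G_sigma, G_mu)

    Returns
    -------
    ll : float
    G_sigma : (p, p) symmetric, ``d ll = trace(G_sigma dSigma)`` (if requested)
    G_mu : (n, p) per-record mean gradient, zero at missing entries (if requested)

    Raises
    ------
    NonPDError if ``sigma`` is not positive definite.
    """
    p = data.p
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise NonPDError("implied covariance is not positive definite") from exc

    ll = 0.0
    G_sigma = np.zeros((p, p)) if want_grad else None
    G_mu = np.zeros_like(data.Y) if want_grad else None

    for obs_idx, rows in data.patterns:
        k = obs_idx.size
        sub = sigma[np.ix_(obs_idx, obs_idx)]
        try:
            cho = cho_factor(sub, lower=True)
        except LinAlgError as exc:  # pragma: no cover - principal submatrix of PD
            raise NonPDError(f"singular covariance for pattern {obs_idx}") from exc
        logdet = 2.0 * np.log(np.diag(cho[0])).sum()
        R = data.Y[np.ix_(rows, obs_idx)] - MU[np.ix_(rows, obs_idx)]
        V = cho_solve(cho, R.T).T  # R @ inv(sub)
        quad = float(np.einsum("ij,ij->", R, V))
        n_g = rows.size
        ll += -0.5 * (n_g * (k * _LOG_2PI + logdet) + quad)
        if want_grad:
            sub_inv = cho_solve(cho, np.eye(k))
            Gp = 0.5 * (V.T @ V - n_g * sub_inv)
            G_sigma[np.ix_(obs_idx, obs_idx)] += Gp
            G_mu[np.ix_(rows, obs_idx)] = V

    if want_grad:
        return ll, G_sigma, G_mu
    return ll
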