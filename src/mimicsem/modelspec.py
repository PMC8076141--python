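"""Pattern-based specification of MIMIC structural equation models.

A MIMIC (multiple indicators, multiple causes) model has, conditional on a
covariate vector ``x``:

- structural part: latent factors ``f = B x + zeta`` with residuals
  ``zeta ~ N(0, Psi)``; identification fixes each factor residual variance
  (the diagonal of ``Psi``) at 1.0, so the free off-diagonals of ``Psi`` are
  residual correlations;
- measurement part: indicators ``y = nu + Lambda f + K x + eps`` with
  measurement residuals ``eps ~ N(0, Theta)``, ``Theta`` having free positive
  diagonal and free covariances only for declared indicator pairs.

Model-implied moments conditional on x:

- mean: ``mu(x) = nu + (Lambda B + K) x``
- covariance: ``Sigma = Lambda Psi Lambda' + Theta`` (constant across records)

The free-parameter vector is packed in a fixed block order (loadings, factor
residual correlations, structural coefficients, direct effects, intercepts,
residual variances, residual correlations). For unconstrained optimization,
variances are carried as logs and correlations as Fisher-z transforms; the
off-diagonal elements of ``Theta`` are parameterized as residual correlations
times the geometric mean of the two residual variances, which keeps every
declared 2x2 residual block positive definite by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

FREE = None  # marker for a free pattern entry


@dataclass(frozen=True)
class ModelSpec:
    """Declares which MIMIC parameters are free.

    Parameters
    ----------
    indicators, factors, covariates : sequences of str
        Ordered variable names. ``covariates`` may be empty (pure CFA).
    loadings : mapping ``(indicator, factor) -> None | float``
        ``None`` marks a free loading; a float fixes the loading at that
        value; absent pairs are fixed at zero.
    factor_corr_pairs : sequence of (factor, factor)
        Free factor residual correlations (diagonal of Psi fixed at 1).
    residual_corr_pairs : sequence of (indicator, indicator)
        Free measurement residual correlations.
    structural : sequence of (covariate, factor)
        Free covariate-to-factor regression coefficients.
    direct : sequence of (covariate, indicator)
        Free covariate-to-indicator direct effects.
    """

    indicators: tuple[str, ...]
    factors: tuple[str, ...]
    covariates: tuple[str, ...] = ()
    loadings: Mapping[tuple[str, str], float | None] = field(default_factory=dict)
    factor_corr_pairs: tuple[tuple[str, str], ...] = ()
    residual_corr_pairs: tuple[tuple[str, str], ...] = ()
    structural: tuple[tuple[str, str], ...] = ()
    direct: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "indicators", tuple(self.indicators))
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "loadings", dict(self.loadings))
        object.__setattr__(self, "factor_corr_pairs", tuple(tuple(p) for p in self.factor_corr_pairs))
        object.__setattr__(
            self, "residual_corr_pairs", tuple(tuple(p) for p in self.residual_corr_pairs)
        )
        object.__setattr__(self, "structural", tuple(tuple(p) for p in self.structural))
        object.__setattr__(self, "direct", tuple(tuple(p) for p in self.direct))
        self._validate()

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        ind, fac, cov = set(self.indicators), set(self.factors), set(self.covariates)
        if len(ind) != len(self.indicators) or len(fac) != len(self.factors):
            raise ValueError("duplicate indicator or factor names")
        for (i, f) in self.loadings:
            if i not in ind or f not in fac:
                raise ValueError(f"loading ({i}, {f}) references unknown names")
        anchored = {f: False for f in self.factors}
        for (_, f), v in self.loadings.items():
            if v is FREE or v != 0:
                anchored[f] = True
        for f, ok in anchored.items():
            if not ok:
                raise ValueError(f"factor {f!r} has no free or fixed nonzero loading")
        for a, b in self.factor_corr_pairs:
            if a not in fac or b not in fac or a == b:
                raise ValueError(f"bad factor correlation pair ({a}, {b})")
        for a, b in self.residual_corr_pairs:
            if a not in ind or b not in ind or a == b:
                raise ValueError(f"bad residual correlation pair ({a}, {b})")
        seen = set()
        for a, b in self.residual_corr_pairs:
            if a in seen or b in seen:
                raise ValueError(
                    "residual correlation pairs must touch disjoint indicators; "
                    f"{a} or {b} appears twice"
                )
            seen.update((a, b))
        for c, f in self.structural:
            if c not in cov or f not in fac:
                raise ValueError(f"bad structural path ({c}, {f})")
        for c, i in self.direct:
            if c not in cov or i not in ind:
                raise ValueError(f"bad direct path ({c}, {i})")

    # -- bookkeeping --------------------------------------------------------
    @property
    def p(self) -> int:
        return len(self.indicators)

    @property
    def m(self) -> int:
        return len(self.factors)

    @property
    def q(self) -> int:
        return len(self.covariates)

    @property
    def free_loadings(self) -> list[tuple[str, str]]:
        return [k for k, v in self.loadings.items() if v is FREE]

    @property
    def fixed_loadings(self) -> dict[tuple[str, str], float]:
        return {k: float(v) for k, v in self.loadings.items() if v is not FREE}

    def blocks(self) -> dict[str, slice]:
        """Slices of each block inside the packed free-parameter vector."""
        sizes = {
            "loading": len(self.free_loadings),
            "factor_corr": len(self.factor_corr_pairs),
            "structural": len(self.structural),
            "direct": len(self.direct),
            "intercept": self.p,
            "resid_var": self.p,
            "resid_corr": len(self.residual_corr_pairs),
        }
        out, start = {}, 0
        for name, size in sizes.items():
            out[name] = slice(start, start + size)
            start += size
        return out

    @property
    def n_free(self) -> int:
        b = self.blocks()
        return b["resid_corr"].stop

    def param_names(self) -> list[str]:
        names = [f"loading:{i}~{f}" for i, f in self.free_loadings]
        names += [f"factor_corr:{a}~{b}" for a, b in self.factor_corr_pairs]
        names += [f"structural:{c}->{f}" for c, f in self.structural]
        names += [f"direct:{c}->{i}" for c, i in self.direct]
        names += [f"intercept:{i}" for i in self.indicators]
        names += [f"resid_var:{i}" for i in self.indicators]
        names += [f"resid_corr:{a}~{b}" for a, b in self.residual_corr_pairs]
        return names

    # -- matrices -----------------------------------------------------------
    def matrices(self, theta: np.ndarray):
        """Unpack a natural-scale free-parameter vector into model matrices.

        Returns ``(Lambda, Psi, B, K, nu, resid_var, resid_corr, Theta)``.
        """
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_free,):
            raise ValueError(f"expected {self.n_free} free parameters, got {theta.shape}")
        b = self.blocks()
        iind = {v: k for k, v in enumerate(self.indicators)}
        ifac = {v: k for k, v in enumerate(self.factors)}
        icov = {v: k for k, v in enumerate(self.covariates)}

        lam = np.zeros((self.p, self.m))
        for (i, f), v in self.fixed_loadings.items():
            lam[iind[i], ifac[f]] = v
        for val, (i, f) in zip(theta[b["loading"]], self.free_loadings):
            lam[iind[i], ifac[f]] = val

        psi = np.eye(self.m)
        for val, (a, c) in zip(theta[b["factor_corr"]], self.factor_corr_pairs):
            psi[ifac[a], ifac[c]] = psi[ifac[c], ifac[a]] = val

        B = np.zeros((self.m, self.q))
        for val, (c, f) in zip(theta[b["structural"]], self.structural):
            B[ifac[f], icov[c]] = val

        K = np.zeros((self.p, self.q))
        for val, (c, i) in zip(theta[b["direct"]], self.direct):
            K[iind[i], icov[c]] = val

        nu = np.array(theta[b["intercept"]])
        resid_var = np.array(theta[b["resid_var"]])
        resid_corr = np.array(theta[b["resid_corr"]])

        Theta = np.diag(resid_var)
        for r, (a, c) in zip(resid_corr, self.residual_corr_pairs):
            j, k = iind[a], iind[c]
            Theta[j, k] = Theta[k, j] = r * np.sqrt(resid_var[j] * resid_var[k])
        return lam, psi, B, K, nu, resid_var, resid_corr, Theta

    # -- transforms ---------------------------------------------------------
    def to_unconstrained(self, theta: np.ndarray) -> np.ndarray:
        """Map natural parameters to the unconstrained optimization space."""
        t = np.array(theta, dtype=float)
        b = self.blocks()
        t[b["factor_corr"]] = np.arctanh(t[b["factor_corr"]])
        t[b["resid_var"]] = np.log(t[b["resid_var"]])
        t[b["resid_corr"]] = np.arctanh(t[b["resid_corr"]])
        return t

    def to_natural(self, t: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_unconstrained`."""
        theta = np.array(t, dtype=float)
        b = self.blocks()
        theta[b["factor_corr"]] = np.tanh(theta[b["factor_corr"]])
        theta[b["resid_var"]] = np.exp(theta[b["resid_var"]])
        theta[b["resid_corr"]] = np.tanh(theta[b["resid_corr"]])
        return theta

    # -- variations ---------------------------------------------------------
    def with_free(self, kind: str, pair: tuple[str, str]) -> "ModelSpec":
        """A copy of this spec with one additional free parameter.

        ``kind`` is one of ``'loading'``, ``'factor_corr'``,
        ``'residual_corr'``, ``'structural'``, ``'direct'``.
        """
        kw = dict(
            indicators=self.indicators,
            factors=self.factors,
            covariates=self.covariates,
            loadings=dict(self.loadings),
            factor_corr_pairs=self.factor_corr_pairs,
            residual_corr_pairs=self.residual_corr_pairs,
            structural=self.structural,
            direct=self.direct,
        )
        if kind == "loading":
            if kw["loadings"].get(pair, 0.0) is FREE:
                raise ValueError(f"loading {pair} already free")
            kw["loadings"][pair] = FREE
        elif kind == "factor_corr":
            if pair in self.factor_corr_pairs or pair[::-1] in self.factor_corr_pairs:
                raise ValueError(f"factor correlation {pair} already free")
            kw["factor_corr_pairs"] = self.factor_corr_pairs + (pair,)
        elif kind == "residual_corr":
            if pair in self.residual_corr_pairs or pair[::-1] in self.residual_corr_pairs:
                raise ValueError(f"residual correlation {pair} already free")
            kw["residual_corr_pairs"] = self.residual_corr_pairs + (pair,)
        elif kind == "structural":
            if pair in self.structural:
                raise ValueError(f"structural path {pair} already free")
            kw["structural"] = self.structural + (pair,)
        elif kind == "direct":
            if pair in self.direct:
                raise ValueError(f"direct path {pair} already free")
            kw["direct"] = self.direct + (pair,)
        else:
            raise ValueError(f"unknown parameter kind {kind!r}")
        return ModelSpec(**kw)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "indicators": list(self.indicators),
            "factors": list(self.factors),
            "covariates": list(self.covariates),
            "loadings": [
                {"indicator": i, "factor": f, "value": ("free" if v is FREE else float(v))}
                for (i, f), v in self.loadings.items()
            ],
            "factor_corr_pairs": [list(p) for p in self.factor_corr_pairs],
            "residual_corr_pairs": [list(p) for p in self.residual_corr_pairs],
            "structural": [list(p) for p in self.structural],
            "direct": [list(p) for p in self.direct],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        loadings = {
            (e["indicator"], e["factor"]): (FREE if e["value"] == "free" else float(e["value"]))
            for e in d["loadings"]
        }
        return cls(
            indicators=tuple(d["indicators"]),
            factors=tuple(d["factors"]),
            covariates=tuple(d.get("covariates", ())),
            loadings=loadings,
            factor_corr_pairs=tuple(tuple(p) for p in d.get("factor_corr_pairs", ())),
            residual_corr_pairs=tuple(tuple(p) for p in d.get("residual_corr_pairs", ())),
            structural=tuple(tuple(p) for p in d.get("structural", ())),
            direct=tuple(tuple(p) for p in d.get("direct", ())),
        )


def implied_moments(
    spec: ModelSpec, theta: np.ndarray, X: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied means and covariance conditional on covariate rows.

    Parameters
    ----------
    spec : ModelSpec
    theta : natural-scale free-parameter vector
    X : (n, q) covariate matrix or None for a covariate-free model

    Returns
    -------
    mu : (n, p) implied mean per record (or (1, p) when X is None)
    sigma : (p, p) implied covariance, constant across records
    """
    lam, psi, B, K, nu, _, _, Theta = spec.matrices(theta)
    sigma = lam @ psi @ lam.T + Theta
    if X is None or spec.q == 0:
        mu = np.tile(nu, (1 if X is None else len(X), 1))
        if X is None:
            mu = nu[None, :]
    else:
        X = np.asarray(X, dtype=float)
        A = lam @ B + K
        mu = nu[None, :] + X @ A.T
    return mu, sigma
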