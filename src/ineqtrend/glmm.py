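"""Random-intercept logistic regression via adaptive Gauss–Hermite quadrature.

Model, for respondent *i* in cluster *j* (class, school, or country):

    logit P(y_ij = 1 | x_ij, u_j) = beta0 + beta1 * x_ij + u_j,
    u_j ~ Normal(0, sigma_u^2), independent across clusters,

where ``x`` is the fractional-rank SES score.  The cluster effect is
integrated out of the likelihood by adaptive Gauss–Hermite quadrature
centred at each cluster's conditional posterior mode (Laplace is the
one-node special case).  The fixed-effect variance-covariance matrix is
the corresponding block of the inverse observed information at the
optimum; only this block is propagated to the simulation stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .data_model import SurveyTable

__all__ = ["FitResult", "fit_cluster_logit", "profile_loglik"]

logger = logging.getLogger(__name__)

_SIGMA_FLOOR = 1e-10  # below this the model is treated as plain logistic


@dataclass
class FitResult:
    """Fixed-effect estimates for one stratum.

    ``vcov`` is the 2x2 covariance of ``(beta0, beta1)``; ``sigma_u`` is
    the cluster random-intercept standard deviation.
    """

    beta0: float
    beta1: float
    vcov: np.ndarray
    sigma_u: float
    n_obs: int
    n_clusters: int
    converged: bool
    stratum: dict = field(default_factory=dict)
    loglik: float = float("nan")
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "vcov": np.asarray(self.vcov).tolist(),
            "sigma_u": self.sigma_u,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "converged": self.converged,
            "loglik": self.loglik,
            "message": self.message,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        d = dict(d)
        d["vcov"] = np.asarray(d["vcov"], dtype=float)
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FitResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _extract_arrays(table, stratum: Mapping | None):
    """Pull (y, x, cluster codes) for a stratum from a table or DataFrame."""
    df = table.data if isinstance(table, SurveyTable) else table
    if stratum:
        mask = pd.Series(True, index=df.index)
        for col, val in stratum.items():
            mask &= df[col] == val
        df = df.loc[mask]
    if "ses" not in df.columns:
        raise ValueError("SES scores not attached; run ses_rank first")
    y = df["outcome"].to_numpy(dtype=float)
    x = df["ses"].to_numpy(dtype=float)
    cl = pd.factorize(df["cluster"].astype(str) + "\x1f" + df["country"].astype(str))[0] \
        if "country" in df.columns else pd.factorize(df["cluster"])[0]
    return y, x, cl


def _plain_logit_loglik(y, eta):
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _marginal_loglik(y, x, cl, n_cl, beta0, beta1, sigma, nodes=15):
    """Marginal log-likelihood, random intercept integrated out per cluster."""
    lin = beta0 + beta1 * x
    if sigma < _SIGMA_FLOOR:
        return _plain_logit_loglik(y, lin)

    inv_s2 = 1.0 / (sigma * sigma)
    # posterior mode of u_j given y: Newton on the (concave) joint log-density
    u = np.zeros(n_cl)
    for _ in range(100):
        eta = lin + u[cl]
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = np.bincount(cl, weights=y - p, minlength=n_cl) - u * inv_s2
        hneg = np.bincount(cl, weights=p * (1.0 - p), minlength=n_cl) + inv_s2
        step = grad / hneg
        u += step
        if np.max(np.abs(grad)) < 1e-10:
            break
    tau = 1.0 / np.sqrt(hneg)

    z, w = np.polynomial.hermite.hermgauss(nodes)
    log_w = np.log(w)
    const = -0.5 * np.log(2.0 * np.pi) - np.log(sigma)
    # h_j(u) evaluated at the shifted/scaled nodes
    terms = np.empty((nodes, n_cl))
    for k in range(nodes):
        uk = u + np.sqrt(2.0) * tau * z[k]
        eta = lin + uk[cl]
        ll_data = np.bincount(cl, weights=y * eta - np.logaddexp(0.0, eta), minlength=n_cl)
        terms[k] = log_w[k] + z[k] ** 2 + ll_data + const - 0.5 * uk * uk * inv_s2
    log_int = np.log(np.sqrt(2.0) * tau) + logsumexp(terms, axis=0)
    return float(np.sum(log_int))


def profile_loglik(table, params, stratum: Mapping | None = None, quad_nodes: int = 15) -> float:
    """Marginal log-likelihood at candidate ``(beta0, beta1, sigma_u)``.

    Uses the same quadrature rule as :func:`fit_cluster_logit`; exposed so
    the fitted optimum can be audited against independent integration.
    """
    beta0, beta1, sigma = (float(v) for v in params)
    if sigma < 0:
        raise ValueError("sigma_u must be nonnegative")
    y, x, cl = _extract_arrays(table, stratum)
    return _marginal_loglik(y, x, cl, int(cl.max()) + 1, beta0, beta1, sigma, quad_nodes)


def _numerical_hessian(f, theta, rel_step=5e-4):
    """Central-difference Hessian with per-coordinate scaled steps."""
    k = len(theta)
    h = rel_step * (1.0 + np.abs(theta))
    H = np.empty((k, k))
    f0 = f(theta)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_cluster_logit(
    table,
    stratum: Mapping | None = None,
    quad_nodes: int = 15,
    gtol: float = 1e-8,
    max_iter: int = 200,
) -> FitResult:
    """Fit the random-intercept logistic model for one stratum.

    Parameters
    ----------
    table
        :class:`SurveyTable` (or DataFrame) with ``outcome``, ``ses`` and
        ``cluster`` columns.
    stratum
        Optional column→value filter, e.g. ``{"year": 2007, "gender": "boy"}``;
        recorded on the result.
    quad_nodes
        Adaptive Gauss–Hermite node count; 1 gives the Laplace
        approximation.

    Notes
    -----
    With fewer than two clusters the model degenerates and a plain
    logistic regression is fitted instead (``sigma_u = 0``, noted in the
    result message).  Strata with a single outcome value (or separated
    data) are flagged ``converged=False`` and should be excluded
    downstream.
    """
    stratum_label = dict(stratum) if stratum else {}
    y, x, cl = _extract_arrays(table, stratum)
    n = y.size
    n_cl = int(cl.max()) + 1 if n else 0

    def failure(msg):
        logger.warning("stratum %s: %s", stratum_label, msg)
        return FitResult(
            beta0=np.nan, beta1=np.nan, vcov=np.full((2, 2), np.nan),
            sigma_u=np.nan, n_obs=n, n_clusters=n_cl, converged=False,
            stratum=stratum_label, message=msg,
        )

    if n == 0:
        return failure("empty stratum")
    if len(np.unique(y)) < 2:
        return failure("all outcomes identical; model not estimable")

    # starting values from ordinary logistic regression
    import statsmodels.api as sm

    X = sm.add_constant(x)
    try:
        glm0 = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        b0, b1 = glm0.params
    except Exception:  # pragma: no cover - degenerate start
        b0, b1 = float(np.log(y.mean() / (1 - y.mean() + 1e-12))), 0.0

    if n_cl < 2:
        logger.info("stratum %s: <2 clusters, plain logistic fallback", stratum_label)
        return FitResult(
            beta0=float(b0), beta1=float(b1),
            vcov=np.asarray(glm0.cov_params()), sigma_u=0.0,
            n_obs=n, n_clusters=n_cl, converged=True, stratum=stratum_label,
            loglik=_plain_logit_loglik(y, b0 + b1 * x),
            message="single cluster: plain logistic regression",
        )

    def nll(theta):
        return -_marginal_loglik(y, x, cl, n_cl, theta[0], theta[1], theta[2], quad_nodes)

    theta0 = np.array([b0, b1, 0.3])
    res = minimize(
        nll, theta0, method="L-BFGS-B",
        bounds=[(None, None), (None, None), (0.0, None)],
        options={"gtol": gtol, "ftol": 1e-14, "maxiter": max_iter},
    )
    beta0_hat, beta1_hat, sigma_hat = res.x
    if not np.isfinite(res.fun):
        return failure("likelihood not finite at optimum (separation?)")

    at_boundary = sigma_hat < 1e-6
    if at_boundary:
        H = _numerical_hessian(lambda t: nll(np.r_[t, 0.0]), res.x[:2])
        vcov2 = np.linalg.inv(0.5 * (H + H.T))
    else:
        H = _numerical_hessian(nll, res.x)
        H = 0.5 * (H + H.T)
        try:
            vcov_full = np.linalg.inv(H)
            vcov2 = vcov_full[:2, :2]
        except np.linalg.LinAlgError:
            return failure("observed information singular at optimum")
    vcov2 = 0.5 * (vcov2 + vcov2.T)
    ok = bool(res.success and np.all(np.diag(vcov2) > 0))

    return FitResult(
        beta0=float(beta0_hat), beta1=float(beta1_hat), vcov=vcov2,
        sigma_u=float(0.0 if at_boundary else sigma_hat),
        n_obs=n, n_clusters=n_cl, converged=ok, stratum=stratum_label,
        loglik=float(-res.fun), message=str(res.message),
    )
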