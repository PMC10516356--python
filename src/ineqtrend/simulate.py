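"""Propagation of coefficient uncertainty to prevalence space.

Coefficient vectors ``(beta0, beta1)`` are drawn from the bivariate
normal implied by the fitted model; each draw maps to a prevalence pair
``(P(1), P(0))`` through the inverse logit at the two ends of the SES
scale.  Confidence regions are the 95% level-set ellipse of the fitted
Gaussian in coefficient space, mapped pointwise to prevalence space — the
mapped curve is no longer an ellipse and bends near 0/1 prevalence, which
is the intended behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import chi2

from .glmm import FitResult

__all__ = [
    "CoefficientDraws",
    "PrevalencePair",
    "ConfidenceRegion",
    "draw_coefficients",
    "prevalence_at_extremes",
    "prevalence_pair",
    "confidence_region",
]


@dataclass
class CoefficientDraws:
    """Simulated ``(beta0, beta1)`` vectors for one stratum."""

    draws: np.ndarray  # (n_sim, 2)
    mean: np.ndarray  # (2,)
    vcov: np.ndarray  # (2, 2)
    seed: int
    stratum: dict = field(default_factory=dict)

    @property
    def n_sim(self) -> int:
        return self.draws.shape[0]


@dataclass
class PrevalencePair:
    """Point estimate and simulated cloud of ``(P(1), P(0))`` for one wave."""

    p1: float
    p0: float
    draw_cloud: np.ndarray  # (n_sim, 2) columns (p1, p0)
    ci_p1: tuple[float, float]
    ci_p0: tuple[float, float]
    stratum: dict = field(default_factory=dict)


@dataclass
class ConfidenceRegion:
    """Closed boundary curve of the mapped 95% region in (p1, p0) space."""

    boundary: np.ndarray  # (m, 2), closed (first point repeated last)
    level: float = 0.95
    degenerate: bool = False
    stratum: dict = field(default_factory=dict)


def draw_coefficients(fit: FitResult, n_sim: int = 10_000, seed: int = 0) -> CoefficientDraws:
    """Draw coefficient vectors from N((beta0, beta1), vcov).

    Deterministic given ``seed``.  The covariance matrix is symmetrized;
    if it is not positive semidefinite after symmetrization a
    ``ValueError`` carrying the matrix is raised.
    """
    if not fit.converged:
        raise ValueError(f"cannot simulate from non-converged fit {fit.stratum}")
    mean = np.array([fit.beta0, fit.beta1], dtype=float)
    vcov = 0.5 * (np.asarray(fit.vcov, dtype=float) + np.asarray(fit.vcov, dtype=float).T)
    eig = np.linalg.eigvalsh(vcov)
    if eig.min() < -1e-12 * max(1.0, eig.max()):
        raise ValueError(f"vcov not positive semidefinite: {vcov!r}")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mean, vcov, size=n_sim, method="eigh")
    return CoefficientDraws(draws=draws, mean=mean, vcov=vcov, seed=seed,
                            stratum=dict(fit.stratum))


def prevalence_at_extremes(beta0, beta1):
    """Prevalence at the top and bottom of the SES scale.

    ``p0 = invlogit(beta0)`` is the model prevalence at SES = 0 (lowest
    parental education), ``p1 = invlogit(beta0 + beta1)`` at SES = 1.
    Returns ``(p1, p0)``; accepts scalars or arrays.
    """
    beta0 = np.asarray(beta0, dtype=float)
    beta1 = np.asarray(beta1, dtype=float)
    p0 = expit(beta0)
    p1 = expit(beta0 + beta1)
    if p0.ndim == 0:
        return float(p1), float(p0)
    return p1, p0


def prevalence_pair(draws: CoefficientDraws, level: float = 0.95) -> PrevalencePair:
    """Map a draw set to prevalence space with percentile intervals."""
    p1_hat, p0_hat = prevalence_at_extremes(draws.mean[0], draws.mean[1])
    p1, p0 = prevalence_at_extremes(draws.draws[:, 0], draws.draws[:, 1])
    lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    return PrevalencePair(
        p1=p1_hat, p0=p0_hat,
        draw_cloud=np.column_stack([p1, p0]),
        ci_p1=(float(np.percentile(p1, lo)), float(np.percentile(p1, hi))),
        ci_p0=(float(np.percentile(p0, lo)), float(np.percentile(p0, hi))),
        stratum=dict(draws.stratum),
    )


def confidence_region(
    draws: CoefficientDraws, level: float = 0.95, n_points: int = 360
) -> ConfidenceRegion:
    """Level-set ellipse of the draws' fitted Gaussian, mapped to prevalences.

    The ellipse uses the sample mean and covariance of the draws with
    radius ``sqrt(chi2.ppf(level, df=2))``; its discretized boundary is
    pushed through :func:`prevalence_at_extremes` point by point, giving a
    closed curve in the open unit square.  A rank-deficient draw
    covariance collapses the region to a segment (flagged ``degenerate``).
    """
    if draws.n_sim < 100:
        raise ValueError("need at least 100 draws for a confidence region")
    m = draws.draws.mean(axis=0)
    S = np.cov(draws.draws, rowvar=False)
    S = 0.5 * (S + S.T)
    evals, evecs = np.linalg.eigh(S)
    evals = np.clip(evals, 0.0, None)
    degenerate = bool(evals.min() <= 1e-14 * max(evals.max(), 1e-300))
    r = np.sqrt(chi2.ppf(level, df=2))
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    ellipse = m + r * circle @ np.diag(np.sqrt(evals)) @ evecs.T
    p1, p0 = prevalence_at_extremes(ellipse[:, 0], ellipse[:, 1])
    boundary = np.column_stack([p1, p0])
    boundary = np.vstack([boundary, boundary[:1]])  # close the curve
    return ConfidenceRegion(boundary=boundary, level=level, degenerate=degenerate,
                            stratum=dict(draws.stratum))
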