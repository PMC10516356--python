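"""Synthetic survey micro-data with known ground truth.

Emulates the structure of repeated cross-sectional school surveys:
countries × quadrennial waves × clusters (classes), a five-level ordinal
parental-education scale with country-specific category distributions,
a logistic SES–outcome gradient that changes by wave, and cluster-level
random variation.  The generating model applies the SES effect to the
*fractional-rank* score computed by the same rule the analysis pipeline
uses, so generator truth and pipeline truth coincide by construction and
every stage can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .data_model import (
    DEFAULT_EDUCATION_LEVELS,
    SurveySchema,
    SurveyTable,
    exclude_incomplete,
    ses_rank,
)

__all__ = ["Scenario", "generate_microdata", "scenario_from_line"]

DEFAULT_WAVES = (2003, 2007, 2011, 2015)


@dataclass
class Scenario:
    """Ground truth for one synthetic study.

    ``true_beta0[t]``/``true_beta1[t]`` are the wave-*t* fixed effects on
    the log-odds scale; ``sigma_u`` the cluster random-intercept SD.
    ``ses_category_probs`` holds one distribution over the education
    categories per country; if ``None``, country-specific distributions
    are drawn from a flat Dirichlet when the data are generated.
    """

    true_beta0: tuple[float, ...]
    true_beta1: tuple[float, ...]
    sigma_u: float = 0.5
    n_countries: int = 10
    waves: tuple[int, ...] = DEFAULT_WAVES
    clusters_per_country: int = 20
    respondents_per_cluster: int = 25
    ses_category_probs: list[list[float]] | None = None
    gender_split: float = 0.5
    seed: int = 0
    education_levels: tuple[str, ...] = DEFAULT_EDUCATION_LEVELS

    def __post_init__(self):
        if len(self.true_beta0) != len(self.waves) or len(self.true_beta1) != len(self.waves):
            raise ValueError("need one (beta0, beta1) pair per wave")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be nonnegative")
        if min(self.n_countries, self.clusters_per_country, self.respondents_per_cluster) < 1:
            raise ValueError("counts must be positive")
        if self.ses_category_probs is not None:
            probs = np.asarray(self.ses_category_probs, dtype=float)
            if probs.shape != (self.n_countries, len(self.education_levels)):
                raise ValueError("ses_category_probs must be n_countries x n_categories")
            if not np.allclose(probs.sum(axis=1), 1.0):
                raise ValueError("category probabilities must sum to 1 per country")

    def true_pairs(self) -> np.ndarray:
        """Closed-form (p1, p0) implied by the per-wave truth; shape (n_waves, 2)."""
        b0 = np.asarray(self.true_beta0, dtype=float)
        b1 = np.asarray(self.true_beta1, dtype=float)
        return np.column_stack([expit(b0 + b1), expit(b0)])

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "true_beta0": list(map(float, self.true_beta0)),
            "true_beta1": list(map(float, self.true_beta1)),
            "sigma_u": float(self.sigma_u),
            "n_countries": self.n_countries,
            "waves": list(self.waves),
            "clusters_per_country": self.clusters_per_country,
            "respondents_per_cluster": self.respondents_per_cluster,
            "ses_category_probs": self.ses_category_probs,
            "gender_split": float(self.gender_split),
            "seed": self.seed,
            "education_levels": list(self.education_levels),
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("true_beta0", "true_beta1", "waves", "education_levels"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def scenario_from_line(
    slope: float, intercept: float, p1_per_wave, **scenario_kwargs
) -> Scenario:
    """Scenario whose per-wave truth lies exactly on a (p1, p0) line.

    Inverts ``p0 = intercept + slope * p1`` to per-wave log-odds
    coefficients: ``beta0 = logit(p0)``, ``beta1 = logit(p1) - logit(p0)``.
    Raises if any implied prevalence falls outside (0, 1).
    """
    p1 = np.asarray(p1_per_wave, dtype=float)
    p0 = intercept + slope * p1
    if np.any((p0 <= 0) | (p0 >= 1) | (p1 <= 0) | (p1 >= 1)):
        raise ValueError(
            f"implied prevalences outside (0,1): p1={p1.tolist()}, p0={p0.tolist()}"
        )
    b0 = logit(p0)
    b1 = logit(p1) - logit(p0)
    scenario_kwargs.setdefault("waves", tuple(DEFAULT_WAVES[: len(p1)]))
    return Scenario(true_beta0=tuple(b0), true_beta1=tuple(b1), **scenario_kwargs)


def generate_microdata(scenario: Scenario) -> SurveyTable:
    """Draw a full respondent-level table from a scenario.

    Clusters are nested in country × wave (fresh classes each wave, as in
    repeated cross-sections).  Education categories are drawn per country,
    the fractional-rank SES score is computed by the pipeline's own rule
    (pooled over waves within country), and the outcome is Bernoulli with
    logit ``beta0[t] + beta1[t] * ses + u_cluster``.  Deterministic given
    ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    K = len(scenario.education_levels)
    if scenario.ses_category_probs is None:
        probs = rng.dirichlet(np.full(K, 2.0), size=scenario.n_countries)
    else:
        probs = np.asarray(scenario.ses_category_probs, dtype=float)

    rows = []
    rid = 0
    for c in range(scenario.n_countries):
        country = f"C{c:02d}"
        for t, year in enumerate(scenario.waves):
            for k in range(scenario.clusters_per_country):
                u_j = rng.normal(0.0, scenario.sigma_u)
                n = scenario.respondents_per_cluster
                edu = rng.choice(K, size=n, p=probs[c])
                girl = rng.random(n) < scenario.gender_split
                for i in range(n):
                    rows.append(
                        (f"R{rid + i:07d}", country, f"{country}_y{year}_k{k:03d}",
                         year, "girl" if girl[i] else "boy", int(edu[i]), t, u_j)
                    )
                rid += n
    df = pd.DataFrame(
        rows,
        columns=["respondent_id", "country", "cluster", "year", "gender",
                 "_edu_code", "_wave_idx", "_u"],
    )
    levels = list(scenario.education_levels)
    df["edu_mother"] = [levels[e] for e in df["_edu_code"]]
    df["edu_father"] = ""
    df["outcome"] = 0  # placeholder until SES scores exist

    schema = SurveySchema(education_levels=tuple(levels))
    table = SurveyTable(data=df, schema=schema)
    table = ses_rank(exclude_incomplete(table))

    d = table.data
    b0 = np.asarray(scenario.true_beta0, dtype=float)[d["_wave_idx"]]
    b1 = np.asarray(scenario.true_beta1, dtype=float)[d["_wave_idx"]]
    p = expit(b0 + b1 * d["ses"].to_numpy() + d["_u"].to_numpy())
    d["outcome"] = (rng.random(len(d)) < p).astype(int)
    d = d.drop(columns=["_edu_code", "_wave_idx", "_u"])
    return SurveyTable(data=d, schema=schema, exclusions=table.exclusions)
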