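"""End-to-end driver: rank → per-stratum GLMM → simulate → trend → summary.

Strata are gender × region combinations (plus the pooled "all" level for
each); within each stratum one random-intercept logistic model is fitted
per survey wave, coefficient uncertainty is propagated by simulation, and
the per-wave prevalence pairs feed the trend line and eradication
likelihood.  Per-stratum random draws use substreams derived
deterministically from one master seed, so any stratum can be recomputed
independently with identical results.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import SurveyTable, exclude_incomplete, read_survey, ses_rank
from .glmm import FitResult, fit_cluster_logit
from .simulate import confidence_region, draw_coefficients, prevalence_pair
from .trend import TrendResult, eradication_likelihood, summarize

__all__ = ["RunConfig", "run_pipeline", "analyze_table", "trends_from_fits", "default_region_map"]

logger = logging.getLogger(__name__)

REGION_ORDER = ("all", "North", "East", "South", "West")


def default_region_map() -> dict[str, str]:
    """The packaged UN-geoscheme country→region map for Europe."""
    ref = importlib.resources.files("ineqtrend") / "data" / "regions_un_europe.yaml"
    return yaml.safe_load(ref.read_text())


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    input: str | None = None
    outdir: str = "ineqtrend_out"
    n_sim: int = 10_000
    seed: int = 0
    threshold: float = 0.05
    stratify_gender: bool = True
    stratify_region: bool = False
    region_map: str | None = None  # YAML path; None with stratify_region uses the packaged map
    rank_mode: str = "pooled"
    quad_nodes: int = 15
    make_plots: bool = True

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.n_sim < 100:
            raise ValueError("n_sim must be at least 100")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        d.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**d)


def _stratum_seed(master: int, stratum: dict, year) -> int:
    """Stable per-(stratum, wave) substream seed below 2**31."""
    key = f"{master}|{stratum.get('region', 'all')}|{stratum.get('gender', 'all')}|{year}"
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def _strata(table: SurveyTable, config: RunConfig):
    genders = [None]
    if config.stratify_gender:
        genders += list(table.schema.genders)
    regions = [None]
    if config.stratify_region and "region" in table.data.columns:
        present = [r for r in table.data["region"].unique() if r != "other"]
        regions += sorted(present, key=lambda r: (REGION_ORDER.index(r) if r in REGION_ORDER else 99, r))
    for region in regions:
        for gender in genders:
            label = {}
            if region is not None:
                label["region"] = region
            if gender is not None:
                label["gender"] = gender
            yield label


def analyze_table(table: SurveyTable, config: RunConfig):
    """Fit every stratum × wave model on an SES-ranked table.

    Returns ``{stratum_key: [FitResult per wave]}`` where ``stratum_key``
    is the ``(region, gender)`` pair (``"all"`` for unstratified levels).
    Non-estimable waves are kept as non-converged results and filtered
    downstream.
    """
    years = sorted(table.data["year"].unique())
    fits: dict[tuple[str, str], list[FitResult]] = {}
    for label in _strata(table, config):
        key = (label.get("region", "all"), label.get("gender", "all"))
        per_wave = []
        for year in years:
            flt = dict(label)
            flt["year"] = int(year)
            fit = fit_cluster_logit(table, stratum=flt, quad_nodes=config.quad_nodes)
            per_wave.append(fit)
        fits[key] = per_wave
    return fits


def trends_from_fits(fits, config: RunConfig):
    """Simulation + trend stage, reproducible from archived fit results.

    For each stratum: draw coefficient vectors per wave, map to
    prevalence pairs with percentile CIs and confidence regions, then fit
    the trend line of P(0) on P(1) and score eradication.  Returns
    ``(trend results, details)`` where ``details`` keeps the per-wave
    pairs and regions for plotting and export.
    """
    results: list[TrendResult] = []
    details: dict[tuple[str, str], dict] = {}
    for key, per_wave in fits.items():
        stratum = {"region": key[0], "gender": key[1]}
        good = [f for f in per_wave if f.converged]
        if len(good) < 2:
            logger.warning("stratum %s: only %d usable waves; dropped", key, len(good))
            continue
        pairs, regions_, clouds, years = [], [], [], []
        for f in good:
            year = f.stratum.get("year")
            draws = draw_coefficients(f, n_sim=config.n_sim,
                                      seed=_stratum_seed(config.seed, stratum, year))
            pp = prevalence_pair(draws)
            pairs.append(pp)
            regions_.append(confidence_region(draws))
            clouds.append(pp.draw_cloud)
            years.append(year)
        sim_points = np.stack(clouds, axis=1)  # (n_sim, n_waves, 2)
        points = [(p.p1, p.p0) for p in pairs]
        try:
            tr = eradication_likelihood(
                sim_points, threshold=config.threshold, points=points, stratum=stratum
            )
        except (ValueError, RuntimeError) as exc:
            logger.warning("stratum %s: trend failed (%s); dropped", key, exc)
            continue
        results.append(tr)
        details[key] = {"pairs": pairs, "regions": regions_, "years": years,
                        "trend": tr, "fits": good}
    return results, details


def run_pipeline(config: RunConfig, table: SurveyTable | None = None) -> dict:
    """Execute the full analysis and write the artifact bundle.

    Writes to ``config.outdir``: ``summary.csv`` / ``summary.txt``
    (Table-style results), ``prevalence.csv`` (per stratum × wave),
    ``fits.json`` (archived coefficient estimates), ``exclusions.json``,
    ``run_log.json`` and per-stratum figures.  Raises ``RuntimeError``
    only when every stratum fails.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if table is None:
        if config.input is None:
            raise ValueError("config.input is required when no table is passed")
        table = read_survey(config.input)
    if "edu" not in table.data.columns:
        table = exclude_incomplete(table)
    if not table.has_ses:
        table = ses_rank(table, mode=config.rank_mode)
    if config.stratify_region:
        rmap = (yaml.safe_load(Path(config.region_map).read_text())
                if config.region_map else default_region_map())
        table = table.attach_regions(rmap)

    fits = analyze_table(table, config)
    results, details = trends_from_fits(fits, config)
    if not results:
        raise RuntimeError("all strata failed; nothing to report")

    summary = summarize(results, region_order=REGION_ORDER)
    summary.to_csv(outdir / "summary.csv", index=False)
    (outdir / "summary.txt").write_text(summary.to_string(index=False) + "\n")

    prev_rows = []
    for key, det in details.items():
        for year, pp in zip(det["years"], det["pairs"]):
            prev_rows.append({
                "region": key[0], "gender": key[1], "year": year,
                "p1": pp.p1, "p0": pp.p0,
                "p1_ci_low": pp.ci_p1[0], "p1_ci_high": pp.ci_p1[1],
                "p0_ci_low": pp.ci_p0[0], "p0_ci_high": pp.ci_p0[1],
            })
    pd.DataFrame(prev_rows).to_csv(outdir / "prevalence.csv", index=False)

    all_fits = [f.to_dict() for per_wave in fits.values() for f in per_wave]
    (outdir / "fits.json").write_text(json.dumps(all_fits, indent=2))
    table.write_exclusion_report(outdir / "exclusions.json")

    figures = []
    if config.make_plots:
        from .viz import plot_trend

        for key, det in details.items():
            stem = outdir / f"trend_{key[0]}_{key[1]}"
            figures += plot_trend(
                det["pairs"], det["regions"], det["trend"].line,
                threshold=config.threshold, years=det["years"],
                path=stem, title=f"region={key[0]}, gender={key[1]}",
            )

    log = {
        "config": asdict(config),
        "seed": config.seed,
        "exclusions": table.exclusions,
        "non_converged": [f.to_dict() for per_wave in fits.values()
                          for f in per_wave if not f.converged],
        "stratum_seeds": {
            f"{k[0]}/{k[1]}/{y}": _stratum_seed(config.seed, {"region": k[0], "gender": k[1]}, y)
            for k, det in details.items() for y in det["years"]
        },
        "versions": _versions(),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))

    return {"summary": summary, "results": results, "details": details,
            "fits": fits, "table": table, "figures": figures}


def _versions() -> dict:
    import matplotlib
    import scipy
    import statsmodels

    from . import __version__

    return {
        "ineqtrend": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "matplotlib": matplotlib.__version__,
    }
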