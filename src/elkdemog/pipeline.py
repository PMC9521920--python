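"""End-to-end orchestration: covariates → bear reconstruction → elk series →
predictor selection → recruitment models → abundance model → density test.

A run consumes either delimited-text inputs (weather, bear mortalities,
composition counts, counts+harvest, timber stands) or a synthetic block
that generates the same tables, then writes screening tables, model
summaries, trend tables, exclusion logs, and a machine-readable manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import bear, covariates, elk, io, recruitment, selection, synth
from .mcmc import MCMCConfig

log = logging.getLogger(__name__)

#: hypothesis -> candidate predictor columns (the covariate-table groupings)
DEFAULT_HYPOTHESES: dict[str, list[str]] = {
    "winter_severity": ["mean_winter_temp", "mean_monthly_min_winter_temp",
                        "total_snowfall", "mean_snow_depth"],
    "spring_bottleneck": ["mean_spring_temp", "spring_precip",
                          "last_spring_freeze", "winter_duration"],
    "maternal_carryover": ["mean_summer_temp", "summer_precip", "gdd",
                           "spei_forest", "spei_grassland", "mean_fall_temp",
                           "fall_precip", "first_fall_freeze"],
    "predation": ["bear_abundance"],
    "timber_harvest": ["timber_age_lt1", "timber_age_1_5", "timber_age_6_30",
                       "timber_age_gt30", "timber_total"],
}

#: hypotheses whose predictors enter the abundance (count growth) model;
#: predation and timber are excluded there (no bear index or logging for the
#: counted herd's island)
ABUNDANCE_HYPOTHESES = ("winter_severity", "spring_bottleneck",
                        "maternal_carryover")


@dataclass
class RunConfig:
    out_dir: str | Path = "out"
    seed: int = 0
    synthetic: bool = True
    input_paths: dict[str, str] = field(default_factory=dict)
    timber_herds: tuple[str, ...] = ("north", "south")
    herd_blocklist: tuple[str, ...] = ()
    correlation_threshold: float = 0.7
    min_group_total: int = 5
    n_boot: int = 2000
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    hypotheses: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_HYPOTHESES.items()})
    latitude: float = 58.0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "mcmc" in d and isinstance(d["mcmc"], dict):
            d["mcmc"] = MCMCConfig(**d["mcmc"])
        for key in ("timber_herds", "herd_blocklist"):
            if key in d:
                d[key] = tuple(d[key])
        if bool(d.get("synthetic", True)) == bool(d.get("input_paths")):
            raise ValueError("exactly one of synthetic / input_paths required")
        return cls(**d)


@dataclass
class PipelineData:
    daily: pd.DataFrame
    mortality_records: pd.DataFrame
    composition: pd.DataFrame
    counts: pd.Series
    harvest: pd.Series | None
    stands: pd.DataFrame | None


def load_synthetic(config: RunConfig) -> PipelineData:
    """Generate a full synthetic data bundle sized like the study system."""
    seed = config.seed
    daily = synth.simulate_daily_weather(synth.WeatherConfig(), seed=seed)
    mortality, _, _ = synth.simulate_bear_harvest(
        synth.BearConfig(deterministic=False, final_cull=False), seed=seed)
    stands = synth.simulate_timber_stands(seed=seed)

    # covariate effects need the real predictor table; build a provisional
    # one (without the bear index) to drive the elk generator
    years = range(1958, 2021)
    table = covariates.build_predictor_table(
        daily, covariates.PredictorTableSpec(years, config.latitude),
        stands=stands)
    cov_cols = ["mean_winter_temp", "mean_spring_temp", "mean_fall_temp",
                "first_fall_freeze", "mean_monthly_min_winter_temp"]
    z, _ = elk.standardize_predictors(table[cov_cols].dropna())
    elk_cfg = synth.ElkConfig(
        cov_coefs={"mean_winter_temp": 0.136, "mean_spring_temp": 0.018,
                   "mean_fall_temp": -0.023},
        ratio_coefs={"mean_monthly_min_winter_temp": -1.1,
                     "first_fall_freeze": 2.8},
    )
    sim = synth.simulate_elk_system(elk_cfg, covariates=z, seed=seed)
    composition = synth.composition_from_ratios(
        sim["ratios"],
        herds=tuple(config.timber_herds) + ("island", "cove"),
        error_prob=0.03, seed=seed)
    return PipelineData(daily, mortality, composition, sim["counts"],
                        sim["harvest"], stands)


def load_from_paths(config: RunConfig) -> PipelineData:
    paths = config.input_paths
    counts, harvest = io.read_count_series(paths["counts"])
    return PipelineData(
        daily=io.read_daily_weather(paths["weather"]),
        mortality_records=io.read_mortality_records(paths["bear_mortalities"]),
        composition=io.read_composition(paths["composition"]),
        counts=counts,
        harvest=harvest,
        stands=io.read_stands(paths["stands"]) if "stands" in paths else None,
    )


def _fit_one_recruitment(
    name: str,
    ratios: pd.Series,
    table: pd.DataFrame,
    hypotheses: dict[str, list[str]],
    config: RunConfig,
    results: dict,
) -> None:
    years = ratios.index.intersection(table.dropna(how="all").index)
    response = ratios.loc[years]
    preds = table.loc[years].dropna(axis=1, how="any")
    r2 = selection.univariate_r2_screen(response, preds)
    corr = selection.pairwise_correlation(preds)
    sel = selection.select_representatives(
        r2, hypotheses, corr, config.correlation_threshold)
    chosen = list(sel.chosen.values())
    z, scaling = elk.standardize_predictors(preds[chosen])
    fit = recruitment.fit_recruitment_glm(response, z, config.mcmc)
    results[name] = {
        "screen_r2": r2, "selection": sel, "scaling": scaling, "fit": fit,
        "n": len(response),
        "trend": elk.linear_trend(response),
        "ranges": {c: (float(preds[c].min()), float(preds[c].max()))
                   for c in chosen},
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the in-memory result bundle.

    Writes, under `config.out_dir`: the predictor table, bear
    reconstruction, exclusion log, trend table, per-model screening and
    posterior summary tables, the density-dependence test result, and a
    run manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.mcmc.seed is None:
        # every random stage derives from the run seed
        config = replace(config, mcmc=replace(config.mcmc, seed=config.seed))
    data = load_synthetic(config) if config.synthetic else load_from_paths(config)
    results: dict = {}

    # --- bear reconstruction -------------------------------------------------
    stage = "bear_recon"
    try:
        table = bear.build_harvest_matrix(data.mortality_records,
                                          unaged_allocation="uniform")
        recon = bear.downing_reconstruct(table)
        results["bear"] = recon
        bear_series = recon.total
    except Exception as exc:  # pragma: no cover - abort path
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # --- covariates ----------------------------------------------------------
    stage = "covariates"
    try:
        years = range(int(data.counts.index.min()),
                      int(data.counts.index.max()) + 1)
        ptable = covariates.build_predictor_table(
            data.daily, covariates.PredictorTableSpec(years, config.latitude),
            stands=data.stands, bear_abundance=bear_series)
        results["predictors"] = ptable
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # --- elk series ----------------------------------------------------------
    stage = "elk_data"
    filt = elk.filter_composition_counts(
        data.composition, config.min_group_total, config.herd_blocklist)
    timber_set = set(config.timber_herds)
    groups = {
        "timber": filt.retained[filt.retained["herd"].isin(timber_set)],
        "non_timber": filt.retained[~filt.retained["herd"].isin(timber_set)],
        "island_wide": filt.retained,
    }
    ratios = {name: elk.aggregate_age_ratios(grp)
              for name, grp in groups.items() if len(grp)}
    count_series = elk.interpolate_missing_counts(data.counts)
    results["exclusions"] = filt.exclusions
    results["ratios"] = ratios
    results["counts"] = count_series

    trends = {name: elk.linear_trend(series) for name, series in ratios.items()}
    trends["counts"] = elk.linear_trend(count_series.counts)
    trends["bear"] = elk.linear_trend(bear_series)
    results["trends"] = pd.DataFrame(trends).T

    # --- recruitment models --------------------------------------------------
    hyp_no_timber = {k: v for k, v in config.hypotheses.items()
                     if k != "timber_harvest"}
    results["recruitment"] = {}
    for name, hyp in (("timber", config.hypotheses),
                      ("non_timber", hyp_no_timber),
                      ("island_wide", config.hypotheses)):
        if name not in ratios:
            continue
        _fit_one_recruitment(name, ratios[name], ptable, hyp, config,
                             results["recruitment"])

    # --- abundance model -----------------------------------------------------
    stage = "abundance_ssm"
    growth = pd.Series(
        np.log(count_series.counts.to_numpy()[1:]
               / count_series.counts.to_numpy()[:-1]),
        index=count_series.counts.index[1:])
    hyp_ab = {k: config.hypotheses[k] for k in ABUNDANCE_HYPOTHESES}
    avail = ptable.loc[ptable.index.intersection(growth.index)].dropna(
        axis=1, how="any")
    r2_ab = selection.univariate_r2_screen(growth.loc[avail.index], avail)
    sel_ab = selection.select_representatives(
        r2_ab, hyp_ab, selection.pairwise_correlation(avail),
        config.correlation_threshold)
    chosen_ab = list(sel_ab.chosen.values())
    z_ab, scaling_ab = elk.standardize_predictors(
        ptable.loc[count_series.counts.index, chosen_ab].dropna())
    ssm_fit = ab.fit_gompertz_ssm(
        count_series.counts.loc[z_ab.index], data.harvest, z_ab, config.mcmc)
    ddtest = ab.dennis_taper_pblrt(count_series.counts, config.n_boot,
                                   seed=config.seed)
    results["abundance"] = {
        "screen_r2": r2_ab, "selection": sel_ab, "scaling": scaling_ab,
        "fit": ssm_fit, "ddtest": ddtest, "n": len(z_ab),
    }

    _write_outputs(config, results, out)
    return results


def _write_outputs(config: RunConfig, results: dict, out: Path) -> None:
    io.write_table(results["predictors"], out / "predictor_table.csv",
                   index_label="year")
    io.write_table(results["bear"].per_class.assign(
        total=results["bear"].total), out / "bear_reconstruction.csv",
        index_label="year")
    io.write_table(results["exclusions"], out / "exclusion_log.csv", index=False)
    io.write_table(results["trends"], out / "trends.csv", index_label="series")

    screening = {}
    summaries = []
    for name, res in results["recruitment"].items():
        screening[name] = res["screen_r2"]
        s = res["fit"].summary.copy()
        s.insert(0, "model", name)
        summaries.append(s)
    ab_res = results["abundance"]
    screening["abundance"] = ab_res["screen_r2"]
    s = ab_res["fit"].summary.copy()
    s.insert(0, "model", "abundance")
    summaries.append(s)
    io.write_table(pd.DataFrame(screening), out / "screening_r2.csv",
                   index_label="predictor")
    io.write_table(pd.concat(summaries), out / "model_summaries.csv",
                   index_label="parameter")
    io.write_table(ab_res["ddtest"].growth_points, out / "growth_diagnostic.csv",
                   index_label="year")

    dd = ab_res["ddtest"]
    manifest = {
        "seed": config.seed,
        "synthetic": config.synthetic,
        "n_boot": config.n_boot,
        "correlation_threshold": config.correlation_threshold,
        "mcmc": {"chains": config.mcmc.chains,
                 "iterations": config.mcmc.iterations,
                 "burn_in": config.mcmc.burn_in, "thin": config.mcmc.thin},
        "models": {name: {"n": res["n"],
                          "bayes_p": res["fit"].bayes_p,
                          "converged": res["fit"].converged,
                          "predictors": list(res["selection"].chosen.values())}
                   for name, res in results["recruitment"].items()},
        "abundance": {"n": ab_res["n"], "bayes_p": ab_res["fit"].bayes_p,
                      "converged": ab_res["fit"].converged,
                      "predictors": list(ab_res["selection"].chosen.values()),
                      "ddtest_p": dd.p_value, "ddtest_statistic": dd.statistic},
        "config_hash": hashlib.sha256(
            json.dumps({"seed": config.seed, "n_boot": config.n_boot},
                       sort_keys=True).encode()).hexdigest()[:16],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
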