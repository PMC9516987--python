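"""End-to-end orchestration: simulate -> describe -> fit -> diagnose ->
report, driven by a single YAML config with one seed per stage.

Each stage writes its outputs into the run directory and the manifest
records seeds, package version and SHA-256 hashes of every output file, so
any single stage can be re-run reproducibly from the manifest alone.

Sensitivity analyses mirror the study design: refitting on the subset of
preschools that participated in every cohort ("always participating"), and
a disease-mapping variant with the ward-year median score as a Gaussian
outcome.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import residual_moran_screen, scaled_residuals
from .disease_mapping import (DMSpec, dm_rr_summaries, fit_dm,
                              fit_dm_median_variant, forward_build_dm)
from .geography import Geography, GeographyConfig, generate_geography
from .mcmc import InferenceConfig
from .multilevel import MLSpec, fit_ml, forward_build_ml, ml_rr_summaries
from .reporting import MapLayer, build_report, render_choropleth
from .sdq import aggregate_ward_year, apply_exclusions, descriptive_tables
from .synthetic import (ExclusionRates, PopulationConfig, TruthParams,
                        generate_children, write_study)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "run"
    seeds: dict = field(default_factory=lambda: {
        "simulate": 1, "fit_dm": 2, "fit_ml": 3, "diagnose": 4})
    geography: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    exclusion_rates: dict | None = None
    dm: dict = field(default_factory=dict)       # DMSpec fields
    ml: dict = field(default_factory=dict)       # MLSpec fields
    inference: dict = field(default_factory=dict)
    forward_build: bool = False
    always_participating_only: bool = False
    median_outcome_dm: bool = False
    render_maps: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def always_participating_subset(records: pd.DataFrame) -> pd.DataFrame:
    """Children of preschools that returned data in every cohort."""
    cohorts = records["cohort"].nunique()
    per_pre = records.groupby("preschool_id")["cohort"].nunique()
    keep = per_pre[per_pre == cohorts].index
    return records[records["preschool_id"].isin(keep)].copy()


def _write_fit(run: Path, prefix: str, fit, rr: dict) -> None:
    (run / f"{prefix}_fit.json").write_text(
        json.dumps(fit.summary_dict(), indent=1))
    for name, table in rr.items():
        table.to_csv(run / f"{prefix}_rr_{name}.csv", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    run = Path(config.out_dir)
    run.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {"version": __version__, "seeds": config.seeds,
                      "config": asdict(config)}

    # --- simulate -----------------------------------------------------
    t0 = time.perf_counter()
    geo_cfg = GeographyConfig(**{"seed": config.seeds["simulate"],
                                 **config.geography})
    pop = PopulationConfig(**{"seed": config.seeds["simulate"],
                              **config.population})
    truth = TruthParams(**config.truth)
    geo = generate_geography(geo_cfg)
    records, ledger = generate_children(geo, pop, truth)
    if config.exclusion_rates:
        from .synthetic import inject_exclusion_noise
        records, n_bad = inject_exclusion_noise(
            records, ExclusionRates(**config.exclusion_rates),
            seed=config.seeds["simulate"] + 1)
        ledger["n_contaminated"] = n_bad
    write_study(run, geo, records, ledger)
    timings["simulate"] = time.perf_counter() - t0
    logger.info("simulate: %d children, %d wards (%.1fs)", len(records),
                geo.n_wards, timings["simulate"])

    # --- describe -----------------------------------------------------
    t0 = time.perf_counter()
    filtered, tally = apply_exclusions(records)
    (run / "exclusions.json").write_text(json.dumps(tally, indent=1))
    desc = descriptive_tables(filtered)
    desc.to_csv(run / "descriptives.csv", index=False)
    counts = aggregate_ward_year(filtered)
    counts.to_csv(run / "ward_year_counts.csv", index=False)
    timings["describe"] = time.perf_counter() - t0

    inf_dm = InferenceConfig(**{"seed": config.seeds["fit_dm"],
                                **config.inference})
    inf_ml = InferenceConfig(**{"seed": config.seeds["fit_ml"],
                                **config.inference})

    # --- disease mapping ---------------------------------------------
    t0 = time.perf_counter()
    if config.forward_build:
        dm_spec, dm_ledger = forward_build_dm(counts, inference=inf_dm)
        dm_ledger.to_csv(run / "dm_dic_ledger.csv", index=False)
    else:
        dm_kwargs = dict(config.dm)
        if "covariates" in dm_kwargs:
            dm_kwargs["covariates"] = tuple(dm_kwargs["covariates"])
        dm_spec = DMSpec(**dm_kwargs)
    dm_fit = fit_dm(counts, dm_spec, inf_dm)
    dm_rr = dm_rr_summaries(dm_fit, force=True)
    _write_fit(run, "dm", dm_fit, dm_rr)
    timings["fit_dm"] = time.perf_counter() - t0
    logger.info("fit_dm: DIC %.1f, max R-hat %.3f (%.1fs)",
                dm_fit.dic["dic"], dm_fit.max_rhat, timings["fit_dm"])

    # --- multilevel ---------------------------------------------------
    t0 = time.perf_counter()
    if config.forward_build:
        ml_spec, ml_ledger = forward_build_ml(filtered, inference=inf_ml)
        ml_ledger.to_csv(run / "ml_dic_ledger.csv", index=False)
    else:
        ml_kwargs = dict(config.ml)
        if "covariates" in ml_kwargs:
            ml_kwargs["covariates"] = tuple(ml_kwargs["covariates"])
        ml_spec = MLSpec(**ml_kwargs)
    ml_fit = fit_ml(filtered, ml_spec, inf_ml)
    ml_rr = ml_rr_summaries(ml_fit, force=True)
    _write_fit(run, "ml", ml_fit, ml_rr)
    timings["fit_ml"] = time.perf_counter() - t0
    logger.info("fit_ml: DIC %.1f, max R-hat %.3f (%.1fs)",
                ml_fit.dic["dic"], ml_fit.max_rhat, timings["fit_ml"])

    # --- diagnostics --------------------------------------------------
    t0 = time.perf_counter()
    seed_d = config.seeds["diagnose"]
    diag: dict = {}
    res_dm = scaled_residuals(dm_fit, counts, seed=seed_d)
    sorted_counts = counts.sort_values(["ward_id", "cohort"])
    m_dm, dec_dm = residual_moran_screen(
        res_dm, sorted_counts["ward_id"].to_numpy(), geo.adjacency,
        ward_ids=geo.ward_ids, seed=seed_d)
    diag["dm"] = {"moran_I": m_dm.I, "p_value": m_dm.p_value,
                  "spatial_structure": dec_dm,
                  "max_rhat": dm_fit.max_rhat,
                  "converged": dm_fit.converged}
    res_ml = scaled_residuals(ml_fit, filtered, seed=seed_d + 1)
    m_ml, dec_ml = residual_moran_screen(
        res_ml, filtered["ward_id"].to_numpy(), geo.adjacency,
        ward_ids=geo.ward_ids, seed=seed_d + 1)
    diag["ml"] = {"moran_I": m_ml.I, "p_value": m_ml.p_value,
                  "spatial_structure": dec_ml,
                  "max_rhat": ml_fit.max_rhat,
                  "converged": ml_fit.converged}

    # --- sensitivity analyses ----------------------------------------
    if config.always_participating_only:
        sub = always_participating_subset(filtered)
        sub_counts = aggregate_ward_year(sub)
        dm_s = fit_dm(sub_counts, dm_spec, inf_dm)
        ml_s = fit_ml(sub, ml_spec, inf_ml)
        diag["sensitivity_always_participating"] = {
            "n_children": int(len(sub)),
            "n_preschools": int(sub["preschool_id"].nunique()),
            "dm_cohort_rr": float(np.exp(dm_s.mean("beta")[1])),
            "ml_cohort_rr": float(np.exp(ml_s.mean("beta")[1])),
        }
    if config.median_outcome_dm:
        med_fit = fit_dm_median_variant(counts, DMSpec(), inf_dm)
        lo, hi = med_fit.ci("sigma2_u0")
        diag["sensitivity_median_outcome"] = {
            "ward_variance_mean": float(med_fit.mean("sigma2_u0")),
            "ward_variance_ci": [float(lo), float(hi)],
        }
    (run / "diagnostics.json").write_text(json.dumps(diag, indent=1))
    timings["diagnose"] = time.perf_counter() - t0

    # --- maps and report ---------------------------------------------
    t0 = time.perf_counter()
    if config.render_maps:
        ward_desc = desc[desc["grouping"] == "ward"]
        render_choropleth(geo, MapLayer(
            dict(zip(ward_desc["group"].astype(int), ward_desc["median"])),
            title="Median total difficulties score"),
            run / "map_median_score.png")
        render_choropleth(geo, MapLayer(
            dict(zip(ward_desc["group"].astype(int),
                     ward_desc["pct_high"])),
            title="% children with high score"),
            run / "map_pct_high.png")
        for prefix, rr in (("dm", dm_rr), ("ml", ml_rr)):
            w = rr["ward"]
            render_choropleth(geo, MapLayer(
                dict(zip(w["label"].astype(int), w["rr_mean"])),
                title=f"{prefix.upper()} ward relative rate"),
                run / f"map_{prefix}_rr.png")
            render_choropleth(geo, MapLayer(
                dict(zip(w["label"].astype(int), w["exceedance"])),
                title=f"{prefix.upper()} exceedance Pr(RR > 1)",
                kind="exceedance"),
                run / f"map_{prefix}_exceedance.png")
    build_report(run)
    timings["report"] = time.perf_counter() - t0

    manifest["timings_s"] = {k: round(v, 2) for k, v in timings.items()}
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(run.iterdir())
        if p.is_file() and p.name != "manifest.json"}
    (run / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return run
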