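"""End-to-end orchestration: simulate → roster → ingest → metrics → fit →
effects → validate, with seeded reproducibility and a run manifest.

Every stage receives a deterministic sub-seed derived by hashing the stage
name with the master seed, so adding a stage never shifts another stage's
random stream. All stage outputs are flat files (CSV/JSON) so any stage can
be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ingest, roster as roster_mod
from .effects import (EffectConfig, class_rows_for_factor, effects_as_percent,
                      effects_table, interaction_significance,
                      predict_gradient)
from .metrics import compute_site_metrics
from .models import (F, Ix, ModelSpec, N, fit_mixed, gate_against_null,
                     select_random_structure, check_overdispersion)
from .simulate import SimConfig, build_taxonomy, generate_corpus, generate_survey
from .validation import jackknife_continents, morans_i_by_study

__all__ = ["RunConfig", "run_analysis", "stage_seed",
           "INVERTEBRATE_ORDERS", "VERTEBRATE_ORDERS", "TAXON_SUBSET"]

log = logging.getLogger(__name__)

INVERTEBRATE_ORDERS = ("Hymenoptera", "Lepidoptera", "Diptera", "Coleoptera")
VERTEBRATE_ORDERS = ("Apodiformes", "Passeriformes")
TAXON_SUBSET = INVERTEBRATE_ORDERS + VERTEBRATE_ORDERS

ANALYSES = ("global_lui", "cropland_zone", "cropland_taxa",
            "fertiliser_zone", "fertiliser_taxa")

RANDOM_CANDIDATES = {
    "poisson": [(("SS",), False), (("SS", "SSB"), False),
                (("SS", "SSB"), True)],
    "gaussian": [(("SS",), False), (("SS", "SSB"), False)],
}


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (stable across stage additions)."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    out_dir: str = "results"
    analysis: str = "global_lui"
    seed: int = 0
    survey_path: str | None = None      # use an existing table instead of simulating
    sim: SimConfig | None = None
    min_sites: int = 30
    baseline_class: str = "Primary_Minimal"
    n_draws: int = 1000
    percentiles: tuple = (2.5, 97.5)
    run_roster: bool = True
    run_moran: bool = True
    run_jackknife: bool = True
    moran_permutations: int = 999

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim:
            cfg.sim = SimConfig(**sim)
        return cfg

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return float(o)
            return str(o)
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _derive_intensity_class(metrics: pd.DataFrame,
                            baseline: str) -> pd.DataFrame:
    """Cropland-analysis factor: Primary baseline + cropland intensities."""
    out = metrics[(metrics["LUI"] == baseline)
                  | (metrics["Predominant_land_use"] == "Cropland")].copy()
    out["intensity_class"] = np.where(out["LUI"] == baseline, "Primary",
                                      out["Use_intensity"])
    return out


def run_analysis(config: RunConfig) -> dict:
    """Run one analysis end-to-end; returns the results bundle.

    The bundle holds the filtered table, site metrics, per-response model
    fits with gate decisions, effects tables, and validation outputs; the
    same content is written as flat files under ``config.out_dir`` along
    with a manifest recording seeds and per-stage row counts.
    """
    if config.analysis not in ANALYSES:
        raise ValueError(f"unknown analysis {config.analysis!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "analysis": config.analysis, "stages": {}}
    bundle: dict = {"manifest": manifest}

    # ----- inputs -----------------------------------------------------
    sim = config.sim or SimConfig()
    sim = sim.replace(seed=stage_seed(config.seed, "simulate"))
    needs_fert = config.analysis.startswith("fertiliser")
    if needs_fert and not sim.fertiliser_slope_by_order:
        sim = sim.replace(fertiliser_slope_by_order={
            "Hymenoptera": -0.25, "Lepidoptera": -0.30, "Diptera": 0.55,
            "Coleoptera": 0.0, "Apodiformes": 0.35, "Passeriformes": 0.0})
    taxonomy = build_taxonomy(sim)
    if config.survey_path:
        table = ingest.read_survey(config.survey_path)
        truth = None
    else:
        table, truth = generate_survey(sim, taxonomy=taxonomy)
        table.to_csv(out / "survey.csv", index=False)
    manifest["stages"]["survey"] = {"seed": sim.seed, "rows": len(table),
                                    "sites": int(table["SSBS"].nunique())}

    # ----- roster -----------------------------------------------------
    if config.run_roster:
        corpus, taxonomy, roster_truth = generate_corpus(sim, taxonomy=taxonomy)
        ev = roster_mod.evidence_from_corpus(corpus, taxonomy)
        conf, block = roster_mod.assign_confidence(ev)
        groups = roster_mod.extrapolate_groups(conf, block, taxonomy)
        roster = roster_mod.compile_roster(conf, groups, taxonomy,
                                           blocklist=block)
        roster.to_csv(out / "roster.csv")
        n_before = table["SSBS"].nunique()
        table = roster_mod.filter_records(table, roster)
        manifest["stages"]["roster"] = {
            "entries": len(roster.entries), "sites_in": int(n_before),
            "sites_out": int(table["SSBS"].nunique()), "rows": len(table)}
        bundle["roster"] = roster
        bundle["roster_truth"] = roster_truth

    # ----- ingest + metrics ------------------------------------------
    n_in = table["SSBS"].nunique()
    table = ingest.apply_site_filters(table)
    table = ingest.rescale_effort(table)
    table, removal_report = ingest.build_lui(
        table, min_sites=config.min_sites, baseline=config.baseline_class)
    removal_report.to_csv(out / "lui_removals.csv", index=False)
    manifest["stages"]["ingest"] = {
        "sites_in": int(n_in), "sites_out": int(table["SSBS"].nunique()),
        "classes_removed": len(removal_report)}

    by = ("SSBS", "Order") if config.analysis.endswith("taxa") else ("SSBS",)
    if config.analysis.endswith("taxa"):
        table = table[table["Order"].isin(TAXON_SUBSET)]
    metrics = compute_site_metrics(table, by=by)
    metrics["zone"] = ingest.assign_zone(metrics["Latitude"])
    if needs_fert:
        metrics["log10fert"] = np.log10(metrics["Fertiliser"].fillna(0) + 1.0)
    metrics.to_csv(out / "site_metrics.csv", index=False)
    manifest["stages"]["metrics"] = {"rows": len(metrics)}
    bundle["table"], bundle["metrics"], bundle["truth"] = table, metrics, truth

    # ----- model set per analysis ------------------------------------
    eff_cfg = EffectConfig(n_draws=config.n_draws,
                           percentiles=config.percentiles,
                           seed=stage_seed(config.seed, "effects"))
    responses = ["richness", "chao1", "abundance_ln1p", "simpson_ln1p"]
    if config.analysis == "global_lui":
        data = metrics
        fixed = [F("LUI", config.baseline_class)]
        factor, base_level, strata = "LUI", config.baseline_class, None
    elif config.analysis in ("cropland_zone", "cropland_taxa"):
        data = _derive_intensity_class(metrics, config.baseline_class)
        strat = "zone" if config.analysis == "cropland_zone" else "Order"
        ref = ("non_tropical" if strat == "zone"
               else sorted(data[strat].unique())[0])
        fixed = [F("intensity_class", "Primary"), F(strat, ref),
                 Ix(F("intensity_class", "Primary"), F(strat, ref))]
        factor, base_level, strata = "intensity_class", "Primary", strat
        responses = ["richness", "abundance_ln1p", "simpson_ln1p"]
    else:                                   # fertiliser gradient analyses
        data = metrics[metrics["Predominant_land_use"] == "Cropland"].copy()
        strat = "zone" if config.analysis == "fertiliser_zone" else "Order"
        ref = ("non_tropical" if strat == "zone"
               else sorted(data[strat].unique())[0])
        fixed = [N("log10fert"), F(strat, ref),
                 Ix(N("log10fert"), F(strat, ref))]
        factor, base_level, strata = None, None, strat
        responses = ["richness", "abundance_ln1p", "simpson_ln1p"]

    bundle["models"] = {}
    for response in responses:
        spec = ModelSpec(response=response, fixed=fixed)
        family = spec.resolved_family()
        try:
            fit = select_random_structure(spec, data,
                                          RANDOM_CANDIDATES[family])
            null = fit_mixed(spec.null(), data, random=fit.random,
                             olre=fit.olre)
        except Exception as exc:
            log.warning("model for %s failed: %s", response, exc)
            bundle["models"][response] = {"status": "failed", "error": str(exc)}
            continue
        decision = gate_against_null(fit, null)
        entry = {"status": "excluded" if decision == "discard" else "kept",
                 "fit": fit, "null_aic": null.aic}
        if family == "poisson":
            entry["overdispersion"] = check_overdispersion(fit)
        if decision == "keep":
            if factor is not None:
                if strata is None:
                    cr, br, labels = class_rows_for_factor(fit, factor,
                                                           base_level)
                    eff = effects_table(
                        effects_as_percent(fit, cr, br, labels, eff_cfg))
                else:
                    frames = []
                    for level in sorted(data[strata].unique()):
                        cr, br, labels = class_rows_for_factor(
                            fit, factor, base_level, fill={strata: level})
                        sub = effects_table(effects_as_percent(
                            fit, cr, br, labels, eff_cfg))
                        sub[strata] = level
                        frames.append(sub)
                    eff = pd.concat(frames, ignore_index=True)
                entry["effects"] = eff
                eff.to_csv(out / f"effects_{response}.csv", index=False)
            else:
                curves = predict_gradient(fit, data, "log10fert", strata,
                                          eff_cfg)
                entry["gradient"] = curves
                entry["interactions"] = interaction_significance(fit)
                curves.to_csv(out / f"gradient_{response}.csv", index=False)
        bundle["models"][response] = entry
        with open(out / f"model_{response}.json", "w") as fh:
            json.dump(fit.to_record() | {"gate": decision}, fh, indent=1)

    # ----- validation -------------------------------------------------
    kept = {r: e for r, e in bundle["models"].items()
            if isinstance(e, dict) and e.get("status") == "kept"}
    if config.run_moran and kept:
        moran_out = {}
        for response, entry in kept.items():
            fit = entry["fit"]
            resid = (fit.result.pearson_residuals()
                     if fit.family == "poisson" else fit.result.residuals)
            sites = data.loc[fit.data_index, ["SS", "Latitude", "Longitude"]]
            tbl, pct = morans_i_by_study(
                pd.Series(resid, index=fit.data_index), sites,
                n_perm=config.moran_permutations,
                seed=stage_seed(config.seed, f"moran:{response}"))
            tbl.to_csv(out / f"moran_{response}.csv", index=False)
            moran_out[response] = {"pct_significant": pct,
                                   "n_studies": len(tbl)}
        bundle["moran"] = moran_out
        manifest["stages"]["moran"] = moran_out
    if (config.run_jackknife and config.analysis == "global_lui"
            and "abundance_ln1p" in kept):
        jk = jackknife_continents(
            data, ModelSpec(response="abundance_ln1p", fixed=fixed),
            "LUI", config.baseline_class, eff_cfg)
        bundle["jackknife"] = jk
        manifest["stages"]["jackknife"] = {
            r.excluded: r.n_sites_removed for r in jk}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return bundle
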