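"""Readers/writers, run configuration and the end-to-end pipeline.

File formats: CSVs with one UTF-8 header row and ISO-8601 dates; rasters
as single-band float32 GeoTIFF (nodata -9999); villages additionally as
GeoJSON point features; configuration as YAML with explicit per-stage
seeds. Validation is strict — malformed rows are collected into the error
message rather than silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geoprofile as gp
from . import prioritize as pr
from . import riskmap as rm
from . import tolerance as tl
from .errors import ValidationError
from .raster import RasterGrid, read_geotiff, write_geotiff
from .synthgen import (ENCOUNTER_CATEGORIES, ITEM_COLUMNS, SCENARIO_COLUMNS,
                       TOLERANCE_LEVELS, LandscapeConfig, TruthParams,
                       gen_encounters, gen_landscape, gen_survey, gen_villages,
                       true_intensity)

logger = logging.getLogger(__name__)

ENCOUNTER_COLUMNS = ("event_id", "x", "y", "date", "category", "village_id")
_SURVEY_RESPONSES = set(TOLERANCE_LEVELS) | {"dont_know", "missing"}


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_encounters(path, records: pd.DataFrame) -> None:
    out = records.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_encounters(path) -> pd.DataFrame:
    """Typed, validated encounter table (see ENCOUNTER_COLUMNS)."""
    table = pd.read_csv(path)
    missing = set(ENCOUNTER_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    problems = []
    cats = table["category"].astype(str)
    for idx in table.index[~cats.isin(ENCOUNTER_CATEGORIES)]:
        problems.append(f"row {idx}: unknown category {table.loc[idx, 'category']!r}")
    dates = pd.to_datetime(table["date"], errors="coerce")
    for idx in table.index[dates.isna()]:
        problems.append(f"row {idx}: unparseable date {table.loc[idx, 'date']!r}")
    coords = table[["x", "y"]].apply(pd.to_numeric, errors="coerce")
    for idx in table.index[~np.isfinite(coords).all(axis=1)]:
        problems.append(f"row {idx}: non-finite coordinates")
    if problems:
        raise ValidationError(f"{path}: {len(problems)} malformed rows\n"
                              + "\n".join(problems[:20]))
    table["date"] = dates
    return table


def write_survey(path, survey: pd.DataFrame) -> None:
    survey.to_csv(path, index=False)


def read_survey(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"village_id", "tolerance", *ITEM_COLUMNS, *SCENARIO_COLUMNS}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    problems = []
    for idx in table.index[~table["tolerance"].astype(str).isin(_SURVEY_RESPONSES)]:
        problems.append(f"row {idx}: unknown tolerance {table.loc[idx, 'tolerance']!r}")
    for col in (*ITEM_COLUMNS, *SCENARIO_COLUMNS):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[vals.notna() & ~vals.isin([1, 2, 3, 4, 5])]
        for idx in bad:
            problems.append(f"row {idx}: {col} = {table.loc[idx, col]!r} outside 1-5")
    if problems:
        raise ValidationError(f"{path}: {len(problems)} malformed rows\n"
                              + "\n".join(problems[:20]))
    return table


def write_villages(path, villages: pd.DataFrame) -> None:
    """CSV or GeoJSON (by extension) of village centroids."""
    path = Path(path)
    if path.suffix.lower() == ".geojson":
        features = [{
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(v["x"]), float(v["y"])]},
            "properties": {k: (v[k] if not isinstance(v[k], (np.floating, np.integer))
                               else v[k].item())
                           for k in villages.columns if k not in ("x", "y")},
        } for _, v in villages.iterrows()]
        path.write_text(json.dumps({"type": "FeatureCollection",
                                    "features": features}, indent=1))
    else:
        villages.to_csv(path, index=False)


def read_villages(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".geojson":
        doc = json.loads(path.read_text())
        rows = []
        for i, feat in enumerate(doc.get("features", [])):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                raise ValidationError(f"{path}: feature {i} is not a Point")
            x, y = geom["coordinates"][:2]
            rows.append({"village_id": feat.get("properties", {}).get("village_id", f"v{i}"),
                         "x": float(x), "y": float(y), **{
                             k: v for k, v in feat.get("properties", {}).items()
                             if k != "village_id"}})
        table = pd.DataFrame(rows)
    else:
        table = pd.read_csv(path)
    missing = {"village_id", "x", "y"} - set(table.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if not np.isfinite(table[["x", "y"]].to_numpy(float)).all():
        raise ValidationError(f"{path}: non-finite village coordinates")
    return table


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

STAGES = ("simulate", "geoprofile", "risk", "tolerance", "prioritize")


@dataclass
class RunConfig:
    """Seeds, stage parameters and output locations for a pipeline run.

    Defaults mirror the published protocol where one is stated (10,000
    pseudo-absences; 70/30 cross-validation with ten replicates; member
    screening at AUC > 0.70; 3.25 km buffers; 50,000 MCMC samples over 10
    chains with 10,000 burn-in; delta AICc < 2; 1-month deduplication and
    6-month linkage). Sizes can be overridden for small exploratory runs.
    """

    outdir: str = "conflictscope_run"
    seed: int = 0
    stages: tuple = STAGES
    # synthetic data
    extent: tuple = (200.0, 200.0)
    cell_size: float = 2.0
    n_events: int = 228
    exact_category_mix: bool = True
    n_villages: int = 75
    n_respondents: int = 2386
    # geoprofile
    samples_per_chain: int = 50_000
    burn_in: int = 10_000
    n_chains: int = 10
    thin: int = 10
    dp_concentration: float = 1.0
    # risk ensemble
    n_absences: int = 10_000
    buffer_radius: float = 3.25
    auc_min: float = 0.70
    cv_reps: int = 10
    train_frac: float = 0.70
    forest_threshold: float = 0.5
    # tolerance
    aicc_correction: bool = True
    delta_max: float = 2.0
    # prioritisation
    dedup_gap_months: float = 1.0
    linkage_window_months: float = 6.0

    def stage_seed(self, stage: str) -> int:
        return int(self.seed * 1000 + STAGES.index(stage)) % (2 ** 31)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["stages"] = list(doc["stages"])
        doc["extent"] = list(doc["extent"])
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        doc["stages"] = tuple(doc.get("stages", STAGES))
        doc["extent"] = tuple(doc.get("extent", (200.0, 200.0)))
        return cls(**doc)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order and write a report.

    Each stage logs its seed, writes its artifacts under ``config.outdir``
    and contributes a section to the JSON + Markdown report. A stage
    failure marks the stage failed and skips everything downstream.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    report: dict = {"stages": {}, "seed": config.seed}
    ctx: dict = {}
    failed = False
    for stage in STAGES:
        if stage not in config.stages:
            continue
        if failed:
            report["stages"][stage] = {"status": "skipped"}
            continue
        runner = _STAGE_RUNNERS[stage]
        try:
            logger.info("stage %s (seed %d)", stage, config.stage_seed(stage))
            section = runner(config, ctx, outdir)
            report["stages"][stage] = {"status": "ok", **section}
        except Exception as exc:  # noqa: BLE001 - report and halt downstream
            logger.exception("stage %s failed", stage)
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            failed = True
    _write_report(outdir, report)
    return report


def _stage_simulate(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    seed = config.stage_seed("simulate")
    landscape = gen_landscape(LandscapeConfig(
        extent=config.extent, cell_size=config.cell_size, seed=seed,
        forest_threshold=config.forest_threshold))
    truth = TruthParams()
    villages = gen_villages(landscape, config.n_villages, seed + 1)
    encounters = gen_encounters(landscape, truth, config.n_events, seed + 2,
                                villages=villages,
                                exact_mix=config.exact_category_mix)
    survey = gen_survey(villages, true_intensity(landscape, truth), truth,
                        config.n_respondents, seed + 3)
    for name, grid in landscape.rasters.items():
        write_geotiff(outdir / f"{name}.tif", grid)
    write_encounters(outdir / "encounters.csv", encounters)
    write_villages(outdir / "villages.geojson", villages)
    write_villages(outdir / "villages.csv", villages)
    write_survey(outdir / "survey.csv", survey)
    ctx.update(landscape=landscape, truth=truth, villages=villages,
               encounters=encounters, survey=survey)
    counts = encounters["category"].value_counts().to_dict()
    return {"n_events": len(encounters), "category_counts": counts,
            "n_respondents": len(survey)}


def _stage_geoprofile(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    enc = ctx["encounters"]
    cfg = gp.DPMConfig(samples_per_chain=config.samples_per_chain,
                       burn_in=config.burn_in, n_chains=config.n_chains,
                       thin=config.thin, dp_concentration=config.dp_concentration,
                       grid=ctx["landscape"].grid,
                       seed=config.stage_seed("geoprofile"))
    sigma_hat, posterior = gp.two_stage_sigma(enc[["x", "y"]], cfg)
    profile = gp.profile_surface(posterior, enc[["x", "y"]], cfg)
    write_geotiff(outdir / "geoprofile.tif", profile.surface)
    write_geotiff(outdir / "geoprofile_rank.tif", profile.rank)

    train = enc[enc["category"] == "sighting"][["x", "y"]]
    test = enc[enc["category"].isin(("livestock_attack", "human_attack",
                                     "removal"))][["x", "y"]]
    val = gp.validate_by_category(train, test, cfg)
    pd.DataFrame({"hitscore": val["hitscores"]}).to_csv(
        outdir / "hitscores.csv", index=False)
    summary = {
        "sigma_hat": sigma_hat,
        "gini_sightings_vs_attacks": val["gini"],
        "search_fractions": val["search_fractions"],
        "modal_cluster_count": posterior.modal_cluster_count(),
        "split_rhat": posterior.split_rhat,
    }
    (outdir / "geoprofile_summary.json").write_text(json.dumps(summary, indent=1))
    ctx.update(profile=profile, geoprofile_summary=summary)
    return summary


def _stage_risk(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    seed = config.stage_seed("risk")
    landscape = ctx["landscape"]
    enc = ctx["encounters"]
    absences = rm.make_pseudoabsences(landscape, n=config.n_absences, seed=seed,
                                      forest_threshold=config.forest_threshold)
    pts = pd.concat([enc[["x", "y"]], absences], ignore_index=True)
    labels = np.r_[np.ones(len(enc)), np.zeros(len(absences))]
    table = rm.extract_covariates(pts, landscape, radius=config.buffer_radius)
    kept, screen_report = rm.screen_collinearity(table)
    ensemble = rm.fit_ensemble(kept, labels, auc_min=config.auc_min, seed=seed,
                               reps=config.cv_reps, train_frac=config.train_frac)
    surface = rm.predict_surface(ensemble, landscape)
    write_geotiff(outdir / "risk.tif", surface)
    importance = rm.variable_importance(ensemble, kept, seed=seed)
    metrics = pd.DataFrame({
        "cv_auc": pd.Series(ensemble.cv_auc),
        "tss": pd.Series(ensemble.tss_raw),
        "weight": pd.Series(ensemble.tss_weight),
    })
    metrics.to_csv(outdir / "member_metrics.csv")
    importance.to_csv(outdir / "importance.csv")
    screen_report.to_csv(outdir / "collinearity_report.csv", index=False)
    ctx.update(risk_surface=surface, ensemble=ensemble)
    return {
        "member_cv_auc": {k: float(v) for k, v in ensemble.cv_auc.items()},
        "selected": list(ensemble.members),
        "tss_weights": {k: float(v) for k, v in ensemble.tss_weight.items()},
        "weighted_mean_auc": rm.weighted_mean_auc(ensemble),
        "dropped_covariates": screen_report["column"].tolist(),
        "importance_pearson_r": {k: float(v) for k, v in importance.items()},
    }


def _stage_tolerance(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    survey = ctx["survey"]
    model_table, exclusions = tl.prepare_responses(survey)
    diagnostics = tl.scale_diagnostics(
        survey.loc[model_table.index, list(SCENARIO_COLUMNS)])
    model_table = tl.attach_risk_covariates(
        model_table, ctx["villages"],
        risk_surface=ctx.get("risk_surface"),
        geoprofile=ctx["profile"].surface if "profile" in ctx else None,
        landscape=ctx.get("landscape"), radius=config.buffer_radius)
    model_table = model_table.dropna(
        subset=[c for c in ("GP", "Prob_conf") if c in model_table.columns])

    social = [*ITEM_COLUMNS, "Scenario", "Age", "sex", "ethnicity"]
    landscape_terms = [c for c in ctx["landscape"].rasters if c in model_table.columns]
    roster = tl.standard_model_set(social, landscape_terms)
    fits = {name: tl.fit_multinomial(model_table, terms, name=name)
            for name, terms in roster.items()
            if all(t in model_table.columns for t in terms)}
    comparison = tl.compare_models(fits, correction=config.aicc_correction,
                                   delta_max=config.delta_max)
    comparison.table.to_csv(outdir / "model_comparison.csv")
    comparison.averaged_coefficients.to_csv(outdir / "averaged_coefficients.csv")
    ratios = {}
    best = comparison.table.index[0]
    for other in comparison.table.index[1:]:
        ratios[f"{best}_vs_{other}"] = comparison.evidence_ratio(best, other)
    diag_doc = {"cronbach_alpha": diagnostics["cronbach_alpha"],
                "kmo_overall": diagnostics["kmo_overall"],
                "kmo_per_item": diagnostics["kmo_per_item"],
                "first_factor_variance_pct": diagnostics["first_factor_variance_pct"],
                "loadings": diagnostics["loadings"].to_dict(),
                "exclusions": exclusions}
    (outdir / "tolerance_diagnostics.json").write_text(json.dumps(diag_doc, indent=1))
    ctx.update(model_table=model_table, comparison=comparison)
    shares = model_table["tolerance"].value_counts(normalize=True)
    return {
        "exclusions": exclusions,
        "category_shares": {k: float(v) for k, v in shares.items()},
        "scale": {k: diag_doc[k] for k in ("cronbach_alpha", "kmo_overall",
                                           "first_factor_variance_pct")},
        "comparison": comparison.table.round(3).to_dict(orient="index"),
        "evidence_ratios": ratios,
        "importance": comparison.importance.round(3).to_dict(),
        "confidence_set": list(comparison.confidence_set),
    }


def _stage_prioritize(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    enc = ctx["encounters"]
    deduped = pr.deduplicate_encounters(enc, config.dedup_gap_months)
    chains, escalation = pr.link_encounters(deduped, config.linkage_window_months)
    scores = pr.village_scores(ctx["villages"], ctx["survey"],
                               ctx["risk_surface"], radius=config.buffer_radius)
    priorities = pr.classify_priority(scores)
    accounting = pr.conflict_accounting(priorities, deduped)
    write_villages(outdir / "priorities.geojson", priorities)
    chains.assign(event_ids=chains["event_ids"].map(lambda t: ";".join(map(str, t)))) \
        .to_csv(outdir / "chains.csv", index=False)
    (outdir / "accounting.json").write_text(json.dumps(accounting, indent=1))
    return {"escalation_rate": escalation,
            "village_shares": accounting["village_shares"],
            "headline": accounting["headline"],
            "n_chains": int(len(chains))}


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "geoprofile": _stage_geoprofile,
    "risk": _stage_risk,
    "tolerance": _stage_tolerance,
    "prioritize": _stage_prioritize,
}


def _write_report(outdir: Path, report: dict) -> None:
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True,
                                                   default=_json_default))
    lines = ["# conflictscope run report", ""]
    for stage, section in report["stages"].items():
        lines.append(f"## {stage} — {section.get('status')}")
        if stage == "tolerance" and "comparison" in section:
            lines.append("")
            lines.append("| model | AICc | dAICc | log-lik | K |")
            lines.append("|---|---|---|---|---|")
            for name, row in section["comparison"].items():
                lines.append(f"| {name} | {row['AICc']:.2f} | {row['delta']:.2f} "
                             f"| {row['loglik']:.2f} | {int(row['K'])} |")
        for key, val in section.items():
            if key in ("status", "comparison"):
                continue
            lines.append(f"- {key}: {val}")
        lines.append("")
    (outdir / "report.md").write_text("\n".join(lines))


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
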