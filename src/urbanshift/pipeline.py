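"""End-to-end orchestration: clean -> select -> thin -> background -> prune
-> tune -> gate -> project -> turnover -> stats, with full provenance.

Every per-species stage draws randomness from a seed derived from the run
seed and the species' rank in the sorted species pool, so per-species work
is order-independent: parallel and serial execution produce byte-identical
outputs. A failed species is quarantined with a reason and the run
continues.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import climate_prep, synthetic_world
from .bias_correction import make_background, thin
from .evaluation import TuningResult, default_grid, quality_gate, tune
from .grids import FUTURE_SCENARIOS, ClimateStack, read_stacks, write_stack
from .maxent import MaxEntResults
from .occurrences import (CityQuadrat, clean_records, city_species_lists,
                          read_city_table, write_city_table)
from .projection import assemble_matrix, build_city_grid, compute_turnover
from .city_stats import stats_report
from .synthetic_world import (DEFAULT_REFERENCE_DATE, RECENCY_YEARS, BiasSurface,
                              generate_climate, generate_species, true_suitability)

log = logging.getLogger("urbanshift")


def TurnoverSummaryEmpty():
    """Empty turnover tables for a run where every species was gated out."""
    from .projection import TurnoverSummary

    city_cols = ["city", "scenario", "gained", "lost", "unaffected_present",
                 "unaffected_absent", "historic_richness", "future_richness", "net"]
    sp_cols = ["species_id", "scenario", "n_new_cities", "n_extirpated_cities",
               "n_unchanged_cities", "historic_cities", "future_cities",
               "net_cities", "fully_extirpated"]
    return TurnoverSummary(
        city_table=pd.DataFrame(columns=city_cols),
        species_table=pd.DataFrame(columns=sp_cols),
        taxon_table=None,
    )


@dataclass
class RunConfig:
    """Every tunable of one pipeline run; unknown keys are rejected."""

    seed: int = 0
    climate_dir: str = ""
    occurrence_csv: str = ""
    city_csv: str = ""
    out_dir: str = "run"
    min_n: int = 10
    thin_cell_km: float = 25.0
    quadrat_half_width: float = 10.0
    city_grid_side: int = 10
    r_threshold: float = 0.7
    n_bg: int = 10_000
    buffer_km: float = 100.0
    auc_gate: float = 0.70
    boyce_windows: int = 101
    boyce_width: float = 0.1
    tau: float = 0.5
    n_hinge_knots: int = 20
    cv_k: int = 4
    threshold_rule: str = "max_sens_spec"
    maxiter: int = 10_000
    tol: float = 1e-6
    reference_date: str = DEFAULT_REFERENCE_DATE.isoformat()
    n_jobs: int = 1
    resume: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @property
    def window(self) -> tuple[dt.date, dt.date]:
        end = dt.date.fromisoformat(self.reference_date)
        return end - dt.timedelta(days=RECENCY_YEARS * 365), end


def _species_seed(run_seed: int, rank: int) -> int:
    return int(np.random.SeedSequence([run_seed, rank]).generate_state(1)[0] % (2**31))


def _fit_one_species(
    sp: str,
    rank: int,
    records: pd.DataFrame,
    historic: ClimateStack,
    kept_vars: list[str],
    cfg: RunConfig,
) -> dict:
    """Thin -> background -> tune -> gate for one species. Returns a verdict
    dict carrying the fitted results when kept."""
    seed = _species_seed(cfg.seed, rank)
    try:
        thinned = thin(records, historic, cell_size_km=cfg.thin_cell_km, seed=seed)
        if len(thinned) < cfg.min_n:
            return {"species_id": sp, "keep": False,
                    "reason": f"insufficient records after thinning (n={len(thinned)})"}
        bg = make_background(
            thinned, historic, n_bg=cfg.n_bg, buffer_km=cfg.buffer_km,
            seed=seed + 1, species_id=sp,
        )
        pres_vals = historic.extract(
            thinned["x"].to_numpy(), thinned["y"].to_numpy(), variables=kept_vars
        )
        ok_p = pres_vals.notna().all(axis=1).to_numpy()
        pres_vals = pres_vals.loc[ok_p].reset_index(drop=True)
        pres_xy = thinned.loc[ok_p, ["x", "y"]].reset_index(drop=True)
        bg_vals = historic.extract(
            bg.points["x"].to_numpy(), bg.points["y"].to_numpy(), variables=kept_vars
        )
        ok_b = bg_vals.notna().all(axis=1).to_numpy()
        bg_vals = bg_vals.loc[ok_b].reset_index(drop=True)
        bg_xy = bg.points.loc[ok_b].reset_index(drop=True)
        # add presence samples to the background (standard MaxEnt practice):
        # keeps the presence feature means inside the hull of the background
        # features, so the penalized likelihood is bounded
        bg_vals = pd.concat([bg_vals, pres_vals], ignore_index=True)
        bg_xy = pd.concat([bg_xy, pres_xy], ignore_index=True)
        tuning = tune(
            pres_vals, bg_vals,
            presence_xy=pres_xy, background_xy=bg_xy,
            grid=default_grid(cfg.n_hinge_knots), k=cfg.cv_k, seed=seed,
            maxiter=cfg.maxiter, tol=cfg.tol, boyce_windows=cfg.boyce_windows,
            boyce_width=cfg.boyce_width, threshold_rule=cfg.threshold_rule,
        )
        keep, reason = quality_gate(tuning, len(thinned), min_n=cfg.min_n,
                                    auc_gate=cfg.auc_gate)
        return {"species_id": sp, "keep": keep, "reason": reason,
                "n_thinned": len(thinned), "tuning": tuning}
    except Exception as err:  # quarantine, keep the run going
        return {"species_id": sp, "keep": False, "reason": f"quarantined: {err}"}


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Writes: cleaning tally, per-city species lists, variable-selection
    audit, per-species model JSONs and the 48-candidate evaluation reports,
    the presence matrix, turnover CSVs (city/species/taxon), the stats
    report, and a manifest with config echo, hash and per-species verdicts.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "models").mkdir(exist_ok=True)

    stacks = read_stacks(cfg.climate_dir)
    historic = stacks["historic"]
    records = synthetic_world.read_occurrences(cfg.occurrence_csv)
    quadrats = read_city_table(cfg.city_csv)
    for q in quadrats:
        q.half_width = cfg.quadrat_half_width

    clean, tally = clean_records(records, historic, window=cfg.window)
    pd.DataFrame([tally]).to_csv(out / "cleaning_tally.csv", index=False)

    listings = city_species_lists(clean, quadrats, min_n=cfg.min_n)
    listings.to_csv(out / "city_species_lists.csv", index=False)
    pool = sorted(listings["species_id"].unique())

    # collinearity judged over the modelling domain: land cells
    land_pts = historic.land_table()[["x", "y"]]
    rng = np.random.default_rng(cfg.seed)
    sample = land_pts.iloc[
        rng.choice(len(land_pts), size=min(5000, len(land_pts)), replace=False)
    ]
    selection = climate_prep.prune_collinear(historic, sample, r_threshold=cfg.r_threshold)
    selection.to_frame().to_csv(out / "variable_selection.csv", index=False)
    kept_vars = selection.kept

    by_species = {sp: df.reset_index(drop=True) for sp, df in clean.groupby("species_id")}
    # crash-resume: species whose serialized model already exists are loaded,
    # everything else (missing or previously quarantined) is recomputed
    resumed: dict[str, MaxEntResults] = {}
    jobs = []
    for rank, sp in enumerate(pool):
        if sp not in by_species:
            continue
        model_path = out / "models" / f"{sp}.json"
        if cfg.resume and model_path.exists():
            resumed[sp] = MaxEntResults.load(model_path)
            continue
        jobs.append(
            delayed(_fit_one_species)(sp, rank, by_species[sp], historic, kept_vars, cfg)
        )
    verdicts = list(Parallel(n_jobs=cfg.n_jobs)(jobs))

    models: dict[str, MaxEntResults] = {}
    verdict_by_sp: dict[str, dict] = {}
    for v in verdicts:
        row = {k: v[k] for k in ("species_id", "keep", "reason")}
        tuning: TuningResult | None = v.get("tuning")
        if tuning is not None:
            tuning.candidates.to_csv(
                out / "models" / f"{v['species_id']}_candidates.csv", index=False
            )
            if v["keep"]:
                res = tuning.winner
                res.tau = cfg.tau
                res.save(out / "models" / f"{v['species_id']}.json")
                models[v["species_id"]] = res
                row.update(
                    classes=res.spec.classes, reg_multiplier=res.spec.reg_multiplier,
                    mean_train_AUC=res.metrics.get("mean_train_AUC"),
                    mean_BCI=res.metrics.get("mean_BCI"),
                    threshold=res.threshold,
                )
        verdict_by_sp[v["species_id"]] = row
    for sp, res in resumed.items():
        models[sp] = res
        verdict_by_sp[sp] = {
            "species_id": sp, "keep": True, "reason": "keep",
            "classes": res.spec.classes, "reg_multiplier": res.spec.reg_multiplier,
            "mean_train_AUC": res.metrics.get("mean_train_AUC"),
            "mean_BCI": res.metrics.get("mean_BCI"), "threshold": res.threshold,
        }
    verdict_rows = [verdict_by_sp[sp] for sp in pool if sp in verdict_by_sp]
    pd.DataFrame(verdict_rows).to_csv(out / "species_verdicts.csv", index=False)

    if models:
        matrix = assemble_matrix(models, stacks, quadrats)
    else:
        matrix = pd.DataFrame(
            columns=["species_id", "city", "scenario", "mean_suitability", "present"]
        )
    matrix.to_csv(out / "presence_matrix.csv", index=False)

    taxa = None
    if "taxon_label" in records.columns:
        taxa = records.groupby("species_id")["taxon_label"].first().to_dict()
    if matrix.empty:
        log.warning("no species survived the quality gate; turnover skipped")
        turnover = TurnoverSummaryEmpty()
    else:
        turnover = compute_turnover(matrix, taxon_labels=taxa)
    turnover.check_conservation()
    turnover.city_table.to_csv(out / "turnover_city.csv", index=False)
    turnover.species_table.to_csv(out / "turnover_species.csv", index=False)
    if turnover.taxon_table is not None:
        turnover.taxon_table.to_csv(out / "turnover_taxon.csv", index=False)

    # city covariates for the stats layer
    cov_rows = []
    hist_rich = (
        turnover.city_table.groupby("city")["historic_richness"].first()
        if not turnover.city_table.empty else pd.Series(dtype=int)
    )
    for q in quadrats:
        grid = build_city_grid(q, n_side=cfg.city_grid_side)
        vals = historic.extract(grid.points["x"].to_numpy(), grid.points["y"].to_numpy(),
                                variables=[v for v in ("MAT", "MAP") if v in historic.variables])
        cov_rows.append(
            {"city": q.city_name,
             "historic_MAT": float(np.nanmean(vals["MAT"])) if "MAT" in vals else np.nan,
             "historic_MAP": float(np.nanmean(vals["MAP"])) if "MAP" in vals else np.nan,
             "population": q.population,
             "historic_richness": int(hist_rich.get(q.city_name, 0))}
        )
    covariates = pd.DataFrame(cov_rows)
    covariates.to_csv(out / "city_covariates.csv", index=False)

    if not turnover.city_table.empty and len(quadrats) >= 4:
        stats_frame, stats_text = stats_report(turnover.city_table, covariates)
        stats_frame.to_csv(out / "stats_report.csv", index=False)
        (out / "stats_report.txt").write_text(stats_text + "\n")

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "species_pool": pool,
        "n_kept": len(models),
        "cleaning_tally": tally,
        "kept_variables": kept_vars,
        "verdicts": {sp: row["reason"] for sp, row in verdict_by_sp.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


# -- demo world -------------------------------------------------------------

@dataclass
class DemoWorld:
    """A self-contained synthetic study: paths plus the underlying truth."""

    config: RunConfig
    stacks: dict[str, ClimateStack]
    species: list
    quadrats: list[CityQuadrat]
    truth: pd.DataFrame  # species x city x scenario true occupancy


def true_city_occupancy(
    species_list, stacks, quadrats, cutoff: float | None = None,
    n_side: int = 10,
) -> pd.DataFrame:
    """Oracle occupancy: mean true suitability over the city grid vs cutoff.

    The default cutoff is per-species: the land-mean of its true suitability
    under the historic climate. For sampling proportional to suitability
    against a uniform background this is where presence density crosses
    background density — the same operating point the fitted models'
    sensitivity=specificity thresholds estimate — so the oracle judges the
    pipeline on the decision rule it actually implements. Pass an explicit
    ``cutoff`` to use one fixed value instead.
    """
    rows = []
    sp_cutoff = {}
    for sp in species_list:
        if cutoff is not None:
            sp_cutoff[sp.species_id] = cutoff
        else:
            hist = true_suitability(sp, stacks["historic"])
            sp_cutoff[sp.species_id] = float(np.nanmean(hist))
    for q in quadrats:
        grid = build_city_grid(q, n_side=n_side)
        for sc, stack in stacks.items():
            row_idx, col_idx = stack.cell_of(grid.points["x"].to_numpy(),
                                             grid.points["y"].to_numpy())
            for sp in species_list:
                suit = true_suitability(sp, stack)
                vals = suit[row_idx, col_idx]
                mean_s = float(np.nanmean(vals))
                rows.append(
                    {"species_id": sp.species_id, "city": q.city_name, "scenario": sc,
                     "true_mean_suitability": mean_s,
                     "true_present": mean_s > sp_cutoff[sp.species_id]}
                )
    return pd.DataFrame(rows)


def make_demo(
    seed: int,
    out_dir: str | Path,
    n_species: int = 12,
    shape: tuple[int, int] = (60, 60),
    n_cities: int = 3,
    n_vars: int = 5,
    collinear_pairs: int = 1,
    n_per_species: int = 150,
    n_bg: int = 2000,
    n_hinge_knots: int = 8,
    n_niche_vars: int = 1,
    cell_size: float = 4.6,
    contamination: dict | None = None,
) -> DemoWorld:
    """Write a complete synthetic study (climate, occurrences, cities, truth)
    plus a matching RunConfig, sized to run end-to-end in minutes.

    Virtual species have Gaussian niches on MAT or MAP (the scenario-driven
    axes); sampling uses the road-band accessibility bias and injects
    duplicate/ocean/stale contamination so cleaning has work to do.
    """
    out_dir = Path(out_dir)
    climate_dir = out_dir / "climate"
    out_dir.mkdir(parents=True, exist_ok=True)
    if contamination is None:
        contamination = {"duplicate_frac": 0.05, "ocean_frac": 0.03,
                         "out_of_window_frac": 0.05}

    stacks = generate_climate(seed, shape=shape, n_vars=n_vars,
                              collinear_pairs=collinear_pairs, cell_size=cell_size)
    for st in stacks.values():
        write_stack(st, climate_dir)
    historic = stacks["historic"]

    species = generate_species(seed + 1, n_species, historic,
                               niche_vars=["MAT", "MAP"], n_niche_vars=n_niche_vars)

    # city centroids spread across the land interior, clear of the coast
    nr, nc = shape
    rng = np.random.default_rng(seed + 2)
    quadrats = []
    xs = np.linspace(0.25, 0.85, n_cities)
    for i in range(n_cities):
        cx = historic.origin[0] + xs[i] * nc * historic.cell_size
        cy = historic.origin[1] + (0.3 + 0.5 * ((i * 0.37 + 0.13) % 1.0)) * nr * historic.cell_size
        quadrats.append(
            CityQuadrat(city_name=f"city{i + 1:02d}", centroid=(float(cx), float(cy)),
                        population=int(rng.integers(400_000, 3_000_000)))
        )
    city_path = out_dir / "cities.csv"
    write_city_table(quadrats, city_path)

    # accessibility bias: road bands plus urban sampling hotspots at cities
    bias = BiasSurface.roads(shape).with_urban_centers(
        historic, [q.centroid for q in quadrats]
    )
    frames = []
    for i, sp in enumerate(species):
        recs = synthetic_world.sample_occurrences(
            sp, historic, bias, n_target=n_per_species,
            seed=_species_seed(seed, 1000 + i), contamination=contamination,
        )
        recs["taxon_label"] = sp.taxon_label
        frames.append(recs)
    occurrences = pd.concat(frames, ignore_index=True)
    occ_path = out_dir / "occurrences.csv"
    occurrences.to_csv(occ_path, index=False)

    truth = true_city_occupancy(species, stacks, quadrats)
    truth.to_csv(out_dir / "truth_occupancy.csv", index=False)
    pd.DataFrame(
        [{"species_id": sp.species_id, "taxon_label": sp.taxon_label,
          "niche_vars": "|".join(sp.niche_vars),
          "optima": "|".join(f"{o:.4f}" for o in sp.optima),
          "breadths": "|".join(f"{b:.4f}" for b in sp.breadths),
          "max_prob": sp.max_prob} for sp in species]
    ).to_csv(out_dir / "truth_species.csv", index=False)

    cfg = RunConfig(
        seed=seed, climate_dir=str(climate_dir), occurrence_csv=str(occ_path),
        city_csv=str(city_path), out_dir=str(out_dir / "run"),
        n_bg=n_bg, n_hinge_knots=n_hinge_knots,
    )
    (out_dir / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    return DemoWorld(config=cfg, stacks=stacks, species=species,
                     quadrats=quadrats, truth=truth)


def recover_niche_optima(world: DemoWorld, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Estimate each virtual species' niche optimum from an LQ fit and
    compare against the generator truth.

    Runs the bias-correction stages (thin, restricted background with
    presences added) and fits a single-variable linear+quadratic model per
    species on its (first) niche variable. Returns one row per species with
    the true optimum, the estimate, the niche breadth, and whether the
    estimate falls within half a breadth of truth.
    """
    from .maxent import fit_lq_optimum

    cfg = cfg or world.config
    historic = world.stacks["historic"]
    records = synthetic_world.read_occurrences(cfg.occurrence_csv)
    clean, _ = clean_records(records, historic, window=cfg.window)
    rows = []
    for rank, sp in enumerate(sorted(world.species, key=lambda s: s.species_id)):
        df = clean[clean["species_id"] == sp.species_id].reset_index(drop=True)
        seed = _species_seed(cfg.seed, rank)
        thinned = thin(df, historic, cell_size_km=cfg.thin_cell_km, seed=seed)
        if len(thinned) < cfg.min_n:
            continue
        bg = make_background(thinned, historic, n_bg=cfg.n_bg,
                             buffer_km=cfg.buffer_km, seed=seed + 1,
                             species_id=sp.species_id)
        var = sp.niche_vars[0]
        pres_vals = historic.extract(
            thinned["x"].to_numpy(), thinned["y"].to_numpy(), variables=[var]
        ).dropna()
        bg_vals = historic.extract(
            bg.points["x"].to_numpy(), bg.points["y"].to_numpy(), variables=[var]
        ).dropna()
        bg_vals = pd.concat([bg_vals, pres_vals], ignore_index=True)
        est = fit_lq_optimum(pres_vals, bg_vals, var)
        true_opt, breadth = sp.optima[0], sp.breadths[0]
        rows.append(
            {"species_id": sp.species_id, "variable": var,
             "true_optimum": true_opt, "estimated_optimum": est,
             "breadth": breadth,
             "within_half_breadth": abs(est - true_opt) <= 0.5 * breadth}
        )
    return pd.DataFrame(rows)


def score_recovery(run_dir: str | Path, truth_csv: str | Path) -> dict:
    """Compare a finished run's presence calls against the synthetic truth.

    Returns {'accuracy': fraction of species x city x scenario cells whose
    presence call matches truth, 'n_cells': ..., 'n_species': ...} over the
    species the pipeline kept.
    """
    matrix = pd.read_csv(Path(run_dir) / "presence_matrix.csv")
    truth = pd.read_csv(truth_csv)
    merged = matrix.merge(truth, on=["species_id", "city", "scenario"], how="inner")
    if merged.empty:
        return {"accuracy": float("nan"), "n_cells": 0, "n_species": 0}
    acc = float((merged["present"] == merged["true_present"]).mean())
    return {"accuracy": acc, "n_cells": int(len(merged)),
            "n_species": int(merged["species_id"].nunique())}
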