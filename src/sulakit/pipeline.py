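"""End-to-end pipeline: simulate -> label -> trips -> space use -> predictors
-> repeatability -> niche -> diet, writing one report directory.

Every stage goes through the library modules; outputs are tidy CSVs plus
plain-text ASCII rasters, and a JSON manifest records the seed, a config
hash and package versions so a run is reproducible byte-for-byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behaviour import fit_embc, label_states, labels_per_fix
from .config import SimConfig, default_config
from .env_layers import extract_at, gradient_stack, vif_screen, write_ascii_grid
from .mixing import fit_mixing, summarize_posterior
from .repeatability import repeatability_table
from .space_use import fit_kernel_ud, lscv_bandwidth, make_grid, permutation_test
from .synthetic import (
    default_extent,
    generate_environment,
    generate_isotopes,
    generate_morphometrics,
    generate_tracks,
)
from .trajectories import split_trips, step_features, trips_to_metrics_table
from .trophic import body_condition_index, niche_table, overlap_table

log = logging.getLogger("sulakit.pipeline")

TRAITS = [
    "duration_h",
    "max_dist_colony_km",
    "prop_travel",
    "prop_forage",
    "prop_rest",
    "distal_lat",
    "distal_lon",
]


def _config_hash(config: SimConfig) -> str:
    def enc(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_inputs(
    fixes: pd.DataFrame | None = None,
    isotopes: pd.DataFrame | None = None,
    env=None,
    grid_res: float | None = None,
) -> list[str]:
    """Schema and consistency checks; returns a list of problems (empty = ok).

    Tables are header-keyed, so column order never matters.
    """
    problems: list[str] = []
    if fixes is not None:
        need = {"bird_id", "timestamp", "lon", "lat"}
        missing = need - set(fixes.columns)
        if missing:
            problems.append(f"fix table missing columns {sorted(missing)}")
        else:
            ts = pd.to_datetime(fixes["timestamp"], utc=True, errors="coerce")
            if ts.isna().any():
                problems.append("fix table has unparseable timestamps")
            if fixes["lon"].abs().max() > 180 or fixes["lat"].abs().max() > 90:
                problems.append("fix coordinates out of range")
            dup = fixes.groupby("bird_id")["timestamp"].apply(lambda s: s.duplicated().any())
            if dup.any():
                problems.append("duplicate timestamps within a bird")
    if isotopes is not None:
        need = {"individual", "group", "d13C", "d15N"}
        missing = need - set(isotopes.columns)
        if missing:
            problems.append(f"isotope table missing columns {sorted(missing)}")
    if env is not None and grid_res is not None:
        res = float(env.lon[1] - env.lon[0])
        if not np.isclose(res, grid_res, rtol=1e-6):
            problems.append(
                f"raster grid at {res:.4f} deg does not match analysis grid {grid_res:.4f} deg"
            )
    return problems


def run_pipeline(
    out_dir: str | Path,
    config: SimConfig | None = None,
    seed: int = 0,
    n_perm: int = 200,
    mcmc_iter: int = 3000,
    skip_trophic: bool = False,
    overlap_pairs: list[tuple[str, str]] | None = None,
) -> dict:
    """Run the full synthetic-mode pipeline into ``out_dir``.

    Returns the manifest dict.  Deterministic for a given (config, seed):
    running twice produces identical outputs.  On a stage failure a FAILED
    marker naming the stage is left next to any partial outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or default_config(seed=seed, scale=0.35)
    stage = "setup"
    try:
        # -- simulate ------------------------------------------------------
        stage = "simulate"
        fixes, truth = generate_tracks(config)
        fixes.to_csv(out / "fixes.csv", index=False)
        truth.bird_traits.to_csv(out / "truth_bird_traits.csv", index=False)
        log.info("simulate: %d fixes, %d birds", len(fixes), truth.bird_traits.shape[0])

        # -- trips ---------------------------------------------------------
        stage = "trips"
        trips = split_trips(fixes, config.colony_lonlat, config.colony_radius_km)
        steps = pd.concat([step_features(t) for t in trips], ignore_index=True)
        log.info("trips: %d trips, %d steps", len(trips), len(steps))

        # -- behaviour -----------------------------------------------------
        stage = "behaviour"
        model = fit_embc(steps, seed=seed)
        steps["state"] = label_states(steps, model)
        steps.to_csv(out / "steps_labelled.csv", index=False)
        (out / "behaviour_model.json").write_text(json.dumps(model.to_dict(), indent=1))

        labels_by_trip = {}
        for t in trips:
            lab = steps.loc[steps["trip_id"] == t.trip_id, "state"]
            lab = lab.ffill().bfill()
            labels_by_trip[t.trip_id] = labels_per_fix(len(t.fixes), lab)
        metrics = trips_to_metrics_table(trips, labels_by_trip, config.colony_lonlat)
        birds = truth.bird_traits[["bird_id", "group", "species", "sex", "season"]]
        metrics = metrics.merge(birds, on="bird_id", how="left")
        metrics.to_csv(out / "trip_metrics.csv", index=False)

        # -- space use -----------------------------------------------------
        stage = "space_use"
        extent = default_extent(config)
        lon, lat = make_grid(extent)
        forage = steps[steps["state"] == "forage"].copy()
        forage["group"] = forage["bird_id"].str.rsplit("_b", n=1).str[0]
        ref_pts = forage[["lon", "lat"]].to_numpy()
        if len(ref_pts) > 1500:
            idx = np.random.default_rng(seed).choice(len(ref_pts), 1500, replace=False)
            ref_pts = ref_pts[idx]
        h, h_degenerate = lscv_bandwidth(ref_pts)
        ud_rows = []
        for g, df in forage.groupby("group"):
            if len(df) < 5:
                continue
            ud = fit_kernel_ud(df[["lon", "lat"]].to_numpy(), lon, lat, h)
            import xarray as xr

            write_ascii_grid(
                xr.DataArray(ud.mass, dims=("lat", "lon"), coords={"lat": lat, "lon": lon}),
                out / f"ud_{g}.asc",
            )
            ud_rows.append({"group": g, "n_points": len(df), "h_deg": h})
        pd.DataFrame(ud_rows).to_csv(out / "ud_summary.csv", index=False)

        if overlap_pairs is None:
            season_groups = forage.groupby("group")["bird_id"].nunique()
            eligible = sorted(season_groups[season_groups >= 2].index)
            overlap_pairs = [
                (a, b)
                for i, a in enumerate(eligible)
                for b in eligible[i + 1:]
                if a.split("_")[-1] == b.split("_")[-1]  # same season
            ]
        ov_rows = []
        for ga, gb in overlap_pairs:
            pts_a = {
                b: d[["lon", "lat"]].to_numpy()
                for b, d in forage[forage["group"] == ga].groupby("bird_id")
            }
            pts_b = {
                b: d[["lon", "lat"]].to_numpy()
                for b, d in forage[forage["group"] == gb].groupby("bird_id")
            }
            if len(pts_a) < 2 or len(pts_b) < 2:
                continue
            for level in (0.50, 0.95):
                res = permutation_test(pts_a, pts_b, lon, lat, h, level, n_perm, seed)
                ov_rows.append(
                    {
                        "group_a": ga,
                        "group_b": gb,
                        "level": level,
                        "observed_ba": res.observed_ba,
                        "perm_mean": res.perm_mean,
                        "perm_sd": res.perm_sd,
                        "p": res.p_value,
                        "n_perm": n_perm,
                        "seed": seed,
                    }
                )
        pd.DataFrame(ov_rows).to_csv(out / "overlap.csv", index=False)

        # -- environmental predictors --------------------------------------
        stage = "env_layers"
        months = sorted(pd.to_datetime(fixes["timestamp"]).dt.month.unique())
        env = generate_environment(extent, months, config)
        grads = gradient_stack(env)
        covars = extract_at(steps, env, grads)
        covars.to_csv(out / "model_ready_covariates.csv", index=False)
        var_cols = [c for c in covars.columns if c in ("DEP", "SST", "CHLA", "SSH", "OMLT", "GDEP", "GSST", "GCHLA", "GSSH", "GOMLT")]
        retained, vif_report = vif_screen(covars[var_cols].dropna())
        vif_report.to_csv(out / "vif_report.csv", index=False)

        # -- repeatability -------------------------------------------------
        stage = "repeatability"
        rpt = repeatability_table(metrics, TRAITS, n_boot=300, seed=seed)
        rpt.to_csv(out / "repeatability.csv", index=False)

        trophic_done = False
        if not skip_trophic:
            # -- isotopes & niche ------------------------------------------
            stage = "trophic_niche"
            consumers, prey = generate_isotopes(config)
            consumers.to_csv(out / "consumers.csv", index=False)
            prey.to_csv(out / "prey.csv", index=False)
            morph = generate_morphometrics(config)
            bci_rows = []
            for sp, df in morph.groupby("species"):
                res = body_condition_index(df["mass_g"], df["wing_mm"])
                sub = df.copy()
                sub["bci_g"] = res.bci.to_numpy()
                bci_rows.append(sub)
            pd.concat(bci_rows).to_csv(out / "bci.csv", index=False)
            niche_table(consumers, seed=seed).to_csv(out / "niche_metrics.csv", index=False)
            overlap_table(consumers, seed=seed).to_csv(out / "niche_overlap.csv", index=False)

            # -- diet mixing -----------------------------------------------
            stage = "diet_mixing"
            mix_rows = []
            for g, df in consumers.groupby("group"):
                post = fit_mixing(
                    df,
                    list(config.source_groups),
                    config.tef,
                    n_iter=mcmc_iter,
                    seed=seed,
                    check_convergence=False,
                )
                summ = summarize_posterior(post)
                summ.insert(0, "group", g)
                summ["max_rhat"] = max(post.rhat.values())
                mix_rows.append(summ)
            pd.concat(mix_rows, ignore_index=True).to_csv(out / "diet_posteriors.csv", index=False)
            trophic_done = True
        else:
            log.info("trophic stages skipped by configuration")

        stage = "manifest"
        manifest = {
            "package": "sulakit",
            "version": __version__,
            "seed": seed,
            "config_hash": _config_hash(config),
            "n_fixes": int(len(fixes)),
            "n_trips": int(len(trips)),
            "bandwidth_deg": float(h),
            "bandwidth_lscv_degenerate": bool(h_degenerate),
            "vif_retained": retained,
            "trophic_stages_run": trophic_done,
            "outputs": sorted(p.name for p in out.glob("*") if p.name != "manifest.json"),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    except Exception as err:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {err}\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err
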