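"""End-to-end orchestration: simulate -> prep -> terrain -> ranges ->
covariates -> HSF, and segment -> LSD, from one validated config.

A single integer seed deterministically spawns independent substreams per
stage, so the whole run (and any stage in isolation) is reproducible
bit-for-bit from (config, seed). All outputs are plain text (CSV, WKT,
ESRI ASCII rasters, JSON, markdown report).
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from pydantic import BaseModel, ConfigDict

from . import covariates as cov
from . import hmm as hmm_mod
from . import hsf as hsf_mod
from . import lsd as lsd_mod
from . import ranges_null as rn
from . import synthetic as syn
from . import track_prep as prep_mod
from .terrain import build_terrain_stack

log = logging.getLogger("tundratrack")

__all__ = ["RunConfig", "run_pipeline", "make_report"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LandscapeConfig(_Strict):
    extent_m: tuple[float, float] = (120_000.0, 160_000.0)
    cell_size: float = 100.0
    veg_range_m: float = 5000.0
    veg_sill: float = 0.004
    veg_mean: float = 0.2
    relief_range_m: float = 12_000.0
    relief_amplitude: float = 200.0
    relief_base: float = 400.0
    water_fraction: float = 0.03


class SimulateConfig(_Strict):
    n_individuals: int = 25
    n_days: int = 365
    fraction_relocating: float = 21 / 25
    goal_distance_m: float = 100_000.0
    missing_rate: float = 0.09
    #: Argos class mix of the daily fixes. The simulated fix is the best
    #: of the several fixes a 3-h daily duty cycle yields, so good classes
    #: dominate.
    class_probs: dict[str, float] = {"3": 0.76, "2": 0.20, "1": 0.03,
                                     "A": 0.01}
    #: designed stopping selection: logit-scale effect of local vegetation
    #: heterogeneity (SAVI sd) on the probability of stopping while
    #: relocating
    stopover_savi_sd_effect: float = 0.4
    #: designed residency selection: site-choice weights on the logit
    #: scale per landscape sd (summer: low elevation; winter: high SAVI)
    summer_elevation_beta: float = -1.0
    winter_savi_beta: float = 1.0


class PrepConfig(_Strict):
    v_cruise: float = 5.0          # km/h
    v_burst: float = 10.0          # km/h
    burst_gap_min: float = 10.0    # minutes
    rate_window: int = 5           # days
    rate_threshold_km: float = 2.0  # km/day
    merge_gap: int = 45            # days; stopover pauses merged within


class RangesConfig(_Strict):
    min_fixes: int = 50
    summer_ratio: int = 5
    winter_ratio: int = 10
    summer_buffer_km: float | None = None   # None: mean-MCP-radius rule
    winter_buffer_km: float | None = None


class HsfConfig(_Strict):
    max_terms: int = 3
    spearman_threshold: float = 0.7
    ci_level: float = 0.85
    priority: list[str] = ["SAVI_mean", "SAVI_sd", "Elevation_mean",
                           "Slope_mean", "Rugosity", "North", "East",
                           "South", "West"]


class SegmentConfig(_Strict):
    n_starts: int = 10


class LsdConfig(_Strict):
    n_quad: int = 15
    bootstrap_reps: int = 999


class RunConfig(_Strict):
    """All tunables of a pipeline run; unknown keys are rejected."""

    seed: int = 0
    landscape: LandscapeConfig = LandscapeConfig()
    simulate: SimulateConfig = SimulateConfig()
    prep: PrepConfig = PrepConfig()
    ranges: RangesConfig = RangesConfig()
    hsf: HsfConfig = HsfConfig()
    segment: SegmentConfig = SegmentConfig()
    lsd: LsdConfig = LsdConfig()


def _season_points(daily: pd.DataFrame, phases, season: str,
                   summer_cutoff=None):
    """Fixes of one season. Residents contribute to summer only up to the
    departure date of the last relocating individual."""
    iv = getattr(phases, season)
    if iv is None:
        return None
    day = daily["timestamp"].dt.normalize()
    hi = iv[1]
    if season == "summer" and phases.is_resident and summer_cutoff is not None:
        hi = min(hi, summer_cutoff)
    sel = daily[(day >= iv[0]) & (day <= hi)]
    return sel[["x", "y"]].to_numpy(dtype=float)


def _season_analysis(season, pts_by_ind, stack, water, ratio, buffer_m,
                     cfg: RunConfig, rng, outdir: Path):
    """Home ranges -> availability -> null ranges -> covariates -> HSF."""
    stable_hr = {}
    for ind, pts in pts_by_ind.items():
        if len(pts) <= cfg.ranges.min_fixes:
            log.info("%s %s: excluded (n=%d <= %d)", season, ind, len(pts),
                     cfg.ranges.min_fixes)
            continue
        curve, stable = rn.range_stability(pts, min_n=cfg.ranges.min_fixes)
        if not stable:
            log.info("%s %s: excluded (unstable range curve)", season, ind)
            continue
        stable_hr[ind] = rn.alocoh(pts, individual_id=ind, season=season)
    if len(stable_hr) < 3:
        raise RuntimeError(f"stage ranges[{season}]: fewer than 3 stable "
                           "home ranges")
    domain = rn.availability_area(
        pts_by_ind, season, water_mask=water, buffer_radius_m=buffer_m,
        extent=stack.savi.extent)
    rows, polys = [], []
    for ind, hr in stable_hr.items():
        try:
            rand, nrej = rn.random_home_ranges(hr, domain, ratio, rng=rng)
        except RuntimeError as exc:
            warnings.warn(f"{season} {ind}: excluded from HSF ({exc})")
            continue
        log.debug("%s %s: %d rejected poses", season, ind, nrej)
        for used, poly in [(1, hr.polygon)] + [(0, p) for p in rand]:
            row = {"individual_id": ind, "used": used,
                   "area_km2": poly.area / 1e6}
            row.update(cov.residency_row(stack, poly))
            rows.append(row)
            polys.append(poly)
    table = pd.DataFrame(rows)
    var_cols = [c for c in cfg.hsf.priority if c in table.columns]
    table_std, meta = cov.standardize(table, var_cols)
    kept, corr_report = cov.prune_correlated(
        table_std, var_cols, threshold=cfg.hsf.spearman_threshold)
    ranking = hsf_mod.rank_models(table_std, "used", kept,
                                  max_terms=cfg.hsf.max_terms,
                                  level=cfg.hsf.ci_level)
    fit = ranking.retained_fit
    nonconst = [n for n in fit.names if n != "const"]
    vifs = hsf_mod.vif(table_std[nonconst]) if len(nonconst) >= 2 else {}
    curves = {v: hsf_mod.log_rss_curve(fit, v, np.linspace(-2, 2, 41))
              for v in nonconst}
    # exports
    table_std.to_csv(outdir / f"covariates_{season}.csv", index=False)
    with open(outdir / f"covariates_{season}_standardization.json",
              "w") as fh:
        json.dump(meta, fh, indent=2)
    ranking.table.to_csv(outdir / f"hsf_ranking_{season}.csv", index=False)
    with open(outdir / f"ranges_{season}.wkt", "w") as fh:
        for poly in polys:
            fh.write(shapely.to_wkt(poly, rounding_precision=2) + "\n")
    for v, c in curves.items():
        c.to_csv(outdir / f"log_rss_{season}_{v}.csv", index=False)
    return {
        "season": season,
        "n_used": len(stable_hr),
        "used_area_km2_mean": float(table.loc[table.used == 1,
                                              "area_km2"].mean()),
        "used_area_km2_sd": float(table.loc[table.used == 1,
                                            "area_km2"].std(ddof=1)),
        "availability_area_km2": domain.area_km2,
        "buffer_radius_km": domain.buffer_radius_m / 1000.0,
        "kept_variables": kept,
        "retained_model": ranking.retained,
        "weights_sum": float(ranking.table["w"].sum()),
        "retained_coefs": {n: fit.coef(n) for n in nonconst},
        "vif": vifs,
    }


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage and write all artifacts into ``outdir``.

    Returns the summary dict (also written as summary.json). Any stage
    failure is re-raised with the stage name attached.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.model_dump_json(indent=2))
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(
        ("landscape", "tracks", "argos", "ranges", "hmm", "boot"),
        ss.spawn(6))}
    summary: dict = {"seed": config.seed}
    stage = "simulate"
    try:
        lc = config.landscape
        landscape = syn.make_landscape(
            seeds["landscape"], extent_m=lc.extent_m, cell_size=lc.cell_size,
            veg_params=syn.VegParams(range_m=lc.veg_range_m, sill=lc.veg_sill,
                                     mean=lc.veg_mean),
            relief_params=syn.ReliefParams(range_m=lc.relief_range_m,
                                           amplitude=lc.relief_amplitude,
                                           base=lc.relief_base),
            water_params=syn.WaterParams(fraction=lc.water_fraction))
        sc = config.simulate
        effects = ({"SAVI_sd": sc.stopover_savi_sd_effect}
                   if sc.stopover_savi_sd_effect else None)
        tracks = syn.simulate_tracks(
            seeds["tracks"], landscape, n_individuals=sc.n_individuals,
            n_days=sc.n_days,
            relocation_params=syn.RelocationParams(
                fraction_relocating=sc.fraction_relocating,
                goal_distance_m=sc.goal_distance_m,
                stopover_logit_effects=effects),
            summer_elevation_beta=sc.summer_elevation_beta,
            winter_savi_beta=sc.winter_savi_beta)
        argos_ss = seeds["argos"].spawn(len(tracks))
        frames = [syn.apply_argos_error(s, t, class_probs=sc.class_probs,
                                        missing_rate=sc.missing_rate)
                  for s, t in zip(argos_ss, tracks)]
        syn.write_tracks_csv(frames, outdir / "tracks.csv")
        landscape.veg_index.write_ascii(outdir / "veg_index.asc")
        landscape.dem.write_ascii(outdir / "dem.asc")
        landscape.water_mask.write_ascii(outdir / "water_mask.asc", fmt="%d")
        summary["n_tracks"] = len(tracks)

        stage = "prep"
        telemetry = syn.read_tracks_csv(outdir / "tracks.csv")
        dailies, phase_by_ind, reloc_frames, logs = {}, {}, {}, []
        for ind, traj in telemetry.groupby("individual_id", sort=True):
            pc = config.prep
            daily, phases, reloc, plog = prep_mod.prep_individual(
                traj.reset_index(drop=True), pc.v_cruise, pc.v_burst,
                pc.burst_gap_min, pc.rate_window, pc.rate_threshold_km,
                pc.merge_gap)
            dailies[ind] = daily
            phase_by_ind[ind] = phases
            if reloc is not None:
                reloc_frames[ind] = reloc
            logs.append(plog)
        pd.DataFrame(logs).to_csv(outdir / "prep_log.csv", index=False)
        summary["n_relocating"] = len(reloc_frames)
        summary["mean_fraction_interpolated"] = float(
            np.mean([l["fraction_interpolated"] for l in logs]))

        stage = "terrain"
        stack = build_terrain_stack(landscape)
        stack.slope.write_ascii(outdir / "slope.asc")

        stage = "ranges/hsf"
        rng_ranges = np.random.default_rng(seeds["ranges"])
        departures = [ph.relocation[0] for ph in phase_by_ind.values()
                      if ph.relocation is not None]
        summer_cutoff = max(departures) if departures else None
        seasons = {}
        for season, ratio, buf in (
                ("summer", config.ranges.summer_ratio,
                 config.ranges.summer_buffer_km),
                ("winter", config.ranges.winter_ratio,
                 config.ranges.winter_buffer_km)):
            pts = {}
            for ind, daily in dailies.items():
                p = _season_points(daily, phase_by_ind[ind], season,
                                   summer_cutoff)
                if p is not None and len(p) >= 3:
                    pts[ind] = p
            if len(pts) < 3:
                log.warning("season %s skipped: too few individuals", season)
                continue
            seasons[season] = _season_analysis(
                season, pts, stack, landscape.water_mask, ratio,
                None if buf is None else buf * 1000.0, config,
                rng_ranges, outdir)
        summary["residency"] = seasons

        stage = "segment"
        if reloc_frames:
            series = [hmm_mod.steps_and_angles(df, ind)
                      for ind, df in reloc_frames.items() if len(df) >= 3]
            rng_hmm = np.random.default_rng(seeds["hmm"])
            fit1 = hmm_mod.fit_hmm(series, n_states=1,
                                   n_starts=config.segment.n_starts,
                                   seed=rng_hmm)
            fit2 = hmm_mod.fit_hmm(series, n_states=2,
                                   n_starts=config.segment.n_starts,
                                   seed=rng_hmm)
            _, gof = hmm_mod.pseudo_residuals(fit2.params, series)
            decoded_frames = []
            for s, (ind, df) in zip(series, [(i, d) for i, d in
                                             reloc_frames.items()
                                             if len(d) >= 3]):
                states = hmm_mod.viterbi_decode(fit2.params, s)
                out = df.iloc[1:].copy()  # one state per step endpoint
                out["state"] = [hmm_mod.STATE_NAMES[k] for k in states]
                decoded_frames.append(out)
            decoded = pd.concat(decoded_frames, ignore_index=True)
            decoded.to_csv(outdir / "decoded_relocation.csv", index=False)
            report = {
                "aic_1state": fit1.aic, "aic_2state": fit2.aic,
                "aic_2state_stationary_k": fit2.aic_stationary,
                "loglik_2state": fit2.loglik,
                "step_mean_km": fit2.params.step_mean.tolist(),
                "step_sd_km": fit2.params.step_sd.tolist(),
                "angle_concentration": fit2.params.angle_conc.tolist(),
                "tpm": fit2.params.tpm.tolist(),
                "pseudo_residual_ks": gof,
                "stopover_fraction": float(
                    (decoded["state"] == "stopover").mean()),
            }
            with open(outdir / "hmm_report.json", "w") as fh:
                json.dump(report, fh, indent=2)
            summary["hmm"] = report

            stage = "lsd"
            table, meta = lsd_mod.build_lsd_table(decoded, stack)
            ranking = lsd_mod.select_lsd_model(table,
                                               n_quad=config.lsd.n_quad)
            fit = ranking.retained_fit
            auc_mean, auc_sd, redrawn = lsd_mod.bootstrap_auc(
                fit, table, B=config.lsd.bootstrap_reps, seed=seeds["boot"])
            ranking.table.to_csv(outdir / "lsd_ranking.csv", index=False)
            fit.odds_ratios().to_csv(outdir / "lsd_odds_ratios.csv",
                                     index=False)
            if "SAVI_mean:Elevation_mean" in fit.names:
                lsd_mod.interaction_curves(fit, meta).to_csv(
                    outdir / "lsd_interaction_curves.csv", index=False)
            summary["lsd"] = {
                "retained_model": ranking.retained,
                "n_fixes": int(len(table)),
                "stopover_share": float(table["stopover"].mean()),
                "random_intercept_sd": fit.random_sd,
                "auc_mean": auc_mean, "auc_sd": auc_sd,
                "odds_ratios": fit.odds_ratios().to_dict("records"),
            }
        else:
            summary["hmm"] = None
            summary["lsd"] = None
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    make_report(outdir)
    return summary


def make_report(run_dir: str | Path) -> str:
    """Render a human-readable markdown summary of a completed run."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.json in {run_dir}; "
                                "incomplete run")
    with open(summary_path) as fh:
        s = json.load(fh)
    lines = ["# Seasonal habitat-selection run report", ""]
    lines.append(f"Seed: {s.get('seed')}  |  tracked individuals: "
                 f"{s.get('n_tracks')}  |  relocating: "
                 f"{s.get('n_relocating')}")
    lines.append("")
    for season, r in (s.get("residency") or {}).items():
        lines += [
            f"## {season.capitalize()} residency",
            f"- stable home ranges: {r['n_used']}, mean area "
            f"{r['used_area_km2_mean']:.1f} ± {r['used_area_km2_sd']:.1f} km²",
            f"- availability area: {r['availability_area_km2']:.0f} km² "
            f"(buffer {r['buffer_radius_km']:.1f} km)",
            f"- retained model: {r['retained_model']} "
            f"(Akaike weights sum {r['weights_sum']:.3f})",
            "",
        ]
    if s.get("hmm"):
        h = s["hmm"]
        frac = h["stopover_fraction"]
        lines += [
            "## Relocation path segmentation",
            f"- 2-state AIC {h['aic_2state']:.1f} vs 1-state "
            f"{h['aic_1state']:.1f}",
            f"- step means {['%.2f' % m for m in h['step_mean_km']]} km/day",
            f"- {100 * frac:.0f}% of relocation locations at stopover",
            "",
        ]
    else:
        lines += ["## Relocation path segmentation", "- skipped "
                  "(no relocating individuals)", ""]
    if s.get("lsd"):
        l = s["lsd"]
        lines += [
            "## Latent selection difference (stopover vs travel)",
            f"- retained model: {l['retained_model']}",
            f"- random-intercept sd: {l['random_intercept_sd']:.3f}",
            f"- bootstrap ROC AUC: {l['auc_mean']:.2f} ± {l['auc_sd']:.2f}",
            "",
        ]
    else:
        lines += ["## Latent selection difference", "- skipped "
                  "(no relocating individuals)", ""]
    text = "\n".join(lines)
    (run_dir / "report.md").write_text(text)
    return text
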