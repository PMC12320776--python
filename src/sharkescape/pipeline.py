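"""End-to-end pipeline: simulate -> respirometry -> TPC; kinematics; SDI; thermal.

Each stage reads the CSVs of its upstream stage from ``out_dir`` and writes
its own outputs there, so stages re-run in isolation reproduce their files.
One global seed fans out to per-stage sub-seeds through a SeedSequence.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, kinematics as km, respirometry as rm, sdi as sd
from . import simulate as sim, thermal as th, tpc
from .config import RunConfig, STAGES
from .io import write_with_sidecar

log = logging.getLogger("sharkescape")

_STAGE_ORDER = {name: i for i, name in enumerate(STAGES)}


def _stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(global_seed, spawn_key=(_STAGE_ORDER[stage],))
    return int(ss.generate_state(1)[0] % 2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "config": config.to_dict(),
        "stages": {},
    }
    runners = {
        "simulate": stage_simulate,
        "respiro": stage_respiro,
        "tpc": stage_tpc,
        "kinematics": stage_kinematics,
        "sdi": stage_sdi,
        "thermal": stage_thermal,
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        log.info("stage %s: starting", stage)
        counts = runners[stage](config, out)
        manifest["stages"][stage] = counts
        log.info("stage %s: %s", stage, counts)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _require(out: Path, name: str, stage: str) -> Path:
    path = out / name
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs {name}; run its upstream stage first"
        )
    return path


# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, out: Path) -> dict:
    seed = _stage_seed(config.seed, "simulate")
    rng = np.random.default_rng(seed)
    scfg = config["simulate"]

    # respirometry cohort: per-shark truths from the canonical aerobic-scope
    # curve plus individual variation, with the stated per-group exclusions
    sigma = tpc.sigma_from_breadth(sim.AAS_BREADTH80)
    meta_rows, trace_frames = [], []
    for g, temp in enumerate(scfg["respiro_temps"]):
        n_excl = scfg["exclusions_per_group"][g]
        for i in range(scfg["n_per_group"]):
            shark = f"r{temp:g}_{i:02d}"
            scaled_min = rng.normal(170.0, 15.0)
            aas_true = max(
                50.0,
                tpc.gaussian_curve(temp, sim.AAS_PEAK, sim.AAS_T_OPT, sigma)
                + rng.normal(0.0, 40.0),
            )
            mass = 0.85
            params = sim.RespiroSimParams(
                mo2_min_true=scaled_min * mass**0.89,
                mo2_max_true=(scaled_min + aas_true) * mass**0.89,
                body_mass=mass,
                total_duration=scfg["respiro_total_duration_h"],
                temperature=temp,
                seed=int(rng.integers(2**31)),
            )
            trace = sim.gen_do_trace(params)
            trace_frames.append(
                pd.DataFrame(
                    {"shark_id": shark, "time_s": trace.time, "do_mg_per_l": trace.do_conc}
                )
            )
            meta_rows.append(
                {
                    "shark_id": shark,
                    "temperature_c": temp,
                    "chamber_volume_l": params.chamber_volume,
                    "body_mass_kg": params.body_mass,
                    "bent_posture": i < n_excl,
                    "equilibrium_loss": False,
                    "died": False,
                }
            )
    write_with_sidecar(pd.concat(trace_frames, ignore_index=True), out / "do_trace.csv",
                       {"seed": seed, **scfg})
    pd.DataFrame(meta_rows).to_csv(out / "respiro_meta.csv", index=False)

    # escape-track cohort: 3 stimulations per shark at 4 temperatures, with
    # mild warming trends in turn rate / speed / accel and shorter latencies
    track_frames, trial_rows = [], []
    for temp in scfg["escape_temps"]:
        for i in range(scfg["n_escape_per_group"]):
            for trial in range(1, scfg["n_trials"] + 1):
                track_id = f"k{temp:g}_{i:02d}_t{trial}"
                latency = int(rng.integers(1, max(2, int(9 - (temp - 25)))))
                params = sim.TrackSimParams(
                    latency_frames=latency,
                    stage1_turn_rate=1700.0 + 110.0 * (temp - 25.0) + rng.normal(0, 60),
                    speed=1.0 + 0.02 * (temp - 25.0) + rng.normal(0, 0.05),
                    accel=35.0 + 1.5 * (temp - 25.0) + rng.normal(0, 2.0),
                    seed=int(rng.integers(2**31)),
                )
                track = sim.gen_escape_track(params)
                n = track.n_frames
                track_frames.append(
                    pd.DataFrame(
                        {
                            "track_id": track_id,
                            "frame": np.arange(n),
                            "head_x": track.head_xy[:, 0],
                            "head_y": track.head_xy[:, 1],
                            "com_x": track.com_xy[:, 0],
                            "com_y": track.com_xy[:, 1],
                            "body_angle_deg": track.body_angle,
                        }
                    )
                )
                trial_rows.append(
                    {
                        "track_id": track_id,
                        "shark_id": f"k{temp:g}_{i:02d}",
                        "trial": trial,
                        "temperature_c": temp,
                        "stimulus_frame": track.stimulus_frame,
                        "fps": track.fps,
                    }
                )
    write_with_sidecar(pd.concat(track_frames, ignore_index=True), out / "tracks.csv",
                       {"seed": seed})
    pd.DataFrame(trial_rows).to_csv(out / "trials.csv", index=False)

    fins = sim.gen_fin_heights("newborn", seed=int(rng.integers(2**31))) + \
        sim.gen_fin_heights("adult", seed=int(rng.integers(2**31)))
    fins_df = pd.DataFrame(
        [
            {
                "individual_id": f.individual_id,
                "life_stage": f.life_stage,
                "fin_height_m": f.fin_height_b,
            }
            for f in fins
        ]
    )
    write_with_sidecar(fins_df, out / "fins.csv", {"seed": seed})

    tcfg = config["thermal"]
    params, start = sim.params_from_field_row(tcfg["site"], tcfg["month"])
    params = sim.ThermalSimParams(
        **{**asdict(params), "n_days": scfg["thermal_n_days"],
           "seed": int(rng.integers(2**31))}
    )
    logs = sim.gen_temperature_log(params, site=tcfg["site"], start=start)
    write_with_sidecar(logs, out / "temperature_log.csv", params)

    return {
        "do_trace_rows": sum(len(f) for f in trace_frames),
        "track_rows": sum(len(f) for f in track_frames),
        "trials": len(trial_rows),
        "fins": len(fins_df),
        "temperature_records": len(logs),
    }


def stage_respiro(config: RunConfig, out: Path) -> dict:
    rcfg = config["respirometry"]
    traces = pd.read_csv(_require(out, "do_trace.csv", "respiro"))
    meta = pd.read_csv(_require(out, "respiro_meta.csv", "respiro"))
    flags = meta.rename(columns={"temperature_c": "group"})[
        ["shark_id", "group", *rm.EXCLUSION_FLAGS]
    ]
    retained, summary = rm.exclusion_filter(flags)
    summary.to_csv(out / "exclusion_summary.csv", index=False)

    series_frames, summary_rows = [], []
    for _, row in meta[meta["shark_id"].isin(retained["shark_id"])].iterrows():
        sub = traces[traces["shark_id"] == row["shark_id"]]
        trace = rm.DOTrace(
            time=sub["time_s"].to_numpy(),
            do_conc=sub["do_mg_per_l"].to_numpy(),
            chamber_volume=row["chamber_volume_l"],
            body_mass=row["body_mass_kg"],
            temperature=row["temperature_c"],
        )
        series = rm.mo2_series(trace, scaling_exponent=rcfg["scaling_exponent"])
        series.insert(0, "shark_id", row["shark_id"])
        series_frames.append(series)
        lo = rm.mo2_min(series["mo2_scaled"].to_numpy(), rcfg["mo2_min_fraction"])
        hi = rm.mo2_max(
            trace,
            n_windows=rcfg["mo2_max_windows"],
            window_span=rcfg["mo2_max_span_s"],
            scaling_exponent=rcfg["scaling_exponent"],
        )
        summ = rm.aerobic_scope(lo, hi, temperature=row["temperature_c"],
                                n_windows_used=len(series))
        summary_rows.append({"shark_id": row["shark_id"], "temperature_c": row["temperature_c"],
                             "mo2_min": summ.mo2_min, "mo2_max": summ.mo2_max,
                             "aas": summ.aas, "negative_aas": summ.negative_aas})
    pd.concat(series_frames, ignore_index=True).to_csv(out / "mo2_series.csv", index=False)
    summary_df = pd.DataFrame(summary_rows)
    summary_df.to_csv(out / "metabolic_summary.csv", index=False)
    summary_df[["shark_id", "temperature_c", "aas"]].to_csv(out / "aas.csv", index=False)
    return {"sharks_retained": len(summary_rows),
            "windows_per_shark": int(series_frames[0].shape[0]) if series_frames else 0}


def stage_tpc(config: RunConfig, out: Path) -> dict:
    tcfg = config["tpc"]
    seed = _stage_seed(config.seed, "tpc")
    data = pd.read_csv(_require(out, "aas.csv", "tpc"))
    fits = {}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for shape in ("gaussian", "quadratic"):
            fits[shape] = tpc.fit_model(data, shape=shape,
                                        n_starts=tcfg["n_starts"], seed=seed)
    warn_msgs = sorted({str(w.message) for w in caught})
    best, delta = tpc.aicc_select([fits["gaussian"], fits["quadratic"]])
    derived = tpc.derive_params(best, fraction=tcfg["breadth_fraction"])
    boot, intervals = tpc.bootstrap_bca(
        best, data, n_boot=tcfg["n_boot"], seed=seed,
        fraction=tcfg["breadth_fraction"], alpha=tcfg["alpha"],
    )
    groups = {
        f"{t:g}C": g["aas"].to_numpy() for t, g in data.groupby("temperature_c")
    }
    contrasts, letters = tpc.holm_sidak_pairwise(groups, alpha=tcfg["alpha"])
    boot.draws.to_csv(out / "tpc_bootstrap_draws.csv", index=False)
    delta.to_csv(out / "tpc_model_selection.csv", index=False)
    report = {
        "selected_shape": best.shape,
        "params": best.params,
        "aicc_delta": float(delta["delta_aicc"].max()),
        "derived": asdict(derived),
        "intervals": intervals.reset_index().to_dict(orient="records"),
        "holm_sidak": contrasts.to_dict(orient="records"),
        "letters": letters,
        "n_boot_converged": boot.n_converged,
        "warnings": warn_msgs,
    }
    (out / "tpc_report.json").write_text(json.dumps(report, indent=2))
    return {"n_obs": best.n_obs, "selected": best.shape,
            "n_boot_converged": boot.n_converged}


def stage_kinematics(config: RunConfig, out: Path) -> dict:
    kcfg = config["kinematics"]
    tracks = pd.read_csv(_require(out, "tracks.csv", "kinematics"))
    trials = pd.read_csv(_require(out, "trials.csv", "kinematics"))
    per_trial = []
    for _, tr in trials.iterrows():
        sub = tracks[tracks["track_id"] == tr["track_id"]].sort_values("frame")
        track = km.EscapeTrack(
            fps=tr["fps"],
            stimulus_frame=int(tr["stimulus_frame"]),
            head_xy=sub[["head_x", "head_y"]].to_numpy(),
            com_xy=sub[["com_x", "com_y"]].to_numpy(),
            body_angle=sub["body_angle_deg"].to_numpy(),
        )
        m = km.extract_metrics(
            track,
            trial_index=int(tr["trial"]),
            min_excursion_deg=kcfg["min_excursion_deg"],
            smooth_window=kcfg["smooth_window"],
        )
        per_trial.append({"shark_id": tr["shark_id"], "temperature_c": tr["temperature_c"],
                          **asdict(m)})
    per_trial_df = pd.DataFrame(per_trial)
    rows = []
    for (shark, temp), grp in per_trial_df.groupby(["shark_id", "temperature_c"]):
        trial_metrics = [
            km.EscapeMetrics(**{k: r[k] for k in (
                "responded", "response_type", "latency_ms", "omega_s1",
                "u_max", "a_max", "trial_index")})
            for _, r in grp.iterrows()
        ]
        best = km.maximal_performance(trial_metrics)
        rows.append({"shark_id": shark, "temperature_c": temp, **asdict(best)})
    metrics = pd.DataFrame(rows)
    metrics.rename(columns={"latency_ms": "latency_ms"}).to_csv(
        out / "escape_metrics.csv", index=False
    )
    regressions = {}
    for var, logt in [("latency_ms", True), ("omega_s1", False),
                      ("u_max", False), ("a_max", False)]:
        reg = km.temperature_regression(metrics, var, log_transform=logt)
        regressions[var] = asdict(reg)
    responsiveness = float(per_trial_df["responded"].mean())
    report = {"responsiveness": responsiveness, "regressions": regressions,
              "n_sharks": len(metrics)}
    (out / "kinematics_report.json").write_text(json.dumps(report, indent=2))
    return {"trials": len(per_trial_df), "sharks": len(metrics),
            "responsiveness": responsiveness}


def stage_sdi(config: RunConfig, out: Path) -> dict:
    scfg = config["sdi"]
    fins = pd.read_csv(_require(out, "fins.csv", "sdi"))
    grid = sd.default_depth_grid(scfg["depth_min_m"], scfg["depth_max_m"],
                                 scfg["depth_step_m"])
    model = sd.sdi_regression(fins, depth_grid=grid,
                              fit_intercept=scfg["fit_intercept"],
                              threshold=scfg["threshold"])
    report = {
        "threshold": model.threshold,
        "slopes": {s: f.slope for s, f in model.stage_fits.items()},
        "critical_depths_m": model.critical_depths,
        "advantage_band_m": model.advantage_band,
        "ancova_f": model.ancova_f,
        "ancova_p": model.ancova_p,
    }
    (out / "sdi_report.json").write_text(json.dumps(report, indent=2))
    return {"individuals": int(fins.shape[0]),
            "band": model.advantage_band}


def stage_thermal(config: RunConfig, out: Path) -> dict:
    tcfg = config["thermal"]
    seed = _stage_seed(config.seed, "thermal")
    logs = pd.read_csv(_require(out, "temperature_log.csv", "thermal"))
    records = th.hourly_aggregate(logs, site=tcfg["site"], months=[tcfg["month"]])
    cycle = th.fit_diel_loess(
        records,
        span_grid=tuple(tcfg["span_grid"]),
        degree_grid=tuple(tcfg["degree_grid"]),
        n_folds=tcfg["n_folds"],
        seed=seed,
        site=tcfg["site"],
        month=tcfg["month"],
    )
    params = th.derive_cycle_params(cycle)
    vol = th.volatility_index(records, cycle)
    pd.DataFrame({"site": tcfg["site"], "month": tcfg["month"],
                  "hour": cycle.hours, "temp_c": cycle.temp_c}).to_csv(
        out / "diel_cycle.csv", index=False)
    vol.to_csv(out / "thermal_volatility.csv", index=False)
    report = {"site": tcfg["site"], "month": tcfg["month"],
              "span": cycle.span, "degree": cycle.degree, **asdict(params)}
    tpc_report = out / "tpc_report.json"
    if tpc_report.exists():
        derived = json.loads(tpc_report.read_text())["derived"]
        hours, frac = th.time_in_breadth(cycle, derived["lower"], derived["upper"])
        report["hours_in_aas_breadth"] = hours
        report["fraction_in_aas_breadth"] = frac
    (out / "thermal_report.json").write_text(json.dumps(report, indent=2))
    return {"records": len(records), "span": cycle.span, "degree": cycle.degree}
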