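"""Seeded synthetic-data generators for every raw data stream.

The generators emulate the four kinds of raw input the analysis consumes:

* post-exercise respirometry traces — whole-animal oxygen uptake decays
  exponentially from a post-chase maximum towards a resting minimum, sampled
  through the 2-s / 5-min-measure / 10-min-flush schedule for 24 h;
* overhead C-start escape tracks at 240 fps with frame-quantized latency;
* caudal-fin-height cohorts for newborn and adult sharks;
* hourly temperature-logger series following an asymmetric diel cycle
  (dawn minimum, mid-afternoon maximum) with hour-wise noise and occasional
  warm spikes;
* absolute-aerobic-scope observations drawn from a Gaussian thermal
  performance curve at the three-temperature study design.

All noise is Gaussian and every generator is bit-reproducible per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import EscapeTrack
from .respirometry import DOTrace, Schedule
from .sdi import FinMeasure
from .tpc import gaussian_curve, sigma_from_breadth
from .thermal import FIELD_DIEL_TABLE, MONTH_NUMBERS

# peak AAS (mg O2 h^-1 kg^-0.89), its temperature (degC) and 80% breadth
# (degC) of the fitted aerobic-scope curve; the canonical simulation truth
AAS_PEAK = 317.10
AAS_T_OPT = 29.15
AAS_BREADTH80 = 3.30

# group mean fin heights (m) and cohort sizes; dispersion reconstructed from
# the reported standard errors (SE * sqrt(n))
FIN_DEFAULTS = {
    "newborn": {"n": 18, "mean": 0.1166, "sd": 0.0062 * math.sqrt(18)},
    "adult": {"n": 10, "mean": 0.3111, "sd": 0.0095 * math.sqrt(10)},
}


# ---------------------------------------------------------------------------
# respirometry

@dataclass(frozen=True)
class RespiroSimParams:
    """Truth and schedule for one simulated 24-h respirometry trial.

    ``mo2_min_true``/``mo2_max_true`` are whole-animal uptake rates
    (mg O2 h^-1); uptake relaxes from the maximum to the minimum with time
    constant ``recovery_tau`` (h).  ``noise_sd`` is optode noise in mg l^-1.
    """

    mo2_min_true: float = 150.0
    mo2_max_true: float = 450.0
    recovery_tau: float = 1.5
    chamber_volume: float = 30.0
    body_mass: float = 0.85
    sample_interval: float = 2.0
    measure_duration: float = 300.0
    flush_duration: float = 600.0
    total_duration: float = 24.0
    noise_sd: float = 0.005
    ambient_do: float = 6.8
    temperature: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mo2_max_true >= self.mo2_min_true > 0:
            raise ValueError("need mo2_max_true >= mo2_min_true > 0")
        if self.recovery_tau <= 0 or self.total_duration <= 0:
            raise ValueError("durations must be positive")
        if self.chamber_volume <= 0 or self.body_mass <= 0:
            raise ValueError("chamber_volume and body_mass must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def schedule(self) -> Schedule:
        return Schedule(self.measure_duration, self.flush_duration, self.sample_interval)


def instantaneous_uptake(params: RespiroSimParams, t_hours):
    """Whole-animal uptake MO2(t) = min + (max - min) * exp(-t / tau)."""
    t = np.asarray(t_hours, dtype=float)
    return params.mo2_min_true + (params.mo2_max_true - params.mo2_min_true) * np.exp(
        -t / params.recovery_tau
    )


def window_mean_uptake(params: RespiroSimParams, t0_h: float, t1_h: float) -> float:
    """Exact time-average of the uptake decay over a window (closed form)."""
    span = t1_h - t0_h
    delta = params.mo2_max_true - params.mo2_min_true
    tau = params.recovery_tau
    return params.mo2_min_true + delta * tau / span * (
        math.exp(-t0_h / tau) - math.exp(-t1_h / tau)
    )


def gen_do_trace(params: RespiroSimParams) -> DOTrace:
    """Simulate a dissolved-oxygen trace through the measure/flush schedule.

    Within each measurement window DO declines linearly at the rate implied
    by the window-averaged uptake (uptake varies slowly relative to a 5-min
    window, matching the per-window linear-slope analysis); each flush resets
    DO to the ambient value.  Defaults yield 96 windows x 150 samples =
    14 400 readings over 24 h.
    """
    sched = params.schedule
    rng = np.random.default_rng(params.seed)
    n_cycles = int(params.total_duration * 3600.0 // sched.period)
    offsets = np.arange(0.0, sched.measure_duration, sched.sample_interval)
    starts = np.arange(n_cycles) * sched.period
    t0_h = starts / 3600.0
    t1_h = (starts + sched.measure_duration) / 3600.0
    delta = params.mo2_max_true - params.mo2_min_true
    tau = params.recovery_tau
    mean_uptake = params.mo2_min_true + delta * tau / (t1_h - t0_h) * (
        np.exp(-t0_h / tau) - np.exp(-t1_h / tau)
    )
    v_eff = params.chamber_volume - params.body_mass  # body density 1 kg/l
    rates = mean_uptake / (3600.0 * v_eff)  # mg/l per second of decline
    times = (starts[:, None] + offsets[None, :]).ravel()
    do = (params.ambient_do - rates[:, None] * offsets[None, :]).ravel()
    if params.noise_sd > 0:
        do = do + rng.normal(0.0, params.noise_sd, size=do.size)
    do = np.clip(do, 0.0, None)
    return DOTrace(
        time=times,
        do_conc=do,
        chamber_volume=params.chamber_volume,
        body_mass=params.body_mass,
        schedule=sched,
        temperature=params.temperature,
    )


# ---------------------------------------------------------------------------
# escape tracks

@dataclass(frozen=True)
class TrackSimParams:
    """Ground truth for one simulated C-start track.

    The centre of mass accelerates along a fixed escape heading at ``accel``
    up to the cruise ``speed``; the body axis turns at ``stage1_turn_rate``
    through Stage 1 and, when ``stage2`` is set, contralaterally through a
    Stage 2 of ``stage2_duration``.  Tracks are generated directly in
    corrected planar coordinates (no camera model).
    """

    fps: float = 240.0
    latency_frames: int = 3
    stage1_duration: float = 0.05      # s
    stage1_turn_rate: float = 1700.0   # deg/s
    stage2: bool = True
    stage2_duration: float = 0.04      # s
    speed: float = 1.2                 # m/s cruise speed after the ramp
    accel: float = 40.0                # m/s^2 ramp acceleration
    jitter_sd: float = 0.0002          # m, tracking noise
    n_pre_frames: int = 24
    n_post_frames: int = 48
    head_offset: float = 0.08          # m from centre of mass to head
    escape_heading_deg: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.latency_frames < 0:
            raise ValueError("latency_frames must be >= 0")
        if self.stage1_duration <= 0 or (self.stage2 and self.stage2_duration <= 0):
            raise ValueError("stage durations must be positive")
        if self.speed < 0 or self.accel <= 0:
            raise ValueError("speed must be >= 0 and accel > 0")


def gen_escape_track(params: TrackSimParams) -> EscapeTrack:
    """Simulate one stimulation trial.

    Coordinates are stationary (plus jitter) until ``latency_frames`` after
    the stimulus; the first moved position appears exactly at frame
    ``stimulus + latency_frames`` so the detected latency round-trips.
    """
    rng = np.random.default_rng(params.seed)
    dt = 1.0 / params.fps
    n_motion = int(
        math.ceil(
            (params.stage1_duration + (params.stage2_duration if params.stage2 else 0.0))
            * params.fps
        )
    )
    n = params.n_pre_frames + params.latency_frames + n_motion + params.n_post_frames
    stimulus = params.n_pre_frames
    onset = stimulus + params.latency_frames

    frames = np.arange(n)
    elapsed = np.where(frames >= onset, (frames - onset + 1) * dt, 0.0)

    # body angle: stage 1 turn, optional contralateral stage 2, then hold
    s1 = np.minimum(elapsed, params.stage1_duration)
    angle = params.stage1_turn_rate * s1
    if params.stage2:
        s2 = np.clip(elapsed - params.stage1_duration, 0.0, params.stage2_duration)
        angle = angle - params.stage1_turn_rate * s2

    # centre of mass: constant-acceleration ramp to cruise speed, straight line
    t_ramp = params.speed / params.accel
    dist = np.where(
        elapsed <= t_ramp,
        0.5 * params.accel * elapsed**2,
        0.5 * params.accel * t_ramp**2 + params.speed * (elapsed - t_ramp),
    )
    heading = math.radians(params.escape_heading_deg)
    u = np.array([math.cos(heading), math.sin(heading)])
    com = dist[:, None] * u[None, :]
    head = com + params.head_offset * np.column_stack(
        [np.cos(np.radians(angle)), np.sin(np.radians(angle))]
    )
    if params.jitter_sd > 0:
        com = com + rng.normal(0.0, params.jitter_sd, size=com.shape)
        head = head + rng.normal(0.0, params.jitter_sd, size=head.shape)
    return EscapeTrack(
        fps=params.fps,
        stimulus_frame=stimulus,
        head_xy=head,
        com_xy=com,
        body_angle=angle,
    )


# ---------------------------------------------------------------------------
# fin heights

def gen_fin_heights(
    stage: str,
    n: int | None = None,
    mean: float | None = None,
    sd: float | None = None,
    seed: int = 0,
) -> list[FinMeasure]:
    """Draw a positive-truncated Gaussian cohort of caudal-fin heights (m)."""
    if stage not in FIN_DEFAULTS:
        raise ValueError(f"stage must be one of {tuple(FIN_DEFAULTS)}")
    d = FIN_DEFAULTS[stage]
    n = d["n"] if n is None else n
    mean = d["mean"] if mean is None else mean
    sd = d["sd"] if sd is None else sd
    if mean <= 0 or sd < 0:
        raise ValueError("mean must be positive and sd non-negative")
    rng = np.random.default_rng(seed)
    heights = rng.normal(mean, sd, size=n)
    while np.any(heights <= 0):  # truncate at > 0 by resampling
        bad = heights <= 0
        heights[bad] = rng.normal(mean, sd, size=bad.sum())
    return [
        FinMeasure(f"{stage}_{i:03d}", stage, float(h)) for i, h in enumerate(heights)
    ]


# ---------------------------------------------------------------------------
# temperature logs

@dataclass(frozen=True)
class ThermalSimParams:
    """Diel-cycle truth for one site x month of logger records.

    ``amplitude`` is the peak excursion above the daily mean (half the daily
    range of the noiseless cycle).  ``min_hour`` places the trough; when it
    is not 12 h opposite the peak, the cosine phase is warped in time so the
    dawn minimum and mid-afternoon maximum of real reef flats are reproduced
    while the daily mean stays exact.
    """

    mean_temp: float = 28.21
    amplitude: float = 2.41
    peak_hour: float = 14.0
    min_hour: float | None = 6.0
    volatility_sd: float | np.ndarray = 0.4
    spike_prob: float = 0.01
    spike_mag: float = 4.0
    n_days: int = 30
    loggers: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0 <= self.peak_hour < 24:
            raise ValueError("peak_hour must lie in [0, 24)")
        if not 0 <= self.spike_prob <= 1:
            raise ValueError("spike_prob must lie in [0, 1]")
        if self.n_days <= 0 or self.loggers <= 0:
            raise ValueError("n_days and loggers must be positive")


def diel_cycle_truth(params: ThermalSimParams, hours):
    """Noiseless cycle value at hours-of-day (time-warped cosine)."""
    h = np.asarray(hours, dtype=float) % 24.0
    min_hour = (
        (params.peak_hour + 12.0) % 24.0 if params.min_hour is None else params.min_hour
    )
    desc = (min_hour - params.peak_hour) % 24.0
    if desc == 0:
        desc = 12.0
    asc = 24.0 - desc
    rel = (h - params.peak_hour) % 24.0
    phase = np.where(rel <= desc, np.pi * rel / desc, np.pi + np.pi * (rel - desc) / asc)
    return params.mean_temp + params.amplitude * np.cos(phase)


def gen_temperature_log(
    params: ThermalSimParams,
    site: str = "site1",
    start: str = "2021-11-01",
) -> pd.DataFrame:
    """Hourly logger records: warped diel cosine + noise + rare warm spikes.

    Returns a frame with columns ``site``, ``logger_id``, ``timestamp``
    (exactly on the hour) and ``temp_c``.
    """
    rng = np.random.default_rng(params.seed)
    hours = np.arange(params.n_days * 24)
    hod = hours % 24
    base = diel_cycle_truth(params, hod)
    sd = np.asarray(params.volatility_sd, dtype=float)
    sd_by_hour = np.broadcast_to(sd, (24,)) if sd.ndim else np.full(24, float(sd))
    timestamps = pd.Timestamp(start) + pd.to_timedelta(hours, unit="h")
    frames = []
    for logger in range(params.loggers):
        temp = base + rng.normal(0.0, 1.0, size=hours.size) * sd_by_hour[hod]
        if params.spike_prob > 0:
            spikes = rng.random(hours.size) < params.spike_prob
            temp = temp + spikes * params.spike_mag
        frames.append(
            pd.DataFrame(
                {
                    "site": site,
                    "logger_id": f"logger_{logger + 1}",
                    "timestamp": timestamps,
                    "temp_c": temp,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def params_from_field_row(site: str, month: str, **overrides) -> ThermalSimParams:
    """Simulation parameters reproducing one site x month field cycle.

    The amplitude is the peak excursion ``max - mean`` so the simulated cycle
    reproduces the observed mean, maximum and time of maximum exactly; the
    observed trough time sets the phase warp.  Returns ``(params, start)``
    where ``start`` is an ISO date in the matching calendar month.
    """
    row = FIELD_DIEL_TABLE[
        (FIELD_DIEL_TABLE["site"] == site) & (FIELD_DIEL_TABLE["month"] == month)
    ]
    if row.empty:
        raise KeyError(f"no field row for {site!r} / {month!r}")
    r = row.iloc[0]
    start_month = MONTH_NUMBERS[month]
    start_year = 2021 if start_month >= 11 else 2022
    defaults = dict(
        mean_temp=float(r["mean_c"]),
        amplitude=float(r["max_c"] - r["mean_c"]),
        peak_hour=float(r["time_max_h"]),
        min_hour=float(r["time_min_h"]),
    )
    defaults.update(overrides)
    params = ThermalSimParams(**defaults)
    return params, f"{start_year}-{start_month:02d}-01"


# ---------------------------------------------------------------------------
# aerobic-scope datasets

def gen_aas_dataset(
    peak: float = AAS_PEAK,
    t_opt: float = AAS_T_OPT,
    breadth80: float = AAS_BREADTH80,
    temps=(27.0, 29.0, 31.0),
    n_per_temp=(9, 8, 8),
    noise_sd: float = 40.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-shark AAS observations from a Gaussian TPC at the study design.

    The Gaussian width is implied by the 80 % performance breadth; values are
    truncated at >= 0.  Returns ``(shark_id, temperature_c, aas)``.
    """
    if peak <= 0 or breadth80 <= 0:
        raise ValueError("peak and breadth80 must be positive")
    temps = np.asarray(temps, dtype=float)
    n_per_temp = np.asarray(n_per_temp, dtype=int)
    if temps.size != n_per_temp.size:
        raise ValueError("temps and n_per_temp lengths differ")
    rng = np.random.default_rng(seed)
    sigma = sigma_from_breadth(breadth80, fraction=0.8)
    rows = []
    sid = 0
    for t, n in zip(temps, n_per_temp):
        mu = gaussian_curve(t, peak, t_opt, sigma)
        vals = mu + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.full(n, mu)
        for v in vals:
            rows.append(
                {"shark_id": f"shark_{sid:03d}", "temperature_c": t, "aas": max(0.0, float(v))}
            )
            sid += 1
    return pd.DataFrame(rows)
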