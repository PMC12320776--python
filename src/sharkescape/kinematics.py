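"""Fast-start escape-response kinematics from overhead video tracks.

A startled shark performs a C-start: a first unilateral body bend (Stage 1),
optionally followed by a contralateral bend (Stage 2).  Responses with only
Stage 1 are "single-bend", with both stages "double-bend".  From a
frame-indexed track (240 fps) five performance variables are extracted:

1. responsiveness — whether the stimulus elicited any escape movement;
2. escape latency (ms) — stimulus onset to first detectable movement,
   quantized by the frame interval;
3. maximum Stage-1 turning rate ω_S1 (deg s⁻¹);
4. maximum speed U_MAX (m s⁻¹) of the centre of mass over the response;
5. maximum acceleration A_MAX (m s⁻²).

Derivatives use local quadratic (Savitzky–Golay) smoothing over a 5-frame
window: raw finite differences amplify digitisation noise quadratically in
the second derivative.  Maximal performance per shark is the best of three
stimulations, variable by variable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.signal import savgol_filter

DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_MIN_EXCURSION_DEG = 10.0
MIN_ONSET_DISPLACEMENT_M = 0.001  # floor for the movement-onset threshold


@dataclass
class EscapeTrack:
    """Frame-indexed planar coordinates of one stimulation trial."""

    fps: float
    stimulus_frame: int
    head_xy: np.ndarray  # (n, 2) metres
    com_xy: np.ndarray   # (n, 2) metres, centre of mass
    body_angle: np.ndarray  # (n,) degrees, anterior midline orientation

    def __post_init__(self) -> None:
        self.head_xy = np.asarray(self.head_xy, dtype=float)
        self.com_xy = np.asarray(self.com_xy, dtype=float)
        self.body_angle = np.asarray(self.body_angle, dtype=float)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        n = self.body_angle.size
        if self.head_xy.shape != (n, 2) or self.com_xy.shape != (n, 2):
            raise ValueError("head_xy/com_xy must be (n, 2) matching body_angle")
        if not 0 <= self.stimulus_frame < n:
            raise ValueError("stimulus_frame outside the track")

    @property
    def n_frames(self) -> int:
        return self.body_angle.size

    @property
    def dt(self) -> float:
        return 1.0 / self.fps


@dataclass
class StageSegmentation:
    stage1: tuple[int, int]          # [onset, end) frame interval
    stage2: tuple[int, int] | None
    response_type: str               # "single_bend" | "double_bend"
    truncated: bool = False


@dataclass
class EscapeMetrics:
    responded: bool
    response_type: str | None = None
    latency_ms: float | None = None
    omega_s1: float | None = None
    u_max: float | None = None
    a_max: float | None = None
    trial_index: int | None = None
    n_trials: int = 1


def detect_response(
    track: EscapeTrack, displacement_threshold: float | None = None
) -> tuple[bool, int | None]:
    """Find the first post-stimulus frame with detectable head movement.

    The baseline is the median pre-stimulus head position; the default
    threshold is 3x the pre-stimulus jitter SD with a 1-mm floor, so it
    adapts to tracking noise but never triggers on sub-millimetre flicker.
    """
    if track.stimulus_frame < 1:
        raise ValueError("no pre-stimulus frames to establish a baseline")
    pre = track.head_xy[: track.stimulus_frame]
    baseline = np.median(pre, axis=0)
    if displacement_threshold is None:
        jitter = np.linalg.norm(pre - baseline, axis=1)
        displacement_threshold = max(3.0 * jitter.std(), MIN_ONSET_DISPLACEMENT_M)
    disp = np.linalg.norm(track.head_xy[track.stimulus_frame :] - baseline, axis=1)
    beyond = np.nonzero(disp > displacement_threshold)[0]
    if beyond.size == 0:
        return False, None
    return True, int(track.stimulus_frame + beyond[0])


def latency_ms(onset_frame: int, stimulus_frame: int, fps: float) -> float:
    """Frame-quantized escape latency, truncated to 2 decimals of a ms.

    One frame at 240 fps is 4.1666... ms, reported as 4.16 ms.
    """
    if onset_frame < stimulus_frame:
        raise ValueError("onset precedes stimulus")
    raw = (onset_frame - stimulus_frame) * 1000.0 / fps
    return math.floor(raw * 100.0 + 1e-9) / 100.0


def _angular_velocity(track: EscapeTrack, window: int) -> np.ndarray:
    return savgol_filter(
        track.body_angle, window_length=window, polyorder=2, deriv=1, delta=track.dt
    )


def stage_segment(
    track: EscapeTrack,
    onset: int,
    min_excursion_deg: float = DEFAULT_MIN_EXCURSION_DEG,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> StageSegmentation:
    """Locate Stage 1 / Stage 2 boundaries and classify the response type.

    Stage 1 runs from onset to the first sign reversal of the smoothed
    angular velocity sustained for >= 2 frames.  A following contralateral
    bend whose angular excursion exceeds ``min_excursion_deg`` makes the
    response a double-bend; otherwise it is a single-bend.
    """
    omega = _angular_velocity(track, smooth_window)
    n = track.n_frames
    post = omega[onset:]
    nz = np.nonzero(np.abs(post) > 1e-9)[0]
    if nz.size == 0:
        return StageSegmentation((onset, n), None, "single_bend", truncated=True)
    s1_sign = np.sign(post[nz[0]])
    end = None
    for f in range(onset + nz[0] + 1, n - 1):
        if np.sign(omega[f]) == -s1_sign and np.sign(omega[f + 1]) == -s1_sign:
            end = f
            break
    if end is None:
        return StageSegmentation((onset, n), None, "single_bend", truncated=True)
    # contralateral excursion after the reversal
    seg = track.body_angle[end:]
    excursion = -s1_sign * (seg - track.body_angle[end])
    if excursion.size and excursion.max() >= min_excursion_deg:
        back = np.nonzero(
            (np.sign(omega[end:-1]) == s1_sign) & (np.sign(omega[end + 1 :]) == s1_sign)
        )[0]
        s2_end = int(end + back[0]) if back.size else n
        return StageSegmentation((onset, end), (end, s2_end), "double_bend")
    return StageSegmentation((onset, end), None, "single_bend")


def omega_s1(
    track: EscapeTrack,
    stage1: tuple[int, int],
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> float:
    """Maximum smoothed turning rate (deg s⁻¹) during Stage 1."""
    a, b = stage1
    if b <= a:
        raise ValueError("empty stage-1 interval")
    omega = _angular_velocity(track, smooth_window)
    return float(np.abs(omega[a:b]).max())


def umax_amax(
    track: EscapeTrack,
    onset: int,
    end: int | None = None,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> tuple[float, float]:
    """Maximum centre-of-mass speed and acceleration over the response.

    Speed and acceleration are the norms of the smoothed first and second
    derivatives of the centre-of-mass position, maximized from onset to
    ``end`` (track end by default, i.e. over Stages 1-2).
    """
    end = track.n_frames if end is None else end
    if end - onset < max(7, smooth_window):
        raise ValueError("too few post-onset frames for smoothed derivatives")
    vel = savgol_filter(
        track.com_xy, window_length=smooth_window, polyorder=2, deriv=1,
        delta=track.dt, axis=0,
    )
    acc = savgol_filter(
        track.com_xy, window_length=smooth_window, polyorder=2, deriv=2,
        delta=track.dt, axis=0,
    )
    speed = np.linalg.norm(vel, axis=1)
    accel = np.linalg.norm(acc, axis=1)
    return float(speed[onset:end].max()), float(accel[onset:end].max())


def extract_metrics(
    track: EscapeTrack,
    trial_index: int = 1,
    displacement_threshold: float | None = None,
    min_excursion_deg: float = DEFAULT_MIN_EXCURSION_DEG,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> EscapeMetrics:
    """Run the full per-trial extraction pipeline on one track."""
    responded, onset = detect_response(track, displacement_threshold)
    if not responded:
        return EscapeMetrics(responded=False, trial_index=trial_index)
    seg = stage_segment(track, onset, min_excursion_deg, smooth_window)
    end = seg.stage2[1] if seg.stage2 else seg.stage1[1]
    u, a = umax_amax(track, onset, end=max(end, onset + max(7, smooth_window)),
                     smooth_window=smooth_window)
    return EscapeMetrics(
        responded=True,
        response_type=seg.response_type,
        latency_ms=latency_ms(onset, track.stimulus_frame, track.fps),
        omega_s1=omega_s1(track, seg.stage1, smooth_window),
        u_max=u,
        a_max=a,
        trial_index=trial_index,
    )


def maximal_performance(trials: list[EscapeMetrics]) -> EscapeMetrics:
    """Best-of-trials estimate of maximal performance, variable by variable.

    The minimum latency and the maxima of turning rate, speed and
    acceleration may come from different trials.  Non-responding trials are
    ignored; at least one responder is required.
    """
    responders = [t for t in trials if t.responded]
    if not responders:
        raise ValueError("no responding trial")
    lat = min(t.latency_ms for t in responders)
    best_lat = next(t for t in responders if t.latency_ms == lat)
    types = {t.response_type for t in responders}
    return EscapeMetrics(
        responded=True,
        response_type="double_bend" if "double_bend" in types else "single_bend",
        latency_ms=lat,
        omega_s1=max(t.omega_s1 for t in responders),
        u_max=max(t.u_max for t in responders),
        a_max=max(t.a_max for t in responders),
        trial_index=best_lat.trial_index,
        n_trials=len(responders),
    )


@dataclass
class TemperatureRegression:
    variable: str
    slope: float
    intercept: float
    f_stat: float
    p_value: float
    df_num: int
    df_den: int
    n: int
    log_transformed: bool


def temperature_regression(
    metrics: pd.DataFrame,
    variable: str,
    log_transform: bool = False,
    double_bend_only: bool = True,
) -> TemperatureRegression:
    """OLS of one escape variable on temperature (single-bends excluded).

    ``metrics`` needs ``temperature_c``, the variable column and (when
    filtering) ``response_type``.  Latency is conventionally natural-log
    transformed to stabilize its variance.  The slope F-test has (1, n-2)
    degrees of freedom.
    """
    df = metrics.dropna(subset=[variable, "temperature_c"])
    if double_bend_only and "response_type" in df:
        df = df[df["response_type"] == "double_bend"]
    if df["temperature_c"].nunique() < 3:
        raise ValueError("need >= 3 temperatures for the regression")
    y = df[variable].to_numpy(dtype=float)
    if log_transform:
        if np.any(y <= 0):
            raise ValueError("log transform requires positive values")
        y = np.log(y)
    X = sm.add_constant(df["temperature_c"].to_numpy(dtype=float))
    fit = sm.OLS(y, X).fit()
    return TemperatureRegression(
        variable=variable,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        f_stat=float(fit.fvalue),
        p_value=float(fit.f_pvalue),
        df_num=1,
        df_den=int(fit.df_resid),
        n=int(fit.nobs),
        log_transformed=log_transform,
    )


def grubbs_test(values, alpha: float = 0.05) -> tuple[int | None, float, float]:
    """Two-sided Grubbs outlier test flagging at most one extreme value.

    Returns ``(index_or_None, G, critical)`` where ``G = max|x - mean| / sd``
    and the critical value derives from the Student t quantile at
    ``alpha / (2n)`` with ``n - 2`` degrees of freedom.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("zero variance: Grubbs statistic undefined")
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = dev[i] / s
    t2 = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2) ** 2
    critical = (n - 1) / math.sqrt(n) * math.sqrt(t2 / (n - 2 + t2))
    return (i if g > critical else None), float(g), float(critical)


def bartlett_test(groups) -> tuple[float, int, float]:
    """Bartlett homogeneity-of-variances test; returns (chi2, df, p)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.var(a, ddof=1) == 0 for a in arrays):
        return 0.0, len(arrays) - 1, 1.0
    stat, p = stats.bartlett(*arrays)
    return float(stat), len(arrays) - 1, float(p)
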