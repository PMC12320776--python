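"""Diel thermal-regime characterization from temperature-logger records.

Paired loggers at each nursery site record water temperature at the top of
every hour.  For a given site and month, hourly readings are averaged across
loggers, pooled across years by hour-of-day, and smoothed with a locally
estimated scatterplot smoother (LOESS: tricube-weighted local polynomials)
whose span and degree are selected by k-fold cross-validation.  The smoothed
24-h cycle yields the mean, extrema, their times and the daily range; a
signed volatility index captures hour-wise dispersion of the raw records
around the cycle; and the overlap of the cycle with the aerobic-scope
performance window (e.g. 27.5-30.8 °C) is measured in hours per day.

Time-of-day is circular, so records are replicated ±6 h beyond the 00-24 h
boundaries before local fitting to avoid edge bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

#: physically plausible bounds for tropical reef-flat water temperature (°C)
TEMP_BOUNDS = (15.0, 40.0)

#: 24-h thermal-regime parameters per nursery site and month (field summary):
#: smoothed cycle mean, minimum and maximum (°C), their times (hour of day)
#: and the daily range.  Used to parameterize realistic simulations.
FIELD_DIEL_TABLE = pd.read_csv(StringIO("""\
site,month,mean_c,min_c,time_min_h,max_c,time_max_h,range_c
Papetoai,November,28.21,26.41,6,30.62,14,4.21
Papetoai,December,28.33,27.01,6,30.28,14,3.27
Papetoai,January,28.41,27.33,6,30.10,13,2.77
Papetoai,February,28.91,27.71,6,30.96,14,3.25
Maharepa,November,27.91,26.85,6,29.12,15,2.27
Maharepa,December,28.25,27.40,6,29.34,15,1.94
Maharepa,January,28.49,27.57,6,29.65,15,2.08
Maharepa,February,29.02,28.04,6,30.18,15,2.14
Vaiare,November,28.27,26.69,6,29.99,14,3.30
Vaiare,December,28.88,27.31,6,30.73,14,3.43
Vaiare,January,28.83,27.34,6,30.58,14,3.24
Vaiare,February,29.25,27.85,6,31.00,15,3.15
Haapiti,November,28.39,26.22,6,30.44,14,4.23
Haapiti,December,28.74,26.59,6,30.92,14,4.33
Haapiti,January,28.72,26.80,6,30.69,14,3.89
Haapiti,February,29.10,27.41,6,30.86,15,3.45
"""))

MONTH_NUMBERS = {"November": 11, "December": 12, "January": 1, "February": 2}


@dataclass
class DielCycle:
    """A smoothed 24-h temperature cycle for one site x month."""

    hours: np.ndarray
    temp_c: np.ndarray
    span: float
    degree: int
    site: str | None = None
    month: str | None = None
    cv_table: pd.DataFrame | None = field(default=None, repr=False)

    def at(self, hour):
        """Smoothed temperature at arbitrary hours-of-day (interpolated)."""
        h = np.asarray(hour, dtype=float) % 24.0
        return np.interp(h, self.hours, self.temp_c, period=24.0)


@dataclass
class CycleParams:
    mean_c: float
    min_c: float
    max_c: float
    time_min_h: float | None
    time_max_h: float | None
    range_c: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# aggregation

def hourly_aggregate(
    logs: pd.DataFrame, site: str | None = None, months=None
) -> pd.DataFrame:
    """Average across loggers per timestamp; pool all years by hour-of-day.

    ``logs`` needs columns ``site``, ``logger_id``, ``timestamp`` (on the
    hour) and ``temp_c``.  ``months`` filters on calendar month numbers or
    names.  Returns a frame with ``timestamp``, ``hour`` and ``temp_c``.
    """
    df = logs.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if site is not None:
        df = df[df["site"] == site]
    if months is not None:
        nums = {MONTH_NUMBERS.get(m, m) for m in np.atleast_1d(months)}
        df = df[df["timestamp"].dt.month.isin(nums)]
    if df.empty:
        raise ValueError("no records for the requested site/month selection")
    out = (
        df.groupby("timestamp", as_index=False)["temp_c"]
        .mean()
        .sort_values("timestamp", ignore_index=True)
    )
    ts = out["timestamp"].dt
    out["hour"] = ts.hour + ts.minute / 60.0
    return out[["timestamp", "hour", "temp_c"]]


# ---------------------------------------------------------------------------
# LOESS

def _tricube(u):
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w**3

def loess_smooth(x, y, x_eval, span: float, degree: int) -> np.ndarray:
    """Tricube-weighted local polynomial regression (vectorized over x_eval).

    The bandwidth at each evaluation point is the distance to its
    ``ceil(span * n)``-th nearest training point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xq = np.atleast_1d(np.asarray(x_eval, dtype=float))
    n = x.size
    k = int(np.ceil(span * n))
    if k < degree + 2:
        raise ValueError("span too small for the requested polynomial degree")
    d = np.abs(xq[:, None] - x[None, :])  # (m, n)
    h = np.partition(d, k - 1, axis=1)[:, k - 1]
    h = np.where(h <= 0, np.finfo(float).eps, h)
    w = _tricube(d / h[:, None])
    xc = x[None, :] - xq[:, None]
    powers = np.stack([xc**j for j in range(degree + 1)], axis=-1)  # (m, n, p)
    wp = w[:, :, None] * powers
    ata = np.einsum("mnp,mnq->mpq", wp, powers)
    atb = np.einsum("mnp,n->mp", wp, y)
    # ridge-free solve with a fallback to the weighted mean where singular
    out = np.empty(xq.size)
    try:
        beta = np.linalg.solve(ata, atb[..., None])[..., 0]
        out[:] = beta[:, 0]
        bad = ~np.isfinite(out)
    except np.linalg.LinAlgError:
        bad = np.ones(xq.size, dtype=bool)
        for i in range(xq.size):
            try:
                out[i] = np.linalg.solve(ata[i], atb[i])[0]
                bad[i] = not np.isfinite(out[i])
            except np.linalg.LinAlgError:
                bad[i] = True
    if bad.any():
        wsum = w.sum(axis=1)
        out[bad] = (w[bad] * y).sum(axis=1) / np.where(wsum[bad] > 0, wsum[bad], 1.0)
    return out


def _replicate_circular(hours, temps, pad: float = 6.0):
    """Copy records near the day boundaries to ±``pad`` h outside [0, 24)."""
    h = np.asarray(hours, dtype=float)
    t = np.asarray(temps, dtype=float)
    left = h >= 24.0 - pad
    right = h < pad
    return (
        np.concatenate([h, h[left] - 24.0, h[right] + 24.0]),
        np.concatenate([t, t[left], t[right]]),
    )


DEFAULT_SPAN_GRID = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
DEFAULT_DEGREE_GRID = (1, 2)


class LoessSmoother(RegressorMixin, BaseEstimator):
    """LOESS estimator over hour-of-day with cross-validated smoothing.

    When ``span``/``degree`` are None, every (span, degree) candidate is
    scored by k-fold cross-validated squared prediction error and the best
    pair is kept.  ``circular=True`` replicates boundary data ±6 h so the
    smooth joins up across midnight.
    """

    def __init__(
        self,
        span=None,
        degree=None,
        span_grid=DEFAULT_SPAN_GRID,
        degree_grid=DEFAULT_DEGREE_GRID,
        n_folds=5,
        circular=True,
        random_state=0,
    ):
        self.span = span
        self.degree = degree
        self.span_grid = span_grid
        self.degree_grid = degree_grid
        self.n_folds = n_folds
        self.circular = circular
        self.random_state = random_state

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("X and y lengths differ")
        if self.span is not None and self.degree is not None:
            self.span_, self.degree_ = float(self.span), int(self.degree)
            self.cv_table_ = None
        else:
            self.span_, self.degree_, self.cv_table_ = self._cross_validate(x, y)
        self.x_train_, self.y_train_ = (
            _replicate_circular(x, y) if self.circular else (x, y)
        )
        return self

    def _cross_validate(self, x, y):
        spans = [self.span] if self.span is not None else list(self.span_grid)
        degrees = [self.degree] if self.degree is not None else list(self.degree_grid)
        kf = KFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.random_state
        )
        rows = []
        for span in spans:
            for degree in degrees:
                errs = []
                ok = True
                for train, test in kf.split(x):
                    xt, yt = x[train], y[train]
                    if self.circular:
                        xt, yt = _replicate_circular(xt, yt)
                    try:
                        pred = loess_smooth(xt, yt, x[test], span, degree)
                    except ValueError:
                        ok = False
                        break
                    errs.append(np.mean((pred - y[test]) ** 2))
                if ok:
                    rows.append({"span": span, "degree": degree, "cv_mse": np.mean(errs)})
        if not rows:
            raise ValueError("no (span, degree) candidate admitted a local fit")
        table = pd.DataFrame(rows)
        best = table.loc[table["cv_mse"].idxmin()]
        return float(best["span"]), int(best["degree"]), table

    def predict(self, X):
        check_is_fitted(self, "x_train_")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return loess_smooth(self.x_train_, self.y_train_, x, self.span_, self.degree_)


def fit_diel_loess(
    records: pd.DataFrame,
    span_grid=DEFAULT_SPAN_GRID,
    degree_grid=DEFAULT_DEGREE_GRID,
    n_folds: int = 5,
    seed: int = 0,
    grid_step: float = 0.1,
    site: str | None = None,
    month: str | None = None,
) -> DielCycle:
    """Fit the cross-validated LOESS diel cycle to pooled hourly records."""
    hours = np.asarray(records["hour"], dtype=float)
    temps = np.asarray(records["temp_c"], dtype=float)
    if np.unique(np.floor(hours)).size < 24:
        raise ValueError("need records covering all 24 hours of the day")
    sm = LoessSmoother(
        span_grid=span_grid,
        degree_grid=degree_grid,
        n_folds=n_folds,
        random_state=seed,
    ).fit(hours, temps)
    grid = np.arange(0.0, 24.0, grid_step)
    return DielCycle(
        hours=grid,
        temp_c=sm.predict(grid),
        span=sm.span_,
        degree=sm.degree_,
        site=site,
        month=month,
        cv_table=sm.cv_table_,
    )


# ---------------------------------------------------------------------------
# derived quantities

def derive_cycle_params(cycle: DielCycle, time_resolution_h: float = 1.0) -> CycleParams:
    """Mean, extrema, their (hour-rounded) times and range of a fitted cycle."""
    t = cycle.temp_c
    mean_c = float(t.mean())
    i_min, i_max = int(np.argmin(t)), int(np.argmax(t))
    rng = float(t[i_max] - t[i_min])
    if rng < 1e-9:
        warnings.warn("flat cycle: extremum times undefined", stacklevel=2)
        return CycleParams(mean_c, float(t[i_min]), float(t[i_max]), None, None, rng, True)
    round_to = time_resolution_h

    def _round_time(h):
        return (round(h / round_to) * round_to) % 24.0

    return CycleParams(
        mean_c=mean_c,
        min_c=float(t[i_min]),
        max_c=float(t[i_max]),
        time_min_h=_round_time(float(cycle.hours[i_min])),
        time_max_h=_round_time(float(cycle.hours[i_max])),
        range_c=rng,
    )


def volatility_index(records: pd.DataFrame, cycle: DielCycle) -> pd.DataFrame:
    """Signed hour-wise dispersion of raw records around the smoothed cycle.

    For each hour of day the index is the SD of the raw-minus-smoothed
    residuals, signed by the mean residual (positive = hotter than the cycle,
    i.e. warming pressure; negative = cooling).  When the mean residual is
    indistinguishable from zero the sign is unstable and the hour is flagged
    low-confidence.
    """
    hours = np.asarray(records["hour"], dtype=float)
    temps = np.asarray(records["temp_c"], dtype=float)
    resid = temps - cycle.at(hours)
    df = pd.DataFrame({"hour": np.floor(hours).astype(int) % 24, "resid": resid})
    rows = []
    for hour, grp in df.groupby("hour", sort=True):
        r = grp["resid"].to_numpy()
        sd = float(r.std(ddof=1)) if r.size > 1 else 0.0
        mean = float(r.mean())
        sign = 1.0 if mean >= 0 else -1.0
        low_conf = r.size < 2 or abs(mean) < 2.0 * sd / np.sqrt(r.size)
        rows.append(
            {
                "hour": int(hour),
                "volatility_c": sign * sd,
                "mean_residual_c": mean,
                "n": int(r.size),
                "low_confidence": bool(low_conf),
            }
        )
    return pd.DataFrame(rows)


def time_in_breadth(cycle: DielCycle, lower: float, upper: float) -> tuple[float, float]:
    """Hours per day (and fraction) the smoothed cycle spends in [lower, upper]."""
    if lower >= upper:
        raise ValueError("lower must be below upper")
    inside = (cycle.temp_c >= lower) & (cycle.temp_c <= upper)
    frac = float(inside.mean())
    return 24.0 * frac, frac
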