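"""Thermal-performance-curve fitting for absolute aerobic scope (AAS).

Two candidate curve families describe AAS as a function of test temperature:

* Gaussian: ``f(T) = a * exp(-0.5 * ((T - t_opt) / sigma)**2)``
* Quadratic: ``f(T) = c0 + c1*T + c2*T**2``

Each family is fitted by nonlinear least squares from 64 random starting
vectors (NLLS surfaces are multimodal; the multistart makes the global
optimum reproducible per seed) and the families are compared by AICc.
Derived quantities — peak AAS, optimum temperature, and the 80 %-of-peak
performance breadth with its lower/upper crossing temperatures — get
uncertainty from a residual bootstrap with bias-corrected and accelerated
(BCa) 95 % intervals.  Pairwise Holm–Šidák contrasts compare mean AAS between
temperature groups.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


# ---------------------------------------------------------------------------
# curve families

def gaussian_curve(t, a, t_opt, sigma):
    """Gaussian thermal-performance curve."""
    t = np.asarray(t, dtype=float)
    return a * np.exp(-0.5 * ((t - t_opt) / sigma) ** 2)


def quadratic_curve(t, c0, c1, c2):
    """Quadratic thermal-performance curve."""
    t = np.asarray(t, dtype=float)
    return c0 + c1 * t + c2 * t**2


def sigma_from_breadth(breadth: float, fraction: float = 0.8) -> float:
    """Gaussian width implied by a performance breadth at ``fraction`` of peak.

    The curve equals ``fraction * a`` at ``t_opt ± sigma*sqrt(2*ln(1/fraction))``,
    so ``sigma = breadth / (2*sqrt(2*ln(1/fraction)))``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    return breadth / (2.0 * math.sqrt(2.0 * math.log(1.0 / fraction)))


def breadth_from_sigma(sigma: float, fraction: float = 0.8) -> float:
    """Inverse of :func:`sigma_from_breadth`."""
    return sigma * 2.0 * math.sqrt(2.0 * math.log(1.0 / fraction))


_PARAM_NAMES = {"gaussian": ("a", "t_opt", "sigma"), "quadratic": ("c0", "c1", "c2")}
_CURVES = {"gaussian": gaussian_curve, "quadratic": quadratic_curve}


# ---------------------------------------------------------------------------
# containers

@dataclass
class TPCModel:
    """A fitted thermal-performance model."""

    shape: str
    params: dict[str, float]
    n_obs: int
    rss: float
    aicc: float
    n_converged: int = 0

    def predict(self, t):
        return _CURVES[self.shape](t, *(self.params[p] for p in _PARAM_NAMES[self.shape]))


@dataclass
class TPCDerived:
    """Point estimates of the biologically interpretable curve parameters."""

    aas_max: float
    t_peak: float
    breadth: float
    lower: float
    upper: float
    fraction: float = 0.8


@dataclass
class BootstrapResult:
    """Residual-bootstrap draws of fit and derived parameters."""

    n_boot: int
    n_converged: int
    draws: pd.DataFrame = field(repr=False)
    seed: int | None = None


# ---------------------------------------------------------------------------
# fitting

def aicc(n: int, rss: float, n_params: int) -> float:
    """Small-sample-corrected AIC on the least-squares likelihood.

    ``k = n_params + 1`` counts the residual variance alongside the curve
    parameters; ``AICc = n*ln(RSS/n) + 2k + 2k(k+1)/(n-k-1)``.
    """
    k = n_params + 1
    if n <= k + 1:
        raise ValueError("AICc undefined: need n > k + 1")
    if rss <= 0:
        rss = np.finfo(float).tiny
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _start_bounds(shape: str, t: np.ndarray, y: np.ndarray):
    """Data-informed ranges from which multistart vectors are drawn."""
    ymax = float(np.max(y)) if np.max(y) > 0 else 1.0
    if shape == "gaussian":
        return np.array(
            [[0.5 * ymax, 1.5 * ymax], [t.min() - 2.0, t.max() + 2.0], [0.1, 10.0]]
        )
    c = np.polyfit(t, y, 2)[::-1]  # c0, c1, c2
    lo = np.minimum(0.5 * c, 1.5 * c) - 1e-3
    hi = np.maximum(0.5 * c, 1.5 * c) + 1e-3
    return np.column_stack([lo, hi])


def _fit_bounds(shape: str, t: np.ndarray, y: np.ndarray):
    ymax = float(np.max(y)) if np.max(y) > 0 else 1.0
    if shape == "gaussian":
        return (
            np.array([1e-8, t.min() - 5.0, 1e-2]),
            np.array([10.0 * ymax, t.max() + 5.0, 50.0]),
        )
    return (np.full(3, -np.inf), np.full(3, np.inf))


def _single_fit(shape, t, y, x0, bounds):
    curve = _CURVES[shape]

    def resid(p):
        return curve(t, *p) - y

    try:
        res = optimize.least_squares(resid, x0, bounds=bounds, method="trf")
    except Exception:  # singular jacobian etc.
        return None
    if not res.success or not np.all(np.isfinite(res.x)):
        return None
    return res.x, float(2.0 * res.cost)


def fit_model(
    data,
    shape: str = "gaussian",
    n_starts: int = 64,
    seed: int | None = None,
) -> TPCModel:
    """Multistart NLLS fit of one curve family.

    ``data`` is either a ``(temperature, aas)`` pair of arrays or a DataFrame
    with ``temperature_c``/``aas`` columns.  Starting vectors are drawn
    uniformly from data-informed bounds; the converged fit with the lowest
    RSS wins.  Deterministic for a given ``seed``.
    """
    t, y = _as_arrays(data)
    if shape not in _CURVES:
        raise ValueError(f"unknown shape {shape!r}")
    if t.size < 4 or np.unique(t).size < 2:
        raise ValueError("need >= 4 points spanning >= 2 distinct temperatures")
    if np.unique(t).size <= 3:
        warnings.warn(
            "optimum informed by only three (or fewer) measured temperatures; "
            "interpret the fitted curve with caution",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    sb = _start_bounds(shape, t, y)
    starts = rng.uniform(sb[:, 0], sb[:, 1], size=(n_starts, 3))
    bounds = _fit_bounds(shape, t, y)
    best = None
    n_conv = 0
    for x0 in starts:
        out = _single_fit(shape, t, y, np.clip(x0, bounds[0], bounds[1]), bounds)
        if out is None:
            continue
        n_conv += 1
        if best is None or out[1] < best[1]:
            best = out
    if best is None:
        raise RuntimeError(f"no start converged; start bounds tried: {sb.tolist()}")
    params = dict(zip(_PARAM_NAMES[shape], map(float, best[0])))
    return TPCModel(
        shape=shape,
        params=params,
        n_obs=int(t.size),
        rss=best[1],
        aicc=aicc(t.size, best[1], 3),
        n_converged=n_conv,
    )


def _as_arrays(data):
    if isinstance(data, pd.DataFrame):
        return (
            np.asarray(data["temperature_c"], dtype=float),
            np.asarray(data["aas"], dtype=float),
        )
    t, y = data
    return np.asarray(t, dtype=float), np.asarray(y, dtype=float)


class ThermalPerformanceCurve(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator wrapping the multistart TPC fit.

    Parameters
    ----------
    shape : {"gaussian", "quadratic"}
        Curve family.
    n_starts : int
        Number of random NLLS starting vectors.
    fraction : float
        Fraction of the peak defining the performance breadth.
    random_state : int or None
        Seed for the multistart draw.

    Attributes
    ----------
    params_ : dict
        Fitted curve parameters.
    rss_, aicc_, n_obs_ : float / int
        Fit diagnostics.
    model_ : TPCModel
        The underlying fitted-model record.
    """

    def __init__(self, shape="gaussian", n_starts=64, fraction=0.8, random_state=None):
        self.shape = shape
        self.n_starts = n_starts
        self.fraction = fraction
        self.random_state = random_state

    def fit(self, X, y):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            if t.shape[1] != 1:
                raise ValueError("X must be a single temperature column")
            t = t[:, 0]
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape:
            raise ValueError("X and y lengths differ")
        self.model_ = fit_model(
            (t, y), shape=self.shape, n_starts=self.n_starts, seed=self.random_state
        )
        self.params_ = self.model_.params
        self.rss_ = self.model_.rss
        self.aicc_ = self.model_.aicc
        self.n_obs_ = self.model_.n_obs
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            t = t[:, 0]
        return self.model_.predict(t)

    def derived(self, method: str = "closed_form") -> TPCDerived:
        check_is_fitted(self, "model_")
        return derive_params(self.model_, fraction=self.fraction, method=method)


def aicc_select(models: list[TPCModel]) -> tuple[TPCModel, pd.DataFrame]:
    """Pick the lowest-AICc model; ties go to the first listed.

    All candidates must be fits to the same data (checked via ``n_obs``).
    Returns the winner and a delta table.
    """
    if not models:
        raise ValueError("no models to compare")
    if len({m.n_obs for m in models}) != 1:
        raise ValueError("models were fitted to different data (n_obs differ)")
    scores = np.array([m.aicc for m in models])
    best_i = int(np.argmin(scores))  # argmin returns the first minimum
    table = pd.DataFrame(
        {
            "shape": [m.shape for m in models],
            "rss": [m.rss for m in models],
            "aicc": scores,
            "delta_aicc": scores - scores[best_i],
        }
    )
    return models[best_i], table


# ---------------------------------------------------------------------------
# derived parameters

def derive_params(
    model: TPCModel, fraction: float = 0.8, method: str = "closed_form"
) -> TPCDerived:
    """Peak AAS, optimum temperature and performance breadth of a fitted curve.

    ``method="closed_form"`` uses the analytic crossing temperatures;
    ``method="root"`` locates them with a bracketed numeric root-finder (the
    two agree to < 1e-8 °C and serve as mutual checks).
    """
    p = model.params
    if model.shape == "gaussian":
        t_peak = p["t_opt"]
        aas_max = p["a"]
        if method == "closed_form":
            half = p["sigma"] * math.sqrt(2.0 * math.log(1.0 / fraction))
            lower, upper = t_peak - half, t_peak + half
        else:
            lower, upper = _crossings_by_root(model, t_peak, aas_max, fraction)
    elif model.shape == "quadratic":
        if p["c2"] >= 0:
            raise ValueError("quadratic has no interior maximum (c2 >= 0)")
        t_peak = -p["c1"] / (2.0 * p["c2"])
        aas_max = float(model.predict(t_peak))
        if method == "closed_form":
            # solve c2 T^2 + c1 T + (c0 - fraction*aas_max) = 0
            disc = p["c1"] ** 2 - 4.0 * p["c2"] * (p["c0"] - fraction * aas_max)
            r = math.sqrt(disc)
            lower = (-p["c1"] + r) / (2.0 * p["c2"])
            upper = (-p["c1"] - r) / (2.0 * p["c2"])
        else:
            lower, upper = _crossings_by_root(model, t_peak, aas_max, fraction)
    else:  # pragma: no cover - guarded at fit time
        raise ValueError(f"unknown shape {model.shape!r}")
    return TPCDerived(
        aas_max=float(aas_max),
        t_peak=float(t_peak),
        breadth=float(upper - lower),
        lower=float(lower),
        upper=float(upper),
        fraction=fraction,
    )


def _crossings_by_root(model, t_peak, aas_max, fraction):
    target = fraction * aas_max

    def f(t):
        return model.predict(t) - target

    if model.shape == "gaussian":
        span = 10.0 * model.params["sigma"]
    else:
        span = 10.0 * abs(t_peak - (-model.params["c1"] / model.params["c2"] - t_peak) + 1)
        span = max(span, 50.0)
    lower = optimize.brentq(f, t_peak - span, t_peak, xtol=1e-12)
    upper = optimize.brentq(f, t_peak, t_peak + span, xtol=1e-12)
    return lower, upper


# ---------------------------------------------------------------------------
# residual bootstrap with BCa intervals

_DERIVED_NAMES = ("aas_max", "t_peak", "breadth", "lower", "upper")


def _refit_from(model, t, y):
    bounds = _fit_bounds(model.shape, t, y)
    x0 = np.clip(
        [model.params[p] for p in _PARAM_NAMES[model.shape]], bounds[0], bounds[1]
    )
    return _single_fit(model.shape, t, y, x0, bounds)


def _quantities(model: TPCModel, fraction: float) -> dict[str, float]:
    d = derive_params(model, fraction=fraction)
    out = dict(model.params)
    out.update({n: getattr(d, n) for n in _DERIVED_NAMES})
    return out


def bootstrap_bca(
    model: TPCModel,
    data,
    n_boot: int = 999,
    seed: int | None = None,
    fraction: float = 0.8,
    alpha: float = 0.05,
    max_fail: float = 0.2,
) -> tuple[BootstrapResult, pd.DataFrame]:
    """Residual bootstrap with BCa intervals for fit and derived parameters.

    Replicate datasets are ``y* = yhat + resampled residuals`` (with
    replacement); each is refitted starting from the point estimate.  The BCa
    interval corrects the percentile interval with a bias term ``z0`` (normal
    quantile of the proportion of draws below the point estimate) and an
    acceleration term estimated by a delete-one jackknife over observations.

    Raises if more than ``max_fail`` of the replicates fail to converge.
    """
    t, y = _as_arrays(data)
    yhat = model.predict(t)
    residuals = y - yhat
    rng = np.random.default_rng(seed)

    rows = []
    n_fail = 0
    for _ in range(n_boot):
        y_star = yhat + rng.choice(residuals, size=residuals.size, replace=True)
        out = _refit_from(model, t, y_star)
        if out is None:
            n_fail += 1
            continue
        rep = TPCModel(model.shape, dict(zip(_PARAM_NAMES[model.shape], out[0])),
                       model.n_obs, out[1], np.nan)
        try:
            rows.append(_quantities(rep, fraction))
        except ValueError:  # e.g. replicate quadratic lost its maximum
            n_fail += 1
    if n_fail > max_fail * n_boot:
        raise RuntimeError(
            f"{n_fail}/{n_boot} bootstrap replicates failed to converge"
        )
    draws = pd.DataFrame(rows)
    point = _quantities(model, fraction)

    # jackknife for the acceleration term
    jack_rows = []
    for i in range(t.size):
        mask = np.ones(t.size, dtype=bool)
        mask[i] = False
        out = _refit_from(model, t[mask], y[mask])
        if out is None:
            continue
        rep = TPCModel(model.shape, dict(zip(_PARAM_NAMES[model.shape], out[0])),
                       t.size - 1, out[1], np.nan)
        try:
            jack_rows.append(_quantities(rep, fraction))
        except ValueError:
            continue
    jack = pd.DataFrame(jack_rows)

    records = []
    for name, theta in point.items():
        lo, hi = _bca_interval(draws[name].to_numpy(), theta, jack.get(name), alpha)
        records.append({"quantity": name, "estimate": theta, "bca_low": lo, "bca_high": hi})
    intervals = pd.DataFrame(records).set_index("quantity")
    result = BootstrapResult(
        n_boot=n_boot, n_converged=len(draws), draws=draws, seed=seed
    )
    return result, intervals


def _bca_interval(draws, theta_hat, jack_values, alpha):
    draws = draws[np.isfinite(draws)]
    if draws.size == 0:
        return np.nan, np.nan
    if np.allclose(draws, draws[0]) and np.isclose(draws[0], theta_hat):
        return float(theta_hat), float(theta_hat)  # zero-residual degenerate case
    prop = np.mean(draws < theta_hat)
    prop = min(max(prop, 1.0 / (draws.size + 1)), draws.size / (draws.size + 1.0))
    z0 = special.ndtri(prop)
    if jack_values is not None and len(jack_values) >= 3:
        jv = np.asarray(jack_values, dtype=float)
        jv = jv[np.isfinite(jv)]
        d = jv.mean() - jv
        denom = 6.0 * (d**2).sum() ** 1.5
        a = (d**3).sum() / denom if denom > 0 else 0.0
    else:
        a = 0.0
    out = []
    for q in (alpha / 2.0, 1.0 - alpha / 2.0):
        z = special.ndtri(q)
        adj = special.ndtr(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
        out.append(float(np.quantile(draws, adj)))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# pairwise contrasts

def holm_sidak_pairwise(
    groups: dict, alpha: float = 0.05, equal_var: bool = False
) -> tuple[pd.DataFrame, dict]:
    """All pairwise Welch t contrasts with Holm–Šidák step-down adjustment.

    Raw p-values are sorted ascending; the i-th smallest (1-indexed, m total)
    is adjusted to ``1 - (1 - p)**(m - i + 1)`` with running-maximum
    monotonicity.  Returns the contrast table and a compact-letter display:
    groups sharing a letter do not differ at ``alpha``.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    pairs, raw = [], []
    for a, b in itertools.combinations(labels, 2):
        xa, xb = arrays[a], arrays[b]
        if np.var(xa) == 0 and np.var(xb) == 0:
            raise ValueError(f"zero variance in both groups {a!r} and {b!r}")
        res = stats.ttest_ind(xa, xb, equal_var=equal_var)
        pairs.append((a, b))
        raw.append(float(res.pvalue))
    raw = np.array(raw)
    m = raw.size
    order = np.argsort(raw, kind="stable")
    adj_sorted = 1.0 - (1.0 - raw[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    table = pd.DataFrame(
        {
            "group_a": [p[0] for p in pairs],
            "group_b": [p[1] for p in pairs],
            "p_raw": raw,
            "p_adjusted": adjusted,
            "significant": adjusted < alpha,
        }
    )
    letters = _compact_letters(labels, pairs, adjusted < alpha, arrays)
    return table, letters


def _compact_letters(labels, pairs, significant, arrays):
    """Letters from maximal cliques of the not-significantly-different graph."""
    adj = {l: set() for l in labels}
    for (a, b), sig in zip(pairs, significant):
        if not sig:
            adj[a].add(b)
            adj[b].add(a)

    cliques: list[set] = []

    def bron_kerbosch(r, p, x):
        if not p and not x:
            cliques.append(set(r))
            return
        for v in list(p):
            bron_kerbosch(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    bron_kerbosch(set(), set(labels), set())
    # order cliques by the mean of their lowest-mean member for stable letters
    means = {l: arrays[l].mean() for l in labels}
    cliques.sort(key=lambda c: min(means[l] for l in c))
    letters = {l: "" for l in labels}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for l in sorted(clique, key=lambda q: means[q]):
            letters[l] += ch
    return letters
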