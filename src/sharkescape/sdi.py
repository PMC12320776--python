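"""Submergence depth index: surface-proximity drag and the depth advantage.

A fish swimming near the surface sheds propulsive energy into surface waves.
The submergence depth index SDI = z / B (habitat water depth over caudal-fin
height, both in metres) captures this: below SDI = 3 the thrust loss is
significant.  Evaluating SDI over a grid of habitat depths for measured
newborn and adult fin heights, fitting per-life-stage linear regressions and
intersecting them with SDI = 3 yields the critical depth for each stage —
and between the two critical depths lies the band where newborns retain full
fast-start thrust while adult (predator-sized) conspecifics do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SDI_THRESHOLD = 3.0
LIFE_STAGES = ("newborn", "adult")


@dataclass(frozen=True)
class FinMeasure:
    individual_id: str
    life_stage: str
    fin_height_b: float  # metres

    def __post_init__(self) -> None:
        if self.fin_height_b <= 0:
            raise ValueError("fin_height_b must be positive")
        if self.life_stage not in LIFE_STAGES:
            raise ValueError(f"life_stage must be one of {LIFE_STAGES}")


@dataclass
class StageFit:
    life_stage: str
    slope: float            # SDI per metre of depth
    intercept: float
    n_individuals: int
    residual_ss: float


@dataclass
class SDIModel:
    stage_fits: dict[str, StageFit]
    ancova_f: float | None
    ancova_p: float | None
    critical_depths: dict[str, float]
    advantage_band: tuple[float, float] | None
    threshold: float = SDI_THRESHOLD
    table: pd.DataFrame | None = field(default=None, repr=False)


def sdi_value(depth_z: float, fin_height_b: float) -> float:
    """SDI = z / B. Dimensionless; invariant to common rescaling of z and B."""
    if depth_z <= 0 or fin_height_b <= 0:
        raise ValueError("depth and fin height must be positive")
    return depth_z / fin_height_b


def default_depth_grid(start: float = 0.1, stop: float = 1.5, step: float = 0.01):
    """Habitat-depth grid (m) over the range used by newborns: 0.1-1.5 m."""
    n = int(round((stop - start) / step))
    return np.round(start + step * np.arange(n + 1), 10)


def _fit_stage(depth: np.ndarray, sdi: np.ndarray, fit_intercept: bool):
    if fit_intercept:
        X = np.column_stack([np.ones_like(depth), depth])
    else:
        X = depth[:, None]
    beta, *_ = np.linalg.lstsq(X, sdi, rcond=None)
    resid = sdi - X @ beta
    if fit_intercept:
        return float(beta[1]), float(beta[0]), float(resid @ resid)
    return float(beta[0]), 0.0, float(resid @ resid)


def sdi_regression(
    fins: list[FinMeasure] | pd.DataFrame,
    depth_grid: np.ndarray | None = None,
    fit_intercept: bool = False,
    threshold: float = SDI_THRESHOLD,
) -> SDIModel:
    """Per-stage SDI-vs-depth regressions with an ANCOVA slope contrast.

    Each individual's SDI is evaluated across the depth grid and pooled into
    per-stage OLS fits.  With the intercept constrained to zero (SDI is
    exactly 0 at z = 0) the fitted slope equals the stage mean of 1/B.  The
    difference in slopes between stages is tested by comparing the
    common-slope model against the stage-specific-slope model (partial
    F-test); with a single stage present the contrast is skipped.
    """
    if isinstance(fins, pd.DataFrame):
        fins = [
            FinMeasure(str(r.individual_id), str(r.life_stage), float(r.fin_height_m))
            for r in fins.itertuples()
        ]
    if depth_grid is None:
        depth_grid = default_depth_grid()
    depth_grid = np.asarray(depth_grid, dtype=float)
    if depth_grid.size < 3:
        raise ValueError("depth grid needs >= 3 depths")

    rows = []
    for f in fins:
        for z in depth_grid:
            rows.append(
                {
                    "individual_id": f.individual_id,
                    "life_stage": f.life_stage,
                    "depth_m": z,
                    "sdi": z / f.fin_height_b,
                }
            )
    table = pd.DataFrame(rows)

    stage_fits: dict[str, StageFit] = {}
    for stage, grp in table.groupby("life_stage", sort=True):
        n_ind = grp["individual_id"].nunique()
        if n_ind < 2:
            warnings.warn(f"stage {stage!r} has < 2 individuals", stacklevel=2)
        slope, intercept, rss = _fit_stage(
            grp["depth_m"].to_numpy(), grp["sdi"].to_numpy(), fit_intercept
        )
        stage_fits[stage] = StageFit(stage, slope, intercept, int(n_ind), rss)

    ancova_f = ancova_p = None
    if len(stage_fits) >= 2:
        ancova_f, ancova_p = _slope_contrast(table, fit_intercept)
    elif len(stage_fits) == 1:
        warnings.warn("single life stage present: slope contrast skipped", stacklevel=2)

    critical = {s: critical_depth(f, threshold) for s, f in stage_fits.items()}
    band = None
    if set(critical) >= {"newborn", "adult"} and critical["newborn"] < critical["adult"]:
        band = advantage_band(critical["newborn"], critical["adult"])
    return SDIModel(
        stage_fits=stage_fits,
        ancova_f=ancova_f,
        ancova_p=ancova_p,
        critical_depths=critical,
        advantage_band=band,
        threshold=threshold,
        table=table,
    )


def _slope_contrast(table: pd.DataFrame, fit_intercept: bool):
    """Partial F-test: stage-specific slopes vs one common slope."""
    from scipy import stats as sps

    depth = table["depth_m"].to_numpy()
    sdi = table["sdi"].to_numpy()
    stages = pd.get_dummies(table["life_stage"], dtype=float).to_numpy()
    cols_full = [depth[:, None] * stages]
    cols_red = [depth[:, None]]
    if fit_intercept:
        cols_full.insert(0, stages)
        cols_red.insert(0, stages)
    Xf = np.column_stack(cols_full)
    Xr = np.column_stack(cols_red)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, sdi, rcond=None)
        r = sdi - X @ beta
        return float(r @ r), X.shape[1]

    rss_f, k_f = rss(Xf)
    rss_r, k_r = rss(Xr)
    df_num = k_f - k_r
    df_den = sdi.size - k_f
    if rss_f <= 1e-12 * max(rss_r, 1.0):
        return float("inf"), 0.0
    f = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
    p = float(sps.f.sf(f, df_num, df_den))
    return float(f), p


def critical_depth(fit: StageFit | float, threshold: float = SDI_THRESHOLD) -> float:
    """Depth (m) where the fitted SDI line crosses the drag threshold.

    For a zero-intercept fit this is ``threshold / slope``; with one
    individual of fin height B it reduces to ``threshold * B``.
    """
    if isinstance(fit, StageFit):
        slope, intercept = fit.slope, fit.intercept
    else:
        slope, intercept = float(fit), 0.0
    if slope <= 0:
        raise ValueError("slope must be positive")
    return (threshold - intercept) / slope


def advantage_band(newborn_zcrit: float, adult_zcrit: float) -> tuple[float, float]:
    """Depth band where newborns keep SDI >= 3 while adults fall below it."""
    if newborn_zcrit >= adult_zcrit:
        raise ValueError("no advantage zone: newborn critical depth >= adult's")
    return (float(newborn_zcrit), float(adult_zcrit))
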