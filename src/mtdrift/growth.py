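"""Colony growth-curve phenotyping.

Doubling times are extracted from log-linear sliding-window fits to cell
counts, normalized against interleaved spatial control colonies (every
k-th plate position carries a founder control), and converted back to
hours via the grand mean of the control doubling times.  Generation
counting and adaptation accounting (fraction of the maximum possible
doubling-time reduction) live here too.

Conventions
-----------
* Doubling time ``D`` is hours per population doubling; its base-2 log
  is the working scale for normalization.
* ``log2_D_norm = log2_D - surface(position)`` where the surface
  interpolates control colonies' log2 doubling times across the plate.
* ``log2_D_adj = log2_D_norm(t) - log2_D_norm(0)`` corrects for the
  controls' different pre-cultivation history between growth cycles.
* Hours back-conversion: ``2**log2_D_norm * D_control_grand``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.ndimage import median_filter
from sklearn.base import BaseEstimator, TransformerMixin

NO_GROWTH_HOURS = 24.0  # sentinel: "no growth" = doubling time above 24 h


# ---------------------------------------------------------------------------
# doubling-time extraction
# ---------------------------------------------------------------------------

@dataclass
class DoublingEstimate:
    """Raw and (optionally) normalized doubling-time estimates for one colony."""

    d_raw_h: float
    log2_d: float
    window_start: int
    qc_flag: str = "ok"
    log2_d_norm: float | None = None
    log2_d_adj: float | None = None
    d_hours_norm: float | None = None


def estimate_doubling_time(
    times: np.ndarray,
    counts: np.ndarray,
    window: int = 41,
    smooth_width: int = 5,
    no_growth_h: float = NO_GROWTH_HOURS,
) -> DoublingEstimate:
    """Extract the doubling time D from one growth curve.

    The curve's counts are median-filtered (width ``smooth_width``),
    log2-transformed, and least-squares slopes are fit in every sliding
    window of ``window`` points.  D is the reciprocal of the maximal
    slope (doublings per hour).  Curves whose best slope corresponds to
    a doubling time above ``no_growth_h`` are flagged as no-growth and
    reported at the sentinel value.
    """
    times = np.asarray(times, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if times.ndim != 1 or times.shape != counts.shape:
        raise ValueError("times and counts must be 1-D arrays of equal length")
    if len(times) < 10:
        raise ValueError("growth curve needs at least 10 time points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(counts <= 0):
        raise ValueError("cell counts must be positive")
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 5")
    if window > len(times):
        raise ValueError("window longer than the curve")

    y = np.log2(counts)
    if smooth_width > 1:
        y = median_filter(y, size=smooth_width, mode="nearest")

    tw = sliding_window_view(times, window)
    yw = sliding_window_view(y, window)
    tc = tw - tw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    denom = (tc ** 2).sum(axis=1)
    slopes = (tc * yc).sum(axis=1) / denom

    best = int(np.argmax(slopes))
    s = float(slopes[best])
    if s <= 1.0 / no_growth_h:
        return DoublingEstimate(
            d_raw_h=no_growth_h,
            log2_d=float(np.log2(no_growth_h)),
            window_start=best,
            qc_flag="no_growth",
        )
    d = 1.0 / s
    return DoublingEstimate(d_raw_h=d, log2_d=float(np.log2(d)), window_start=best)


class DoublingTimeEstimator(BaseEstimator):
    """Per-position doubling-time extraction for a whole plate.

    Parameters
    ----------
    window : int
        Sliding-window width in time points for the log-linear fit.
    smooth_width : int
        Median-filter width applied to log2 counts before fitting.
    no_growth_h : float
        Sentinel doubling time (hours) for flat or shrinking colonies.

    Attributes
    ----------
    estimates_ : pandas.DataFrame
        One row per position: row, col, d_raw_h, log2_d, window_start,
        qc_flag.
    """

    def __init__(self, window: int = 41, smooth_width: int = 5,
                 no_growth_h: float = NO_GROWTH_HOURS):
        self.window = window
        self.smooth_width = smooth_width
        self.no_growth_h = no_growth_h

    def fit(self, X: pd.DataFrame, y=None):
        """Fit on a long-format curve table (row, col, time_h, cells)."""
        required = {"row", "col", "time_h", "cells"}
        if not required.issubset(X.columns):
            raise ValueError(f"curve table must have columns {sorted(required)}")
        rows = []
        for (r, c), grp in X.groupby(["row", "col"], sort=True):
            grp = grp.sort_values("time_h")
            est = estimate_doubling_time(
                grp["time_h"].to_numpy(), grp["cells"].to_numpy(),
                window=self.window, smooth_width=self.smooth_width,
                no_growth_h=self.no_growth_h,
            )
            rows.append((r, c, est.d_raw_h, est.log2_d, est.window_start, est.qc_flag))
        self.estimates_ = pd.DataFrame(
            rows, columns=["row", "col", "d_raw_h", "log2_d", "window_start", "qc_flag"]
        )
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).estimates_


# ---------------------------------------------------------------------------
# spatial control normalization
# ---------------------------------------------------------------------------

@dataclass
class ControlSurface:
    """Interpolated control log2 doubling-time surface over the plate grid.

    Piecewise-linear interpolation on the Delaunay triangulation of the
    control positions (exact at controls, reproduces planes inside the
    convex hull) with nearest-neighbour extrapolation at plate edges.
    """

    control_points: np.ndarray
    control_values: np.ndarray
    _linear: LinearNDInterpolator = field(repr=False, default=None)
    _nearest: NearestNDInterpolator = field(repr=False, default=None)

    def __post_init__(self):
        if self._linear is None:
            self._linear = LinearNDInterpolator(self.control_points, self.control_values)
            self._nearest = NearestNDInterpolator(self.control_points, self.control_values)

    def __call__(self, row, col):
        pts = np.column_stack([np.atleast_1d(row), np.atleast_1d(col)]).astype(float)
        vals = self._linear(pts)
        mask = np.isnan(vals)
        if mask.any():
            vals[mask] = self._nearest(pts[mask])
        return vals if np.ndim(row) else float(vals[0])


def build_control_surface(estimates: pd.DataFrame, layout: pd.DataFrame) -> ControlSurface:
    """Build the spatial control surface from per-position log2 doubling times.

    ``estimates`` needs columns row, col, log2_d; ``layout`` needs row,
    col, is_control.  At least 4 control positions are required.
    """
    merged = estimates.drop(columns=["is_control"], errors="ignore").merge(
        layout[["row", "col", "is_control"]], on=["row", "col"], how="left")
    if merged["is_control"].isna().any():
        raise ValueError("layout does not cover all estimated positions")
    ctrl = merged[merged["is_control"].astype(bool)]
    if "qc_flag" in ctrl.columns:
        ctrl = ctrl[ctrl["qc_flag"] == "ok"]
    if len(ctrl) < 4:
        raise ValueError("need at least 4 control positions to interpolate")
    pts = ctrl[["row", "col"]].to_numpy(dtype=float)
    return ControlSurface(pts, ctrl["log2_d"].to_numpy(dtype=float))


def normalize_doubling(log2_d: float, surface: ControlSurface, row, col) -> float:
    """log2(D)_norm: subtract the interpolated local control log2 doubling time."""
    return log2_d - surface(row, col)


def adjust(log2_d_norm_t: float, log2_d_norm_0: float) -> float:
    """log2(D)_adj: cycle-t normalized value relative to cycle 0."""
    return log2_d_norm_t - log2_d_norm_0


def to_hours(log2_d_norm, d_control_grand: float):
    """Back-convert a normalized log2 doubling time to hours."""
    return 2.0 ** np.asarray(log2_d_norm) * d_control_grand


class PlateNormalizer(BaseEstimator, TransformerMixin):
    """Spatial normalization of doubling times against interleaved controls.

    ``fit`` builds the control surface and the grand mean of raw control
    doubling times; ``transform`` adds ``log2_d_norm`` and
    ``d_hours_norm`` columns to an estimates table.

    Attributes
    ----------
    surface_ : ControlSurface
    d_control_grand_ : float
        Grand mean of the raw doubling times (hours) of all QC-passing
        controls.
    """

    def fit(self, X: pd.DataFrame, y=None, *, layout: pd.DataFrame):
        self.surface_ = build_control_surface(X, layout)
        merged = X.drop(columns=["is_control"], errors="ignore").merge(
            layout[["row", "col", "is_control"]], on=["row", "col"])
        ctrl = merged[merged["is_control"].astype(bool)]
        if "qc_flag" in ctrl.columns:
            ctrl = ctrl[ctrl["qc_flag"] == "ok"]
        self.d_control_grand_ = float(ctrl["d_raw_h"].mean())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        out["log2_d_norm"] = out["log2_d"].to_numpy() - self.surface_(
            out["row"].to_numpy(), out["col"].to_numpy()
        )
        out["d_hours_norm"] = to_hours(out["log2_d_norm"].to_numpy(), self.d_control_grand_)
        return out


# ---------------------------------------------------------------------------
# generation counting
# ---------------------------------------------------------------------------

@dataclass
class GenerationLedger:
    """Per-cycle generation counts with interpolation bookkeeping."""

    per_cycle: np.ndarray
    interpolated: np.ndarray
    cumulative: np.ndarray

    @property
    def total(self) -> float:
        return float(self.cumulative[-1])


def count_generations(n_initial, n_final) -> GenerationLedger:
    """Count generations per growth cycle as log2 of the fold expansion.

    ``n_initial`` and ``n_final`` are per-cycle cell counts; cycles with
    NaN in either are treated as missing and filled with the mean of the
    nearest observed cycle on each side.  Missing cycles at either end
    cannot be anchored and are refused.
    """
    n_initial = np.asarray(n_initial, dtype=float)
    n_final = np.asarray(n_final, dtype=float)
    if n_initial.shape != n_final.shape or n_initial.ndim != 1 or len(n_initial) == 0:
        raise ValueError("need equal-length, non-empty 1-D count arrays")
    missing = np.isnan(n_initial) | np.isnan(n_final)
    with np.errstate(invalid="ignore"):
        if np.any((~missing) & ((n_initial <= 0) | (n_final <= 0))):
            raise ValueError("cell counts must be positive")
    per_cycle = np.where(missing, np.nan, np.log2(n_final / n_initial))
    if missing[0] or missing[-1]:
        raise ValueError("missing cycle at a series end has no interpolation anchor")
    if missing.any():
        idx = np.where(missing)[0]
        obs = np.where(~missing)[0]
        for i in idx:
            left = obs[obs < i][-1]
            right = obs[obs > i][0]
            per_cycle[i] = 0.5 * (per_cycle[left] + per_cycle[right])
    return GenerationLedger(
        per_cycle=per_cycle,
        interpolated=missing,
        cumulative=np.cumsum(per_cycle),
    )


# ---------------------------------------------------------------------------
# adaptation accounting
# ---------------------------------------------------------------------------

@dataclass
class AdaptationAccount:
    d_floor_h: float
    d_init_stress_h: float
    reduction_h: float
    percent_of_max: float


def percent_max_adaptation(d_t, d_init_stress, d_floor):
    """Percent of the maximum possible doubling-time reduction realized.

    The maximum reduction spans from the initial stressed doubling time
    down to the founder's unstressed doubling time, taken as the
    physiological floor.  Values outside [0, 100] are clipped with a
    warning (measurement noise can put D_t slightly outside the span).
    """
    d_t = np.asarray(d_t, dtype=float)
    if not d_init_stress > d_floor:
        raise ValueError("initial stressed doubling time must exceed the floor")
    pct = 100.0 * (d_init_stress - d_t) / (d_init_stress - d_floor)
    if np.any(pct < -1e-6) or np.any(pct > 100 + 1e-6):
        warnings.warn("percent of maximum adaptation outside [0, 100]; clipping")
    pct = np.clip(pct, 0.0, 100.0)
    return float(pct) if pct.ndim == 0 else pct


def additive_combination(reductions_h) -> float:
    """Combine doubling-time reductions under the additive-effect assumption."""
    reductions = list(reductions_h)
    if not reductions:
        raise ValueError("need at least one reduction to combine")
    return float(np.sum(reductions))


def adjust_curve_for_display(counts, median_n0: float) -> np.ndarray:
    """Rescale a growth curve so it starts at ``median_n0`` on the log2 scale.

    N_adj(t) = 2**(log2(N_t) * log2(median_n0) / log2(N_0)).  A monotone
    transform of the log-scale curve that forces N_adj(0) = median_n0,
    removing initial-population-size offsets from display figures.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or len(counts) == 0:
        raise ValueError("counts must be a non-empty 1-D array")
    if counts[0] <= 1 or median_n0 <= 1:
        raise ValueError("initial count and median_n0 must exceed 1")
    if np.any(counts <= 0):
        raise ValueError("counts must be positive")
    scale = np.log2(median_n0) / np.log2(counts[0])
    return 2.0 ** (np.log2(counts) * scale)
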