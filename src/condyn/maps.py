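"""Condensate detection on single-molecule localization density maps.

High-density single-molecule localizations (nm coordinates) are
accumulated over time windows and clustered with DBSCAN to call
condensates; the working defaults are an interparticle distance
threshold of 48 nm and a minimum of 5 points per condensate.  Each
cluster's radius is the circle-equivalent radius of its convex-hull
area, ``R = sqrt(A / pi)``.  Repeating the detection on maps cumulated
at successive time points yields the condensate growth curve, fitted by
a power law ``<R> ~ t^beta`` at early times and by a plateau later on.
Condensate radii at a fixed time point typically follow a log-normal
distribution, the hallmark of growth by Brownian-motion coalescence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from sklearn.cluster import DBSCAN

__all__ = [
    "CondensateCluster",
    "GrowthCurve",
    "window_localizations",
    "detect_condensates",
    "cluster_radius",
    "percent_condensed",
    "growth_curve",
    "fit_lognormal",
]

DEFAULT_EPS_NM = 48.0
DEFAULT_MIN_PTS = 5


@dataclass
class CondensateCluster:
    """One DBSCAN-detected condensate in a localization map."""

    members: np.ndarray  # indices into the source table
    centroid: np.ndarray  # (2,) nm
    area: float  # nm^2, convex hull of member points
    radius: float  # nm, circle-equivalent sqrt(area/pi)
    degenerate: bool = False  # hull collapsed (collinear/coincident points)

    @property
    def n_points(self) -> int:
        return len(self.members)


@dataclass
class GrowthCurve:
    time_points: np.ndarray  # minutes
    mean_radius: np.ndarray  # nm (NaN where no condensate was found)
    radii_distributions: list[np.ndarray]
    beta: float
    beta_intercept: float
    plateau_radius: float


def _as_xy(table: pd.DataFrame) -> np.ndarray:
    return table[["x_nm", "y_nm"]].to_numpy(dtype=float)


def window_localizations(
    table: pd.DataFrame, window_frames: int, frame_interval: float = 0.015
) -> list[pd.DataFrame]:
    """Partition a localization table into consecutive frame windows.

    Window ``k`` covers frames ``[k*w, (k+1)*w)``.  Every localization
    falls in exactly one window; empty windows up to the last occupied
    one are returned as empty tables.  ``frame_interval`` (s) is only
    used to annotate each window with its start time.
    """
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    if len(table) == 0:
        return []
    idx = table["frame"].to_numpy(dtype=np.int64) // window_frames
    n_windows = int(idx.max()) + 1
    out = []
    for k in range(n_windows):
        win = table.loc[idx == k].copy()
        win.attrs["window_index"] = k
        win.attrs["start_time_s"] = k * window_frames * frame_interval
        out.append(win)
    return out


def detect_condensates(
    points: pd.DataFrame,
    eps: float = DEFAULT_EPS_NM,
    min_pts: int = DEFAULT_MIN_PTS,
) -> tuple[list[CondensateCluster], np.ndarray]:
    """DBSCAN condensate calling on one localization map.

    Returns the detected clusters and the integer indices (into
    ``points``) of the free, unclustered localizations.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 2:
        raise ValueError("min_pts must be >= 2")
    if len(points) == 0:
        return [], np.empty(0, dtype=np.int64)
    xy = _as_xy(points)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(xy)
    clusters = []
    for lab in np.unique(labels[labels >= 0]):
        members = np.flatnonzero(labels == lab)
        pts = xy[members]
        area, radius, degenerate = _hull_radius(pts)
        clusters.append(
            CondensateCluster(
                members=members,
                centroid=pts.mean(axis=0),
                area=area,
                radius=radius,
                degenerate=degenerate,
            )
        )
    free = np.flatnonzero(labels == -1)
    return clusters, free


def _hull_radius(pts: np.ndarray) -> tuple[float, float, bool]:
    """Convex-hull area and circle-equivalent radius of a point set.

    A degenerate hull (all points collinear or coincident) has zero
    area; its radius falls back to half the maximum pairwise distance.
    """
    try:
        hull = ConvexHull(pts)
        # in 2D, ConvexHull.volume is the enclosed area
        area = float(hull.volume)
        return area, float(np.sqrt(area / np.pi)), False
    except QhullError:
        if len(pts) < 2:
            return 0.0, 0.0, True
        return 0.0, float(pdist(pts).max() / 2.0), True


def cluster_radius(cluster: CondensateCluster) -> float:
    """Circle-equivalent radius sqrt(A/pi) of a detected condensate (nm)."""
    return cluster.radius


def percent_condensed(
    points: pd.DataFrame, clusters: list[CondensateCluster]
) -> float:
    """Percentage of localizations inside detected condensates."""
    total = len(points)
    if total == 0:
        raise ValueError("empty localization table")
    clustered = sum(c.n_points for c in clusters)
    return 100.0 * clustered / total


def growth_curve(
    tables: list[pd.DataFrame],
    time_points: np.ndarray,
    eps: float = DEFAULT_EPS_NM,
    min_pts: int = DEFAULT_MIN_PTS,
    fit_window: tuple[float, float] | None = None,
    plateau_window: tuple[float, float] | None = None,
) -> GrowthCurve:
    """Condensate growth curve from maps cumulated at successive times.

    For each time point, condensates are detected and their radii
    collected; the mean radius per time point gives <R>(t).  The growth
    exponent beta of ``<R> ~ t^beta`` is fitted by least squares on
    log-log axes over ``fit_window`` (min and max time, in the units of
    ``time_points``; default: all time points), and the plateau radius
    is the mean of <R> over ``plateau_window`` (default: the last
    quarter of the time course).
    """
    time_points = np.asarray(time_points, dtype=float)
    if len(tables) != len(time_points):
        raise ValueError("tables and time_points must have equal length")
    if len(tables) < 3:
        raise ValueError("need at least 3 time points to fit a growth exponent")

    mean_r = np.full(len(tables), np.nan)
    dists: list[np.ndarray] = []
    for i, tab in enumerate(tables):
        clusters, _ = detect_condensates(tab, eps=eps, min_pts=min_pts)
        radii = np.array([c.radius for c in clusters])
        dists.append(radii)
        if len(radii) == 0:
            warnings.warn(f"time point {time_points[i]}: no condensates; excluded")
        else:
            mean_r[i] = radii.mean()

    ok = np.isfinite(mean_r) & (time_points > 0)
    if fit_window is not None:
        lo, hi = fit_window
        fit_ok = ok & (time_points >= lo) & (time_points <= hi)
    else:
        fit_ok = ok
    if fit_ok.sum() < 3:
        raise ValueError("fewer than 3 usable time points in the fit window")
    beta, intercept = np.polyfit(
        np.log(time_points[fit_ok]), np.log(mean_r[fit_ok]), 1
    )

    if plateau_window is not None:
        lo, hi = plateau_window
        plat_ok = ok & (time_points >= lo) & (time_points <= hi)
    else:
        n = len(time_points)
        plat_ok = ok & (np.arange(n) >= n - max(1, n // 4))
    plateau = float(np.nanmean(mean_r[plat_ok])) if plat_ok.any() else float("nan")

    return GrowthCurve(
        time_points=time_points,
        mean_radius=mean_r,
        radii_distributions=dists,
        beta=float(beta),
        beta_intercept=float(intercept),
        plateau_radius=plateau,
    )


def fit_lognormal(radii: np.ndarray) -> tuple[float, float, float]:
    """Log-normal fit of a radius sample.

    Maximum-likelihood normal fit on log radii; returns (mu_log,
    sigma_log, p) where p is the D'Agostino-Pearson normality test
    p-value on the log radii (large p: consistent with log-normal).
    """
    radii = np.asarray(radii, dtype=float)
    if len(radii) < 20:
        raise ValueError("need at least 20 radii")
    if np.any(radii <= 0) or not np.all(np.isfinite(radii)):
        raise ValueError("radii must be positive and finite")
    logs = np.log(radii)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))  # MLE
    if sigma <= 1e-12 * max(1.0, abs(mu)):  # constant sample
        return mu, 0.0, float("nan")
    _, p = stats.normaltest(logs)
    return mu, sigma, float(p)
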