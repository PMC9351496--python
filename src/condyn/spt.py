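"""Single-particle-tracking statistics.

Per-trajectory and ensemble quantities routinely extracted from 2D
single-molecule tracking data at ~15 ms frame intervals:

* time-averaged mean square displacement (tMSD) and the instantaneous
  diffusion coefficient ``D_2-4`` from a linear fit of tMSD at lags 2-4,
  ``tMSD = 4 D Delta + offset``;
* turning angles between consecutive displacement segments and their
  anisotropy fold change (backward 180 deg +/- 30 deg over forward
  0 deg +/- 30 deg), a signature of confinement or viscoelasticity;
* a two-component cumulative-distribution fit of squared displacements
  separating slow and fast molecular populations;
* a confined-diffusion fit ``r2(t) = a + (L^2/3)(1 - exp(-t/tau))``
  yielding the confinement size L.

Positions are in micrometres, lag times in seconds, diffusion
coefficients in um^2/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Trajectory",
    "TMSDCurve",
    "DiffusionFit",
    "AngleSet",
    "CPDFitResult",
    "ConfinementFitResult",
    "compute_tmsd",
    "ensemble_tmsd",
    "fit_d24",
    "turning_angles",
    "anisotropy",
    "displacements_by_lag",
    "fit_cpd",
    "fit_confinement",
]

#: default minimum track length (frames); tracks of 10 or fewer
#: detections are conventionally discarded as too short to analyse
MIN_TRACK_FRAMES = 11


@dataclass
class Trajectory:
    """A single 2D track sampled at a regular frame interval."""

    track_id: int | str
    frames: np.ndarray
    positions: np.ndarray  # (T, 2) in um
    frame_interval: float = 0.015  # s

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64).reshape(-1)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if len(self.frames) != len(self.positions):
            raise ValueError("frames and positions must have equal length")
        if len(self.frames) < 2:
            raise ValueError("a trajectory needs at least 2 points")
        if not np.all(np.diff(self.frames) > 0):
            raise ValueError("frames must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def is_contiguous(self) -> bool:
        return bool(np.all(np.diff(self.frames) == 1))


@dataclass
class TMSDCurve:
    """tMSD(Delta) with the number of displacement pairs behind each lag."""

    lags: np.ndarray  # in frames
    values: np.ndarray  # um^2
    n_pairs: np.ndarray
    frame_interval: float = 0.015

    @property
    def lag_times(self) -> np.ndarray:
        return self.lags * self.frame_interval


@dataclass
class DiffusionFit:
    d24: float  # um^2/s
    offset: float  # um^2


@dataclass
class AngleSet:
    """Turning angles in degrees, each in [0, 360)."""

    angles: np.ndarray
    bin_width: float = 30.0

    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        edges = np.arange(0.0, 360.0 + self.bin_width, self.bin_width)
        counts, _ = np.histogram(self.angles, bins=edges)
        return counts, edges


@dataclass
class CPDFitResult:
    """Two-population displacement-distribution fit.

    ``s``, ``rs2`` and ``rf2`` are per-lag arrays: the slow fraction and
    the characteristic squared displacements (um^2) of the slow and fast
    populations at each fitted lag.  ``d_slow`` / ``d_fast`` come from
    refitting rs2 and rf2 against lag time with ``r2 = 4 D t + offset``.
    """

    lags: np.ndarray
    s: np.ndarray
    rs2: np.ndarray
    rf2: np.ndarray
    slow_fraction: float
    d_slow: float
    d_fast: float
    converged: bool
    message: str = ""

    def cdf(self, r2: np.ndarray, lag_index: int = 0) -> np.ndarray:
        return _cpd_model(
            np.asarray(r2, dtype=float),
            self.s[lag_index],
            self.rs2[lag_index],
            self.rf2[lag_index],
        )


@dataclass
class ConfinementFitResult:
    offset_a: float  # um^2
    confinement_size: float  # um
    tau: float  # s
    converged: bool
    message: str = ""

    def model(self, lag_times: np.ndarray) -> np.ndarray:
        return self.offset_a + (self.confinement_size**2 / 3.0) * (
            1.0 - np.exp(-np.asarray(lag_times) / self.tau)
        )


# ---------------------------------------------------------------------------
# tMSD


def _pair_sums(traj: Trajectory, lag: int, gap_tolerant: bool) -> tuple[float, int]:
    """Sum of squared displacements and pair count at one lag (in frames)."""
    if traj.is_contiguous:
        d = traj.positions[lag:] - traj.positions[:-lag]
        return float((d**2).sum()), len(d)
    # match pairs of detections exactly `lag` frames apart
    index = {int(f): i for i, f in enumerate(traj.frames)}
    total, n = 0.0, 0
    for f, i in index.items():
        j = index.get(f + lag)
        if j is not None:
            d = traj.positions[j] - traj.positions[i]
            total += float(d @ d)
            n += 1
    if not gap_tolerant and n < len(traj) - lag:
        raise ValueError(
            "trajectory has frame gaps; pass gap_tolerant=True to skip "
            "pairs spanning gaps"
        )
    return total, n


def compute_tmsd(
    traj: Trajectory, max_lag: int | None = None, gap_tolerant: bool = False
) -> TMSDCurve:
    """Time-averaged MSD of one trajectory.

    tMSD(Delta) = (1/(T-Delta)) sum_i |r(t_{i+Delta}) - r(t_i)|^2, the
    average running over all start points.  ``max_lag`` defaults to
    T - 1 frames.
    """
    span = int(traj.frames[-1] - traj.frames[0])
    if max_lag is None:
        max_lag = span
    if max_lag < 1 or max_lag > span:
        raise ValueError(f"max_lag must be in [1, {span}]")
    if not traj.is_contiguous and not gap_tolerant:
        # raises with a helpful message
        _pair_sums(traj, 1, gap_tolerant=False)
    lags = np.arange(1, max_lag + 1)
    values = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=np.int64)
    for k, lag in enumerate(lags):
        total, n = _pair_sums(traj, int(lag), gap_tolerant=True)
        values[k] = total / n if n else np.nan
        n_pairs[k] = n
    return TMSDCurve(lags, values, n_pairs, traj.frame_interval)


def ensemble_tmsd(trajs: list[Trajectory], max_lag: int | None = None) -> TMSDCurve:
    """Cumulative tMSD pooled over trajectories.

    At each lag, squared displacements from all tracks are pooled, which
    is the pair-count-weighted average of the individual tMSD curves.
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    dt = trajs[0].frame_interval
    if max_lag is None:
        max_lag = max(int(t.frames[-1] - t.frames[0]) for t in trajs)
    totals = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=np.int64)
    for traj in trajs:
        span = int(traj.frames[-1] - traj.frames[0])
        for lag in range(1, min(max_lag, span) + 1):
            s, n = _pair_sums(traj, lag, gap_tolerant=True)
            totals[lag - 1] += s
            counts[lag - 1] += n
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, totals / np.maximum(counts, 1), np.nan)
    return TMSDCurve(np.arange(1, max_lag + 1), values, counts, dt)


def fit_d24(curve: TMSDCurve) -> DiffusionFit:
    """Instantaneous diffusion coefficient from tMSD lags 2-4.

    Ordinary least squares of tMSD on lag time over Delta in {2, 3, 4};
    the slope of ``tMSD = 4 D t + offset`` gives ``D_2-4 = slope / 4``.
    """
    sel = np.isin(curve.lags, (2, 3, 4)) & np.isfinite(curve.values)
    if sel.sum() < 3:
        raise ValueError("curve must contain finite tMSD values at lags 2, 3 and 4")
    t = curve.lag_times[sel]
    y = curve.values[sel]
    slope, intercept = np.polyfit(t, y, 1)
    return DiffusionFit(d24=float(slope / 4.0), offset=float(intercept))


# ---------------------------------------------------------------------------
# turning angles


def turning_angles(traj: Trajectory, bin_width: float = 30.0) -> AngleSet:
    """Angle between consecutive displacement segments, in [0, 360) deg.

    Computed as atan2 of the z-cross-product and the dot product of the
    two segments (the planar vectors are treated as 3D with z = 0).
    Pairs involving a zero-length segment carry no direction and are
    skipped.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 points for turning angles")
    seg = np.diff(traj.positions, axis=0)
    v1, v2 = seg[:-1], seg[1:]
    lengths = np.linalg.norm(seg, axis=1)
    ok = (lengths[:-1] > 0) & (lengths[1:] > 0)
    if not ok.any():
        warnings.warn("all segments have zero length; no angles computed")
        return AngleSet(np.empty(0), bin_width)
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = (v1 * v2).sum(axis=1)
    theta = np.degrees(np.arctan2(cross[ok], dot[ok])) % 360.0
    return AngleSet(theta, bin_width)


def anisotropy(angles: AngleSet) -> float:
    """Fold change of backward over forward turning angles.

    count(theta in 180 +/- 30 deg) / count(theta in 0 +/- 30 deg); the
    forward window wraps, [330, 360) union [0, 30].  Values near 1 mean
    isotropic (Brownian) motion; values > 1 indicate a backward bias as
    produced by confinement or anti-persistent (e.g. fractional
    Brownian) motion.
    """
    a = np.asarray(angles.angles, dtype=float)
    if len(a) == 0:
        raise ValueError("empty angle set")
    backward = int(((a >= 150.0) & (a <= 210.0)).sum())
    forward = int(((a >= 330.0) | (a <= 30.0)).sum())
    if forward == 0:
        warnings.warn("no forward angles; anisotropy is infinite")
        return float("inf")
    return backward / forward


# ---------------------------------------------------------------------------
# two-component CPD fit


def displacements_by_lag(
    trajs: list[Trajectory], lags: tuple[int, ...] = (1, 2, 3, 4)
) -> dict[int, np.ndarray]:
    """Pooled squared displacements (um^2) at each requested lag."""
    out: dict[int, list[np.ndarray]] = {lag: [] for lag in lags}
    for traj in trajs:
        for lag in lags:
            if traj.is_contiguous and lag < len(traj):
                d = traj.positions[lag:] - traj.positions[:-lag]
                out[lag].append((d**2).sum(axis=1))
            else:
                index = {int(f): i for i, f in enumerate(traj.frames)}
                vals = [
                    float(np.sum((traj.positions[j] - traj.positions[i]) ** 2))
                    for f, i in index.items()
                    if (j := index.get(f + lag)) is not None
                ]
                if vals:
                    out[lag].append(np.asarray(vals))
    return {
        lag: (np.concatenate(v) if v else np.empty(0)) for lag, v in out.items()
    }


def _cpd_model(r2: np.ndarray, s: float, rs2: float, rf2: float) -> np.ndarray:
    return 1.0 - (s * np.exp(-r2 / rs2) + (1.0 - s) * np.exp(-r2 / rf2))


def _fit_cpd_single_lag(
    r2: np.ndarray, n_starts: int, rng: np.random.Generator
) -> tuple[float, float, float, bool]:
    """Fit the two-exponential CDF at one lag, multi-start least squares."""
    r2 = np.sort(r2)
    n = len(r2)
    p_emp = np.arange(1, n + 1) / n
    scale = float(np.mean(r2))

    def residuals(theta: np.ndarray) -> np.ndarray:
        s, log_rs2, log_rf2 = theta
        return _cpd_model(r2, s, np.exp(log_rs2), np.exp(log_rf2)) - p_emp

    best = None
    # spread of initial guesses: slow scale below the mean r2, fast above
    for k in range(n_starts):
        if k == 0:
            x0 = np.array([0.5, np.log(scale * 0.1), np.log(scale * 2.0)])
        else:
            x0 = np.array(
                [
                    rng.uniform(0.05, 0.95),
                    np.log(scale) + rng.uniform(-4.0, 0.0),
                    np.log(scale) + rng.uniform(-1.0, 2.0),
                ]
            )
        try:
            res = least_squares(
                residuals,
                x0,
                bounds=([0.0, -np.inf, -np.inf], [1.0, np.inf, np.inf]),
            )
        except Exception:  # noqa: BLE001 - optimizer failure is data-dependent
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return np.nan, np.nan, np.nan, False
    s, rs2, rf2 = best.x[0], float(np.exp(best.x[1])), float(np.exp(best.x[2]))
    if rs2 > rf2:  # enforce slow <= fast by relabelling
        rs2, rf2 = rf2, rs2
        s = 1.0 - s
    return float(s), rs2, rf2, bool(best.success)


def fit_cpd(
    displacements: dict[int, np.ndarray],
    frame_interval: float = 0.015,
    n_starts: int = 5,
    seed: int = 0,
    min_displacements: int = 50,
) -> CPDFitResult:
    """Two-population fit of the cumulative distribution of r^2 per lag.

    At each lag the empirical CDF of squared displacements is fitted by

        P(r2, t) = 1 - [s exp(-r2/rs2) + (1 - s) exp(-r2/rf2)]

    (both exponents negative; the slow population has the smaller
    characteristic displacement rs2).  The per-lag rs2 and rf2 are then
    regressed on lag time with ``r2 = 4 D t + offset`` to yield the
    slow- and fast-population diffusion coefficients.
    """
    rng = np.random.default_rng(seed)
    lags = sorted(displacements)
    s_arr, rs2_arr, rf2_arr, ok_all = [], [], [], True
    used_lags = []
    for lag in lags:
        r2 = np.asarray(displacements[lag], dtype=float)
        r2 = r2[r2 > 0]
        if len(r2) < min_displacements:
            warnings.warn(
                f"lag {lag}: only {len(r2)} displacements (<{min_displacements}); skipped"
            )
            continue
        s, rs2, rf2, ok = _fit_cpd_single_lag(r2, n_starts, rng)
        used_lags.append(lag)
        s_arr.append(s)
        rs2_arr.append(rs2)
        rf2_arr.append(rf2)
        ok_all &= ok
    if not used_lags:
        raise ValueError("no lag had enough displacements to fit")

    lags_a = np.asarray(used_lags)
    t = lags_a * frame_interval
    rs2_a = np.asarray(rs2_arr)
    rf2_a = np.asarray(rf2_arr)

    def _d_of(r2_per_lag: np.ndarray) -> float:
        if len(t) >= 2:
            slope, _ = np.polyfit(t, r2_per_lag, 1)
            return float(slope / 4.0)
        return float(r2_per_lag[0] / (4.0 * t[0]))

    return CPDFitResult(
        lags=lags_a,
        s=np.asarray(s_arr),
        rs2=rs2_a,
        rf2=rf2_a,
        slow_fraction=float(np.mean(s_arr)),
        d_slow=_d_of(rs2_a),
        d_fast=_d_of(rf2_a),
        converged=ok_all,
        message="" if ok_all else "one or more per-lag fits did not converge",
    )


# ---------------------------------------------------------------------------
# confinement fit


def fit_confinement(
    curve: TMSDCurve, n_starts: int = 5, seed: int = 0
) -> ConfinementFitResult:
    """Fit the saturating confined-diffusion MSD model.

        r2(t) = a + (L^2 / 3) (1 - exp(-t / tau))

    where ``a`` is an offset (um^2), ``L`` the confinement size (um) and
    ``tau`` the saturation time (s).  The long-time plateau of the curve
    is ``a + L^2/3``.  Multi-start nonlinear least squares; the best
    sum-of-squares solution is returned.
    """
    ok = np.isfinite(curve.values)
    t = curve.lag_times[ok]
    y = curve.values[ok]
    if len(t) < 4:
        raise ValueError("need at least 4 finite tMSD points")
    rng = np.random.default_rng(seed)
    plateau = float(np.mean(y[-max(1, len(y) // 4):]))
    l0 = np.sqrt(max(3.0 * plateau, 1e-12))
    t_span = float(t[-1])

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, log_l, log_tau = theta
        return a + (np.exp(2 * log_l) / 3.0) * (
            1.0 - np.exp(-t / np.exp(log_tau))
        ) - y

    best = None
    for k in range(n_starts):
        if k == 0:
            x0 = np.array([0.0, np.log(l0), np.log(t_span / 5.0)])
        else:
            x0 = np.array(
                [
                    rng.uniform(-0.1, 0.1) * plateau,
                    np.log(l0) + rng.uniform(-1.0, 1.0),
                    np.log(t_span) + rng.uniform(-4.0, 0.5),
                ]
            )
        try:
            res = least_squares(residuals, x0)
        except Exception:  # noqa: BLE001
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return ConfinementFitResult(np.nan, np.nan, np.nan, False, "fit failed")
    a, log_l, log_tau = best.x
    return ConfinementFitResult(
        offset_a=float(a),
        confinement_size=float(np.exp(log_l)),
        tau=float(np.exp(log_tau)),
        converged=bool(best.success),
        message="" if best.success else best.message,
    )
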