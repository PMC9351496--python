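"""Seeded synthetic-data generators.

Trajectory models commonly used to interpret nuclear single-particle
tracking, plus clustered localization maps:

* ``brownian`` -- ordinary Brownian motion with diffusivity D;
* ``fbm`` -- fractional Brownian motion with anomalous exponent
  ``alpha`` (Hurst H = alpha/2); for alpha < 1 increments are negatively
  correlated (anti-persistent), the model that best describes diffusion
  inside condensates;
* ``attm`` -- an annealed-transient-time-style walk: Brownian segments
  whose diffusivity is redrawn from a power law at random intervals,
  producing heterogeneous, sub-linear ensemble MSDs;
* ``confined`` -- Brownian motion reflected at the boundary of a disk,
  whose ensemble MSD saturates at a plateau set by the disk radius.

Localization maps place log-normally sized condensates in a field,
fill them uniformly with points, add ~20 nm localization noise and a
uniform background, and return the ground-truth labels.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spt import Trajectory

__all__ = [
    "GeneratorSpec",
    "SyntheticMapSpec",
    "gen_brownian",
    "gen_fbm",
    "gen_attm",
    "gen_confined",
    "generate_trajectory",
    "generate_trajectories",
    "gen_localization_map",
    "fbm_covariance",
]

_MODELS = ("brownian", "fbm", "attm", "confined")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic trajectory generator."""

    model: str = "brownian"
    n_steps: int = 100
    dt: float = 0.015  # s
    diffusivity: float = 0.1  # um^2/s (generalized for fbm: um^2/s^alpha)
    alpha: float = 1.0  # anomalous exponent, (0, 1]
    sigma_attm: float = 1.0  # exponent of the diffusivity power law
    gamma_attm: float = 1.5  # duration exponent, tau = D^(-gamma)
    confine_radius: float = 0.075  # um
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.model == "confined" and self.confine_radius <= 0:
            raise ValueError("confine_radius must be positive")
        if self.model == "attm" and (self.sigma_attm <= 0 or self.gamma_attm <= 0):
            raise ValueError("ATTM exponents must be positive")
        if self.dt <= 0 or self.diffusivity < 0:
            raise ValueError("dt must be positive and diffusivity non-negative")


@dataclass(frozen=True)
class SyntheticMapSpec:
    """Parameters of a synthetic clustered localization map."""

    field_size: float = 2400.0  # nm (typical analysed region)
    n_condensates: int = 10
    radius_log_mu: float = math.log(70.0)  # log-nm
    radius_log_sigma: float = 0.3
    points_per_condensate: int = 100  # mean, Poisson
    background_density: float = 2.0  # points per um^2
    localization_sd: float = 20.0  # nm localization precision
    n_frames: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_size <= 0 or self.n_frames < 1:
            raise ValueError("field_size and n_frames must be positive")
        if self.n_condensates < 0 or self.points_per_condensate < 1:
            raise ValueError("invalid condensate counts")
        if self.localization_sd < 0 or self.background_density < 0:
            raise ValueError("noise and background must be non-negative")


def _traj(spec: GeneratorSpec, positions: np.ndarray, track_id=0) -> Trajectory:
    return Trajectory(
        track_id=track_id,
        frames=np.arange(len(positions)),
        positions=positions,
        frame_interval=spec.dt,
    )


def gen_brownian(spec: GeneratorSpec, rng=None, track_id=0) -> Trajectory:
    """Brownian track: cumulative i.i.d. Gaussian steps, variance 2 D dt per axis."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    sd = math.sqrt(2.0 * spec.diffusivity * spec.dt)
    steps = rng.normal(0.0, sd, size=(spec.n_steps - 1, 2))
    pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    return _traj(spec, pos, track_id)


def fbm_covariance(times: np.ndarray, diffusivity: float, alpha: float) -> np.ndarray:
    """Per-axis covariance kernel of FBM scaled to MSD_x(t) = 2 D t^alpha.

    Cov(B(s), B(t)) = D (s^alpha + t^alpha - |t - s|^alpha), so the 2D
    ensemble MSD is 4 D t^alpha.
    """
    t = np.asarray(times, dtype=float)
    s, u = np.meshgrid(t, t, indexing="ij")
    return diffusivity * (s**alpha + u**alpha - np.abs(s - u) ** alpha)


def gen_fbm(spec: GeneratorSpec, rng=None, track_id=0) -> Trajectory:
    """Fractional Brownian track via exact Cholesky of the FBM covariance.

    Hurst exponent H = alpha/2; the two coordinates are independent FBM
    processes scaled so the 2D ensemble MSD is 4 D t^alpha (t in
    seconds).  Exact (dense covariance) construction, intended for
    tracks up to ~10^3 steps.
    """
    if spec.n_steps > 2000:
        raise ValueError("exact FBM construction is limited to 2000 steps")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    times = spec.dt * np.arange(1, spec.n_steps)
    cov = fbm_covariance(times, spec.diffusivity, spec.alpha)
    # tiny jitter keeps the Cholesky stable for alpha near 1
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(times)))
    z = rng.normal(size=(len(times), 2))
    pos = np.vstack([np.zeros(2), chol @ z])
    return _traj(spec, pos, track_id)


def gen_attm(spec: GeneratorSpec, rng=None, track_id=0, max_segments=None) -> Trajectory:
    """Heterogeneous-diffusivity walk (annealed transient time style).

    The walk is Brownian within segments.  Segment diffusivities are
    drawn from the power-law density p(D) ~ D^(sigma-1) on (0, 1]
    (times the overall ``diffusivity`` scale) and each is held for
    ``tau = D^(-gamma)`` steps.  For sigma < gamma < sigma + 1 the
    ensemble MSD grows as t^(sigma/gamma), i.e. subdiffusively.
    ``max_segments=1`` forces a single segment (a plain Brownian track
    with a random D).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    steps = np.empty((spec.n_steps - 1, 2))
    done = 0
    n_seg = 0
    while done < spec.n_steps - 1:
        d_rel = rng.uniform() ** (1.0 / spec.sigma_attm)  # p(D) ~ D^(sigma-1)
        duration = max(1, int(round(d_rel**-spec.gamma_attm)))
        n_seg += 1
        if max_segments is not None and n_seg >= max_segments:
            duration = spec.n_steps - 1 - done
        take = min(duration, spec.n_steps - 1 - done)
        sd = math.sqrt(2.0 * spec.diffusivity * d_rel * spec.dt)
        steps[done : done + take] = rng.normal(0.0, sd, size=(take, 2))
        done += take
    pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    return _traj(spec, pos, track_id)


def gen_confined(spec: GeneratorSpec, rng=None, track_id=0) -> Trajectory:
    """Brownian motion reflected at the boundary of a disk.

    The walk starts at the disk center; a proposed step landing outside
    the disk of radius ``confine_radius`` is reflected radially back
    inside.  The long-time ensemble MSD saturates at a plateau close to
    the squared disk radius.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    r_c = spec.confine_radius
    sd = math.sqrt(2.0 * spec.diffusivity * spec.dt)
    pos = np.zeros((spec.n_steps, 2))
    cur = np.zeros(2)
    steps = rng.normal(0.0, sd, size=(spec.n_steps - 1, 2))
    for i in range(1, spec.n_steps):
        cur = cur + steps[i - 1]
        rad = np.hypot(*cur)
        while rad > r_c:
            cur = cur * ((2.0 * r_c - rad) / rad)
            rad = abs(2.0 * r_c - rad)
        pos[i] = cur
    return _traj(spec, pos, track_id)


_GENERATORS = {
    "brownian": gen_brownian,
    "fbm": gen_fbm,
    "attm": gen_attm,
    "confined": gen_confined,
}


def generate_trajectory(spec: GeneratorSpec, rng=None, track_id=0) -> Trajectory:
    return _GENERATORS[spec.model](spec, rng=rng, track_id=track_id)


def generate_trajectories(spec: GeneratorSpec, n_tracks: int) -> list[Trajectory]:
    """n_tracks independent tracks from one seeded RNG stream."""
    rng = np.random.default_rng(spec.seed)
    return [
        generate_trajectory(spec, rng=rng, track_id=i) for i in range(n_tracks)
    ]


def gen_localization_map(
    spec: SyntheticMapSpec,
) -> tuple[pd.DataFrame, dict]:
    """Clustered localization map with ground truth.

    Condensate centers are drawn uniformly with rejection so that no two
    lie closer than twice the median planted radius; per-condensate
    radii are log-normal; member points are uniform inside each disk and
    jittered by the localization noise.  Background points are uniform
    over the field.  Frames are assigned uniformly at random.

    Returns (table, truth): the table has columns (frame, x_nm, y_nm)
    and truth carries the planted centers, radii and per-row labels
    (condensate index, or -1 for background).
    """
    rng = np.random.default_rng(spec.seed)
    min_sep = 2.0 * math.exp(spec.radius_log_mu)
    centers = np.empty((spec.n_condensates, 2))
    placed = 0
    tries = 0
    while placed < spec.n_condensates:
        cand = rng.uniform(0.0, spec.field_size, size=2)
        if placed == 0 or np.min(
            np.linalg.norm(centers[:placed] - cand, axis=1)
        ) >= min_sep:
            centers[placed] = cand
            placed += 1
        tries += 1
        if tries > 10_000:
            raise RuntimeError(
                "could not place condensate centers without overlap; "
                "field too crowded"
            )

    radii = np.exp(
        rng.normal(spec.radius_log_mu, spec.radius_log_sigma, spec.n_condensates)
    )

    xs, ys, labels = [], [], []
    for i in range(spec.n_condensates):
        n_pts = rng.poisson(spec.points_per_condensate)
        u = rng.uniform(size=n_pts)
        theta = rng.uniform(0.0, 2.0 * math.pi, size=n_pts)
        rr = radii[i] * np.sqrt(u)  # uniform over the disk
        px = centers[i, 0] + rr * np.cos(theta)
        py = centers[i, 1] + rr * np.sin(theta)
        if spec.localization_sd > 0:
            px = px + rng.normal(0.0, spec.localization_sd, n_pts)
            py = py + rng.normal(0.0, spec.localization_sd, n_pts)
        xs.append(px)
        ys.append(py)
        labels.append(np.full(n_pts, i))

    area_um2 = (spec.field_size / 1000.0) ** 2
    n_bg = rng.poisson(spec.background_density * area_um2)
    xs.append(rng.uniform(0.0, spec.field_size, n_bg))
    ys.append(rng.uniform(0.0, spec.field_size, n_bg))
    labels.append(np.full(n_bg, -1))

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    lab = np.concatenate(labels).astype(int)
    frames = rng.integers(0, spec.n_frames, size=len(x))
    order = np.argsort(frames, kind="stable")

    table = pd.DataFrame(
        {"frame": frames[order], "x_nm": x[order], "y_nm": y[order]}
    ).reset_index(drop=True)
    truth = {
        "centers_nm": centers,
        "radii_nm": radii,
        "labels": lab[order],
        "n_background": int(n_bg),
    }
    return table, truth
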