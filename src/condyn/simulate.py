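"""Brownian-motion-coalescence (BMC) simulator with stochastic unbinding.

A 2D box of ``N`` circular particles of radius ``r`` diffusing with
coefficient ``D``.  Particles that come into contact fuse into droplets;
a droplet of ``M`` particles conserves total area, so its radius is
``R_M = sqrt(M) * r``, and it feels Stokes drag, diffusing with
``D_R = D / R_M``.  The model extension over classical BMC is a per-step,
per-particle unbinding probability ``P_u``: at every time step each
particle inside a droplet may escape and become a free particle again.
With ``P_u = 0`` the system coarsens as ``<R> ~ t^(1/3)`` towards a single
droplet; with ``P_u > 0`` growth arrests at a finite steady-state size.

Each time step executes three phases in a fixed order:

1. **unbind** -- every member of every multi-particle droplet escapes
   independently with probability ``P_u``; escapers are placed just
   outside the shrunken droplet and are barred from coalescing until the
   next step;
2. **move** -- every entity (free particle or droplet) takes an
   independent Gaussian step of per-axis variance ``2 * D_R * dt``;
3. **coalesce** -- entities whose center distance is below the sum of
   their radii merge; multi-body contacts are resolved as connected
   components, the merged droplet sits at the mass-weighted centroid.

All lengths are in units of the particle radius (``r = 1`` by default)
and times in units of the time step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "SimConfig",
    "Droplet",
    "SimState",
    "SimTrace",
    "init_state",
    "unbind_phase",
    "move_phase",
    "coalesce_phase",
    "run_simulation",
    "mean_radius",
    "condensed_fraction",
    "radius_distribution",
    "diffusion_histogram",
    "fit_power_law",
    "growth_exponent",
    "condensed_growth_exponent",
    "steady_state_radius",
]

# offset added to the escape distance so an escaper never starts exactly
# in contact with its source droplet
_ESCAPE_EPS = 1e-6


@dataclass(frozen=True)
class SimConfig:
    """Free parameters of the coalescence-with-unbinding model.

    Either ``box_length`` (L) or ``density`` (number density rho, with
    L = sqrt(N / rho)) must be given.
    """

    n_particles: int
    box_length: float | None = None
    density: float | None = None
    particle_radius: float = 1.0
    diffusivity: float = 1.0
    unbind_prob: float = 0.0
    n_steps: int = 1000
    boundary: str = "periodic"
    rng_seed: int = 0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.box_length is None and self.density is None:
            raise ValueError("give either box_length or density")
        if self.box_length is not None and self.density is not None:
            raise ValueError("give box_length or density, not both")
        if self.density is not None:
            object.__setattr__(
                self, "box_length", math.sqrt(self.n_particles / self.density)
            )
        for name in ("box_length", "particle_radius", "dt"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v!r}")
        if not np.isfinite(self.diffusivity) or self.diffusivity < 0:
            raise ValueError("diffusivity must be finite and non-negative")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if not 0.0 <= self.unbind_prob <= 1.0:
            raise ValueError("unbind_prob must lie in [0, 1]")
        if self.box_length <= 2 * self.particle_radius:
            raise ValueError("box_length must exceed twice the particle radius")
        if self.boundary not in ("periodic", "reflecting"):
            raise ValueError("boundary must be 'periodic' or 'reflecting'")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass(frozen=True)
class Droplet:
    """A condensate of ``members`` particles (a free particle has M = 1)."""

    center: tuple[float, float]
    members: int
    particle_radius: float = 1.0
    diffusivity: float = 1.0

    @property
    def radius(self) -> float:
        # area conservation: M circles of radius r -> one of sqrt(M) r
        return math.sqrt(self.members) * self.particle_radius

    @property
    def drag_diffusivity(self) -> float:
        # Stokes drag: D_R = D / R
        return self.diffusivity / self.radius


@dataclass
class SimState:
    """Array-of-droplets world state.

    ``positions[i]`` / ``masses[i]`` describe entity ``i`` (a free
    particle when ``masses[i] == 1``).  ``newly_unbound`` flags entities
    that escaped a droplet this step and may not coalesce until the next.
    """

    positions: np.ndarray  # (k, 2) float
    masses: np.ndarray  # (k,) int
    newly_unbound: np.ndarray  # (k,) bool
    step_index: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.masses = np.asarray(self.masses, dtype=np.int64).reshape(-1)
        self.newly_unbound = np.asarray(self.newly_unbound, dtype=bool).reshape(-1)

    @property
    def n_entities(self) -> int:
        return len(self.masses)

    @property
    def total_particles(self) -> int:
        return int(self.masses.sum())

    def radii(self, config: SimConfig) -> np.ndarray:
        return np.sqrt(self.masses) * config.particle_radius

    def droplets(self, config: SimConfig) -> list[Droplet]:
        return [
            Droplet(
                center=(float(x), float(y)),
                members=int(m),
                particle_radius=config.particle_radius,
                diffusivity=config.diffusivity,
            )
            for (x, y), m in zip(self.positions, self.masses)
        ]

    def copy(self) -> "SimState":
        return SimState(
            self.positions.copy(),
            self.masses.copy(),
            self.newly_unbound.copy(),
            self.step_index,
        )


@dataclass
class SimTrace:
    """Recorded summary curves of one simulation run."""

    times: np.ndarray  # step indices at records
    mean_radius: np.ndarray
    condensed_fraction: np.ndarray
    n_particles: int
    particle_radius: float
    snapshots: dict[int, SimState] = field(default_factory=dict)


def _wrap(positions: np.ndarray, box: float) -> np.ndarray:
    return np.mod(positions, box)


def _reflect(positions: np.ndarray, box: float) -> np.ndarray:
    # triangular fold of each coordinate into [0, box]
    p = np.mod(positions, 2.0 * box)
    return np.where(p > box, 2.0 * box - p, p)


def _apply_boundary(positions: np.ndarray, config: SimConfig) -> np.ndarray:
    if config.boundary == "periodic":
        return _wrap(positions, config.box_length)
    return _reflect(positions, config.box_length)


def init_state(config: SimConfig) -> SimState:
    """All N particles free, i.i.d. uniform over the box."""
    rng = config.rng()
    pos = rng.uniform(0.0, config.box_length, size=(config.n_particles, 2))
    return SimState(
        positions=pos,
        masses=np.ones(config.n_particles, dtype=np.int64),
        newly_unbound=np.zeros(config.n_particles, dtype=bool),
        step_index=0,
    )


def unbind_phase(
    state: SimState, config: SimConfig, rng: np.random.Generator
) -> SimState:
    """Stochastic escape of particles from multi-particle droplets.

    Every member of every droplet with M >= 2 leaves independently with
    probability ``P_u`` (interior members included).  Escapers become
    free particles placed at a uniformly random angle at distance
    ``R_after + r`` (plus a tiny offset) from the droplet center, where
    ``R_after`` is the droplet radius after all of its departures, and
    are flagged ``newly_unbound``.  A droplet reduced to a single
    particle simply becomes a free particle.

    RNG draw order (part of the reproducibility contract): one binomial
    vector over droplets with M >= 2 in entity order, then for each such
    droplet with leavers, its escape angles, in entity order.
    """
    p_u = config.unbind_prob
    multi = np.flatnonzero(state.masses >= 2)
    if p_u == 0.0 or len(multi) == 0:
        return state.copy()

    n_leave = rng.binomial(state.masses[multi], p_u)

    positions = [state.positions]
    masses = [state.masses.copy()]
    flags = [state.newly_unbound.copy()]
    new_pos: list[np.ndarray] = []
    keep = np.ones(state.n_entities, dtype=bool)
    r = config.particle_radius

    for idx, k in zip(multi, n_leave):
        if k == 0:
            continue
        m_after = int(state.masses[idx] - k)
        r_after = math.sqrt(m_after) * r if m_after > 0 else 0.0
        theta = rng.uniform(0.0, 2.0 * math.pi, size=int(k))
        dist = r_after + r + _ESCAPE_EPS
        offsets = dist * np.column_stack([np.cos(theta), np.sin(theta)])
        new_pos.append(state.positions[idx] + offsets)
        if m_after == 0:
            keep[idx] = False
        else:
            masses[0][idx] = m_after

    if not new_pos:
        return state.copy()

    escaped = _apply_boundary(np.concatenate(new_pos, axis=0), config)
    out_pos = np.concatenate([positions[0][keep], escaped], axis=0)
    out_mass = np.concatenate(
        [masses[0][keep], np.ones(len(escaped), dtype=np.int64)]
    )
    out_flags = np.concatenate(
        [flags[0][keep], np.ones(len(escaped), dtype=bool)]
    )
    return SimState(out_pos, out_mass, out_flags, state.step_index)


def move_phase(
    state: SimState, config: SimConfig, rng: np.random.Generator
) -> SimState:
    """Gaussian displacement of every entity, variance 2*D_R*dt per axis."""
    d_eff = config.diffusivity / state.radii(config)
    sd = np.sqrt(2.0 * d_eff * config.dt)
    steps = rng.normal(0.0, 1.0, size=state.positions.shape) * sd[:, None]
    pos = _apply_boundary(state.positions + steps, config)
    return SimState(pos, state.masses.copy(), state.newly_unbound.copy(), state.step_index)


def _minimum_image(delta: np.ndarray, box: float) -> np.ndarray:
    return delta - box * np.round(delta / box)


def coalesce_phase(state: SimState, config: SimConfig) -> SimState:
    """Merge all entities in contact (center distance < sum of radii).

    Contacts are resolved as connected components of the contact graph,
    so multi-body encounters merge in a single, order-independent pass.
    Entities flagged ``newly_unbound`` take part in no contact this step;
    the flag is cleared on return.  The merged droplet's center is the
    mass-weighted centroid of its components (minimum-image convention
    under periodic boundaries, unwrapping relative to the heaviest
    component member).
    """
    n = state.n_entities
    radii = state.radii(config)
    box = config.box_length
    periodic = config.boundary == "periodic"

    eligible = np.flatnonzero(~state.newly_unbound)
    pairs = np.empty((0, 2), dtype=np.int64)
    if len(eligible) >= 2:
        pos = state.positions[eligible]
        if periodic:
            # cKDTree boxsize requires coordinates strictly inside [0, box)
            tree = cKDTree(np.mod(pos, box), boxsize=box)
        else:
            tree = cKDTree(pos)
        cutoff = 2.0 * radii[eligible].max()
        cand = tree.query_pairs(cutoff, output_type="ndarray")
        if len(cand):
            cand = eligible[cand]
            delta = state.positions[cand[:, 0]] - state.positions[cand[:, 1]]
            if periodic:
                delta = _minimum_image(delta, box)
            dist = np.hypot(delta[:, 0], delta[:, 1])
            pairs = cand[dist < radii[cand[:, 0]] + radii[cand[:, 1]]]

    if len(pairs) == 0:
        out = state.copy()
        out.newly_unbound[:] = False
        return out

    # resolve multi-body contacts among the touched entities only
    touched = np.unique(pairs)
    local = np.searchsorted(touched, pairs)
    graph = sparse.coo_matrix(
        (np.ones(len(local)), (local[:, 0], local[:, 1])),
        shape=(len(touched), len(touched)),
    )
    n_comp, labels = connected_components(graph, directed=False)

    merged_pos = np.empty((n_comp, 2))
    merged_mass = np.empty(n_comp, dtype=np.int64)
    order = np.argsort(labels, kind="stable")
    bounds = np.searchsorted(labels[order], np.arange(n_comp + 1))
    for comp in range(n_comp):
        members = touched[order[bounds[comp] : bounds[comp + 1]]]
        m = state.masses[members]
        merged_mass[comp] = m.sum()
        ref = state.positions[members[np.argmax(m)]]
        delta = state.positions[members] - ref
        if periodic:
            delta = _minimum_image(delta, box)
        merged_pos[comp] = ref + (m[:, None] * delta).sum(axis=0) / m.sum()

    untouched = np.setdiff1d(np.arange(n), touched, assume_unique=False)
    out_pos = np.concatenate(
        [state.positions[untouched], _apply_boundary(merged_pos, config)]
    )
    out_mass = np.concatenate([state.masses[untouched], merged_mass])
    return SimState(
        out_pos,
        out_mass,
        np.zeros(len(out_mass), dtype=bool),
        state.step_index,
    )


def step(state: SimState, config: SimConfig, rng: np.random.Generator) -> SimState:
    """One full time step: unbind -> move -> coalesce."""
    state = unbind_phase(state, config, rng)
    state = move_phase(state, config, rng)
    state = coalesce_phase(state, config)
    state.step_index += 1
    return state


def run_simulation(
    config: SimConfig,
    record_every: int = 1,
    min_size: int = 2,
    include_singles: bool = True,
    snapshot_every: int | None = None,
) -> SimTrace:
    """Run ``config.n_steps`` steps, recording summary curves.

    ``mean_radius`` and ``condensed_fraction`` are recorded at step 0 and
    at every ``record_every``-th step thereafter.  If ``snapshot_every``
    is given, full states are additionally stored at those steps.
    """
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    rng = config.rng()
    state = init_state(config)

    times = [0]
    mean_r = [mean_radius(state, config, include_singles=include_singles)]
    cond = [condensed_fraction(state, config, min_size=min_size)]
    snapshots: dict[int, SimState] = {}
    if snapshot_every is not None:
        snapshots[0] = state.copy()

    for t in range(1, config.n_steps + 1):
        state = step(state, config, rng)
        if t % record_every == 0 or t == config.n_steps:
            times.append(t)
            mean_r.append(mean_radius(state, config, include_singles=include_singles))
            cond.append(condensed_fraction(state, config, min_size=min_size))
        if snapshot_every is not None and t % snapshot_every == 0:
            snapshots[t] = state.copy()

    return SimTrace(
        times=np.array(times),
        mean_radius=np.array(mean_r),
        condensed_fraction=np.array(cond),
        n_particles=config.n_particles,
        particle_radius=config.particle_radius,
        snapshots=snapshots,
    )


def mean_radius(
    state: SimState, config: SimConfig, include_singles: bool = True
) -> float:
    """Arithmetic mean of droplet radii, <R>.

    With ``include_singles`` free particles count with radius ``r``;
    otherwise only droplets with M >= 2 are averaged.
    """
    radii = state.radii(config)
    if not include_singles:
        radii = radii[state.masses >= 2]
    if len(radii) == 0:
        raise ValueError("no droplets in the selected set")
    return float(radii.mean())


def condensed_fraction(
    state: SimState, config: SimConfig, min_size: int = 2
) -> float:
    """Fraction of all particles sitting in droplets with M >= min_size."""
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    total = state.masses.sum()
    in_cond = state.masses[state.masses >= min_size].sum()
    return float(in_cond) / float(total)


def radius_distribution(
    trace: SimTrace,
    window: tuple[int, int],
    min_size: int = 2,
    bins: int = 30,
) -> dict:
    """Pooled droplet radii over the snapshot steps inside ``window``.

    Returns the raw radii, the mean-normalized radii and a unit-area
    histogram of the raw radii.
    """
    lo, hi = window
    radii = []
    for t, snap in trace.snapshots.items():
        if lo <= t <= hi:
            r = np.sqrt(snap.masses[snap.masses >= min_size]) * trace.particle_radius
            radii.append(r)
    if not radii or sum(len(r) for r in radii) == 0:
        raise ValueError("no qualifying droplets inside the window")
    pooled = np.concatenate(radii)
    hist, edges = np.histogram(pooled, bins=bins, density=True)
    return {
        "radii": pooled,
        "normalized_radii": pooled / pooled.mean(),
        "histogram": hist,
        "bin_edges": edges,
    }


def diffusion_histogram(
    state: SimState,
    config: SimConfig,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """log10 diffusion coefficient per entity, with multiplicative noise.

    Free particles carry ``D``; a droplet of radius ``R`` carries the
    Stokes-drag value ``D / R``.  Each value is multiplied by
    ``exp(eps)`` with ``eps ~ Normal(0, noise_sd)``, emulating cell-to-
    cell heterogeneity.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    d = np.where(
        state.masses >= 2,
        config.diffusivity / state.radii(config),
        config.diffusivity,
    )
    if noise_sd > 0:
        d = d * np.exp(rng.normal(0.0, noise_sd, size=d.shape))
    return np.log10(d)


# ---------------------------------------------------------------------------
# scaling-law fits on traces


def fit_power_law(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept of log(y) vs log(t)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (t > 0) & (y > 0)
    if ok.sum() < 3:
        raise ValueError("need at least 3 positive (t, y) points for a power-law fit")
    slope, intercept = np.polyfit(np.log(t[ok]), np.log(y[ok]), 1)
    return float(slope), float(intercept)


def growth_exponent(
    trace: SimTrace, cond_min: float = 0.8, cap_frac: float = 0.5
) -> float:
    """Log-log slope of <R>(t) in the droplet-coarsening window.

    The classical BMC scaling <R> ~ t^(1/3) holds once essentially all
    particles are condensed (droplet-droplet coalescence dominates over
    free-particle accretion) and before the finite system saturates
    toward a single droplet.  The fitted window is therefore the
    records with condensed fraction >= ``cond_min`` and
    <R> <= ``cap_frac`` * sqrt(N) * r.
    """
    r_max = math.sqrt(trace.n_particles) * trace.particle_radius
    mask = (
        (trace.condensed_fraction >= cond_min)
        & (trace.mean_radius <= cap_frac * r_max)
        & (trace.times > 0)
    )
    slope, _ = fit_power_law(trace.times[mask], trace.mean_radius[mask])
    return slope


def condensed_growth_exponent(
    trace: SimTrace,
    min_count: int = 10,
    hi_frac: float = 0.5,
    min_plateau: float = 0.05,
) -> float:
    """Early-time log-log slope of the condensed-particle fraction.

    The fitted window is the rise of the curve before its plateau:
    records with at least ``min_count`` condensed particles (below
    that, the fraction is dominated by counting noise) and a condensed
    fraction below ``hi_frac`` of the late-time plateau (mean over the
    last quarter of the records).  A run whose plateau stays below
    ``min_plateau`` never develops a condensation growth phase
    (unbinding dominates); fitting it would measure noise, so it is
    rejected.
    """
    frac = trace.condensed_fraction
    n = len(frac)
    plateau = frac[-max(1, n // 4):].mean()
    if plateau < min_plateau:
        raise ValueError(
            f"condensed fraction plateaus at {plateau:.3g} < {min_plateau}; "
            "no condensation growth phase to fit"
        )
    mask = (
        (trace.times > 0)
        & (frac * trace.n_particles >= min_count)
        & (frac < hi_frac * plateau)
    )
    slope, _ = fit_power_law(trace.times[mask], frac[mask])
    return slope


def steady_state_radius(trace: SimTrace, tail_frac: float = 0.25) -> float:
    """Mean <R> over the last ``tail_frac`` of the recorded steps."""
    n = len(trace.times)
    k = max(1, int(round(tail_frac * n)))
    return float(trace.mean_radius[-k:].mean())


def late_window_slope(trace: SimTrace, tail_frac: float = 0.25) -> float:
    """Log-log slope of <R>(t) over the late window (plateau check)."""
    n = len(trace.times)
    k = max(3, int(round(tail_frac * n)))
    slope, _ = fit_power_law(trace.times[-k:], trace.mean_radius[-k:])
    return slope
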