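"""Unit and property tests for the coalescence-with-unbinding simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from condyn import simulate as sim
from condyn.simulate import SimConfig, SimState

# ---------------------------------------------------------------------------
# brute-force reference implementation (all-pairs, union-find), used as the
# independent oracle for a full simulation step


def _min_image_dist(p, q, box):
    """Minimum-image distance by explicit enumeration of the 9 images."""
    best = np.inf
    for sx in (-box, 0.0, box):
        for sy in (-box, 0.0, box):
            d = math.hypot(p[0] - q[0] + sx, p[1] - q[1] + sy)
            best = min(best, d)
    return best


def _nearest_image(p, ref, box):
    best, best_p = np.inf, p
    for sx in (-box, 0.0, box):
        for sy in (-box, 0.0, box):
            cand = (p[0] + sx, p[1] + sy)
            d = math.hypot(cand[0] - ref[0], cand[1] - ref[1])
            if d < best:
                best, best_p = d, cand
    return np.array(best_p)


def oracle_step(positions, masses, config, rng):
    """One unbind -> move -> coalesce step, explicitly enumerated.

    Follows the simulator's documented RNG draw order so the two
    implementations consume the same random stream.
    """
    box = config.box_length
    r = config.particle_radius
    pos = [np.array(p, dtype=float) for p in positions]
    mass = [int(m) for m in masses]
    flags = [False] * len(mass)

    # unbind
    multi = [i for i, m in enumerate(mass) if m >= 2]
    if config.unbind_prob > 0 and multi:
        leavers = rng.binomial([mass[i] for i in multi], config.unbind_prob)
        removed = []
        for i, k in zip(multi, leavers):
            if k == 0:
                continue
            m_after = mass[i] - int(k)
            r_after = math.sqrt(m_after) * r if m_after > 0 else 0.0
            angles = rng.uniform(0.0, 2.0 * math.pi, size=int(k))
            for th in angles:
                d = r_after + r + 1e-6
                newp = pos[i] + d * np.array([math.cos(th), math.sin(th)])
                pos.append(np.mod(newp, box))
                mass.append(1)
                flags.append(True)
            if m_after == 0:
                removed.append(i)
            else:
                mass[i] = m_after
        for i in sorted(removed, reverse=True):
            del pos[i], mass[i], flags[i]

    # move
    draws = rng.normal(0.0, 1.0, size=(len(pos), 2))
    for i in range(len(pos)):
        d_eff = config.diffusivity / (math.sqrt(mass[i]) * r)
        pos[i] = np.mod(pos[i] + draws[i] * math.sqrt(2 * d_eff * config.dt), box)

    # coalesce: union-find over all eligible pairs
    parent = list(range(len(pos)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            if flags[i] or flags[j]:
                continue
            ri = math.sqrt(mass[i]) * r
            rj = math.sqrt(mass[j]) * r
            if _min_image_dist(pos[i], pos[j], box) < ri + rj:
                parent[find(i)] = find(j)

    groups = {}
    for i in range(len(pos)):
        groups.setdefault(find(i), []).append(i)
    # entity order contract: untouched entities first (original order),
    # then merged components ordered by their smallest member index
    singles = [g for g in groups.values() if len(g) == 1]
    merged = sorted((g for g in groups.values() if len(g) > 1), key=min)
    out_pos, out_mass = [], []
    for members in [*singles, *merged]:
        total = sum(mass[i] for i in members)
        heaviest = max(members, key=lambda i: mass[i])
        ref = pos[heaviest]
        acc = np.zeros(2)
        for i in members:
            acc += mass[i] * (_nearest_image(pos[i], ref, box) - ref)
        out_pos.append(np.mod(ref + acc / total, box))
        out_mass.append(total)
    return out_pos, out_mass


def _canon(positions, masses):
    arr = np.column_stack(
        [np.asarray(masses, float), np.round(np.asarray(positions, float), 9)]
    )
    return arr[np.lexsort(arr.T[::-1])]


@pytest.mark.parametrize("unbind_prob", [0.0, 0.3])
@pytest.mark.parametrize("seed", [1, 2, 3])
def test_step_matches_brute_force_oracle(unbind_prob, seed):
    """A full step on 10 particles matches all-pairs enumeration exactly."""
    config = SimConfig(
        n_particles=10, box_length=8.0, unbind_prob=unbind_prob, rng_seed=seed
    )
    state = sim.init_state(config)
    # pre-grow some droplets so unbinding has something to act on
    rng_a = np.random.default_rng(seed + 100)
    rng_b = np.random.default_rng(seed + 100)
    warm = SimConfig(
        n_particles=10, box_length=8.0, unbind_prob=0.0, rng_seed=seed
    )
    for _ in range(5):
        state = sim.step(state, warm, rng_a)
        oracle_step(state.positions, state.masses, warm, rng_b)  # keep streams aligned
    rng_impl = np.random.default_rng(seed)
    rng_orac = np.random.default_rng(seed)
    ref_pos, ref_mass = state.positions.copy(), state.masses.copy()
    for _ in range(3):
        state = sim.step(state, config, rng_impl)
        ref_pos, ref_mass = oracle_step(ref_pos, ref_mass, config, rng_orac)
        np.testing.assert_allclose(
            _canon(state.positions, state.masses),
            _canon(ref_pos, ref_mass),
            atol=1e-9,
        )


# ---------------------------------------------------------------------------
# configuration and initialization


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_particles=0, box_length=10.0),
        dict(n_particles=5, box_length=1.5),  # < 2r
        dict(n_particles=5, box_length=10.0, unbind_prob=1.5),
        dict(n_particles=5, box_length=10.0, dt=0.0),
        dict(n_particles=5, box_length=float("nan")),
        dict(n_particles=5),  # neither L nor density
        dict(n_particles=5, box_length=10.0, density=0.05),  # both
        dict(n_particles=5, box_length=10.0, diffusivity=-1.0),
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ValueError):
        SimConfig(**kwargs)


def test_density_sets_box_length():
    config = SimConfig(n_particles=500, density=0.01)
    assert config.box_length == pytest.approx(math.sqrt(500 / 0.01))


def test_init_single_particle_and_determinism():
    config = SimConfig(n_particles=1, box_length=10.0, rng_seed=7)
    state = sim.init_state(config)
    assert state.n_entities == 1 and state.masses[0] == 1
    d = state.droplets(config)[0]
    assert d.radius == config.particle_radius
    assert d.drag_diffusivity == config.diffusivity / config.particle_radius

    c100 = SimConfig(n_particles=100, box_length=50.0, rng_seed=3)
    a, b = sim.init_state(c100), sim.init_state(c100)
    np.testing.assert_array_equal(a.positions, b.positions)


def test_init_positions_uniform_chi_square():
    """Initial positions fill the box uniformly (10x10 grid GOF)."""
    config = SimConfig(n_particles=10_000, box_length=1000.0, rng_seed=11)
    state = sim.init_state(config)
    bins = np.linspace(0, 1000.0, 11)
    counts, *_ = np.histogram2d(
        state.positions[:, 0], state.positions[:, 1], bins=[bins, bins]
    )
    p = stats.chisquare(counts.ravel()).pvalue
    assert p > 0.01


# ---------------------------------------------------------------------------
# unbind phase


def _state(positions, masses):
    return SimState(
        np.asarray(positions, float),
        np.asarray(masses),
        np.zeros(len(masses), bool),
    )


def test_unbind_zero_probability_is_identity(rng):
    config = SimConfig(n_particles=9, box_length=20.0, unbind_prob=0.0)
    state = _state([[5, 5], [10, 10]], [4, 5])
    out = sim.unbind_phase(state, config, rng)
    np.testing.assert_array_equal(out.masses, state.masses)
    np.testing.assert_array_equal(out.positions, state.positions)


def test_unbind_certain_escape_dissolves_droplet(rng):
    config = SimConfig(n_particles=5, box_length=20.0, unbind_prob=1.0)
    state = _state([[10, 10]], [5])
    out = sim.unbind_phase(state, config, rng)
    assert out.n_entities == 5
    assert np.all(out.masses == 1)
    assert np.all(out.newly_unbound)
    assert out.total_particles == 5


def test_unbind_mean_leavers_matches_binomial(rng):
    """10^4 droplets of M=10 at P_u=0.2 lose 2 +/- 3 sigma members each."""
    n_drop, m, p_u = 10_000, 10, 0.2
    config = SimConfig(n_particles=n_drop * m, box_length=4000.0, unbind_prob=p_u)
    pos = np.random.default_rng(0).uniform(100, 3900, size=(n_drop, 2))
    state = _state(pos, np.full(n_drop, m))
    out = sim.unbind_phase(state, config, rng)
    n_escaped = int((out.masses == 1).sum())
    mean_leavers = n_escaped / n_drop
    sigma = math.sqrt(m * p_u * (1 - p_u) / n_drop)
    assert abs(mean_leavers - m * p_u) < 3 * sigma
    assert out.total_particles == n_drop * m


def test_unbind_escapers_placed_outside_shrunken_droplet(rng):
    config = SimConfig(n_particles=100, box_length=100.0, unbind_prob=0.05)
    state = _state([[50.0, 50.0]], [100])
    out = sim.unbind_phase(state, config, rng)
    escaped = out.positions[out.newly_unbound]
    remaining = out.masses.max()
    r_after = math.sqrt(remaining)
    dists = np.hypot(*(escaped - [50.0, 50.0]).T)
    assert np.all(dists > r_after + 1.0)


# ---------------------------------------------------------------------------
# move phase


def test_move_frozen_when_diffusivity_zero(rng):
    config = SimConfig(n_particles=4, box_length=20.0, diffusivity=0.0)
    state = _state([[1, 1], [2, 2], [3, 3], [4, 4]], [1, 1, 1, 1])
    out = sim.move_phase(state, config, rng)
    np.testing.assert_array_equal(out.positions, state.positions)


def test_move_variance_free_particles(rng):
    """Per-axis displacement variance of free particles is 2 D dt."""
    n = 40_000
    config = SimConfig(n_particles=n, box_length=1e6, diffusivity=1.0)
    pos = np.full((n, 2), 5e5)
    state = _state(pos, np.ones(n, int))
    out = sim.move_phase(state, config, rng)
    disp = out.positions - pos
    var = disp.var(axis=0)
    tol = 3 * 2.0 * math.sqrt(2.0 / n)  # 3 sigma of the sample variance
    assert abs(var[0] - 2.0) < tol and abs(var[1] - 2.0) < tol


def test_move_variance_stokes_drag(rng):
    """Droplets of M=16 step with variance 2 (D / 4) dt = 0.5 per axis."""
    n = 40_000
    config = SimConfig(n_particles=16 * n, box_length=1e6, diffusivity=1.0)
    pos = np.full((n, 2), 5e5)
    state = _state(pos, np.full(n, 16))
    out = sim.move_phase(state, config, rng)
    var = (out.positions - pos).var(axis=0)
    tol = 3 * 0.5 * math.sqrt(2.0 / n)
    assert abs(var[0] - 0.5) < tol and abs(var[1] - 0.5) < tol


# ---------------------------------------------------------------------------
# coalesce phase


def test_no_merge_beyond_contact_distance():
    config = SimConfig(n_particles=2, box_length=50.0)
    state = _state([[10.0, 10.0], [12.0 + 1e-9, 10.0]], [1, 1])
    out = sim.coalesce_phase(state, config)
    assert out.n_entities == 2


def test_pair_merge_midpoint_and_area_conservation():
    config = SimConfig(n_particles=2, box_length=50.0)
    state = _state([[10.0, 10.0], [11.0, 10.0]], [1, 1])
    out = sim.coalesce_phase(state, config)
    assert out.n_entities == 1
    assert out.masses[0] == 2
    assert out.radii(config)[0] == pytest.approx(math.sqrt(2))
    np.testing.assert_allclose(out.positions[0], [10.5, 10.0])


def test_three_body_merge_connected_component():
    config = SimConfig(n_particles=3, box_length=50.0)
    state = _state([[10, 10], [11.5, 10], [10.75, 11.2]], [1, 1, 1])
    out = sim.coalesce_phase(state, config)
    assert out.n_entities == 1 and out.masses[0] == 3
    # total area 3 pi r^2 conserved via radius = sqrt(3) r
    assert out.radii(config)[0] == pytest.approx(math.sqrt(3))


def test_chain_merge_through_intermediate():
    """A merges with C through B even if A and C are not in contact."""
    config = SimConfig(n_particles=3, box_length=100.0)
    state = _state([[10, 10], [11.8, 10], [13.6, 10]], [1, 1, 1])
    out = sim.coalesce_phase(state, config)
    assert out.n_entities == 1 and out.masses[0] == 3


def test_merge_across_periodic_boundary_uses_minimum_image():
    config = SimConfig(n_particles=2, box_length=50.0)
    state = _state([[0.5, 25.0], [49.5, 25.0]], [1, 1])
    out = sim.coalesce_phase(state, config)
    assert out.n_entities == 1
    # centroid of the two images around the seam is at x = 0
    assert out.positions[0][0] == pytest.approx(0.0, abs=1e-9)


def test_newly_unbound_excluded_then_cleared():
    config = SimConfig(n_particles=2, box_length=50.0)
    state = SimState(
        np.array([[10.0, 10.0], [11.0, 10.0]]),
        np.array([1, 1]),
        np.array([True, False]),
    )
    out = sim.coalesce_phase(state, config)
    assert out.n_entities == 2  # no merge this step
    assert not out.newly_unbound.any()  # flag cleared for the next step


# ---------------------------------------------------------------------------
# whole runs and recorders


def test_single_particle_never_grows():
    config = SimConfig(n_particles=1, box_length=10.0, n_steps=50, unbind_prob=0.3)
    trace = sim.run_simulation(config)
    assert np.all(trace.mean_radius == 1.0)
    assert np.all(trace.condensed_fraction == 0.0)


def test_run_deterministic_under_seed():
    config = SimConfig(n_particles=40, density=0.05, n_steps=200, rng_seed=9,
                       unbind_prob=0.1)
    a = sim.run_simulation(config, record_every=10)
    b = sim.run_simulation(config, record_every=10)
    np.testing.assert_array_equal(a.mean_radius, b.mean_radius)
    np.testing.assert_array_equal(a.condensed_fraction, b.condensed_fraction)


def test_certain_unbinding_prevents_growth():
    """P_u = 1: droplets dissolve every step, no sustained growth."""
    config = SimConfig(
        n_particles=100, density=0.05, unbind_prob=1.0, n_steps=400, rng_seed=2
    )
    trace = sim.run_simulation(config, record_every=4)
    late = trace.mean_radius[len(trace.mean_radius) // 2 :]
    assert late.mean() < 2.0


def test_droplet_count_non_increasing_without_unbinding():
    config = SimConfig(n_particles=60, density=0.05, n_steps=300, rng_seed=4)
    rng = config.rng()
    state = sim.init_state(config)
    counts = [state.n_entities]
    for _ in range(config.n_steps):
        state = sim.step(state, config, rng)
        counts.append(state.n_entities)
    assert np.all(np.diff(counts) <= 0)


@settings(max_examples=20, deadline=None)
@given(
    n=st.integers(2, 30),
    p_u=st.floats(0.0, 1.0),
    seed=st.integers(0, 2**20),
)
def test_particle_count_conserved_through_phases(n, p_u, seed):
    """Sum of droplet masses equals N after every phase of every step."""
    config = SimConfig(
        n_particles=n, box_length=max(3.0, math.sqrt(n / 0.05)),
        unbind_prob=p_u, rng_seed=seed,
    )
    rng = config.rng()
    state = sim.init_state(config)
    for _ in range(10):
        for phase in (sim.unbind_phase, sim.move_phase):
            state = phase(state, config, rng)
            assert state.total_particles == n
        state = sim.coalesce_phase(state, config)
        assert state.total_particles == n
        # radius-mass consistency (area conservation)
        np.testing.assert_allclose(
            state.radii(config), np.sqrt(state.masses), atol=1e-12
        )


def test_mean_radius_selection_and_bounds():
    config = SimConfig(n_particles=5, box_length=30.0)
    state = _state([[5, 5], [15, 15]], [1, 4])
    assert sim.mean_radius(state, config) == pytest.approx(1.5)
    assert sim.mean_radius(state, config, include_singles=False) == pytest.approx(2.0)
    singles = _state([[5, 5], [15, 15]], [1, 1])
    assert sim.mean_radius(singles, config) == 1.0
    with pytest.raises(ValueError):
        sim.mean_radius(singles, config, include_singles=False)
    # <R> = sqrt(N) when one droplet holds everything
    one = _state([[5, 5]], [5])
    assert sim.mean_radius(one, config) == pytest.approx(math.sqrt(5))


def test_condensed_fraction_arithmetic():
    config = SimConfig(n_particles=10, box_length=50.0)
    state = _state([[1, 1], [9, 9], [20, 20], [30, 30], [40, 40], [45, 45]],
                   [4, 2, 1, 1, 1, 1])
    assert sim.condensed_fraction(state, config) == pytest.approx(0.6)
    allfree = _state([[float(i), 1.0] for i in range(1, 11)], [1] * 10)
    assert sim.condensed_fraction(allfree, config) == 0.0
    one = _state([[5, 5]], [10])
    assert sim.condensed_fraction(one, config) == 1.0


def test_radius_distribution_point_mass_and_normalization():
    config = SimConfig(n_particles=8, box_length=50.0, n_steps=0)
    trace = sim.run_simulation(config, snapshot_every=1)
    trace.snapshots = {0: _state([[5, 5], [20, 20]], [4, 4])}
    out = sim.radius_distribution(trace, window=(0, 0))
    assert np.all(out["radii"] == 2.0)
    assert np.all(out["normalized_radii"] == 1.0)
    widths = np.diff(out["bin_edges"])
    assert (out["histogram"] * widths).sum() == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError):
        sim.radius_distribution(trace, window=(5, 10))


def test_diffusion_histogram_values(rng):
    config = SimConfig(n_particles=17, box_length=50.0, diffusivity=1.0)
    state = _state([[5, 5], [20, 20]], [1, 16])
    logd = sim.diffusion_histogram(state, config, noise_sd=0.0, rng=rng)
    assert logd[0] == pytest.approx(0.0)  # free particle at log10 D = 0
    assert logd[1] == pytest.approx(math.log10(0.25))  # D / R with R = 4
    with pytest.raises(ValueError):
        sim.diffusion_histogram(state, config, noise_sd=-1.0, rng=rng)


def test_diffusion_histogram_condensate_mode_shifts_with_unbinding():
    """Higher P_u leaves smaller droplets, so the slow mode sits at larger D."""

    def low_mode(p_u):
        config = SimConfig(
            n_particles=200, density=0.01, unbind_prob=p_u,
            n_steps=3000, rng_seed=5,
        )
        rng = config.rng()
        state = sim.init_state(config)
        for _ in range(config.n_steps):
            state = sim.step(state, config, rng)
        logd = sim.diffusion_histogram(state, config, noise_sd=0.05, rng=rng)
        return logd[state.masses >= 2].mean()

    assert low_mode(0.4) > low_mode(0.05)


def test_reflecting_boundary_keeps_positions_inside():
    config = SimConfig(
        n_particles=50, box_length=10.0, boundary="reflecting",
        n_steps=300, rng_seed=6, diffusivity=2.0,
    )
    rng = config.rng()
    state = sim.init_state(config)
    for _ in range(config.n_steps):
        state = sim.step(state, config, rng)
        assert np.all(state.positions >= 0) and np.all(
            state.positions <= config.box_length
        )
    assert state.total_particles == 50
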