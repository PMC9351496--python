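# Methods

## The coalescence-with-unbinding model

The simulator implements Brownian-motion coalescence (BMC) of `N`
equal circular particles (radius `r`, diffusivity `D`) in a 2D square
box of side `L`, extended with stochastic unbinding. Each time step of
duration `dt` executes three phases in a fixed order:

1. **Unbind.** Every member of every droplet with `M ≥ 2` particles
   escapes independently with probability `P_u` — interior members
   included; for the small droplets of interest the difference between
   volumetric and surface escape is negligible. An escaper becomes a
   free particle placed at a uniformly random angle at distance
   `R_after + r + 1e-6` from the droplet center, where `R_after` is the
   droplet radius after all of that step's departures; it may not
   coalesce until the next step (it is "newly unbound"). A droplet
   reduced to one particle becomes a free particle.
2. **Move.** Every entity takes an independent Gaussian step with
   per-axis variance `2·D_R·dt`, where `D_R = D / R` is the
   Stokes-drag diffusivity of an entity of radius `R` (free particles:
   `R = r`). Positions are wrapped (periodic boundary, the default) or
   reflected.
3. **Coalesce.** Entities whose center distance is below the sum of
   their radii are in contact (for two free particles this reduces to
   the 2r contact rule). Contacts are resolved as connected components
   of the contact graph, so multi-body encounters merge in one
   order-independent pass. The merged droplet has mass `M = Σ M_i`,
   radius `√M·r` (area conservation) and its center at the
   mass-weighted centroid; under periodic boundaries distances and
   centroids use the minimum-image convention, unwrapping members
   relative to the heaviest component member. Newly-unbound flags are
   cleared at the end of the phase.

Contact search uses a periodic k-d tree with cutoff `2·R_max`
followed by an exact per-pair radius check, keeping a step on a few
hundred entities around a millisecond.

Reproducibility contract: a single seeded generator drives a run; per
step the draw order is (i) one binomial vector over the multi-particle
droplets in entity order, (ii) the escape angles per shedding droplet
in entity order, (iii) one `(n, 2)` standard-normal block for the
moves. Runs with equal configurations are bit-identical.

### Box-size conventions and the two dynamical regimes

`SimConfig` accepts either the box side `L` directly or a number
density `ρ` with `L = √(N/ρ)`. Two conventions matter in practice and
both are exposed:

* **Dilute** (`ρ = 1e-4`, equivalently `L = √N/0.01`): the scaling
  regimes are resolved. With `P_u = 0`, the condensed percentage rises
  as `~t^0.75` over more than a decade before saturating, and once
  condensation is essentially complete the mean radius coarsens as
  `<R> ~ t^(1/3)`. This is the convention used by the acceptance
  measurements of both exponents. In this dilute box, unbinding
  probabilities of 0.01 or more dissolve condensates almost entirely
  (the collision flux cannot balance the escape flux), so arrested
  growth at a finite size is not observable there at those `P_u`.
* **Dense** (`ρ = 0.01`): condensation completes within tens of steps
  and a persistent condensate population exists for `P_u` up to 0.2,
  with a steady-state mean radius that decreases monotonically in
  `P_u` — the growth-arrest phenomenology. The early-time rise of the
  condensed percentage is compressed into about a decade and its
  apparent exponent is lower (~0.55).

### Trace statistics and fitting windows

* `<R>(t)` is the arithmetic mean of entity radii, singletons included
  by default (so `<R>(0) = r`); `<R> ≤ √N·r` always, with equality only
  for a single terminal droplet.
* The **coarsening exponent** fits `log <R>` vs `log t` over the window
  where the condensed fraction is ≥ 0.8 (droplet–droplet coalescence
  dominates over free-particle accretion) and `<R> ≤ 0.5·√N·r` (far
  from single-droplet saturation).
* The **condensed-fraction exponent** fits the rise of the condensed
  percentage from the counting-noise floor (≥ 10 condensed particles)
  up to half of its late-time plateau (plateau = mean over the last
  quarter of the records). Traces whose plateau stays below 5%
  condensed have no growth phase and are rejected rather than fitted.
* The steady-state radius is the mean of `<R>` over the last quarter of
  the records; plateau checks use the log–log slope over that window.

## SPT statistics

Trajectories are `(x, y)` in μm at a regular frame interval (default
15 ms); tracks with 10 or fewer detections are conventionally dropped
at I/O time. The tMSD at lag `Δ` averages squared displacements over
all start points; with frame gaps, pairs spanning a gap are skipped in
gap-tolerant mode. `D_2–4` is the slope/4 of an ordinary least-squares
fit of tMSD against lag time at lags 2–4. Ensemble (cumulative) tMSD
pools displacements across tracks, i.e. a pair-count-weighted average.

Turning angles use `atan2(cross, dot)` of consecutive displacement
segments mapped to [0°, 360°); zero-length segments carry no direction
and are skipped. The anisotropy fold change is the count of angles in
180° ± 30° over the count in 0° ± 30°; it is ~1 for isotropic motion
and grows with confinement or anti-persistence.

The two-component displacement fit uses the empirical CDF of `r²` at
each requested lag (no binning — a bin width would be an undocumented
free parameter) fitted by
`P(r²) = 1 − [s·e^(−r²/r_s²) + (1−s)·e^(−r²/r_f²)]`
with `s ∈ [0, 1]` enforced by bounds and `r_s² ≤ r_f²` by relabelling.
Per-lag `r_s²`/`r_f²` are then regressed on lag time (`r² = 4Dt + c`)
to give the slow and fast diffusion coefficients; the reported slow
fraction is the mean of the per-lag `s`. The confined-diffusion model
`r²(t) = a + (L²/3)(1 − e^(−t/τ))` is fitted the same way. Both
nonlinear fits use multi-start (5 seeded initializations, log-scale
parameters for positivity) with best-SSE selection; non-convergence is
flagged on the result rather than raised. As printed in common
references the slow-population and confinement exponentials sometimes
appear with positive signs, which diverge; the implemented forms use
the standard negative exponents.

## Localization maps

Localization tables are `(frame, x, y)` in nm, frames 0-based, windows
half-open (`[k·w, (k+1)·w)`; the experimental cadence is 300 frames =
4.5 s per window, 5-min cumulation for growth curves). Condensates are
DBSCAN clusters (defaults `eps = 48 nm`, `min_pts = 5`); the cluster
area is the convex hull of member localizations — deterministic and
parameter-free — and the radius is the circle-equivalent `√(A/π)`.
Collinear or coincident clusters are flagged degenerate and fall back
to half the maximum pairwise distance. Percent condensed counts
localizations (not distinct molecules). Growth curves fit
`log <R>` vs `log t` by least squares over a user-selected early
window and report the plateau as the mean `<R>` over a late window
(default: last quarter of the time points). Log-normality of a radius
sample is assessed by a maximum-likelihood normal fit on log radii
with the D'Agostino–Pearson test.

## Synthetic data

The generators emulate the trajectory classes used to interpret
nuclear SPT data, at the experimental scales (15 ms frames, ~20 nm
localization noise, diffusivities of 10⁻³–1 μm²/s):

* **Brownian**: cumulative Gaussian steps, per-axis variance `2·D·dt`.
* **FBM**: exact construction — Cholesky factor of the covariance
  `K(s, t) = D(s^α + t^α − |t−s|^α)` per axis, so the 2D ensemble MSD
  is `4·D·t^α` with Hurst `H = α/2`; α < 1 gives the anti-persistent,
  backward-biased motion seen inside condensates. Dense-matrix cost
  limits tracks to 2000 steps, ample for fixture purposes.
* **ATTM-style**: piecewise-Brownian with diffusivities drawn from
  `p(D) ∝ D^(σ−1)` on (0, 1] held for `τ = D^(−γ)` steps; for
  `σ < γ < σ + 1` the ensemble MSD grows as `t^(σ/γ)` while the
  time-averaged MSD stays linear (weak ergodicity breaking), the
  signature used in the tests. Defaults σ = 1, γ = 1.5.
* **Confined**: Brownian steps radially reflected at a disk boundary;
  the long-time tMSD plateau is close to the squared disk radius.
* **Localization maps**: condensate centers uniform with rejection
  (minimum separation twice the median planted radius), log-normal
  per-condensate radii, member points uniform in each disk with
  Gaussian localization noise (default 20 nm), Poisson background,
  frames uniform. Ground-truth labels are returned for
  planted-partition tests.

What the generators do *not* emulate: detection/linking errors,
blinking and gaps, drift, anisotropic localization precision, and
molecule re-identification across frames. Passing tests demonstrate
correct statistics on clean, well-specified motion models, not
robustness to those experimental artefacts.

## Problem sizes and numerical choices

Acceptance measurements use N = 500 particles: dilute-box runs of
1–2·10⁵ steps for the two growth exponents (5 seeds per condition) and
dense-box runs of 1.5·10⁴ steps for the unbinding grid
`P_u ∈ {0.01, 0.05, 0.1, 0.2}` (5 seeds each); parameter-recovery
fixtures use 10²–10³ tracks of 20–200 frames and localization maps of
a few thousand points. Power-law fits are plain least squares in
log–log coordinates. Radius–mass consistency is maintained to
< 10⁻¹² by construction (radii are derived from integer masses).

## Known limitations

* Simulated droplet radii take the discrete values `√M·r`, so at
  strong unbinding (steady states dominated by masses 2–7) a
  continuous goodness-of-fit test against a log-normal rejects even
  though the histogram envelope is log-normal-like; smooth log-normal
  radius distributions emerge only in coarsening regimes with a broad
  mass spectrum.
* No hydrodynamic interactions, Ostwald ripening, or 3D geometry; no
  spatially varying viscosity.
* The CPD fit assumes exactly two populations; more heterogeneous
  mixtures bias `s` toward an effective average.
* DBSCAN condensate calling treats localizations as independent
  points; repeated localizations of slow molecules inflate apparent
  density (an optional per-track thinning is deliberately not applied
  by default, matching standard map construction).
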