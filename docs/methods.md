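# Methods

## The model

`synaptrans` studies a minimal feedback circuit for FMRP-dependent local
translation at an activated glutamatergic synapse.  Three pools evolve in
time (all in arbitrary concentration units, time in minutes):

* `x` — active (membrane-exposed) glutamate receptors,
* `y` — active, dephosphorylated FMRP (the translational regulator),
* `z` — receptors held in the recycling endosome.

The dynamics is a system of delay differential equations

    dx/dt = f_x(y(t − τ_e)) + k_rz · z(t − τ_r) − (k_rx + k_dx) · x
    dy/dt = f_a(x(t − τ_a)) · (y0 − y) − f_b(x(t − τ_b)) · y
    dz/dt = k_rx · x − (k_rz + k_dz) · z

with generalized Hill control functions

    f_δ(u) = k_δ0 + k_δ (u/K_δ)^h_δ / (1 + (u/K_δ)^h_δ),   δ ∈ {x, a, b}.

Receptor signalling activates translation through fast dephosphorylation
of FMRP (`f_a`, delay τ_a ≈ 1 min, h_a = 1 because PP2A acts without
intermediaries) and suppresses it through the multi-step mTOR
phosphorylation cascade (`f_b`, delay τ_b, steep Hill coefficient h_b =
5–20 summarising the cascade's effective cooperativity).  Active FMRP
drives synthesis and membrane incorporation of new receptors with the
translation/assembly delay τ_e (`f_x`).  Membrane receptors are
internalised into the endosome (k_rx), degraded there (k_dz) or returned
to the membrane after the endosomal residence time τ_r with efficiency
k_rz.  `k_rz = 0` removes recycling entirely and decouples z from the
rest of the circuit.

### Parameters and defaults

Defaults are the basic reference set: k_a0=0, k_a=1, K_a=1, h_a=1, y0=1,
k_b0=1, k_b=200, K_b=3, h_b=15, h_x=3, k_x=40, k_dx=0.1, k_rx=0.9,
k_dz=0.8, k_rz=0.2, τ_a=1, τ_b=1, τ_r=10, τ_e=15.  Two constants of the
synthesis term are not part of that set and are package defaults:

* `K_x = 1.0` — the synthesis half-saturation is put on the FMRP
  capacity scale (y0 = 1), so `y/K_x` spans [0, 1];
* `k_x0 = 0.0` — no constitutive, FMRP-independent receptor synthesis,
  consistent with the existence of zero stationary states in several
  reference regimes.

These reproduce every reference quantity checked by the test suite
without further adjustment and are ordinary configurable parameters.

Recycling sweeps use the endosomal-balance convention `k_dz = 1 − k_rz`
(total endosomal exit rate one per minute, split between recycling and
degradation).  It is a scan-mode flag, not a model constraint.
Validation enforces hard invariants (nonnegativity, K > 0, Hill
coefficients ≥ 1, K_a ≤ K_b, delays ≥ 0) and merely warns outside the
physiological variation ranges (h_x 1–3, h_b 5–20, k_x 10–40, k_b
100–200, K_a 1–3, τ_b 1–5, τ_e 3–20, τ_r 3–15), so the tool remains a
general explorer.

## Integration

The Cauchy problem needs an initial *history* on [−τ_max, 0]; the
standard history is the constant triple x=2.5, y=0.5, z=5.  The solver
is a fixed-step classical RK4 advance by the method of steps: lagged
values are read from the stored solution record via local cubic Hermite
interpolation (node values and node derivatives), whose O(h⁴) accuracy
matches the scheme.  The step must not exceed the smallest positive
delay, so a lag never lands inside the step being taken; histories may
also be dense solution segments (`SegmentHistory`), which makes
warm-started continuations exact.

Defaults: h = 0.01 min, t_end = 4000 min.  Delays are O(1–20) and
observed oscillation periods O(10), so h resolves all timescales with
two decades of margin; step-halving tests confirm fourth-order
convergence.  Derivative discontinuities propagating from t = 0 (at
multiples of the delays) are handled by the small fixed step rather than
breakpoint tracking: with constant histories the initial discontinuity
is mild, and all downstream diagnostics are statistical rather than
pointwise.  A trajectory that leaves the nonnegative orthant by more
than 10⁻⁹ aborts with an error naming the violation time; round-off
undershoots smaller than that are clamped to zero.

Zero delays are supported (each zero-delay term reads the current
state), which reduces the system to an ODE — used by the tests to check
the integrator against an independent adaptive solver.

## Regime classification

Long-term dynamics is labelled with the regime-table alphabet: `0`
(zero stationary state), `S` (nonzero stationary), `P`/`mP` (cycle with
m Poincaré clusters / m coexisting cycles in table cells), `QP`
(quasi-periodic), `C` (chaotic).  The default transient discard is the
first half of the run (2000 min at defaults); the reference horizon is
long enough that every labelled regime is reproduced unchanged under
doubling t_end and halving h (checked in the acceptance suite).

1. **Stationary**: post-transient peak-to-peak amplitude of x below
   10⁻⁴.  `0` additionally requires the final state norm below 10⁻⁶
   (and agrees with the origin fixed point of the algebraic reduction).
2. **Poincaré structure**: crossings of the plane x = c (default c = 2,
   increasing direction) are located by sign change between nodes and
   refined by bisection on the dense output; the crossing ordinate is
   the y value.  Ordinates are clustered by a 10⁻² gap rule (cap 64
   clusters).  A trajectory is **periodic** when the cluster count is
   stable across window halves, each cluster is tight (spread ≤ 10⁻²),
   and the cluster revisit order is cyclic (≥ 98% of the label sequence
   obeys an m-periodic pattern, tolerating isolated tangential
   crossings); the multiplicity is the cluster count.
3. **Sensitivity tie-break**: otherwise a twin run is integrated whose
   history differs by 10⁻⁶ in x.  If the twin difference of x reaches
   10% of the oscillation amplitude in the post-transient window the
   dynamics is **chaotic**; an unordered-but-insensitive crossing set is
   **quasi-periodic**.  The 10% threshold implements an
   order-of-magnitude criterion ("difference comparable with the
   fluctuation amplitude"): reaching it requires ~10⁵-fold growth of
   the probe.
4. Anything else (too few crossings, too short a run) is **UNRESOLVED**
   — reported, never guessed or merged.

When an oscillating solution never reaches the configured plane the
classifier falls back to a section through the middle of its x band and
flags the result (`plane_missed`).  The `on_section` flag of an
attractor fingerprint records whether the attractor intersects the
*configured* plane — exactly what a plotted bifurcation diagram at that
plane shows.  The reference recycling sweeps print their thresholds as
features of such diagrams, so the periodic→stationary "transition" of a
sweep is computed here as the loss of section visibility: a
small-amplitude cycle that no longer reaches x = 2 leaves the diagram
blank even though it is still, strictly, a cycle.  Both notions
(amplitude-stationarity and section visibility) are computed and
reported separately.

## Attractor census and multistability

Coexisting attractors are found by integrating from multiple constant
histories: the standard history plus uniform draws from the start box
x ∈ [0,5], y ∈ [0,1], z ∈ [0,10] (seeded RNG).  Each run is classified
and reduced to a fingerprint — cluster centers for cycles, robust
(10%, 50%, 90%) ordinate quantiles for aperiodic motion, the resting
state for stationary runs.  Fingerprints merge when they agree within
0.05 (cycles, Hausdorff distance on centers; stationary states) or 0.1
(aperiodic quantile summaries, which fluctuate more across finite
samples).

Uniform sampling is blind to thin basins.  Two refinements make the
census reliable where it matters:

* **Radial probes.**  Concentric coexisting cycles (the `2P` cells) can
  own a few percent of the start box.  After the first pass each found
  oscillatory attractor is re-launched with its deviation from the orbit
  mean scaled by 0.5 and 3.0; an inward and an outward push off a found
  orbit lands in a concentric basin deterministically, independent of
  the RNG seed.
* **Branch continuation in sweeps.**  A parameter sweep feeds the
  trailing solution segment of every attractor found at the previous
  grid value back in as a warm start.  The delayed state on an attractor
  is a function segment, not a point: continuing from the segment tracks
  a branch whose basin shrinks (the simple-cycle branch of the τ_e sweep
  survives ~0.3 τ_e-units further under segment continuation than under
  point restarts, and its endpoint then matches the reference diagram).

Bifurcation diagrams attach branch identities across adjacent grid
values by nearest-fingerprint geometry (low/mid/high ordinate summary,
tolerance 0.3, gaps up to 2 grid points).  Branch matching deliberately
ignores the category: a cycle that period-doubles into chaos along the
sweep remains one branch.  Transition location brackets a category
change on the grid and can refine it by bisection with fresh censuses at
probe points; the refined value always lies inside its bracket.

## Regime tables

Table cells run a 12-start census per (h_b, k_x, K_a, k_rz) cell under
the k_dz = 1 − k_rz convention and render the census with the table
alphabet (`2P` = two coexisting cycles, `P+C` = cycle and chaotic
attractor coexisting).  The reference tables do not state their k_b;
the shipped table configs use k_b = 100, the value the corresponding
h_x = 2 sweep figures use, which also reproduces the spot-checked cells
(k_b's influence on the regime structure is weak).

## Problem sizes and numerical choices

Reference sweeps: k_rz thresholds on a 0.01 grid (101 single-history
integrations to t = 4000 each), τ_e attractor census on a 0.02 grid
(101 census points, 3 starts plus continuations per point).  The
acceptance script runs exactly these.  Unit tests use shorter horizons
(50–2000 min) wherever the property under test does not require the
full reference horizon.

Known limitations:

* Regime labels near a bifurcation boundary depend on the finite
  horizon; a cycle with decay time ≫ 4000 min is labelled periodic.
  The sweeps report grid-resolution brackets, not continuation-grade
  boundaries.
* The census is a sampling method: an attractor whose basin avoids the
  start box, the standard history, and the radial probes can be missed.
  Probes only explore radially off found orbits.
* The sensitivity criterion is an empirical chaos test, not a Lyapunov
  spectrum; extremely long chaotic transients can masquerade as chaos
  (and vice versa) at any finite horizon.
* No stochastic (Langevin/Gillespie) variant, no spatial structure, and
  no fitting to experimental data: the tool explores the deterministic
  parameter space of the circuit.
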