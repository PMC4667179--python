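# Methods

## The model

`rhorac` simulates the core regulatory circuit of cancer-cell migration
plasticity: the mutually inhibitory Rac1/RhoA GTPase switch (the
mesenchymal-amoeboid decision module) driven by two microRNA signals that
couple it to the EMT machinery. The signal `mu1` represents translational
inhibition of RhoA and `mu2` inhibition of Rac1 (either of miR-34/miR-200
in vivo); both are treated as external boundary inputs, not dynamical
species. Two further inputs, Grb2 and Gab1, stand for the c-Met/HGF
effectors that stimulate GTP loading of Rac1 and RhoA respectively.

Each GTPase X cycles between three pools: the active GTP-loaded form, the
inactive GDP form, and a GDI-sequestered form. The detailed model is six
mass-action rate equations:

```
d[X-GTP]/dt = B_X [X-GDP] − (J_X + k_X) [X-GTP]
d[X-GDP]/dt = g_X P(mu) − B_X [X-GDP] + J_X [X-GTP]
              − on [X-GDP] + off [X-GDI] − k_X [X-GDP]
d[X-GDI]/dt = on [X-GDP] − off [X-GDI] − k_X [X-GDI]
```

with production entering the GDP pool, uniform first-order degradation
`k_X` of every pool, and GDI binding/unbinding rates `on`, `off` that are
fast compared with protein turnover (`on/k ≥ 100`). For RhoA the
production rate is `g⁰ + g·H(ρ)` with a shifted-Hill transcriptional
self-activation `H`; for Rac1 it is a constant `g`.

`B_X` and `J_X` are the total GTP-loading and hydrolysis rates: an
intrinsic rate multiplied by one shifted-Hill factor
`H(x) = λ + (1−λ)/(1+(x/x₀)ⁿ)` per regulator. The defaults encode

* GEF-mediated self-activation of Rac1 loading (λ = 12),
* mutual repression: each active GTPase suppresses the other's loading,
* activation of Rac1 loading by Grb2 and of RhoA loading by Gab1
  (half-activation thresholds 500,000 molecules; a variant file with
  250,000 ships as `lowthresh_params.json`).

MicroRNA silencing multiplies production by `P(mu) = 1/(1+(mu/mu₀)ⁿ)`,
which spans [0, 1] with `P(0) = 1` (no silencing).

**Model reductions.** Setting the GDI pools to equilibrium gives the
4-variable model used by the stochastic simulator, with the GDI pool
tracking `c·[GDP]`, `c = on/(off + k)`. Additionally placing the GDP
pool at quasi-steady state yields the effective two-variable model in
(Rac1-GTP, RhoA-GTP):

```
dX-GTP/dt = g_X P(mu) · B_X/(B_X + J_eff,X) − k_X [X-GTP],
J_eff,X = (J_X + k_X)(1 + c_X)
```

Because the reduction is exact at stationarity, the effective model's
fixed points coincide with those of the 4- and 6-variable models; this is
verified by tests rather than assumed. All bifurcation and stability
analysis runs on the effective model; temporal and stochastic simulations
use the detailed/reduced models.

## Phenotype mapping

Stable states are labelled High/Low per axis, ordered (RhoA, Rac1):
HL is amoeboid (A), LH mesenchymal (M), HH hybrid amoeboid/mesenchymal
(A/M) and LL the hybrid epithelial/mesenchymal (E/M) collective state.
The High/Low thresholds are frozen numbers in the parameter file, set at
calibration time to the geometric mean of the smallest and largest
stable-state coordinate of the standalone (`mu = 0`) circuit
(Rac1 377.66, RhoA 373.37 molecules). States within a 0.1% relative band
of a threshold are flagged ambiguous.

## Default calibration

The algebraic structure fixes the physics but not the numbers; the
shipped defaults (`scripts/calibrate_params.py`, which regenerates
`src/rhorac/data/*.json`) were chosen so the circuit realises the
canonical phase structure of the coupled switch:

* `mu = 0`: exactly three stable states {HL, LH, HH} — the standalone
  three-way switch;
* LL "ignition" saddle-node near `mu ≈ 8`: below it, each GTPase's low
  state self-ignites, so no collective state exists; above it LL is
  stable;
* HH extinction near `mu ≈ 24`: the cross-inhibited high states lose
  stability, removing A/M;
* hence a four-phenotype window `mu ≈ [10, 24]`, tri-stability
  {HL, LL, LH} at `mu = 100` (five fixed points: three stable, two
  saddles), {LL, LH} around `mu ≈ 300–700`, and mono-stable {LL} above
  `mu ≈ 700`.

Each GTPase arm is deliberately poised near these two saddle-node events;
the silencing factor `P` then acts as the bifurcation dial. Rac1's
intrinsic hydrolysis is faster than RhoA's (8/h vs 1/h at equal loading
partition), which under equal additive noise makes the Rac1 axis stiffer:
spontaneous A/M entry from A is rare while RhoA fluctuations drive
frequent A ↔ E/M exchanges — the transition anatomy the circuit is known
for. Concentrations are molecule counts (active pools of order 10¹–10³),
time is in hours with degradation at 1/h.

## Deterministic analysis

Nullclines are computed by a contour method (contourpy) on a vectorised
evaluation of the effective rates over a bounding box derived from the
production/degradation balance, which provably contains every fixed
point (default grid 256², sweeps use 128–160²). Contour intersections
(plus slightly displaced copies, to split near-tangent twin roots) seed a
Newton-type polish to `|RHS| < 1e−8` relative to the production scale;
duplicates merge within a 1e−4 relative tolerance keeping the
smaller-residual root. Stability comes from the eigenvalues of a
central-difference Jacobian. Since the planar fixed-point count is odd
away from bifurcations, an even count triggers one automatic retry on a
2× finer grid.

Sweeps recompute the full fixed-point set per grid point (robust,
embarrassingly parallel) rather than using arclength continuation; folds
are therefore bracketed at grid resolution. Branches are assembled by
globally-sorted nearest-neighbour matching with a 15% relative jump
tolerance. An independent oracle — multi-start RK4 integration from a
grid of initial conditions, endpoint clustering — must agree with the
nullcline route; this dual-route check runs in the test suite over
randomly perturbed parameter sets.

Temporal transitions integrate the detailed model with LSODA under
piecewise-linear signal schedules, starting from the LL attractor of the
initial signal levels. With `mu1` decaying faster than `mu2` the cell
exits E/M to A (the collective-to-amoeboid transition); with `mu2` faster
it completes the EMT to M.

## Stochastic simulation and landscapes

The reduced 4-variable model is integrated by Euler–Maruyama with equal
additive Gaussian white noise `ϒ` on all components (default
240 molecules/√hour) and reflection at zero, in a numba-compiled kernel
whose drift is tested for exact agreement with the reference NumPy
implementation. A start-up check rejects a `dt` for which a 10%
displacement from an attractor would relax by more than 5% of the state
per step. Trajectories are thinned (default every 0.1 h).

The effective landscape is `E = −ln P(x)` from a 2-D histogram over
(RhoA-GTP, Rac1-GTP). Basins are the High/Low quadrants of the phase
plane: this detects the noise-induced E/M basin of the standalone
circuit, which has no deterministic fixed point at `mu = 0` and is
invisible to a nearest-stable-state rule (kept as an option). Each
basin's depth is summarised by the minimum of `E` over its bins; at
`mu = 0` the A/M basin has the highest minimum potential — it is the
least favoured of the four — robustly across seeds. Integrated quadrant
occupancy tells a subtler story: the A/M attractor, however shallow,
retains slightly more total time than the ghost-like E/M corridor
(roughly 0.1% vs 0.07% of a 10⁵-hour run), so "least occupied" is
asserted on the landscape potential, not on integrated time. Transitions
between basins are counted only when the new basin persists for 10
consecutive thinned samples, which suppresses boundary chatter; the most
frequent exchanged pair is A ↔ E/M. Direct M ↔ E/M falls are strongly
suppressed by the stiff Rac1 axis, so E/M traffic is dominated by the
amoeboid side at these defaults.

Default trajectory length is 10⁵ hours (a desk-scale run of a few
seconds; longer runs are a parameter, not a code change), with a 100-hour
burn-in before histogramming.

## Population heterogeneity

Non-genetic variability is modelled by perturbing every continuous rate,
threshold and fold change independently and uniformly within ±5% of its
default and drawing each Hill coefficient from the discrete uniform
[n−1, n+1] floored at 1. The controlled signals and the frozen
classification thresholds are not perturbed — they are the experimental
condition and the phenotype definition respectively. Each cell's stable
states are found deterministically; each state's phenotype receives
weight 1/(number of stable states), so fractions sum to one over included
cells; cells whose analysis fails are excluded and counted. The default
population is 500 cells (analysis-quality runs use the full 5,000 via
`--n-cells`); at high `mu` the E/M fraction dominates.

## What the defaults do and do not show

The calibration is a reconstruction: it reproduces the phase topology,
state counts, transition logic and landscape ordering of the coupled
switch, in molecule-count units of order 10²–10³ for the active pools.
Absolute rates, the exact positions of fold points in `mu`, and
occupancy values are properties of this parameter set, not measurements;
conclusions that depend on them (for example the precise `mu` at which
A/M disappears) should be treated as illustrative. Real GTPase circuits
also have spatial organisation (membrane recruitment, zones of GEF/GAP
activity) that a well-mixed model cannot capture, and the epithelial
phenotype proper is outside the model's state space.

## Numerical choices

* merge tolerance for duplicate roots 1e−4 relative; ambiguity band for
  classification 1e−3 relative; oracle agreement tolerance 0.1%.
* Euler–Maruyama default `dt = 0.01 h`; reflection (not absorption) at
  zero preserves stationarity.
* dwell threshold 10 thinned samples for transition counting.
* sweeps: 200 points (1-D) and 100×100 (2-D) by default, smaller grids
  in tests and the acceptance script to keep runs at desk scale.
* all randomness flows through explicit integer seeds; identical seeds
  give bitwise-identical trajectories, populations and fixtures.
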