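# Methods

## Model overview and assumptions

The spatial model is a discrete-time stochastic lattice (torus, so no edge
effects) in which the only protection available to bacteria is proximity to
spatially fixed phage sinks. EPS is permanent and immobile; debris appears
where cells lyse and decays after a fixed number of steps. Cells are sessile
and reproduce locally; phage move by local diffusion. All rates are per-step
probabilities, so one grid step is the natural time unit and is equated with
one minute when comparing against the delay-ODE model.

Key simplifications: at most one live cell per patch (no vertical biofilm
structure), nutrient-unlimited growth (constant reproduction probability),
no cell motility, no lysogeny, and phage death only via adsorption to
sinks — there is no intrinsic free-phage decay. Superinfection, when
enabled, is a pure phage loss (no lysis inhibition or burst-size change).

## Phase structure and stochastic details

Each step applies lysis, reproduction, infection and diffusion as *global*
phases (each completes across all patches before the next starts). Points
where the discrete dynamics required a concrete choice:

- **Lysis timing.** Ages increment at the start of the lysis phase, and a
  cell bursts when its age reaches `infected_lifespan` — exactly that many
  steps after the infection event. Debris counters decrement before new
  debris is laid down, so a fresh burst on a debris patch refreshes the
  debris clock; debris does not stack (a patch has debris or not).
- **Reproduction collisions.** Reproductive fates are Bernoulli draws for
  the pre-phase set of uninfected cells, but placements execute
  sequentially in random cell order against current occupancy, so two
  daughters can never land on one patch. Orthogonal empty neighbors are
  preferred; diagonals are a fallback; a fully surrounded cell skips its
  chance.
- **Adsorption.** A phage gets one trial per entity type present, in a
  uniformly random type order, stopping at the first success. The escape
  probability is the order-independent product of `(1 - k_x)` over present
  sinks; randomizing the order removes allocation bias among sinks. A cell
  infected mid-phase is immediately a superinfection target (`k_I`) for the
  remaining phage of that patch and step. Phage that fail all trials wait
  for the next step. The per-patch outcome is *sampled exactly* rather than
  simulated phage-by-phage: the number of phage processed before the first
  productive infection is geometric in the first-success probability of the
  uninfected cell, and the remaining phage split multinomially over the
  other sinks — equivalent to the sequential process but O(1) draws per
  patch.
- **Diffusion.** The kernel is the mass of a symmetric bivariate normal
  (scale `sigma`) over the nine unit squares of the Moore neighborhood,
  renormalized; phage loads are redistributed deterministically and made
  integral by unbiased stochastic rounding (floor + Bernoulli on the
  fractional part). Runs are parameterized by the per-step *leave fraction*
  `1 - w_center`, inverted to `sigma` by Brent root-finding at 1e-12
  tolerance. The leave fraction of a 3x3 kernel cannot exceed 8/9 (the
  `sigma -> inf` limit where all nine weights equal 1/9); the constructor
  enforces that domain.
- **Extinction.** Cells are extinct when no live (uninfected or infected)
  cell remains; phage are extinct when free phage are zero *and* no
  infected cell remains (latent bursts count as alive). Runs stop at
  extinction and report the step; extinct trials are excluded from ensemble
  means, with the extinction count reported alongside.

The mass-action grid variant interleaves shuffles where they belong in the
cycle: lysis, then global phage relocation (one multinomial draw over
patches), reproduction, then cell relocation (uniform sample of distinct
patches, ages preserved), then infection; local diffusion is off. Clustered
EPS is rejected in this mode because with global shuffling only the EPS
amount matters.

## Metrics

`alpha*b` is computed per step from the instantaneous global densities and
averaged over the trailing window (default 3,000 steps of a 10,000-step
run); evaluating `alpha` at the window-mean densities instead is exposed as
an option (`alpha_of_means`) and agrees within a few percent on
low-variance runs. Per-burst losses divide total window losses by total
window bursts. As a spread diagnostic for the per-step `alpha*b`
distribution the summary reports the 10th–90th percentile span. When
superinfection or debris is active the closed-form equilibrium density no
longer applies, so `A_g` is suppressed and `alpha*b` is the reported
statistic; the generalized equilibrium density is available only on demand
with caller-supplied `I`, `D` values and is flagged approximate.

## Delay-ODE integration

The delayed system is integrated by the method of steps: segments of
length `L`, each solved with an adaptive RK45 step (`rtol 1e-8`,
`atol 1e-18`, `max_step 5` min) whose dense output supplies the lagged
terms of the next segment; the pre-history is constant `(C0, P0)`.
Defaults `C0 = 1e6`, `P0 = 1e4` /mL: the window averages from t >= 10,000
min are insensitive to this choice for coexistence parameter sets (checked
against `C0 = 1e7, P0 = 1e5`), because trajectories settle onto a fixed
point or a stable limit cycle well before the burn-in ends. Effective
extinction is operationalized as any state crossing 1e-30 (underflow) and
expanding oscillations as crossing 1e30 (blowup); either terminates the
run and suppresses `A_ode`. Halving the tolerances changes window-mean
`A_ode` by under 1% on the tested parameter sets.

## Baseline parameters

Attachment probabilities default to `k_C = 0.25` (uninfected cells) and
`k_E = 0.35` (EPS), with superinfection and debris off unless requested
(`k_I = k_D = 0.25` and a 2-step debris lifespan are the standard settings
when they are on). The cell reproduction probability (0.1/step) and phage
leave fraction (0.3/step) are this package's baseline choices for a
moderate-growth, moderate-diffusion regime; both are routinely swept.
Infected cells burst 20 steps after infection; initial occupancy is 30% of
patches for cells and 30% for phage (one burst of phage per seeded patch),
sampled independently. EPS allotments are exact counts (`round(E*N)`
patches, sampled without replacement) rather than independent Bernoulli
flags, so the `E` entering the metrics is exact and identical across
seeds. Replicate ensembles default to 15 trials cycling through three
initial occupancy pairs {(0.3, 0.3), (0.1, 0.1), (0.5, 0.5)}, with child
seeds spawned from a master seed via `SeedSequence` (stable across
platforms, < 2^31).

## What the tests show (and what they do not)

Unit and property tests check the phases against exact oracles: binomial
and multinomial sampling laws for infection and shuffling, numerical
integration of the bivariate normal for the kernel, conservation
bookkeeping for phage counts, and closed forms for the metrics and ODE
limits. End-to-end grid checks run scaled-down worlds (20x20 patches,
2,000 steps, 5 seeds) chosen to finish quickly: at that scale extinction
is likelier and window averages noisier than on the 100x100 default, so
those tests assert qualitative structure — cell–EPS association near 1,
phage avoidance of EPS, infections shifting into the EPS zone as burst
size grows, and mass-action collapse where spatial runs persist — not
exact table values. Full-scale sweeps are available through
`phagegrid sweep` but are not part of the test suite. The delay-ODE
amplification values are reproduced quantitatively at full scale
(50,000-minute horizons), since each integration takes seconds.

The simulator emulates the study conditions, not any particular empirical
biofilm: real systems add nutrient gradients, multi-cell depth,
three-dimensional interfaces and phenotypic heterogeneity, all outside
this model. Passing tests therefore validate the implementation of the
stated dynamics, not the biological completeness of the model.

## Known limitations

- Pure-Python patch loops make full 100x100 x 10,000-step runs take on the
  order of ten minutes; sweeps at that scale are batch work.
- The 3x3 kernel caps per-step dispersal at a leave fraction of 8/9;
  near-mass-action diffusion regimes should use the shuffled variant
  instead.
- `A_g` is undefined by construction whenever debris or superinfection is
  active; comparisons then rest on `alpha*b` alone.
- The method-of-steps integrator assumes the delay `L` is fixed;
  state-dependent lysis delays would need a different solver design.
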