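# phagegrid

Bacteria growing on surfaces routinely survive lytic bacteriophage attack at
densities far above anything seen in liquid culture, without genetic
resistance. `phagegrid` is a simulation toolkit for asking how much of that
protection can come from *spatial structure alone*: it models bacteria that
escape phage only by living next to spatially fixed phage sinks —
exopolysaccharide (EPS) that irreversibly binds phage, and short-lived debris
from lysed cells — and quantifies the resulting elevation of cell density
relative to well-mixed (mass-action) dynamics.

It is aimed at microbial ecologists and phage-therapy modelers who want a
small, fully reproducible platform for lattice predator–prey experiments with
an exact mass-action reference point.

## The models

**Spatial grid model.** A `width x height` torus of patches; each patch holds
at most one live cell (uninfected or infected), an immutable EPS flag,
transient debris, and any number of free phage. Each time step applies four
global phases:

1. *Lysis* — an infected cell bursts exactly `infected_lifespan` steps after
   infection, releasing `burst_b` phage (and, optionally, debris that sinks
   phage for `debris_lifespan` steps);
2. *Reproduction* — each uninfected cell divides with probability
   `cell_repro_prob` into an empty orthogonal neighbor (diagonal as
   fallback); cells never move;
3. *Infection* — each free phage gets one Bernoulli trial per entity type in
   its patch (probabilities `k_C`, `k_I`, `k_D`, `k_E`), in random order,
   stopping at the first success; adsorption to anything but an uninfected
   cell kills the phage;
4. *Diffusion* — phage redistribute over the 3x3 neighborhood with weights
   from a truncated bivariate normal kernel (`A = 2F(0.5/sigma) - 1`,
   `B = F(1.5/sigma) - F(0.5/sigma)`; center `A^2`, orthogonal `AB`, diagonal
   `B^2`, normalized by `A^2 + 4AB + 4B^2`), then stochastic rounding makes
   the counts integral without bias.

**Mass-action grid model.** The identical machinery, but all phage are
reassigned to uniform random patches after lysis and all cells to distinct
random patches after reproduction — same finite population, no spatial
structure.

**Delay-ODE mass-action model.**

```
dC/dt = r C (1 - C/K) - kappa C P
dP/dt = b kappa C_L P_L - kappa C P - delta P
```

with lagged values `C_L, P_L` taken `L` minutes in the past, integrated by
the method of steps.

**The amplification metrics.** At mass-action equilibrium every infection
replaces itself: `alpha * b = 1`, where
`alpha = k_C C / (k_C C + k_I I + k_D D + k_E E)` is the productive fraction
of all phage loss routes. With `k_I = k_D = 0` the equilibrium cell density
is `C_hat = k_E E / (k_C (b-1))`, and

- `A_g = C_obs / C_hat` — fold elevation of cell density over mass action
  (bounded by `A_ub,g = 1 / C_hat`);
- `A_ode = <C> / C_bar` with `C_bar = delta / (kappa (b-1))` — the analogous
  statistic for the delay ODE (bounded by `K / C_bar`).

Runs also report the self-organization diagnostics `C:E`, `P:E`, `I:E` (the
fractions of uninfected cells, free phage and infection events located on
EPS patches) and the per-burst losses `P->C, P->I, P->E, P->D`.

## Worked example

```python
from phagegrid import SimParams, run_spatial

params = SimParams(width=30, height=30, burst_b=10, eps_fraction_E=0.3,
                   eps_layout="clustered_rows", k_C=0.25, k_E=0.35,
                   cell_repro_prob=0.1, diffuse_fraction=0.3,
                   n_steps=3000, avg_window=1000, seed=7)
s = run_spatial(params)
print(s.alpha_b, s.A_g, s.C_on_E, s.P_on_E)
```

This run (see `examples/self_organization.py`) prints

```
alpha*b = 2.23   A_g = 2.61 (bound 21.4)
C:E = 0.978   P:E = 0.064   I:E = 0.849
per-burst losses: {'P_to_C': 1.0, 'P_to_I': 0.0, 'P_to_E': 8.96, 'P_to_D': 0.0}
```

Cells sit almost exclusively on the EPS band (`C:E = 0.98`) while free phage
avoid it (`P:E = 0.06`); the cell density is 2.6-fold what mass action would
sustain, and of each 10-phage burst about 9 die on EPS while exactly 1
(on average) starts the next infection. The other scripts in `examples/`
demonstrate the kernel math, the spatial-versus-shuffled contrast, and the
delay-ODE amplification.

A thin CLI mirrors the library:

```sh
phagegrid simulate --grid 30 30 --burst 10 --eps 0.3 --layout clustered_rows \
    --steps 3000 --window 1000 --seed 7 --out series.tsv
phagegrid sweep --bursts 2,6,10 --eps 0.3,0.9 --trials 6 --seed 1
phagegrid ode --preset table5
```

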