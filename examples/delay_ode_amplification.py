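"""Amplification under well-mixed (delay-ODE) dynamics.

Integrates the delayed predator-prey system for two parameter sets: a
non-oscillatory one (A_ode = 1: the average sits at equilibrium) and an
oscillatory one (A_ode > 1: sustained cycles lift the *average* cell
density above equilibrium because C can exceed C_bar by much more than it
can fall below it).
"""

from phagegrid import OdeParams, a_ode, c_bar, integrate_dde

for label, p in (
    ("non-oscillatory", OdeParams(b=20, delta=0.3, kappa=3e-11, L=20, r=0.03)),
    ("oscillatory", OdeParams(b=10, delta=0.1, kappa=1e-10, L=20, r=0.03)),
):
    traj = integrate_dde(p, C0=1e6, P0=1e4)
    res = a_ode(traj, p)
    print(f"{label:16s} C_bar = {c_bar(p):.3e} /mL   "
          f"A_ode = {res['A_ode']:.2f} (windows "
          f"{[round(w, 2) for w in res['windows']]}, bound {res['A_ub_ode']:.1f})")
# A_ode is the time-average of C(t)/C_bar over four consecutive
# 10,000-minute windows after a 10,000-minute burn-in. Elevation here
# comes purely from oscillation asymmetry, unlike the spatial model where
# it is intrinsic and steady.
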