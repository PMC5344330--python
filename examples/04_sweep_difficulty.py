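"""Re-optimize across environmental difficulty: when are big brains favored?

Each row re-runs the full optimization with a different difficulty alpha
under exponential competence.  Adult brain mass rises with difficulty —
harder challenges demand more skill, hence more brain to power it — and
then collapses when the environment is so hard that growing at all stops
paying and the optimum is to reproduce early at small size.
"""

from brainlife import SolverOptions, benchmark_parameters, sweep

p = benchmark_parameters("exponential")
opts = SolverOptions(n_intervals=25, n_multistart=2, max_iter=250, seed=0)

table = sweep(p, "alpha", [0.5, 1.0, 2.0, 4.0, 8.0], opts)
cols = ["alpha", "adult_body_mass", "adult_brain_mass", "EQ", "R0"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:8.3f}"))
# The interior peak in adult_brain_mass is the model's central qualitative
# prediction: brains are favored by intermediately challenging environments.
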