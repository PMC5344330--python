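"""Render the full report bundle for an optimized life history.

Writes a predicted-vs-observed summary table (supplying a small synthetic
"observed" series for illustration), the trajectory CSV, and three figures:
stage-shaded tissue masses, growth metabolic rate and skill against age,
and the median-filtered allocation schedule.
"""

from pathlib import Path

from brainlife import SolverOptions, benchmark_parameters, optimize
from brainlife.report import ObservedSeries, report

p = benchmark_parameters("power")
control, traj, summary = optimize(
    p, SolverOptions(n_intervals=25, n_multistart=2, max_iter=250, seed=0))

# synthetic stand-in for a user-supplied observed series (age, body, brain in kg)
observed = ObservedSeries(
    age=[0.0, 1.0, 5.0, 10.0, 15.0, 20.0, 30.0],
    body_mass=[3.4, 9.0, 18.0, 31.0, 48.0, 51.0, 51.1],
    brain_mass=[0.35, 0.95, 1.24, 1.30, 1.31, 1.31, 1.31],
    source="synthetic illustration",
)

out = Path("scratch/example_report")
paths = report(summary, traj, observed, out_dir=out)
print("report written:")
for name, path in paths.items():
    print(f"  {name:14s} {path}")
print()
print((out / "summary_table.txt").read_text())
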