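"""Estimate L5S1 joint reaction forces under the three hand-load models.

Runs the full inverse pipeline (inverse kinematics, inverse dynamics with
ground-pelvis residuals, static optimization, joint reaction analysis) for
each approach and prints the per-phase reaction peaks and the 5% residual
-force compliance checks.
"""
from liftsim import BoxSpec, TaskConfig, synthesize_trial
from liftsim.study import approach_comparison_rows

anthro = {"body_mass": 75.16, "stature": 1.74}
task = TaskConfig(n_repetitions=1, grip_ramp_duration=0.3)
trial = synthesize_trial(task, BoxSpec(), anthro, seed=1)

rows = approach_comparison_rows(trial)
print(f"{'approach':8s} {'phase':9s} {'init peak':>16s} {'final peak':>16s} "
      f"{'resid peak':>11s} {'5% checks':>10s}")
for r in rows:
    checks = ("pass" if r["residual_peak_pass"] else "FAIL") + "/" + \
             ("pass" if r["residual_rms_pass"] else "FAIL")
    print(f"{r['approach']:8s} {r['phase_kind']:9s} "
          f"{r['peak_initial_N']:8.0f} N @{r['peak_initial_time_pct']:3.0f}% "
          f"{r['peak_final_N']:8.0f} N @{r['peak_final_time_pct']:3.0f}% "
          f"{r['residual_peak_N']:9.1f} N {checks:>10s}")
print("\nAt the table-side boundary (final lifting / initial lowering peak) the")
print("simplified approaches overestimate the reaction: their model carries the")
print("full box weight while the real load is still ramping on or off the hands.")
print("The same mismatch drives their vertical residual force far beyond the 5%")
print("recommendation, while the measured-load analysis stays dynamically")
print("consistent over the whole cycle.")
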