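"""Boundary-error growth with grip-ramp duration, with repeated-measures
statistics across approaches.

Longer load-transfer ramps leave more samples inside the handling phase in
which the hands carry only part of the box weight, so the boundary-quartile
hand-force error grows monotonically with ramp duration.  A one-way
repeated-measures ANOVA (Greenhouse-Geisser corrected, Bonferroni post hoc)
then compares final lifting-peak reactions across the three approaches.
"""
import numpy as np

from liftsim import BoxSpec, TaskConfig, synthesize_trial
from liftsim.metrics import rm_anova_bonferroni
from liftsim.study import approach_comparison_rows, ehf_error_rows

anthro = {"body_mass": 75.16, "stature": 1.74}
box = BoxSpec()

print("grip-ramp sweep: boundary (Q1+Q4) hand-force RMSE, mean over 3 seeds")
for ramp in (0.1, 0.3, 0.5):
    vals = []
    for seed in (1, 2, 3):
        task = TaskConfig(n_repetitions=1, grip_ramp_duration=ramp,
                          marker_noise_sd=0.0003)
        trial = synthesize_trial(task, box, anthro, seed=seed)
        vals.extend(r["Q1"] + r["Q4"] for r in ehf_error_rows(trial))
    print(f"  ramp {ramp:.1f} s -> {np.mean(vals):6.1f} N")

print("\nrepeated-measures ANOVA on final lifting-peak L5S1 reactions")
task = TaskConfig(n_repetitions=3, grip_ramp_duration=0.3, marker_noise_sd=3e-4)
trial = synthesize_trial(task, box, anthro, seed=5)
rows = approach_comparison_rows(trial)
peaks = {app: [r["peak_final_N"] for r in rows
               if r["approach"] == app and r["phase_kind"] == "lifting"]
         for app in ("APP1", "APP2", "APP3")}
Y = np.stack([peaks[a] for a in ("APP1", "APP2", "APP3")], axis=1)
res = rm_anova_bonferroni(Y)
print(f"  F({res['df1_gg']:.2f}, {res['df2_gg']:.2f}) = {res['F']:.1f}, "
      f"p = {res['p_gg']:.4f} (Greenhouse-Geisser)")
for pair, p in res["posthoc"].items():
    print(f"  {pair}: p_bonf = {p['p_bonf']:.4f}")
print("A significant effect with APP1 differing from both simplified models")
print("mirrors the overestimation of boundary-adjacent reaction peaks.")
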