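"""Full retrieval on a simulated benchmark: calibrated estimate vs the
raw conductance index.

A target AL with fixed pore conductance 0.31 mol m-2 s-1 is imaged next
to the five references while the fan steps through three speeds. The
calibrated (DynG) estimate should stay at 0.31 regardless of wind; the
raw index, read directly as a conductance, drifts with the microclimate.
"""

import numpy as np

from dyng import (
    PipelineOptions,
    estimate_pipeline,
    scenario_environment,
    simulate_reference_set,
    standard_reference_set,
    standard_target_al,
)
from dyng.scenarios import wind_step_scenario

samples = standard_reference_set() + [standard_target_al(0.31)]
steps = wind_step_scenario(duration=120.0, noise_sd=0.03)
series = simulate_reference_set(samples, steps, sampling_dt=2.0, seed=1)
env = scenario_environment(steps, 2.0)

result = estimate_pipeline(
    series, env, samples,
    PipelineOptions(methods=("dyng", "ig_only"), target_ids=("target",)))

print("per-wind-step mean estimate of the target's conductance "
      "(truth 0.31 mol m-2 s-1):")
print(f"{'wind':>6s} {'DynG':>8s} {'I_g only':>9s} {'g_bw':>7s} {'slope':>7s}")
for i, step in enumerate(steps):
    lo, hi = 120.0 * i + 40.0, 120.0 * (i + 1)
    seg = result[(result.time_s > lo) & (result.time_s <= hi)]
    cal = seg[seg.method == "dyng"]
    raw = seg[seg.method == "ig_only"]
    print(f"{step.wind:>6.1f} {cal.g_sw.mean():>8.3f} {raw.g_sw.mean():>9.3f} "
          f"{cal.g_bw.mean():>7.3f} {cal.DynG.mean():>7.3f}")
print("\nThe calibration slope falls as wind rises, absorbing the")
print("microclimate change; the raw index conflates it with conductance.")
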