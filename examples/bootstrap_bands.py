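"""Bootstrap confidence bands for the total intervention hazard ratio.

The total effect exp{gamma1 + alpha (beta2 + beta3 t)} is time-varying; its
uncertainty comes from a cluster bootstrap that resamples whole subjects and
refits the joint model per replicate.
"""

import numpy as np

import jointtrial as jt

ds = jt.simulate_trial(jt.default_config(n_subjects=150, seed=3))
spec = jt.JointSpec("value", quadrature_points=7, n_baseline_intervals=3)
grid = np.linspace(0.0, 2.0, 9)
curve = jt.bootstrap_bands(ds, spec, time_grid=grid, n_boot=200, seed=1)
curve.cox_reference = jt.cox_reference_effect(ds, include_bmmse=True)

print("  t     total HR   95% percentile band")
for t, hr, lo, hi in zip(grid, curve.total, curve.lower, curve.upper):
    print(f"{t:5.2f}   {hr:7.2f}    [{lo:5.2f}, {hi:5.2f}]")
print(f"\n{curve.n_failed}/{curve.n_boot} bootstrap refits failed; "
      f"time-fixed PH reference HR = {curve.cox_reference:.2f}")
print("A band excluding 1 at late times indicates a growing, "
      "trajectory-mediated benefit of the intervention.")
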